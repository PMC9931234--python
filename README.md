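# illdyn

Illness-dynamics phenotyping of intensive-care admissions from continuous
severity-risk scores. Each admission's score trajectory is discretized
into four illness states, summarized by Markov transition matrices, and
scored by the Shannon entropy (natural log) of its joint transition
density. Entropy drives hierarchical Ward phenotyping and is related to a
rank-based composite of negative outcomes (mortality, ventilator days,
hospital stay) with loess, OLS and restricted-cubic-spline-adjusted
regression. A seeded synthetic-cohort generator with known per-admission
chains supplies ground truth for every stage.

## Layout

| Module | Purpose |
| --- | --- |
| `illdyn.synthetic` | Markov chain construction, stationary laws, true joint-transition entropy, score-series simulation with gap injection, outcome simulation, cohort file generation |
| `illdyn.prep` | 30-minute resampling, adjacency filtering, fixed/equiprobable binning into illness states |
| `illdyn.entropy` | transition counts, row-stochastic transition matrices, joint transition density ("entropy matrix"), Shannon entropy, per-admission summaries |
| `illdyn.composite` | min-tie ranking and the three-component negative-outcome composite |
| `illdyn.cluster` | Ward dendrograms, exact-k cuts, entropy-ordered phenotype labels, chi-squared / ANOVA / Kruskal–Wallis group comparisons with Tukey post hoc |
| `illdyn.regression` | tricube loess smoother, univariate OLS, 3-knot restricted cubic spline basis and adjusted fits |
| `illdyn.pipeline` / `illdyn.cli` | end-to-end orchestration, cohort summaries, provenance-stamped artifacts, `illdyn` console command |

## CLI

Run the whole pipeline on a freshly simulated cohort:

```bash
illdyn all --seed 7 --outdir out/ --n-admissions 164 --binning both
```

`--binning both` adds an equiprobable-bin entropy column and reports the
correlation between the two schemes (sensitivity analysis). Individual
stages are available as subcommands (`simulate`, `prep`, `entropy`,
`composite`, `cluster`, `associate`, `report`); see `illdyn --help`.
Options can also be given via a YAML file matching the
`PipelineConfig` field names (`--config config.yaml`).

Outputs are CSV/JSON with a `# seed=... / # config_hash=...` provenance
header; the same seed yields byte-identical artifacts.

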