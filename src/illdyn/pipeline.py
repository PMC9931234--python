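"""End-to-end orchestration: simulate -> prep -> entropy -> composite -> cluster -> associate.

Every stage writes a CSV/JSON artifact with a provenance header (seed and
config hash) so runs are byte-reproducible and stages can be re-run in
isolation.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import composite as _composite
from . import entropy as _entropy
from . import prep as _prep
from . import regression as _regression
from . import synthetic as _synthetic

log = logging.getLogger("illdyn")


@dataclass
class PipelineConfig:
    outdir: str = "illdyn_out"
    seed: int = 0
    n_admissions: int = 164
    binning: str = "fixed"              # fixed | equiprobable | both
    ks: tuple[int, ...] = (2, 4)
    min_pairs: int = 2
    gap_rate: float = 0.003
    mortality_link: tuple[float, float] = (-2.3, 0.55)
    outcome_link: float = 0.6
    stay_distribution: tuple[float, float] = (3.0, 0.9)
    adjacency_tol: int = 0
    ward_dialect: str = "ward"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for name in ("ks", "mortality_link", "stay_distribution"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def hash(self) -> str:
        # outdir is excluded: the same analysis in a different directory
        # must hash identically
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class CohortSummary:
    n_admissions: int
    mortality_pct: float | None
    male_pct: float | None
    sepsis_incidence_pct: float | None
    variables: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def cohort_summary(outcomes: pd.DataFrame, n_screened: int | None = None) -> CohortSummary:
    """Descriptive cohort table: counts, percentages and distributional summaries.

    Percentages are rounded to one decimal. ``n_screened``, when given, is
    the total number of screened admissions used for the incidence
    percentage (cohort size / screened total).
    """
    n = len(outcomes)
    mortality = (
        round(100.0 * outcomes["died"].sum() / n, 1) if "died" in outcomes and n else None
    )
    male = (
        round(100.0 * (outcomes["sex"] == "M").mean(), 1)
        if "sex" in outcomes and n
        else None
    )
    incidence = round(100.0 * n / n_screened, 1) if n_screened else None
    variables = {}
    for col in ("age_years", "vent_days", "hospital_los_days", "icu_los_days"):
        if col not in outcomes or outcomes[col].dropna().empty:
            variables[col] = None
            continue
        v = outcomes[col].dropna()
        variables[col] = {
            "mean": round(float(v.mean()), 1),
            "sd": round(float(v.std(ddof=1)), 1) if len(v) > 1 else 0.0,
            "median": round(float(v.median()), 1),
            "q1": round(float(v.quantile(0.25)), 1),
            "q3": round(float(v.quantile(0.75)), 1),
            "min": round(float(v.min()), 1),
            "max": round(float(v.max()), 1),
        }
    return CohortSummary(n, mortality, male, incidence, variables)


def load_scores(path: str | Path) -> dict[str, _prep.RiskScoreSeries]:
    df = pd.read_csv(path, comment="#")
    out = {}
    for adm, grp in df.groupby("admission_id", sort=True):
        grp = grp.sort_values("t_minutes")
        out[str(adm)] = _prep.RiskScoreSeries(
            str(adm), grp["t_minutes"].to_numpy(), grp["score"].to_numpy()
        )
    return out


def _write_csv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    buf = io.StringIO()
    for key, val in meta.items():
        buf.write(f"# {key}={val}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def prep_stage(
    series_map: dict[str, _prep.RiskScoreSeries],
    binning: str = "fixed",
    tol: int = 0,
):
    """Prep all admissions under one binning scheme; returns series, states, report."""
    # adjacency-filtered continuous series first (equiprobable edges pool
    # analysis-ready observations)
    filtered = {}
    reports = []
    for adm, series in series_map.items():
        resampled = _prep.resample_30min(series)
        flt, n_removed = _prep.remove_nonadjacent(resampled, tol=tol)
        filtered[adm] = flt
        reports.append(
            {
                "admission_id": adm,
                "n_raw": len(series),
                "n_after_resample": len(resampled),
                "n_removed_nonadjacent": n_removed,
                "n_final": len(flt),
            }
        )
    if binning == "equiprobable":
        pooled = np.concatenate([s.scores for s in filtered.values()])
        scheme = _prep.equiprobable_edges(pooled, k=4)
    else:
        scheme = _prep.BinningScheme()
    states = {
        adm: _prep.bin_scores(s, scheme, tol=tol) for adm, s in filtered.items()
    }
    return filtered, states, pd.DataFrame(reports), scheme


def entropy_stage(filtered, states, min_pairs: int = 2) -> pd.DataFrame:
    records = [
        _entropy.admission_summary(filtered[adm], states[adm], min_pairs=min_pairs)
        for adm in sorted(states)
    ]
    return pd.DataFrame(records)


def run_pipeline(config: PipelineConfig, scores_path: str | Path | None = None) -> dict:
    """Run the full pipeline; returns paths of all written artifacts.

    Without ``scores_path`` a synthetic cohort is generated first. With
    ``binning='both'`` entropies are computed under the fixed and the
    equiprobable schemes and their correlation is reported (sensitivity
    analysis).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.hash()}
    artifacts: dict[str, Path] = {}

    stage = "simulate"
    try:
        if scores_path is None:
            cohort_cfg = _synthetic.CohortConfig(
                n_admissions=config.n_admissions,
                mortality_link=config.mortality_link,
                outcome_link=config.outcome_link,
                stay_distribution=config.stay_distribution,
                gap_rate=config.gap_rate,
                seed=config.seed,
            )
            paths = _synthetic.generate_cohort(cohort_cfg, outdir)
            artifacts.update(paths)
            scores_path = paths["scores"]
            outcomes = pd.read_csv(paths["outcomes"], comment="#")
        else:
            stage = "prep"
            outcomes = pd.read_csv(
                Path(scores_path).parent / "outcomes.csv", comment="#"
            )

        stage = "prep"
        series_map = load_scores(scores_path)
        schemes = (
            ["fixed", "equiprobable"] if config.binning == "both" else [config.binning]
        )
        summaries = {}
        for kind in schemes:
            filtered, states, report, scheme = prep_stage(
                series_map, binning=kind, tol=config.adjacency_tol
            )
            if kind == schemes[0]:
                _write_csv(report, outdir / "prep_report.csv", meta)
                artifacts["prep_report"] = outdir / "prep_report.csv"
                log.info(
                    "prep: removed %d nonadjacent observations",
                    report["n_removed_nonadjacent"].sum(),
                )
            stage = "entropy"
            summaries[kind] = entropy_stage(filtered, states, config.min_pairs)

        primary = schemes[0]
        summary = summaries[primary]
        if len(schemes) == 2:
            summary = summary.merge(
                summaries["equiprobable"][["admission_id", "entropy_nats"]].rename(
                    columns={"entropy_nats": "entropy_nats_equiprobable"}
                ),
                on="admission_id",
            )
            both = summary[["entropy_nats", "entropy_nats_equiprobable"]].dropna()
            meta["entropy_scheme_correlation"] = round(
                float(both.corr().iloc[0, 1]), 4
            )
        _write_csv(summary, outdir / "entropy_summary.csv", meta)
        artifacts["entropy_summary"] = outdir / "entropy_summary.csv"

        stage = "composite"
        comp = _composite.composite_score(outcomes)
        _write_csv(comp, outdir / "composite.csv", meta)
        artifacts["composite"] = outdir / "composite.csv"

        stage = "cluster"
        usable = summary[~summary["excluded"]].reset_index(drop=True)
        n_excluded = len(summary) - len(usable)
        if n_excluded:
            log.info("cluster: excluded %d admissions below min-pairs", n_excluded)
        assignment = _cluster.assign_phenotypes(
            usable["entropy_nats"].to_numpy(), ks=config.ks, dialect=config.ward_dialect
        )
        labels = assignment.to_frame(usable["admission_id"])
        _write_csv(labels, outdir / "phenotypes.csv", meta)
        artifacts["phenotypes"] = outdir / "phenotypes.csv"
        dendro = {
            "merges": assignment.linkage_matrix[:, :2].astype(int).tolist(),
            "heights": assignment.linkage_matrix[:, 2].tolist(),
            **{k: str(v) for k, v in meta.items()},
        }
        (outdir / "dendrogram.json").write_text(json.dumps(dendro, indent=1))
        artifacts["dendrogram"] = outdir / "dendrogram.json"

        merged = (
            usable.merge(outcomes, on="admission_id")
            .merge(comp, on="admission_id")
            .merge(labels, on="admission_id")
        )
        for kcol in ("phenotype_k2", "phenotype_k4"):
            tab = _cluster.compare_groups(
                merged,
                merged[kcol].to_numpy(),
                continuous=["age_years", "vent_days", "hospital_los_days",
                            "mean_score", "entropy_nats", "composite"],
                categorical=["sex", "died"],
            )
            _write_csv(tab.table, outdir / f"comparison_{kcol}.csv",
                       {**meta, "adjusted_alpha": tab.adjusted_alpha})
            artifacts[f"comparison_{kcol}"] = outdir / f"comparison_{kcol}.csv"

        stage = "associate"
        uni = _regression.fit_univariate(merged["composite"], merged["entropy_nats"])
        adj = _regression.fit_adjusted(
            merged["composite"], merged["entropy_nats"], merged["mean_score"]
        )
        models = {
            "univariate": uni.to_dict(),
            "adjusted": adj.to_dict(),
            **{k: str(v) for k, v in meta.items()},
        }
        (outdir / "association.json").write_text(json.dumps(models, indent=1))
        artifacts["association"] = outdir / "association.json"
        if len(merged) >= 10:
            curve = _regression.loess_curve(
                merged["entropy_nats"].to_numpy(), merged["composite"].to_numpy()
            )
            _write_csv(
                pd.DataFrame({"x": curve.x, "fitted": curve.fitted}),
                outdir / "loess_curve.csv",
                meta,
            )
            artifacts["loess_curve"] = outdir / "loess_curve.csv"
        else:
            log.info("associate: fewer than 10 admissions, loess skipped")

        stage = "report"
        summary_obj = cohort_summary(outcomes)
        (outdir / "cohort_summary.json").write_text(
            json.dumps({**summary_obj.to_dict(), **{k: str(v) for k, v in meta.items()}},
                       indent=1)
        )
        artifacts["cohort_summary"] = outdir / "cohort_summary.json"
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return artifacts
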