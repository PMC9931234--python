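"""Seeded synthetic cohorts with known Markov ground truth.

Each admission is driven by a time-homogeneous Markov chain over k
illness states. The chain emits continuous scores on a 15-minute grid
(two samples per 30-minute state, drawn uniformly from the state's score
bin), so the prep stage — 30-minute resampling, adjacency filtering,
binning — can be exercised and inverted exactly when no gaps are
injected.

Chain heterogeneity across admissions (varying diagonal "stickiness" and
varying concentration of the attracting distribution) produces a joint
transition-entropy spectrum spanning roughly 0.5–2.0 nats, and outcomes
(mortality, ventilator days, length of stay) are generated with a
configurable monotone link to each chain's true entropy.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.special import expit, xlogy

from .prep import SCORE_MAX


class ChainError(ValueError):
    """Raised for invalid chain parameters or chains lacking a stationary law."""


@dataclass(frozen=True)
class ChainSpec:
    """Parameters of one admission's transition kernel.

    ``spread`` controls where the off-diagonal mass (1 - stickiness) goes:

    * ``uniform`` — equally over the other states (diagonal = stickiness);
    * ``decay``   — proportional to exp(-|i - j|);
    * ``attract`` — toward a common target distribution ``target``
      (P = s*I + (1-s)*1 target'), whose stationary law is ``target``
      itself; concentrated targets yield low-entropy chains.
    """

    n_states: int = 4
    stickiness: float = 0.8
    spread: str = "uniform"
    target: tuple[float, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ChainError("n_states must be >= 2")
        if not (0.0 <= self.stickiness <= 1.0):
            raise ChainError(f"stickiness {self.stickiness} outside [0, 1]")
        if self.spread not in ("uniform", "decay", "attract"):
            raise ChainError(f"unknown spread {self.spread!r}")
        if self.target is not None:
            t = np.asarray(self.target, float)
            if t.size != self.n_states or np.any(t < 0) or abs(t.sum() - 1) > 1e-9:
                raise ChainError("target must be a length-n probability vector")


def make_chain(spec: ChainSpec) -> np.ndarray:
    """Build the row-stochastic matrix implied by a :class:`ChainSpec`."""
    n, s = spec.n_states, spec.stickiness
    if spec.spread == "uniform":
        off = (1.0 - s) / (n - 1)
        P = np.full((n, n), off)
        np.fill_diagonal(P, s)
    elif spec.spread == "decay":
        idx = np.arange(n)
        w = np.exp(-np.abs(idx[:, None] - idx[None, :]).astype(float))
        np.fill_diagonal(w, 0.0)
        w /= w.sum(axis=1, keepdims=True)
        P = (1.0 - s) * w
        np.fill_diagonal(P, s)
    else:  # attract
        if spec.target is not None:
            target = np.asarray(spec.target, float)
        else:
            rng = np.random.default_rng(spec.seed)
            target = rng.dirichlet(np.ones(n))
        P = s * np.eye(n) + (1.0 - s) * np.tile(target, (n, 1))
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
    return P


def _validate_stochastic(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ChainError("P must be square")
    if np.any(P < -1e-12) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ChainError("P must be row-stochastic")
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Unique stationary law of an irreducible finite chain.

    Solves pi P = pi with the normalization sum(pi) = 1. Reducible chains
    (more than one strongly connected component of the support graph) have
    no unique stationary distribution and raise :class:`ChainError`.
    """
    P = _validate_stochastic(P)
    n = P.shape[0]
    n_comp, _ = connected_components(P > 0, directed=True, connection="strong")
    if n_comp != 1:
        raise ChainError("chain is reducible; stationary law is not unique")
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def true_entropy(P: np.ndarray, pi: np.ndarray | None = None) -> float:
    """Shannon entropy (nats) of the stationary joint transition law.

    With q_ij = pi_i P_ij, returns -sum q ln q (0 ln 0 := 0). This is the
    population value that the empirical transition-density entropy
    estimates for a long realization of the chain.
    """
    P = _validate_stochastic(P)
    if pi is None:
        pi = stationary_distribution(P)
    q = np.asarray(pi, float)[:, None] * P
    return float(-xlogy(q, q).sum())


def simulate_states(
    P: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    start_state: int | None = None,
) -> np.ndarray:
    """Sample a state path of length ``n_steps`` from kernel ``P``."""
    P = _validate_stochastic(P)
    n = P.shape[0]
    if start_state is None:
        try:
            start = rng.choice(n, p=stationary_distribution(P))
        except ChainError:
            start = rng.integers(n)
    else:
        start = start_state
    cum = np.cumsum(P, axis=1)
    u = rng.random(n_steps)
    states = np.empty(n_steps, dtype=np.int64)
    s = int(start)
    for t in range(n_steps):
        states[t] = s
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        s = min(s, n - 1)  # guard against u landing on cum rounding
    return states


def _emit_scores(states: np.ndarray, n_states: int, rng: np.random.Generator) -> np.ndarray:
    """Two uniform draws per state from its score bin; top bin is [k-1, 8]."""
    reps = np.repeat(states, 2)
    low = reps.astype(float)
    high = np.where(reps == n_states - 1, SCORE_MAX, reps + 1.0)
    return low + rng.random(reps.size) * (high - low)


def simulate_admission(
    P: np.ndarray,
    duration_days: float,
    gap_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    start_state: int | None = None,
    admission_id: str = "sim",
):
    """Simulate one admission's raw 15-minute score series.

    The chain advances every 30 minutes for ``duration_days * 48`` steps;
    each state emits two 15-minute scores drawn from its bin. Gap
    injection removes single 30-minute grid points flanking randomly
    chosen targets, so a fraction of about ``gap_rate`` of the 30-minute
    observations becomes isolated (and is later dropped by the adjacency
    filter).
    """
    from .prep import RiskScoreSeries

    if duration_days < 1:
        raise ChainError("duration_days must be >= 1")
    if not (0.0 <= gap_rate < 0.5):
        raise ChainError("gap_rate must be in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_slots = int(round(duration_days * 48))
    states = simulate_states(P, n_slots, rng, start_state=start_state)
    k = P.shape[0]
    scores = _emit_scores(states, k, rng)
    t = 15 * np.arange(2 * n_slots, dtype=np.int64)

    keep = np.ones(2 * n_slots, dtype=bool)
    n_iso = int(round(gap_rate * n_slots))
    if n_iso > 0:
        # candidate 30-min slots spaced >= 5 apart, away from the ends so
        # the resampling anchor (first observation) is never disturbed
        candidates = np.arange(3, n_slots - 3, 5)
        n_iso = min(n_iso, candidates.size)
        targets = rng.choice(candidates, size=n_iso, replace=False)
        for j in targets:
            keep[2 * (j - 1)] = False  # 30-min sample of left neighbor
            keep[2 * (j + 1)] = False  # 30-min sample of right neighbor
    return RiskScoreSeries(admission_id, t[keep], scores[keep])


@dataclass(frozen=True)
class CohortConfig:
    """Knobs for a full synthetic cohort.

    ``mortality_link`` is (intercept, slope) on the logit scale in true
    entropy; ``outcome_link`` multiplies entropy in the log-days models
    for hospital stay and the ventilation propensity. With all slopes
    zero, outcomes are independent of entropy.
    """

    n_admissions: int = 164
    mortality_link: tuple[float, float] = (-1.621, 0.0)
    outcome_link: float = 0.0
    stay_distribution: tuple[float, float] = (3.0, 0.9)  # log-normal mu, sigma
    gap_rate: float = 0.0
    seed: int = 0
    n_states: int = 4
    duration_days_range: tuple[float, float] = (2.0, 28.0)
    stickiness_range: tuple[float, float] = (0.25, 0.95)
    target_concentration_range: tuple[float, float] = (0.25, 6.0)

    def __post_init__(self) -> None:
        if self.n_admissions < 2:
            raise ChainError("n_admissions must be >= 2")
        if not (0.0 <= self.gap_rate < 0.5):
            raise ChainError("gap_rate must be in [0, 0.5)")
        if np.exp(self.stay_distribution[0]) < 1:
            raise ChainError("stay distribution must center at >= 1 day")


def draw_chain_specs(config: CohortConfig, rng: np.random.Generator) -> list[ChainSpec]:
    """Heterogeneous per-admission chains spanning a wide entropy range."""
    specs = []
    s_lo, s_hi = config.stickiness_range
    c_lo, c_hi = config.target_concentration_range
    for _ in range(config.n_admissions):
        stickiness = rng.uniform(s_lo, s_hi)
        conc = np.exp(rng.uniform(np.log(c_lo), np.log(c_hi)))
        target = rng.dirichlet(np.full(config.n_states, conc))
        target = np.clip(target, 1e-6, None)
        target = target / target.sum()
        specs.append(
            ChainSpec(
                n_states=config.n_states,
                stickiness=float(stickiness),
                spread="attract",
                target=tuple(float(x) for x in target),
            )
        )
    return specs


def simulate_outcomes(
    true_entropies: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Outcome table with a monotone entropy link.

    mortality ~ Bernoulli(expit(a + b H)); hospital LOS is log-normal
    with log-mean shifted by ``outcome_link * H``; ventilator days are a
    fraction of hospital LOS (never exceeding it), with ventilation
    propensity also increasing in H.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    H = np.asarray(true_entropies, dtype=float)
    n = H.size
    a, b = config.mortality_link
    if not (np.isfinite(a) and np.isfinite(b) and np.isfinite(config.outcome_link)):
        raise ChainError("link coefficients must be finite")
    died = (rng.random(n) < expit(a + b * H)).astype(int)

    mu, sigma = config.stay_distribution
    c = config.outcome_link
    los = np.exp(mu + c * (H - H.mean() if n > 1 else H) + sigma * rng.standard_normal(n))
    los = np.maximum(np.round(los, 1), 1.0)

    ventilated = rng.random(n) < expit(0.3 + c * H)
    frac = expit(-0.6 + c * H + 0.9 * rng.standard_normal(n))
    vent = np.where(ventilated, np.round(frac * los, 1), 0.0)
    vent = np.minimum(vent, los)

    icu = np.maximum(np.round(los * rng.uniform(0.25, 0.95, n), 1), 1.0)
    icu = np.minimum(icu, los)

    age = np.round(np.clip(np.exp(rng.normal(0.4, 1.2, n)), 0.0, 17.9), 1)
    sex = rng.integers(0, 2, n)
    return pd.DataFrame(
        {
            "admission_id": [f"adm{i:04d}" for i in range(n)],
            "age_years": age,
            "sex": np.where(sex == 1, "M", "F"),
            "died": died,
            "vent_days": vent,
            "hospital_los_days": los,
            "icu_los_days": icu,
        }
    )


def _csv_with_header(df: pd.DataFrame, path: Path, meta: dict) -> None:
    buf = io.StringIO()
    for key, val in meta.items():
        buf.write(f"# {key}={val}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def config_hash(config: CohortConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def generate_cohort(config: CohortConfig, outdir: str | Path) -> dict[str, Path]:
    """Write scores.csv, outcomes.csv and truth.csv for a seeded cohort.

    Deterministic: the same config (including seed) yields byte-identical
    files. truth.csv stores every admission's chain parameters and true
    entropy so downstream estimates can be checked against ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    specs = draw_chain_specs(config, rng)

    score_frames = []
    truth_rows = []
    entropies = np.empty(config.n_admissions)
    d_lo, d_hi = config.duration_days_range
    for i, spec in enumerate(specs):
        adm = f"adm{i:04d}"
        P = make_chain(spec)
        entropies[i] = true_entropy(P)
        duration = float(np.round(rng.uniform(d_lo, d_hi), 2))
        series = simulate_admission(
            P, duration, gap_rate=config.gap_rate, seed=rng, admission_id=adm
        )
        score_frames.append(
            pd.DataFrame(
                {
                    "admission_id": adm,
                    "t_minutes": series.t_minutes,
                    "score": np.round(series.scores, 6),
                }
            )
        )
        row = {
            "admission_id": adm,
            "n_states": spec.n_states,
            "stickiness": round(spec.stickiness, 6),
            "spread": spec.spread,
            "duration_days": duration,
            "true_entropy": round(float(entropies[i]), 6),
        }
        for j, t in enumerate(spec.target or ()):
            row[f"target_{j}"] = round(t, 6)
        truth_rows.append(row)

    outcomes = simulate_outcomes(entropies, config, rng)
    meta = {"seed": config.seed, "config_hash": config_hash(config)}
    paths = {
        "scores": outdir / "scores.csv",
        "outcomes": outdir / "outcomes.csv",
        "truth": outdir / "truth.csv",
    }
    _csv_with_header(pd.concat(score_frames, ignore_index=True), paths["scores"], meta)
    _csv_with_header(outcomes, paths["outcomes"], meta)
    _csv_with_header(pd.DataFrame(truth_rows), paths["truth"], meta)
    return paths
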