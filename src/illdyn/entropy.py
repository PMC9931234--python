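"""Per-admission transition matrices and Shannon entropy of the transition density.

Three k x k summaries are built from one admission's discretized series:

* **count matrix** — cell (i, j) counts adjacent 30-minute pairs moving
  from state i to state j;
* **transition matrix** — counts row-normalized by the number of
  observations leaving each initial state (rows sum to one; rows for
  never-visited states are masked rather than filled);
* **entropy matrix** — counts divided by the *total* number of observed
  transitions, i.e. the joint density of transitions (all cells sum to
  one).

The admission's entropy is the Shannon entropy, in natural-log units, of
the entropy-matrix cells: ``H = -sum p ln p`` with ``0 ln 0 := 0``. For
k states the value lies in ``[0, ln(k^2)]``; for k = 4 the maximum is
``ln 16 = 2.77`` (2 d.p.).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .prep import IllnessStateSeries


class EntropyError(ValueError):
    """Raised for empty or inconsistent matrix inputs."""


@dataclass
class TransitionCountMatrix:
    counts: np.ndarray  # k x k, nonnegative integers
    n_transitions: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise EntropyError("counts must be square")
        if np.any(self.counts < 0):
            raise EntropyError("counts must be nonnegative")
        if self.n_transitions != int(self.counts.sum()):
            raise EntropyError("n_transitions must equal the sum of counts")

    @property
    def k(self) -> int:
        return self.counts.shape[0]


@dataclass
class TransitionProbabilityMatrix:
    probs: np.ndarray        # k x k, visited rows sum to 1
    visited: np.ndarray      # bool mask per row

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.visited = np.asarray(self.visited, dtype=bool)


@dataclass
class EntropyMatrix:
    density: np.ndarray  # k x k, cells sum to 1

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise EntropyError("density entries must be nonnegative")


@dataclass
class EntropyScore:
    value: float          # nats
    n_transitions: int


def count_transitions(series: IllnessStateSeries, k: int | None = None) -> TransitionCountMatrix:
    """Count flagged adjacent-pair transitions into a k x k matrix.

    Pairs spanning a gap (no adjacency flag) contribute nothing.
    """
    k = k if k is not None else series.n_states
    states = series.states
    if states.size and (states.min() < 0 or states.max() >= k):
        raise EntropyError(f"states outside 0..{k - 1}")
    counts = np.zeros((k, k), dtype=np.int64)
    if states.size >= 2:
        mask = series.adjacent_next[:-1]
        np.add.at(counts, (states[:-1][mask], states[1:][mask]), 1)
    return TransitionCountMatrix(counts, int(counts.sum()))


def transition_matrix(counts: TransitionCountMatrix) -> TransitionProbabilityMatrix:
    """Row-normalize counts; zero-count rows are masked, not normalized."""
    if counts.n_transitions < 1:
        raise EntropyError("no observed transitions")
    row_sums = counts.counts.sum(axis=1)
    visited = row_sums > 0
    probs = np.zeros_like(counts.counts, dtype=float)
    probs[visited] = counts.counts[visited] / row_sums[visited, None]
    return TransitionProbabilityMatrix(probs, visited)


def entropy_matrix(counts: TransitionCountMatrix) -> EntropyMatrix:
    """Joint transition density: counts over the total number of transitions."""
    if counts.n_transitions < 1:
        raise EntropyError("no observed transitions")
    return EntropyMatrix(counts.counts / counts.n_transitions)


def shannon_entropy(
    density: EntropyMatrix | np.ndarray, n_transitions: int = 0, tol: float = 1e-8
) -> EntropyScore:
    """Shannon entropy (natural log) of the transition-density cells."""
    p = density.density if isinstance(density, EntropyMatrix) else np.asarray(density, float)
    if np.any(p < 0):
        raise EntropyError("density entries must be nonnegative")
    total = p.sum()
    if abs(total - 1.0) > tol:
        raise EntropyError(f"density sums to {total}, not 1")
    value = float(-xlogy(p, p).sum())
    return EntropyScore(max(value, 0.0), n_transitions)


def admission_summary(
    continuous_series,
    state_series: IllnessStateSeries,
    k: int | None = None,
    min_pairs: int = 2,
) -> dict:
    """One record per admission: entropy, mean 30-min score, counts, flags.

    The mean score is computed on the retained continuous 30-minute scores,
    before binning. Admissions with fewer than ``min_pairs`` valid adjacent
    pairs are flagged for exclusion from clustering.
    """
    counts = count_transitions(state_series, k)
    n_obs = len(state_series)
    if counts.n_transitions >= 1:
        score = shannon_entropy(entropy_matrix(counts), counts.n_transitions)
        ent = score.value
    else:
        ent = np.nan
    mean_score = float(np.mean(continuous_series.scores)) if len(continuous_series) else np.nan
    return {
        "admission_id": state_series.admission_id,
        "entropy_nats": ent,
        "mean_score": mean_score,
        "n_obs": n_obs,
        "n_transitions": counts.n_transitions,
        "excluded": counts.n_transitions < min_pairs,
    }
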