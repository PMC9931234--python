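"""Preparation of raw risk-score series for transition analysis.

Raw series arrive on a 15-minute grid. Analysis operates on 30-minute
samples restricted to observations that have at least one neighbor exactly
30 minutes away ("adjacent pairs"); everything else is discarded before
states are assigned.

Scores are continuous severity values on [0, 8] and are discretized into
``k`` ordinal illness states by a half-open binning scheme: state ``i``
covers ``[edge_{i-1}, edge_i)`` with the top state unbounded above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

BASE_GRID_MIN = 15
STEP_MIN = 30

#: Fixed four-state scheme: [0,1), [1,2), [2,3), [3, inf)
FIXED_EDGES = (1.0, 2.0, 3.0)

SCORE_MAX = 8.0


class PrepError(ValueError):
    """Raised for invalid series or binning-scheme inputs."""


@dataclass
class RiskScoreSeries:
    """One admission's timestamped continuous risk scores.

    Parameters
    ----------
    admission_id : str
        Identifier of the admission.
    t_minutes : ndarray of int
        Minutes since admission start; strictly increasing, multiples of
        the 15-minute base grid.
    scores : ndarray of float
        Continuous severity scores, finite.
    """

    admission_id: str
    t_minutes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.t_minutes = np.asarray(self.t_minutes, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.t_minutes.shape != self.scores.shape:
            raise PrepError("t_minutes and scores must have equal length")
        if self.t_minutes.size:
            if np.any(np.diff(self.t_minutes) <= 0):
                raise PrepError("t_minutes must be strictly increasing")
            if np.any(self.t_minutes % BASE_GRID_MIN != 0):
                raise PrepError(
                    f"t_minutes must be multiples of {BASE_GRID_MIN} min"
                )
        if not np.all(np.isfinite(self.scores)):
            raise PrepError("scores must be finite")

    def __len__(self) -> int:
        return int(self.t_minutes.size)


@dataclass(frozen=True)
class BinningScheme:
    """Half-open score bins: ``k - 1`` ascending interior edges for ``k`` states."""

    edges: tuple[float, ...] = FIXED_EDGES
    kind: str = "fixed"

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        if len(edges) < 1:
            raise PrepError("at least one interior edge is required")
        if np.any(np.diff(edges) <= 0):
            raise PrepError("edges must be strictly increasing")
        if self.kind not in ("fixed", "equiprobable"):
            raise PrepError(f"unknown scheme kind {self.kind!r}")

    @property
    def n_states(self) -> int:
        return len(self.edges) + 1


@dataclass
class IllnessStateSeries:
    """Discretized series with adjacency flags for valid 30-min pairs.

    ``adjacent_next[i]`` is True iff observation ``i + 1`` occurs exactly
    one 30-minute step after observation ``i`` (within ``tol`` minutes);
    only flagged pairs count as transitions downstream.
    """

    admission_id: str
    t_minutes: np.ndarray
    states: np.ndarray
    adjacent_next: np.ndarray
    n_states: int = 4
    scores: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t_minutes = np.asarray(self.t_minutes, dtype=np.int64)
        self.states = np.asarray(self.states, dtype=np.int64)
        self.adjacent_next = np.asarray(self.adjacent_next, dtype=bool)
        if self.states.size and (
            self.states.min() < 0 or self.states.max() >= self.n_states
        ):
            raise PrepError("states outside 0..k-1")

    def __len__(self) -> int:
        return int(self.t_minutes.size)

    @property
    def n_pairs(self) -> int:
        return int(self.adjacent_next.sum())


def resample_30min(series: RiskScoreSeries) -> RiskScoreSeries:
    """Thin a 15-min series to 30-min samples.

    Keeps observations whose offset from the *first* observation is a
    multiple of 30 minutes; the anchor is the admission's own first
    sample, not clock time.
    """
    if len(series) == 0:
        warnings.warn(f"{series.admission_id}: empty series", stacklevel=2)
        return series
    offset = series.t_minutes - series.t_minutes[0]
    keep = offset % STEP_MIN == 0
    return RiskScoreSeries(
        series.admission_id, series.t_minutes[keep], series.scores[keep]
    )


def remove_nonadjacent(
    series: RiskScoreSeries, step: int = STEP_MIN, tol: int = 0
) -> tuple[RiskScoreSeries, int]:
    """Drop observations lacking a neighbor exactly one step away.

    Returns the filtered series and the number of removed observations.
    """
    t = series.t_minutes
    n = t.size
    if n == 0:
        return series, 0
    gaps = np.diff(t)
    ok = np.abs(gaps - step) <= tol
    keep = np.zeros(n, dtype=bool)
    keep[:-1] |= ok
    keep[1:] |= ok
    removed = int(n - keep.sum())
    return (
        RiskScoreSeries(series.admission_id, t[keep], series.scores[keep]),
        removed,
    )


def bin_scores(
    series: RiskScoreSeries,
    scheme: BinningScheme | None = None,
    step: int = STEP_MIN,
    tol: int = 0,
) -> IllnessStateSeries:
    """Assign each score to its half-open bin and flag adjacent pairs.

    Boundary values map upward: a score equal to an interior edge belongs
    to the bin starting at that edge. Negative scores are rejected; scores
    above 8 are clipped with a warning.
    """
    scheme = scheme or BinningScheme()
    scores = series.scores
    if np.any(scores < 0):
        raise PrepError(f"{series.admission_id}: negative score encountered")
    if np.any(scores > SCORE_MAX):
        warnings.warn(
            f"{series.admission_id}: scores above {SCORE_MAX} clipped",
            stacklevel=2,
        )
        scores = np.minimum(scores, SCORE_MAX)
    states = np.searchsorted(np.asarray(scheme.edges), scores, side="right")
    if len(series) > 1:
        adjacent = np.abs(np.diff(series.t_minutes) - step) <= tol
    else:
        adjacent = np.zeros(0, dtype=bool)
    adjacent_next = np.append(adjacent, False) if len(series) else adjacent
    return IllnessStateSeries(
        series.admission_id,
        series.t_minutes,
        states,
        adjacent_next,
        n_states=scheme.n_states,
        scores=scores,
    )


def equiprobable_edges(pooled_scores: np.ndarray, k: int = 4) -> BinningScheme:
    """Interior edges at the 1/k .. (k-1)/k empirical quantiles.

    Quantiles use linear interpolation on order statistics at positions
    ``(n - 1) * p``. The pooled vector is expected to hold all admissions'
    analysis-ready 30-minute observations.
    """
    pooled = np.asarray(pooled_scores, dtype=float)
    if pooled.size < k:
        raise PrepError(f"need at least k={k} pooled observations")
    if np.unique(pooled).size < k:
        raise PrepError("fewer distinct values than bins; degenerate pooling")
    probs = np.arange(1, k) / k
    edges = np.quantile(pooled, probs, method="linear")
    if np.any(np.diff(edges) <= 0):
        raise PrepError("tied quantiles produce degenerate edges")
    return BinningScheme(tuple(edges), kind="equiprobable")


def prepare_admission(
    series: RiskScoreSeries,
    scheme: BinningScheme | None = None,
    tol: int = 0,
) -> tuple[RiskScoreSeries, IllnessStateSeries, dict]:
    """Full prep: resample to 30 min, drop nonadjacent, bin.

    Returns the retained continuous 30-min series (used for mean-score
    summaries), the discretized state series, and a removal report.
    """
    n_raw = len(series)
    resampled = resample_30min(series)
    filtered, n_removed = remove_nonadjacent(resampled, tol=tol)
    states = bin_scores(filtered, scheme, tol=tol)
    report = {
        "admission_id": series.admission_id,
        "n_raw": n_raw,
        "n_after_resample": len(resampled),
        "n_removed_nonadjacent": n_removed,
        "n_final": len(filtered),
    }
    return filtered, states, report
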