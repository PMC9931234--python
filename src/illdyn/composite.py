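"""Rank-based composite of negative outcomes.

The composite for each admission is the sum of three ascending min-tie
ranks over the cohort: in-hospital mortality (0/1), ventilator days, and
hospital length of stay. Min-tie ranking assigns every member of a tie
group the lowest rank of the group, i.e. rank(x) = 1 + #{values < x}.
Larger composites are worse; the theoretical minimum is 3 (survivor with
tied-lowest ventilator days and stay).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CompositeOutcome:
    admission_id: str
    rank_mortality: int
    rank_vent: int
    rank_los: int

    @property
    def composite(self) -> int:
        return self.rank_mortality + self.rank_vent + self.rank_los


def rank_min_ties(values, ascending: bool = True) -> np.ndarray:
    """Ascending min-tie ranks: rank of x is 1 + count of values strictly below x."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot rank an empty vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if not ascending:
        v = -v
    order = np.sort(v)
    return np.searchsorted(order, v, side="left") + 1


def composite_score(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-admission composite table from an outcomes frame.

    Requires columns ``admission_id, died, vent_days, hospital_los_days``.
    Admissions missing any component are excluded with a warning; ranks are
    computed over the complete-case cohort.
    """
    cols = ["died", "vent_days", "hospital_los_days"]
    df = outcomes.copy()
    complete = df[cols].notna().all(axis=1)
    if not complete.all():
        dropped = df.loc[~complete, "admission_id"].tolist()
        warnings.warn(
            f"excluding {len(dropped)} admissions with missing components: {dropped}",
            stacklevel=2,
        )
        df = df[complete]
    if df.empty:
        raise ValueError("no complete-case admissions to rank")
    died = df["died"].to_numpy()
    if not np.isin(died, [0, 1]).all():
        raise ValueError("died must be coded 0/1")
    if (df["vent_days"] < 0).any() or (df["hospital_los_days"] < 0).any():
        raise ValueError("day counts must be nonnegative")
    out = pd.DataFrame(
        {
            "admission_id": df["admission_id"].to_numpy(),
            "rank_mortality": rank_min_ties(died),
            "rank_vent": rank_min_ties(df["vent_days"].to_numpy()),
            "rank_los": rank_min_ties(df["hospital_los_days"].to_numpy()),
        }
    )
    out["composite"] = out["rank_mortality"] + out["rank_vent"] + out["rank_los"]
    return out
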