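"""Entropy-based phenotyping: Ward clustering plus group comparisons.

Admissions are clustered on their scalar transition entropy with
agglomerative hierarchical clustering (Euclidean distance, Ward
criterion). The dendrogram is cut at k = 2 and k = 4; phenotype labels
are reordered so phenotype 1 always carries the highest mean entropy.

Group comparisons follow a test-selection rule: chi-squared for
categorical variables; for continuous variables, per-group Shapiro-Wilk
and across-group Levene checks decide between one-way ANOVA (assumptions
met) and Kruskal-Wallis. ANOVA-significant variables get a Tukey HSD
post hoc, and the significance threshold is Bonferroni-adjusted by the
number of continuous comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class ClusterError(ValueError):
    pass


@dataclass
class PhenotypeAssignment:
    linkage_matrix: np.ndarray
    labels_k2: np.ndarray
    labels_k4: np.ndarray

    def to_frame(self, admission_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "admission_id": admission_ids,
                "phenotype_k2": self.labels_k2,
                "phenotype_k4": self.labels_k4,
            }
        )


@dataclass
class GroupComparisonTable:
    table: pd.DataFrame
    adjusted_alpha: float
    tukey: dict = field(default_factory=dict)
    assumption_checks: dict = field(default_factory=dict)


def ward_cluster(entropies, dialect: str = "ward") -> np.ndarray:
    """Full merge tree for scalar entropies.

    ``dialect='ward'`` is the variance-minimizing criterion on squared
    Euclidean increments (R's ward.D2 on Euclidean input). The legacy
    ``'ward.D'`` dialect, which treats the plain distances as if already
    squared, is emulated by feeding the square roots of the Euclidean
    distances to the same criterion.
    """
    x = np.asarray(entropies, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ClusterError("need at least two scalar entropy values")
    if not np.all(np.isfinite(x)):
        raise ClusterError("non-finite entropy values")
    if dialect == "ward":
        Z = linkage(x[:, None], method="ward")
    elif dialect == "ward.D":
        Z = linkage(np.sqrt(pdist(x[:, None])), method="ward")
    else:
        raise ClusterError(f"unknown Ward dialect {dialect!r}")
    return Z


def cut_k(Z: np.ndarray, k: int) -> np.ndarray:
    """Labels (1..k) from cutting the tree into exactly k clusters."""
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ClusterError(f"k={k} outside 1..{n}")
    labels = fcluster(Z, t=k, criterion="maxclust")
    found = np.unique(labels).size
    if found != k:
        raise ClusterError(
            f"cannot cut into exactly k={k} clusters (tied merge heights "
            f"yield {found}); choose another k"
        )
    return labels


def order_phenotypes(labels: np.ndarray, entropies) -> np.ndarray:
    """Relabel clusters 1..k by descending mean entropy (ties: larger cluster first)."""
    labels = np.asarray(labels)
    x = np.asarray(entropies, dtype=float)
    uniq = np.unique(labels)
    means = np.array([x[labels == u].mean() for u in uniq])
    sizes = np.array([(labels == u).sum() for u in uniq])
    order = sorted(range(uniq.size), key=lambda i: (-means[i], -sizes[i]))
    mapping = {uniq[old]: new + 1 for new, old in enumerate(order)}
    return np.array([mapping[l] for l in labels])


def assign_phenotypes(entropies, ks=(2, 4), dialect: str = "ward") -> PhenotypeAssignment:
    Z = ward_cluster(entropies, dialect=dialect)
    labels = [order_phenotypes(cut_k(Z, k), entropies) for k in ks]
    return PhenotypeAssignment(Z, labels[0], labels[-1])


def _select_continuous_test(groups, alpha=0.05):
    """Shapiro per group + Levene across groups decide ANOVA vs Kruskal-Wallis."""
    normal = True
    checks = {"shapiro_p": [], "levene_p": None}
    for g in groups:
        if len(g) < 3 or np.ptp(g) == 0:
            normal = False
            checks["shapiro_p"].append(np.nan)
            continue
        p = stats.shapiro(g).pvalue
        checks["shapiro_p"].append(float(p))
        if p <= alpha:
            normal = False
    if all(len(g) >= 2 for g in groups):
        lev_p = float(stats.levene(*groups).pvalue)
        checks["levene_p"] = lev_p
        if lev_p <= alpha:
            normal = False
    return ("anova" if normal else "kruskal"), checks


def compare_groups(
    df: pd.DataFrame,
    labels,
    continuous: list[str],
    categorical: list[str] | None = None,
    alpha: float = 0.05,
) -> GroupComparisonTable:
    """Per-variable tests across phenotype groups with summaries.

    Returns a table with one row per variable: the test used, its
    statistic, p-value, degrees of freedom where applicable, and
    per-group summaries (percent for categorical, mean +/- SD for
    continuous). ``adjusted_alpha = alpha / len(continuous)``.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ClusterError("need at least two groups")
    categorical = categorical or []
    rows = []
    tukey_results: dict = {}
    assumption_checks: dict = {}
    n = len(df)

    for var in categorical:
        tab = pd.crosstab(labels, df[var])
        expected = stats.contingency.expected_freq(tab.to_numpy())
        summaries = {}
        for u in uniq:
            sub = df[var][labels == u]
            # report percent of the modal "positive" level when binary
            lev = sorted(sub.dropna().unique())
            top = lev[-1] if lev else None
            summaries[int(u)] = (
                f"{100 * (sub == top).mean():.1f}% {top}" if top is not None else "n/a"
            )
        if np.any(expected == 0):
            warnings.warn(f"{var}: zero expected cell count; chi-squared skipped")
            rows.append(
                {"variable": var, "test": "chi-squared (skipped)", "statistic": np.nan,
                 "p_value": np.nan, "df": np.nan, **{f"group_{u}": s for u, s in summaries.items()}}
            )
            continue
        chi2 = stats.chi2_contingency(tab, correction=False)
        rows.append(
            {"variable": var, "test": "chi-squared", "statistic": float(chi2.statistic),
             "p_value": float(chi2.pvalue), "df": float(chi2.dof),
             **{f"group_{u}": s for u, s in summaries.items()}}
        )

    for var in continuous:
        groups = [df[var][labels == u].dropna().to_numpy() for u in uniq]
        if any(len(g) == 0 for g in groups):
            raise ClusterError(f"{var}: empty group")
        test, checks = _select_continuous_test(groups, alpha)
        assumption_checks[var] = checks
        summaries = {
            int(u): f"{g.mean():.2f}±{g.std(ddof=1) if len(g) > 1 else 0:.2f}"
            for u, g in zip(uniq, groups)
        }
        if test == "anova":
            res = stats.f_oneway(*groups)
            dof = (uniq.size - 1, n - uniq.size)
            rows.append(
                {"variable": var, "test": "anova", "statistic": float(res.statistic),
                 "p_value": float(res.pvalue), "df": dof,
                 **{f"group_{u}": s for u, s in summaries.items()}}
            )
            if res.pvalue < alpha:
                tukey_results[var] = pairwise_tukeyhsd(
                    df[var].to_numpy(), labels, alpha=alpha
                )
        else:
            res = stats.kruskal(*groups)
            rows.append(
                {"variable": var, "test": "kruskal-wallis", "statistic": float(res.statistic),
                 "p_value": float(res.pvalue), "df": float(uniq.size - 1),
                 **{f"group_{u}": s for u, s in summaries.items()}}
            )

    return GroupComparisonTable(
        table=pd.DataFrame(rows),
        adjusted_alpha=alpha / max(len(continuous), 1),
        tukey=tukey_results,
        assumption_checks=assumption_checks,
    )
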