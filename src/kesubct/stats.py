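"""Group statistics and reporting arithmetic for the structural indices.

Structural indices from micro-CT frequently violate normality and
homoscedasticity, so group differences are tested nonparametrically:
Kruskal-Wallis across groups, followed by Dunn's pairwise z-tests on the
pooled ranks with a family-wise adjustment. Paired t-tests serve for
within-group comparisons (body-weight change). Reporting helpers compute
percent contrasts between group means and check that vessel-size-specific
quantities partition their totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, pd.DataFrame):
        raise TypeError("pass a mapping {group label: values}; see group_table()")
    return {str(k): np.asarray(v, dtype=float) for k, v in dict(groups).items()}


def group_table(df: pd.DataFrame, value: str, group: str = "group") -> dict[str, np.ndarray]:
    """Extract {group label: values} for one index from a specimen table."""
    return {str(g): sub[value].to_numpy(dtype=float) for g, sub in df.groupby(group)}


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value (df = k-1)."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    vals = list(gs.values())
    if np.ptp(np.concatenate(vals)) == 0:
        return 0.0, 1.0  # H is 0/0 under the tie correction; no evidence
    try:
        h, p = sps.kruskal(*vals)
    except ValueError:  # all numbers identical
        return 0.0, 1.0
    return float(h), float(p)


def dunn_posthoc(groups, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise post-hoc z-tests on pooled ranks, tie-corrected.

    Returns a symmetric DataFrame of family-wise adjusted two-sided
    p-values over all k(k-1)/2 pairs. ``adjust`` is ``"bonferroni"``
    (default, matching the usual Dunn convention) or ``"holm"``. Groups
    with fewer than 2 observations are excluded with a warning.
    """
    gs = _as_groups(groups)
    small = [k for k, v in gs.items() if v.size < 2]
    if small:
        warnings.warn(f"groups excluded from Dunn test (n < 2): {small}")
        gs = {k: v for k, v in gs.items() if v.size >= 2}
    labels = list(gs)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups with n >= 2")

    pooled = np.concatenate([gs[l] for l in labels])
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    i = 0
    for l in labels:
        n = gs[l].size
        mean_rank[l] = ranks[i : i + n].mean()
        i += n
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_tot - 1)) if n_tot > 1 else 0.0
    var_factor = n_tot * (n_tot + 1) / 12.0 - tie_term

    pairs, praw = [], []
    for a in range(k):
        for b in range(a + 1, k):
            la, lb = labels[a], labels[b]
            se = np.sqrt(var_factor * (1.0 / gs[la].size + 1.0 / gs[lb].size))
            if se == 0:
                p = 1.0
            else:
                z = (mean_rank[la] - mean_rank[lb]) / se
                p = 2.0 * sps.norm.sf(abs(z))
            pairs.append((la, lb))
            praw.append(p)
    method = {"bonferroni": "bonferroni", "holm": "holm"}[adjust]
    padj = multipletests(praw, method=method)[1] if praw else np.array([])

    out = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    for (la, lb), p in zip(pairs, padj):
        out.loc[la, lb] = out.loc[lb, la] = min(1.0, float(p))
    return out


def paired_t(before, after) -> tuple[float, float]:
    """Two-sided paired t-test; errors on zero-variance differences."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before/after must be equal-length 1D vectors")
    if before.size < 2:
        raise ValueError("need at least 2 pairs")
    d = after - before
    if np.ptp(d) == 0 and d.std() == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        raise ValueError("zero variance of paired differences; t undefined")
    t, p = sps.ttest_rel(after, before)
    return float(t), float(p)


@dataclass(frozen=True)
class Contrast:
    """A reference-vs-comparator percent difference for reporting."""

    percent: float          # signed: >0 means comparator smaller than reference
    direction: str          # "smaller" or "larger"

    @property
    def rounded(self) -> int:
        return int(round(abs(self.percent)))


def percent_contrast(reference: float, comparator: float) -> Contrast:
    """Percent by which ``comparator`` is smaller/larger than ``reference``.

    smaller: 100 x (ref - comp) / ref;  larger: 100 x (comp - ref) / ref.
    """
    if reference == 0:
        raise ValueError("reference value must be non-zero")
    pct = 100.0 * (reference - comparator) / reference
    return Contrast(percent=pct, direction="smaller" if pct >= 0 else "larger")


def partition_check(per_bin, total: float, tol: float) -> dict:
    """Do five size-specific values sum to the printed total within tol?"""
    per_bin = np.asarray(per_bin, dtype=float)
    if per_bin.size != 5:
        raise ValueError("expected five diameter-class values")
    s = float(per_bin.sum())
    disc = abs(s - total)
    return {"sum": s, "total": float(total), "discrepancy": disc, "pass": disc <= tol}


def group_summary(df: pd.DataFrame, group: str = "group") -> pd.DataFrame:
    """Mean and SEM of every numeric index per group."""
    num = df.select_dtypes("number")
    g = df[[group]].join(num).groupby(group)
    mean = g.mean()
    sem = g.sem()
    out = pd.concat({"mean": mean, "sem": sem}, axis=1)
    return out.swaplevel(axis=1).sort_index(axis=1, level=0, sort_remaining=False)
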