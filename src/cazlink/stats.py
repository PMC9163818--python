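"""Group-contrast statistics for bins, CAZy families and linkage targets.

All contrasts follow the same recipe the motivating feeding trial used:
equal-variance two-sample Student's t-tests on the per-animal values of
two diet groups with raw p <= 0.05 (no multiplicity correction by
default), a dual significance filter for feature abundances (p below
alpha AND at least a 20% relative change against the reference group),
compact-letter displays for multi-group summaries, and Spearman rank
correlation between feature abundances and a per-animal phenotype such
as CH4 yield.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .profiles import phylum_of

__all__ = [
    "two_sample_t",
    "TTestResult",
    "classify_bins",
    "phylum_classification_counts",
    "letters",
    "filter_features",
    "spearman_phenotype",
]

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_CHANGE = 20.0  # percent

REFERENCE_DOMINANT = "reference-dominant"
CONTRAST_DOMINANT = "contrast-dominant"
NOT_SIGNIFICANT = "not-significant"


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    degenerate: bool = False  # zero pooled variance


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Equal-variance two-sample Student's t-test, two-sided.

    Degrees of freedom are ``n_x + n_y - 2``.  With zero pooled variance
    the test is degenerate: equal means give ``t = 0, p = 1``; unequal
    means give ``p = 0`` with the result flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    sx = x.var(ddof=1)
    sy = y.var(ddof=1)
    if sx == 0.0 and sy == 0.0:
        if x.mean() == y.mean():
            return TTestResult(0.0, 1.0, degenerate=True)
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return TTestResult(sign * np.inf, 0.0, degenerate=True)
    stat, p = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(stat), float(p))


def _vectorised_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise equal-variance t p-values with the degenerate-row convention."""
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sps.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.asarray(p)
    flat = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[flat & equal] = 1.0
    p[flat & ~equal] = 0.0
    return p


def _group_columns(
    columns: Sequence[str], groups: Mapping[str, str], name: str
) -> list[str]:
    cols = [c for c in columns if groups.get(c) == name]
    if len(cols) < 2:
        raise ValueError(f"group {name!r} needs >= 2 samples, found {len(cols)}")
    return cols


def classify_bins(
    abundances: pd.DataFrame,
    groups: Mapping[str, str],
    reference: str,
    contrast: str,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Label every bin reference-/contrast-dominant or not-significant.

    A bin is *dominant* in the group with the larger mean when the
    equal-variance t-test between the two groups' per-sample abundances
    has p <= *alpha*; otherwise it is not significant.  Bins absent
    (all-zero) in both groups are not significant and flagged absent.
    """
    ref_cols = _group_columns(abundances.columns, groups, reference)
    con_cols = _group_columns(abundances.columns, groups, contrast)
    a = abundances[ref_cols].to_numpy(dtype=float)
    b = abundances[con_cols].to_numpy(dtype=float)
    p = _vectorised_t(a, b)
    mean_ref = a.mean(axis=1)
    mean_con = b.mean(axis=1)
    absent = (a.sum(axis=1) == 0) & (b.sum(axis=1) == 0)
    direction = np.where(
        absent | (p > alpha),
        NOT_SIGNIFICANT,
        np.where(mean_ref > mean_con, REFERENCE_DOMINANT, CONTRAST_DOMINANT),
    )
    return pd.DataFrame(
        {
            "mean_ref": mean_ref,
            "mean_con": mean_con,
            "p": p,
            "direction": direction,
            "absent": absent,
        },
        index=abundances.index,
    )


def phylum_classification_counts(
    classification: pd.DataFrame, bins: pd.DataFrame
) -> pd.DataFrame:
    """Per-phylum counts of the three bin classes, plus a Total row.

    The three category counts partition the bin total of every phylum.
    """
    phyla = bins.set_index("bin_id")["taxonomy"].map(phylum_of)
    tab = pd.crosstab(
        phyla.reindex(classification.index), classification["direction"]
    )
    for col in (REFERENCE_DOMINANT, CONTRAST_DOMINANT, NOT_SIGNIFICANT):
        if col not in tab.columns:
            tab[col] = 0
    tab = tab[[REFERENCE_DOMINANT, CONTRAST_DOMINANT, NOT_SIGNIFICANT]]
    tab.insert(0, "total", tab.sum(axis=1))
    tab.loc["Total"] = tab.sum(axis=0)
    tab.index.name = "phylum"
    return tab


def letters(
    group_values: Mapping[str, Sequence[float]], alpha: float = DEFAULT_ALPHA
) -> dict[str, str]:
    """Compact-letter display from all pairwise equal-variance t-tests.

    Two groups share a letter iff their pairwise test has p > *alpha*
    (insert-and-absorb algorithm).  Intransitive significance patterns
    legally produce multiple letters per group.
    """
    names = list(group_values)
    if len(names) < 2:
        raise ValueError("need >= 2 groups for a letter display")
    differ = {
        (a, b): two_sample_t(group_values[a], group_values[b]).p_value <= alpha
        for i, a in enumerate(names)
        for b in names[i + 1:]
    }

    def different(a: str, b: str) -> bool:
        return differ.get((a, b), differ.get((b, a), False))

    # Insert-and-absorb: letters are column sets of mutually compatible groups.
    columns: list[set[str]] = [set(names)]
    for (a, b), diff in differ.items():
        if not diff:
            continue
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend(({g for g in col if g != b}, {g for g in col if g != a}))
        # absorb: drop columns contained in another
        columns = [
            c for c in columns
            if not any(c < other for other in columns)
        ]
        # deduplicate
        unique: list[set[str]] = []
        for c in columns:
            if c not in unique:
                unique.append(c)
        columns = unique
    columns.sort(key=lambda c: (min(names.index(g) for g in c), -len(c)))
    assignment = {name: "" for name in names}
    for letter, col in zip(string.ascii_uppercase, columns):
        for g in names:
            if g in col:
                assignment[g] += letter
    return assignment


def filter_features(
    profile: pd.DataFrame,
    groups: Mapping[str, str],
    reference: str,
    contrast: str,
    alpha: float = DEFAULT_ALPHA,
    min_change: float = DEFAULT_MIN_CHANGE,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Dual-criterion differential test of every feature (row) of a profile.

    A feature is significant iff the equal-variance t-test between the
    reference and contrast group columns has p < *alpha* AND the relative
    change ``|mean_con - mean_ref| / mean_ref * 100`` is at least
    *min_change* percent.  A zero reference mean with a nonzero contrast
    mean counts as an infinite change (the feature effectively appears or
    disappears), which passes the change rule.  Optionally the p-values
    are Benjamini–Hochberg adjusted before the alpha rule (off by
    default).
    """
    ref_cols = _group_columns(profile.columns, groups, reference)
    con_cols = _group_columns(profile.columns, groups, contrast)
    a = profile[ref_cols].to_numpy(dtype=float)
    b = profile[con_cols].to_numpy(dtype=float)
    p = _vectorised_t(a, b)
    if bh_correct:
        p = sps.false_discovery_control(p, method="bh")
    mean_ref = a.mean(axis=1)
    mean_con = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        change = np.abs(mean_con - mean_ref) / mean_ref * 100.0
    change = np.where(
        mean_ref == 0.0, np.where(mean_con > 0.0, np.inf, 0.0), change
    )
    significant = (p < alpha) & (change >= min_change)
    direction = np.where(
        ~significant,
        NOT_SIGNIFICANT,
        np.where(mean_ref > mean_con, REFERENCE_DOMINANT, CONTRAST_DOMINANT),
    )
    return pd.DataFrame(
        {
            "mean_ref": mean_ref,
            "sd_ref": a.std(axis=1, ddof=1),
            "mean_con": mean_con,
            "sd_con": b.std(axis=1, ddof=1),
            "p": p,
            "percent_change": change,
            "direction": direction,
            "significant": significant,
        },
        index=profile.index,
    )


def spearman_phenotype(
    profile: pd.DataFrame,
    phenotype: Mapping[str, float],
    exclude_zero_mass: bool = True,
) -> pd.DataFrame:
    """Spearman rank correlation of every feature against a phenotype.

    Samples are pooled across all groups; ties get average ranks.  All-zero
    profile columns (no CAZyme mass) are excluded by default.  Features
    constant across the usable samples get ``NaN`` rho and p (undefined).
    """
    samples = [s for s in profile.columns if s in phenotype]
    if exclude_zero_mass:
        totals = profile[samples].sum(axis=0)
        samples = [s for s in samples if totals[s] > 0]
    if len(samples) < 3:
        raise ValueError(
            f"need >= 3 samples with phenotype values, found {len(samples)}"
        )
    y = np.asarray([phenotype[s] for s in samples], dtype=float)
    x = profile[samples].to_numpy(dtype=float)
    constant = np.ptp(x, axis=1) == 0
    rho = np.full(len(profile), np.nan)
    p = np.full(len(profile), np.nan)
    usable = np.flatnonzero(~constant)
    if usable.size == 1:
        res = sps.spearmanr(x[usable[0]], y)
        rho[usable[0]] = res.statistic
        p[usable[0]] = res.pvalue
    elif usable.size > 1:
        with np.errstate(invalid="ignore"):
            res = sps.spearmanr(x[usable].T, y)
        rho[usable] = np.asarray(res.statistic)[:-1, -1]
        p[usable] = np.asarray(res.pvalue)[:-1, -1]
    return pd.DataFrame(
        {"spearman_rho": rho, "spearman_p": p, "n_samples": len(samples)},
        index=profile.index,
    )
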