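"""Per-sample CAZyme profiles from bin abundances and protein annotations.

The central transformation of the pipeline: per-protein CAZyme domain
annotations are aggregated per bin (optionally through the linkage-target
ontology, with fractional weights for multi-target families), weighted by
each bin's relative DNA abundance in every sample, and re-scaled so every
sample's feature profile sums to 100%.  Group means ± SD over the animals
of a diet group are then taken from these per-sample profiles.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .ontology import TargetMapping

logger = logging.getLogger(__name__)

__all__ = [
    "parse_taxonomy",
    "phylum_of",
    "filter_bins",
    "bin_feature_counts",
    "sample_profiles",
    "zero_mass_samples",
    "group_summary",
    "phylum_abundance",
]

#: Completeness (%) below which a bin is not considered a partial genome.
DEFAULT_MIN_COMPLETENESS = 10.0

_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

UNKNOWN_PHYLUM = "Unknown phylum"


def parse_taxonomy(taxonomy: str) -> dict[str, str]:
    """Parse a GTDB-style 7-rank taxonomy string into a rank → name dict.

    Missing or empty trailing ranks yield empty strings; an unparseable
    string yields all-empty ranks rather than raising, mirroring how
    unclassifiable bins are summarised under "Unknown phylum".
    """
    out = dict.fromkeys(_RANKS, "")
    if not isinstance(taxonomy, str):
        return out
    for part in taxonomy.split(";"):
        part = part.strip()
        for rank, prefix in zip(_RANKS, _PREFIXES):
            if part.startswith(prefix):
                out[rank] = part[len(prefix):].strip()
                break
    return out


def phylum_of(taxonomy: str) -> str:
    """Phylum name of a taxonomy string, or ``"Unknown phylum"``."""
    return parse_taxonomy(taxonomy)["phylum"] or UNKNOWN_PHYLUM


def filter_bins(
    bins: pd.DataFrame, min_completeness: float = DEFAULT_MIN_COMPLETENESS
) -> pd.DataFrame:
    """Bins admitted to analysis: completeness >= *min_completeness* %."""
    kept = bins[bins["completeness"] >= min_completeness]
    logger.info(
        "completeness >= %.4g%%: kept %d of %d bins",
        min_completeness, len(kept), len(bins),
    )
    return kept


def bin_feature_counts(
    annotations: pd.DataFrame,
    mapping: Optional[TargetMapping] = None,
    feature_kind: str = "linkage_target",
) -> pd.DataFrame:
    """Bin-by-feature matrix of (weighted) CAZyme domain counts.

    Parameters
    ----------
    annotations:
        One row per CAZyme domain with columns ``protein_id``, ``bin_id``,
        ``family`` and optional ``cupp_group``.
    mapping:
        Linkage-target ontology; required for ``feature_kind="linkage_target"``.
    feature_kind:
        ``"family"`` counts CAZy families directly; ``"linkage_target"``
        resolves each domain through the ontology and sums the fractional
        target weights (domains of unknown families contribute nothing).

    Returns
    -------
    DataFrame indexed by bin id with one column per feature.
    """
    if feature_kind not in ("family", "linkage_target"):
        raise ValueError(
            f"feature_kind must be 'family' or 'linkage_target', got {feature_kind!r}"
        )
    ann = annotations.copy()
    if "cupp_group" not in ann.columns:
        ann["cupp_group"] = ""
    ann["cupp_group"] = ann["cupp_group"].fillna("").astype(str)

    if feature_kind == "family":
        counts = pd.crosstab(ann["bin_id"], ann["family"]).astype(float)
        counts.index.name = "bin_id"
        counts.columns.name = "feature"
        return counts

    if mapping is None:
        raise ValueError("a TargetMapping is required for linkage_target counts")

    # Resolve each distinct (family, group) key once, then aggregate the
    # per-key domain counts into weighted target columns.
    key_counts = (
        ann.groupby(["bin_id", "family", "cupp_group"]).size().reset_index(name="n")
    )
    records: dict[tuple[str, str], float] = {}
    for row in key_counts.itertuples(index=False):
        for target, weight in mapping.resolve_weighted(row.family, row.cupp_group):
            key = (row.bin_id, target.canonical())
            records[key] = records.get(key, 0.0) + weight * row.n
    if not records:
        counts = pd.DataFrame(index=pd.Index(sorted(ann["bin_id"].unique()),
                                             name="bin_id"))
        counts.columns.name = "feature"
        return counts
    series = pd.Series(records)
    counts = series.unstack(fill_value=0.0)
    counts.index.name = "bin_id"
    counts.columns.name = "feature"
    # Bins whose domains all resolved to nothing still get an all-zero row.
    missing = sorted(set(ann["bin_id"]) - set(counts.index))
    if missing:
        counts = counts.reindex(counts.index.union(missing), fill_value=0.0)
    return counts


def sample_profiles(
    counts: pd.DataFrame, abundances: pd.DataFrame
) -> pd.DataFrame:
    """Percent-normalised feature-by-sample profile matrix.

    For sample *s*, the raw mass of feature *f* is
    ``sum_b abundance(b, s) * counts(b, f)``; every sample column is then
    rescaled to sum to 100.  Samples with zero total feature mass are kept
    as all-zero columns and logged.
    """
    unknown = set(counts.index) - set(abundances.index)
    if unknown:
        raise ValueError(
            f"count matrix references bins missing from the abundance matrix: "
            f"{sorted(unknown)[:5]}"
        )
    common = counts.index
    mass = counts.T.to_numpy(dtype=float) @ abundances.loc[common].to_numpy(dtype=float)
    # copy the axis labels: .name assignments below must not leak back
    # into the caller's matrices through shared Index objects
    profile = pd.DataFrame(mass, index=counts.columns.copy(),
                           columns=abundances.columns.copy())
    totals = profile.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        logger.warning(
            "samples with zero CAZyme mass left as all-zero columns: %s",
            ", ".join(map(str, profile.columns[zero])),
        )
    scale = totals.where(~zero, 1.0)
    profile = profile.div(scale, axis=1) * 100.0
    profile.loc[:, zero] = 0.0
    profile.index.name = "feature"
    profile.columns.name = "sample"
    return profile


def zero_mass_samples(profile: pd.DataFrame) -> list[str]:
    """Sample ids whose profile column is all-zero (no CAZyme mass)."""
    return list(profile.columns[(profile.sum(axis=0) <= 0)])


def group_summary(
    profile: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-feature per-group mean ± sample SD over each group's columns.

    Returns a DataFrame indexed like *profile* with a two-level column
    index ``(group, statistic)``.  Groups with a single sample get ``NaN``
    SD (undefined, not 0).
    """
    unlabeled = [s for s in profile.columns if s not in groups]
    if unlabeled:
        raise ValueError(f"samples without a group label: {unlabeled}")
    pieces = {}
    for group in dict.fromkeys(groups.values()):
        cols = [s for s in profile.columns if groups[s] == group]
        if not cols:
            continue
        sub = profile[cols]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1) if len(cols) > 1 else pd.Series(
            np.nan, index=profile.index
        )
        pieces[(group, "mean")] = mean
        pieces[(group, "sd")] = sd
    out = pd.DataFrame(pieces)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["group", "stat"])
    return out


def phylum_abundance(
    bins: pd.DataFrame,
    abundances: pd.DataFrame,
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Per-phylum summed abundance, summarised per group, plus bin counts.

    Bin abundances are summed over the member bins of each phylum per
    sample, then the group mean ± SD is taken.  Bins with unparseable
    taxonomy fall into ``"Unknown phylum"``.
    """
    phyla = bins["taxonomy"].map(phylum_of)
    phyla.index = bins["bin_id"] if "bin_id" in bins.columns else bins.index
    common = [b for b in abundances.index if b in set(phyla.index)]
    if len(common) < len(abundances.index):
        missing = set(abundances.index) - set(common)
        raise ValueError(f"abundance matrix has bins absent from the bin table: "
                         f"{sorted(missing)[:5]}")
    sums = abundances.groupby(phyla.reindex(abundances.index)).sum()
    sums.index.name = "phylum"
    summary = group_summary(sums, groups)
    counts = phyla.reindex(abundances.index).value_counts()
    summary[("bins", "n")] = counts.reindex(summary.index).fillna(0).astype(int)
    return summary
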