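"""End-to-end analysis pipeline and run manifest.

Reproduces the analysis order of the motivating study on any consistent
set of input tables: completeness filter → phylum summary with letters →
per-bin classification → CAZy-family contrast → linkage-target contrast →
phenotype correlations → sample ordinations with separation scores →
binary Jaccard/Ward tree of the significantly changed bins and targets.
Every output is TSV/JSON under one output directory, together with a
manifest (input checksums, parameters, versions) that makes the run
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__, clustering, io, ordination, profiles, stats
from .ontology import TargetMapping, default_mapping

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunBundle", "run_pipeline", "analyse_study"]

PathLike = Union[str, Path]


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    bins: PathLike
    abundance: PathLike
    annotations: PathLike
    metadata: PathLike
    outdir: PathLike
    mapping: Optional[PathLike] = None  # None -> packaged default ontology
    reference: str = "Standard"
    contrast: str = "Extreme"
    alpha: float = 0.05
    min_change: float = 20.0
    completeness_min: float = 10.0
    separation_variant: str = "sum"
    correlation_method: str = "spearman"
    phenotype_column: str = "ch4_l_per_kg_dmi"
    seed: int = 0

    def validate(self) -> None:
        for name in ("bins", "abundance", "annotations", "metadata"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise FileNotFoundError(f"{name} table not found: {path}")
        if self.mapping is not None and not Path(self.mapping).exists():
            raise FileNotFoundError(f"mapping table not found: {self.mapping}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_change < 0:
            raise ValueError("min_change must be >= 0")
        if not 0 <= self.completeness_min <= 100:
            raise ValueError("completeness_min must lie in [0, 100]")
        if self.separation_variant not in ("sum", "mean"):
            raise ValueError("separation_variant must be 'sum' or 'mean'")
        if self.correlation_method not in ("spearman", "pearson"):
            raise ValueError("correlation_method must be 'spearman' or 'pearson'")


@dataclass
class RunBundle:
    """In-memory results of a pipeline run."""

    phylum_summary: pd.DataFrame
    bin_classification: pd.DataFrame
    bin_class_counts: pd.DataFrame
    family_results: pd.DataFrame
    target_results: pd.DataFrame
    embeddings: dict[str, pd.DataFrame]
    separation_scores: dict[str, float]
    tree: Optional[clustering.DendrogramTree]
    newick: Optional[str]
    tree_annotations: Optional[pd.DataFrame]
    summary: dict
    manifest: dict = field(default_factory=dict)


def _sha256(path: PathLike) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _ordinate(
    profile: pd.DataFrame,
    metadata: pd.DataFrame,
    config: RunConfig,
) -> tuple[pd.DataFrame, float]:
    """Embed samples in 2-D and score the reference/contrast separation."""
    distances = ordination.correlation_distance(
        profile, method=config.correlation_method
    )
    embedding = ordination.embed_2d(distances)
    coords = embedding.coordinates.copy()
    group_of = dict(zip(metadata["sample_id"], metadata["group"]))
    coords.insert(0, "group", [group_of[s] for s in coords.index])
    ref_points = coords.loc[coords["group"] == config.reference, ["x", "y"]]
    con_points = coords.loc[coords["group"] == config.contrast, ["x", "y"]]
    score = ordination.separation_score(
        ordination.PointCluster(config.reference, ref_points.to_numpy()),
        ordination.PointCluster(config.contrast, con_points.to_numpy()),
        variant=config.separation_variant,
    )
    return coords, score


def analyse_study(
    bins: pd.DataFrame,
    abundance: pd.DataFrame,
    annotations: pd.DataFrame,
    metadata: pd.DataFrame,
    mapping: TargetMapping,
    config: RunConfig,
) -> RunBundle:
    """Run the full analysis on in-memory tables (no file I/O)."""
    groups = dict(zip(metadata["sample_id"], metadata["group"]))
    for name in (config.reference, config.contrast):
        if name not in set(groups.values()):
            raise ValueError(f"group {name!r} not present in the metadata")
    phenotype = dict(
        zip(metadata["sample_id"], metadata[config.phenotype_column])
    )

    # 1. completeness filter
    kept_bins = profiles.filter_bins(bins, config.completeness_min)
    kept_ids = [b for b in abundance.index if b in set(kept_bins["bin_id"])]
    if not kept_ids:
        raise ValueError("no bins survive the completeness filter")
    abund = abundance.loc[kept_ids]
    ann = annotations[annotations["bin_id"].isin(kept_ids)]
    logger.info("analysis set: %d bins, %d CAZyme domains, %d samples",
                len(kept_ids), len(ann), abund.shape[1])

    # 2. phylum summary with compact letters and a reference->contrast trend
    phylum_summary = _phylum_stage(kept_bins, abund, groups, config)

    # 3. per-bin classification
    classification = stats.classify_bins(
        abund, groups, config.reference, config.contrast, config.alpha
    )
    class_counts = stats.phylum_classification_counts(classification, kept_bins)

    # 4./5. family and target contrasts with phenotype correlation
    family_counts = profiles.bin_feature_counts(ann, mapping, "family")
    family_profile = profiles.sample_profiles(family_counts, abund)
    family_results = _contrast_stage(family_profile, groups, phenotype, config)

    target_counts = profiles.bin_feature_counts(ann, mapping, "linkage_target")
    target_profile = profiles.sample_profiles(target_counts, abund)
    target_results = _contrast_stage(target_profile, groups, phenotype, config)
    logger.info(
        "differential features: %d/%d families, %d/%d targets significant",
        int(family_results["significant"].sum()), len(family_results),
        int(target_results["significant"].sum()), len(target_results),
    )

    # 6. ordinations of the samples on bins, families and targets
    embeddings, scores = {}, {}
    for name, profile in (
        ("bins", abund), ("families", family_profile), ("targets", target_profile)
    ):
        coords, score = _ordinate(profile, metadata, config)
        embeddings[name] = coords
        scores[name] = score
    logger.info("separation scores (%s variant): %s", config.separation_variant,
                {k: round(v, 3) for k, v in scores.items()})

    # 7. binary Jaccard/Ward tree: significant bins x significant targets
    significant_bins = classification.index[
        classification["direction"] != stats.NOT_SIGNIFICANT
    ]
    significant_targets = list(
        target_results.index[target_results["significant"]]
    )
    tree = newick = annotations_table = None
    if len(significant_bins) >= 2 and significant_targets:
        observed = [t for t in significant_targets if t in target_counts.columns]
        binary = clustering.binary_matrix(
            target_counts.reindex(significant_bins, fill_value=0.0), observed
        )
        tree = clustering.ward_tree(clustering.jaccard_distance(binary))
        newick = clustering.export_newick(tree)
        phylum = dict(zip(kept_bins["bin_id"],
                          kept_bins["taxonomy"].map(profiles.phylum_of)))
        ref_cols = [s for s, g in groups.items() if g == config.reference]
        con_cols = [s for s, g in groups.items() if g == config.contrast]
        annotations_table = clustering.leaf_annotations(
            tree, binary, phylum,
            abund[ref_cols].mean(axis=1), abund[con_cols].mean(axis=1),
        )
    else:
        logger.warning("tree stage skipped: %d significant bins, %d targets",
                       len(significant_bins), len(significant_targets))

    summary = {
        "n_bins_input": int(len(bins)),
        "n_bins_analysed": int(len(kept_ids)),
        "n_cazyme_domains": int(len(ann)),
        "n_families_observed": int(family_profile.shape[0]),
        "n_targets_observed": int(target_profile.shape[0]),
        "n_bins_reference_dominant": int(
            (classification["direction"] == stats.REFERENCE_DOMINANT).sum()
        ),
        "n_bins_contrast_dominant": int(
            (classification["direction"] == stats.CONTRAST_DOMINANT).sum()
        ),
        "n_bins_not_significant": int(
            (classification["direction"] == stats.NOT_SIGNIFICANT).sum()
        ),
        "n_families_significant": int(family_results["significant"].sum()),
        "n_targets_significant": int(target_results["significant"].sum()),
        "separation_scores": {k: float(v) for k, v in scores.items()},
        "separation_variant": config.separation_variant,
        "reference": config.reference,
        "contrast": config.contrast,
    }
    return RunBundle(
        phylum_summary, classification, class_counts, family_results,
        target_results, embeddings, scores, tree, newick, annotations_table,
        summary,
    )


def _phylum_stage(bins, abund, groups, config) -> pd.DataFrame:
    summary = profiles.phylum_abundance(bins, abund, groups)
    phyla = bins.set_index("bin_id")["taxonomy"].map(profiles.phylum_of)
    sums = abund.groupby(phyla.reindex(abund.index)).sum()
    group_names = list(dict.fromkeys(groups.values()))
    flat = pd.DataFrame(index=summary.index)
    for g in group_names:
        flat[f"mean_{g}"] = summary[(g, "mean")]
        flat[f"sd_{g}"] = summary[(g, "sd")]
    letter_col, trend_col = [], []
    for phylum in flat.index:
        values = {
            g: sums.loc[phylum, [s for s, gg in groups.items() if gg == g]]
            .to_numpy() for g in group_names
        }
        letter_map = stats.letters(values, config.alpha)
        letter_col.append("".join(letter_map[g] for g in group_names))
        test = stats.two_sample_t(values[config.reference],
                                  values[config.contrast])
        if test.p_value <= config.alpha:
            ref_mean = values[config.reference].mean()
            con_mean = values[config.contrast].mean()
            trend_col.append("Increase" if con_mean > ref_mean else "Decrease")
        else:
            trend_col.append("No change")
    flat["letters"] = letter_col
    flat["trend"] = trend_col
    flat["n_bins"] = summary[("bins", "n")]
    return flat


def _contrast_stage(profile, groups, phenotype, config) -> pd.DataFrame:
    results = stats.filter_features(
        profile, groups, config.reference, config.contrast,
        alpha=config.alpha, min_change=config.min_change,
    )
    spearman = stats.spearman_phenotype(profile, phenotype)
    return results.join(spearman[["spearman_rho", "spearman_p"]])


def run_pipeline(config: RunConfig) -> RunBundle:
    """Read the inputs, run the analysis, write the result bundle to disk."""
    config.validate()
    bins = io.read_bin_table(config.bins)
    abundance = io.read_abundance_matrix(config.abundance)
    annotations = io.read_annotations(config.annotations)
    metadata = io.read_metadata(config.metadata, config.phenotype_column)
    mapping = (
        default_mapping() if config.mapping is None
        else io.read_mapping(config.mapping)
    )
    bundle = analyse_study(bins, abundance, annotations, metadata, mapping,
                           config)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"cazlink v{__version__}"
    io.write_tsv(bundle.phylum_summary, outdir / "phylum_summary.tsv",
                 comment=stamp)
    io.write_tsv(bundle.bin_classification, outdir / "bin_classification.tsv",
                 comment=stamp)
    io.write_tsv(bundle.bin_class_counts, outdir / "bin_class_counts.tsv",
                 comment=stamp)
    io.write_tsv(bundle.family_results, outdir / "family_differential.tsv",
                 comment=stamp)
    io.write_tsv(bundle.target_results, outdir / "target_differential.tsv",
                 comment=stamp)
    for name, coords in bundle.embeddings.items():
        io.write_tsv(coords, outdir / f"embedding_{name}.tsv", comment=stamp)
    if bundle.newick is not None:
        (outdir / "tree.nwk").write_text(bundle.newick + "\n", encoding="utf-8")
        io.write_tsv(bundle.tree_annotations, outdir / "tree_annotations.tsv",
                     comment=stamp)
    (outdir / "run_summary.json").write_text(
        json.dumps(bundle.summary, indent=2, sort_keys=True), encoding="utf-8"
    )

    manifest = {
        "package": "cazlink",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
        "inputs": {
            name: _sha256(getattr(config, name))
            for name in ("bins", "abundance", "annotations", "metadata")
        },
    }
    if config.mapping is not None:
        manifest["inputs"]["mapping"] = _sha256(config.mapping)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    bundle.manifest = manifest
    return bundle
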