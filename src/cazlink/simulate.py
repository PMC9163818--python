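"""Seedable generator of complete synthetic rumen metagenome studies.

Emits the five input tables of the pipeline (bin table, bin-by-sample
abundance matrix, per-protein CAZyme annotations, linkage-target mapping,
sample metadata with a CH4-like phenotype) together with a ground-truth
ledger of every planted effect, so that each pipeline stage can be tested
end-to-end without any download.

The default configuration mirrors the structure of the motivating feeding
trial: 3 diet groups × 4 animals, ~500 bins spread over 15 phyla with a
heavy-tailed (lognormal) abundance distribution, multiplicative
within-group noise, a planted fraction of bins with a group fold-change,
a handful of starch-rich "takeover" bins dominating the contrast group,
phylum-conditioned CAZyme repertoires, and a phenotype linearly coupled
(plus Gaussian noise) to the normalised abundance of selected linkage
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import profiles
from .ontology import TargetMapping, default_mapping

__all__ = ["SimulationConfig", "SyntheticStudy", "simulate", "write_study"]


# Phylum universe with sampling weights proportional to the reference
# trial's per-phylum bin counts; domain and CAZyme repertoire class per
# phylum.  Classes: "archaeal" (nearly CAZyme-free), "fibrolytic"
# (pectin/xylan/cellulose-leaning), "amylolytic" (starch/glucan-leaning),
# "generalist".
_PHYLA: tuple[tuple[str, int, str, str], ...] = (
    ("Crenarchaeota", 1, "Archaea", "archaeal"),
    ("Euryarchaeota", 13, "Archaea", "archaeal"),
    ("Actinobacteriota", 18, "Bacteria", "amylolytic"),
    ("Bacteroidota", 157, "Bacteria", "fibrolytic"),
    ("Chloroflexota", 1, "Bacteria", "generalist"),
    ("Cyanobacteria", 5, "Bacteria", "generalist"),
    ("Desulfobacterota_A", 1, "Bacteria", "generalist"),
    ("Fibrobacterota", 4, "Bacteria", "fibrolytic"),
    ("Firmicutes", 30, "Bacteria", "amylolytic"),
    ("Firmicutes_A", 272, "Bacteria", "generalist"),
    ("Firmicutes_C", 11, "Bacteria", "amylolytic"),
    ("Patescibacteria", 14, "Bacteria", "generalist"),
    ("Proteobacteria", 4, "Bacteria", "amylolytic"),
    ("Verrucomicrobiota", 1, "Bacteria", "fibrolytic"),
    ("Unknown phylum", 29, "Bacteria", "generalist"),
)

_DEFAULT_PHYLUM_WEIGHTS = {
    name: count / sum(c for _, c, _, _ in _PHYLA) for name, count, _, _ in _PHYLA
}

#: Mean CAZyme domains per bin for each repertoire class (Poisson rate).
_DEFAULT_CAZYME_RATES = {
    "archaeal": 2.0,
    "fibrolytic": 45.0,
    "amylolytic": 30.0,
    "generalist": 22.0,
}

#: Majors that define the two specialised repertoire leanings.
_FIBER_MAJORS = frozenset({"Pectin", "Xylan", "Homoxylan", "Cellulose",
                           "Xyloglucan", "Arabinan", "Mannan",
                           "Arabinogalactan proteins"})
_STARCH_MAJORS = frozenset({"Starch", "Glucan", "Inulin", "Pullulan",
                            "Sucrose", "Raffinose"})

_DEFAULT_COUPLED_TARGETS = (
    "Starch::Starch - Backbone::α-1,4::Glc",
    "Starch::Starch - Backbone::α-1,4::[Glc]n",
)

# Within-class family emphasis: real genomes devote a disproportionate
# share of their CAZyme domains to a few hallmark families (GH13 is the
# largest starch-active family; GH43/GH10/GH2/GH3 dominate fibre
# degraders), so the pools are not uniform over the primary set.
_HALLMARK_WEIGHTS = {
    "amylolytic": {"GH13": 12, "GH97": 4, "GH77": 3, "GH57": 3, "GH31": 3,
                   "GH32": 3, "GH15": 2, "GH1": 2, "GH4": 2},
    "fibrolytic": {"GH43": 6, "GH10": 4, "GH2": 4, "GH3": 4, "GH5": 3,
                   "GH28": 3, "CE1": 3, "GH51": 2, "CE8": 2, "GH11": 2},
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; the defaults are the study conditions.

    ``lognormal_sd`` is the SD of the natural-log multiplicative
    within-group abundance noise.  ``planted_fraction`` of the bins get a
    ``planted_fold`` abundance change in the contrast (last) group, a
    ``planted_down_fraction`` of them in the downward direction (i.e.
    reference-dominant, mirroring the trial's 274:89 split);
    ``dominance`` starch-leaning bins additionally take over the contrast
    group at ``dominance_fold``.  The phenotype (CH4 L/kg DMI scale) is
    ``baseline - effect * sum(coupled-target %) + N(0, noise_sd)`` per
    sample.
    """

    seed: int = 0
    n_groups: int = 3
    samples_per_group: int = 4
    n_bins: int = 500
    phylum_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PHYLUM_WEIGHTS)
    )
    base_abundance_sd: float = 1.5
    lognormal_sd: float = 0.5
    planted_fraction: float = 0.10
    planted_fold: float = 4.0
    planted_down_fraction: float = 0.75
    dominance: int = 5
    dominance_fold: float = 25.0
    cazyme_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CAZYME_RATES)
    )
    phenotype_baseline: float = 25.3
    phenotype_effect: float = 1.0
    phenotype_noise_sd: float = 0.9
    coupled_targets: Sequence[str] = _DEFAULT_COUPLED_TARGETS
    low_completeness_bins: int = 0

    def validate(self) -> None:
        if self.n_groups < 2 or self.samples_per_group < 2:
            raise ValueError("need >= 2 groups and >= 2 samples per group")
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if not 0.0 <= self.planted_down_fraction <= 1.0:
            raise ValueError("planted_down_fraction must lie in [0, 1]")
        if self.planted_fold <= 0 or self.dominance_fold <= 0:
            raise ValueError("folds must be positive")
        if self.dominance < 0 or self.dominance > self.n_bins:
            raise ValueError("dominance must lie in [0, n_bins]")
        if self.lognormal_sd < 0 or self.phenotype_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if any(r < 0 for r in self.cazyme_rates.values()):
            raise ValueError("cazyme_rates must be non-negative")
        total = sum(self.phylum_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phylum_weights sum to {total!r}, expected 1")

    @property
    def group_names(self) -> list[str]:
        base = ["Standard", "High", "Extreme"]
        if self.n_groups <= 3:
            return base[: self.n_groups - 1] + ["Extreme"] if self.n_groups == 2 \
                else base[: self.n_groups]
        return base + [f"Group{i}" for i in range(4, self.n_groups + 1)]


@dataclass
class SyntheticStudy:
    """The five pipeline input tables plus the ground-truth ledger."""

    bins: pd.DataFrame
    abundance: pd.DataFrame
    annotations: pd.DataFrame
    metadata: pd.DataFrame
    mapping: TargetMapping
    ground_truth: pd.DataFrame
    config: SimulationConfig

    @property
    def reference_group(self) -> str:
        return self.config.group_names[0]

    @property
    def contrast_group(self) -> str:
        return self.config.group_names[-1]

    @property
    def planted_up(self) -> list[str]:
        gt = self.ground_truth
        return list(gt.loc[(gt["kind"] == "planted_bin") & (gt["fold"] > 1), "id"])

    @property
    def planted_down(self) -> list[str]:
        gt = self.ground_truth
        return list(gt.loc[(gt["kind"] == "planted_bin") & (gt["fold"] < 1), "id"])

    @property
    def dominant_bins(self) -> list[str]:
        gt = self.ground_truth
        return list(gt.loc[gt["kind"] == "dominant_bin", "id"])

    @property
    def coupled_targets(self) -> dict[str, float]:
        gt = self.ground_truth
        sub = gt[gt["kind"] == "coupled_target"]
        return dict(zip(sub["id"], sub["coefficient"]))


def _taxonomy(phylum: str, domain: str, index: int) -> str:
    if phylum == "Unknown phylum":
        return f"d__{domain}"
    return (
        f"d__{domain};p__{phylum};c__c{index % 7};o__o{index % 13};"
        f"f__f{index % 29};g__g{index % 97};s__s{index}"
    )


def _family_pools(mapping: TargetMapping) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per-class family pools with sampling probabilities.

    Fibrolytic bins draw 75% of domains from fibre-active families,
    amylolytic bins 70% from starch/glucan-active families; generalists
    draw uniformly; archaea draw from a small generic subset.
    """
    fibre, starch, other = set(), set(), set()
    for (family, _group), rule in mapping.rules.items():
        majors = {t.major_polysaccharide for t, _ in rule}
        if majors & _FIBER_MAJORS:
            fibre.add(family)
        if majors & _STARCH_MAJORS:
            starch.add(family)
        if not majors & (_FIBER_MAJORS | _STARCH_MAJORS):
            other.add(family)
    families = sorted(fibre | starch | other)
    idx = {f: i for i, f in enumerate(families)}

    def weights(primary: set, share: float,
                hallmark: Optional[Mapping[str, float]] = None) -> np.ndarray:
        w = np.full(len(families), (1 - share) / max(len(families) - len(primary), 1))
        mult = {f: (hallmark or {}).get(f, 1.0) for f in primary}
        total = sum(mult.values())
        for f in primary:
            w[idx[f]] = share * mult[f] / total
        return w / w.sum()

    uniform = np.full(len(families), 1.0 / len(families))
    return {
        "fibrolytic": (families, weights(fibre, 0.75,
                                         _HALLMARK_WEIGHTS["fibrolytic"])),
        "amylolytic": (families, weights(starch, 0.70,
                                         _HALLMARK_WEIGHTS["amylolytic"])),
        "generalist": (families, uniform),
        "archaeal": (families, weights(other or starch, 0.9)),
    }


def simulate(config: Optional[SimulationConfig] = None, **kwargs) -> SyntheticStudy:
    """Draw one complete synthetic study; the seed fixes every byte."""
    if config is None:
        config = SimulationConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config object or keyword overrides")
    config.validate()
    rng = np.random.default_rng(config.seed)
    mapping = default_mapping()
    groups = config.group_names
    info = {name: (domain, klass) for name, _, domain, klass in _PHYLA}

    # --- bins ------------------------------------------------------------
    n = config.n_bins
    phyla_names = list(config.phylum_weights)
    weights = np.asarray(list(config.phylum_weights.values()), dtype=float)
    phyla = rng.choice(phyla_names, size=n, p=weights / weights.sum())
    completeness = rng.uniform(10.0, 100.0, size=n)
    n_low = config.low_completeness_bins
    if n_low:
        phyla = np.concatenate([phyla, rng.choice(phyla_names, size=n_low,
                                                  p=weights / weights.sum())])
        completeness = np.concatenate([completeness, rng.uniform(2.0, 10.0 - 1e-9,
                                                                 size=n_low)])
    n_total = n + n_low
    bin_ids = [f"bin{i:04d}" for i in range(1, n_total + 1)]
    contamination = np.abs(rng.normal(0.0, 2.0, size=n_total))
    bins = pd.DataFrame(
        {
            "bin_id": bin_ids,
            "taxonomy": [
                _taxonomy(p, info.get(p, ("Bacteria", "generalist"))[0], i)
                for i, p in enumerate(phyla)
            ],
            "completeness": np.round(completeness, 2),
            "contamination": np.round(contamination, 2),
        }
    )

    # --- planted effects -------------------------------------------------
    analysed = np.arange(n)  # low-completeness spike-ins never carry effects
    n_planted = int(round(config.planted_fraction * n))
    planted = rng.choice(analysed, size=n_planted, replace=False)
    n_down = int(round(config.planted_down_fraction * n_planted))
    down, up = planted[:n_down], planted[n_down:]
    classes = np.array([info.get(p, ("Bacteria", "generalist"))[1] for p in phyla])
    starchy = np.setdiff1d(np.flatnonzero(classes[:n] == "amylolytic"), planted)
    n_dom = min(config.dominance, starchy.size)
    dominant = rng.choice(starchy, size=n_dom, replace=False) if n_dom else \
        np.empty(0, dtype=int)

    # --- abundances ------------------------------------------------------
    samples = [f"{g}_{i + 1}" for g in groups for i in range(config.samples_per_group)]
    group_of = {s: s.rsplit("_", 1)[0] for s in samples}
    base = rng.lognormal(mean=0.0, sigma=config.base_abundance_sd, size=n_total)
    noise = rng.lognormal(mean=0.0, sigma=config.lognormal_sd,
                          size=(n_total, len(samples)))
    value = base[:, None] * noise
    contrast_cols = [j for j, s in enumerate(samples)
                     if group_of[s] == groups[-1]]
    value[np.ix_(up, contrast_cols)] *= config.planted_fold
    value[np.ix_(down, contrast_cols)] /= config.planted_fold
    value[np.ix_(dominant, contrast_cols)] *= config.dominance_fold
    value = value / value.sum(axis=0, keepdims=True) * 100.0
    abundance = pd.DataFrame(value, index=pd.Index(bin_ids, name="bin_id"),
                             columns=samples)

    # --- CAZyme annotations ----------------------------------------------
    pools = _family_pools(mapping)
    rates = {k: config.cazyme_rates.get(k, 0.0) for k in pools}
    n_domains = rng.poisson(
        [rates[info.get(p, ("Bacteria", "generalist"))[1]] for p in phyla]
    )
    rows_bin, rows_fam = [], []
    for i, (bin_id, phylum) in enumerate(zip(bin_ids, phyla)):
        k = n_domains[i]
        if k == 0:
            continue
        fams, w = pools[info.get(phylum, ("Bacteria", "generalist"))[1]]
        chosen = rng.choice(len(fams), size=k, p=w)
        rows_bin.extend([bin_id] * k)
        rows_fam.extend(fams[c] for c in chosen)
    annotations = pd.DataFrame({"bin_id": rows_bin, "family": rows_fam})
    annotations.insert(0, "protein_id",
                       [f"prot{i:06d}" for i in range(1, len(annotations) + 1)])
    # a fifth of GH13 domains carry a resolving CUPP group
    annotations["cupp_group"] = ""
    gh13 = annotations.index[annotations["family"] == "GH13"]
    tagged = gh13[rng.random(gh13.size) < 0.2]
    annotations.loc[tagged, "cupp_group"] = rng.choice(
        ["GH13_11", "GH13_14"], size=tagged.size
    )

    # --- phenotype --------------------------------------------------------
    counts = profiles.bin_feature_counts(annotations, mapping, "linkage_target")
    profile = profiles.sample_profiles(counts, abundance)
    coupled = [t for t in config.coupled_targets if t in profile.index]
    missing = set(config.coupled_targets) - set(coupled)
    if missing:
        raise ValueError(f"coupled targets absent from the generated profiles: "
                         f"{sorted(missing)}")
    coupled_sum = profile.loc[coupled].sum(axis=0)
    phenotype = (
        config.phenotype_baseline
        - config.phenotype_effect * coupled_sum
        + rng.normal(0.0, config.phenotype_noise_sd, size=len(samples))
    )
    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "animal": [f"cow{i + 1:02d}" for i in range(len(samples))],
            "group": [group_of[s] for s in samples],
            "ch4_l_per_kg_dmi": np.round(phenotype.to_numpy(), 4),
        }
    )

    # --- ground truth -----------------------------------------------------
    records = []
    for idx in up:
        records.append(("planted_bin", bin_ids[idx], config.planted_fold, np.nan))
    for idx in down:
        records.append(("planted_bin", bin_ids[idx], 1.0 / config.planted_fold,
                        np.nan))
    for idx in dominant:
        records.append(("dominant_bin", bin_ids[idx], config.dominance_fold,
                        np.nan))
    for t in coupled:
        records.append(("coupled_target", t, np.nan, -config.phenotype_effect))
    ground_truth = pd.DataFrame(records,
                                columns=["kind", "id", "fold", "coefficient"])
    return SyntheticStudy(bins, abundance, annotations, metadata, mapping,
                          ground_truth, config)


def write_study(study: SyntheticStudy, outdir: Union[str, Path]) -> dict[str, Path]:
    """Write the study's tables as TSV (plus config.yaml); returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# cazlink synthetic study, seed={study.config.seed}\n"
    paths = {}

    def _write(name: str, df: pd.DataFrame, index: bool) -> None:
        path = outdir / f"{name}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=index)
        paths[name] = path

    _write("bins", study.bins, index=False)
    _write("abundance", study.abundance, index=True)
    _write("annotations", study.annotations, index=False)
    _write("metadata", study.metadata, index=False)
    mapping_rows = [
        {"family": fam, "cupp_group": grp, "major": t.major_polysaccharide,
         "branch": t.branch, "specific": t.specific_target, "weight": w}
        for (fam, grp), rule in sorted(study.mapping.rules.items())
        for t, w in rule
    ]
    _write("mapping", pd.DataFrame(mapping_rows), index=False)
    _write("ground_truth", study.ground_truth, index=False)
    config_path = outdir / "config.yaml"
    payload = asdict(study.config)
    payload["phylum_weights"] = dict(payload["phylum_weights"])
    payload["cazyme_rates"] = dict(payload["cazyme_rates"])
    payload["coupled_targets"] = list(payload["coupled_targets"])
    config_path.write_text(yaml.safe_dump(payload, allow_unicode=True,
                                          sort_keys=False), encoding="utf-8")
    paths["config"] = config_path
    return paths
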