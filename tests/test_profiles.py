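"""Profile construction: counts, normalisation, group and phylum summaries."""

import numpy as np
import pandas as pd
import pytest

from cazlink.ontology import load_mapping
from cazlink.profiles import (
    bin_feature_counts,
    filter_bins,
    group_summary,
    parse_taxonomy,
    phylum_abundance,
    phylum_of,
    sample_profiles,
    zero_mass_samples,
)


class TestTaxonomy:
    def test_full_string(self):
        ranks = parse_taxonomy(
            "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
            "f__F082;g__Prevotella;s__Prevotella copri"
        )
        assert ranks["phylum"] == "Bacteroidota"
        assert ranks["species"] == "Prevotella copri"

    def test_missing_ranks_are_empty(self):
        ranks = parse_taxonomy("d__Archaea;p__Euryarchaeota")
        assert ranks["genus"] == "" and ranks["species"] == ""

    @pytest.mark.parametrize("junk", ["", "not a taxonomy", None, "d__Bacteria"])
    def test_unparseable_phylum_is_unknown(self, junk):
        assert phylum_of(junk) == "Unknown phylum"


class TestBinFeatureCounts:
    def annotations(self, families, bin_id="binA"):
        return pd.DataFrame(
            {
                "protein_id": [f"p{i}" for i in range(len(families))],
                "bin_id": bin_id,
                "family": families,
                "cupp_group": "",
            }
        )

    def test_family_counts_worked_example(self):
        counts = bin_feature_counts(
            self.annotations(["GH13", "GH13", "GH43"]), feature_kind="family"
        )
        assert counts.loc["binA", "GH13"] == 2
        assert counts.loc["binA", "GH43"] == 1

    def test_weight_split_halves_one_domain(self, tiny_mapping):
        m = load_mapping(tiny_mapping)
        counts = bin_feature_counts(self.annotations(["GH43"]), m,
                                    "linkage_target")
        assert sorted(counts.loc["binA"]) == [0.5, 0.5]

    def test_total_weight_matches_per_protein_loop(self, mapping, rng):
        families = rng.choice(mapping.families, size=50)
        bins = rng.choice(["b1", "b2", "b3"], size=50)
        ann = pd.DataFrame({"protein_id": [f"p{i}" for i in range(50)],
                            "bin_id": bins, "family": families,
                            "cupp_group": ""})
        counts = bin_feature_counts(ann, mapping, "linkage_target")
        # brute-force oracle: resolve every protein individually
        expected = sum(
            w for fam in families for _, w in mapping.resolve_weighted(fam)
        )
        assert counts.to_numpy().sum() == pytest.approx(expected, abs=1e-9)

    def test_unknown_feature_kind_rejected(self):
        with pytest.raises(ValueError, match="feature_kind"):
            bin_feature_counts(self.annotations(["GH13"]),
                               feature_kind="protein")


class TestSampleProfiles:
    def test_weighted_sum_worked_example(self):
        counts = pd.DataFrame({"starch": [2, 0], "xylan": [0, 2]},
                              index=["b1", "b2"])
        abundance = pd.DataFrame({"cow1": [0.75, 0.25]}, index=["b1", "b2"])
        profile = sample_profiles(counts, abundance)
        assert profile.loc["starch", "cow1"] == pytest.approx(75.0)
        assert profile.loc["xylan", "cow1"] == pytest.approx(25.0)

    def test_columns_sum_to_100(self, small_study, mapping):
        counts = bin_feature_counts(small_study.annotations, mapping,
                                    "linkage_target")
        profile = sample_profiles(counts, small_study.abundance)
        np.testing.assert_allclose(profile.sum(axis=0), 100.0, atol=1e-6)

    def test_zero_mass_sample_kept_and_flagged(self):
        counts = pd.DataFrame({"starch": [1]}, index=["b1"])
        abundance = pd.DataFrame({"cow1": [2.0], "cow2": [0.0]}, index=["b1"])
        profile = sample_profiles(counts, abundance)
        assert zero_mass_samples(profile) == ["cow2"]
        assert (profile["cow2"] == 0).all()

    def test_scale_invariance_per_sample(self, small_study, mapping):
        counts = bin_feature_counts(small_study.annotations, mapping,
                                    "linkage_target")
        abundance = small_study.abundance.copy()
        profile = sample_profiles(counts, abundance)
        scaled = abundance.copy()
        scaled.iloc[:, 0] *= 17.3
        rescaled = sample_profiles(counts, scaled)
        pd.testing.assert_frame_equal(profile, rescaled)

    def test_unknown_bin_rejected(self):
        counts = pd.DataFrame({"starch": [1]}, index=["ghost"])
        abundance = pd.DataFrame({"cow1": [1.0]}, index=["b1"])
        with pytest.raises(ValueError, match="ghost"):
            sample_profiles(counts, abundance)


class TestGroupSummary:
    def test_mean_and_sample_sd(self):
        profile = pd.DataFrame([[10.4, 10.6, 10.8, 10.6]], index=["f"],
                               columns=list("abcd"))
        groups = dict.fromkeys("abcd", "Standard")
        out = group_summary(profile, groups)
        assert out.loc["f", ("Standard", "mean")] == pytest.approx(10.6)
        assert out.loc["f", ("Standard", "sd")] == pytest.approx(0.1633, abs=1e-4)

    def test_identical_columns_have_zero_sd(self):
        profile = pd.DataFrame([[3.0, 3.0], [7.0, 7.0]], columns=["a", "b"])
        out = group_summary(profile, {"a": "g", "b": "g"})
        assert (out[("g", "sd")] == 0).all()

    def test_single_sample_group_sd_is_undefined(self):
        profile = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"])
        out = group_summary(profile, {"a": "g1", "b": "g2"})
        assert np.isnan(out.loc[0, ("g1", "sd")])

    def test_group_means_of_normalised_profile_sum_to_100(self, small_study,
                                                          mapping):
        counts = bin_feature_counts(small_study.annotations, mapping, "family")
        profile = sample_profiles(counts, small_study.abundance)
        groups = dict(zip(small_study.metadata.sample_id,
                          small_study.metadata.group))
        out = group_summary(profile, groups)
        for g in set(groups.values()):
            assert out[(g, "mean")].sum() == pytest.approx(100.0, abs=1e-6)

    def test_unlabeled_sample_rejected(self):
        profile = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            group_summary(profile, {"a": "g"})


class TestPhylumAbundance:
    def test_two_bins_one_phylum(self):
        bins = pd.DataFrame({
            "bin_id": ["b1", "b2"],
            "taxonomy": ["d__Bacteria;p__Bacteroidota"] * 2,
            "completeness": [50.0, 60.0],
            "contamination": [1.0, 1.0],
        })
        abundance = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [1.0, 2.0]}, index=["b1", "b2"]
        )
        out = phylum_abundance(bins, abundance, {"s1": "g", "s2": "g"})
        assert out.loc["Bacteroidota", ("g", "mean")] == pytest.approx(3.0)
        assert out.loc["Bacteroidota", ("g", "sd")] == pytest.approx(0.0)
        assert out.loc["Bacteroidota", ("bins", "n")] == 2

    def test_counts_partition_and_sums_match_loop(self, small_study):
        study = small_study
        groups = dict(zip(study.metadata.sample_id, study.metadata.group))
        out = phylum_abundance(study.bins, study.abundance, groups)
        assert out[("bins", "n")].sum() == len(study.abundance)
        # brute-force per-bin loop oracle for one group's mean
        group = study.metadata.group.iloc[0]
        cols = study.metadata.loc[study.metadata.group == group, "sample_id"]
        phyla = study.bins.set_index("bin_id")["taxonomy"].map(phylum_of)
        for phylum in out.index:
            members = [b for b in study.abundance.index if phyla[b] == phylum]
            expected = study.abundance.loc[members, cols].sum(axis=0).mean()
            assert out.loc[phylum, (group, "mean")] == pytest.approx(expected)


class TestCompletenessFilter:
    def test_low_completeness_bins_dropped(self):
        bins = pd.DataFrame({
            "bin_id": ["ok", "low"],
            "taxonomy": ["d__Bacteria"] * 2,
            "completeness": [10.0, 9.99],
            "contamination": [0.0, 0.0],
        })
        kept = filter_bins(bins)
        assert list(kept["bin_id"]) == ["ok"]
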