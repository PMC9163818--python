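"""Group-contrast statistics: t-test, classification, letters, dual filter,
Spearman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cazlink.stats import (
    NOT_SIGNIFICANT,
    REFERENCE_DOMINANT,
    classify_bins,
    filter_features,
    letters,
    phylum_classification_counts,
    spearman_phenotype,
    two_sample_t,
)
from conftest import make_profile


def pooled_t(x, y):
    """Independent oracle: textbook pooled-variance t statistic."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
        len(x) + len(y) - 2
    )
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))


def permutation_p(x, y, n_perm, rng):
    """Monte-Carlo permutation p for the two-sided pooled t."""
    pooled = np.concatenate([x, y])
    t_obs = abs(pooled_t(x, y))
    order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    perm = pooled[order]
    px, py = perm[:, : len(x)], perm[:, len(x):]
    sp2 = (
        (len(x) - 1) * px.var(axis=1, ddof=1)
        + (len(y) - 1) * py.var(axis=1, ddof=1)
    ) / (len(x) + len(y) - 2)
    t_perm = (px.mean(axis=1) - py.mean(axis=1)) / np.sqrt(
        sp2 * (1 / len(x) + 1 / len(y))
    )
    return (np.abs(t_perm) >= t_obs - 1e-12).mean()


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_worked_example(self):
        res = two_sample_t([1, 2, 3, 4], [2, 3, 4, 5])
        assert res.statistic == pytest.approx(-1.095, abs=1e-3)
        assert res.p_value == pytest.approx(0.315, abs=1e-3)

    def test_matches_pooled_oracle(self, rng):
        x, y = rng.normal(0, 1, 5), rng.normal(0.5, 1, 7)
        res = two_sample_t(x, y)
        assert res.statistic == pytest.approx(pooled_t(x, y))

    def test_zero_variance_equal_means(self):
        res = two_sample_t([2, 2, 2], [2, 2])
        assert (res.statistic, res.p_value) == (0.0, 1.0)
        assert res.degenerate

    def test_zero_variance_unequal_means(self):
        res = two_sample_t([1, 1], [2, 2])
        assert res.p_value == 0.0 and res.degenerate

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1], [2, 3])

    def test_matches_permutation_oracle(self, rng):
        # 12 per group keeps the permutation null dense enough for the
        # Student-t reference distribution to apply
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        res = two_sample_t(x, y)
        p_perm = permutation_p(x, y, 20_000, rng)
        assert res.p_value == pytest.approx(p_perm, abs=0.02)


class TestClassifyBins:
    def abundances(self, rows):
        return pd.DataFrame(
            rows, index=[f"b{i}" for i in range(len(rows))],
            columns=[f"r{i}" for i in range(4)] + [f"c{i}" for i in range(4)],
        )

    groups = {f"r{i}": "ref" for i in range(4)} | {f"c{i}": "con" for i in range(4)}

    def test_clear_separation_is_reference_dominant(self):
        ab = self.abundances([[10, 11, 10, 11, 1, 1, 2, 1]])
        out = classify_bins(ab, self.groups, "ref", "con")
        assert out["direction"].iloc[0] == REFERENCE_DOMINANT

    def test_identical_values_not_significant(self):
        ab = self.abundances([[5, 6, 5, 6, 5, 6, 5, 6]])
        out = classify_bins(ab, self.groups, "ref", "con")
        assert out["direction"].iloc[0] == NOT_SIGNIFICANT

    def test_absent_bin_flagged(self):
        ab = self.abundances([[0] * 8])
        out = classify_bins(ab, self.groups, "ref", "con")
        assert out["direction"].iloc[0] == NOT_SIGNIFICANT
        assert bool(out["absent"].iloc[0])

    def test_null_type_one_error_near_alpha(self, rng):
        ab = self.abundances(rng.normal(10, 1, size=(2000, 8)))
        out = classify_bins(ab, self.groups, "ref", "con")
        frac = (out["direction"] != NOT_SIGNIFICANT).mean()
        assert frac == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / 2000))

    def test_counts_partition_bins(self, small_study):
        study = small_study
        groups = dict(zip(study.metadata.sample_id, study.metadata.group))
        cls = classify_bins(study.abundance, groups, "Standard", "Extreme")
        counts = phylum_classification_counts(cls, study.bins)
        body = counts.drop(index="Total")
        assert (body[["reference-dominant", "contrast-dominant",
                      "not-significant"]].sum(axis=1) == body["total"]).all()
        assert counts.loc["Total", "total"] == len(study.abundance)


class TestLetters:
    def test_all_mutually_different(self):
        out = letters({"a": [0, 0.1, 0, 0.1], "b": [5, 5.1, 5, 5.1],
                       "c": [10, 10.1, 10, 10.1]})
        assert [out[g] for g in "abc"] == ["A", "B", "C"]

    def test_all_indistinct(self):
        vals = {"a": [1, 2, 3, 4], "b": [1.1, 2.1, 3.1, 4.1],
                "c": [0.9, 1.9, 2.9, 3.9]}
        out = letters(vals)
        assert out["a"] == out["b"] == out["c"] == "A"

    def test_reference_pattern_a_a_b(self):
        # two similar groups, one strongly shifted group
        out = letters({
            "Standard": [0.40, 0.45, 0.50, 0.42],
            "High": [0.46, 0.44, 0.48, 0.46],
            "Extreme": [4.0, 5.0, 4.5, 3.8],
        })
        assert out["Standard"] == out["High"] == "A"
        assert out["Extreme"] == "B"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            letters({"only": [1, 2, 3]})

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(3, 5))
    def test_share_letter_iff_not_different(self, seed, k):
        rng = np.random.default_rng(seed)
        values = {
            f"g{i}": rng.normal(rng.uniform(0, 3), 1, size=4) for i in range(k)
        }
        out = letters(values)
        names = list(values)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                different = two_sample_t(values[a], values[b]).p_value <= 0.05
                share = bool(set(out[a]) & set(out[b]))
                assert share != different


class TestFilterFeatures:
    groups = {f"r{i}": "ref" for i in range(4)} | {f"c{i}": "con" for i in range(4)}

    def run(self, ref_values, con_values):
        profile = make_profile([list(ref_values) + list(con_values)],
                               samples=list(self.groups))
        return filter_features(profile, self.groups, "ref", "con").iloc[0]

    def test_large_change_is_significant(self):
        row = self.run([1.0, 1.01, 0.99, 1.0], [1.5, 1.51, 1.49, 1.5])
        assert row["significant"]
        assert row["percent_change"] == pytest.approx(50.0, abs=0.5)

    def test_small_change_fails_dual_criterion(self):
        row = self.run([1.0, 1.01, 0.99, 1.0], [1.1, 1.11, 1.09, 1.1])
        assert row["p"] < 0.05
        assert row["percent_change"] < 20
        assert not row["significant"]

    def test_zero_baseline_counts_as_infinite_change(self):
        row = self.run([0, 0, 0, 0], [0.5, 0.55, 0.45, 0.5])
        assert np.isinf(row["percent_change"])
        assert row["significant"]

    def test_both_groups_zero_not_significant(self):
        row = self.run([0, 0, 0, 0], [0, 0, 0, 0])
        assert row["percent_change"] == 0
        assert not row["significant"]

    def test_recovers_planted_twofold_changes_at_low_noise(self, rng):
        # 2-fold planted features under 10% multiplicative noise, 4 vs 4
        ref = rng.lognormal(0, 0.1, size=(500, 4))
        con = 2.0 * rng.lognormal(0, 0.1, size=(500, 4))
        profile = make_profile(np.hstack([ref, con]), samples=list(self.groups))
        out = filter_features(profile, self.groups, "ref", "con")
        assert out["significant"].mean() >= 0.90

    def test_bh_option_only_reduces_hits(self, rng):
        profile = make_profile(rng.normal(10, 1, size=(500, 8)),
                               samples=list(self.groups))
        raw = filter_features(profile, self.groups, "ref", "con")
        adj = filter_features(profile, self.groups, "ref", "con",
                              bh_correct=True)
        assert adj["significant"].sum() <= raw["significant"].sum()


class TestSpearmanPhenotype:
    def test_printed_four_point_example(self):
        profile = make_profile([[1, 2, 3, 4]])
        out = spearman_phenotype(profile, {"s0": 1, "s1": 3, "s2": 2, "s3": 4})
        assert out["spearman_rho"].iloc[0] == pytest.approx(0.8)

    def test_perfect_monotone_pairs(self):
        profile = make_profile([[1, 2, 3, 4], [4, 3, 2, 1]])
        out = spearman_phenotype(profile, {f"s{i}": i for i in range(4)})
        assert out["spearman_rho"].tolist() == pytest.approx([1.0, -1.0])

    def test_invariant_under_monotone_transform(self, rng):
        profile = make_profile(rng.random((5, 8)))
        pheno = dict(zip(profile.columns, rng.random(8)))
        warped = {s: np.exp(3 * v) + 1 for s, v in pheno.items()}
        a = spearman_phenotype(profile, pheno)["spearman_rho"]
        b = spearman_phenotype(profile, warped)["spearman_rho"]
        assert a.tolist() == pytest.approx(b.tolist())

    def test_constant_feature_undefined(self):
        profile = make_profile([[2, 2, 2, 2], [1, 2, 3, 4]])
        out = spearman_phenotype(profile, {f"s{i}": i for i in range(4)})
        assert np.isnan(out["spearman_rho"].iloc[0])
        assert out["spearman_rho"].iloc[1] == pytest.approx(1.0)

    def test_explicit_rank_formula_oracle(self, rng):
        x = rng.permutation(9).astype(float) + 1  # keep totals nonzero
        y = rng.permutation(9).astype(float) + 1
        profile = make_profile([x])
        out = spearman_phenotype(profile, dict(zip(profile.columns, y)))
        d = np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))
        rho = 1 - 6 * (d ** 2).sum() / (9 * (81 - 1))
        assert out["spearman_rho"].iloc[0] == pytest.approx(rho)

    def test_too_few_samples_rejected(self):
        profile = make_profile([[1, 2]])
        with pytest.raises(ValueError):
            spearman_phenotype(profile, {"s0": 1, "s1": 2})
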