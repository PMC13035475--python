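import math

import numpy as np
import pandas as pd
import pytest

from mosaicpool import sensitivity
from mosaicpool.core import MutationMatrix, ValidationError


class TestGrowthRate:
    def test_no_growth_is_zero(self):
        assert sensitivity.growth_rate(1000, 1000, 24) == 0.0

    def test_doubling_in_72h(self):
        r = sensitivity.growth_rate(50_000, 100_000, 72.0)
        assert r == pytest.approx(math.log(2) / 72.0, rel=1e-12)

    def test_inverse_round_trip(self):
        r = sensitivity.growth_rate(3000, 8000, 48.0)
        assert 3000 * math.exp(r * 48.0) == pytest.approx(8000, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        for args in [(0, 1, 1), (1, 0, 1), (1, 1, 0)]:
            with pytest.raises(ValidationError):
                sensitivity.growth_rate(*args)


class TestBalanceSeeding:
    def test_equal_rates_equal_seeds(self):
        seeds = sensitivity.balance_seeding(np.array([0.01, 0.01]), 1000, horizon=72)
        assert list(seeds) == [500, 500]

    def test_ratio_matches_exp_formula(self):
        rates = np.array([math.log(2) / 24.0, math.log(2) / 48.0])
        seeds = sensitivity.balance_seeding(rates, 100_000, horizon=72.0)
        # exp(−3 ln2)/exp(−1.5 ln2) = 2^−1.5: slower line seeds 2^1.5× more
        assert seeds[1] / seeds[0] == pytest.approx(2**1.5, rel=1e-3)

    def test_sums_to_total(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            rates = rng.uniform(-0.01, 0.05, size=7)
            total = int(rng.integers(10, 10_000))
            assert sensitivity.balance_seeding(rates, total, horizon=100).sum() == total

    def test_literal_mode_requires_positive_rates(self):
        seeds = sensitivity.balance_seeding(np.array([0.02, 0.01]), 300, mode="literal")
        assert seeds[1] == pytest.approx(2 * seeds[0], abs=1)
        with pytest.raises(ValidationError):
            sensitivity.balance_seeding(np.array([0.02, -0.01]), 300, mode="literal")


def counts_fixture():
    return pd.DataFrame(
        {
            "DMSO_r1": [100, 200, 300],
            "drug_r1": [50, 200, 600],
        },
        index=["A", "B", "C"],
    )


class TestRepresentation:
    def test_fractions_sum_to_one(self):
        frac = sensitivity.pool_fractions(counts_fixture())
        np.testing.assert_allclose(frac.sum(axis=0), 1.0, atol=1e-12)

    def test_identical_arms_ratio_one(self):
        c = counts_fixture()
        c["drug_r1"] = c["DMSO_r1"]
        rep = sensitivity.relative_representation(c, ["drug_r1"], ["DMSO_r1"])
        np.testing.assert_allclose(rep["ratio"], 1.0, atol=1e-12)

    def test_matches_independent_tally(self):
        c = counts_fixture()
        rep = sensitivity.relative_representation(c, ["drug_r1"], ["DMSO_r1"])
        expected_a = (50 / 850) / (100 / 600)
        assert rep.loc["A", "ratio"] == pytest.approx(expected_a, rel=1e-12)

    def test_zero_count_pseudocounted(self):
        c = counts_fixture()
        c.loc["A", "drug_r1"] = 0
        rep = sensitivity.relative_representation(c, ["drug_r1"], ["DMSO_r1"])
        total_t = 0.5 + 200 + 600
        expected = (0.5 / total_t) / (100 / 600)
        assert rep.loc["A", "ratio"] == pytest.approx(expected, rel=1e-12)

    def test_missing_sample_rejected(self):
        with pytest.raises(ValidationError):
            sensitivity.relative_representation(counts_fixture(), ["nope"], ["DMSO_r1"])


class TestRelativeSurvival:
    def test_no_depletion_scores_zero(self):
        c = counts_fixture()
        c["drug_r1"] = c["DMSO_r1"] * 3  # proportions unchanged
        scores, _ = sensitivity.relative_survival(c, ["drug_r1"], ["DMSO_r1"])
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_fourfold_depletion_is_minus_two(self):
        c = pd.DataFrame({"DMSO_r1": [400, 400], "drug_r1": [100, 400]}, index=["A", "B"])
        scores, _ = sensitivity.relative_survival(c, ["drug_r1"], ["DMSO_r1"])
        # A's fraction drops 0.5 → 0.2, B rises: antilog difference is 4× between lines
        assert scores["A"] - scores["B"] == pytest.approx(-2.0, abs=1e-12)

    def test_antisymmetric_under_arm_swap(self):
        c = counts_fixture()
        fwd, _ = sensitivity.relative_survival(c, ["drug_r1"], ["DMSO_r1"])
        rev, _ = sensitivity.relative_survival(c, ["DMSO_r1"], ["drug_r1"])
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)

    def test_group_aggregates(self):
        c = counts_fixture()
        scores, groups = sensitivity.relative_survival(
            c, ["drug_r1"], ["DMSO_r1"], mutation_groups={"mut": ["A", "B"]}
        )
        row = groups.set_index("group").loc["mut"]
        assert row["score"] == pytest.approx(scores[["A", "B"]].mean())
        with pytest.raises(ValidationError):
            sensitivity.relative_survival(
                c, ["drug_r1"], ["DMSO_r1"], mutation_groups={"bad": []}
            )


class TestDoseSlope:
    def test_halving_per_decade(self):
        doses = [0.1, 1.0, 10.0]
        ratios = [1.0, 0.5, 0.25]
        slope, _, _ = sensitivity.dose_slope(doses, ratios)
        assert slope == pytest.approx(math.log10(0.5), rel=1e-9)

    def test_flat_is_half_one_sided(self):
        slope, r, p = sensitivity.dose_slope([0.1, 1, 10], [0.8, 0.8, 0.8])
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValidationError):
            sensitivity.dose_slope([0.1, 1, 10], [1.0, 0.0, 0.5])


class TestMutationLasso:
    def make_mm(self, n=11, seed=0):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            {
                "KRAS_G12C": [1] * 5 + [0] * (n - 5),
                "BRAF_V600E": [0] * 5 + [1, 1] + [0] * (n - 7),
                "TP53_mut": rng.integers(0, 2, n),
            },
            index=[f"L{i}" for i in range(n)],
        )
        return MutationMatrix(data)

    def test_tracking_mutation_selected_negative(self):
        mm = self.make_mm()
        rng = np.random.default_rng(1)
        y = pd.Series(
            -2.0 * mm.data["KRAS_G12C"] + rng.normal(0, 0.1, 11), index=mm.line_ids
        )
        coefs = sensitivity.mutation_lasso(mm, y)
        assert "KRAS_G12C" in coefs.index
        assert coefs["KRAS_G12C"] < -0.5

    def test_constant_response_empty_selection(self, caplog):
        mm = self.make_mm()
        y = pd.Series(0.0, index=mm.line_ids)
        with caplog.at_level("WARNING"):
            coefs = sensitivity.mutation_lasso(mm, y)
        assert coefs.empty

    def test_duplicated_covariates_reproducible(self):
        mm = self.make_mm()
        dup = mm.data.copy()
        dup["KRAS_G12C_copy"] = dup["KRAS_G12C"]
        mm2 = MutationMatrix(dup)
        rng = np.random.default_rng(2)
        y = pd.Series(
            -1.5 * dup["KRAS_G12C"] + rng.normal(0, 0.1, 11), index=mm2.line_ids
        )
        c1 = sensitivity.mutation_lasso(mm2, y)
        c2 = sensitivity.mutation_lasso(mm2, y)
        pd.testing.assert_series_equal(c1, c2)
        mass = c1.reindex(["KRAS_G12C", "KRAS_G12C_copy"]).fillna(0).sum()
        assert mass < -0.5
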