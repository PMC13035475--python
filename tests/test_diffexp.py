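import numpy as np
import pandas as pd
import pytest
import scipy.stats

from mosaicpool import diffexp, simdata
from mosaicpool.core import ValidationError


def make_log2fc(n_genes=300, n_lines=6, shared=None, seed=0):
    """Synthetic per-line log2FC table with an optional shared shifted geneset."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    fc = pd.DataFrame(
        rng.normal(0, 0.5, size=(n_genes, n_lines)),
        index=genes,
        columns=[f"L{i}" for i in range(n_lines)],
    )
    if shared:
        fc.loc[shared] += -1.0
    return fc


class TestPerLineLog2FC:
    def test_identical_arms_near_zero(self, two_line_pool):
        exp, _ = two_line_pool
        # compare DMSO against itself by relabeling half the vehicle cells
        meta = exp.cell_meta
        dmso = meta.index[meta["condition"] == "DMSO"]
        meta.loc[dmso[: len(dmso) // 2], "condition"] = "mock"
        de = diffexp.per_line_log2fc(exp, "B", "mock", "DMSO", min_cells=10)
        assert np.abs(de["log2fc"]).mean() < 0.2

    def test_planted_program_recovered(self):
        genes = [f"GENE{i + 1:05d}" for i in range(20, 60)]
        cfg = simdata.SimConfig(
            lines=[simdata.LineSpec("A")],
            conditions=[
                simdata.ConditionSpec("DMSO", 0.0, 1),
                simdata.ConditionSpec("drug", 1.0, 1),
            ],
            n_genes=500,
            pool_size=2000,
            programs=[simdata.ProgramSpec("p", genes, 1.0)],
            seed=11,
        )
        exp, _ = simdata.simulate_pool(cfg)
        de = diffexp.per_line_log2fc(exp, "A", "drug", "DMSO").set_index("gene")
        assert de.loc[genes, "log2fc"].mean() == pytest.approx(1.0, abs=0.15)
        assert (de.loc[genes, "p"] < 0.01).mean() > 0.9

    def test_too_few_cells_skipped(self, two_line_pool):
        exp, _ = two_line_pool
        assert diffexp.per_line_log2fc(exp, "A", "drug", "DMSO", min_cells=10_000) is None


class TestCrossModelAggregate:
    def test_z_normalization_moments(self):
        fc = make_log2fc()
        z = diffexp.zscore_within_line(fc)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_shared_shift_detected(self):
        shared = [f"g{i}" for i in range(15)]
        fc = make_log2fc(shared=shared, seed=1)
        res = diffexp.cross_model_aggregate(fc, n_boot=10_000, seed=2)
        assert (res.q.loc[shared] < 0.05).mean() > 0.9
        assert res.mean_z.loc[shared].mean() < -0.5  # down-shift → negative

    def test_unshifted_genes_centered(self):
        fc = make_log2fc(seed=3)
        res = diffexp.cross_model_aggregate(fc, n_boot=2000, seed=4)
        assert abs(res.mean_z.median()) < 0.05

    def test_line_order_invariance(self):
        fc = make_log2fc(seed=5)
        a = diffexp.cross_model_aggregate(fc, n_boot=1000, seed=6)
        b = diffexp.cross_model_aggregate(fc[fc.columns[::-1]], n_boot=1000, seed=6)
        pd.testing.assert_series_equal(a.mean_z, b.mean_z)

    def test_bh_monotone_in_p(self):
        fc = make_log2fc(seed=7)
        res = diffexp.cross_model_aggregate(fc, n_boot=1000, seed=8)
        order = res.p.sort_values().index
        q_sorted = res.q.loc[order].to_numpy()
        assert (np.diff(q_sorted) >= -1e-12).all()

    def test_single_line_rejected(self):
        with pytest.raises(ValidationError):
            diffexp.cross_model_aggregate(make_log2fc(n_lines=1))


class TestGroupDelta:
    def test_equal_groups_zero_delta(self):
        fc = make_log2fc(n_lines=4, seed=9)
        fc["L2"], fc["L3"] = fc["L0"], fc["L1"]
        res = diffexp.group_delta(fc, ["L0", "L1"], ["L2", "L3"])
        np.testing.assert_allclose(res["delta"], 0.0, atol=1e-12)

    def test_welch_t_matches_closed_form(self):
        fc = pd.DataFrame(
            {
                "a1": [1.0, 0.2, -0.5],
                "a2": [1.4, 0.1, -0.2],
                "a3": [0.9, 0.4, -0.7],
                "b1": [0.1, 0.0, 0.3],
                "b2": [-0.2, 0.2, 0.1],
            },
            index=["g1", "g2", "g3"],
        )
        res = diffexp.group_delta(fc, ["a1", "a2", "a3"], ["b1", "b2"])
        for g in fc.index:
            x = fc.loc[g, ["a1", "a2", "a3"]].astype(float)
            y = fc.loc[g, ["b1", "b2"]].astype(float)
            t_ref = scipy.stats.ttest_ind(x, y, equal_var=False)
            assert res.loc[g, "p"] == pytest.approx(t_ref.pvalue, rel=1e-9)
            assert res.loc[g, "delta"] == pytest.approx(x.mean() - y.mean(), rel=1e-12)

    def test_g12c_style_split_ranks_planted_genes(self):
        # 8 vs 2 lines; planted shift only in the majority group
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(200)]
        g12c = [f"c{i}" for i in range(8)]
        wt = ["w0", "w1"]
        fc = pd.DataFrame(
            rng.normal(0, 0.3, size=(200, 10)), index=genes, columns=g12c + wt
        )
        planted = genes[:15]
        fc.loc[planted, g12c] += 1.2
        res = diffexp.group_delta(fc, g12c, wt)
        top = res["delta"].nlargest(15).index
        assert len(set(planted) & set(top)) >= 13

    def test_small_group_withholds_p(self):
        fc = make_log2fc(n_lines=3, seed=11)
        res = diffexp.group_delta(fc, ["L0", "L1"], ["L2"])
        assert res["p"].isna().all()
        assert res["delta"].notna().all()


class TestGenesetShift:
    def test_random_set_p_uniform(self):
        rng = np.random.default_rng(12)
        stat = pd.Series(rng.normal(size=2000), index=[f"g{i}" for i in range(2000)])
        pvals = [
            diffexp.geneset_shift_test(
                stat, set(rng.choice(stat.index, 50, replace=False))
            )["mw_p"]
            for _ in range(200)
        ]
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_shifted_set_detected(self):
        rng = np.random.default_rng(13)
        stat = pd.Series(rng.normal(size=2000), index=[f"g{i}" for i in range(2000)])
        members = list(stat.index[:50])
        stat.loc[members] -= 1.0
        res = diffexp.geneset_shift_test(stat, set(members))
        assert res["mw_p"] < 1e-4 and res["t_p"] < 1e-4
        assert res["direction"] == -1

    def test_set_equal_to_background_p_one(self):
        stat = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        res = diffexp.geneset_shift_test(stat, {"a", "b", "c"}, {"a", "b", "c"})
        assert res["mw_p"] == 1.0

    def test_disjoint_set_rejected(self):
        stat = pd.Series([1.0], index=["a"])
        with pytest.raises(ValidationError):
            diffexp.geneset_shift_test(stat, {"zzz"})


class TestDownsampleModels:
    def test_full_k_reproduces_full_analysis(self):
        shared = [f"g{i}" for i in range(30)]
        fc = make_log2fc(n_lines=4, shared=shared, seed=14)
        summary, draws = diffexp.downsample_models(
            fc, ks=[4], n_draws=5, genesets={"s": set(shared)}, n_boot=1000, seed=15
        )
        agg = diffexp.cross_model_aggregate(fc, n_boot=1000, seed=0)
        full_p = diffexp.geneset_shift_test(agg.mean_z, set(shared))["mw_p"]
        tgt = summary[(summary["set"] == "s")]
        assert tgt["median_p"].iloc[0] == pytest.approx(full_p, rel=1e-6)
        assert (draws[draws["set"] == "s"]["k"] == 4).all()

    def test_k_out_of_range_rejected(self):
        fc = make_log2fc(n_lines=4)
        with pytest.raises(ValidationError):
            diffexp.downsample_models(fc, ks=[1], n_draws=2, genesets={"s": {"g0"}})
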