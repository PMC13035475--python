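import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicpool import demux, simdata
from mosaicpool.core import CellAlleleCounts, GenotypeReference, ValidationError


class TestSingletLoglik:
    def test_closed_form_single_variant(self):
        # 5 alt reads of 5 at a hom-alt site: C(5,5)·0.99⁵
        ll = demux.singlet_loglik([0], [5], [1.0], epsilon=0.01)
        assert ll == pytest.approx(5 * math.log(0.99), abs=1e-12)

    def test_empty_evidence_is_zero(self):
        assert demux.singlet_loglik([], [], [], epsilon=0.01) == 0.0
        assert demux.singlet_loglik([0, 0], [0, 0], [1.0, 0.5], epsilon=0.01) == 0.0

    def test_matches_bruteforce_binomial_product(self):
        # direct oracle: per-variant binomial pmf via math.comb
        ref, alt = [2, 1, 4], [3, 0, 2]
        dosage, eps = [0.5, 1.0, 0.0], 0.05
        expected = 0.0
        for r, a, d in zip(ref, alt, dosage):
            p = (1 - eps) * d + eps * (1 - d)
            expected += math.log(math.comb(r + a, a) * p**a * (1 - p) ** r)
        assert demux.singlet_loglik(ref, alt, dosage, eps) == pytest.approx(
            expected, abs=1e-10
        )

    def test_missing_dosage_skipped(self):
        full = demux.singlet_loglik([1], [2], [0.5], epsilon=0.01)
        with_missing = demux.singlet_loglik(
            [1, 9], [2, 9], [0.5, np.nan], epsilon=0.01
        )
        assert with_missing == pytest.approx(full)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_additive_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        ref = rng.integers(0, 6, n)
        alt = rng.integers(0, 6, n)
        d = rng.choice([0.0, 0.5, 1.0], n)
        whole = demux.singlet_loglik(ref, alt, d, 0.01)
        left = demux.singlet_loglik(ref[:4], alt[:4], d[:4], 0.01)
        right = demux.singlet_loglik(ref[4:], alt[4:], d[4:], 0.01)
        assert whole == pytest.approx(left + right, abs=1e-9)
        perm = rng.permutation(n)
        assert demux.singlet_loglik(ref[perm], alt[perm], d[perm], 0.01) == pytest.approx(
            whole, abs=1e-9
        )

    def test_epsilon_range_enforced(self):
        with pytest.raises(ValidationError):
            demux.singlet_loglik([1], [1], [0.5], epsilon=0.7)


class TestAssignHash:
    def test_clear_calls(self):
        rng = np.random.default_rng(0)
        n = 200
        counts = rng.poisson(2.0, size=(n, 3)).astype(float)
        owner = rng.integers(0, 3, n)
        counts[np.arange(n), owner] += 120
        counts[0] = [100, 1, 2]
        counts[1] = [80, 75, 1]
        counts[2] = [0, 0, 0]
        calls = demux.assign_hash(pd.DataFrame(counts, columns=["h1", "h2", "h3"]))
        assert calls.iloc[0] == "h1"
        assert calls.iloc[1] == "doublet"
        assert calls.iloc[2] == "unassigned"
        bulk = calls.iloc[3:]
        expect = pd.Series([f"h{o + 1}" for o in owner[3:]])
        assert (bulk.to_numpy() == expect.to_numpy()).mean() > 0.98

    def test_otsu_separates_two_clusters(self):
        vals = np.concatenate([np.zeros(50), np.ones(50) * 10])
        thr = demux.otsu_threshold(vals)
        assert 0 < thr < 10


def _alleles_from_dense(ref, alt, variant_ids, barcodes):
    return CellAlleleCounts(
        barcodes, variant_ids, sp.csr_matrix(ref), sp.csr_matrix(alt)
    )


class TestAssignGenotype:
    def setup_method(self):
        self.ref = GenotypeReference(
            ["A", "B"],
            [f"v{i}" for i in range(20)],
            np.vstack([np.ones(20), np.zeros(20)]),
        )

    def test_mixed_reads_call_doublet(self):
        # 50:50 alt/ref reads across hom-opposite lines
        ref_r = np.full((1, 20), 2)
        alt_r = np.full((1, 20), 2)
        ac = _alleles_from_dense(ref_r, alt_r, list(self.ref.variant_ids), ["c1"])
        calls = demux.assign_genotype(ac, self.ref, epsilon=0.01)
        assert calls.loc[0, "call_type"] == "doublet"
        assert calls.loc[0, "genotype_call"] == "A+B"
        assert calls.loc[0, "best_doublet_ll"] > calls.loc[0, "best_singlet_ll"]

    def test_no_reads_is_ambiguous(self):
        ac = _alleles_from_dense(
            np.zeros((1, 20)), np.zeros((1, 20)), list(self.ref.variant_ids), ["c1"]
        )
        calls = demux.assign_genotype(ac, self.ref)
        assert calls.loc[0, "call_type"] == "ambiguous"

    def test_simulated_singlets_recovered(self):
        lines = [simdata.LineSpec(f"L{i}") for i in range(4)]
        cfg = simdata.SimConfig(
            lines=lines,
            conditions=[simdata.ConditionSpec("DMSO", 0.0, 1)],
            n_genes=50,
            pool_size=300,
            seed=1,
        )
        exp, truth = simdata.simulate_pool(cfg)
        gref = simdata.random_genotype_reference([l.line_id for l in lines], 100, seed=2)
        ac = simdata.simulate_allele_counts(exp, truth, gref, depth=40, seed=3)
        calls = demux.assign_genotype(ac, gref)
        singlets = calls["call_type"] == "singlet"
        acc = (
            calls.loc[singlets, "genotype_call"].to_numpy()
            == truth.cell_line[singlets.to_numpy()]
        ).mean()
        assert acc >= 0.99


class TestPseudobulkClusters:
    def test_pure_clusters_recover_truth_map(self):
        lines = [simdata.LineSpec("A"), simdata.LineSpec("B"), simdata.LineSpec("C")]
        cfg = simdata.SimConfig(
            lines=lines,
            conditions=[simdata.ConditionSpec("DMSO", 0.0, 1)],
            n_genes=40,
            pool_size=300,
            seed=4,
        )
        exp, truth = simdata.simulate_pool(cfg)
        gref = simdata.random_genotype_reference(["A", "B", "C"], 60, seed=5)
        ac = simdata.simulate_allele_counts(exp, truth, gref, depth=20, seed=6)
        clusters = pd.Series(truth.cell_line, index=exp.barcodes)
        mapping = demux.assign_clusters_by_pseudobulk(clusters, ac, gref)
        assert dict(zip(mapping["cluster"], mapping["line_id"])) == {
            "A": "A",
            "B": "B",
            "C": "C",
        }
        assert (mapping["correlation"] > 0.9).all()

    def test_identical_reference_lines_tie_break_by_order(self, caplog):
        ref = GenotypeReference(
            ["A", "B"],
            ["v1", "v2", "v3", "v4"],
            np.vstack([[0, 1, 0, 1], [0, 1, 0, 1]]).astype(float),
        )
        ac = _alleles_from_dense(
            np.array([[5, 0, 5, 0]]),
            np.array([[0, 5, 0, 5]]),
            ["v1", "v2", "v3", "v4"],
            ["c1"],
        )
        clusters = pd.Series(["k0"], index=["c1"])
        with caplog.at_level("WARNING"):
            mapping = demux.assign_clusters_by_pseudobulk(clusters, ac, ref)
        assert mapping.loc[0, "line_id"] == "A"
        assert "tie" in caplog.text
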