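"""Filtering, pairwise PCC, permutation null, thresholding, sub-networks."""

import numpy as np
import pandas as pd
import pytest

import stemwall as sw
from stemwall import coexpression as cx
from stemwall.containers import StudyDesign

from conftest import matrix_from_array


def network_matrix(values: np.ndarray, probe_ids=None):
    return matrix_from_array(values, probe_ids=probe_ids, stem_only=False)


class TestFilterProbesets:
    def _matrix(self):
        rng = np.random.default_rng(31)
        vals = 2.0 ** rng.normal(8, 0.05, size=(6, 37))
        # rows: control with big range, constant, exactly 2-fold, 10-fold, flat-noise, 3-fold
        vals[0, :15] = np.linspace(100, 1000, 15)
        vals[1, :] = 50.0
        vals[2, :15] = 100.0
        vals[2, 0] = 200.0
        vals[3, :15] = np.linspace(100, 1000, 15)
        vals[5, :15] = np.linspace(100, 300, 15)
        ids = ["AFFX-123", "Mtr.A", "Mtr.B", "Mtr.C", "Mtr.D", "Sme.X"]
        return network_matrix(vals, probe_ids=ids)

    def test_prefix_and_range_rules(self):
        kept = cx.filter_probesets(self._matrix()).values.index
        assert "AFFX-123" not in kept        # control prefix, despite 10-fold range
        assert "Sme.X" not in kept           # control prefix
        assert "Mtr.A" not in kept           # constant (max/min = 1)
        assert "Mtr.B" in kept               # exactly 2-fold: "at least two-fold"
        assert "Mtr.C" in kept

    def test_filter_uses_stem_chips_only(self):
        rng = np.random.default_rng(32)
        vals = np.full((2, 37), 100.0) * (1 + rng.normal(0, 1e-6, (2, 37)))
        vals[0, 20] = 1000.0  # varies only in an atlas chip
        m = network_matrix(vals)
        kept = cx.filter_probesets(m).values.index
        assert "P0000" not in kept


class TestPairwisePCC:
    def test_pair_count_formula(self):
        assert cx.n_pairs(12576) == 79_071_600
        rng = np.random.default_rng(33)
        m = network_matrix(2.0 ** rng.normal(8, 1, size=(25, 37)))
        assert len(cx.pairwise_pcc(m)) == 25 * 24 // 2

    def test_duplicated_row_perfect_correlation(self):
        rng = np.random.default_rng(34)
        vals = 2.0 ** rng.normal(8, 1, size=(5, 37))
        vals[1] = vals[0]
        m = network_matrix(vals)
        pcc = cx.pairwise_pcc(m)
        assert pcc[0] == pytest.approx(1.0, abs=1e-12)  # pair (0, 1) is first

    def test_exact_anticorrelation(self):
        vals = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        m = matrix_from_array(vals, design=StudyDesign())
        pcc = cx.pairwise_pcc(m, log2=False)
        assert pcc[0] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_two_pass_bruteforce(self):
        """Blockwise standardized products equal the textbook two-pass
        Pearson formula on small instances to 1e-12."""
        rng = np.random.default_rng(35)
        for trial in range(10):
            vals = 2.0 ** rng.normal(8, 1, size=(5, 5))
            m = matrix_from_array(vals, design=StudyDesign())
            got = cx.pairwise_pcc(m, block=2)
            x = np.log2(vals)
            pos = 0
            for i in range(5):
                for j in range(i + 1, 5):
                    a, b = x[i], x[j]
                    num = ((a - a.mean()) * (b - b.mean())).sum()
                    den = np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
                    assert got[pos] == pytest.approx(num / den, abs=1e-12)
                    pos += 1

    def test_too_few_samples_rejected(self):
        vals = np.array([[1.0, 2.0], [3.0, 2.0]])
        m = matrix_from_array(vals, design=StudyDesign())
        with pytest.raises(ValueError, match="3 samples"):
            cx.pairwise_pcc(m)


class TestPermuteRows:
    def test_row_multisets_preserved(self, network_2000):
        m, _ = network_2000
        perm = cx.permute_rows(m, seed=40)
        a = np.sort(m.values.to_numpy(), axis=1)
        b = np.sort(perm.values.to_numpy(), axis=1)
        np.testing.assert_array_equal(a, b)

    def test_single_column_identity(self):
        rng = np.random.default_rng(41)
        m = network_matrix(2.0 ** rng.normal(8, 1, size=(10, 37)))
        m.values = m.values.iloc[:, :1]
        perm = cx.permute_rows(m, seed=4)
        pd.testing.assert_frame_equal(perm.values, m.values)

    def test_seeded_determinism(self, network_2000):
        m, _ = network_2000
        a = cx.permute_rows(m, seed=4)
        b = cx.permute_rows(m, seed=4)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestThreshold:
    def test_degenerate_null_gives_first_grid_point(self):
        null = np.random.default_rng(42).uniform(-0.09, 0.09, size=1000)
        assert cx.estimate_threshold(null) == pytest.approx(0.1)

    def test_histogram_counts_conserve_pairs(self):
        rng = np.random.default_rng(43)
        m = network_matrix(2.0 ** rng.normal(8, 1, size=(40, 37)))
        hist, _ = cx.null_pcc_summary(m)
        assert hist["count"].sum() == cx.n_pairs(40)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cx.estimate_threshold(np.array([0.5, 1.7]))

    def test_threshold_is_smallest_grid_cover(self):
        assert cx.estimate_threshold(null_max_abs=0.74) == pytest.approx(0.8)
        assert cx.estimate_threshold(null_max_abs=0.8) == pytest.approx(0.8)
        with pytest.raises(ValueError, match="usable threshold"):
            cx.estimate_threshold(null_max_abs=0.95)


class TestBuildNetwork:
    def test_threshold_one_gives_no_edges(self):
        rng = np.random.default_rng(44)
        m = network_matrix(2.0 ** rng.normal(8, 1, size=(20, 37)))
        net = cx.build_network(m, threshold=1.0)
        assert net.n_edges == 0

    def test_duplicated_rows_linked(self):
        rng = np.random.default_rng(45)
        vals = 2.0 ** rng.normal(8, 1, size=(30, 37))
        vals[7] = vals[3]
        net = cx.build_network(network_matrix(vals), threshold=0.8)
        assert net.graph.has_edge("P0003", "P0007")

    def test_planted_clique_recovered(self):
        """12 genes at planted pairwise r = 0.95 keep >= 60 of 66 edges."""
        rng = np.random.default_rng(46)
        clique = sw.synthetic.correlated_block(rng, 12, 37, rho=0.95)
        noise = 2.0 ** rng.normal(9, 1, size=(88, 37))
        net = cx.build_network(network_matrix(np.vstack([clique, noise])), threshold=0.8)
        ids = [f"P{i:04d}" for i in range(12)]
        edges = sum(net.graph.has_edge(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :])
        assert edges >= 60

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(47)
        m = network_matrix(2.0 ** rng.normal(8, 1, size=(40, 37)))
        lo = cx.build_network(m, threshold=0.5)
        hi = cx.build_network(m, threshold=0.8)
        assert set(hi.graph.edges) <= set(lo.graph.edges)


class TestPathwaySubnetwork:
    def test_hub_recovery(self, network_2000):
        net_m, truth = network_2000
        filt = cx.filter_probesets(net_m)
        perm = cx.permute_rows(filt, seed=50)
        _, mx = cx.null_pcc_summary(perm)
        thr = cx.estimate_threshold(null_max_abs=mx)
        net = cx.build_network(filt, thr)
        present = set(filt.values.index)
        tfs = [t for t in truth.tf_probes() if t in present]
        lignin = [g for g in truth.pathway_probes("lignin") if g in present]
        _, degree = cx.extract_pathway_subnetwork(net, tfs, lignin)
        found = set(cx.rank_hub_tfs(degree, min_degree=4))
        planted = set(truth.hub_probes())
        assert len(found & planted) / len(planted) >= 0.9
        assert len(found & planted) / max(len(found), 1) >= 0.9

    def test_overlap_rejected(self, network_2000):
        net_m, truth = network_2000
        filt = cx.filter_probesets(net_m)
        net = cx.build_network(filt, 0.99)
        some = list(filt.values.index[:3])
        with pytest.raises(ValueError, match="both"):
            cx.extract_pathway_subnetwork(net, some, some[:1])

    def test_rank_ordering_and_min_degree(self):
        degree = pd.Series({"b": 5, "a": 5, "c": 2, "d": 11})
        assert cx.rank_hub_tfs(degree, min_degree=4) == ["d", "a", "b"]
        assert cx.rank_hub_tfs(degree, min_degree=0) == ["d", "a", "b", "c"]
        assert cx.rank_hub_tfs(degree, min_degree=12) == []
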