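"""Generator contracts: determinism, planted structure, zero-noise limits."""

import numpy as np
import pandas as pd
import pytest

import stemwall as sw
from stemwall import config
from stemwall.containers import StudyDesign


class TestStudyDesign:
    def test_chip_accounting(self, design):
        assert design.n_stem_chips == 15
        assert design.n_atlas_chips == 22
        assert design.n_network_chips == 37
        assert len(design.atlas_tissues) == 18

    def test_reference_internode_required(self):
        with pytest.raises(ValueError, match="reference"):
            StudyDesign(internodes=("IN3", "IN5"), reference_internode="IN2")


class TestStemMatrix:
    def test_dimensions_at_default_scale_constant(self, design):
        # 12,576 probe sets x 15 stem chips is the default full-scale shape.
        m, _ = sw.generate_stem_matrix(12576, design, seed=0)
        assert m.values.shape == (12576, 15)

    def test_same_seed_identical(self, design):
        a, ta = sw.generate_stem_matrix(200, design, seed=7)
        b, tb = sw.generate_stem_matrix(200, design, seed=7)
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(ta.table, tb.table)

    def test_different_seed_differs(self, design):
        a, _ = sw.generate_stem_matrix(200, design, seed=7)
        b, _ = sw.generate_stem_matrix(200, design, seed=8)
        assert not a.values.equals(b.values)

    def test_zero_noise_profile_equals_archetype(self, design):
        m, t = sw.generate_stem_matrix(200, design, noise_sd_log2=0.0, seed=3)
        probes10 = t.table.index[t.table["archetype"] == 10]
        prof = sw.relative_profile(m, list(probes10))
        expected = config.ARCHETYPES[10]
        for _, row in prof.iterrows():
            np.testing.assert_allclose(row.to_numpy(), expected, rtol=1e-12)
        assert prof.columns[prof.iloc[0].argmax()] == "IN5"

    def test_background_is_flat_in_expectation(self, design):
        m, t = sw.generate_stem_matrix(400, design, noise_sd_log2=0.0, seed=5)
        bg = t.table.index[t.table["archetype"].isna()]
        prof = sw.relative_profile(m, list(bg))
        np.testing.assert_allclose(prof.to_numpy(), 1.0, rtol=1e-12)

    def test_pathway_sizes_planted(self, stem_500):
        _, truth = stem_500
        counts = truth.table["pathway"].value_counts()
        assert counts["lignin"] == 11
        assert counts["cellulose"] == 3
        assert counts["hemicellulose"] == 4

    def test_pathway_genes_are_archetype_10(self, stem_500):
        _, truth = stem_500
        arch = truth.table.loc[truth.pathway_probes(), "archetype"]
        assert (arch == 10).all()

    def test_rejects_bad_arguments(self, design):
        with pytest.raises(ValueError):
            sw.generate_stem_matrix(10, design)
        with pytest.raises(ValueError):
            sw.generate_stem_matrix(100, design, noise_sd_log2=-0.1)
        with pytest.raises(ValueError):
            sw.generate_stem_matrix(100, design, archetype_fractions={1: 0.9, 10: 0.2})


class TestAtlasMatrix:
    def test_18_tissue_columns(self, design):
        probes = [f"T{i}" for i in range(40)]
        atlas = sw.generate_atlas_matrix(probes, design, seed=1)
        assert atlas.values.shape == (40, 18)

    def test_null_fold_is_flat(self, design):
        probes = [f"T{i}" for i in range(40)]
        atlas = sw.generate_atlas_matrix(
            probes, design, wall_tissue_fold=1.0, wall_specific=probes[:10],
            noise_sd_log2=0.0, seed=1,
        )
        sd = np.log2(atlas.values).std(axis=1)
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_wall_specific_elevated(self, design):
        probes = [f"T{i}" for i in range(40)]
        atlas = sw.generate_atlas_matrix(
            probes, design, wall_tissue_fold=8.0, wall_specific=probes[:10],
            noise_sd_log2=0.0, seed=1,
        )
        tissues = atlas.design.loc[atlas.values.columns, "tissue"]
        wall_cols = [c for c in atlas.values.columns if tissues[c] in config.WALL_TISSUES]
        other_cols = [c for c in atlas.values.columns if tissues[c] not in config.WALL_TISSUES]
        ratio = atlas.values[wall_cols].mean(axis=1) / atlas.values[other_cols].mean(axis=1)
        assert (ratio[probes[:10]] > 7).all()
        np.testing.assert_allclose(ratio[probes[10:]], 1.0, rtol=1e-9)

    def test_unknown_wall_specific_rejected(self, design):
        with pytest.raises(ValueError, match="wall_specific"):
            sw.generate_atlas_matrix(["A", "B"], design, wall_specific=["Z"])


class TestNetworkMatrix:
    def test_37_chips(self, network_2000):
        net, _ = network_2000
        assert net.values.shape[1] == 37

    def test_hubs_are_archetype10_tfs(self, network_2000):
        _, truth = network_2000
        hubs = truth.hub_probes()
        assert len(hubs) == 3
        sub = truth.table.loc[hubs]
        assert sub["is_tf"].all()
        assert (sub["archetype"] == 10).all()

    def test_stem_columns_unchanged(self, stem_2000, network_2000):
        stem, _ = stem_2000
        net, _ = network_2000
        pd.testing.assert_frame_equal(net.values[stem.values.columns], stem.values)


class TestQPCRGenerator:
    def test_flat_profile_gives_unity_ratios(self, design):
        flat = pd.DataFrame(1.0, index=pd.Index([f"G{i}" for i in range(5)], name="gene"),
                            columns=list(design.internodes))
        table, _ = sw.generate_qpcr_table(
            5, design, fold_profile=flat, seed=2, ct_noise_sd=0.0,
            frac_not_expressed=0.0,
        )
        folds = sw.relative_expression(table)
        np.testing.assert_allclose(folds.to_numpy(dtype=float), 1.0, rtol=1e-9)

    def test_default_panel_size(self, design):
        table, _ = sw.generate_qpcr_table(1045, design, seed=1)
        assert len([g for g in table.genes if g != table.reference_gene]) == 1045

    def test_planted_ct_shift_matches_pfaffl_inverse(self, design):
        # E = 2 and an 8-fold rise at IN9 means Ct drops exactly 3 cycles.
        prof = pd.DataFrame(1.0, index=pd.Index(["G1"], name="gene"),
                            columns=list(design.internodes))
        prof.loc["G1", "IN9"] = 8.0
        table, _ = sw.generate_qpcr_table(
            1, design, fold_profile=prof,
            efficiencies=pd.Series({"G1": 2.0}), seed=3, ct_noise_sd=0.0,
            frac_not_expressed=0.0,
        )
        cts = table.records.groupby(["gene", "internode"])["ct"].mean()
        assert cts[("G1", "IN9")] - cts[("G1", "IN2")] == pytest.approx(-3.0, abs=1e-9)
        ref = table.reference_gene
        assert cts[(ref, "IN9")] == pytest.approx(cts[(ref, "IN2")], abs=1e-9)

    def test_reference_gene_collision_rejected(self, design):
        prof = pd.DataFrame(1.0, index=pd.Index(["Ubiquitin"], name="gene"),
                            columns=list(design.internodes))
        with pytest.raises(ValueError):
            sw.generate_qpcr_table(1, design, fold_profile=prof,
                                   efficiencies=pd.Series({"Ubiquitin": 2.0}), seed=1)

    def test_seeded_determinism(self, design):
        a, _ = sw.generate_qpcr_table(20, design, seed=11)
        b, _ = sw.generate_qpcr_table(20, design, seed=11)
        pd.testing.assert_frame_equal(a.records, b.records)
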