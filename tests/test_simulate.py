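"""The generator must record exactly what it did: every truth-table field is
checked against the emitted sequences and labels."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from pctrace import io as pio
from pctrace import simulate as sim


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestConfigValidation:
    def test_rejects_more_clones_than_cells(self):
        with pytest.raises(sim.SimulationConfigError, match="n_clones"):
            sim.SimConfig(n_cells=10, n_clones=11).validate()

    def test_rejects_empty_state_map(self):
        with pytest.raises(sim.SimulationConfigError, match="state_proportions"):
            sim.SimConfig(state_proportions={}).validate()

    def test_rejects_unnormalized_proportions(self):
        with pytest.raises(sim.SimulationConfigError, match="sums to"):
            sim.SimConfig(compartment_proportions={"spleen": 0.5, "bone_marrow": 0.4}).validate()

    def test_rejects_marker_overflow(self):
        with pytest.raises(sim.SimulationConfigError, match="n_genes"):
            sim.SimConfig(n_genes=50, n_marker_genes_per_state=10).validate()


class TestGermline:
    def test_translation_and_affinity_residue(self, germline):
        for rec in germline.records:
            assert len(rec.nt) % 3 == 0
            assert str(Seq(rec.nt).translate()) == rec.aa
            assert rec.aa[rec.affinity_position - 1] == rec.affinity_from == "W"

    def test_fasta_round_trip(self, germline, tmp_path):
        path = tmp_path / "germ.fasta"
        germline.to_fasta(path)
        back = sim.GermlineSet.from_fasta(path)
        assert back.names() == germline.names()
        for rec in back.records:
            orig = germline[rec.name]
            assert rec.nt == orig.nt and rec.affinity_position == orig.affinity_position


class TestRepertoire:
    def test_deterministic_for_fixed_seed(self, germline):
        cfg = sim.SimConfig(n_cells=150, n_clones=20, seed=5)
        c1, t1 = sim.simulate_repertoire(cfg, germline)
        c2, t2 = sim.simulate_repertoire(cfg, germline)
        assert c1.to_csv(index=False) == c2.to_csv(index=False)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_clone_count_and_coverage(self, germline):
        cfg = sim.SimConfig(n_cells=200, n_clones=10, seed=3)
        _, truth = sim.simulate_repertoire(cfg, germline)
        assert truth["clone_id"].nunique() == 10
        assert len(truth) == 200 and truth["barcode"].is_unique

    def test_each_cell_one_heavy_at_least_one_light(self, small_sim):
        _, contigs, truth = small_sim
        per_cell = contigs.groupby(["barcode", "locus"]).size().unstack(fill_value=0)
        heavy = per_cell.get("IGH", 0)
        light = per_cell.get("IGK", 0) + per_cell.get("IGL", 0)
        assert (heavy == 1).all()
        assert (light >= 1).all()
        assert set(per_cell.index) == set(truth["barcode"])

    def test_clone_mates_share_identity_fields(self, small_sim, germline):
        _, contigs, truth = small_sim
        paired = pio.pair_cell_chains(contigs).cells.merge(truth, on="barcode")
        for _, grp in paired.groupby("clone_id"):
            for col in ["heavy_v", "heavy_d", "heavy_j", "heavy_cdr3_aa", "light_v", "light_j"]:
                assert grp[col].nunique() == 1

    def test_recorded_mutation_counts_equal_hamming_distance(self, small_sim, germline):
        _, contigs, truth = small_sim
        heavy = contigs[contigs["locus"] == "IGH"].set_index("barcode")
        for _, row in truth.iterrows():
            h = heavy.loc[row["barcode"]]
            assert _hamming(h["v_sequence_nt"], h["germline_v_nt"]) == row["n_v_mutations"]

    def test_affinity_flag_iff_translated_residue(self, small_sim, germline):
        _, contigs, truth = small_sim
        heavy = contigs[contigs["locus"] == "IGH"].set_index("barcode")
        for _, row in truth.iterrows():
            h = heavy.loc[row["barcode"]]
            rec = germline[h["v_call"]]
            aa = str(Seq(h["v_sequence_nt"]).translate())
            assert (aa[rec.affinity_position - 1] == rec.affinity_to) == row["has_affinity_mutation"]

    def test_mutation_mean_tracks_poisson(self, germline):
        # rate 3 at timepoint index 2 -> Poisson mean 6 per V segment
        cfg = sim.SimConfig(
            n_cells=1000, n_clones=1000, seed=17, affinity_mutation_prob=0.0,
            timepoint_proportions={"35": 1.0},
        )
        _, truth = sim.simulate_repertoire(cfg, germline)
        mean = truth["n_v_mutations"].mean()
        se = np.sqrt(6.0 / len(truth))
        assert abs(mean - 6.0) <= 3 * se

    def test_conservation_across_states_and_compartments(self, base_sim):
        cfg, _, truth = base_sim
        assert truth.groupby(["state", "compartment"]).size().sum() == cfg.n_cells

    def test_progenitor_clones_confined_to_spleen(self, base_sim):
        _, _, truth = base_sim
        prog_clones = truth.loc[truth["state"] == "PC progenitor", "clone_id"].unique()
        sub = truth[truth["clone_id"].isin(prog_clones)]
        assert (sub["compartment"] == "spleen").all()


class TestExpression:
    def test_marker_elevation_in_home_state(self, germline):
        cfg = sim.SimConfig(n_cells=500, n_clones=100, seed=23, marker_fold=8.0)
        _, truth = sim.simulate_repertoire(cfg, germline)
        adata, marker_map = sim.simulate_expression(truth, cfg)
        X = np.asarray(adata.X.todense(), dtype=float)
        state = truth["state"].to_numpy()
        from scipy import stats

        s = "PC-Tigit"
        cols = [adata.var_names.get_loc(g) for g in marker_map[s]]
        home = X[state == s][:, cols].mean(axis=1)
        away = X[state != s][:, cols].mean(axis=1)
        res = stats.mannwhitneyu(home, away, alternative="greater")
        assert home.mean() > away.mean()
        assert res.pvalue < 0.01

    def test_deterministic_for_fixed_seed(self, germline):
        cfg = sim.SimConfig(n_cells=120, n_clones=20, seed=9)
        _, truth = sim.simulate_repertoire(cfg, germline)
        a1, _ = sim.simulate_expression(truth, cfg)
        a2, _ = sim.simulate_expression(truth, cfg)
        assert (a1.X != a2.X).nnz == 0

    def test_columns_match_truth_order(self, germline):
        cfg = sim.SimConfig(n_cells=80, n_clones=10, seed=2)
        _, truth = sim.simulate_repertoire(cfg, germline)
        adata, _ = sim.simulate_expression(truth, cfg)
        assert list(adata.obs_names) == list(truth["barcode"])


class TestFixtureBundle:
    def test_manifest_lists_exactly_seven_files(self, small_sim, germline, tmp_path):
        cfg, contigs, truth = small_sim
        adata, _ = sim.simulate_expression(truth, cfg)
        manifest = sim.write_fixture_bundle(contigs, adata, truth, germline, tmp_path)
        assert len(manifest["files"]) == 7
        assert len(manifest["checksums"]) == 7

    def test_rerun_reproduces_checksums(self, small_sim, germline, tmp_path):
        cfg, contigs, truth = small_sim
        adata, _ = sim.simulate_expression(truth, cfg)
        m1 = sim.write_fixture_bundle(contigs, adata, truth, germline, tmp_path / "a")
        m2 = sim.write_fixture_bundle(contigs, adata, truth, germline, tmp_path / "b")
        assert m1["checksums"] == m2["checksums"]

    def test_airr_round_trip_is_lossless(self, small_sim, germline, tmp_path):
        cfg, contigs, truth = small_sim
        adata, _ = sim.simulate_expression(truth, cfg)
        sim.write_fixture_bundle(contigs, adata, truth, germline, tmp_path)
        back = pio.read_contigs(tmp_path / "airr_rearrangement.tsv", dialect="airr_tsv")
        pd.testing.assert_frame_equal(back, contigs.reset_index(drop=True))

    def test_tenx_round_trip_on_dialect_columns(self, small_sim, germline, tmp_path):
        cfg, contigs, truth = small_sim
        adata, _ = sim.simulate_expression(truth, cfg)
        sim.write_fixture_bundle(contigs, adata, truth, germline, tmp_path)
        back = pio.read_contigs(tmp_path / "filtered_contig_annotations.csv", dialect="tenx_csv")
        shared = ["barcode", "locus", "v_call", "d_call", "j_call", "cdr3_aa", "productive", "umi_count"]
        pd.testing.assert_frame_equal(back[shared], contigs.reset_index(drop=True)[shared])

    def test_expression_round_trip(self, small_sim, germline, tmp_path):
        cfg, contigs, truth = small_sim
        adata, _ = sim.simulate_expression(truth, cfg)
        sim.write_fixture_bundle(contigs, adata, truth, germline, tmp_path)
        back = pio.read_expression(tmp_path, format="mtx_dir")
        assert back.shape == adata.shape
        assert (back.X != adata.X).nnz == 0


class TestDEGGroups:
    def test_planted_genes_have_elevated_means(self):
        A, B, planted = sim.simulate_deg_groups(seed=0, n_planted=20, fold=2.0)
        assert len(planted) == 20
        Xa = np.asarray(A.X.todense(), dtype=float)
        Xb = np.asarray(B.X.todense(), dtype=float)
        idx = [list(A.var_names).index(g) for g in planted]
        ratio = (Xa[:, idx].mean(axis=0) + 1) / (Xb[:, idx].mean(axis=0) + 1)
        # balanced planting: half up in A, half up in B
        assert (ratio > 1.5).sum() + (ratio < 1 / 1.5).sum() == 20

    def test_null_groups_are_exchangeable_draws(self):
        A, B, planted = sim.simulate_deg_groups(seed=1, n_planted=0)
        assert planted == []
        assert A.shape == B.shape
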