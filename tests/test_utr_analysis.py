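import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tricoord import data_io, indices, synthetic_data, utr_analysis
from tricoord.utr_analysis import (annotate_utr, group_utr_summary, select_defiers,
                                   utr_binned_association, utr_shift_test)

TOY_GTF = """\
chr1\ttoy\ttranscript\t1\t300\t.\t+\t.\tgene_id "GA"; transcript_id "GA.t1";
chr1\ttoy\texon\t1\t100\t.\t+\t.\tgene_id "GA"; transcript_id "GA.t1";
chr1\ttoy\texon\t201\t300\t.\t+\t.\tgene_id "GA"; transcript_id "GA.t1";
chr1\ttoy\tCDS\t51\t100\t.\t+\t0\tgene_id "GA"; transcript_id "GA.t1";
chr1\ttoy\tCDS\t201\t250\t.\t+\t1\tgene_id "GA"; transcript_id "GA.t1";
chr2\ttoy\ttranscript\t1\t1000\t.\t-\t.\tgene_id "GB"; transcript_id "GB.t1";
chr2\ttoy\texon\t1\t1000\t.\t-\t.\tgene_id "GB"; transcript_id "GB.t1";
chr2\ttoy\tCDS\t101\t700\t.\t-\t0\tgene_id "GB"; transcript_id "GB.t1";
chr3\ttoy\ttranscript\t1\t500\t.\t+\t.\tgene_id "GC"; transcript_id "GC.t1";
chr3\ttoy\texon\t1\t500\t.\t+\t.\tgene_id "GC"; transcript_id "GC.t1";
chr3\ttoy\tCDS\t101\t400\t.\t+\t0\tgene_id "GC"; transcript_id "GC.t1";
chr3\ttoy\ttranscript\t1\t500\t.\t+\t.\tgene_id "GC"; transcript_id "GC.t2";
chr3\ttoy\texon\t1\t500\t.\t+\t.\tgene_id "GC"; transcript_id "GC.t2";
chr3\ttoy\tCDS\t201\t350\t.\t+\t0\tgene_id "GC"; transcript_id "GC.t2";
chr4\ttoy\ttranscript\t1\t200\t.\t+\t.\tgene_id "GD"; transcript_id "GD.t1";
chr4\ttoy\texon\t1\t200\t.\t+\t.\tgene_id "GD"; transcript_id "GD.t1";
"""


class TestAnnotateUtr:
    def test_table_arithmetic_human_typical(self):
        # ~200 nt 5'UTR + 1000 nt ORF + ~800 nt 3'UTR: half the mRNA is UTR
        ann = annotate_utr(pd.DataFrame({"gene_id": ["G1"], "utr5_len": [200],
                                         "cds_len": [1000], "utr3_len": [800]}))
        assert ann.loc["G1", "mrna_len"] == 2000
        assert ann.loc["G1", "utr_proportion"] == pytest.approx(0.5)

    def test_no_utr_gives_zero_proportion(self):
        ann = annotate_utr(pd.DataFrame({"gene_id": ["G1"], "utr5_len": [0],
                                         "cds_len": [300], "utr3_len": [0]}))
        assert ann.loc["G1", "utr_proportion"] == 0.0

    def test_negative_length_is_error(self):
        with pytest.raises(ValueError, match="negative"):
            annotate_utr(pd.DataFrame({"gene_id": ["G1"], "utr5_len": [-5],
                                       "cds_len": [300], "utr3_len": [0]}))

    def test_gtf_interval_arithmetic(self, tmp_path):
        p = tmp_path / "toy.gtf"
        p.write_text(TOY_GTF)
        ann = annotate_utr(p)
        # GA (+, spliced): exonic bases before CDS start 51 -> 50 nt 5'UTR,
        # after CDS end 250 -> 50 nt 3'UTR, 100 nt exonic CDS
        assert ann.loc["GA", ["utr5_len", "cds_len", "utr3_len"]].tolist() == [50, 100, 50]
        assert ann.loc["GA", "utr_proportion"] == pytest.approx(0.5)
        # GB (- strand): genomically-left bases are the 3'UTR
        assert ann.loc["GB", ["utr5_len", "cds_len", "utr3_len"]].tolist() == [300, 600, 100]
        # GC: longest-CDS transcript (t1: 300 nt) wins over t2 (150 nt)
        assert ann.loc["GC", "cds_len"] == 300
        # GD has no CDS -> skipped
        assert "GD" not in ann.index

    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "utr.tsv"
        p.write_text("gene_id\tutr5_len\tcds_len\tutr3_len\nG1\t100\t300\t100\n")
        ann = annotate_utr(p)
        assert ann.loc["G1", "utr_proportion"] == pytest.approx(0.4)

    @given(k=st.integers(min_value=1, max_value=50))
    @settings(deadline=None, max_examples=20)
    def test_proportion_scale_invariant(self, k):
        base = annotate_utr(pd.DataFrame({"gene_id": ["G"], "utr5_len": [120],
                                          "cds_len": [900], "utr3_len": [480]}))
        scaled = annotate_utr(pd.DataFrame({"gene_id": ["G"], "utr5_len": [120 * k],
                                            "cds_len": [900 * k], "utr3_len": [480 * k]}))
        assert scaled.loc["G", "utr_proportion"] == pytest.approx(
            base.loc["G", "utr_proportion"])


class TestBinnedAssociation:
    def test_single_bin_equals_global(self, small_dataset, small_index_table):
        curve = utr_binned_association(small_index_table, small_dataset.utr,
                                       bin_edges=[0.0, 1.0], min_occupancy=3)
        shared = small_index_table.index.intersection(small_dataset.utr.index)
        global_assoc = indices.index_association(small_index_table.loc[shared])
        assert len(curve) == 1
        assert curve.iloc[0]["pearson_r"] == pytest.approx(global_assoc.r, rel=1e-12)
        assert curve.iloc[0]["regression_slope"] == pytest.approx(global_assoc.slope, rel=1e-12)

    def test_decaying_coupling_gives_decreasing_curve(self, default_dataset):
        table = indices.compute_indices(default_dataset.profile)
        curve = utr_binned_association(table, default_dataset.utr)
        rank_r = stats.spearmanr(curve["bin_center"], curve["pearson_r"]).statistic
        assert rank_r < 0

    def test_constant_coupling_gives_flat_curve(self):
        truth = synthetic_data.SyntheticTruth(n_genes=12000, utr_effect="constant",
                                              defier_fraction=0.0, n_groups=0, seed=3)
        ds = synthetic_data.generate(truth)
        table = indices.compute_indices(ds.profile)
        curve = utr_binned_association(table, ds.utr)
        # per-bin sampling bound: 4 standard errors of a Pearson r
        bounds = 4 * (1 - truth.rho0 ** 2) / np.sqrt(curve["n_genes"])
        assert ((curve["pearson_r"] - truth.rho0).abs() <= bounds).all()

    def test_underpopulated_bins_error(self, small_index_table, small_dataset):
        with pytest.raises(ValueError, match="occupancy"):
            utr_binned_association(small_index_table, small_dataset.utr,
                                   min_occupancy=10 ** 6)


class TestSelectDefiers:
    def test_unbounded_thresholds_select_all(self, small_index_table):
        sel = select_defiers(small_index_table, stability_min=-np.inf,
                             translation_max=np.inf)
        assert sel.n == len(small_index_table)

    def test_boundary_gene_included(self):
        t = pd.DataFrame({"stability_index": [0.0], "translation_index": [-1.0]},
                         index=["G1"])
        assert select_defiers(t).gene_ids == ("G1",)

    def test_planted_defiers_recovered(self, default_dataset):
        table = indices.compute_indices(default_dataset.profile)
        sel = set(select_defiers(table).gene_ids)
        tt = default_dataset.truth_table
        planted = set(tt.index[tt["is_defier"]])
        recall = len(planted & sel) / len(planted)
        assert recall >= 0.9

    @given(ds=st.floats(min_value=0, max_value=2), dt=st.floats(min_value=0, max_value=2))
    @settings(deadline=None, max_examples=20)
    def test_monotone_in_thresholds(self, small_index_table, ds, dt):
        tight = set(select_defiers(small_index_table, stability_min=0.0,
                                   translation_max=-1.0).gene_ids)
        relaxed = set(select_defiers(small_index_table, stability_min=-ds,
                                     translation_max=-1.0 + dt).gene_ids)
        assert tight <= relaxed


class TestUtrShift:
    def test_selection_equal_to_background(self, small_dataset, small_index_table):
        sel = select_defiers(small_index_table, stability_min=-np.inf,
                             translation_max=np.inf)
        res = utr_shift_test(sel, small_dataset.utr.loc[small_index_table.index])
        np.testing.assert_array_equal(res.selection_counts, res.background_counts)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_defiers_shift_right(self, default_dataset):
        table = indices.compute_indices(default_dataset.profile)
        sel = select_defiers(table)
        res = utr_shift_test(sel, default_dataset.utr)
        assert res.selection_mean > res.background_mean
        assert res.p_value < 0.01

    def test_counts_conserved(self, default_dataset):
        table = indices.compute_indices(default_dataset.profile)
        sel = select_defiers(table)
        res = utr_shift_test(sel, default_dataset.utr)
        assert res.selection_counts.sum() == len(
            [g for g in sel.gene_ids if g in default_dataset.utr.index])
        assert res.background_counts.sum() == len(default_dataset.utr)

    def test_tiny_selection_is_error(self, small_dataset, small_index_table):
        sel = select_defiers(small_index_table, stability_min=np.inf,
                             translation_max=-np.inf)
        with pytest.raises(ValueError):
            utr_shift_test(sel, small_dataset.utr)


class TestGroupUtrSummary:
    @staticmethod
    def _ann(props):
        return annotate_utr(pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(len(props))],
            "utr5_len": [int(1000 * p / 2) for p in props],
            "cds_len": [int(1000 * (1 - p)) for p in props],
            "utr3_len": [1000 - int(1000 * p / 2) - int(1000 * (1 - p)) for p in props],
        }))

    def test_identical_proportions(self):
        ann = self._ann([0.3, 0.3, 0.5, 0.5])
        out = group_utr_summary({"a": ["G0", "G1"], "b": ["G2", "G3"]}, ann)
        assert out["groups"]["a"]["mean"] == pytest.approx(0.3)
        assert out["groups"]["a"]["median"] == pytest.approx(0.3)

    def test_matches_hand_computed_pooled_t(self):
        ann = self._ann([0.2, 0.3, 0.4, 0.6, 0.7, 0.8])
        out = group_utr_summary({"low": ["G0", "G1", "G2"],
                                 "high": ["G3", "G4", "G5"]}, ann)
        a = ann.loc[["G0", "G1", "G2"], "utr_proportion"].to_numpy()
        b = ann.loc[["G3", "G4", "G5"], "utr_proportion"].to_numpy()
        # pooled-variance two-sample t statistic, by the textbook formula
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=4)
        got = out["t_tests"]["low_vs_high"]
        assert got["t_statistic"] == pytest.approx(t_hand, rel=1e-10)
        assert got["p_value"] == pytest.approx(p_hand, rel=1e-10)
        assert out["groups"]["high"]["mean"] - out["groups"]["low"]["mean"] \
            == pytest.approx(0.4, abs=0.01)

    def test_group_against_itself(self):
        ann = self._ann([0.2, 0.4, 0.6])
        out = group_utr_summary({"a": ["G0", "G1", "G2"],
                                 "b": ["G0", "G1", "G2"]}, ann)
        assert out["t_tests"]["a_vs_b"]["p_value"] == pytest.approx(1.0)

    def test_unknown_ids_listed(self):
        ann = self._ann([0.2, 0.4, 0.6])
        out = group_utr_summary({"a": ["G0", "G1", "NOPE"], "b": ["G1", "G2"]}, ann)
        assert out["groups"]["a"]["unknown_ids"] == ["NOPE"]
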