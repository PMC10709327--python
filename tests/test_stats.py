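"""Composition, flanking, fold-change and expression-matrix statistics."""

import numpy as np
import pandas as pd
import pytest

from cappedpep.secretome import ProteinRecord, predict_capped_peptides
from cappedpep.stats import (
    RESIDUES,
    benjamini_hochberg,
    compare_composition,
    composition_vector,
    expression_zscore,
    flanking_profile,
    fold_change_table,
)
from cappedpep.synthetic import make_quant_experiment


class TestCompareComposition:
    def test_identical_sets_give_p_one_and_zero_differences(self):
        peps = ["QLLM", "QSSA", "QKRG"]
        df = compare_composition(peps, list(peps))
        assert np.allclose(df["mean_capped"], df["mean_ref"])
        assert np.allclose(df["p_value"].dropna(), 1.0)

    def test_planted_leucine_enrichment(self):
        a, b = ["QLLL"] * 10, ["QSSS"] * 10
        df = compare_composition(a, b).set_index("residue")
        assert df.loc["L", "mean_capped"] == pytest.approx(0.75)
        assert df.loc["L", "mean_ref"] == 0.0
        # zero within-group variance: degenerate flag, p collapses to 0
        assert df.loc["L", "degenerate"]
        assert df.loc["L", "p_value"] == 0.0

    def test_singleton_group_reports_means_without_p(self):
        df = compare_composition(["QLL"], ["QSS", "QST"]).set_index("residue")
        assert np.isnan(df.loc["L", "p_value"])
        assert df.loc["L", "mean_capped"] == pytest.approx(2 / 3)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            compare_composition([], ["QAA"])

    def test_frequency_vectors_sum_to_one(self):
        for pep in ["Q", "QLLM", "QWWWWY"]:
            assert composition_vector(pep).sum() == pytest.approx(1.0, abs=1e-9)


class TestFlankingProfile:
    def test_single_candidate_one_hot_columns(self):
        rec = ProteinRecord("P", "MKLVQAAGKRWD")
        (cand,) = predict_capped_peptides(rec)
        freq, n_obs = flanking_profile([cand], {"P": rec.sequence}, k=2, terminus="N")
        assert freq.loc["V", -1] == 1.0 and freq.loc["L", -2] == 1.0
        assert freq.loc["A", 1] == 1.0
        assert np.allclose(freq.sum(axis=0)[n_obs > 0], 1.0)

    def test_c_terminal_plus_one_is_motif_glycine(self):
        rec = ProteinRecord("P", "MKLVQAAGKRWD")
        (cand,) = predict_capped_peptides(rec)
        freq, _ = flanking_profile([cand], {"P": rec.sequence}, k=2, terminus="C")
        assert freq.loc["G", 1] == 1.0  # the amide-donor glycine

    def test_into_peptide_convention_skips_motif(self):
        rec = ProteinRecord("P", "MKLVQAAGKRWD")
        (cand,) = predict_capped_peptides(rec)
        freq, _ = flanking_profile(
            [cand], {"P": rec.sequence}, k=1, terminus="C", offsets_into="peptide"
        )
        assert freq.loc["W", 1] == 1.0  # first residue past G-K-R

    def test_planted_frequency_recovered(self):
        rng = np.random.default_rng(42)
        cands, seqs = [], {}
        for i in range(200):
            minus1 = "A" if rng.random() < 0.9 else "V"
            seq = "MKL" + minus1 + "QWAGKRDD"
            acc = f"P{i}"
            seqs[acc] = seq
            (cand,) = predict_capped_peptides(ProteinRecord(acc, seq))
            cands.append(cand)
        freq, _ = flanking_profile(cands, seqs, k=1, terminus="N")
        assert freq.loc["A", -1] == pytest.approx(0.9, abs=0.06)

    def test_positions_outside_precursor_skipped(self):
        rec = ProteinRecord("P", "QAAGKR")  # nothing upstream of the Q
        (cand,) = predict_capped_peptides(rec)
        freq, n_obs = flanking_profile([cand], {"P": rec.sequence}, k=4, terminus="N")
        assert n_obs[-1] == 0 and freq[-1].sum() == 0.0


class TestFoldChangeTable:
    def test_identical_groups_fc_one(self):
        quant = pd.DataFrame(
            {"a1": [10.0], "a2": [10.0], "b1": [10.0], "b2": [10.0]}, index=["pep"]
        )
        mapping = {"a1": "ctl", "a2": "ctl", "b1": "trt", "b2": "trt"}
        out = fold_change_table(quant, mapping, "ctl", "trt")
        assert out.loc["pep", "fold_change"] == pytest.approx(1.0)

    def test_planted_induction_and_reduction_recovered(self):
        quant, mapping, truth = make_quant_experiment(
            ["up", "down"], ("ctl", "trt"), {"up": 84.0, "down": 0.42},
            n_per_group=3, cv=0.05, seed=0,
        )
        out = fold_change_table(quant, mapping, "ctl", "trt")
        assert out.loc["up", "fold_change"] == pytest.approx(84.0, rel=0.10)
        assert out.loc["down", "fold_change"] == pytest.approx(0.42, rel=0.10)

    def test_zero_denominator_flagged_infinite(self):
        quant = pd.DataFrame({"a1": [0.0, 1.0], "b1": [5.0, 2.0]}, index=["x", "y"])
        out = fold_change_table(quant, {"a1": "ctl", "b1": "trt"}, "ctl", "trt")
        assert np.isinf(out.loc["x", "fold_change"]) and out.loc["x", "zero_denominator"]
        assert out.loc["y", "log2_fold_change"] == pytest.approx(1.0)

    def test_unknown_condition_rejected(self):
        quant = pd.DataFrame({"a1": [1.0]}, index=["x"])
        with pytest.raises(ValueError):
            fold_change_table(quant, {"a1": "ctl"}, "ctl", "missing")

    def test_noiseless_table_exact(self):
        quant, mapping, _ = make_quant_experiment(
            ["p"], ("ctl", "trt"), {"p": 2.6}, n_per_group=3, cv=0.0, seed=1
        )
        out = fold_change_table(quant, mapping, "ctl", "trt")
        assert out.loc["p", "fold_change"] == pytest.approx(2.6, abs=1e-12)


class TestExpressionZscore:
    def test_rows_mean_zero_unit_variance(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(
            rng.lognormal(2, 1, size=(12, 6)),
            index=[f"g{i}" for i in range(12)],
            columns=[f"t{j}" for j in range(6)],
        )
        res = expression_zscore(mat)
        z = res.zscores.to_numpy()
        assert np.allclose(z.mean(axis=1), 0, atol=1e-6)
        assert np.allclose(z.var(axis=1, ddof=1), 1, atol=1e-6)

    def test_hand_computed_row(self):
        mat = pd.DataFrame([[1.0, 10.0, 100.0]], index=["g"], columns=list("abc"))
        res = expression_zscore(mat)
        z = res.zscores.loc["g"].to_numpy()
        # log10 relative expression is arithmetic (-2.045,-1.045,-0.045):
        # symmetric z-scores under the sample-sd convention
        assert z[1] == pytest.approx(0.0, abs=1e-9)
        assert z[2] == pytest.approx(1.0, abs=1e-9)
        assert z[0] == pytest.approx(-1.0, abs=1e-9)

    def test_replicates_averaged(self):
        mat = pd.DataFrame([[2.0, 4.0, 8.0, 50.0]], index=["g"],
                           columns=["liver_1", "liver_2", "brain", "gut"])
        rep = {"liver_1": "liver", "liver_2": "liver", "brain": "brain", "gut": "gut"}
        res = expression_zscore(mat, rep)
        assert list(res.zscores.columns) == ["brain", "gut", "liver"]
        # averaged liver = 3, so relative = 8/61, 50/61, 3/61

    def test_constant_row_flagged_and_excluded(self):
        mat = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 4.0]], index=["const", "ok"],
                           columns=list("abc"))
        res = expression_zscore(mat)
        assert res.flagged_genes == ("const",)
        assert list(res.zscores.index) == ["ok"]

    def test_two_block_structure_separated(self):
        rng = np.random.default_rng(7)
        cols = [f"t{j}" for j in range(8)]
        rows = {}
        for i in range(6):
            base = np.full(8, 10.0)
            block = slice(0, 4) if i < 3 else slice(4, 8)
            base[block] *= 50
            rows[f"g{i}"] = base * rng.lognormal(0, 0.05, 8)
        mat = pd.DataFrame(rows).T
        mat.columns = cols
        res = expression_zscore(mat)
        order = list(res.row_order)
        first_block = {f"g{i}" for i in range(3)}
        assert {g for g in order[:3]} in ({f"g{i}" for i in range(3)},
                                          {f"g{i}" for i in range(3, 6)})


def test_benjamini_hochberg_monotone_and_bounded():
    p = [0.001, 0.01, 0.02, 0.5, 0.9]
    q = benjamini_hochberg(p)
    assert (q >= p).all() and (q <= 1).all()
    assert q[0] == pytest.approx(0.005)
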