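"""Single-cell stages: QC strictness, rank-based signature scoring against a
brute-force oracle, epitope positivity, dropout bounds, Venn accounting and
pseudobulk conservation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_adata
from ctcdll3 import scxpr, synth
from oracles import ucell_brute, venn_brute


def qc_test_matrix():
    """Cells engineered to sit exactly at each QC boundary.

    Genes: 600 ordinary + 2 mitochondrial.  Rows (in order):
      0: 500 genes, 2000 UMIs, mito 0      -> fails gene floor (strict)
      1: 501 genes, 2000 UMIs, mito 0      -> passes
      2: 501 genes, 1000 UMIs, mito 0      -> fails UMI floor (strict)
      3: 501 genes, 1001 UMIs, mito 0      -> passes
      4: 501 genes, 2000 UMIs, mito 0.10   -> fails mito ceiling (strict)
      5: 501 genes, 2000 UMIs, mito 0.099  -> passes
      6: 400 genes, 600 UMIs,  mito 0      -> fails default, passes CTC mode
    """
    n_genes = 602
    X = np.zeros((7, n_genes), int)

    def fill(row, n_detect, total, mito_frac):
        mito_umis = int(round(total * mito_frac))
        body = total - mito_umis
        X[row, :n_detect] = 1
        X[row, 0] += body - n_detect
        if mito_umis:
            X[row, 600] = mito_umis  # MT- gene, adds one detected gene
    fill(0, 500, 2000, 0.0)
    fill(1, 501, 2000, 0.0)
    fill(2, 501, 1000, 0.0)
    fill(3, 501, 1001, 0.0)
    fill(4, 500, 2000, 0.10)   # +1 mito gene detected -> 501 genes
    fill(5, 500, 2000, 0.099)
    fill(6, 400, 600, 0.0)
    genes = [f"G{j:04d}" for j in range(600)] + ["MT-ND1", "MT-CO1"]
    return make_adata(X, gene_names=genes)


class TestQC:
    def test_boundary_strictness(self):
        adata = qc_test_matrix()
        _, flags, _ = scxpr.qc_filter(
            adata, scxpr.QCThresholds(min_cells_per_gene=0))
        assert list(flags["pass"]) == [False, True, False, True, False, True,
                                       False]

    def test_ctc_mode_relaxes_floors(self):
        adata = qc_test_matrix()
        thr = scxpr.QCThresholds.ctc_mode(min_cells_per_gene=0)
        _, flags, _ = scxpr.qc_filter(adata, thr)
        assert bool(flags["pass"].iloc[6])   # 400 genes / 600 UMIs now kept
        assert bool(flags["pass"].iloc[0])   # 500 genes clears the 300 floor
        assert bool(flags["pass"].iloc[2])   # 1000 UMIs clears the 500 floor
        assert not bool(flags["pass"].iloc[4])  # mito ceiling unchanged

    def test_gene_filter_after_cell_filter(self):
        # a gene detected only in a QC-failing cell must be dropped
        X = np.zeros((3, 5), int)
        X[0] = [600, 1, 0, 0, 1]         # 3 genes: fails the strict > 3 floor
        X[1, :4] = [500, 500, 500, 500]
        X[2, :4] = [500, 500, 500, 500]
        adata = make_adata(X)
        thr = scxpr.QCThresholds(min_genes=3, min_umi=100, max_mito=0.5,
                                 min_cells_per_gene=2)
        out, cell_flags, gene_flags = scxpr.qc_filter(adata, thr)
        assert list(cell_flags["pass"]) == [False, True, True]
        assert not gene_flags.loc["G0004", "pass"]
        assert out.shape == (2, 4)

    def test_low_capture_fraction_filter(self):
        X = np.zeros((2, 100), int)
        X[0, :4] = 200   # 4% of genes detected -> removed
        X[1, :6] = 200   # 6% -> kept
        thr = scxpr.QCThresholds(min_genes=0, min_umi=0, max_mito=1.0,
                                 min_cells_per_gene=0,
                                 min_gene_detection_frac=0.05)
        _, flags, _ = scxpr.qc_filter(make_adata(X), thr)
        assert list(flags["pass"]) == [False, True]

    def test_order_stability(self, small_counts):
        _, adata, _ = small_counts
        rng = np.random.default_rng(0)
        perm = rng.permutation(adata.n_obs)
        out1, _, _ = scxpr.qc_filter(adata)
        out2, _, _ = scxpr.qc_filter(adata[perm].copy())
        assert set(out1.obs_names) == set(out2.obs_names)
        assert set(out1.var_names) == set(out2.var_names)


class TestUCell:
    def test_signature_at_top_ranks_scores_one(self):
        expr = np.array([9.0, 8.0, 7.0, 1.0, 0.5, 0.2, 0.1, 0.05, 0.02, 0.01])
        score = scxpr.ucell_score_cell(expr, np.array([0, 1, 2]), max_rank=8)
        assert score == 1.0

    def test_no_detected_signature_gene_scores_zero(self):
        expr = np.array([0.0, 0.0, 5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.2, 0.1])
        assert scxpr.ucell_score_cell(expr, np.array([0, 1]), max_rank=8) == 0.0

    def test_matches_brute_force_on_toy_cells(self, rng):
        for _ in range(100):
            expr = np.round(rng.gamma(0.6, 4.0, 12), 1)
            sig = rng.choice(12, size=3, replace=False)
            got = scxpr.ucell_score_cell(expr, sig, max_rank=9)
            want = ucell_brute(list(expr), list(sig), 9)
            assert got == pytest.approx(want, abs=1e-12)

    def test_signature_size_must_be_below_cap(self):
        with pytest.raises(ValueError):
            scxpr.ucell_score_cell(np.ones(5), np.arange(4), max_rank=4)

    def test_invariant_under_monotone_transform(self, small_counts):
        _, adata, _ = small_counts
        sigs = scxpr.load_signatures().subtypes
        base = scxpr.ucell_scores(adata, sigs, max_rank=500)
        scaled = adata.copy()
        scaled.X = scaled.X * 7
        logd = adata.copy()
        logd.X = logd.X.astype(float)
        logd.X.data = np.log1p(logd.X.data)
        for other in (scaled, logd):
            alt = scxpr.ucell_scores(other, sigs, max_rank=500)
            assert np.allclose(base.to_numpy(), alt.to_numpy())

    def test_vectorized_matches_per_cell_path(self, small_counts):
        _, adata, _ = small_counts
        sigs = {"SCLC-A": scxpr.load_signatures().subtypes["SCLC-A"]}
        table = scxpr.ucell_scores(adata, sigs, max_rank=700)
        pos = [adata.var_names.get_loc(g) for g in sigs["SCLC-A"]
               if g in adata.var_names]
        for i in (0, 5, 100, adata.n_obs - 1):
            expr = np.asarray(adata.X[i].todense()).ravel()
            want = scxpr.ucell_score_cell(expr, np.array(pos), max_rank=700)
            assert table.iloc[i, 0] == pytest.approx(want)


class TestAssign:
    def test_argmax_assignment(self):
        scores = pd.DataFrame(
            [[0.9, 0.1, 0.1, 0.1]], index=["c0"],
            columns=["SCLC-A", "SCLC-N", "SCLC-P", "SCLC-I"])
        out = scxpr.assign_subtypes(scores)
        assert out.loc["c0", "subtype"] == "SCLC-A"
        assert not out.loc["c0", "tie"]

    def test_tie_breaks_by_priority_and_flags(self):
        scores = pd.DataFrame(
            [[0.7, 0.7, 0.2, 0.1]], index=["c0"],
            columns=["SCLC-A", "SCLC-N", "SCLC-P", "SCLC-I"])
        out = scxpr.assign_subtypes(scores)
        assert out.loc["c0", "subtype"] == "SCLC-A"
        assert bool(out.loc["c0", "tie"])

    def test_recovery_at_default_dropout(self):
        params = synth.SCCountParams(
            n_cells={"tumor": 600, "reference": 0},
            subtype_mixture=(0.7, 0.2, 0.1, 0.0), seed=31)
        adata, truth = synth.simulate_counts(params)
        scores = scxpr.ucell_scores(adata, scxpr.load_signatures().subtypes)
        out = scxpr.assign_subtypes(scores)
        acc = (out["subtype"].to_numpy() == truth["subtype"].to_numpy()).mean()
        assert acc >= 0.9


class TestEpitope:
    def test_one_umi_rule(self):
        X = np.array([[0, 5], [1, 0], [3, 0]])
        adata = make_adata(X, gene_names=["DLL3", "SEZ6"])
        flags = scxpr.call_epitope(adata, "DLL3")
        assert list(flags) == [False, True, True]

    def test_absent_gene_warns_all_negative(self):
        adata = make_adata(np.ones((2, 2), int), gene_names=["A", "B"])
        flags = scxpr.call_epitope(adata, "DLL3")
        assert not flags.any()

    def test_fraction_recovery_without_dropout(self):
        f = 0.35
        params = synth.SCCountParams(n_cells={"tumor": 5000, "reference": 0},
                                     dropout=0.0, dll3_positive_fraction=f,
                                     seed=41)
        adata, _ = synth.simulate_counts(params)
        obs = scxpr.call_epitope(adata, "DLL3").mean()
        assert abs(obs - f) < 3 * np.sqrt(f * (1 - f) / 5000)


class TestDropoutAssessment:
    def test_all_positive_gives_zero_candidates(self):
        X = np.ones((4, 9), int)
        genes = ["DLL3"] + scxpr.load_signatures().notch
        adata = make_adata(X, gene_names=genes)
        res = scxpr.dropout_assessment(adata, scxpr.call_epitope(adata, "DLL3"))
        assert res.candidate_fraction == 0.0
        assert res.corrected_upper == res.observed_fraction == 1.0

    def test_null_candidates_equal_negative_notch_rate(self):
        params = synth.SCCountParams(n_cells={"tumor": 2000, "reference": 0},
                                     dropout=0.0, seed=51)
        adata, truth = synth.simulate_counts(params)
        dll3 = scxpr.call_epitope(adata, "DLL3")
        res = scxpr.dropout_assessment(adata, dll3)
        # with no detection loss every DLL3-negative is truly negative, so
        # the candidate rate equals the truly-negative Notch >= k rate
        notch = [g for g in scxpr.load_signatures().notch]
        sub = adata[:, notch].X.toarray()
        neg = ~truth["dll3_positive"].to_numpy()
        rate = (((sub > 0).sum(axis=1) >= 2) & neg).mean()
        assert res.candidate_fraction == pytest.approx(rate)

    def test_upper_bound_covers_injected_dropout(self):
        covered = 0
        n_seeds = 25
        for seed in range(n_seeds):
            params = synth.SCCountParams(
                n_cells={"tumor": 800, "reference": 0},
                gene_dropout={"DLL3": 0.2}, seed=seed)
            adata, truth = synth.simulate_counts(params)
            dll3 = scxpr.call_epitope(adata, "DLL3")
            res = scxpr.dropout_assessment(adata, dll3)
            truth_frac = truth["dll3_positive"].mean()
            covered += res.corrected_lower <= truth_frac <= res.corrected_upper
        assert covered >= round(0.95 * n_seeds)

    def test_empty_notch_intersection_undefined(self):
        adata = make_adata(np.ones((2, 2), int), gene_names=["A", "B"])
        res = scxpr.dropout_assessment(
            adata, pd.Series([True, False], index=adata.obs_names))
        assert np.isnan(res.corrected_upper)


class TestVenn:
    def test_no_positive_cells(self):
        adata = make_adata(np.zeros((5, 3), int),
                           gene_names=["DLL3", "SEZ6", "CD276"])
        v = scxpr.coexpression_venn(adata, ["DLL3", "SEZ6", "CD276"])
        assert v.none == 5 and v.any_positive == 0
        assert all(n == 0 for n in v.regions.values())

    def test_three_cell_worked_example(self):
        X = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 1]])
        adata = make_adata(X, gene_names=["D", "S", "B"])
        v = scxpr.coexpression_venn(adata, ["D", "S", "B"])
        assert v.regions[frozenset({"D"})] == 1
        assert v.regions[frozenset({"D", "S"})] == 1
        assert v.regions[frozenset({"S", "B"})] == 1
        assert sum(v.regions.values()) == 3 and v.none == 0

    def test_partition_and_brute_force(self, rng):
        genes = ["DLL3", "SEZ6", "CD276", "EPCAM"]
        X = (rng.random((60, 4)) < 0.4).astype(int) * rng.integers(1, 5, (60, 4))
        adata = make_adata(X, gene_names=genes)
        v = scxpr.coexpression_venn(adata, genes)
        rows = [{g: X[i, j] >= 1 for j, g in enumerate(genes)}
                for i in range(60)]
        regions, none = venn_brute(rows, genes)
        assert v.regions == regions and v.none == none
        assert sum(v.regions.values()) + v.none == 60

    def test_progression_percentages(self):
        # 21 cells: 1 DLL3+, 18 with SEZ6 and/or B7H3, 2 triple-negative
        X = np.zeros((21, 3), int)
        X[0, 0] = 1                      # the single DLL3-positive CTC
        X[1:7, 1] = 1                    # SEZ6 only
        X[7:11, 2] = 1                   # B7H3 only
        X[11:19, 1] = X[11:19, 2] = 1    # both
        adata = make_adata(X, gene_names=["DLL3", "SEZ6", "CD276"])
        assert scxpr.call_epitope(adata, "DLL3").sum() == 1
        v = scxpr.coexpression_venn(adata, ["DLL3", "SEZ6", "CD276"])
        assert v.count_positive(["SEZ6", "CD276"]) == 18
        assert round(100 * 1 / 21) == 5
        assert round(v.percent_of_total(["SEZ6", "CD276"])) == 86


class TestPseudobulkAndOrigin:
    def test_single_group_conserves_totals(self, small_counts):
        _, adata, _ = small_counts
        groups = pd.Series("all", index=adata.obs_names)
        out = scxpr.pseudobulk(adata, groups)
        totals = np.asarray(adata.X.sum(axis=0)).ravel()
        assert np.allclose(out.loc["all"].to_numpy(), totals)

    def test_group_sums_conserve_gene_totals(self, small_counts):
        _, adata, _ = small_counts
        out = scxpr.pseudobulk(adata, "population")
        totals = np.asarray(adata.X.sum(axis=0)).ravel()
        assert np.allclose(out.sum(axis=0).to_numpy(), totals)

    def test_identical_groups_identical_profiles(self):
        X = np.tile(np.arange(6), (4, 1))
        adata = make_adata(X)
        groups = pd.Series(["a", "a", "b", "b"], index=adata.obs_names)
        out = scxpr.pseudobulk(adata, groups)
        assert np.allclose(out.loc["a"], out.loc["b"])

    def test_dll3_pseudobulk_higher_in_a_enriched_group(self):
        params = synth.SCCountParams(n_cells={"tumor": 800, "reference": 0},
                                     subtype_mixture=(1.0, 0.0, 0.0, 0.0),
                                     dll3_positive_fraction=0.8, seed=3)
        a_enriched, _ = synth.simulate_counts(params)
        params_n = synth.SCCountParams(n_cells={"tumor": 800, "reference": 0},
                                       subtype_mixture=(0.0, 1.0, 0.0, 0.0),
                                       dll3_positive_fraction=0.2, seed=3)
        n_enriched, _ = synth.simulate_counts(params_n)
        pa = scxpr.pseudobulk(a_enriched, pd.Series("A", index=a_enriched.obs_names),
                              per_million=True)
        pn = scxpr.pseudobulk(n_enriched, pd.Series("N", index=n_enriched.obs_names),
                              per_million=True)
        assert pa.loc["A", "DLL3"] > pn.loc["N", "DLL3"]

    def test_epithelial_origin_matches_set_logic(self, rng):
        genes = ["DLL3", "EPCAM", "KRT8", "KRT18"]
        X = (rng.random((10, 4)) < 0.5).astype(int)
        adata = make_adata(X, gene_names=genes)
        series, fracs = scxpr.epithelial_origin(adata)
        for i in range(10):
            dll3 = X[i, 0] >= 1
            epi = (X[i, 1:] >= 1).any()
            want = ("dll3+epith+" if dll3 and epi else "dll3+only" if dll3
                    else "epith+only" if epi else "neither")
            assert series.iloc[i] == want
        assert sum(fracs.values()) == pytest.approx(1.0)

    def test_all_zero_cell_is_neither(self):
        adata = make_adata(np.zeros((1, 2), int), gene_names=["DLL3", "EPCAM"])
        series, _ = scxpr.epithelial_origin(adata)
        assert series.iloc[0] == "neither"


class TestSignatures:
    def test_packaged_lists_load(self):
        sigs = scxpr.load_signatures()
        assert sigs.subtypes["SCLC-A"] == ["ASCL1", "SOX4", "STMN2", "DOC2A"]
        assert len(sigs.subtypes["SCLC-N"]) == 8
        assert len(sigs.subtypes["SCLC-P"]) == 6
        assert sigs.subtypes["SCLC-I"][0] == "CD274"
        assert set(sigs.epitopes) == {"DLL3", "SEZ6", "CD276"}
        assert len(sigs.notch) == 8 and "EPCAM" in sigs.epithelial
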