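"""Rank statistics, exact tests, multiple-testing correction and qPCR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from limbdual import (
    benjamini_hochberg,
    bonferroni,
    ddct,
    de_dual_vs_union,
    find_markers,
    fisher_exact_2x2,
    fraction_expressing_compare,
    top_markers,
    wilcoxon_rank_sum,
)

from conftest import make_adata


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 2, 5], [2, 5, 1, 2])
        assert p == 1.0

    def test_fully_separated_triplets(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=1, max_size=6))
    def test_exchangeable_samples_never_significant(self, xs):
        _, p = wilcoxon_rank_sum(xs, xs)
        assert p == 1.0

    def test_exact_branch_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            x = rng.integers(0, 4, rng.integers(1, 6)).astype(float)
            y = rng.integers(0, 4, rng.integers(1, 6)).astype(float)
            pooled = np.concatenate([x, y])
            ranks = sps.rankdata(pooled)
            W = ranks[: len(x)].sum()
            sums = np.array(
                [ranks[list(s)].sum() for s in itertools.combinations(range(len(pooled)), len(x))]
            )
            expected = min(1.0, 2 * min((sums <= W + 1e-9).mean(), (sums >= W - 1e-9).mean()))
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(expected, abs=1e-12)

    def test_normal_branch_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            x = rng.integers(0, 8, rng.integers(8, 30)).astype(float)
            y = rng.integers(0, 8, rng.integers(8, 30)).astype(float)
            _, p = wilcoxon_rank_sum(x, y)
            sp = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert p == pytest.approx(sp, abs=1e-10)

    @pytest.mark.parametrize("alternative", ["less", "greater"])
    def test_one_sided_exact_matches_scipy(self, alternative):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.choice(200, size=rng.integers(1, 7), replace=False).astype(float)
            y = rng.choice(200, size=rng.integers(1, 7), replace=False).astype(float) + 0.5
            _, p = wilcoxon_rank_sum(x, y, alternative)
            sp = sps.mannwhitneyu(x, y, alternative=alternative.replace("_", "-"),
                                  method="exact").pvalue
            assert p == pytest.approx(sp, abs=1e-12)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            _, p = wilcoxon_rank_sum(x, y)
            rejections += p < 0.05
        rate = rejections / n_rep
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n_rep)
        assert 0.05 - half_width <= rate <= 0.05 + half_width

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

class TestFisher:
    def test_diagonal_two_by_two(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3, abs=1e-12)

    def test_eight_two_split(self):
        assert fisher_exact_2x2([[8, 2], [2, 8]]) == pytest.approx(0.023014, abs=1e-6)

    def test_empty_margin_gives_p_one(self):
        assert fisher_exact_2x2([[0, 7], [0, 3]]) == 1.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            t = rng.integers(0, 12, size=4)
            table = [[int(t[0]), int(t[1])], [int(t[2]), int(t[3])]]
            assert fisher_exact_2x2(table) == pytest.approx(
                sps.fisher_exact(table)[1], abs=1e-9
            )

    @pytest.mark.parametrize("alternative", ["less", "greater"])
    def test_one_sided_matches_scipy(self, alternative):
        rng = np.random.default_rng(5)
        for _ in range(50):
            t = rng.integers(0, 10, size=4)
            table = [[int(t[0]), int(t[1])], [int(t[2]), int(t[3])]]
            sp = sps.fisher_exact(table, alternative=alternative)[1]
            assert fisher_exact_2x2(table, alternative) == pytest.approx(sp, abs=1e-9)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

class TestBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3])[0] == 0.3

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_capped(self, ps):
        adj = benjamini_hochberg(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(
                benjamini_hochberg(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_order_equivariance(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(benjamini_hochberg(p)[perm], benjamini_hochberg(p[perm]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_bonferroni(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.4]), [0.02, 0.8])


# ---------------------------------------------------------------------------
# marker discovery
# ---------------------------------------------------------------------------

def _grouped_adata(seed=0, n_per_group=40, n_genes=20):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(5, size=(2 * n_per_group, n_genes))
    counts[:n_per_group, 0] += 30  # planted marker of group A
    counts[:, 1] = 4  # constant gene
    adata = make_adata(counts)
    groups = np.array(["A"] * n_per_group + ["B"] * n_per_group)
    return adata, groups


class TestFindMarkers:
    def test_planted_marker_recovered_with_positive_logfc(self):
        adata, groups = _grouped_adata()
        table = find_markers(adata, groups, min_pct=0.1, logfc_min=0.0)
        hit = table[(table["group"] == "A") & (table["gene"] == "G0")]
        assert len(hit) == 1 and bool(hit["significant"].iloc[0]) and hit["log_fc"].iloc[0] > 0

    def test_constant_gene_never_significant(self):
        # constant normalized values: depth effects removed by construction
        rng = np.random.default_rng(10)
        vals = rng.random((80, 10))
        vals[:, 1] = 0.4
        adata = make_adata(np.ones((80, 10), dtype=int), normalize=False)
        adata.layers["lognorm"] = vals
        groups = np.array(["A"] * 40 + ["B"] * 40)
        table = find_markers(adata, groups, min_pct=0.0, logfc_min=0.0)
        rows = table[table["gene"] == "G1"]
        assert not rows["significant"].any()
        assert (rows["p_raw"] == 1.0).all()

    def test_small_group_skipped_with_warning(self):
        adata, _ = _grouped_adata()
        groups = np.array(["tiny"] * 2 + ["rest"] * (adata.n_obs - 2), dtype=object)
        with pytest.warns(UserWarning, match="tiny"):
            table = find_markers(adata, groups)
        assert set(table["group"]) == {"rest"}

    def test_label_permutation_controls_false_positives(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(5, size=(100, 30))
        adata = make_adata(counts)
        clean = 0
        n_perm = 100
        for i in range(n_perm):
            groups = np.array(["A"] * 50 + ["B"] * 50)
            np.random.default_rng(i).shuffle(groups)
            table = find_markers(adata, groups, min_pct=0.1, logfc_min=0.0, alpha_adj=0.05)
            clean += not table["significant"].any()
        assert clean >= 95

    def test_top_markers_caps_per_group(self):
        adata, groups = _grouped_adata()
        table = find_markers(adata, groups, min_pct=0.0, logfc_min=0.0)
        top = top_markers(table, n=3)
        assert top.groupby("group").size().max() <= 3


class TestDualVsUnion:
    def test_no_dual_cells_is_a_status_not_an_error(self):
        adata, groups = _grouped_adata()
        labels = np.array(["CT"] * 40 + ["M"] * 40)
        from limbdual import MarkerPanel

        panel = MarkerPanel(ct_genes=("G2", "G3"), m_genes=("G4", "G5"))
        de, summary, status = de_dual_vs_union(adata, labels, panel)
        assert status == "no dual cells"
        assert de.empty and summary.empty

    def test_planted_shift_flagged_down_and_up(self):
        rng = np.random.default_rng(9)
        n = 90
        counts = rng.poisson(5, size=(3 * n, 12))
        counts[:, 0] += 20          # "ct marker": high everywhere except M
        counts[2 * n :, 0] = rng.poisson(1, n)
        counts[n : 2 * n, 0] = rng.poisson(8, n)  # dual cells: lower than CT
        counts[2 * n :, 1] += 25    # "m marker": high in M
        counts[n : 2 * n, 1] += 25  # and just as high in dual cells
        adata = make_adata(counts)
        labels = np.array(["CT"] * n + ["CT_M"] * n + ["M"] * n)
        from limbdual import MarkerPanel

        panel = MarkerPanel(ct_genes=("G0",), m_genes=("G1",))
        _, summary, status = de_dual_vs_union(adata, labels, panel)
        assert status == "ok"
        calls = summary.set_index("gene")["call"]
        assert calls["G0"] == "down"
        assert calls["G1"] == "up"


class TestFractionExpressing:
    def test_eight_vs_two_of_ten(self):
        counts = np.zeros((20, 3), dtype=int)
        counts[:, 2] = 5
        counts[:8, 0] = 1
        counts[10:12, 0] = 1
        adata = make_adata(counts)
        labels = np.array(["CT"] * 10 + ["M"] * 10)
        out = fraction_expressing_compare(adata, ["G0"], labels, "CT", "M")
        row = out[out["gene"] == "G0"].iloc[0]
        assert row["frac_CT"] == pytest.approx(0.8)
        assert row["frac_M"] == pytest.approx(0.2)
        assert row["p"] == pytest.approx(fisher_exact_2x2([[8, 2], [2, 8]]), abs=1e-12)

    def test_identical_groups_give_p_one(self):
        counts = np.zeros((20, 2), dtype=int)
        counts[:, 1] = 5
        counts[:4, 0] = 1  # two expressing cells in each alternating group
        adata = make_adata(counts)
        labels = np.array(["CT", "M"] * 10)
        out = fraction_expressing_compare(adata, ["G0"], labels, "CT", "M")
        assert (out["p"] == 1.0).all()

    def test_pooled_row_uses_any_gene(self):
        counts = np.zeros((10, 3), dtype=int)
        counts[:, 2] = 5
        counts[:5, 0] = 1  # group A expresses G0 only
        adata = make_adata(counts)
        labels = np.array(["A"] * 5 + ["B"] * 5)
        out = fraction_expressing_compare(adata, ["G0", "G1"], labels, "A", "B")
        pooled = out[out["gene"] == "__pooled__"].iloc[0]
        assert pooled["frac_A"] == 1.0 and pooled["frac_B"] == 0.0


# ---------------------------------------------------------------------------
# qPCR ddCt
# ---------------------------------------------------------------------------

def _ddct_frame(samples):
    rows = []
    for sample, cond, cts in samples:
        for gene, ct in cts.items():
            rows.append((sample, cond, gene, ct))
    return pd.DataFrame(rows, columns=["sample", "condition", "gene", "ct"])


class TestDdct:
    def test_unit_ddct_halves_expression(self):
        data = _ddct_frame(
            [
                ("c1", "control", {"T": 23, "GAPDH": 20, "RPS17": 20}),
                ("s1", "treat", {"T": 24, "GAPDH": 20, "RPS17": 20}),
            ]
        )
        out = ddct(data, "T").table
        assert out.loc["s1", "rel_level"] == pytest.approx(0.5)
        assert out.loc["c1", "rel_level"] == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        # target 25 with refs (20, 22): dCt = 4; control dCt = 3 -> level 0.5
        data = _ddct_frame(
            [
                ("c1", "control", {"T": 24, "GAPDH": 20, "RPS17": 22}),
                ("s1", "treat", {"T": 25, "GAPDH": 20, "RPS17": 22}),
            ]
        )
        out = ddct(data, "T").table
        assert out.loc["s1", "delta_ct"] == pytest.approx(4.0)
        assert out.loc["s1", "rel_level"] == pytest.approx(0.5)

    def test_control_condition_geometric_mean_is_one(self):
        data = _ddct_frame(
            [
                ("c1", "control", {"T": 22.0, "GAPDH": 20, "RPS17": 20}),
                ("c2", "control", {"T": 24.5, "GAPDH": 20, "RPS17": 20}),
                ("s1", "treat", {"T": 21.0, "GAPDH": 20, "RPS17": 20}),
            ]
        )
        out = ddct(data, "T").table
        controls = out.loc[out["condition"] == "control", "rel_level"]
        assert np.exp(np.log(controls).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_global_ct_shift(self):
        base = [
            ("c1", "control", {"T": 23, "GAPDH": 19, "RPS17": 21}),
            ("s1", "treat", {"T": 26, "GAPDH": 20, "RPS17": 20}),
            ("s2", "treat", {"T": 22, "GAPDH": 18, "RPS17": 19}),
        ]
        shifted = [(s, c, {g: ct + 3.5 for g, ct in d.items()}) for s, c, d in base]
        r1 = ddct(_ddct_frame(base), "T").table["rel_level"]
        r2 = ddct(_ddct_frame(shifted), "T").table["rel_level"]
        np.testing.assert_allclose(r1, r2)

    def test_missing_reference_is_error(self):
        data = _ddct_frame([("c1", "control", {"T": 23, "GAPDH": 20})])
        with pytest.raises(ValueError, match="RPS17"):
            ddct(data, "T")

    def test_missing_control_condition_is_error(self):
        data = _ddct_frame([("s1", "treat", {"T": 23, "GAPDH": 20, "RPS17": 20})])
        with pytest.raises(ValueError, match="control"):
            ddct(data, "T")
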