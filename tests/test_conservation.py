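"""Gene conservation scoring, grouping, KS and chi-square comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cytoqtl.conservation import (assign_groups, chi2_enrichment,
                                  gene_conservation_score, ks_one_sided,
                                  run_comparisons, score_genes)
from cytoqtl.synth import GeneConservation


def _gc(cds, elements, scores):
    return GeneConservation(chrom="chr1", cds=cds, elements=elements,
                            scores=scores)


class TestGeneScore:
    def test_all_sites_score_one(self):
        gc = _gc([(0, 10)], [(2, 6)], [(2, 6, 1.0)])
        assert gene_conservation_score(gc) == pytest.approx(1.0)

    def test_hand_interval_intersection(self):
        """CDS [10,20); elements [0,12)@0.9 and [15,18)@0.6 ->
        sites 10,11 at 0.9 and 15,16,17 at 0.6 -> 0.72."""
        gc = _gc([(10, 20)], [(0, 12), (15, 18)],
                 [(0, 12, 0.9), (15, 18, 0.6)])
        assert gene_conservation_score(gc) == pytest.approx(0.72, abs=1e-9)

    def test_no_overlap_is_missing(self):
        gc = _gc([(100, 200)], [(0, 10)], [(0, 10, 0.5)])
        assert gene_conservation_score(gc) is None

    def test_split_elements_invariant(self):
        whole = _gc([(0, 20)], [(4, 12)], [(4, 12, 0.7)])
        split = _gc([(0, 20)], [(4, 8), (8, 12)], [(4, 12, 0.7)])
        assert (gene_conservation_score(whole)
                == pytest.approx(gene_conservation_score(split), abs=1e-12))

    def test_element_weighted_differs_when_lengths_differ(self):
        gc = _gc([(0, 100)], [(0, 8), (10, 12)],
                 [(0, 8, 1.0), (10, 12, 0.0)])
        site = gene_conservation_score(gc)                  # 8/10
        element = gene_conservation_score(gc, element_weighted=True)  # 0.5
        assert site == pytest.approx(0.8)
        assert element == pytest.approx(0.5)

    def test_uncovered_site_rejected(self):
        gc = _gc([(0, 10)], [(0, 6)], [(0, 3, 0.5)])
        with pytest.raises(ValueError, match="coverage"):
            gene_conservation_score(gc)

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            gene_conservation_score(_gc([(10, 10)], [(0, 5)], [(0, 5, 1.0)]))


class TestAssignGroups:
    def _classified(self, rows):
        return pd.DataFrame(rows, columns=["gene", "cell_type", "mode"])

    def test_b_subtypes_collapse_to_single_type(self):
        out = assign_groups(self._classified(
            [("g", "proB", "cis"), ("g", "lateB", "cis")]))
        assert not out["multi_cell_type"].iloc[0]

    def test_distinct_collapsed_types_are_multi(self):
        out = assign_groups(self._classified(
            [("g", "GN", "cis"), ("g", "CD4", "cis")]))
        assert out["multi_cell_type"].iloc[0]

    def test_gn_mo_collapse(self):
        out = assign_groups(self._classified(
            [("g", "GN", "cis"), ("g", "MO", "cis")]))
        assert not out["multi_cell_type"].iloc[0]

    def test_any_trans_association_flags_gene(self):
        out = assign_groups(self._classified(
            [("g", "B", "cis"), ("g", "NK", "trans")]))
        assert out["has_cyto_trans"].iloc[0]


class TestKS:
    def test_identical_samples(self):
        d, p = ks_one_sided([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_fully_separated_samples(self):
        """a = {1,2,3}, b = {4,5,6}: D = 1, p = exp(-3)."""
        d, p = ks_one_sided([1, 2, 3], [4, 5, 6])
        assert d == pytest.approx(1.0)
        assert p == pytest.approx(np.exp(-3.0), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_one_sided([], [1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_d_matches_brute_force_sup(self, seed):
        """On instances of size <= 20, D equals the brute-force sup of
        ECDF_a - ECDF_b over all pooled points, and scipy's one-sided
        statistic."""
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(2, 21))
        b = rng.normal(0.3, 1, rng.integers(2, 21))
        d, p = ks_one_sided(a, b)
        brute = max(max((a <= x).mean() - (b <= x).mean()
                        for x in np.concatenate([a, b])), 0.0)
        assert d == pytest.approx(brute, abs=1e-12)
        scipy_d = stats.ks_2samp(a, b, alternative="greater").statistic
        assert d == pytest.approx(scipy_d, abs=1e-12)
        assert 0.0 <= d <= 1.0 and 0.0 < p <= 1.0

    def test_exact_option_delegates_to_exact_distribution(self):
        a, b = [1.0, 2.0, 3.0], [2.5, 3.5, 4.5]
        d, p = ks_one_sided(a, b, exact=True)
        ref = stats.ks_2samp(a, b, alternative="greater", method="exact")
        assert d == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


class TestChi2:
    def test_exact_independence(self):
        stat, p = chi2_enrichment([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_table(self):
        """[[20,10],[10,20]]: chi2 = 60*(20*20-10*10)^2 / 30^4 = 6.667."""
        stat, p = chi2_enrichment([[20, 10], [10, 20]])
        assert stat == pytest.approx(20.0 / 3.0, abs=1e-9)
        assert p == pytest.approx(0.009823274507519235, abs=1e-12)

    def test_row_swap_invariant(self):
        s1, _ = chi2_enrichment([[20, 10], [10, 20]])
        s2, _ = chi2_enrichment([[10, 20], [20, 10]])
        assert s1 == pytest.approx(s2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            chi2_enrichment([[0, 0], [5, 5]])


class TestRunComparisons:
    def _records(self, rng, n=40, shift=True):
        trans = np.arange(n) < n // 2
        scores = np.where(trans, rng.beta(4, 6, n), rng.beta(7, 3, n))
        return pd.DataFrame({
            "gene": [f"g{i}" for i in range(n)],
            "mean_conservation": scores,
            "has_cyto_trans": trans,
            "multi_cell_type": rng.random(n) < 0.5,
        })

    def test_planted_shift_detected(self, rng):
        rep = run_comparisons(self._records(rng, n=80))
        assert rep["comparisons"]["trans_vs_cis_only"]["p"] < 0.05

    def test_small_group_skipped_with_note(self, rng):
        rec = self._records(rng, n=10)
        rec["multi_cell_type"] = False
        rep = run_comparisons(rec)
        assert "skipped" in rep["comparisons"]["multi_vs_single"]

    def test_missing_scores_dropped_and_counted(self, rng):
        rec = self._records(rng, n=20)
        rec.loc[:4, "mean_conservation"] = np.nan
        rep = run_comparisons(rec)
        assert rep["n_genes_missing"] == 5
        assert rep["n_genes_scored"] == 15

    def test_background_curves_exported(self, rng):
        rep = run_comparisons(self._records(rng),
                              background={"immune_set": rng.beta(5, 5, 30)})
        assert "background_immune_set" in rep["ecdf"]


def test_score_genes_returns_nan_for_missing(default_panel):
    scores = score_genes(default_panel.conservation)
    empties = [g for g, gc in default_panel.conservation.items()
               if not gc.elements]
    assert scores[empties].isna().all()
    ok = scores.dropna()
    assert ((ok >= 0) & (ok <= 1)).all()
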