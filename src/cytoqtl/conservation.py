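"""Gene-level evolutionary conservation and group comparisons.

Each gene's conservation is the mean of per-site scores (e.g. PhastCons
posterior probabilities of negative selection) over the positions where a
conserved element overlaps the gene's coding sequence; genes with no such
overlap have a missing score. Genes are then grouped by whether any of
their associations is cyto-trans and by whether they associate with more
than one cell type after lineage collapsing (all B subtypes count as one
type, granulocytes + monocytes as one). Groups are compared with a
one-sided two-sample Kolmogorov-Smirnov test (alternative: the focal group
is less conserved) and a Pearson chi-square enrichment test.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .synth import GeneConservation

#: Lineage collapsing used when counting distinct associated cell types.
LINEAGE_COLLAPSE = {"B": "B-lineage", "proB": "B-lineage", "lateB": "B-lineage",
                    "GN": "myeloid", "MO": "myeloid"}


# ---------------------------------------------------------------------------
# interval machinery

def _check_intervals(ivals, name):
    for s, e in ivals:
        if s >= e:
            raise ValueError(f"malformed {name} interval [{s}, {e})")


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]):
    """Intersection of two interval sets (0-based half-open, need not be
    sorted or disjoint on input)."""
    out = []
    for s1, e1 in sorted(a):
        for s2, e2 in sorted(b):
            s, e = max(s1, s2), min(e1, e2)
            if s < e:
                out.append((s, e))
    # merge overlaps introduced by overlapping inputs
    out.sort()
    merged: list[tuple[int, int]] = []
    for s, e in out:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _score_sum(interval, runs):
    """(sum of per-site scores, site count) over one interval, from
    bedgraph-style (start, end, value) runs. Errors on uncovered sites."""
    s, e = interval
    total, covered = 0.0, 0
    for rs, re, v in runs:
        lo, hi = max(s, rs), min(e, re)
        if lo < hi:
            total += v * (hi - lo)
            covered += hi - lo
    if covered != e - s:
        raise ValueError(f"positions in [{s}, {e}) lack score-track coverage")
    return total, covered


def gene_conservation_score(gc: GeneConservation,
                            element_weighted: bool = False) -> float | None:
    """Mean conservation over (conserved elements ∩ CDS) sites, or None.

    Site-weighted by default: every overlapping site contributes equally.
    ``element_weighted`` instead averages per-element means, giving short
    elements the same weight as long ones.
    """
    _check_intervals(gc.cds, "CDS")
    _check_intervals(gc.elements, "element")
    if element_weighted:
        means = []
        for el in gc.elements:
            overlap = _intersect([el], gc.cds)
            if not overlap:
                continue
            tot = cnt = 0
            for iv in overlap:
                t, c = _score_sum(iv, gc.scores)
                tot, cnt = tot + t, cnt + c
            means.append(tot / cnt)
        return float(np.mean(means)) if means else None
    overlap = _intersect(gc.elements, gc.cds)
    if not overlap:
        return None
    tot = cnt = 0
    for iv in overlap:
        t, c = _score_sum(iv, gc.scores)
        tot, cnt = tot + t, cnt + c
    return tot / cnt


def score_genes(conservation: dict[str, GeneConservation],
                element_weighted: bool = False) -> pd.Series:
    """Per-gene conservation scores; genes without CDS-overlapping conserved
    elements come back as NaN."""
    out = {}
    for g, gc in conservation.items():
        score = gene_conservation_score(gc, element_weighted)
        out[g] = np.nan if score is None else score
    return pd.Series(out, dtype=float, name="mean_conservation")


# ---------------------------------------------------------------------------
# grouping

def assign_groups(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-gene evolutionary comparison flags.

    has_cyto_trans: the gene has at least one trans association.
    multi_cell_type: the gene associates with >= 2 cell types after lineage
    collapsing. Unclassifiable associations are ignored.
    """
    known = classified[classified["mode"].notna()]
    rows = []
    for gene, sub in known.groupby("gene"):
        collapsed = {LINEAGE_COLLAPSE.get(ct, ct) for ct in sub["cell_type"]}
        rows.append({
            "gene": gene,
            "has_cyto_trans": bool((sub["mode"] == "trans").any()),
            "multi_cell_type": len(collapsed) >= 2,
        })
    return pd.DataFrame(rows, columns=["gene", "has_cyto_trans",
                                       "multi_cell_type"])


# ---------------------------------------------------------------------------
# statistics

def ks_one_sided(sample_a, sample_b, exact: bool = False):
    """One-sided two-sample KS test that group a is stochastically smaller.

    D = sup_x [ECDF_a(x) - ECDF_b(x)]; the asymptotic p-value is the
    standard one-sided tail bound exp(-2 D^2 n_a n_b / (n_a + n_b)).
    ``exact=True`` delegates to the exact small-sample distribution.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two non-empty samples")
    if exact:
        res = stats.ks_2samp(a, b, alternative="greater", method="exact")
        return float(res.statistic), float(res.pvalue)
    pooled = np.concatenate([a, b])
    ecdf_a = np.searchsorted(np.sort(a), pooled, side="right") / a.size
    ecdf_b = np.searchsorted(np.sort(b), pooled, side="right") / b.size
    d = float(max(np.max(ecdf_a - ecdf_b), 0.0))
    n_eff = a.size * b.size / (a.size + b.size)
    p = min(1.0, math.exp(-2.0 * d * d * n_eff))
    return d, p


def chi2_enrichment(table, correction: bool = False):
    """Pearson chi-square with 1 df on a 2x2 gene-count table
    (has_cyto_trans x multi_cell_type); no continuity correction by default."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or t.sum() == 0:
        raise ValueError("need a non-negative, non-empty 2x2 table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected == 0).any():
        raise ValueError("a margin of the 2x2 table is zero: expected cell = 0")
    res = stats.chi2_contingency(t, correction=correction)
    return float(res.statistic), float(res.pvalue)


def _ecdf_table(scores: np.ndarray, group: str) -> pd.DataFrame:
    x = np.sort(scores)
    return pd.DataFrame({"group": group, "score": x,
                         "ecdf": np.arange(1, x.size + 1) / x.size})


def run_comparisons(records: pd.DataFrame,
                    background: dict[str, np.ndarray] | None = None,
                    exact: bool = False) -> dict:
    """The three one-sided KS comparisons plus the chi-square enrichment.

    ``records`` columns: gene, mean_conservation, has_cyto_trans,
    multi_cell_type. Genes with missing conservation are dropped pairwise;
    a comparison with a group of < 2 genes is skipped with a report entry.
    ``background`` may provide extra score vectors (e.g. immune-set and
    non-immune genes) exported alongside the ECDF tables.
    """
    rec = records.dropna(subset=["mean_conservation"])
    report: dict = {"n_genes_scored": int(len(rec)),
                    "n_genes_missing": int(records["mean_conservation"].isna().sum()),
                    "comparisons": {}, "ecdf": {}}

    def _compare(name, mask_a, mask_b, label_a, label_b):
        a = rec.loc[mask_a, "mean_conservation"].to_numpy()
        b = rec.loc[mask_b, "mean_conservation"].to_numpy()
        if a.size < 2 or b.size < 2:
            report["comparisons"][name] = {
                "skipped": f"group sizes {a.size} vs {b.size} (< 2)"}
            return
        d, p = ks_one_sided(a, b, exact=exact)
        report["comparisons"][name] = {"D": d, "p": p,
                                       "n_a": int(a.size), "n_b": int(b.size)}
        report["ecdf"][name] = pd.concat([_ecdf_table(a, label_a),
                                          _ecdf_table(b, label_b)],
                                         ignore_index=True)

    trans = rec["has_cyto_trans"].to_numpy(dtype=bool)
    multi = rec["multi_cell_type"].to_numpy(dtype=bool)
    _compare("trans_vs_cis_only", trans, ~trans, "has_cyto_trans", "cis_only")
    _compare("multi_vs_single", multi, ~multi, "multi_cell_type", "single_cell_type")
    _compare("trans_vs_cis_within_multi", trans & multi, ~trans & multi,
             "multi_trans", "multi_cis_only")

    t = np.array([[int((trans & multi).sum()), int((trans & ~multi).sum())],
                  [int((~trans & multi).sum()), int((~trans & ~multi).sum())]])
    try:
        stat, p = chi2_enrichment(t)
        report["chi2_trans_multi"] = {"table": t.tolist(), "statistic": stat, "p": p}
    except ValueError as err:
        report["chi2_trans_multi"] = {"table": t.tolist(), "skipped": str(err)}

    if background:
        for name, scores in background.items():
            scores = np.asarray(scores, dtype=float)
            scores = scores[~np.isnan(scores)]
            if scores.size:
                report["ecdf"][f"background_{name}"] = _ecdf_table(scores, name)
    return report
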