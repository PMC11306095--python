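"""Cyto-cis / cyto-trans classification of gene--cell-type associations.

A gene associated with the frequency of a cell type in which it is itself
expressed acts in *cyto-cis*; a gene associated with a cell type in which it
is silent acts in *cyto-trans* and must exert its effect through some other
cell type. Expression calls come from a sorted-population reference matrix
binarized at the microarray detection threshold of 47 a.u. (below which a
gene is silent with >= 95% probability; above 120 a.u. it is expressed with
>= 95% probability — 47 is the conservative choice against over-calling
trans). When an assayed cell type maps to several reference populations,
expression in any one of them counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Conservative detection threshold (arbitrary microarray units).
EXPRESSION_THRESHOLD = 47.0


def binarize_expression(matrix: pd.DataFrame,
                        threshold: float = EXPRESSION_THRESHOLD) -> pd.DataFrame:
    """Boolean expressed/silent calls: expressed iff intensity >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression intensities must be non-negative")
    return matrix.ge(threshold)


def gene_expressed_in_celltype(gene: str, cell_type: str,
                               boolean_matrix: pd.DataFrame,
                               population_map: dict) -> bool:
    """True iff any reference population mapped to ``cell_type`` expresses
    the gene."""
    if cell_type not in population_map:
        raise KeyError(f"cell type {cell_type!r} not covered by the population map")
    pops = list(population_map[cell_type])
    missing = [p for p in pops if p not in boolean_matrix.index]
    if missing:
        raise KeyError(f"populations {missing} absent from the expression matrix")
    return bool(boolean_matrix.loc[pops, gene].any())


def classify_associations(assoc: pd.DataFrame, boolean_matrix: pd.DataFrame,
                          population_map: dict) -> pd.DataFrame:
    """Label each association cis or trans; record the expressed-in set.

    Genes absent from the expression reference are flagged unclassifiable
    (mode NaN) and excluded from tallies downstream.
    """
    cell_types = list(population_map)
    modes, expressed_sets = [], []
    for rec in assoc.itertuples():
        if rec.gene not in boolean_matrix.columns:
            modes.append(None)
            expressed_sets.append(None)
            continue
        expr_in = tuple(ct for ct in cell_types
                        if gene_expressed_in_celltype(rec.gene, ct,
                                                      boolean_matrix,
                                                      population_map))
        modes.append("cis" if rec.cell_type in expr_in else "trans")
        expressed_sets.append(expr_in)
    out = assoc.copy().reset_index(drop=True)
    out["mode"] = modes
    out["expressed_in"] = expressed_sets
    return out


def tally(classified: pd.DataFrame) -> dict:
    """Counts, percentages and the trans bipartite edge list.

    Returns overall and per-cell-type cis/trans counts with percentages (one
    decimal of precision is meaningful), distinct gene counts per mode, and
    for every trans association one edge per cell type expressing the gene
    (source = expressing cell type, target = associated cell type).
    """
    if classified.empty:
        return {"n_total": 0, "n_cis": 0, "n_trans": 0, "n_unclassifiable": 0,
                "pct_cis": 0.0, "pct_trans": 0.0, "genes_cis": 0,
                "genes_trans": 0, "per_cell_type": {},
                "trans_edges": pd.DataFrame(columns=["source_celltype",
                                                     "target_celltype", "gene"])}
    known = classified[classified["mode"].notna()]
    n_cis = int((known["mode"] == "cis").sum())
    n_trans = int((known["mode"] == "trans").sum())
    n_known = n_cis + n_trans
    per_ct = {}
    for ct, sub in known.groupby("cell_type"):
        c = int((sub["mode"] == "cis").sum())
        t = int((sub["mode"] == "trans").sum())
        per_ct[ct] = {"n_cis": c, "n_trans": t,
                      "pct_cis": 100.0 * c / max(1, c + t),
                      "pct_trans": 100.0 * t / max(1, c + t)}
    edges = []
    for rec in known[known["mode"] == "trans"].itertuples():
        for src in rec.expressed_in:
            edges.append({"source_celltype": src,
                          "target_celltype": rec.cell_type, "gene": rec.gene})
    return {
        "n_total": int(len(classified)),
        "n_cis": n_cis,
        "n_trans": n_trans,
        "n_unclassifiable": int(classified["mode"].isna().sum()),
        "pct_cis": 100.0 * n_cis / max(1, n_known),
        "pct_trans": 100.0 * n_trans / max(1, n_known),
        "genes_cis": int(known.loc[known["mode"] == "cis", "gene"].nunique()),
        "genes_trans": int(known.loc[known["mode"] == "trans", "gene"].nunique()),
        "per_cell_type": per_ct,
        "trans_edges": pd.DataFrame(edges, columns=["source_celltype",
                                                    "target_celltype", "gene"]),
    }
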