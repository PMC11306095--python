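"""End-to-end orchestration: panel -> prep -> scan -> validate -> propagate
-> classify -> conserve, with per-stage artifacts and a final JSON report.

A single global seed deterministically derives all per-stage seeds, so a
run is bit-reproducible, and any stage can be re-run from its persisted
inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from . import conservation as cons
from . import propagate as prop
from .haplotypes import compute_kinship, filter_loci, reconstruct_haplotypes
from .replication import validate_associations
from .scan import collapse_to_genes, loo_stability, permutation_threshold
from .synth import PanelConfig, SyntheticPanel, generate_panel

log = logging.getLogger("cytoqtl")

HUMAN_CELL_TYPES = ("basophil", "eosinophil", "lymphocyte", "monocyte",
                    "neutrophil")


@dataclass
class StageParams:
    """Tunable parameters of the analysis stages."""

    eps: float = 0.01               # HMM genotyping-error emission
    tau: float = 0.002              # HMM per-interval founder-switch probability
    n_perm: int = 100
    fdr_level: float = 0.05
    alpha_validation: float = 0.05
    pool_replicates: bool = False
    k_min: int = 2
    k_max: int = 10
    threshold_fraction: float = 0.4
    expression_threshold: float = 47.0
    ks_exact: bool = False
    element_weighted: bool = False
    seed: int = 0


def _stage_seed(base: int, stage: int) -> int:
    return int(np.random.SeedSequence([base, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(panel: SyntheticPanel | PanelConfig,
                 params: StageParams | None = None,
                 outdir=None) -> dict:
    """Run the full inference chain and return the report dict.

    ``panel`` may be an already generated panel or a PanelConfig (the panel
    is then generated first). When ``outdir`` is given, every stage artifact
    is written there as TSV/JSON.
    """
    params = params or StageParams()
    if isinstance(panel, PanelConfig):
        panel = generate_panel(panel)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: locus prep -------------------------------------------------
    filtered, filter_report = filter_loci(panel.genotypes)
    log.info("locus filter: %s", filter_report)
    if filtered.n_loci == 0:
        raise RuntimeError("no loci survive filtering; nothing to scan")
    probs = reconstruct_haplotypes(filtered, eps=params.eps, tau=params.tau)
    K = compute_kinship(probs)
    if out is not None:
        pd.DataFrame(K, index=filtered.strains,
                     columns=filtered.strains).to_csv(out / "kinship.tsv", sep="\t")

    # --- stage 2: discovery-cohort scan -------------------------------------
    ph = panel.phenotypes
    disc = ph.samples["cohort"].to_numpy() == 1
    strain_row = {s: i for i, s in enumerate(filtered.strains)}
    soi = ph.samples.loc[disc, "strain"].map(strain_row).to_numpy()
    cell_types = list(ph.freq.columns)

    stage1_frames, scan_lods, thresholds = [], {}, {}
    for j, ct in enumerate(cell_types):
        y = ph.freq.loc[disc, ct].to_numpy()
        seed_ct = _stage_seed(params.seed, 100 + j)
        thr, obs, _ = permutation_threshold(
            y, probs.probs, K, n_perm=params.n_perm,
            fdr_level=params.fdr_level, seed=seed_ct, strain_of_sample=soi)
        scan_lods[ct] = obs
        thresholds[ct] = thr
        candidates = np.where(obs >= thr)[0]
        retained = loo_stability(y, probs.probs, K, candidates, thr,
                                 strain_of_sample=soi)
        stage1_frames.append(collapse_to_genes(obs, retained, filtered.loci, ct))
        log.info("scan %s: threshold=%.3g, %d candidate loci, %d retained",
                 ct, thr, candidates.size, retained.size)
        if out is not None:
            pd.DataFrame({"locus": np.arange(obs.size), "lod": obs}).to_csv(
                out / f"scan_{ct}.tsv", sep="\t", index=False)
    nonempty = [f for f in stage1_frames if not f.empty]
    stage1 = (pd.concat(nonempty, ignore_index=True) if nonempty
              else stage1_frames[0])
    if out is not None:
        pd.Series(thresholds, name="threshold").rename_axis("cell_type").to_csv(
            out / "thresholds.tsv", sep="\t")
        stage1.to_csv(out / "associations_stage1.tsv", sep="\t", index=False)

    # --- stage 3: validation cohort ------------------------------------------
    validation = validate_associations(stage1, filtered, ph,
                                       alpha=params.alpha_validation,
                                       pool_replicates=params.pool_replicates)
    validated = validation[validation["validated"]]
    if out is not None:
        validation.to_csv(out / "validation.tsv", sep="\t", index=False)

    # --- stage 4: signal propagation -----------------------------------------
    genes_v = sorted(validated["gene"].unique())
    if genes_v:
        lod_matrix = pd.DataFrame(0.0, index=genes_v, columns=cell_types)
        gene_loci = {g: np.where(filtered.loci["gene"].to_numpy() == g)[0]
                     for g in genes_v}
        for ct in cell_types:
            for g in genes_v:
                lod_matrix.loc[g, ct] = scan_lods[ct][gene_loci[g]].max()
        labels, chosen_k = prop.cluster_genes(
            lod_matrix, k_range=(params.k_min, params.k_max),
            seed=_stage_seed(params.seed, 200))
        propagation = prop.propagate(labels, lod_matrix, validated,
                                     threshold_fraction=params.threshold_fraction)
        final = propagation["associations"]
    else:
        labels, chosen_k = pd.Series(dtype=int), 0
        final = validated[["gene", "cell_type"]].assign(origin="validated")
    if out is not None:
        labels.rename("cluster").rename_axis("gene").to_csv(
            out / "clusters.tsv", sep="\t")
        final.to_csv(out / "propagated_associations.tsv", sep="\t", index=False)

    # --- stage 5: cis/trans classification ------------------------------------
    boolean = cls.binarize_expression(panel.expression,
                                      params.expression_threshold)
    classified = cls.classify_associations(final, boolean, panel.population_map)
    tallies = cls.tally(classified)
    if out is not None:
        exp = classified.copy()
        exp["expressed_in"] = exp["expressed_in"].map(
            lambda t: ",".join(t) if t is not None else "")
        exp.to_csv(out / "classified_associations.tsv", sep="\t", index=False)
        tallies["trans_edges"].to_csv(out / "trans_edges.tsv", sep="\t", index=False)

    # --- stage 6: conservation -------------------------------------------------
    scores = cons.score_genes(panel.conservation,
                              element_weighted=params.element_weighted)
    groups = cons.assign_groups(classified)
    records = groups.merge(scores.rename("mean_conservation"),
                           left_on="gene", right_index=True, how="left")
    immune = panel.genotypes.immune_genes
    background = {
        "immune_set": scores[scores.index.isin(immune)].to_numpy(),
        "non_immune": scores[~scores.index.isin(immune)].to_numpy(),
    }
    fig4 = cons.run_comparisons(records, background=background,
                                exact=params.ks_exact)
    if out is not None:
        records.to_csv(out / "gene_conservation.tsv", sep="\t", index=False)
        for name, tab in fig4["ecdf"].items():
            tab.to_csv(out / f"ecdf_{name}.tsv", sep="\t", index=False)

    report = {
        "params": dataclasses.asdict(params),
        "panel_seed": panel.config.seed,
        "filter": filter_report,
        "thresholds": {k: (v if np.isfinite(v) else None)
                       for k, v in thresholds.items()},
        "n_stage1": int(len(stage1)),
        "n_validated": int(len(validated)),
        "n_final": int(len(final)),
        "chosen_k": int(chosen_k),
        "tally": {k: v for k, v in tallies.items() if k != "trans_edges"},
        "n_trans_edges": int(len(tallies["trans_edges"])),
        "fig4": {"comparisons": fig4["comparisons"],
                 "chi2_trans_multi": fig4["chi2_trans_multi"],
                 "n_genes_scored": fig4["n_genes_scored"]},
    }
    report["truth_recovery"] = _truth_recovery(panel, stage1, validated, final,
                                               classified)
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _truth_recovery(panel, stage1, validated, final, classified) -> dict:
    """Score recovered planted signals against the truth record."""
    planted = [(q["gene"], q["cell_type"]) for q in panel.truth.planted_qtl]
    if not planted:
        return {"n_planted": 0}
    def frac(df):
        pairs = set(zip(df["gene"], df["cell_type"]))
        return sum(p in pairs for p in planted) / len(planted)
    mode_of = {(q["gene"], q["cell_type"]): q["mode"]
               for q in panel.truth.planted_qtl}
    correct = total = 0
    for rec in classified.itertuples():
        key = (rec.gene, rec.cell_type)
        if key in mode_of and rec.mode is not None:
            total += 1
            correct += rec.mode == mode_of[key]
    return {
        "n_planted": len(planted),
        "recovered_stage1": frac(stage1),
        "recovered_validated": frac(validated),
        "recovered_final": frac(final),
        "mode_accuracy": (correct / total) if total else None,
    }


# ---------------------------------------------------------------------------
# human re-run

def run_human_mode(associations: pd.DataFrame, expression: pd.DataFrame,
                   scores: pd.Series, apply_lymphocyte_rule: bool = True,
                   exact: bool = False) -> dict:
    """Re-run classification + conservation comparison on human inputs.

    Parameters
    ----------
    associations : (gene, cell_type) table; cell types must be blood
        subsets (basophil, eosinophil, lymphocyte, monocyte, neutrophil).
    expression : pre-binarized boolean table, genes x cell types. May carry
        separate ``B`` and ``T`` columns instead of ``lymphocyte``; with
        ``apply_lymphocyte_rule`` the composite lymphocyte call requires
        expression in both.
    scores : per-gene conservation scores.

    Runs classification, tally, and the trans-vs-cis-only KS comparison;
    no QTL stages.
    """
    bad = set(associations["cell_type"]) - set(HUMAN_CELL_TYPES)
    if bad:
        raise ValueError(f"unknown human cell type labels: {sorted(bad)}")
    expr = expression.astype(bool).copy()
    if apply_lymphocyte_rule and "lymphocyte" not in expr.columns:
        if not {"B", "T"} <= set(expr.columns):
            raise ValueError("need a lymphocyte column or both B and T columns")
        expr["lymphocyte"] = expr["B"] & expr["T"]
    expr = expr[[c for c in expr.columns if c in HUMAN_CELL_TYPES]]
    boolean = expr.T                      # populations (cell types) x genes
    popmap = {ct: (ct,) for ct in boolean.index}

    classified = cls.classify_associations(associations, boolean, popmap)
    tallies = cls.tally(classified)
    groups = cons.assign_groups(classified)
    records = groups.merge(scores.rename("mean_conservation"),
                           left_on="gene", right_index=True, how="left")
    rec = records.dropna(subset=["mean_conservation"])
    report = {"tally": {k: v for k, v in tallies.items() if k != "trans_edges"},
              "comparisons": {}}
    a = rec.loc[rec["has_cyto_trans"], "mean_conservation"].to_numpy()
    b = rec.loc[~rec["has_cyto_trans"], "mean_conservation"].to_numpy()
    if a.size >= 2 and b.size >= 2:
        d, p = cons.ks_one_sided(a, b, exact=exact)
        report["comparisons"]["trans_vs_cis_only"] = {
            "D": d, "p": p, "n_a": int(a.size), "n_b": int(b.size)}
    else:
        report["comparisons"]["trans_vs_cis_only"] = {
            "skipped": f"group sizes {a.size} vs {b.size} (< 2)"}
    return report
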