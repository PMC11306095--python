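"""Plain-text readers/writers for panel artifacts.

Every artifact is TSV, BED (0-based half-open), bedgraph or JSON so any
stage can be inspected, replaced, or re-run from disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import (GeneConservation, GenotypeTable, PhenotypeTable,
                    SyntheticPanel, TruthRecord)


def write_panel(panel: SyntheticPanel, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotypes(panel.genotypes, out / "genotypes.tsv")
    write_phenotypes(panel.phenotypes, out / "phenotypes.tsv")
    panel.expression.rename_axis("population").to_csv(out / "expression.tsv", sep="\t")
    pd.DataFrame(
        [{"cell_type": ct, "population": p}
         for ct, ps in panel.population_map.items() for p in ps]
    ).to_csv(out / "population_map.tsv", sep="\t", index=False)
    write_conservation(panel.conservation, out)
    (out / "truth.json").write_text(json.dumps(panel.truth.to_jsonable(), indent=1))


def write_genotypes(gt: GenotypeTable, path) -> None:
    df = gt.loci.copy()
    for i, f in enumerate(gt.founders):
        df[f"F_{f}"] = gt.founder_alleles[i]
    for i, s in enumerate(gt.strains):
        df[f"S_{s}"] = gt.strain_alleles[i]
    df.insert(0, "immune", df["gene"].isin(gt.immune_genes))
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t")
    founders = [c[2:] for c in df.columns if c.startswith("F_")]
    strains = [c[2:] for c in df.columns if c.startswith("S_")]
    loci = df[["chrom", "pos_bp", "gene", "exonic"]].copy()
    fa = df[[f"F_{f}" for f in founders]].to_numpy().T.astype(np.int8)
    sa = df[[f"S_{s}" for s in strains]].to_numpy().T.astype(float)
    immune = set(df.loc[df["immune"], "gene"])
    return GenotypeTable(loci=loci, founder_alleles=fa, strain_alleles=sa,
                         founders=founders, strains=strains, immune_genes=immune)


def write_phenotypes(ph: PhenotypeTable, path) -> None:
    df = ph.samples.copy()
    for ct in ph.freq.columns:
        df[ct] = ph.freq[ct].to_numpy()
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    meta = ["sample", "strain", "cohort", "replicate"]
    cts = [c for c in df.columns if c not in meta]
    samples = df[meta].copy()
    freq = df[cts].copy()
    freq.index = samples["sample"]
    return PhenotypeTable(samples=samples, freq=freq)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_population_map(path) -> dict[str, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t")
    return {ct: tuple(sub["population"]) for ct, sub in df.groupby("cell_type", sort=False)}


def write_conservation(cons: dict[str, GeneConservation], outdir) -> None:
    out = Path(outdir)
    cds_rows, el_rows, score_rows = [], [], []
    for gene, gc in cons.items():
        for s, e in gc.cds:
            cds_rows.append((gc.chrom, s, e, gene))
        for s, e in gc.elements:
            el_rows.append((gc.chrom, s, e, gene))
        for s, e, v in gc.scores:
            score_rows.append((gc.chrom, s, e, v))
    _write_bed(cds_rows, out / "cds.bed")
    _write_bed(el_rows, out / "conserved_elements.bed")
    with open(out / "site_scores.bedgraph", "w") as fh:
        for chrom, s, e, v in score_rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def _write_bed(rows, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, name in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def read_conservation(cds_bed, elements_bed, scores_bedgraph
                      ) -> dict[str, GeneConservation]:
    cds = pd.read_csv(cds_bed, sep="\t", header=None,
                      names=["chrom", "start", "end", "gene"])
    els = pd.read_csv(elements_bed, sep="\t", header=None,
                      names=["chrom", "start", "end", "gene"])
    runs = pd.read_csv(scores_bedgraph, sep="\t", header=None,
                       names=["chrom", "start", "end", "score"])
    out: dict[str, GeneConservation] = {}
    genes = sorted(set(cds["gene"]) | set(els["gene"]))
    for gene in genes:
        c = cds[cds["gene"] == gene]
        e = els[els["gene"] == gene]
        chrom = (c["chrom"].iloc[0] if len(c) else e["chrom"].iloc[0])
        spans = pd.concat([c, e])
        lo, hi = int(spans["start"].min()), int(spans["end"].max())
        r = runs[(runs["chrom"] == chrom) & (runs["end"] > lo) & (runs["start"] < hi)]
        out[gene] = GeneConservation(
            chrom=chrom,
            cds=[(int(a), int(b)) for a, b in zip(c["start"], c["end"])],
            elements=[(int(a), int(b)) for a, b in zip(e["start"], e["end"])],
            scores=[(int(a), int(b), float(v))
                    for a, b, v in zip(r["start"], r["end"], r["score"])],
        )
    return out


def read_truth(path) -> TruthRecord:
    d = json.loads(Path(path).read_text())
    return TruthRecord(planted_qtl=d["planted_qtl"],
                       conservation_group_means=d["conservation_group_means"],
                       cluster_structure=d["cluster_structure"],
                       genes=d["genes"])
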