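"""Synthetic Collaborative-Cross-like panel generator.

Emulates the study design of an eight-founder recombinant-inbred mouse panel
phenotyped for immune-cell frequencies: founder genotypes with gene/exon
annotation, recombinant strain mosaics, replicate phenotypes with planted
additive QTL and kinship-structured noise, a bimodal reference expression
matrix, and per-gene conservation scores with planted group differences.
Every generator is deterministic given the config seed, and a machine-readable
truth record accompanies the panel so downstream stages can be scored against
known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

#: Assayed bone-marrow cell subsets. B-lineage appears as three subtypes and
#: the myeloid compartment as granulocytes + monocytes so that downstream
#: lineage-collapsing rules are exercised.
CELL_TYPES = ("HSC", "NK", "CD4", "CD8", "B", "proB", "lateB", "GN", "MO")

#: Typical bone-marrow frequency baselines per cell type (fraction of live cells).
_BASELINE_FREQ = {
    "HSC": 0.01,
    "NK": 0.02,
    "CD4": 0.10,
    "CD8": 0.08,
    "B": 0.20,
    "proB": 0.03,
    "lateB": 0.05,
    "GN": 0.30,
    "MO": 0.06,
}


@dataclass
class PanelConfig:
    """Parameters of the synthetic panel.

    Counts default to the study design they emulate: 8 founders, 54
    recombinant strains split into a 30-strain discovery cohort and a
    24-strain validation cohort, 2 replicate mice per strain per cohort,
    9 assayed cell types.
    """

    n_founders: int = 8
    n_strains: int = 54
    n_replicates: int = 2
    n_chromosomes: int = 3
    n_loci: int = 300
    n_genes: int = 60
    n_cell_types: int = 9
    n_discovery: int = 30
    recomb_rate: float = 1.0          # expected recombinations / chromosome / strain
    genotyping_error: float = 0.0     # per-call allele flip probability
    allele_flip_rate: float = 0.05    # per-locus divergence from the gene haplotype
    qtl_effect: float = 1.5           # additive allele effect, logit units
    noise_sd: float = 0.25            # replicate-level residual, logit units
    kinship_sd: float = 0.15          # strain-level shared noise, logit units
    missing_rate: float = 0.0         # per (strain, cell type) missingness
    n_cis_qtl: int = 2
    n_trans_qtl: int = 2
    exonic_fraction: float = 0.7
    immune_fraction: float = 0.8
    monomorphic_fraction: float = 0.1
    expr_silent_mean: float = 20.0
    expr_silent_sd: float = 5.0
    expr_expressed_mean: float = 200.0
    expr_expressed_sd: float = 20.0
    expr_base_rate: float = 0.4       # background P(expressed) per (population, gene)
    cons_mean_trans: float = 0.4      # site-score mean, genes with a trans QTL
    cons_mean_other: float = 0.7      # site-score mean, all other genes
    cons_concentration: float = 10.0  # Beta concentration of site scores
    cons_elements_per_gene: float = 3.0
    cons_element_len: int = 20
    cons_missing_element_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_founders": self.n_founders,
            "n_strains": self.n_strains,
            "n_replicates": self.n_replicates,
            "n_chromosomes": self.n_chromosomes,
            "n_loci": self.n_loci,
            "n_genes": self.n_genes,
            "n_cell_types": self.n_cell_types,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.n_loci < self.n_genes:
            raise ValueError("each gene needs at least one locus (n_loci < n_genes)")
        if not 1 <= self.n_cell_types <= len(CELL_TYPES):
            raise ValueError(f"n_cell_types must be in [1, {len(CELL_TYPES)}]")
        if not 0 < self.n_discovery < self.n_strains:
            raise ValueError("n_discovery must split strains into two non-empty cohorts")
        for name in ("recomb_rate", "genotyping_error", "noise_sd", "kinship_sd",
                     "missing_rate", "qtl_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def cell_types(self) -> tuple[str, ...]:
        return CELL_TYPES[: self.n_cell_types]

    @classmethod
    def from_dict(cls, d: dict) -> "PanelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class FounderPanel:
    """Founder alleles plus locus annotation.

    ``loci`` columns: chrom, pos_bp, gene, exonic. Alleles are biallelic
    {0, 1}; founders are fully observed.
    """

    loci: pd.DataFrame
    alleles: np.ndarray            # (n_founders, n_loci) int8
    founders: list[str]
    immune_genes: set[str]


@dataclass
class StrainMosaics:
    """Founder-of-origin label per strain and locus."""

    origins: np.ndarray            # (n_strains, n_loci) int
    strains: list[str]


@dataclass
class GenotypeTable:
    """Observed biallelic genotypes for founders and recombinant strains."""

    loci: pd.DataFrame
    founder_alleles: np.ndarray    # (n_founders, n_loci) int8
    strain_alleles: np.ndarray     # (n_strains, n_loci) float, NaN = missing
    founders: list[str]
    strains: list[str]
    immune_genes: set[str]

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass
class TruthRecord:
    """Ground truth of the planted signals.

    ``planted_qtl`` entries carry the target gene, the causal locus (row index
    into the locus table), the associated cell type, the per-founder additive
    effect vector (logit units) and the planted expression mode.
    """

    planted_qtl: list[dict]
    conservation_group_means: dict[str, float]
    cluster_structure: dict[str, str]
    genes: list[str]

    def to_jsonable(self) -> dict:
        return {
            "planted_qtl": [
                {**q, "effects": [float(e) for e in q["effects"]]}
                for q in self.planted_qtl
            ],
            "conservation_group_means": self.conservation_group_means,
            "cluster_structure": self.cluster_structure,
            "genes": list(self.genes),
        }


@dataclass
class PhenotypeTable:
    """Per-sample immune-cell frequencies.

    ``samples`` columns: sample, strain, cohort, replicate. ``freq`` is a
    samples x cell-types DataFrame of frequencies in (0, 1); NaN marks
    excluded (strain, cell type) measurements.
    """

    samples: pd.DataFrame
    freq: pd.DataFrame


@dataclass
class GeneConservation:
    """Interval data for one gene: CDS, conserved elements, per-site scores.

    All intervals are 0-based half-open on the gene's chromosome. ``scores``
    is a list of (start, end, value) runs covering every conserved-element
    position.
    """

    chrom: str
    cds: list[tuple[int, int]]
    elements: list[tuple[int, int]]
    scores: list[tuple[int, int, float]]


@dataclass
class SyntheticPanel:
    config: PanelConfig
    founders: FounderPanel
    mosaics: StrainMosaics
    genotypes: GenotypeTable
    phenotypes: PhenotypeTable
    expression: pd.DataFrame             # populations x genes
    population_map: dict[str, tuple[str, ...]]
    conservation: dict[str, GeneConservation]
    truth: TruthRecord


# ---------------------------------------------------------------------------
# founders + annotation

def generate_founders(config: PanelConfig, rng: np.random.Generator | None = None):
    """Generate founder alleles with gene/exon annotation.

    Loci are assigned to genes in contiguous blocks along chromosomes; a
    configurable fraction is forced monomorphic across founders so the locus
    filter has something to remove.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_loci, n_genes = config.n_loci, config.n_genes
    genes = [f"Gene{g:03d}" for g in range(n_genes)]
    # contiguous locus blocks per gene, each gene on one chromosome
    gene_of_locus = np.sort(rng.integers(0, n_genes, size=n_loci - n_genes))
    gene_of_locus = np.sort(np.concatenate([gene_of_locus, np.arange(n_genes)]))
    chrom_of_gene = np.sort(rng.integers(0, config.n_chromosomes, size=n_genes))
    chrom = chrom_of_gene[gene_of_locus]

    pos = np.empty(n_loci, dtype=np.int64)
    for c in range(config.n_chromosomes):
        idx = np.where(chrom == c)[0]
        if idx.size:
            pos[idx] = np.sort(rng.choice(np.arange(1, 2_000_001), size=idx.size,
                                          replace=False))
    loci = pd.DataFrame({
        "chrom": [f"chr{c + 1}" for c in chrom],
        "pos_bp": pos,
        "gene": [genes[g] for g in gene_of_locus],
        "exonic": rng.random(n_loci) < config.exonic_fraction,
    })

    # founder allele patterns are locally correlated (shared descent): each
    # gene carries a base pattern that individual loci deviate from at a
    # small flip rate, mimicking LD between nearby exonic variants
    base = (rng.random((config.n_founders, n_genes)) < 0.5)
    flips = rng.random((config.n_founders, n_loci)) < config.allele_flip_rate
    alleles = (base[:, gene_of_locus] ^ flips).astype(np.int8)
    mono = rng.random(n_loci) < config.monomorphic_fraction
    alleles[:, mono] = alleles[0, mono]

    n_immune = int(round(config.immune_fraction * n_genes))
    immune = set(rng.choice(genes, size=n_immune, replace=False))
    founders = [f"F{k}" for k in range(config.n_founders)]
    return FounderPanel(loci=loci, alleles=alleles, founders=founders,
                        immune_genes=immune)


# ---------------------------------------------------------------------------
# truth / planted QTL

def plant_truth(founders: FounderPanel, config: PanelConfig,
                rng: np.random.Generator | None = None) -> TruthRecord:
    """Choose causal loci and plant additive QTL with cis/trans expression modes.

    Each planted QTL sits at an exonic, polymorphic locus of a distinct
    immune-set gene; among eligible loci, those with a balanced founder
    allele split (minor-allele founder count >= 3) are preferred so the
    additive contrast is identifiable in a small panel. The per-founder
    effect vector is ``±qtl_effect x founder allele``, which makes the
    effect collapsible to the biallelic variant for validation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    loci, alleles = founders.loci, founders.alleles
    n_f = config.n_founders
    poly = (alleles != alleles[0]).any(axis=0)
    eligible = np.where(poly & loci["exonic"].to_numpy()
                        & loci["gene"].isin(founders.immune_genes).to_numpy())[0]
    n_qtl = config.n_cis_qtl + config.n_trans_qtl
    if n_qtl == 0:
        return TruthRecord([], _group_means(config), {},
                           sorted(loci["gene"].unique()))
    counts = alleles[:, eligible].sum(axis=0)
    balanced = eligible[(counts >= min(3, n_f - 1)) & (counts <= max(n_f - 3, 1))]
    pool = balanced if balanced.size else eligible
    pool_genes = loci["gene"].to_numpy()[pool]
    _, first = np.unique(pool_genes, return_index=True)
    candidates = pool[np.sort(first)]
    if len(candidates) < n_qtl:
        raise ValueError("not enough eligible (immune, exonic, polymorphic) genes "
                         f"to plant {n_qtl} QTL")
    picked = rng.choice(candidates, size=n_qtl, replace=False)
    cell_types = list(config.cell_types)
    if n_qtl <= len(cell_types):
        # one planted trait per QTL: stacked QTL on a single trait inflate
        # the null-model heritability and are a different power regime
        targets = list(rng.choice(cell_types, size=n_qtl, replace=False))
    else:
        targets = list(rng.choice(cell_types, size=n_qtl, replace=True))
    modes = ["cis"] * config.n_cis_qtl + ["trans"] * config.n_trans_qtl

    planted, cluster = [], {}
    for locus, mode, ct in zip(picked, modes, targets):
        sign = rng.choice([-1.0, 1.0])
        effects = sign * config.qtl_effect * alleles[:, locus].astype(float)
        gene = loci["gene"].iloc[locus]
        planted.append({
            "gene": gene, "cell_type": ct, "locus": int(locus),
            "effects": effects, "mode": mode,
        })
        cluster[gene] = ct
    return TruthRecord(planted_qtl=planted, conservation_group_means=_group_means(config),
                       cluster_structure=cluster, genes=sorted(loci["gene"].unique()))


def _group_means(config: PanelConfig) -> dict[str, float]:
    return {"trans": config.cons_mean_trans, "other": config.cons_mean_other}


# ---------------------------------------------------------------------------
# recombinant strains

def generate_strains(founders: FounderPanel, config: PanelConfig,
                     rng: np.random.Generator | None = None):
    """Build per-chromosome founder mosaics and observed genotypes.

    Breakpoint counts per (strain, chromosome) are Poisson with mean
    ``recomb_rate``; each breakpoint switches to a uniformly drawn different
    founder. Observed genotype is the mosaic founder's allele, flipped with
    probability ``genotyping_error``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n_strains, n_loci = config.n_strains, config.n_loci
    chrom = founders.loci["chrom"].to_numpy()
    origins = np.empty((n_strains, n_loci), dtype=np.int64)

    for s in range(n_strains):
        for c in pd.unique(chrom):
            idx = np.where(chrom == c)[0]
            cur = int(rng.integers(config.n_founders))
            n_bp = rng.poisson(config.recomb_rate)
            if n_bp == 0 or idx.size < 2:
                origins[s, idx] = cur
                continue
            # breakpoints fall uniformly between adjacent loci
            cuts = np.sort(rng.integers(1, idx.size, size=n_bp))
            labels = np.empty(idx.size, dtype=np.int64)
            prev = 0
            for cut in list(cuts) + [idx.size]:
                labels[prev:cut] = cur
                nxt = int(rng.integers(config.n_founders - 1))
                cur = nxt if nxt < cur else nxt + 1
                prev = cut
            origins[s, idx] = labels

    observed = founders.alleles[origins, np.arange(n_loci)].astype(float)
    if config.genotyping_error > 0:
        flip = rng.random(observed.shape) < config.genotyping_error
        observed = np.where(flip, 1.0 - observed, observed)

    strains = [f"CC{s + 1:03d}" for s in range(n_strains)]
    mosaics = StrainMosaics(origins=origins, strains=strains)
    genotypes = GenotypeTable(
        loci=founders.loci, founder_alleles=founders.alleles,
        strain_alleles=observed, founders=founders.founders,
        strains=strains, immune_genes=founders.immune_genes,
    )
    return mosaics, genotypes


# ---------------------------------------------------------------------------
# phenotypes

def generate_phenotypes(mosaics: StrainMosaics, truth: TruthRecord,
                        config: PanelConfig,
                        rng: np.random.Generator | None = None) -> PhenotypeTable:
    """Simulate replicate immune-cell frequencies with planted QTL.

    Generation is on the logit scale so frequencies stay in (0, 1):
    ``logit(freq) = baseline + planted founder effects + strain noise +
    replicate noise``. Discovery and validation cohorts come from disjoint
    strain sets but share the planted effects.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    cell_types = list(config.cell_types)
    n_ct = len(cell_types)
    n_strains = config.n_strains

    genetic = np.zeros((n_strains, n_ct))
    for q in truth.planted_qtl:
        if q["cell_type"] not in cell_types:
            raise ValueError(f"planted cell type {q['cell_type']} not assayed")
        effects = np.asarray(q["effects"], dtype=float)
        if not np.any(effects != effects[0]):
            pass  # a flat effect vector is legal, just undetectable
        origin = mosaics.origins[:, q["locus"]]
        genetic[:, cell_types.index(q["cell_type"])] += effects[origin]

    base = np.array([logit(_BASELINE_FREQ[ct]) for ct in cell_types])
    strain_noise = rng.normal(0.0, config.kinship_sd, size=(n_strains, n_ct))

    rows, values = [], []
    cohort_of_strain = np.where(np.arange(n_strains) < config.n_discovery, 1, 2)
    for s, strain in enumerate(mosaics.strains):
        for r in range(config.n_replicates):
            rep = rng.normal(0.0, config.noise_sd, size=n_ct)
            x = base + genetic[s] + strain_noise[s] + rep
            rows.append({
                "sample": f"{strain}_r{r + 1}", "strain": strain,
                "cohort": int(cohort_of_strain[s]), "replicate": r + 1,
            })
            values.append(expit(x))
    samples = pd.DataFrame(rows)
    freq = pd.DataFrame(values, columns=cell_types, index=samples["sample"])

    if config.missing_rate > 0:
        drop = rng.random((n_strains, n_ct)) < config.missing_rate
        for s, strain in enumerate(mosaics.strains):
            for j in np.where(drop[s])[0]:
                freq.loc[samples.loc[samples["strain"] == strain, "sample"],
                         cell_types[j]] = np.nan
    return PhenotypeTable(samples=samples, freq=freq)


# ---------------------------------------------------------------------------
# expression reference

def default_population_map(cell_types) -> dict[str, tuple[str, ...]]:
    """One reference population per assayed cell type, except B cells which
    map to two subpopulations (exercising the at-least-one rule)."""
    pm = {ct: (f"{ct}.1",) for ct in cell_types}
    if "B" in pm:
        pm["B"] = ("B.1", "B.2")
    return pm


def generate_expression(truth: TruthRecord, config: PanelConfig,
                        rng: np.random.Generator | None = None):
    """Draw a populations x genes intensity matrix from a two-Gaussian mixture.

    Background expression calls are Bernoulli per (population, gene); planted
    cis genes are forced expressed in >= 1 population mapped to their target
    cell type, planted trans genes are forced silent in all of them but
    expressed somewhere else. Silent draws sit well below the 47 a.u.
    detection threshold, expressed draws above 120 a.u.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    genes = truth.genes
    popmap = default_population_map(config.cell_types)
    pops = [p for ps in popmap.values() for p in ps]

    expressed = rng.random((len(pops), len(genes))) < config.expr_base_rate
    pop_idx = {p: i for i, p in enumerate(pops)}
    gene_idx = {g: j for j, g in enumerate(genes)}

    for q in truth.planted_qtl:
        j = gene_idx[q["gene"]]
        mapped = [pop_idx[p] for p in popmap[q["cell_type"]]]
        if q["mode"] == "cis":
            if not expressed[mapped, j].any():
                expressed[mapped[int(rng.integers(len(mapped)))], j] = True
        else:
            expressed[mapped, j] = False
            others = [i for i in range(len(pops)) if i not in mapped]
            if not expressed[others, j].any():
                expressed[others[int(rng.integers(len(others)))], j] = True

    silent_draw = rng.normal(config.expr_silent_mean, config.expr_silent_sd,
                             size=expressed.shape)
    expr_draw = rng.normal(config.expr_expressed_mean, config.expr_expressed_sd,
                           size=expressed.shape)
    # keep planted modes consistent with the 47/120 a.u. detection bands
    silent_draw = np.clip(silent_draw, 0.0, 46.0)
    expr_draw = np.maximum(expr_draw, 120.0)
    mat = np.where(expressed, expr_draw, silent_draw)
    expr = pd.DataFrame(mat, index=pops, columns=genes)
    return expr, popmap


# ---------------------------------------------------------------------------
# conservation

def generate_conservation(truth: TruthRecord, config: PanelConfig,
                          rng: np.random.Generator | None = None,
                          ) -> dict[str, GeneConservation]:
    """Per-gene CDS + conserved elements + Beta-distributed per-site scores.

    Genes carrying a planted trans QTL draw site scores from the lower-mean
    group; all other genes from the higher-mean group. A small fraction of
    genes is emitted with no conserved element overlapping the CDS, which
    downstream scoring must treat as missing.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 5)
    for name, m in _group_means(config).items():
        if not 0.0 < m < 1.0:
            raise ValueError(f"conservation group mean '{name}' must be in (0,1), got {m}")
    trans_genes = {q["gene"] for q in truth.planted_qtl if q["mode"] == "trans"}
    conc = config.cons_concentration
    out: dict[str, GeneConservation] = {}
    for g_i, gene in enumerate(truth.genes):
        chrom = "chrG"
        start = g_i * 10_000
        cds = [(start, start + 600), (start + 800, start + 1_400)]
        mean = (config.cons_mean_trans if gene in trans_genes
                else config.cons_mean_other)
        a, b = mean * conc, (1.0 - mean) * conc
        elements: list[tuple[int, int]] = []
        scores: list[tuple[int, int, float]] = []
        if rng.random() >= config.cons_missing_element_rate or gene in trans_genes:
            n_el = 1 + rng.poisson(max(config.cons_elements_per_gene - 1, 0.0))
            offsets = np.sort(rng.choice(
                np.arange(0, 1_400 - config.cons_element_len,
                          config.cons_element_len),
                size=min(n_el, 1_400 // config.cons_element_len - 1),
                replace=False))
            for off in offsets:
                s, e = start + int(off), start + int(off) + config.cons_element_len
                elements.append((s, e))
                for p, v in zip(range(s, e), rng.beta(a, b, size=e - s)):
                    scores.append((p, p + 1, float(v)))
        out[gene] = GeneConservation(chrom=chrom, cds=cds, elements=elements,
                                     scores=_merge_runs(scores))
    return out


def _merge_runs(scores: list[tuple[int, int, float]]) -> list[tuple[int, int, float]]:
    """Collapse adjacent equal-valued score runs (bedgraph-style)."""
    merged: list[tuple[int, int, float]] = []
    for s, e, v in scores:
        if merged and merged[-1][1] == s and merged[-1][2] == v:
            merged[-1] = (merged[-1][0], e, v)
        else:
            merged.append((s, e, v))
    return merged


# ---------------------------------------------------------------------------
# one-call panel

def generate_panel(config: PanelConfig) -> SyntheticPanel:
    """Generate the full panel with one master seed.

    Stage RNGs are spawned from the config seed so each stage is individually
    reproducible and insensitive to upstream draw counts.
    """
    config.validate()
    founders = generate_founders(config)
    truth = plant_truth(founders, config)
    mosaics, genotypes = generate_strains(founders, config)
    _check_planted(genotypes, truth)
    phenotypes = generate_phenotypes(mosaics, truth, config)
    expression, popmap = generate_expression(truth, config)
    conservation = generate_conservation(truth, config)
    return SyntheticPanel(config=config, founders=founders, mosaics=mosaics,
                          genotypes=genotypes, phenotypes=phenotypes,
                          expression=expression, population_map=popmap,
                          conservation=conservation, truth=truth)


def _check_planted(genotypes: GenotypeTable, truth: TruthRecord) -> None:
    fa = genotypes.founder_alleles
    for q in truth.planted_qtl:
        col = fa[:, q["locus"]]
        if (col == col[0]).all():
            raise ValueError(f"planted gene {q['gene']} has no polymorphic locus")
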