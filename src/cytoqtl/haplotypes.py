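"""Locus filtering, founder-haplotype reconstruction and kinship.

The recombinant strains are inbred mosaics of the founder genomes, so the
hidden state at each locus is simply which founder the segment came from.
Reconstruction runs a per-chromosome forward-backward pass over that
founder-state chain; kinship is the mean locus-wise inner product of two
strains' founder-probability vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import GenotypeTable


@dataclass
class HaplotypeProbs:
    """Posterior founder-of-origin probabilities per (strain, locus)."""

    probs: np.ndarray          # (n_strains, n_loci, n_founders)
    strains: list[str]
    loci: pd.DataFrame

    def __post_init__(self):
        s = self.probs.sum(axis=2)
        if not np.allclose(s, 1.0, atol=1e-8):
            raise ValueError("posterior rows must sum to 1")


def filter_loci(genotypes: GenotypeTable,
                immune_gene_set: set[str] | None = None):
    """Keep loci that are exonic, inside an immune-set gene, and polymorphic.

    Mirrors the marker-reduction step that narrows a ~78k SNP chip to loci
    carrying exonic variants in immune-related genes. Returns the filtered
    table and a count report.
    """
    if immune_gene_set is None:
        immune_gene_set = genotypes.immune_genes
    if not immune_gene_set:
        warnings.warn("empty immune gene set: no loci retained")
    loci = genotypes.loci
    fa = genotypes.founder_alleles
    polymorphic = (fa != fa[0]).any(axis=0)
    keep = (
        loci["gene"].isin(immune_gene_set).to_numpy()
        & loci["exonic"].to_numpy()
        & polymorphic
    )
    idx = np.where(keep)[0]
    filtered = GenotypeTable(
        loci=loci.iloc[idx].reset_index(drop=True),
        founder_alleles=fa[:, idx],
        strain_alleles=genotypes.strain_alleles[:, idx],
        founders=genotypes.founders,
        strains=genotypes.strains,
        immune_genes=set(immune_gene_set),
    )
    report = {
        "n_loci_before": int(len(loci)),
        "n_loci_after": int(idx.size),
        "n_genes_after": int(filtered.loci["gene"].nunique()),
    }
    return filtered, report


def reconstruct_haplotypes(genotypes: GenotypeTable, eps: float = 0.01,
                           tau: float = 0.002) -> HaplotypeProbs:
    """Forward-backward posterior over founder origins for each strain.

    Emission: P(observed allele | founder allele) is 1 - eps on a match and
    eps on a mismatch; missing genotypes are uninformative (uniform
    emission). Transitions between adjacent loci stay on the same founder
    with probability 1 - tau and switch to each specific other founder with
    tau / (n_founders - 1). Chromosomes are independent chains.
    """
    loci = genotypes.loci
    for _, sub in loci.groupby("chrom", sort=False):
        if not sub["pos_bp"].is_monotonic_increasing:
            raise ValueError("loci must be sorted by position within chromosome")

    fa = genotypes.founder_alleles          # (F, L)
    obs = genotypes.strain_alleles          # (S, L) float with NaN
    n_strains, n_loci = obs.shape
    n_f = fa.shape[0]
    post = np.empty((n_strains, n_loci, n_f))

    stay = 1.0 - tau
    switch = tau / (n_f - 1)
    chrom = loci["chrom"].to_numpy()
    blocks = [np.where(chrom == c)[0] for c in pd.unique(chrom)]

    for s in range(n_strains):
        for idx in blocks:
            # emission likelihoods for this strain on this chromosome
            o = obs[s, idx]                             # (Lc,)
            f = fa[:, idx].T.astype(float)              # (Lc, F)
            match = (f == o[:, None])
            em = np.where(match, 1.0 - eps, eps)
            em[np.isnan(o), :] = 1.0                    # missing -> uninformative
            post[s, idx, :] = _forward_backward(em, stay, switch)
    return HaplotypeProbs(probs=post, strains=list(genotypes.strains),
                          loci=loci.copy())


def _forward_backward(em: np.ndarray, stay: float, switch: float) -> np.ndarray:
    """Scaled forward-backward for a chain with uniform prior and a
    stay/uniform-switch transition kernel. ``em`` is (L, F)."""
    L, F = em.shape
    alpha = np.empty((L, F))
    scale = np.empty(L)
    a = em[0] / F
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    d = stay - switch
    for t in range(1, L):
        # T^t a = switch * sum(a) + (stay - switch) * a, since rows are
        # constant off-diagonal
        pred = switch * alpha[t - 1].sum() + d * alpha[t - 1]
        a = pred * em[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.ones(F)
    post = np.empty((L, F))
    post[L - 1] = alpha[L - 1]
    for t in range(L - 2, -1, -1):
        w = beta * em[t + 1]
        beta = (switch * w.sum() + d * w) / scale[t + 1]
        p = alpha[t] * beta
        post[t] = p / p.sum()
    return post


def compute_kinship(probs: HaplotypeProbs) -> np.ndarray:
    """Strain x strain kinship: mean over loci of the founder-probability
    inner product, i.e. the probability that both strains carry the same
    founder allele at a random filtered locus."""
    p = probs.probs
    if p.shape[1] == 0:
        raise ValueError("cannot compute kinship with zero loci")
    n_s, n_l, _ = p.shape
    flat = p.reshape(n_s, -1)
    K = (flat @ flat.T) / n_l
    return (K + K.T) / 2.0
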