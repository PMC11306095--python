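"""Kinship-aware additive-haplotype genome scan.

The trait model is the standard mixed model y = mu + Xb + g + e with
cov(g) = sigma_g^2 K built from founder-haplotype similarity. Variance
components are estimated once per trait under the null (single
eigendecomposition of K, 1-D profile likelihood over the heritability
fraction), after which null and per-locus models are ordinary weighted
least squares in the rotated space and LOD = log10 likelihood ratio.

Significance is calibrated by strain-label permutations (replicates keep
identical labels) with an empirical tail-count FDR, followed by
leave-one-sample-out stability filtering and gene-level collapsing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_H_GRID = np.linspace(0.0, 0.99, 100)
_RIDGE = 1e-9


@dataclass
class TraitFit:
    """Null-model fit shared by all loci of one trait."""

    U: np.ndarray              # eigenvectors of sample-level kinship
    weights: np.ndarray        # 1 / (h * lambda_i + (1 - h))
    h: float                   # heritability fraction sigma_g^2 / total
    rss0: float                # weighted null RSS in rotated space
    r: np.ndarray              # rotated phenotype
    n: int


def _expand(y, probs, kinship, strain_of_sample):
    """Align sample-level phenotype with strain-level genotypes; drop NaN."""
    y = np.asarray(y, dtype=float)
    if strain_of_sample is None:
        strain_of_sample = np.arange(y.shape[0])
    strain_of_sample = np.asarray(strain_of_sample)
    keep = ~np.isnan(y)
    return y[keep], strain_of_sample[keep]


def _fit_null(y, Ks) -> TraitFit:
    """EMMA-style single-rotation null fit with profiled variance scale."""
    n = y.shape[0]
    lam, U = np.linalg.eigh(Ks)
    lam = np.clip(lam, 0.0, None)
    r = U.T @ y
    c = U.T @ np.ones(n)
    best = (-np.inf, 0.0)
    for h in _H_GRID:
        v = h * lam + (1.0 - h)
        w = 1.0 / v
        mu = (w * c * r).sum() / (w * c * c).sum()
        rss = (w * (r - c * mu) ** 2).sum()
        if rss <= 0:
            rss = np.finfo(float).tiny
        ll = -0.5 * (n * np.log(rss / n) + np.log(v).sum())
        if ll > best[0]:
            best = (ll, h)
    h = best[1]
    v = h * lam + (1.0 - h)
    w = 1.0 / v
    mu = (w * c * r).sum() / (w * c * c).sum()
    rss0 = float((w * (r - c * mu) ** 2).sum())
    return TraitFit(U=U, weights=w, h=h, rss0=rss0, r=r, n=n)


def _lods(fit: TraitFit, X: np.ndarray) -> np.ndarray:
    """LOD at every locus by batched weighted least squares.

    ``X`` is (n_samples, n_loci, n_founders); one founder column is dropped
    against the intercept. A tiny relative ridge keeps exactly singular
    (monomorphic-posterior) designs solvable; their residual then equals the
    null residual and the LOD clips to 0.
    """
    n, L, F = X.shape
    if fit.rss0 <= 1e-12:
        return np.zeros(L)
    sw = np.sqrt(fit.weights)
    Xr = (fit.U.T @ X.reshape(n, L * F)).reshape(n, L, F)
    D = np.concatenate([np.broadcast_to(fit.U.sum(axis=0)[:, None, None], (n, L, 1)),
                        Xr[:, :, 1:]], axis=2)        # intercept + F-1 dosage cols
    Dw = D * sw[:, None, None]
    yw = fit.r * sw
    A = np.einsum("nlp,nlq->lpq", Dw, Dw, optimize=True)
    rhs = np.einsum("nlp,n->lp", Dw, yw, optimize=True)
    tr = np.trace(A, axis1=1, axis2=2) / F
    A_r = A + (_RIDGE * np.maximum(tr, 1.0))[:, None, None] * np.eye(F)
    coef = np.linalg.solve(A_r, rhs[..., None])[..., 0]
    resid = yw[:, None] - np.einsum("nlp,lp->nl", Dw, coef, optimize=True)
    rss1 = np.maximum((resid ** 2).sum(axis=0), np.finfo(float).tiny)
    lod = (n / 2.0) * (np.log10(fit.rss0) - np.log10(rss1))
    return np.clip(lod, 0.0, None)


def scan(phenotype, probs, kinship, strain_of_sample=None) -> np.ndarray:
    """Genome scan of one trait; returns a LOD per locus.

    Parameters
    ----------
    phenotype : (n_samples,) trait values; NaN samples are dropped.
    probs : (n_strains, n_loci, n_founders) founder posterior probabilities.
    kinship : (n_strains, n_strains) strain kinship.
    strain_of_sample : optional (n_samples,) integer map from sample to
        strain row; identity when omitted (one sample per strain).
    """
    y, soi = _expand(phenotype, probs, kinship, strain_of_sample)
    n_founders = probs.shape[2]
    if len(np.unique(soi)) <= n_founders + 1:
        raise ValueError("too few strains for an additive haplotype scan "
                         f"(need > n_founders + 1 = {n_founders + 1})")
    Ks = kinship[np.ix_(soi, soi)]
    fit = _fit_null(y, Ks)
    return _lods(fit, probs[soi])


def permutation_threshold(phenotype, probs, kinship, n_perm: int,
                          fdr_level: float = 0.05, seed=0,
                          strain_of_sample=None, statistic: str = "lods"):
    """Permutation FDR threshold for one trait.

    Strain labels are shuffled on the genotype side (haplotype probabilities
    and kinship rows/columns move together) so replicate samples of a strain
    always receive identical labels. For each candidate threshold t among
    the sorted observed LODs,

        FDR(t) = mean_perm #{loci: LOD_perm >= t} / max(1, #{loci: LOD_obs >= t})

    and the smallest t with FDR(t) <= fdr_level is returned (inf if none).
    ``statistic="max"`` keeps only each permutation's genome-wide maximum in
    the numerator (a genome-wide error rate rather than a locus-count FDR).

    Returns (threshold, observed LODs, (n_perm, n_loci) permutation LODs).
    """
    if statistic not in ("lods", "max"):
        raise ValueError("statistic must be 'lods' or 'max'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives an unstable FDR estimate")
    rng = np.random.default_rng(seed)
    y, soi = _expand(phenotype, probs, kinship, strain_of_sample)
    Ks = kinship[np.ix_(soi, soi)]
    obs = _lods(_fit_null(y, Ks), probs[soi])

    n_strains = probs.shape[0]
    perm_lods = np.empty((n_perm, obs.shape[0]))
    for p in range(n_perm):
        pi = rng.permutation(n_strains)
        soi_p = pi[soi]
        Ks_p = kinship[np.ix_(soi_p, soi_p)]
        perm_lods[p] = _lods(_fit_null(y, Ks_p), probs[soi_p])

    null = (perm_lods if statistic == "lods"
            else perm_lods.max(axis=1, keepdims=True))
    threshold = np.inf
    for t in np.sort(np.unique(obs)):
        n_obs = int((obs >= t).sum())
        fdr = (null >= t).sum(axis=1).mean() / max(1, n_obs)
        if fdr <= fdr_level:
            threshold = float(t)
            break
    return threshold, obs, perm_lods


def loo_stability(phenotype, probs, kinship, candidate_loci, threshold,
                  strain_of_sample=None) -> np.ndarray:
    """Leave-one-sample-out stability filter.

    Each sample (mouse) is dropped in turn and the scan recomputed at the
    candidate loci; a locus is retained only if its LOD stays at or above
    the full-data threshold in every refit. Returns the retained subset of
    ``candidate_loci``.
    """
    candidate_loci = np.asarray(candidate_loci, dtype=int)
    if candidate_loci.size == 0:
        return candidate_loci
    y, soi = _expand(phenotype, probs, kinship, strain_of_sample)
    n = y.shape[0]
    keep = np.ones(candidate_loci.size, dtype=bool)
    Xc = probs[:, candidate_loci, :]
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_i, soi_i = y[mask], soi[mask]
        if len(np.unique(soi_i)) < 3:
            raise ValueError("fewer than 3 strains remain after leave-one-out")
        fit = _fit_null(y_i, kinship[np.ix_(soi_i, soi_i)])
        lod_i = _lods(fit, Xc[soi_i])
        keep &= lod_i >= threshold
        if not keep.any():
            break
    return candidate_loci[keep]


def collapse_to_genes(lods: np.ndarray, retained_loci, loci: pd.DataFrame,
                      cell_type: str) -> pd.DataFrame:
    """One association record per gene: the retained locus with maximal LOD
    (smallest genomic position on exact ties) becomes the gene's lead locus."""
    retained_loci = np.asarray(retained_loci, dtype=int)
    if retained_loci.size == 0:
        return pd.DataFrame(columns=["gene", "cell_type", "lead_locus", "lod"])
    sub = loci.iloc[retained_loci][["gene", "pos_bp"]].copy()
    sub["lead_locus"] = retained_loci
    sub["lod"] = lods[retained_loci]
    sub = sub.sort_values(["gene", "lod", "pos_bp"],
                          ascending=[True, False, True], kind="mergesort")
    lead = sub.groupby("gene", sort=True).first().reset_index()
    lead["cell_type"] = cell_type
    return lead[["gene", "cell_type", "lead_locus", "lod"]]
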