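"""Second-cohort validation of gene--cell-type associations.

Stage-1 associations are re-tested in an independent cohort: a one-way
ANOVA asks whether the trait varies with the biallelic genotype at the lead
locus, p-values are Benjamini-Hochberg corrected across all tested
associations, and a Spearman correlation of allele-stratified trait means
between the cohorts enforces consistent directionality (rho > 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def anova_by_allele(values: np.ndarray, alleles: np.ndarray):
    """One-way ANOVA of trait values across biallelic genotype groups.

    Returns (F, p, testable). Untestable when any group has < 2 samples or
    fewer than 2 groups exist; degenerate zero-variance input yields p = 1.
    """
    ok = ~(np.isnan(values) | np.isnan(alleles))
    values, alleles = values[ok], alleles[ok]
    groups = [values[alleles == a] for a in np.unique(alleles)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        return np.nan, np.nan, False
    if np.ptp(values) == 0:
        return 0.0, 1.0, True
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):
        return 0.0, 1.0, True
    return float(f), float(p), True


def allele_group_means(values: np.ndarray, alleles: np.ndarray) -> dict[float, float]:
    ok = ~(np.isnan(values) | np.isnan(alleles))
    values, alleles = values[ok], alleles[ok]
    return {float(a): float(values[alleles == a].mean()) for a in np.unique(alleles)}


def check_directionality(means1: dict, means2: dict):
    """Spearman rho between allele-stratified trait means of both cohorts.

    Pass requires strictly positive rho over the allele groups common to
    both cohorts; a single common group is untestable.
    """
    common = sorted(set(means1) & set(means2))
    if len(common) < 2:
        return np.nan, False
    a = [means1[g] for g in common]
    b = [means2[g] for g in common]
    rho = stats.spearmanr(a, b).statistic
    if np.isnan(rho):               # ties everywhere -> no direction evidence
        return float("nan"), False
    return float(rho), bool(rho > 0)


def validate_associations(assoc: pd.DataFrame, genotypes, phenotypes,
                          alpha: float = 0.05,
                          pool_replicates: bool = False) -> pd.DataFrame:
    """Run the two validation gates on every stage-1 association.

    Parameters
    ----------
    assoc : stage-1 records with columns gene, cell_type, lead_locus, lod.
    genotypes : GenotypeTable with strain_alleles at the lead loci.
    phenotypes : PhenotypeTable carrying both cohorts (cohort column: 1 =
        discovery, 2 = validation).
    pool_replicates : average replicate mice to one value per strain before
        the ANOVA grouping (off by default: samples enter individually).

    Returns the input frame plus p, p_adj, rho and validated columns.
    Associations untestable in cohort 2 (an allele group with < 2 samples)
    are flagged and never validated.
    """
    out = assoc.copy().reset_index(drop=True)
    if out.empty:
        for col in ("p", "p_adj", "rho"):
            out[col] = pd.Series(dtype=float)
        out["testable"] = pd.Series(dtype=bool)
        out["validated"] = pd.Series(dtype=bool)
        return out

    samples = phenotypes.samples
    strain_idx = {s: i for i, s in enumerate(genotypes.strains)}
    results = []
    for _, rec in out.iterrows():
        locus = int(rec["lead_locus"])
        geno_of_strain = genotypes.strain_alleles[:, locus]
        row_p, row_rho = np.nan, np.nan
        means = {}
        for cohort in (1, 2):
            mask = samples["cohort"].to_numpy() == cohort
            sub = samples[mask]
            vals = phenotypes.freq.loc[sub["sample"], rec["cell_type"]].to_numpy()
            alle = np.array([geno_of_strain[strain_idx[s]] for s in sub["strain"]])
            if pool_replicates:
                df = pd.DataFrame({"strain": sub["strain"].to_numpy(),
                                   "v": vals, "a": alle})
                pooled = df.groupby("strain").agg({"v": "mean", "a": "first"})
                vals, alle = pooled["v"].to_numpy(), pooled["a"].to_numpy()
            if cohort == 2:
                _, row_p, testable = anova_by_allele(vals, alle)
            means[cohort] = allele_group_means(vals, alle)
        row_rho, direction_ok = check_directionality(means[1], means[2])
        results.append((row_p, row_rho, testable and direction_ok is not None,
                        direction_ok))
    out["p"] = [r[0] for r in results]
    out["rho"] = [r[1] for r in results]
    out["testable"] = [not np.isnan(r[0]) for r in results]

    padj = np.full(len(out), np.nan)
    tested = out["testable"].to_numpy()
    if tested.any():
        padj[tested] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["p_adj"] = padj
    direction = np.array([r[3] for r in results])
    out["validated"] = tested & (out["p_adj"].to_numpy() < alpha) & direction
    return out
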