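# Methods

## Scope and model

`cytoqtl` implements a complete inference chain from genotypes and
immune-cell-frequency phenotypes in an eight-founder recombinant-inbred
(Collaborative-Cross-like) mouse panel to (i) validated gene–cell-type
frequency associations, (ii) their classification as cyto-cis or
cyto-trans, and (iii) a comparison of evolutionary conservation between
those classes. The chain runs end-to-end on a synthetic panel with a
machine-readable truth record; every stage also reads/writes plain TSV, BED
and JSON so real inputs can be substituted stage by stage.

## Synthetic panel: what it emulates, and what it does not

The generator (`cytoqtl.synth`) emulates the *design* of a
CC-style study, not the biology of any particular mouse:

- **Founders and markers.** 8 homozygous founders; biallelic markers
  annotated to genes in contiguous blocks along chromosomes, with exonic
  flags (default 70%) and an immune-gene set (default 80% of genes).
  Founder allele patterns are locally correlated: each gene carries one
  base pattern per founder that individual loci deviate from with
  probability `allele_flip_rate` (default 0.05). This mimics linkage
  disequilibrium between nearby exonic variants in real founder
  haplotypes; without it, the lead marker of a gene would not tag the
  causal allele and the allele-stratified validation stage could not work
  on any input, synthetic or real. A fraction of markers (default 10%) is
  forced monomorphic to exercise the filter.
- **Strains.** Default 54 strains as per-chromosome founder mosaics;
  breakpoint counts are Poisson with mean `recomb_rate` (default 1 per
  chromosome), switch targets uniform over the other founders. The first
  30 strains form the discovery cohort, the remaining 24 the validation
  cohort, 2 replicate mice each — mirroring a discovery n=30 / validation
  n=24 two-cohort design. Genotyping error is an allele-flip rate
  (default 0).
- **Phenotypes.** Generated on the logit scale so frequencies stay in
  (0,1): logit(freq) = cell-type baseline (typical bone-marrow fractions,
  e.g. granulocytes 0.30, HSC 0.01) + planted founder effects +
  strain-level shared noise (sd 0.15) + replicate noise (sd 0.25). The
  scan analyses raw frequencies, which is what the assay measures; the
  trait scale used inside the original mapping software is not documented,
  so this choice is fixed here and noted. Frequencies are generated
  independently per cell type (no sum-to-one constraint), matching
  per-trait scans.
- **Planted QTL.** Default 2 cis + 2 trans QTL, each at an exonic,
  polymorphic immune-gene locus with a balanced founder allele split
  (minor-allele founder count ≥ 3), each targeting a *distinct* cell type.
  The per-founder effect vector is ±`qtl_effect` × founder allele
  (default 1.5 logit units), i.e. the QTL collapses exactly to its
  biallelic variant. One trait per QTL is a deliberate regime choice:
  stacking several QTL on one trait inflates the null-model heritability
  and tests a different (and much harder) detection problem.
- **Expression reference.** A populations × genes intensity matrix from a
  two-component Gaussian mixture (silent mean 20 sd 5, clipped below the
  47 a.u. detection threshold; expressed mean 200 sd 20, floored at
  120 a.u.), with each assay cell type mapped to one reference population
  except B cells, which map to two (exercising the
  at-least-one-subpopulation rule). Planted cis genes are forced expressed
  in ≥ 1 mapped population of their target cell type; planted trans genes
  silent in all of them and expressed somewhere else.
- **Conservation.** Per gene: two CDS intervals, Poisson-many conserved
  elements of 20 bp, and per-site scores drawn from a Beta distribution
  with mean 0.4 (genes carrying a planted trans QTL) or 0.7 (all others),
  concentration 10. A small fraction of genes (default 5%) has no
  conserved element and must be handled as missing downstream.

**Not emulated:** raw cytometry events, gating, antibody chemistry,
genetic-map distances (transitions are per-interval, not per-cM),
population structure beyond the founder mosaic, realistic gene lengths or
marker densities, and any correlation between expression level and
conservation. Passing tests therefore demonstrate correctness and
calibration of the *procedure* under a faithful study design, not
biological realism of any particular signal.

## Analysis stages: numerical choices

- **Haplotype HMM** (`haplotypes.reconstruct_haplotypes`): states = 8
  homozygous founders only (the panel is inbred; no heterozygous states).
  Emission 1−ε on allele match, ε on mismatch (default ε = 0.01); missing
  genotypes are uninformative (uniform emission). Transition: stay with
  1−τ, switch to each other founder with τ/(F−1) (default τ = 0.002),
  constant per adjacent-locus interval — a documented simplification in
  the absence of map distances. Scaled forward–backward per chromosome;
  posteriors sum to 1 within 1e-8.
- **Kinship** (`compute_kinship`): mean locus-wise inner product of
  founder-probability vectors; symmetric PSD with entries in [0,1] and
  unit diagonal for hard assignments.
- **Scan** (`scan.scan`): variance components are estimated once per trait
  under the null (EMMA-style): eigendecomposition of the sample-expanded
  kinship, profile likelihood of the heritability fraction h on a 100-point
  grid over [0, 0.99] (deterministic, accurate to ~0.01 in h, and exactly
  OLS when K = I because the likelihood is then flat and the first grid
  point h = 0 is taken). Locus models use the intercept plus founder-dosage
  columns 2..8 (one column dropped against the intercept). Per-locus
  weighted normal equations are solved in one batch with a tiny relative
  ridge (1e-9 of the mean diagonal); residuals are computed explicitly, so
  the ridge never biases the reported RSS, and exactly singular
  (monomorphic-posterior) designs fall through to LOD = 0. LOD is clipped
  at 0. Replicates enter as individual samples with the strain's
  haplotype row and a sample-expanded kinship (replicate pairs fully
  correlated through the strain effect).
- **Permutation FDR** (`permutation_threshold`): permutations act on the
  genotype side — a strain permutation applied to both the haplotype
  probabilities and the kinship rows/columns — which is equivalent to
  shuffling strain labels with replicates moving together and keeps the
  kinship consistent with the genotypes. The default estimator is the
  empirical tail-count ratio over all loci; `statistic="max"` switches the
  numerator to per-permutation genome-wide maxima (a genome-wide error
  rate). The threshold is the smallest observed LOD with estimated
  FDR ≤ 0.05, +inf when none qualifies. Null-model heritability is
  re-estimated in every permutation.
- **Leave-one-out** (`loo_stability`): one *sample* (mouse) out at a time;
  retention requires LOD ≥ the full-data threshold in every refit. This is
  the strictest reading of "association across all leave-one-out options"
  and is deliberately conservative.
- **Validation** (`replication`): one-way ANOVA across biallelic genotype
  groups at the lead locus, samples entering individually (a
  `pool_replicates` flag averages per strain first); BH correction jointly
  across all stage-1 associations; any allele group with < 2 samples makes
  the association untestable (flagged, never validated). Directionality:
  Spearman ρ of allele-stratified means across cohorts, pass iff ρ > 0
  strictly; an all-ties ρ (NaN) fails.
- **Propagation** (`propagate`): k-means (fixed seed, 10 restarts) on the
  genes × cell-types matrix of lead-locus LODs (0 where no locus was
  tested for a trait); k maximizes the mean Euclidean silhouette over
  [2, min(10, n−1)]; degenerate inputs (n < 3 or identical rows) collapse
  to a single cluster with a warning. The cluster-to-cell-type rule uses
  ≥ (not >) at exactly 40% of the cluster's maximum median; the 40%
  default is a config value, not re-derived. LOD standardization before
  clustering is available but off by default.
- **Classification** (`classify`): expressed iff intensity ≥ 47 a.u.; the
  boundary counts as expressed, the conservative direction against
  over-calling trans. Genes absent from the reference are flagged
  unclassifiable and excluded from tallies and conservation grouping, with
  counts reported. Human mode consumes a pre-binarized table (no numeric
  human threshold is assumed) and derives the composite lymphocyte call as
  B AND T.
- **Conservation** (`conservation`): site-weighted mean over
  (elements ∩ CDS) by default; an element-weighted mean-of-means sits
  behind a flag (the finer-grained site-weighted reading is the default
  because per-site scores are what the underlying track provides).
  Requesting a site with no score-track coverage is an error, not a
  silent skip. The one-sided KS direction is fixed a priori: the focal
  (trans / multi-type) group is tested for being *less* conserved. The
  asymptotic p-value is the standard one-sided bound
  exp(−2D²·n_a·n_b/(n_a+n_b)) — slightly conservative at small n (null
  rejection ~0.04 at n=50, inside the [0.03, 0.07] calibration band) —
  with the exact small-sample distribution behind a flag. Lineage
  collapsing for the multi-cell-type flag: {B, proB, lateB} → one type,
  {GN, MO} → one type.
- **Pipeline** (`pipeline.run_pipeline`): per-stage seeds derive
  deterministically from one global seed; all artifacts are TSV/JSON; the
  report includes truth-recovery metrics whenever the panel carries a
  truth record.

## Problem sizes used in the test and acceptance runs

Defaults: 54 strains (30 + 24), 2 replicates, 3 chromosomes, 300 markers,
60 genes, 9 cell types, 100 scan permutations (64 in the 50-run recovery
experiment). The null-calibration suite uses a reduced panel (28 strains,
100 markers, 2 cell types, 50 permutations, 60 seeds) and the KS/χ² null
calibrations use 1,000 seeds; the conservation power experiment uses 70
genes (35 per group) over 100 seeds. These sizes keep the full suite in a
few minutes on one CPU while leaving every statistical conclusion
well-resolved.

## Known limitations

- Transitions in the haplotype HMM ignore genetic distance; posterior
  uncertainty between tightly linked founders is therefore uniform along a
  chromosome rather than distance-scaled.
- The kinship matrix includes the causal locus (no leave-one-chromosome-out
  option), so strong QTL partially absorb into the random effect and LODs
  are conservative — the permutation threshold inherits the same
  absorption, which keeps the calibration honest.
- The FDR tail-count estimator counts correlated loci in the numerator;
  with long founder blocks one lucky permutation contributes a whole
  block. This makes thresholds conservative for block-structured genomes.
- Gene-level collapsing assigns each marker to at most one gene;
  overlapping genes are out of scope.
- The propagation stage imputes LOD 0 for cell types where a gene had no
  tested locus, which slightly biases cluster profiles toward sparsity.
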