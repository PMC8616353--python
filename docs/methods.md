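# Methods

## Glycan representation and classification

A glycan is represented by its monosaccharide composition — counts of
hexose (H), N-acetylhexosamine (N), fucose (F), N-acetylneuraminic acid
(S), phosphorylation (P) and sulfation (Su) — plus an optional one-letter
isomer suffix that encodes chromatographic elution order only; no
structural meaning is attached to the letter. Structural detail beyond the
composition (glycan type, antenna count, bisecting GlcNAc, fucose
placement, sialic acid linkages, epitope flags) lives in a curated
annotation, because fragmentation-level evidence cannot be reconstructed
from a composition. `validate_annotation` enforces the internal
consistency constraints (linkage counts sum to the sialic acid count,
core + antennary fucoses sum to the fucose count, O-glycans carry neither
antennae nor bisection, epitope flags require their prerequisite
residues) and reports *all* violations rather than the first.

Where no curation is available, a composition-based default classifier is
used. For N-glycans: paucimannose iff HexNAc = 2, Hex ≤ 3, at most one
(core) fucose and no sialic acid; oligomannose iff HexNAc = 2, Hex 4–9,
unfucosylated and nonsialylated; hybrid iff HexNAc = 3 and Hex ≥ 4;
complex otherwise. Two conventions here were genuinely open and are design
choices of this package: H4N2 (Man4) is classified oligomannose — the
paucimannose/oligomannose boundary is drawn at Hex ≤ 3, the common
glycobiology convention for truncated structures — and phosphorylated
H(x)N2 species remain oligomannose, with phosphorylation expressed as a
separate derived trait rather than a fifth type. O-glycans are split into
core 1 (single HexNAc, the core GalNAc) and core 2 (branching GlcNAc
present); core 3/4 are not modeled. Curated annotation, when present,
overrides the default classifier; a disagreement where the composition is
decisive is surfaced as a warning-level violation, not an error.

Alditol masses assume the borohydride-reduced free glycan (the analyte
form in porous-graphitized-carbon LC-MS): the sum of condensed monoisotopic
residue masses plus water plus two reduction hydrogens (terminus
20.026215 Da).

## Derived traits

A trait is a membership function over annotated glycans plus an
aggregation rule. Percentage traits report the summed fractional abundance
of member glycans over a denominator set, ×100; the default denominator is
the glycan's whole class, so the four N-types sum to 100% per sample, as
do the two O-cores. A `complex_only` denominator is selectable per call
for traits conventionally quoted as a share of complex-type glycans.

Two open conventions, resolved as defaults with the alternative exposed:

* **Occurrence weighting.** A glycan carrying two sialic acids counts its
  full abundance once toward "total sialylation" (`weight="presence"`,
  the default, which keeps percentage traits bounded by 100); abundance ×
  occurrence-count weighting is available per trait definition.
* **Antennarity** is the summed abundance of glycans with ≥ 3 antennae
  (a percentage), not an abundance-weighted mean antenna count.

Sialic acids whose linkage could not be determined contribute to total
sialylation but to no linkage-specific trait. On N-glycans, neutral and
sialylated antennary-fucose epitopes are pooled into one (s)Lewis x/a
trait; on O-glycans Lewis x/a and sialyl-Lewis x/a are kept separate.
Ratio traits (core1:core2) with a zero denominator yield NaN, a data
condition rather than an exception.

## Quality control and normalization

A peak is quantifiable iff its retention time matches, the isotope dot
product is ≥ 0.85 and the signal-to-noise ratio is ≥ 6 — both thresholds
inclusive, both tunable. Fractional abundance then normalizes each area to
the total of *observed* same-class glycans in that sample; i.e. fractions
are renormalized over the post-QC glycan set, since fractional abundances
over a set containing rejected peaks would be ill-defined. Missing cells
(glycans quantified in some samples but absent in others) are imputed with
the constant 0.01% *after* normalization and before any multivariate
statistics; the floor is treated as a pseudo-abundance and fractions are
not renormalized after imputation. Observed values pass through
imputation bit-for-bit.

Replicate precision is the per-glycan relative standard deviation across
replicates (n−1 standard deviation over the mean, ×100); the headline
average is restricted to glycans of ≥ 1.0% mean abundance because RSDs of
trace glycans are dominated by counting noise. Technical and biological
precision are the same computation grouped by different replicate labels.

## PCA and Hotelling T²

PCA mean-centers and, by default, unit-variance scales each feature
(Pareto and no scaling are selectable for sensitivity analyses), then
decomposes by SVD. The sign of each loading vector is fixed by making its
largest-magnitude element positive, so score plots are reproducible across
SVD implementations. The pipeline runs PCA on the combined per-glycan
abundances plus derived traits (ratio traits excluded: unbounded scale).
The Hotelling T² limit for A components and n samples at level α is
`A(n−1)(n+1)/(n(n−A)) · F(1−α; A, n−A)`; per-sample T² is the sum of
squared scores over component variances.

## Correlation and regularized CCA

Trait–gene association uses Pearson correlation on index-matched samples,
with the exact two-sided p-value from `t = r√((n−2)/(1−r²))` on n−2
degrees of freedom and significance tiers `*` (p ≤ 0.05) and `***`
(p ≤ 0.001) on the raw p-values. A Benjamini–Hochberg q column is emitted
for convenience but the tiers never use it, matching the convention of
reporting raw tiers in correlation panels of this size.

Regularized CCA replaces the within-block covariances with `Cxx + λ₁I`
and `Cyy + λ₂I` (ridge shrinkage), which keeps the canonical eigenproblem
well-posed when features rival or exceed samples. The implementation
whitens with the inverse matrix square roots and takes the SVD of the
whitened cross-covariance; canonical variates have unit variance under the
regularized metric, and with λ = 0 on well-conditioned blocks the
canonical correlations equal classical CCA (verified against an
independent generalized-eigenvalue oracle to 1e−6). Defaults λ₁ = λ₂ =
0.1 and K = 2 components; both blocks are z-scored by the pipeline before
fitting. The cross-block similarity between original variables is
`sim(i,j) = Σ_{d≤K} cor(X_i, Z_d)·cor(Y_j, Z_d)` with `Z_d` the average
of the d-th X- and Y-variates; entries are reported unclipped — |sim| can
exceed 1 for K > 1 — and heatmap color scales saturate at ±1. Rows and
columns of the map are ordered by complete-linkage hierarchical clustering
on Euclidean distances, with labels pre-sorted so the leaf order is
deterministic and invariant to input permutation.

## Synthetic cohorts

The generator emulates the *data model* of a released-glycan LC-MS study
of a leukemia cell line panel: it produces the quantification, annotation,
expression and metadata tables the pipeline consumes, with known ground
truth. It does not emulate raw spectra, chromatograms, retention times,
isotope envelopes (QC metrics are drawn, not computed), batch effects, or
count noise in expression — the expression model is a continuous log-like
scale, as public cell line expression datasets are already
log-transformed. Passing recovery tests therefore demonstrates
correctness of the estimators under the generator's assumptions, not
robustness to real-data artifacts outside them.

Per FAB class, a mean abundance vector over the packaged library is fitted
by iterative proportional fitting: member glycans of each targeted trait
are scaled toward the target share and non-members toward the complement,
renormalizing within glycan class until convergence (tolerance 1e−10,
residuals recorded in the ground truth; residuals above 0.5 percentage
points warn). Infeasible effect tables — type shares that cannot close to
100% — are rejected before sampling. Default class targets encode the
qualitative contrasts of myeloid differentiation states: monocytic classes
high in paucimannose, hybrid glycans and (s)Lewis x/a; the erythroid class
high in bisection, antennarity, sialylation and α2,8 sialylation (absent
from the least differentiated classes); the promyelocytic class high in
phosphorylation and H antigen; the single megakaryoblastic line with
strikingly high O-glycan sialyl-Lewis x/a.

Within-class noise is Dirichlet with concentration 500 (biological
replicates of a ~5% glycan then vary with RSD ≈ 14%, large glycans ≈ 5%,
comparable to biological triplicate precision of the assay class being
emulated); technical replicates use concentration 10 000 (average RSD over
≥ 1% glycans ≈ 8–10%, matching good technical precision for this assay
class). Peak areas scale fractions by a per-sample log-normal total; a
configured fraction of peaks (default 5%) fails one QC criterion chosen at
random, and a further 2% of cells are dropped entirely to exercise
imputation. One designated sample (first of the largest class) is emitted
in technical triplicate.

Gene expression for a linked gene with target correlation r is
`baseline + spread·(r·z_trait + √(1−r²)·ε)` with standardized driving
trait and unit Gaussian ε, so the population correlation equals r;
unlinked genes are pure noise. The default 21-sample cohort mirrors a
realistic panel size for demonstrations; statistical recovery tests use
n = 200 because sampling error at n = 21 (±0.2 on r) would make
correlation assertions vacuous. Silhouette calibration tests use cohorts
without singleton classes — strong-effect cohorts with 7 samples in each
of the three well-separated classes (M4/M5/M6), null cohorts (no trait
effects) with 15 per class, where the small-sample bias of the
min-over-clusters step in the silhouette is negligible.

## Numerical and interface choices

* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; equal seeds give identical outputs
  byte-for-byte, and nothing reads the system clock.
* Constant features are z-scored to zero with a warning rather than
  raising, so heatmaps keep their columns.
* Zero-variance vectors in correlations yield NaN with the pair retained;
  pairs with fewer than 3 complete observations are skipped with a warning.
* Degenerate QC thresholds that reject every peak halt the pipeline with
  an informative error rather than propagating empty matrices.
* Tables are UTF-8 text: long tables as CSV, matrices as TSV with a
  `# units:` header line; schema violations name the file and column.

## Known limitations

* Structural annotation is consumed, not inferred: no MS² fragment
  assignment, topology encoding, or retention-time prediction.
* The trait engine does not infer epitopes from composition alone; a
  glycan without curated annotation contributes only through the default
  type classifier.
* rCCA hyperparameters default to λ = 0.1, K = 2; no automatic model
  selection is performed (a leave-one-out λ grid would be a natural
  extension), and similarity values are not directly comparable across
  different K.
* The generator's Dirichlet noise is exchangeable within class; it cannot
  produce the correlated glycan co-regulation real biosynthesis induces
  beyond what the class means encode.
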