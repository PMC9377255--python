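# Methods

This note documents the models, conventions and design choices behind
`gusome`, in the order the pipeline runs them.

## Sequence screen

**Alignment.** The screen uses local (Smith–Waterman) alignment with
affine gaps under BLOSUM62, gap open 11 and gap extend 1 (a gap of
length *k* costs 11 + *k*), the protein–protein BLAST defaults. The
dynamic program is fully deterministic: the traceback starts at the
highest-scoring cell with the lexicographically smallest (query row,
target column) and prefers diagonal over up over left at score ties.
Matrix and penalties are config-exposed. The implementation is a
numba-compiled kernel; the test suite checks its scores and identities
exactly against a plain-Python DP and against Biopython's
`PairwiseAligner`.

**Identity statistics.** Identity is reported in two modes:
`aligned_columns` (identical / aligned columns, the BLAST reporting
convention; default) and `query_length` (identical / query length, a
global-coverage flavour). The distinction matters: under local
alignment, two unrelated proteins typically share a short spurious
alignment at 30–45% identity, so aligned-columns identity of the *best*
local alignment cannot separate homologs from noise by itself. Three
consequences shaped the design:

- **Hit ranking is by alignment score**, not identity. Ranking by raw
  identity would let a 10-column perfect spurious hit outrank the true
  source homolog (observed: identity 0.8 over ~10 columns). Score ranks,
  identity gates — which is also how a BLAST-based screen behaves.
- **The 25% identity gate alone does not reject non-homologs** in
  aligned-columns mode; the seven-residue check provides the actual
  specificity. In `query_length` mode the gate itself is discriminative,
  and non-homologs are rejected as `below_identity`.
- **Redundancy clustering uses identical columns / shorter sequence
  length** (the CD-HIT convention) for cluster membership; the
  aligned-columns ratio would merge unrelated genes on short perfect
  local hits.

**Residue rule.** A candidate above the identity gate is accepted iff
all seven annotated catalytic positions of the best-scoring
representative align to *identical* residues (gaps and conservative
substitutions fail; "conserved" is read literally). A config flag
switches to `any_rep` mode, where any above-threshold representative may
satisfy the check. Thresholds are strict `>` for the screen and `>=` for
the 90% redundancy clustering.

**Class assignment** is a two-step rule. First the FMN test: if the
candidate matches an FMN representative's annotated C-terminal segment
at ≥ 0.30 identity while covering ≥ 75% of the segment, the class is
FMN (the coverage requirement keeps short spurious hits out; measured
margins on synthetic cohorts are ≥ 0.85 coverage for true FMN genes vs
≈ 0.5 for others on a 120-residue segment). Otherwise the candidate is
projected through the alignment column map onto the nearest
(best-scoring) representative's two loop windows, and the projected span
classifies it: ≥ 16 residues → L1/L2, 7–15 → mL1/mL2 (both → mL1,2),
below → No Loop; the thresholds sit mid-margin between the no-loop span
(≈ 4), mini-loop span (≈ 12) and long-loop span (≈ 21) of the bundled
representative architecture and are config-overridable. Unalignable
windows fall back to the nearest representative's class, flagged
`by_nearest`; equal-score ties across classes resolve by a fixed class
order and are flagged `ambiguous`. At the low end of the identity band
(≈ 0.42) the loop projection can mislabel between adjacent mini/long
classes in a few percent of clusters — alignment gap placement inside a
divergent loop is genuinely ambiguous — while FMN assignment stays
robust through the segment test.

**Taxonomy** is the label of the best-scoring reference in a labeled
protein set, reported with its identity; below a 0.40 floor the cluster
is `unassigned`.

## Abundance normalization

Relative count = log10((count / total assigned in sample) × (total
assigned across samples / number of samples) + 1); zero counts map to
exactly 0. Length de-biasing adds slope × (average gene length − gene
length), where the slope comes from one pooled OLS fit of relative count
on length across all samples (a per-sample-slope mode exists). When the
correction uses the fitted slope and the mean length, regressing
normalized abundance on length returns slope 0 to machine precision —
an algebraic identity the tests assert at 1e-10. The length unit
(amino-acid here) is recorded in output headers. Note the pooled fit
shares each gene's abundance offset across samples, so its standard
error is for point estimation only; calibrated confidence intervals for
the bias slope come from single-sample fits, which have independent
per-gene residuals.

## Diversity

Shannon index uses log base 2 by default (base is a parameter);
Bray–Curtis is Σ|x−y| / Σ(x+y). Ordination is classical PCoA — double
centring of the squared-distance matrix, eigendecomposition, axes from
positive eigenvalues only (negative eigenvalues are reported, not
embedded), each axis oriented so its first nonzero loading is positive.
A distance-based constrained ordination with no constraints reduces to
exactly this, which is why no separate constrained mode exists.
PERMANOVA uses the among/within pseudo-F with seeded label permutations
and the add-one convention p = (1 + #{F\* ≥ F}) / (1 + n\_perm), so p
is never zero.

## Proteomics quantification

Peptides match proteins by exact substring with I and L collapsed
(isobaric; disablable). Uniqueness is defined at the redundancy-cluster
level, mirroring "unique peptide" against a non-redundant database; a
protein-level mode is one flag away. Protein intensity is the sum of
unique-peptide areas per (cluster, sample) with log2 applied after
summing — never a mean of logs — and undetected proteins are absent
rows, not zeros or imputations; group tests therefore treat undetected
classes as missing. Coverage is the union of all occurrence intervals
of the matched peptides divided by protein length (checked against a
per-residue bitmap oracle). Spectral FDR is consumed, not computed: the
input table is assumed already 1%-FDR filtered upstream.

Welch's t statistic uses sample variances (ddof 1) with
Welch–Satterthwaite degrees of freedom; two constant groups give p = 1
(equal means) or p = 0 with a degeneracy flag. The signed-rank test
drops zero differences, requires n ≥ 3, and is exact (verified against
full 2ⁿ enumeration) for n ≤ 25 without ties, falling back to the
tie-corrected normal approximation.

## Kinetics and association

The lysate assay tracks MPAG disappearance: each replicate's
concentration-vs-time trace is fit by OLS and the reactivation rate is
the magnitude of the negative slope in nM/s; a rising trace is flagged
and contributes 0 rather than a negative rate. Replicate rates are
averaged, SEM = sd/√k, and log2 of the mean is taken (undefined at 0).
The purified-enzyme assay tracks product formation; the initial rate is
the slope of the best contiguous window of at least max(3, 25% of
points) maximizing r² (ties: longer, then earlier window; flat windows
score r² = 0 so a plateau never wins), with an r² floor of 0.90 below
which "no linear phase" is an error; dividing by enzyme concentration
gives specific activity in 1/s. Absorbance-to-concentration conversion
is an input calibration factor.

The Wald slope test is OLS slope / SE referred to N(0,1) by default,
with a t(n−2) mode matching common graphing software; outputs record
which reference ran. At small n the normal reference is anticonservative
(the null statistic is exactly t(n−2) under Gaussian errors — true size
≈ 0.09 at n = 9), which is why the calibration checks in the test suite
and acceptance script run the t mode; the pipeline default stays normal
as the literal reading of "Wald test". Association scans run one test
per predictor with no multiplicity adjustment by default (matching the
per-test presentation such scans usually get); Benjamini–Hochberg is
available for taxon-level scans.

## Synthetic cohort generator

The generator is the package's test bed and defines what passing means.
Defaults mirror the study design: nine samples (five MMF-treated
transplant recipients T1–T5, four healthy donors H1–H4), a 400 µM MPAG
start concentration, five endpoints including t = 0 (0–60 min in
seconds) and three biological replicates. All randomness flows from one
seed, stream-split by stage name (SHA-256 of the stage), so stages can
be regenerated independently and every generator is a pure function of
(parameters, seed).

**Representatives.** Seventeen synthetic representatives descend from a
single core scaffold: seven catalytic residues at fixed positions whose
±3-residue context is conserved family-wide (as in real active sites —
and the exact-match blocks are what anchor optimal local alignments at
those positions), class-specific loop segments inserted at two anchor
sites (17 residues for long loops, 8 for mini), and a 120-residue
C-terminal FMN segment on FMN-class members. Classes covered: 3×L1,
2×mL1, 3×L2, 2×mL2, 2×mL1,2, 3×NL, 2×FMN; "No Coverage" remains an
assignment outcome rather than a planted class.

**Catalog.** True genes are mutated copies of representatives
(substitutions only by default; flat replacement over the 19
alternatives — the screen is matrix-aware, the generator need not be)
at identities drawn from [0.42, 0.95], measured by the discovery aligner
itself and adjusted to ±0.02. The lower bound reflects a measurement
floor: with conserved active-site blocks, the aligned-columns identity
of even a maximally mutated homolog is ≈ 0.40, because the local
alignment keeps the conserved islands. FMN genes draw from [0.45, 0.95]
(their conserved domain — every other residue of the segment kept —
raises the attainable floor further). Decoys: `residue_ablated`
(homologs with 1–3 catalytic residues substituted), `low_identity`
(heavily mutated, verified < 0.20 query-length identity to every
representative), `random` (composition-preserving shuffles). Half the
true genes (by default) get a near-identical variant at ≥ 0.96 with
mutations kept away from the termini, so planted redundancy groups sit
safely above the 0.90 clustering threshold. One tryptic peptide is
copied between genes of two different classes (cleavage context kept)
to exercise the unique-peptide filter.

**Counts.** Per-sample totals are log-uniform over 200k–800k (≥ 2-fold
spread); gene weights are 10^(u\_g + slope·length + e\_gs) with
u\_g ~ N(0, 0.5), e\_gs ~ N(0, 0.3), sampled multinomially, so expected
log10 relative count rises linearly in length with the planted slope
(default 8×10⁻⁴ per residue).

**Proteome.** A fixed 70% of base genes (always including an FMN gene)
are expressed cohort-wide; protein log2 intensity is 20 + protein offset
(sd 1) + group shift + sample noise (sd 1), with default class effects
FMN +2 and No-Loop −2 in the MMF group — the qualitative pattern the
assay design expects to detect. Tryptic digestion cleaves after K/R
except before P, keeping 7–30-mers; peptide intensities are lognormal
around the protein mean split across peptides (sd 0.5 in log2).

**Time courses.** True rate r = a + b·fmn + ε with ε ~ N(0, noise\_sd²),
clipped at zero, where fmn is the per-sample planted log2 FMN intensity
(centred in the one-call cohort so *a* is the cohort-mean rate; defaults
a = 12 nM/s, b = 8 nM/s per log2 unit, noise 3 nM/s give rates spanning
roughly 0–30 nM/s with MMF samples fastest). Measurement noise (sd
2 µM) is added per concentration point. Parameter-recovery checks run
at a = 40 so the linear model stays clear of the zero-rate floor, where
clipping would bias any linear fit by construction.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: read-level sequencing error and assembly
artifacts, phylogenetically realistic sequence evolution (mutations are
i.i.d., no rate heterogeneity or indel processes beyond an opt-in),
spectrum-level proteomics (missed cleavages, modifications, FDR),
compositional coupling between taxa, and any nonlinearity in enzyme
kinetics (Michaelis–Menten saturation is out of scope; traces are
linear by design).

## Problem sizes

Tests and the acceptance script run on compact representatives (core
240 residues, FMN tail 120; the bundled default set uses core 420) and
cohorts of ~35–40 catalog entries, 200-candidate oracle comparisons,
200×199-permutation PERMANOVA calibrations, 1000-replicate Wald
calibrations and 100-seed end-to-end recovery runs — sizes chosen so the
full suite completes in about a minute on one CPU while every check
retains its statistical meaning.

## Known limitations

- Structural-class accuracy degrades by a few percent at the identity
  band floor for adjacent loop classes (see above); FMN and No-Loop —
  the classes carrying the study's planted effects — are robust.
- The Wilcoxon exact path requires tie-free differences; ties always use
  the corrected normal approximation regardless of n.
- The initial-rate window rule is a deliberate reconstruction of an
  under-specified "custom linear regression" step; its window length
  floor and r² criterion are config-visible constants rather than fits
  to any reference implementation.
- PERMANOVA assumes exchangeability under the null; with n = 9 samples
  its permutation p has granularity 1/(n_perm + 1).
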