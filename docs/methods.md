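# Methods

This note documents the models and procedures implemented in `splicetope`,
the parameters that matter, the synthetic data the tests run on, and the
numerical choices made where the design was open.

## Differential intensity analysis

Input is a features × samples matrix of log2 intensities with missing
entries, two sample groups (control/treated, each ≥ 2 samples). The
processing order is fixed: transform → filter → (normalise) → impute → test;
every stochastic step takes an explicit seed and is bit-reproducible.

**Validity filter.** A feature is kept when its fraction of observed values
reaches `min_fraction` in at least one group. Two presets ship with the
module: `proteome` (0.75) and `phospho` (1.0). Phosphosite tables are
additionally filtered for reverse-database and contaminant flags and for a
site localization probability ≥ 0.75 (inclusive).

**Median normalisation** subtracts each sample's median of observed values,
so post-normalisation sample medians are exactly 0.

**Imputation.** Missing values are assumed missing-not-at-random (low
abundance). Each missing entry in sample *s* is drawn from
N(μ_s − downshift·σ_s, (width·σ_s)²) with μ_s, σ_s the observed mean and SD
of that sample. Defaults: width 0.3; downshift 2.4 (proteome) or 1.8
(phospho). Imputation is per sample; a per-matrix mode exists but is not the
default. A sample with fewer than two observed values cannot parameterise
the distribution and raises an error.

**SAM/S0 test.** The moderated statistic is d = Δm/(s + s₀), where Δm is the
treated − control mean difference, s the pooled two-sample standard error
and s₀ a variance-stabilising offset (0.35 proteome, 0.1 phospho). At s₀ = 0,
d is identical to the classical pooled-variance t statistic (asserted to
1e−9 in tests). False discovery is controlled by group-label permutations:
all distinct label assignments when they number at most `n_permutations`
(C(6,3) = 20 at n = 3+3), otherwise a seeded random sample (default 250).
The q-value of a feature is the median, over permutations, of the count of
permuted |d| values at or above its |d| (ties count as exceeding), divided
by the observed count at that cut-off, made monotone non-decreasing as |d|
decreases and capped at 1. This convention is deliberately conservative with
few samples: permutations that swap only one sample per group retain part of
a true effect, inflating the estimated false-positive count.

Consequence worth knowing: at n = 3+3 with many strong effects, ranking by
|d| with a small s₀ is noisy because the per-feature standard error is
estimated from 4 degrees of freedom. The calibration simulations in the test
suite therefore use the proteome default s₀ = 0.35, which shifts weight from
the noisy variance estimate to the fold change; measured on 2000 features
with 10% planted log2 effects of 2 at noise SD 0.5 this yields ≈ 0.95
sensitivity at ≈ 0.05 empirical FDR, while s₀ = 0.1 tops out near 0.7 (an
oracle cut on the same |d| ranking cannot exceed ≈ 0.88 at 10% FDR).

**Protein phosphorylation classes.** A site "counts" when its q-value is
significant and |log2FC| > 0.58 (≈ 1.5-fold). A protein with counting sites
in both directions is *biphasic*; only up, *hyper*; only down, *hypo*;
otherwise *unchanged*. The classes partition the protein set.

**Condition-specific features** are those with ≥ 1 observed raw value in one
group and none in the other, whose post-imputation two-sample t-test has
p below the threshold (default 0.05); the direction (treated-only /
control-only) is reported.

## Splicing events

Event tables use the rMATS 4.1.2 `*.MATS.JC.txt` dialect (headers frozen per
event type, replicate junction counts comma-separated). PSI per replicate is
the length-normalised inclusion fraction ψ = (I/lI)/((I/lI) + (S/lS));
a replicate with I = S = 0 is undefined and excluded from the group mean.
ΔPSI = ψ_treated − ψ_control; rMATS reports sample1 − sample2 without naming
the conditions, so the caller declares which sample group is treated
(default: sample 1). Significance uses strict inequalities, FDR < 0.05 AND
|ΔPSI| > 0.1; events with undefined PSI in either group are excluded.
Directional skew within an event family is the one-sided upper hypergeometric
tail of drawing at least the observed number of UP events from the pooled
UP+DOWN population.

## Sequence features and branch points

For skipped exons: cassette exon length (half-open end − start), exon GC
content, transcript-upstream intron length, and branch-point distance to the
3' splice site. For retained introns: intron length and GC. All sequence
work is strand-aware (intron sequences are taken 5'→3' on the mRNA), and a
mirrored-genome property test (reverse-complement all chromosomes, flip all
coordinates and strands) asserts full invariance.

The branch point is called with a consensus position-weight model rather
than a trained classifier: a 7-column PWM encoding the yUnAy branch motif
with the branch adenosine fixed at the centre column, shipped as a versioned
TSV fixture and pluggable. Every adenosine whose distance to the intron's 3'
end lies in the 15–100 nt window (standard for human branch points; bounds
configurable) is scored by the summed log2 odds of its centred 7-mer against
a uniform background; the best scorer wins, ties resolve to the A closest to
the 3' splice site. Distance convention: the number of bases strictly
between the branch A and the final intron base. Introns with no scorable A
yield a missing value.

Group comparisons use the two-sided Mann–Whitney U test. When both groups
have ≤ 8 observations the null distribution of U is enumerated exhaustively
over all label assignments (midranks are permutation-invariant, so this is
exact under ties); the two-sided p is twice the smaller tail, capped at 1.
Larger samples use the tie-corrected, continuity-corrected normal
approximation; its deviation from enumeration is bounded by the exact
distribution's largest point mass (~0.012 at n₁ = n₂ = 8). The regulated
exon-length comparison ("are UP exons shorter?") is a per-feature test; no
multiple-testing correction is applied across features.

## Motif RNA-maps

For each cassette exon, four anchor windows are extracted in transcript
orientation: 300 nt of the upstream intron before the 3' splice site, 50 nt
into the exon from each edge, and 300 nt of the downstream intron after the
5' splice site (defaults; configurable). Motif hits are PWM log-odds matches
against a uniform 0.25 background with threshold 80% of the maximal score by
default. Coverage at a position is the fraction of events in a group with at
least one hit overlapping it (presence/absence, not hit density), smoothed
by a 31-nt running mean whose edge windows shrink to the available span
(mean approximately preserved). Significance between two groups is a
per-position permutation test on the coverage difference (event labels
shuffled, add-one corrected), Benjamini–Hochberg adjusted across positions
within an anchor. Note the floor: with n permutations the smallest
achievable p is 1/(n+1), and BH across W positions raises the smallest
achievable q to roughly W/(k·(n+1)) when k positions carry signal — detecting
a ~5-position motif peak at q < 0.05 inside a 300-nt window needs ≥ ~2000
permutations, which is what the tests use.

## Neopeptide generation

Only the two "productive" event classes generate libraries: skipped exons
with decreased inclusion (the exclusion isoform gains abundance) and
retained introns with increased retention. Gene models are single-isoform
(one transcript per gene, exons ordered, CDS beginning ATG; CDS intervals
include the stop codon). SE exclusion removes the cassette exon from the
exon chain; RI inclusion merges the flanking exons across the intron.
Translation assumes: the annotated canonical START only; no readthrough and
no internal initiation; the product runs to the first stop codon. If the
event removes the START-containing exon the product is empty with reason
`start_lost`. `frameshifted` flags a changed CDS length not divisible by 3;
`premature_stop` flags a stop codon arriving before the transcript position
of the canonical stop (for frameshifted products whose new stop falls beyond
that position the flag can be False — the flags are independent).

Proteins are digested into all substrings of length 8–14, de-duplicated
("unique" is read as: de-duplication within the library AND absence from the
canonical background proteome, tested as substring of any canonical
protein). Only novel peptides proceed to binding prediction.

Binding is an interface, not a model: NetMHCpan v4.1-style whitespace tables
are parsed and joined on peptide; binder classes follow the usual %rank
convention (strong ≤ 0.5, weak ≤ 2.0). For offline tests a toy anchor-matrix
scorer ranks 9-mers against a seeded sample of proteome peptides
(%rank = add-one-corrected fraction of background scoring strictly higher);
it exists to make the stage testable and makes no biological claim. The
HLA allele is a free parameter. GTF coordinates are converted to 0-based
half-open at the boundary and back on output.

## Set statistics

Overlap significance is the exact upper hypergeometric tail
P(X ≥ |A ∩ B|) with X ~ Hypergeom(|U|, |A|, |B|). The universe is never
defaulted silently: callers must pass it (a sensible choice is all genes
testable in both experiments). Depletion is available as the lower tail.
Foreground/background shift tests report fg − bg direction with a two-sided
t or Mann–Whitney test; identical zero-variance samples return p = 1.

## Synthetic data

The generator is first-class, tested code; its defaults define the study
conditions used throughout the tests.

*Toy genome*: single-chromosome, 3–5 exons per gene on a random strand,
25–60 codons of CDS per exon with phase-0 exon boundaries, 30-nt UTRs,
80–150-nt GT..AG introns that carry a planted branch-point box 20–40 nt from
the 3' end followed by a pyrimidine tract. Proteins are drawn first and
back-translated, so CDSs never contain internal stops by construction.

*Planted neoepitopes*: an RI planting rewrites one intron in place (length
preserved) so in-frame readthrough encodes Val + peptide + stop — the
leading GTT keeps the donor GT, the trailing AG is preserved; an SE planting
rewrites the coding sequence flanking an internal exon so that the exclusion
junction spells the peptide. Peptides colliding with the canonical proteome
are re-randomised, and all planted peptides are re-verified against the
final proteome. True PSI defaults: 0.85 → 0.35 for planted SE (inclusion
loss), 0.10 → 0.60 for planted RI (retention gain).

*rMATS tables*: junction counts are Binomial(reads_per_event, p) with p
chosen so the length-normalised PSI expectation equals the planted PSI
(binomial, not negative binomial: the simplest model whose expectation is
right; overdispersion is out of scope). Effective lengths follow the
two-inclusion-junction/one-skip-junction geometry: lI = 2(read_length − 1),
lS = read_length − 1 for SE/RI/MXE and lI = lS = read_length − 1 for
A3SS/A5SS. Planted-significant events receive FDR 0.001 and their counts are
re-drawn (bounded retries) until the realized |ΔPSI| clears the 0.1 cut-off
in the planted direction — the planted truth is recoverable by construction;
non-significant events draw FDR uniformly on (0.2, 1) and fail the filter on
FDR alone.

*Intensity matrices*: value = baseline + effect·1[treated] + N(0, noise²)
with baseline ~ N(25, 2²) on the log2 scale; missing-not-at-random dropout
censors entries with logistic probability 1/(1 + exp((x − mid)/scale)),
disabled by default so planted-effect recovery can be tested exactly.

What the synthetic data does **not** emulate: read-level sequencing noise and
alignment artefacts, junction-count overdispersion, multi-isoform genes,
correlated features, batch effects, peptide detectability/flyability, and
real MHC binding specificity. Passing tests therefore demonstrate the
correctness of the statistical and sequence machinery on data satisfying the
models' assumptions, not performance on real measurements.

## Numerical choices and degenerate inputs

- PSI with I = S = 0 propagates as missing; events with missing group PSI
  are excluded from filtering rather than guessed.
- Zero-variance, zero-difference features get d = 0 (not NaN); zero-variance
  identical samples get p = 1 in shift tests.
- Permutation tie-breaks use ≥ comparisons throughout; permutation p-values
  are add-one corrected; q-value monotonicity is enforced explicitly.
- Branch-point ties resolve toward the 3' splice site; motif hit intervals
  are half-open and may overlap.
- Problem sizes in tests and in `scripts/acceptance.py` (5–10 genes, 10³–10⁴
  events, 2000-feature matrices, 20 simulation seeds, ≤ 2000 permutations)
  were chosen so every planted contrast is detected with wide margin while a
  full run completes in seconds on a single CPU.

## Known limitations

- Single-isoform gene models only; matching events to one of several
  isoforms is out of scope.
- A3SS/A5SS/MXE events are counted and tested for skew but do not generate
  peptide libraries (only SE exclusion and RI inclusion are treated as
  productive).
- The SAM q-value convention (median false-positive count, no π₀
  estimation) is conservative under strong signal with tiny groups, as
  quantified above.
- The toy binding scorer is a stand-in for a real predictor; %rank values
  from it are only meaningful relative to its own background sample.
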