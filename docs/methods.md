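# Methods

## Scope and model organism context

The package analyses the translational consequences of selective tRNA
depletion in brain tissue: loss of m¹G9 tRNA methylation destabilizes the
initiator tRNA and tRNA-Gln(CUG), which should surface as (i) elevated
ribosome A-site occupancy on the Gln CAG codon, (ii) gene-level shifts in
translational efficiency, (iii) release of uORF-repressed transcripts with
an *Atf4*-type leader, and (iv) reduced relative abundance of the affected
isodecoders in tRNA-seq. Every stage operates on transcript-space
coordinates (0-based, half-open); genome alignment, splicing and UTR
structure are out of scope.

## Synthetic data generators

The generators define the study conditions under which all tests and the
acceptance script operate; they are first-class, tested code.

**Transcriptome.** CDSs are built codon-wise from a configurable usage
table (uniform over the 61 sense codons by default), ATG + internal codons
+ stop, with Poisson-distributed internal length (default mean CDS 300 nt,
the desk-scale stand-in for a mammalian mRNA pool), 100-nt 5' leaders and
50-nt 3' trailers. Leaders are scrubbed of unintended ATGs so annotated
start codons are the only initiation sites; relative abundances are
log-normal (σ = 0.75 by default; σ = 0 gives equal abundances for null
experiments). The two-uORF architecture (uORF1 of 9 nt, 87-nt spacer,
uORF2 of 180 nt overlapping the CDS out of frame, 100 nt from uORF2 start
to CDS start) mirrors the *Atf4* leader arrangement.

**Footprints.** Steady-state, traffic-free elongation: a footprint's
A-site codon is drawn with probability ∝ abundance × dwell weight over all
sense-codon positions; the stop codon carries no elongation dwell.
Footprint lengths follow {28: 0.2, 29: 0.4, 30: 0.3, 31: 0.1} with A-site
offsets 15 nt (28–30-mers) and 16 nt (31-mers) — standard mammalian
monosome values, config-overridable since the underlying experiment's
digestion parameters are protocol-dependent. Footprints that would
overhang the transcript are excluded from the sampling support. Reads are
error-free; ribosome collisions and initiation/termination pausing are
deliberately not modeled — the trim step of the occupancy estimator exists
for real data where they are.

**uORF footprints.** For two-uORF transcripts a separate generator places
footprints per the reinitiation model: every ribosome translates uORF1
(initiation there is obligatory; a leak parameter exists but defaults to
0), then translates uORF2 or the CDS with the closed-form outcome
probabilities; each translated codon emits a footprint with a fixed
sampling rate, uniform within region.

**RNA-seq.** Transcript chosen ∝ abundance × length, 5' ends uniform over
valid positions, fixed read length (50 nt default).

**tRNA-seq.** A synthetic 40-isodecoder reference (random 73-nt bodies +
CCA; labelled synthetic — these are not database gene sequences) includes
iMet-CAT and both Gln isodecoders, with Gln-TTG placed one substitution
from Gln-CTG to reproduce the cross-hybridization hazard of near-identical
anticodon neighbours. Reads are full-length mature molecules; the end
model adds one non-templated 5' nucleotide with probability `p_extra5`
(reverse-transcriptase terminal transferase activity) and drops the
terminal A of the CCA with `p_trunc3`.

**Count matrices.** Replicate counts for TE studies are negative binomial
with var = μ + αμ² (α = 0.05 default), 3 footprint and 5 RNA replicates
per genotype, gene mean 500 — the noise model and design the TE contrast
is intended for.

**Scanning cohorts.** Per-nucleotide Bernoulli reacquisition: the
geometric first-success position decides uORF2 (≤ d₁), CDS (≤ d₁+d₂) or
no reinitiation. All generators are deterministic given a seed.

## Estimators and numerical choices

**Offset calibration.** For each footprint length, distances
Δ = cds_start − 5'-end within [10, 20] are histogrammed over all
transcripts; elongating-ribosome A-sites sit on codon boundaries, so Δ
occupies one frame class (offset, offset−3, …). The dominant frame is
selected first — footprints of out-of-frame upstream ORFs land in other
frames and are excluded — and the offset is the largest in-frame Δ holding
≥ 10% of the frame's mass. This recovers planted offsets exactly on
synthetic data; a start-codon initiation peak is not required. Length
classes under the read floor (default 100) are omitted; if none survive,
the caller is instructed to supply offsets manually.

**Occupancy.** A-site = 5' + offset(length); codon index floor((A −
cds_start)/3), off-frame A-sites assigned to the containing codon;
multimapped footprints dropped by default (fractional weighting optional)
because their codon assignment is ambiguous. Transcripts need ≥ 64 in-CDS
footprints; 5 codons are trimmed from each CDS end and the stop codon is
excluded. The pooled sum-over-sum ratio was chosen over a mean of
per-position ratios for small-count stability. Rescaling to mean 1 makes
profiles scale-invariant; it also means a single perturbed codon's weight
w is estimated as w/w̄ (w̄ = mean weight), a ~2% deflation at w = 2 across
61 codons — inside the recovery tolerances used in the tests.

**TE contrast.** Log2 of size-factor-normalized counts + 0.5 pseudocount;
the four-group Welch contrast handles the unpaired 3-footprint / 5-RNA
design without per-sample ratios. Gene-wise group variances are moderated
toward a scaled-inverse-chi-square prior fitted by matching the moments of
log s² (prior df via a Newton trigamma inverse); this empirical-Bayes
information sharing is what makes per-gene variance estimation workable at
3–5 replicates, and the measured false-positive rate stays at the nominal
5% level. The unmoderated contrast remains available
(`moderate_var=False`). No multiple-testing correction enters the up/down
labels (raw p < 0.05, |log2FC| > 0.5, strict inequalities); BH q-values
are emitted alongside. Median-of-ratios normalization assumes most genes
unchanged; simulations with a majority of shifted genes will see the shift
partially absorbed into the size factors.

**Reinitiation fit.** The multinomial likelihood in q is maximized by
bounded 1-D optimization (xatol 1e-10); all-uORF2 or all-none counts are
boundary cases (q̂ = 1 or 0, flagged). The 95% CI is the χ²₁
profile-likelihood interval found by bisection on each side. The uORF2∩CDS
overlap is credited to uORF2 in region counts (a uORF2-initiated ribosome
reads through the CDS start out of frame); a "both" mode exists. The
release statistic uses per-replicate CDS/uORF1 density ratios, averaged
within genotype.

**tRNA quantification.** Uniform multimap splitting (1/k) is the default —
it makes ambiguity explicit rather than electing one hit; the EM mode
(fixed point to 1e-8, ≤ 100 iterations, monotone in the mixture
likelihood) is provided for sensitivity analysis. Totals are conserved
exactly in both modes. Mapping allows one 5' soft-clipped nucleotide for
tRNA reads only. Per-isodecoder Welch tests on relative abundances are
Sidak-adjusted, p_adj = 1 − (1−p)^m; a two-way ANOVA omnibus
(genotype × isodecoder) is additionally available. Isodecoder pairs within
edit distance 1 are reported as cross-hybridization risks. Note that
relative abundances are compositional: depleting two species slightly
inflates the rest, so a planted 0.5× depletion is recovered as a ratio a
few percent above 0.5.

**Codon statistics.** Codon fractions exclude the stop codon from the
denominator by default (`include_stop` reverses this; `of_amino_acid`
restricts the denominator to synonymous codons). The Mann-Whitney test is
exact by full enumeration of group assignments for min(n₁,n₂) ≤ 8 —
correct under ties — and the continuity-corrected normal approximation
with tie correction otherwise. The worst-case gap between the two at
n₁ = n₂ = 8 is 0.0109 (enumerated exhaustively over all achievable U).

**Mapper.** Seed-and-verify with (max_mismatches+1) non-overlapping
k-mer seeds (k = 12): by pigeonhole any alignment within the mismatch
budget keeps one seed intact, so the mapper is exhaustive and provably
equal to a brute-force scan; reads too short for that many seeds fall back
to brute force. All tied minimal-mismatch hits are reported with their tie
count. Reads are assumed sense-strand (stranded protocols);
reverse-complement search is flag-enabled. External ungapped SAM is
accepted (indel CIGARs rejected with a clear message, since all coordinate
arithmetic assumes ungapped transcript alignments).

## Statistical conventions

Welch's t for two-group comparisons, two-sided; significance tiers
\*/\*\*/\*\*\*/\*\*\*\* at 0.05/0.01/0.001/0.0001; degenerate
(zero-variance-in-both-groups) comparisons report p = 1 with a flag rather
than NaN.

## Problem sizes

Tests and the acceptance script use: 200-transcript pools; footprint
depths 10⁶ (single-profile recovery) and 2×10⁶ per replicate (3 vs 3
genotype comparisons); TE designs of 2,000 genes × (3 fp + 5 RNA)
replicates per genotype; scanning cohorts of 10⁵ ribosomes on a 5×5×5
(q, d₁, d₂) grid; tRNA libraries of 2×10⁵ reads × 4 replicates per
genotype; 10³-case mapper oracle comparisons. Seed-fraction checks
(e.g. "top-ranked in ≥ 18/20 seeds") use 20 seeds in the test suite and
10 in the acceptance script.

## Known limitations

The dwell model is traffic-free: no collisions, queueing, initiation-rate
coupling or positional pausing, so occupancy recovery on synthetic data
bounds estimator error only, not model misspecification on real data. The
TE contrast operates on log counts rather than a full NB GLM; at very low
counts (mean ≪ 50) its calibration degrades before a count model's would.
The scanning model is single-parameter by design — start-codon context,
reinitiation-competence decay and uORF1 leakiness are collapsed into q.
Synthetic tRNA bodies are mutually distant, so multimapping is rarer than
with real isodecoder families; the EM mode is exercised on constructed
shared-read instances instead.
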