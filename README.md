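# ribodwell

Codon-resolved analysis of translation for a mouse model in which loss of a
tRNA methyltransferase depletes specific tRNAs — the initiator tRNA
(tRNA<sup>iMet</sup>) and tRNA<sup>Gln(CUG)</sup> — and thereby perturbs
both elongation (slow decoding of Gln CAG codons) and initiation (release of
uORF-repressed mRNAs such as *Atf4*). The package implements the full
computational chain of such a study — ribosome-profiling A-site occupancy,
translational efficiency (TE), a quantitative uORF-reinitiation model, and
tRNA-seq isodecoder quantification — together with synthetic-data
generators that plant known ground truth at every stage, so each estimator
is verifiable by parameter recovery without any external download.

## What it computes

**Per-codon A-site occupancy** (`ribodwell.occupancy`). Footprint 5' ends
are converted to A-site codons with per-length offsets calibrated from the
start-codon metagene. For codon *c*, the occupancy

&nbsp;&nbsp;&nbsp;&nbsp;*O<sub>c</sub>* = Σ<sub>(t,i): codon=c</sub> *n<sub>t,i</sub>* / Σ<sub>(t,i): codon=c</sub> *n̄<sub>t</sub>*,

a pooled ratio of observed counts to the transcript-mean expectation
(terminal codons trimmed, stop codons excluded), rescaled to mean 1 over
the 61 sense codons. Under a steady-state traffic-free elongation model,
*O<sub>c</sub>* estimates the relative dwell time of codon *c*; genotypes
are compared per codon with Welch's *t*.

**Translational efficiency** (`ribodwell.te`). With size-factor
(median-of-ratios) normalized, log2-transformed counts,

&nbsp;&nbsp;&nbsp;&nbsp;log2FC<sub>TE</sub> = (x̄<sup>fp</sup><sub>null</sub> − x̄<sup>fp</sup><sub>WT</sub>) − (x̄<sup>rna</sup><sub>null</sub> − x̄<sup>rna</sup><sub>WT</sub>),

tested with a Welch–Satterthwaite four-group contrast whose group
variances are moderated toward an empirical-Bayes prior shared across
genes. Genes are labeled up/down at *p* < 0.05 and |log2FC| > 0.5.

**Delayed reinitiation** (`ribodwell.uorf`). After translating uORF1, a
scanning 40S reacquires the ternary complex with per-nucleotide
probability *q*; with spacers *d₁* (to the uORF2 start) and *d₂* (uORF2
start to main CDS start),

&nbsp;&nbsp;&nbsp;&nbsp;p<sub>uORF2</sub> = 1 − (1−q)<sup>d₁</sup>, p<sub>CDS</sub> = (1−q)<sup>d₁</sup>(1 − (1−q)<sup>d₂</sup>), p<sub>none</sub> = (1−q)<sup>d₁+d₂</sup>.

Lower *q* (less ternary complex, e.g. a depleted initiator tRNA) shifts
initiation from the inhibitory, CDS-overlapping uORF2 to the main CDS.
The module quantifies footprints per leader region, forms the
CDS-release statistic, and fits *q* by maximum likelihood with a
profile-likelihood CI.

**tRNA-seq quantification** (`ribodwell.trna`). Mature-reference
construction (introns spliced, CCA appended), mapping that tolerates one
non-templated 5' nucleotide, multimap resolution by uniform splitting or
EM, Sidak-adjusted per-isodecoder Welch tests, and 5'/3' read-end
profiles.

## Worked example

```python
from ribodwell.models import DwellModel
from ribodwell.simulate import generate_transcriptome, simulate_asite_counts
from ribodwell.occupancy import codon_occupancy

txs = generate_transcriptome(200, seed=2024, abundance_sigma=0)
annotation = {t.id: {"CDS": t.cds} for t in txs}
sequences = {t.id: t.sequence for t in txs}
counts = simulate_asite_counts(txs, DwellModel({"CAG": 2.0}), depth=1_000_000, seed=1)
profile = codon_occupancy(counts, annotation, sequences)
print(f"O_CAG = {profile.occupancy['CAG']:.3f}")
```

prints `O_CAG = 1.950`: a planted two-fold CAG dwell weight is recovered as
an occupancy just below 2 (the mean-1 normalization spreads the excess
dwell over the other 60 codons, a ~2% deflation at one perturbed codon).

The numbered scripts under `analysis/` run the full narrative on simulated
libraries — `01_simulate_data.py` through `07_codon_composition.py` —
writing tables to `results/`. On the default seeds the occupancy comparison
ranks CAG first (ratio 1.310, *p* = 7.0×10⁻⁶, with a planted 1.3× dwell
weight), the Atf4-like CDS-release statistic is 1.73 (Welch *p* =
1.3×10⁻⁵) when *q* drops from 0.02 to 0.005, and the fitted *q̂* values are
0.01997 and 0.00504.

A thin CLI mirrors the pipeline stages:
`ribodwell simulate|map|occupancy|te|uorf|trna|codonstat --help`.

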