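"""Stochastic simulator of delayed reinitiation after uORF1 translation.

Each post-termination 40S subunit scans downstream nucleotide by
nucleotide and at each position reacquires the ternary complex with
probability q; it then initiates at the next start codon it reaches:
the uORF2 start if reacquisition happened within the d1-nt spacer, the
main-CDS start if within the following d2 nt, otherwise it never
reinitiates. The matching closed form lives in ``ribodwell.uorf``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..models import Read, ReadOrigin, ReadSet, ScanningParams, TranscriptModel


@dataclass(frozen=True)
class InitiationCounts:
    """Outcome tallies for a cohort of post-uORF1 scanning ribosomes."""

    uorf2: int
    cds: int
    none: int

    @property
    def total(self) -> int:
        return self.uorf2 + self.cds + self.none

    def as_array(self) -> np.ndarray:
        return np.array([self.uorf2, self.cds, self.none])


def simulate_scanning_cohort(params: ScanningParams, n_ribosomes: int, seed: int = 0) -> InitiationCounts:
    """Simulate ``n_ribosomes`` scanning outcomes; deterministic under seed."""
    if n_ribosomes < 0:
        raise ValueError("n_ribosomes must be >= 0")
    if n_ribosomes == 0 or params.q == 0.0:
        return InitiationCounts(uorf2=0, cds=0, none=n_ribosomes)
    rng = np.random.default_rng(seed)
    # Position of first reacquisition, 1-indexed geometric draw.
    x = rng.geometric(params.q, size=n_ribosomes)
    n_uorf2 = int((x <= params.d1).sum())
    n_cds = int(((x > params.d1) & (x <= params.d1 + params.d2)).sum())
    return InitiationCounts(uorf2=n_uorf2, cds=n_cds, none=n_ribosomes - n_uorf2 - n_cds)


def simulate_uorf_footprints(
    transcript: TranscriptModel,
    params: ScanningParams,
    n_ribosomes: int = 10_000,
    sampling_rate: float = 0.05,
    length_dist: dict[int, float] | None = None,
    offsets: dict[int, int] | None = None,
    seed: int = 0,
) -> ReadSet:
    """Footprints on a two-uORF transcript under the delayed-reinitiation model.

    Every loaded ribosome translates uORF1 (initiation there is obligatory);
    a fraction given by the reinitiation outcome probabilities then
    translates uORF2 or the main CDS. Each translated codon yields a
    footprint with probability ``sampling_rate``, its A-site uniform over
    the region's codons (uniform dwell), so region footprint densities are
    proportional to 1 : p_uORF2 : p_CDS.
    """
    from .footprints import DEFAULT_LENGTH_DIST, DEFAULT_OFFSETS

    if len(transcript.uorfs) < 2:
        raise ValueError(f"{transcript.id}: two uORFs required for the scanning model")
    length_dist = length_dist or DEFAULT_LENGTH_DIST
    offsets = offsets or DEFAULT_OFFSETS
    rng = np.random.default_rng(seed)
    counts = simulate_scanning_cohort(params, n_ribosomes, seed=int(rng.integers(1 << 31)))
    u1, u2 = transcript.uorfs[0], transcript.uorfs[1]
    regions = [
        (u1.start, len(u1) // 3, n_ribosomes),
        (u2.start, len(u2) // 3, counts.uorf2),
        (transcript.cds.start, transcript.n_codons, counts.cds),
    ]
    lengths = sorted(length_dist)
    p_len = np.array([length_dist[L] for L in lengths], dtype=float)
    p_len /= p_len.sum()
    reads: list[Read] = []
    read_no = 0
    for start, n_codons, n_events in regions:
        n_fp = rng.binomial(n_events * n_codons, sampling_rate)
        codon_idx = rng.integers(0, n_codons, size=n_fp)
        fp_lengths = np.array(lengths)[rng.choice(len(lengths), size=n_fp, p=p_len)]
        for ci, L in zip(codon_idx, fp_lengths):
            five = start + 3 * int(ci) - offsets[int(L)]
            if five < 0 or five + int(L) > len(transcript):
                continue  # truncated at transcript bounds
            reads.append(
                Read(
                    id=f"ufp{read_no}",
                    sequence=transcript.sequence[five : five + int(L)],
                    origin=ReadOrigin(transcript.id, five, int(L)),
                )
            )
            read_no += 1
    return ReadSet(reads=reads, format="fastq")
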