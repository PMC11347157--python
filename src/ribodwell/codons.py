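"""Genetic-code tables shared across the package.

The standard nuclear genetic code: 61 sense codons, 3 stop codons.
Codon occupancy, dwell models and codon-composition statistics all index
into ``SENSE_CODONS`` in this fixed lexicographic order.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

STOP_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.stop_codons))

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

assert len(SENSE_CODONS) == 61 and len(STOP_CODONS) == 3

SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

NUCLEOTIDES = "ACGT"


def codons_of(cds: str) -> list[str]:
    """Split an in-frame CDS into codons. Length must be divisible by 3."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]
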