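"""Core domain types: transcripts, reads, alignments, dwell/scanning models.

Coordinates are 0-based, half-open, in transcript space throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codons import SENSE_CODONS, STOP_CODONS, codons_of


@dataclass(frozen=True)
class Interval:
    """Half-open [start, end) interval in transcript coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class TranscriptModel:
    """One transcript: sequence plus CDS and (optional) uORF intervals.

    Invariants enforced on construction: the CDS starts with ATG, ends with a
    stop codon and has length divisible by 3; every uORF starts with ATG and
    has length divisible by 3; uORFs are sorted by start.
    """

    id: str
    sequence: str
    cds: Interval
    uorfs: list[Interval] = field(default_factory=list)
    abundance: float = 1.0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - set("ACGT"):
            raise ValueError(f"{self.id}: non-ACGT characters in sequence")
        if self.cds.end > len(seq):
            raise ValueError(f"{self.id}: CDS extends past transcript end")
        if len(self.cds) % 3:
            raise ValueError(f"{self.id}: CDS length not divisible by 3")
        if seq[self.cds.start : self.cds.start + 3] != "ATG":
            raise ValueError(f"{self.id}: CDS does not start with ATG")
        if seq[self.cds.end - 3 : self.cds.end] not in STOP_CODONS:
            raise ValueError(f"{self.id}: CDS does not end with a stop codon")
        for u in self.uorfs:
            if u.end > len(seq):
                raise ValueError(f"{self.id}: uORF extends past transcript end")
            if len(u) % 3:
                raise ValueError(f"{self.id}: uORF length not divisible by 3")
            if seq[u.start : u.start + 3] != "ATG":
                raise ValueError(f"{self.id}: uORF does not start with ATG")
        if any(a.start > b.start for a, b in zip(self.uorfs, self.uorfs[1:])):
            raise ValueError(f"{self.id}: uORFs not sorted by start")
        if self.abundance < 0:
            raise ValueError(f"{self.id}: negative abundance")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_codons(self) -> int:
        """Number of CDS codons including the stop codon."""
        return len(self.cds) // 3

    def cds_codons(self) -> list[str]:
        return codons_of(self.sequence[self.cds.start : self.cds.end])


@dataclass
class DwellModel:
    """Per-codon ribosome dwell weights; 1.0 is the baseline.

    The steady-state, traffic-free elongation model: footprint density on a
    codon is proportional to its dwell weight, so the weight is exactly the
    ground truth that A-site occupancy estimates.
    """

    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {c: 1.0 for c in SENSE_CODONS}
        for codon, w in self.weights.items():
            codon = codon.upper()
            if codon not in full:
                raise ValueError(f"{codon} is not a sense codon")
            if w <= 0:
                raise ValueError(f"dwell weight for {codon} must be > 0")
            full[codon] = float(w)
        self.weights = full

    def as_array(self) -> np.ndarray:
        return np.array([self.weights[c] for c in SENSE_CODONS])

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon.upper()]


@dataclass(frozen=True)
class ScanningParams:
    """Delayed-reinitiation scanning model parameters.

    q   per-nucleotide probability that a scanning 40S reacquires the
        ternary complex (eIF2-GTP-initiator tRNA);
    d1  nucleotides from the uORF1 stop to the uORF2 start codon;
    d2  nucleotides from the uORF2 start to the main-CDS start codon.
    """

    q: float
    d1: int
    d2: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must be in [0, 1]")
        if self.d1 < 1 or self.d2 < 1:
            raise ValueError("d1 and d2 must be >= 1")


@dataclass(frozen=True)
class ReadOrigin:
    """Provenance of a simulated read: where it was sliced from."""

    transcript_id: str
    position: int
    length: int


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    origin: ReadOrigin | None = None


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)
    format: str = "fastq"

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


@dataclass(frozen=True)
class Alignment:
    """Ungapped transcriptome alignment of one read.

    ``multiplicity`` is the number of equally-best hits the read had; each
    of those hits is emitted as its own Alignment carrying the same
    multiplicity.
    """

    read_id: str
    reference_id: str
    position: int
    length: int
    mismatches: int = 0
    multiplicity: int = 1
    soft5: int = 0  # non-templated 5' nucleotides clipped before matching

    @property
    def end(self) -> int:
        return self.position + self.length
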