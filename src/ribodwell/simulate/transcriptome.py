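"""Synthetic transcriptome generation with known ground truth.

Transcripts are built codon-by-codon from a configurable codon-usage table,
with ATG-free untranslated leaders so the annotated start codons are the
only initiation sites a scanning ribosome can see. Optionally a subset of
transcripts carries the stress-responsive two-uORF leader architecture
(a short uORF1, a spacer, and a uORF2 that overlaps the main CDS out of
frame) that places main-CDS translation under delayed-reinitiation control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..codons import SENSE_CODONS, STOP_CODONS
from ..io import write_annotation, write_fasta
from ..models import Interval, TranscriptModel

_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class UorfSpec:
    """Two-uORF leader architecture for a subset of transcripts.

    uorf1_len and uorf2_len are nucleotide lengths (multiples of 3);
    d1 is the distance from the uORF1 stop to the uORF2 start, d2 from the
    uORF2 start to the main-CDS start. uorf2_len must exceed d2 so that
    uORF2 overlaps the CDS, and d2 must not be a multiple of 3 so the
    overlap is out of frame.
    """

    n_transcripts: int = 1
    uorf1_len: int = 9
    d1: int = 87
    d2: int = 100
    uorf2_len: int = 180

    def __post_init__(self) -> None:
        if self.uorf1_len % 3 or self.uorf1_len < 9:
            raise ValueError("uorf1_len must be a multiple of 3 and >= 9 (ATG + codon + stop)")
        if self.uorf2_len % 3:
            raise ValueError("uorf2_len must be a multiple of 3")
        if self.d1 < 1 or self.d2 < 4:
            raise ValueError("d1 must be >= 1 and d2 >= 4")
        if self.uorf2_len <= self.d2:
            raise ValueError(
                f"uORF2 (len {self.uorf2_len}) must overlap the CDS: requires uorf2_len > d2 ({self.d2})"
            )
        if self.d2 % 3 == 0:
            raise ValueError(f"d2={self.d2} puts uORF2 in frame with the CDS; an out-of-frame overlap is required")

    @property
    def overlap_nt(self) -> int:
        return self.uorf2_len - self.d2


def _normalized_codon_usage(codon_usage: dict[str, float] | np.ndarray | None) -> np.ndarray:
    if codon_usage is None:
        w = np.ones(len(SENSE_CODONS))
    elif isinstance(codon_usage, dict):
        w = np.array([float(codon_usage.get(c, 0.0)) for c in SENSE_CODONS])
    else:
        w = np.asarray(codon_usage, dtype=float)
        if w.shape != (len(SENSE_CODONS),):
            raise ValueError("codon_usage array must have one weight per sense codon")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("codon usage weights must be non-negative and not all zero")
    return w / w.sum()


def _random_codons(rng: np.random.Generator, n: int, p: np.ndarray) -> str:
    idx = rng.choice(len(SENSE_CODONS), size=n, p=p)
    return "".join(SENSE_CODONS[i] for i in idx)


def _random_utr(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def _repair_leader_atgs(seq: list[str], region_end: int, allowed_starts: set[int]) -> None:
    """Mutate the G of any unintended ATG in seq[:region_end] to C in place."""
    i = 0
    while i <= region_end - 3:
        if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G" and i not in allowed_starts:
            seq[i + 2] = "C"
            i = max(0, i - 2)  # repair may expose a new ATG ending earlier
        else:
            i += 1


def _draw_cds_codons(rng: np.random.Generator, cds_length_dist: float | dict) -> int:
    """Number of internal (non-ATG, non-stop) CDS codons."""
    if isinstance(cds_length_dist, dict):
        mean_nt = float(cds_length_dist.get("mean", 300.0))
    else:
        mean_nt = float(cds_length_dist)
    if mean_nt < 30:
        raise ValueError("mean CDS length must be >= 30 nt")
    internal_mean = mean_nt / 3.0 - 2.0
    return int(max(4, rng.poisson(internal_mean)))


def generate_transcriptome(
    n_genes: int,
    cds_length_dist: float | dict = 300.0,
    codon_usage: dict[str, float] | np.ndarray | None = None,
    uorf_spec: UorfSpec | None = None,
    seed: int = 0,
    utr5_length: int = 100,
    utr3_length: int = 50,
    abundance_sigma: float = 0.75,
) -> list[TranscriptModel]:
    """Generate ``n_genes`` transcripts with known CDS/uORF architecture.

    Relative expression weights are drawn log-normally (sigma in log space
    ``abundance_sigma``; 0 gives equal abundances). When ``uorf_spec`` is
    given, the first ``uorf_spec.n_transcripts`` transcripts carry the
    two-uORF leader; they are named ``uorf_tx{i}``, the rest ``tx{i}``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    n_uorf = uorf_spec.n_transcripts if uorf_spec else 0
    if n_uorf > n_genes:
        raise ValueError("uorf_spec requests more uORF transcripts than n_genes")
    usage = _normalized_codon_usage(codon_usage)
    transcripts: list[TranscriptModel] = []
    for g in range(n_genes):
        internal = _draw_cds_codons(rng, cds_length_dist)
        cds = "ATG" + _random_codons(rng, internal, usage) + str(rng.choice(STOP_CODONS))
        abundance = float(np.exp(rng.normal(0.0, abundance_sigma))) if abundance_sigma > 0 else 1.0
        if g < n_uorf:
            assert uorf_spec is not None
            if uorf_spec.overlap_nt > len(cds):
                raise ValueError(
                    f"uORF2 overlap of {uorf_spec.overlap_nt} nt exceeds the CDS length "
                    f"{len(cds)}; increase the CDS length or reduce uorf2_len - d2"
                )
            head = _random_utr(rng, utr5_length)
            u1_internal = uorf_spec.uorf1_len // 3 - 2
            # TAA/TAG only: a TGA stop preceded by an A would form an ATG that
            # the leader repair pass would destroy.
            uorf1 = "ATG" + _random_codons(rng, u1_internal, usage) + str(rng.choice(["TAA", "TAG"]))
            spacer = _random_utr(rng, uorf_spec.d1)
            between = _random_utr(rng, uorf_spec.d2 - 3)  # after the uORF2 ATG, before the CDS ATG
            leader = head + uorf1 + spacer + "ATG" + between
            u1_start = utr5_length
            u2_start = u1_start + uorf_spec.uorf1_len + uorf_spec.d1
            cds_start = u2_start + uorf_spec.d2
            seq = list(leader + cds + _random_utr(rng, utr3_length))
            _repair_leader_atgs(seq, cds_start + 3, {u1_start, u2_start, cds_start})
            t = TranscriptModel(
                id=f"uorf_tx{g}",
                sequence="".join(seq),
                cds=Interval(cds_start, cds_start + len(cds)),
                uorfs=[
                    Interval(u1_start, u1_start + uorf_spec.uorf1_len),
                    Interval(u2_start, u2_start + uorf_spec.uorf2_len),
                ],
                abundance=abundance,
            )
        else:
            seq = list(_random_utr(rng, utr5_length) + cds + _random_utr(rng, utr3_length))
            _repair_leader_atgs(seq, utr5_length + 3, {utr5_length})
            t = TranscriptModel(
                id=f"tx{g}",
                sequence="".join(seq),
                cds=Interval(utr5_length, utr5_length + len(cds)),
                abundance=abundance,
            )
        transcripts.append(t)
    return transcripts


def write_transcriptome(transcripts: list[TranscriptModel], out_dir: str | Path, prefix: str = "transcriptome") -> tuple[Path, Path]:
    """Write FASTA + annotation TSV; returns the two paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / f"{prefix}.fa"
    annot = out / f"{prefix}.annotation.tsv"
    write_fasta({t.id: t.sequence for t in transcripts}, fasta)
    write_annotation(transcripts, annot)
    return fasta, annot
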