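"""File I/O: FASTA/FASTQ, the region-annotation TSV, alignment TSV and SAM.

The annotation format is a tab-separated table with columns
``transcript_id  feature  start  end`` where feature is one of
CDS / uORF1 / uORF2 and coordinates are 0-based half-open in transcript
space — the same convention every module of the package uses.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import Alignment, Interval, Read, ReadSet, TranscriptModel

ANNOTATION_COLUMNS = ("transcript_id", "feature", "start", "end")


# ---------------------------------------------------------------- FASTA/FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as an ordered {id: sequence} mapping."""
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    return records


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: ReadSet | Iterable[Read], path: str | Path) -> None:
    """Write reads as FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def read_fastq(path: str | Path) -> ReadSet:
    reads = [Read(id=r.id, sequence=str(r.seq).upper()) for r in SeqIO.parse(str(path), "fastq")]
    return ReadSet(reads=reads, format="fastq")


# ---------------------------------------------------------------- annotation


def write_annotation(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for t in transcripts:
            writer.writerow([t.id, "CDS", t.cds.start, t.cds.end])
            for i, u in enumerate(t.uorfs, start=1):
                writer.writerow([t.id, f"uORF{i}", u.start, u.end])


def read_annotation(path: str | Path) -> dict[str, dict[str, Interval]]:
    """Load the annotation TSV as {transcript_id: {feature: Interval}}."""
    out: dict[str, dict[str, Interval]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(ANNOTATION_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        for row in reader:
            feats = out.setdefault(row["transcript_id"], {})
            feats[row["feature"]] = Interval(int(row["start"]), int(row["end"]))
    return out


def cds_map(annotation: dict[str, dict[str, Interval]]) -> dict[str, Interval]:
    return {tid: feats["CDS"] for tid, feats in annotation.items() if "CDS" in feats}


# ---------------------------------------------------------------- alignments

ALIGNMENT_COLUMNS = ("read_id", "reference_id", "position", "length", "mismatches", "multiplicity", "soft5")


def write_alignments_tsv(alignments: Iterable[Alignment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ALIGNMENT_COLUMNS)
        for a in alignments:
            writer.writerow([a.read_id, a.reference_id, a.position, a.length, a.mismatches, a.multiplicity, a.soft5])


def read_alignments_tsv(path: str | Path) -> list[Alignment]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                Alignment(
                    read_id=row["read_id"],
                    reference_id=row["reference_id"],
                    position=int(row["position"]),
                    length=int(row["length"]),
                    mismatches=int(row.get("mismatches", 0) or 0),
                    multiplicity=int(row.get("multiplicity", 1) or 1),
                    soft5=int(row.get("soft5", 0) or 0),
                )
            )
    return out


# ----------------------------------------------------------------------- SAM


def read_sam(path: str | Path) -> list[Alignment]:
    """Ingest externally produced ungapped SAM alignments.

    Only coordinate fields are used (read id, reference, position, length,
    NH tag for multiplicity). Records whose CIGAR contains indels or
    reference skips are rejected: downstream coordinate arithmetic assumes
    ungapped transcript alignments.
    """
    out: list[Alignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            bad = [op for op, _ in (rec.cigartuples or []) if op in (1, 2, 3)]  # I, D, N
            if bad:
                raise ValueError(
                    f"read {rec.query_name}: CIGAR {rec.cigarstring} contains "
                    "indels/skips; only ungapped transcript alignments are supported"
                )
            soft5 = 0
            if rec.cigartuples and rec.cigartuples[0][0] == 4:  # leading soft clip
                soft5 = rec.cigartuples[0][1]
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(
                Alignment(
                    read_id=rec.query_name,
                    reference_id=rec.reference_name,
                    position=rec.reference_start,
                    length=rec.reference_length or rec.query_length,
                    mismatches=int(nm),
                    multiplicity=int(nh),
                    soft5=soft5,
                )
            )
    return out


def write_sam(alignments: Iterable[Alignment], references: dict[str, str], path: str | Path) -> None:
    """Write minimal coordinate-only SAM (no sequences or qualities)."""
    ref_names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in references.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for a in alignments:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = a.read_id
            rec.reference_id = ref_names.index(a.reference_id)
            rec.reference_start = a.position
            rec.cigarstring = (f"{a.soft5}S" if a.soft5 else "") + f"{a.length}M"
            rec.mapping_quality = 255
            rec.set_tag("NH", a.multiplicity)
            rec.set_tag("NM", a.mismatches)
            sam.write(rec)
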