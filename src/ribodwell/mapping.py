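"""Lightweight exact/near-exact ungapped transcriptome mapper.

Seed-and-verify against a k-mer index. To keep the mapper exhaustive up to
the configured mismatch budget, a read is seeded with (max_mismatches + 1)
non-overlapping k-mers (pigeonhole: any alignment with <= max_mismatches
substitutions leaves at least one seed intact); reads too short to carry
that many seeds fall back to a brute-force scan over every offset. All
minimal-mismatch hits are reported, each stamped with the tie count
(multiplicity). Reads are assumed sense-strand; reverse-complement search
is available behind a flag for unstranded input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import Alignment, Read, ReadSet

_RC = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class ReferenceIndex:
    k: int
    lookup: dict[str, list[tuple[str, int]]]
    references: dict[str, str]

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("k must be >= 8")


def build_index(references: dict[str, str], k: int = 12) -> ReferenceIndex:
    """Index every k-mer occurrence; k-mers containing N are skipped."""
    if not references:
        raise ValueError("cannot index an empty reference set")
    if k < 8:
        raise ValueError("k must be >= 8")
    shortest = min(len(s) for s in references.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds the shortest reference length ({shortest})")
    lookup: dict[str, list[tuple[str, int]]] = {}
    refs = {}
    for name, seq in references.items():
        seq = seq.upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"{name}: reference alphabet must be ACGTN")
        refs[name] = seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            lookup.setdefault(kmer, []).append((name, i))
    return ReferenceIndex(k=k, lookup=lookup, references=refs)


def _hamming(a: str, b: str, limit: int) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def _candidates(read: str, index: ReferenceIndex, max_mismatches: int) -> set[tuple[str, int]]:
    L, k = len(read), index.k
    n_seeds = max_mismatches + 1
    cands: set[tuple[str, int]] = set()
    if n_seeds * k <= L:
        seg = L // n_seeds
        for i in range(n_seeds):
            o = i * seg
            for ref, pos in index.lookup.get(read[o : o + k], ()):
                start = pos - o
                if start >= 0 and start + L <= len(index.references[ref]):
                    cands.add((ref, start))
    else:
        for ref, seq in index.references.items():
            for start in range(len(seq) - L + 1):
                cands.add((ref, start))
    return cands


def _map_one(read: Read, index: ReferenceIndex, max_mismatches: int, rc: bool) -> list[Alignment]:
    variants = [read.sequence.upper()]
    if rc:
        variants.append(reverse_complement(variants[0]))
    best: list[tuple[str, int, int]] = []
    best_mm = max_mismatches + 1
    for seq in variants:
        if len(seq) < index.k:
            continue
        for ref, start in _candidates(seq, index, max_mismatches):
            mm = _hamming(seq, index.references[ref][start : start + len(seq)], best_mm)
            if mm < best_mm:
                best_mm = mm
                best = [(ref, start, mm)]
            elif mm == best_mm and mm <= max_mismatches:
                best.append((ref, start, mm))
    if best_mm > max_mismatches:
        return []
    best = sorted(set(best))
    return [
        Alignment(
            read_id=read.id,
            reference_id=ref,
            position=start,
            length=len(read.sequence),
            mismatches=mm,
            multiplicity=len(best),
        )
        for ref, start, mm in best
    ]


@dataclass
class MappingResult:
    alignments: list[Alignment] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)


def map_reads(
    reads: ReadSet | list[Read],
    index: ReferenceIndex,
    max_mismatches: int = 0,
    rc: bool = False,
) -> MappingResult:
    """Report all minimal-mismatch hits (<= max_mismatches) for each read.

    Identical read sequences are aligned once and the hit list replayed
    per read, which keeps deep libraries of low sequence complexity
    (e.g. full-length tRNA reads) cheap.
    """
    result = MappingResult()
    cache: dict[str, list[Alignment]] = {}
    for read in reads:
        seq = read.sequence.upper()
        hits = cache.get(seq)
        if hits is None:
            hits = _map_one(read, index, max_mismatches, rc)
            cache[seq] = hits
        if hits:
            result.alignments.extend(
                Alignment(
                    read_id=read.id,
                    reference_id=h.reference_id,
                    position=h.position,
                    length=h.length,
                    mismatches=h.mismatches,
                    multiplicity=h.multiplicity,
                    soft5=h.soft5,
                )
                for h in hits
            )
        else:
            result.unmapped.append(read.id)
    return result


def filter_contaminants(
    reads: ReadSet,
    contaminant_index: ReferenceIndex,
    max_mismatches: int = 0,
) -> tuple[ReadSet, ReadSet]:
    """Partition reads into (kept, removed-as-contaminant), order preserved."""
    kept, removed = [], []
    for read in reads:
        if _map_one(read, contaminant_index, max_mismatches, rc=False):
            removed.append(read)
        else:
            kept.append(read)
    return (
        ReadSet(reads=kept, format=reads.format),
        ReadSet(reads=removed, format=reads.format),
    )
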