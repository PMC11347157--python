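"""RNA-seq read simulation: uniform coverage, abundance-weighted sampling."""

from __future__ import annotations

import numpy as np

from ..models import Read, ReadOrigin, ReadSet, TranscriptModel


def simulate_rnaseq(
    transcripts: list[TranscriptModel],
    depth: int = 100_000,
    read_length: int = 50,
    seed: int = 0,
) -> ReadSet:
    """Draw ``depth`` RNA-seq reads.

    A transcript is chosen with probability proportional to
    abundance * length; the read 5' end is uniform over the transcript's
    valid start positions. Deterministic under ``seed``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return ReadSet(reads=[], format="fastq")
    if not transcripts:
        raise ValueError("empty transcript list")
    for t in transcripts:
        if read_length > len(t):
            raise ValueError(f"read_length {read_length} exceeds transcript {t.id} length {len(t)}")
    rng = np.random.default_rng(seed)
    weights = np.array([t.abundance * len(t) for t in transcripts], dtype=float)
    n_per_tx = rng.multinomial(depth, weights / weights.sum())
    reads: list[Read] = []
    read_no = 0
    for t, n in zip(transcripts, n_per_tx):
        if n == 0:
            continue
        starts = rng.integers(0, len(t) - read_length + 1, size=n)
        for s in starts:
            s = int(s)
            reads.append(
                Read(
                    id=f"rna{read_no}",
                    sequence=t.sequence[s : s + read_length],
                    origin=ReadOrigin(t.id, s, read_length),
                )
            )
            read_no += 1
    return ReadSet(reads=reads, format="fastq")
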