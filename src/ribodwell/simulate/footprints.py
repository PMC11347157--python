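"""Forward simulation of ribosome footprints under a codon dwell model.

Steady-state, traffic-free elongation: the probability that a footprint's
A-site sits on CDS codon i of transcript t is proportional to
abundance_t * w(codon_{t,i}) over all sense codons of all transcripts.
The footprint's 5' end is the A-site first nucleotide minus the A-site
offset for its (sampled) length; footprints that would run past the
transcript bounds are excluded from the sampling support (equivalent to
resampling truncated footprints).
"""

from __future__ import annotations

import numpy as np

from ..codons import SENSE_INDEX
from ..models import DwellModel, Read, ReadOrigin, ReadSet, TranscriptModel
from ..occupancy import ASiteCountMatrix

# Standard mammalian monosome defaults; override per experiment.
DEFAULT_LENGTH_DIST: dict[int, float] = {28: 0.2, 29: 0.4, 30: 0.3, 31: 0.1}
DEFAULT_OFFSETS: dict[int, int] = {28: 15, 29: 15, 30: 15, 31: 16}


def _position_table(transcripts: list[TranscriptModel], dwell: DwellModel):
    """Flattened arrays over all sense-codon A-site positions of all transcripts."""
    if not transcripts:
        raise ValueError("empty transcript list")
    w = dwell.as_array()
    tx_idx, a_sites, codon_idx, weights = [], [], [], []
    for ti, t in enumerate(transcripts):
        codons = t.cds_codons()[:-1]  # stop codon carries no dwell weight
        for ci, codon in enumerate(codons):
            if codon not in SENSE_INDEX:  # internal stop: no elongating A-site
                continue
            tx_idx.append(ti)
            a_sites.append(t.cds.start + 3 * ci)
            codon_idx.append(ci)
            weights.append(t.abundance * w[SENSE_INDEX[codon]])
    return (
        np.array(tx_idx),
        np.array(a_sites),
        np.array(codon_idx),
        np.array(weights, dtype=float),
    )


def simulate_footprints(
    transcripts: list[TranscriptModel],
    dwell: DwellModel | None = None,
    depth: int = 100_000,
    length_dist: dict[int, float] | None = None,
    offsets: dict[int, int] | None = None,
    seed: int = 0,
) -> ReadSet:
    """Draw ``depth`` ribosome footprints; deterministic under ``seed``."""
    dwell = dwell or DwellModel()
    length_dist = length_dist or DEFAULT_LENGTH_DIST
    offsets = offsets or DEFAULT_OFFSETS
    missing = set(length_dist) - set(offsets)
    if missing:
        raise ValueError(f"no A-site offset defined for footprint lengths {sorted(missing)}")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return ReadSet(reads=[], format="fastq")
    tx_idx, a_sites, _, weights = _position_table(transcripts, dwell)
    tx_lengths = np.array([len(t) for t in transcripts])
    rng = np.random.default_rng(seed)
    lengths = sorted(length_dist)
    p_len = np.array([length_dist[L] for L in lengths], dtype=float)
    p_len = p_len / p_len.sum()
    n_per_len = rng.multinomial(depth, p_len)
    reads: list[Read] = []
    read_no = 0
    for L, n in zip(lengths, n_per_len):
        if n == 0:
            continue
        off = offsets[L]
        five = a_sites - off
        valid = (five >= 0) & (five + L <= tx_lengths[tx_idx])
        if not valid.any():
            raise ValueError(f"no valid footprint position for length {L}")
        p = weights * valid
        p = p / p.sum()
        picks = rng.choice(len(p), size=n, p=p)
        for k in picks:
            t = transcripts[tx_idx[k]]
            start = int(five[k])
            reads.append(
                Read(
                    id=f"fp{read_no}",
                    sequence=t.sequence[start : start + L],
                    origin=ReadOrigin(t.id, start, L),
                )
            )
            read_no += 1
    return ReadSet(reads=reads, format="fastq")


def simulate_asite_counts(
    transcripts: list[TranscriptModel],
    dwell: DwellModel | None = None,
    depth: int = 1_000_000,
    seed: int = 0,
    sample_id: str = "sim",
) -> ASiteCountMatrix:
    """Sample A-site codon counts directly, without materializing reads.

    Same sampling distribution as ``simulate_footprints`` (minus the
    footprint-bound truncation, which removes no position under the default
    UTR lengths); useful for occupancy recovery experiments at high depth.
    """
    dwell = dwell or DwellModel()
    if depth < 0:
        raise ValueError("depth must be >= 0")
    tx_idx, a_sites, codon_idx, weights = _position_table(transcripts, dwell)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, weights / weights.sum())
    m = ASiteCountMatrix(sample_id=sample_id)
    nz = np.nonzero(counts)[0]
    for k in nz:
        t = transcripts[tx_idx[k]]
        m.counts[(t.id, int(codon_idx[k]))] = float(counts[k])
        m.positions[(t.id, int(a_sites[k]))] = float(counts[k])
    return m


def expected_asite_fractions(
    transcripts: list[TranscriptModel],
    dwell: DwellModel | None = None,
) -> dict[str, float]:
    """Exact per-codon-identity A-site probability under the dwell model.

    Closed-form enumeration over every codon position; the ground truth
    that simulated footprint fractions converge to.
    """
    dwell = dwell or DwellModel()
    tx_idx, _, codon_idx, weights = _position_table(transcripts, dwell)
    total = weights.sum()
    out: dict[str, float] = {}
    for k in range(len(weights)):
        t = transcripts[tx_idx[k]]
        codon = t.cds_codons()[codon_idx[k]]
        out[codon] = out.get(codon, 0.0) + weights[k] / total
    return out
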