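"""A-site offset calibration, codon assignment and per-codon occupancy.

The occupancy statistic O_c answers: relative to the average codon of the
same transcripts, how densely do ribosomes sit with codon c in the A-site?
Under a steady-state traffic-free elongation model O_c estimates the
relative dwell time of codon c, so a codon decoded by a depleted tRNA shows
O_c > 1. Profiles are normalized to mean 1 over observed codons and
compared between genotypes with per-codon Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codons import CODON_TO_AA, SENSE_CODONS
from .models import Alignment, Interval

OFFSET_WINDOW = (10, 20)


def significance_tier(p: float) -> str:
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < threshold:
            return stars
    return "ns"


@dataclass
class OffsetTable:
    """Footprint length -> distance from the 5' end to the A-site first nt."""

    offsets: dict[int, int]
    diagnostics: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = OFFSET_WINDOW
        for length, off in self.offsets.items():
            if not lo <= off <= hi:
                raise ValueError(f"offset {off} for length {length} outside [{lo}, {hi}]")

    def __getitem__(self, length: int) -> int:
        return self.offsets[length]

    def __contains__(self, length: int) -> bool:
        return length in self.offsets


@dataclass
class ASiteCountMatrix:
    """Per-transcript A-site footprint tallies for one sample.

    ``counts`` holds in-CDS counts keyed by (transcript, codon index from
    the CDS start); ``positions`` keeps every assigned A-site at nucleotide
    resolution (including 5'UTR/3'UTR hits) for region-level quantification.
    """

    sample_id: str
    counts: dict[tuple[str, int], float] = field(default_factory=dict)
    positions: dict[tuple[str, int], float] = field(default_factory=dict)
    upstream: float = 0.0
    downstream: float = 0.0
    dropped_length: int = 0
    dropped_multimapped: int = 0

    @property
    def total_in_cds(self) -> float:
        return float(sum(self.counts.values()))

    def transcript_vector(self, transcript_id: str, n_codons: int) -> np.ndarray:
        v = np.zeros(n_codons)
        for (tid, idx), n in self.counts.items():
            if tid == transcript_id:
                v[idx] += n
        return v


@dataclass
class CodonOccupancyProfile:
    sample_id: str
    occupancy: dict[str, float]
    transcripts_used: int

    def __post_init__(self) -> None:
        vals = np.array(list(self.occupancy.values()))
        if len(vals) and abs(vals.mean() - 1.0) > 1e-9:
            raise ValueError("occupancy profile not normalized to mean 1")
        if (vals < 0).any():
            raise ValueError("negative occupancy")

    def as_series(self) -> pd.Series:
        return pd.Series(self.occupancy, name=self.sample_id)


def calibrate_offsets(
    alignments: list[Alignment],
    annotation: dict[str, dict[str, Interval]],
    min_reads_per_length: int = 100,
) -> OffsetTable:
    """Infer the A-site offset per footprint length from the start-codon metagene.

    For footprints whose 5' end lies upstream of the CDS start, the distance
    (cds_start - five_prime_end) can only take the values offset, offset-3,
    offset-6, ... (A-sites of CDS-frame elongating ribosomes sit on codon
    boundaries). Within the plausible window the dominant frame class is
    selected first — footprints from out-of-frame upstream ORFs fall in a
    different frame and are thereby excluded — and the offset is the largest
    distance in that frame carrying substantial read mass (>= 10% of the
    frame total). Lengths with fewer than ``min_reads_per_length``
    alignments are omitted.
    """
    lo, hi = OFFSET_WINDOW
    cds_starts = {tid: feats["CDS"].start for tid, feats in annotation.items() if "CDS" in feats}
    by_length: dict[int, np.ndarray] = {}
    totals: dict[int, int] = {}
    for a in alignments:
        totals[a.length] = totals.get(a.length, 0) + 1
        start = cds_starts.get(a.reference_id)
        if start is None:
            continue
        delta = start - a.position
        if lo <= delta <= hi:
            hist = by_length.setdefault(a.length, np.zeros(hi - lo + 1))
            hist[delta - lo] += 1
    offsets: dict[int, int] = {}
    diagnostics: dict[int, np.ndarray] = {}
    for length, total in sorted(totals.items()):
        if total < min_reads_per_length:
            continue
        hist = by_length.get(length)
        if hist is None or hist.sum() == 0:
            continue
        deltas = np.arange(lo, hi + 1)
        frame_mass = [hist[deltas % 3 == f].sum() for f in range(3)]
        f_star = int(np.argmax(frame_mass))
        in_frame = (deltas % 3 == f_star) & (hist >= 0.1 * frame_mass[f_star])
        offsets[length] = int(deltas[in_frame].max())
        diagnostics[length] = hist
    if not offsets:
        raise ValueError(
            "no footprint length class passed the read-count floor for offset "
            "calibration; supply an OffsetTable manually"
        )
    return OffsetTable(offsets=offsets, diagnostics=diagnostics)


def assign_a_sites(
    alignments: list[Alignment],
    offsets: OffsetTable,
    annotation: dict[str, dict[str, Interval]],
    sample_id: str = "sample",
    multimapped: str = "drop",
) -> ASiteCountMatrix:
    """Assign footprints to A-site codons: A-site nt = 5' position + offset(length).

    Codon index = floor((a_site - cds_start) / 3); an off-frame A-site counts
    toward its containing codon. A-sites outside the CDS are tallied in the
    upstream/downstream totals (and kept at nt resolution in ``positions``).
    Multimapped footprints are dropped by default, or down-weighted 1/k with
    ``multimapped="fractional"``.
    """
    if multimapped not in ("drop", "fractional"):
        raise ValueError("multimapped must be 'drop' or 'fractional'")
    m = ASiteCountMatrix(sample_id=sample_id)
    for a in alignments:
        if a.length not in offsets:
            m.dropped_length += 1
            continue
        if a.multiplicity > 1 and multimapped == "drop":
            m.dropped_multimapped += 1
            continue
        weight = 1.0 / a.multiplicity if multimapped == "fractional" else 1.0
        a_site = a.position + offsets[a.length]
        key = (a.reference_id, a_site)
        m.positions[key] = m.positions.get(key, 0.0) + weight
        feats = annotation.get(a.reference_id)
        if feats is None or "CDS" not in feats:
            continue
        cds = feats["CDS"]
        if a_site < cds.start:
            m.upstream += weight
        elif a_site >= cds.end:
            m.downstream += weight
        else:
            idx = (a_site - cds.start) // 3
            ckey = (a.reference_id, idx)
            m.counts[ckey] = m.counts.get(ckey, 0.0) + weight
    return m


def codon_occupancy(
    asite: ASiteCountMatrix,
    annotation: dict[str, dict[str, Interval]],
    sequences: dict[str, str],
    min_reads_per_transcript: int = 64,
    trim_codons: int = 5,
) -> CodonOccupancyProfile:
    """Pooled-ratio per-codon occupancy over qualifying transcripts.

    For each transcript passing the in-CDS read floor, positions
    trim..K-trim-1 (stop codon excluded) contribute the observed count to
    the numerator of their codon identity and the transcript's mean count
    over that window to the denominator; O_c is the pooled ratio, rescaled
    to mean 1 over observed codons.
    """
    per_transcript: dict[str, np.ndarray] = {}
    for (tid, idx), n in asite.counts.items():
        cds = annotation[tid]["CDS"]
        v = per_transcript.setdefault(tid, np.zeros(len(cds) // 3))
        v[idx] += n
    numerator = {c: 0.0 for c in SENSE_CODONS}
    denominator = {c: 0.0 for c in SENSE_CODONS}
    used = 0
    for tid, v in per_transcript.items():
        if v.sum() < min_reads_per_transcript:
            continue
        cds = annotation[tid]["CDS"]
        codon_seq = sequences[tid][cds.start : cds.end]
        n_codons = len(v)
        lo = trim_codons
        hi = n_codons - trim_codons - 1  # inclusive; also excludes the stop at n_codons-1
        hi = min(hi, n_codons - 2)
        if hi - lo < 1:
            continue
        window = v[lo : hi + 1]
        mean = window.mean()
        if mean == 0:
            continue
        used += 1
        for i in range(lo, hi + 1):
            codon = codon_seq[3 * i : 3 * i + 3]
            if codon in numerator:
                numerator[codon] += v[i]
                denominator[codon] += mean
    if used == 0:
        raise ValueError("no transcript passed the occupancy read floor")
    occ = {c: numerator[c] / denominator[c] for c in SENSE_CODONS if denominator[c] > 0}
    scale = np.mean(list(occ.values()))
    occ = {c: o / scale for c, o in occ.items()}
    return CodonOccupancyProfile(sample_id=asite.sample_id, occupancy=occ, transcripts_used=used)


def compare_occupancy(
    wt_profiles: list[CodonOccupancyProfile],
    null_profiles: list[CodonOccupancyProfile],
) -> pd.DataFrame:
    """Per-codon genotype comparison: group means, null/WT ratio, Welch t.

    Requires >= 2 replicates per group. Codons where both groups have zero
    variance are reported with p = 1 and the ``degenerate`` flag.
    """
    if len(wt_profiles) < 2 or len(null_profiles) < 2:
        raise ValueError("compare_occupancy needs >= 2 replicates per group")
    wt = pd.DataFrame([p.as_series() for p in wt_profiles])
    null = pd.DataFrame([p.as_series() for p in null_profiles])
    codons = [c for c in SENSE_CODONS if c in wt.columns and c in null.columns]
    rows = []
    for c in codons:
        x, y = wt[c].to_numpy(), null[c].to_numpy()
        degenerate = bool((x == x[0]).all() and (y == y[0]).all())
        if degenerate:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(y, x, equal_var=False)
        rows.append(
            {
                "codon": c,
                "aa": CODON_TO_AA[c],
                "mean_wt": x.mean(),
                "sem_wt": stats.sem(x),
                "mean_null": y.mean(),
                "sem_null": stats.sem(y),
                "ratio": y.mean() / x.mean() if x.mean() > 0 else np.nan,
                "t": float(t_stat),
                "p": float(p),
                "tier": significance_tier(float(p)),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("codon")
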