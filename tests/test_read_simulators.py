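"""Footprint, RNA-seq and tRNA-seq simulators against closed-form expectations."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from ribodwell.models import DwellModel, ScanningParams
from ribodwell.simulate import (
    EndModel,
    simulate_asite_counts,
    simulate_footprints,
    simulate_rnaseq,
    simulate_scanning_cohort,
    simulate_trna_reads,
    synthetic_trna_reference,
)
from ribodwell.simulate.footprints import DEFAULT_OFFSETS

from .conftest import sequences_of


def codon_position_expectation(transcripts, dwell: DwellModel) -> dict[str, float]:
    """Independent enumeration: P(A-site codon identity) under the dwell model."""
    total = 0.0
    per_codon: Counter = Counter()
    for t in transcripts:
        for codon in t.cds_codons()[:-1]:
            if codon in dwell.weights:
                w = t.abundance * dwell.weights[codon]
                per_codon[codon] += w
                total += w
    return {c: w / total for c, w in per_codon.items()}


def observed_asite_fractions(reads, transcripts) -> Counter:
    by_id = {t.id: t for t in transcripts}
    obs: Counter = Counter()
    for r in reads:
        t = by_id[r.origin.transcript_id]
        a = r.origin.position + DEFAULT_OFFSETS[r.origin.length]
        idx = (a - t.cds.start) // 3
        obs[t.cds_codons()[idx]] += 1
    return obs


def test_uniform_dwell_codon_fractions_match_frequency(small_transcriptome):
    depth = 200_000
    reads = simulate_footprints(small_transcriptome, DwellModel(), depth=depth, seed=1)
    expected = codon_position_expectation(small_transcriptome, DwellModel())
    obs = observed_asite_fractions(reads, small_transcriptome)
    for codon, p in expected.items():
        se = np.sqrt(p * (1 - p) / depth)
        assert abs(obs[codon] / depth - p) <= 3 * se + 1e-9, codon


def test_elevated_cag_dwell_matches_renormalized_expectation(small_transcriptome):
    dwell = DwellModel({"CAG": 2.0})
    depth = 200_000
    reads = simulate_footprints(small_transcriptome, dwell, depth=depth, seed=2)
    expected = codon_position_expectation(small_transcriptome, dwell)
    obs = observed_asite_fractions(reads, small_transcriptome)
    p = expected["CAG"]
    se = np.sqrt(p * (1 - p) / depth)
    assert abs(obs["CAG"] / depth - p) <= 3 * se


def test_footprint_edges_and_determinism(small_transcriptome):
    assert len(simulate_footprints(small_transcriptome, depth=0, seed=1)) == 0
    with pytest.raises(ValueError):
        simulate_footprints([], depth=10, seed=1)
    with pytest.raises(ValueError, match="offset"):
        simulate_footprints(small_transcriptome, depth=10, length_dist={27: 1.0}, offsets={28: 15}, seed=1)
    a = simulate_footprints(small_transcriptome, depth=500, seed=9)
    b = simulate_footprints(small_transcriptome, depth=500, seed=9)
    assert [(r.id, r.sequence, r.origin) for r in a] == [(r.id, r.sequence, r.origin) for r in b]


def test_read_origin_reproduces_sequence(weighted_transcriptome):
    seqs = sequences_of(weighted_transcriptome)
    for readset in (
        simulate_footprints(weighted_transcriptome, depth=300, seed=3),
        simulate_rnaseq(weighted_transcriptome, depth=300, read_length=40, seed=4),
    ):
        for r in readset:
            o = r.origin
            assert r.sequence == seqs[o.transcript_id][o.position : o.position + o.length]


def test_uniform_dwell_chisquare_null_calibration(small_transcriptome):
    """A-site counts are multinomial around codon-frequency expectations."""
    expected = codon_position_expectation(small_transcriptome, DwellModel())
    codons = sorted(expected)
    p = np.array([expected[c] for c in codons])
    depth = 50_000
    nonsig = 0
    n_runs = 100
    for seed in range(n_runs):
        m = simulate_asite_counts(small_transcriptome, depth=depth, seed=seed)
        by_codon = Counter()
        by_id = {t.id: t for t in small_transcriptome}
        for (tid, idx), n in m.counts.items():
            by_codon[by_id[tid].cds_codons()[idx]] += n
        obs = np.array([by_codon[c] for c in codons])
        stat = ((obs - depth * p) ** 2 / (depth * p)).sum()
        if stats.chi2.sf(stat, df=len(codons) - 1) > 0.01:
            nonsig += 1
    assert nonsig >= 0.95 * n_runs


def test_rnaseq_abundance_ratio_and_edges():
    from ribodwell.models import Interval, TranscriptModel

    seq = "G" * 30 + "ATG" + "GCT" * 30 + "TAA" + "G" * 30
    t1 = TranscriptModel(id="a", sequence=seq, cds=Interval(30, 126), abundance=1.0)
    t2 = TranscriptModel(id="b", sequence=seq, cds=Interval(30, 126), abundance=3.0)
    depth = 100_000
    reads = simulate_rnaseq([t1, t2], depth=depth, read_length=40, seed=5)
    n_b = sum(1 for r in reads if r.origin.transcript_id == "b")
    p = 0.75
    se = np.sqrt(p * (1 - p) / depth)
    assert abs(n_b / depth - p) <= 3 * se
    assert len(simulate_rnaseq([t1], depth=0, read_length=40, seed=1)) == 0
    with pytest.raises(ValueError, match="\\bb\\b|exceeds"):
        simulate_rnaseq([t1, t2], depth=10, read_length=1000, seed=1)
    r1 = simulate_rnaseq([t1, t2], depth=200, read_length=40, seed=6)
    r2 = simulate_rnaseq([t1, t2], depth=200, read_length=40, seed=6)
    assert [(r.id, r.sequence) for r in r1] == [(r.id, r.sequence) for r in r2]


class TestTrnaSimulator:
    def test_extra5_fraction_recovered(self):
        ref = synthetic_trna_reference(seed=0)
        ab = {name: 1.0 for name in ref.records}
        depth = 50_000
        reads = simulate_trna_reads(ref, ab, EndModel(p_extra5=0.3), depth=depth, seed=7)
        n_extra = sum(1 for r in reads if len(r.sequence) == len(ref.records[r.origin.transcript_id]) + 1)
        se = np.sqrt(0.3 * 0.7 / depth)
        assert abs(n_extra / depth - 0.3) <= 3 * se

    def test_no_end_variation_reads_equal_reference(self):
        ref = synthetic_trna_reference(seed=0)
        reads = simulate_trna_reads(ref, {n: 1.0 for n in ref.records}, EndModel(0, 0), depth=500, seed=8)
        for r in reads:
            assert r.sequence == ref.records[r.origin.transcript_id]

    def test_zero_abundance_isodecoder_never_sampled(self):
        ref = synthetic_trna_reference(seed=0)
        ab = {n: (0.0 if "iMet" in n else 1.0) for n in ref.records}
        reads = simulate_trna_reads(ref, ab, depth=2000, seed=9)
        assert not any("iMet" in r.origin.transcript_id for r in reads)


class TestScanningSimulator:
    def test_certain_reacquisition_all_uorf2(self):
        c = simulate_scanning_cohort(ScanningParams(q=1.0, d1=50, d2=100), 1000, seed=1)
        assert (c.uorf2, c.cds, c.none) == (1000, 0, 0)

    def test_no_reacquisition_all_none(self):
        c = simulate_scanning_cohort(ScanningParams(q=0.0, d1=50, d2=100), 1000, seed=1)
        assert (c.uorf2, c.cds, c.none) == (0, 0, 1000)

    def test_matches_closed_form_within_3_se(self):
        from ribodwell.uorf import reinit_probabilities

        params = ScanningParams(q=0.01, d1=100, d2=200)
        n = 100_000
        c = simulate_scanning_cohort(params, n, seed=2)
        p = reinit_probabilities(params).as_array()
        obs = c.as_array() / n
        se = np.sqrt(p * (1 - p) / n)
        assert (np.abs(obs - p) <= 3 * se).all()
        assert c.total == n
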