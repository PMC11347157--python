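"""tRNA reference construction, multimap quantification, comparisons, end profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ribodwell.models import Alignment
from ribodwell.simulate import EndModel, dirichlet_abundances, simulate_trna_reads, synthetic_trna_reference
from ribodwell.trna import (
    IsodecoderAbundanceTable,
    build_mature_reference,
    compare_abundance,
    em_allocate,
    end_profiles,
    group_by_hit_set,
    map_trna_reads,
    multimap_log_likelihood,
    quantify_isodecoders,
    similar_isodecoders,
)


class TestBuildMatureReference:
    def test_cca_preserved_or_appended(self):
        ref = build_mature_reference({"a": "ACGT" * 17 + "CCA", "b": "TGCA" * 17})
        assert ref.records["a"] == "ACGT" * 17 + "CCA"
        assert ref.records["b"] == "TGCA" * 17 + "CCA"
        assert len(ref.records["b"]) == 68 + 3

    def test_intron_spliced(self):
        seq = "AAACCCGGGTTT"
        ref = build_mature_reference({"a": seq}, intron_annotations={"a": (3, 6)})
        assert ref.records["a"] == "AAAGGGTTTCCA"

    def test_identical_mature_sequences_collapsed_with_copy_count(self):
        ref = build_mature_reference({"g1": "ACGTACGTACGTACGT", "g2": "ACGTACGTACGTACGT"})
        assert list(ref.records) == ["g1"]
        assert ref.copies["g1"] == 2

    def test_his_g_minus_one(self):
        ref = build_mature_reference({"tRNA-His-GTG-1": "ACGTACGTACGTACGT"})
        assert ref.records["tRNA-His-GTG-1"].startswith("G")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_mature_reference({})


def test_soft_clipped_extra_5prime_nucleotide_mapped():
    ref = synthetic_trna_reference(seed=0)
    reads = simulate_trna_reads(ref, {n: 1.0 for n in ref.records}, EndModel(p_extra5=1.0), depth=200, seed=1)
    alns = map_trna_reads(reads, ref)
    assert len({a.read_id for a in alns}) == 200
    assert all(a.soft5 == 1 for a in alns)


class TestQuantify:
    def aln(self, rid, ref, mult=1):
        return Alignment(rid, ref, 0, 76, multiplicity=mult)

    def test_unique_reads_equal_raw_counts(self):
        ref = synthetic_trna_reference(seed=0)
        names = list(ref.records)[:3]
        alns = [self.aln(f"r{i}", names[i % 3]) for i in range(9)]
        tab = quantify_isodecoders({"s": alns}, ref)
        for n in names:
            assert tab.counts.loc[n, "s"] == 3.0

    def test_shared_read_split_half_conserving_total(self):
        ref = synthetic_trna_reference(seed=0)
        a, b = list(ref.records)[:2]
        alns = [self.aln("r0", a, 2), self.aln("r0", b, 2), self.aln("r1", a)]
        tab = quantify_isodecoders({"s": alns}, ref)
        assert tab.counts.loc[a, "s"] == 1.5 and tab.counts.loc[b, "s"] == 0.5
        assert tab.counts["s"].sum() == pytest.approx(2.0, abs=1e-9)

    def test_em_matches_fixed_point_oracle(self):
        ref = synthetic_trna_reference(seed=0)
        a, b = list(ref.records)[:2]
        alns = []
        for i in range(90):
            alns.append(self.aln(f"ua{i}", a))
        for i in range(10):
            alns.append(self.aln(f"ub{i}", b))
        for i in range(100):
            alns.extend([self.aln(f"sh{i}", a, 2), self.aln(f"sh{i}", b, 2)])
        tab = quantify_isodecoders({"s": alns}, ref, mode="em")
        # independent fixed-point oracle on the two-isodecoder system:
        # ca' = 90 + 100 * ca / (ca + cb) with ca + cb = 200
        ca = 90.0 + 100.0 * 0.5
        for _ in range(10_000):
            new = 90.0 + 100.0 * ca / 200.0
            if abs(new - ca) < 1e-12:
                break
            ca = new
        assert tab.counts.loc[a, "s"] == pytest.approx(ca, abs=1e-6)
        assert tab.counts["s"].sum() == pytest.approx(200.0, abs=1e-6)

    def test_em_log_likelihood_never_decreases(self):
        rng = np.random.default_rng(5)
        isos = [f"i{k}" for k in range(6)]
        for _ in range(20):
            groups = {}
            for _ in range(8):
                size = int(rng.integers(1, 4))
                hits = tuple(sorted(rng.choice(isos, size=size, replace=False)))
                groups[hits] = groups.get(hits, 0) + int(rng.integers(1, 50))
            _, trajectory = em_allocate(groups, isos)
            assert all(b >= a - 1e-9 for a, b in zip(trajectory, trajectory[1:]))

    def test_zero_mapped_reads_rejected(self):
        ref = synthetic_trna_reference(seed=0)
        with pytest.raises(ValueError):
            quantify_isodecoders({"s": []}, ref)


def test_abundance_recovery_unique_mappable():
    ref = synthetic_trna_reference(seed=0)
    truth = dirichlet_abundances(ref, alpha=5.0, seed=3)
    reads = simulate_trna_reads(ref, truth, depth=200_000, seed=4)
    alns = map_trna_reads(reads, ref)
    tab = quantify_isodecoders({"s": alns}, ref)
    rel = tab.relative_abundance["s"]
    err = max(abs(rel[n] - truth[n]) for n in truth)
    assert err < 0.01


class TestCompareAbundance:
    def table(self, wt, null):
        counts = pd.DataFrame({**{f"w{i}": c for i, c in enumerate(wt)}, **{f"n{i}": c for i, c in enumerate(null)}})
        genotype = {**{f"w{i}": "WT" for i in range(len(wt))}, **{f"n{i}": "null" for i in range(len(null))}}
        return IsodecoderAbundanceTable(counts=counts, genotype=genotype)

    def test_identical_groups_unit_ratio(self):
        c = pd.Series({"a": 100.0, "b": 300.0})
        tab = self.table([c, c], [c, c])
        out = compare_abundance(tab)
        assert (out["ratio"] == 1.0).all()
        assert out["degenerate"].all()

    def test_sidak_closed_form(self):
        # p_adj = 1 - (1 - p)^m
        assert 1 - (1 - 0.001) ** 40 == pytest.approx(0.0392, abs=5e-4)
        rng = np.random.default_rng(0)
        idx = [f"tRNA-Xaa-NNN-{k}" for k in range(40)]
        wt = [pd.Series(rng.poisson(1000.0, 40).astype(float), index=idx) for _ in range(3)]
        null = [pd.Series(rng.poisson(1000.0, 40).astype(float), index=idx) for _ in range(3)]
        out = compare_abundance(self.table(wt, null))
        expected = 1 - (1 - out["p"]) ** len(out)
        assert np.allclose(out["p_adj"], np.minimum(1.0, expected))

    def test_depleted_isodecoders_rank_first(self):
        ref = synthetic_trna_reference(seed=0)
        base = dirichlet_abundances(ref, alpha=5.0, seed=6)
        targets = [n for n in base if "iMet" in n or "Gln-CTG" in n]
        samples, genotype = {}, {}
        for g in ("WT", "null"):
            ab = dict(base)
            if g == "null":
                for t in targets:
                    ab[t] *= 0.5
            for r in range(3):
                reads = simulate_trna_reads(ref, ab, depth=30_000, seed=700 + r + (50 if g == "null" else 0))
                s = f"{g}{r}"
                samples[s] = map_trna_reads(reads, ref)
                genotype[s] = g
        tab = quantify_isodecoders(samples, ref, genotype=genotype)
        out = compare_abundance(tab)
        assert set(out.nsmallest(2, "p_adj").index) == set(targets)
        for t in targets:
            assert 0.4 <= out.loc[t, "ratio"] <= 0.6


class TestEndProfiles:
    def test_extra5_mass_recovered(self):
        ref = synthetic_trna_reference(seed=0)
        depth = 20_000
        reads = simulate_trna_reads(ref, {n: 1.0 for n in ref.records}, EndModel(p_extra5=0.3), depth=depth, seed=8)
        profiles = end_profiles(map_trna_reads(reads, ref), ref)
        total_minus1 = sum(
            p.five_prime.get(-1, 0.0) * n
            for p, n in ((profiles[i], sum(1 for r in reads if r.origin.transcript_id == i)) for i in profiles)
        )
        se = np.sqrt(0.3 * 0.7 / depth)
        assert abs(total_minus1 / depth - 0.3) <= 3 * se

    def test_clean_reads_all_mass_at_origin(self):
        ref = synthetic_trna_reference(seed=0)
        reads = simulate_trna_reads(ref, {n: 1.0 for n in ref.records}, EndModel(0, 0), depth=2000, seed=9)
        profiles = end_profiles(map_trna_reads(reads, ref), ref)
        for p in profiles.values():
            assert p.five_prime[0] == 1.0 and p.three_prime[0] == 1.0
            assert p.five_prime[-1] == 0.0  # category always reported

    def test_trunc3_category(self):
        ref = synthetic_trna_reference(seed=0)
        reads = simulate_trna_reads(ref, {n: 1.0 for n in ref.records}, EndModel(0, 1.0), depth=500, seed=10)
        profiles = end_profiles(map_trna_reads(reads, ref), ref)
        for p in profiles.values():
            assert p.three_prime[-1] == 1.0


def test_similarity_warning_for_near_identical_isodecoders():
    ref = synthetic_trna_reference(seed=0)
    pairs = similar_isodecoders(ref)
    assert ("tRNA-Gln-CTG-1", "tRNA-Gln-TTG-1", 1) in pairs
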