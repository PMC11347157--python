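"""uORF region quantification and the delayed-reinitiation model."""

from __future__ import annotations

import numpy as np
import pytest

from ribodwell.models import Interval, ScanningParams
from ribodwell.occupancy import ASiteCountMatrix
from ribodwell.simulate import InitiationCounts, simulate_scanning_cohort
from ribodwell.uorf import (
    cds_release,
    fit_reacquisition,
    quantify_regions,
    reinit_probabilities,
    scanning_log_likelihood,
)

REGIONS = {
    "uORF1": Interval(100, 109),
    "uORF2": Interval(196, 376),
    "CDS": Interval(296, 596),
}


def matrix_with(positions: dict[int, float], tid: str = "atf4") -> ASiteCountMatrix:
    m = ASiteCountMatrix(sample_id="s")
    m.positions = {(tid, pos): n for pos, n in positions.items()}
    return m


class TestQuantifyRegions:
    def test_uniform_coverage_equal_densities(self):
        positions = {}
        for iv in REGIONS.values():
            for p in range(iv.start, iv.end):
                positions[p] = positions.get(p, 0) + 1.0
        # overlap positions got 2.0; assign per the uORF2-priority rule by
        # using density of non-overlapping placement instead: one count per nt
        positions = {p: 1.0 for p in positions}
        rq = quantify_regions(matrix_with(positions), "atf4", REGIONS, library_size=1e6)
        # uORF2 swallows the overlap: its density is 1 count/nt like uORF1;
        # CDS keeps count only outside the overlap
        assert rq.density["uORF1"] == pytest.approx(rq.density["uORF2"], abs=1e-9)
        assert rq.counts["CDS"] == len(REGIONS["CDS"]) - (376 - 296)

    def test_all_footprints_in_uorf1(self):
        rq = quantify_regions(matrix_with({100: 5.0, 105: 3.0}), "atf4", REGIONS, 1e6)
        assert rq.counts["CDS"] == 0 and rq.counts["uORF1"] == 8.0

    def test_overlap_counts_toward_uorf2_only(self):
        rq = quantify_regions(matrix_with({300: 1.0}), "atf4", REGIONS, 1e6)
        assert rq.counts["uORF2"] == 1.0 and rq.counts["CDS"] == 0.0
        rq_both = quantify_regions(matrix_with({300: 1.0}), "atf4", REGIONS, 1e6, overlap="both")
        assert rq_both.counts["uORF2"] == 1.0 and rq_both.counts["CDS"] == 1.0

    def test_region_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            quantify_regions(matrix_with({300: 1.0}), "atf4", REGIONS, 1e6, transcript_length=400)


class TestCdsRelease:
    def quant(self, uorf1: float, cds: float):
        from ribodwell.uorf import RegionQuant

        return RegionQuant(
            transcript_id="atf4",
            counts={"uORF1": uorf1, "uORF2": 0.0, "CDS": cds},
            lengths={r: len(iv) for r, iv in REGIONS.items()},
            density={"uORF1": uorf1, "uORF2": 0.0, "CDS": cds},
        )

    def test_identical_groups_release_one(self):
        q = [self.quant(10.0, 2.0)] * 3
        res = cds_release(q, q)
        assert res.release == pytest.approx(1.0)

    def test_zero_uorf1_density_flagged(self):
        res = cds_release([self.quant(0.0, 2.0)], [self.quant(10.0, 2.0)])
        assert res.undefined

    def test_release_detected_when_q_drops(self):
        """End-to-end: footprint densities generated by the scanning model."""
        d1, d2 = 87, 100
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)

            def quants(q, n_reps, lam=2000.0):
                probs = reinit_probabilities(ScanningParams(q=q, d1=d1, d2=d2))
                out = []
                for _ in range(n_reps):
                    # loading on uORF1 is obligatory; downstream regions scale
                    # with the reinitiation outcome probabilities
                    u1 = rng.poisson(lam)
                    u2 = rng.poisson(lam * probs.p_uorf2)
                    cds = rng.poisson(lam * probs.p_cds)
                    out.append(self.quant(float(u1), float(cds)))
                return out

            res = cds_release(quants(0.02, 3), quants(0.005, 3))
            if res.release > 1:
                detected += 1
        assert detected >= 18


class TestUorfFootprintSimulator:
    def test_region_densities_follow_reinit_probabilities(self):
        from ribodwell.occupancy import ASiteCountMatrix
        from ribodwell.simulate import UorfSpec, generate_transcriptome, simulate_uorf_footprints
        from ribodwell.simulate.footprints import DEFAULT_OFFSETS

        spec = UorfSpec(uorf1_len=9, d1=87, d2=100, uorf2_len=180)
        t = generate_transcriptome(1, uorf_spec=spec, seed=13)[0]
        params = ScanningParams(q=0.02, d1=87, d2=100)
        reads = simulate_uorf_footprints(t, params, n_ribosomes=40_000, seed=14)
        m = ASiteCountMatrix(sample_id="s")
        for r in reads:
            a = r.origin.position + DEFAULT_OFFSETS[r.origin.length]
            m.positions[(t.id, a)] = m.positions.get((t.id, a), 0.0) + 1.0
        regions = {"uORF1": t.uorfs[0], "uORF2": t.uorfs[1], "CDS": t.cds}
        rq = quantify_regions(m, t.id, regions, library_size=len(reads))
        probs = reinit_probabilities(params)
        # uORF2 swallows the CDS overlap, so compare per-codon rates of the
        # unambiguous regions: uORF1 vs the CDS portion outside the overlap
        cds_outside = len(t.cds) - (t.uorfs[1].end - t.cds.start)
        rate_u1 = rq.counts["uORF1"] / (len(t.uorfs[0]) / 3)
        rate_cds = rq.counts["CDS"] / (cds_outside / 3)
        assert rate_cds / rate_u1 == pytest.approx(probs.p_cds, rel=0.15)

    def test_deterministic_and_requires_two_uorfs(self):
        from ribodwell.simulate import generate_transcriptome, simulate_uorf_footprints

        t = generate_transcriptome(1, seed=15)[0]
        with pytest.raises(ValueError, match="two uORFs"):
            simulate_uorf_footprints(t, ScanningParams(0.02, 87, 100), 100, seed=1)


class TestReinitProbabilities:
    def test_certain_and_zero_reacquisition(self):
        p1 = reinit_probabilities(ScanningParams(1.0, 10, 20))
        assert (p1.p_uorf2, p1.p_cds, p1.p_none) == (1.0, 0.0, 0.0)
        p0 = reinit_probabilities(ScanningParams(0.0, 10, 20))
        assert (p0.p_uorf2, p0.p_cds, p0.p_none) == (0.0, 0.0, 1.0)

    def test_closed_form_reference_values(self):
        p = reinit_probabilities(ScanningParams(0.01, 100, 200))
        assert p.p_uorf2 == pytest.approx(0.6340, abs=1e-4)
        assert p.p_cds == pytest.approx(0.3170, abs=1e-4)
        assert p.p_none == pytest.approx(0.0490, abs=1e-4)

    def test_sum_to_one_on_grid(self):
        for q in np.linspace(0, 1, 101):
            p = reinit_probabilities(ScanningParams(float(q), 87, 100))
            assert abs(p.p_uorf2 + p.p_cds + p.p_none - 1.0) <= 1e-12

    def test_cds_probability_unimodal_in_q(self):
        grid = np.linspace(0, 1, 101)
        pcds = np.array([reinit_probabilities(ScanningParams(float(q), 87, 100)).p_cds for q in grid])
        assert pcds[0] == 0 and pcds[-1] == 0
        peak = pcds.argmax()
        assert 0 < peak < 100
        assert (np.diff(pcds[: peak + 1]) >= 0).all()
        assert (np.diff(pcds[peak:]) <= 0).all()


class TestFitReacquisition:
    def test_recovery_at_true_q(self):
        ok = 0
        for seed in range(10):
            counts = simulate_scanning_cohort(ScanningParams(0.01, 100, 200), 100_000, seed=seed)
            fit = fit_reacquisition(counts, 100, 200)
            if 0.009 <= fit.q_hat <= 0.011:
                ok += 1
        assert ok >= 9

    def test_boundaries(self):
        hi = fit_reacquisition(InitiationCounts(500, 0, 0), 100, 200)
        assert hi.q_hat == 1.0 and hi.boundary
        lo = fit_reacquisition(InitiationCounts(0, 0, 500), 100, 200)
        assert lo.q_hat == 0.0 and lo.boundary

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(17)
        grid = np.arange(1e-5, 1.0, 1e-5)
        for _ in range(10):
            q_true = float(rng.uniform(0.002, 0.05))
            counts = simulate_scanning_cohort(
                ScanningParams(q_true, 100, 200), 20_000, seed=int(rng.integers(1 << 30))
            )
            fit = fit_reacquisition(counts, 100, 200)
            ll = scanning_log_likelihood(grid, counts, 100, 200)
            q_grid = grid[np.argmax(ll)]
            assert abs(fit.q_hat - q_grid) <= 2e-5

    def test_ci_contains_estimate_and_covers_truth(self):
        covered = 0
        for seed in range(40):
            counts = simulate_scanning_cohort(ScanningParams(0.01, 100, 200), 10_000, seed=seed)
            fit = fit_reacquisition(counts, 100, 200)
            assert fit.ci_low <= fit.q_hat <= fit.ci_high
            if fit.ci_low <= 0.01 <= fit.ci_high:
                covered += 1
        assert covered >= 0.90 * 40 - 2

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_reacquisition(InitiationCounts(0, 0, 0), 100, 200)
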