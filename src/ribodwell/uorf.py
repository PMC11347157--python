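"""uORF region quantification and the delayed-reinitiation scanning model.

The two-uORF leader (uORF1, spacer d1, uORF2 overlapping the main CDS out
of frame) suppresses main-CDS translation: after terminating on uORF1 the
40S subunit resumes scanning and must reacquire the ternary complex
before it can initiate again. With per-nucleotide reacquisition
probability q the outcome probabilities are closed-form geometric tails:

    p_uORF2 = 1 - (1-q)^d1
    p_CDS   = (1-q)^d1 * (1 - (1-q)^d2)
    p_none  = (1-q)^(d1+d2)

Lower ternary-complex availability (smaller q — e.g. a depleted initiator
tRNA) shifts mass from uORF2 to the main CDS: translational release. The
module quantifies footprints per region, forms the WT-vs-null release
statistic, and fits q by maximum likelihood from outcome counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .models import Interval, ScanningParams
from .occupancy import ASiteCountMatrix
from .simulate.scanning import InitiationCounts

REGIONS = ("uORF1", "uORF2", "CDS")


@dataclass(frozen=True)
class ReinitProbabilities:
    p_uorf2: float
    p_cds: float
    p_none: float

    def __post_init__(self) -> None:
        for p in (self.p_uorf2, self.p_cds, self.p_none):
            if not -1e-12 <= p <= 1 + 1e-12:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.p_uorf2 + self.p_cds + self.p_none - 1.0) > 1e-12:
            raise ValueError("outcome probabilities must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_uorf2, self.p_cds, self.p_none])


def reinit_probabilities(params: ScanningParams) -> ReinitProbabilities:
    """Closed-form outcome distribution of a post-uORF1 scanning ribosome."""
    s1 = (1.0 - params.q) ** params.d1
    s2 = (1.0 - params.q) ** params.d2
    return ReinitProbabilities(p_uorf2=1.0 - s1, p_cds=s1 * (1.0 - s2), p_none=s1 * s2)


@dataclass
class RegionQuant:
    """Footprint counts and densities for the uORF1/uORF2/CDS regions."""

    transcript_id: str
    counts: dict[str, float]
    lengths: dict[str, int]
    density: dict[str, float]  # count per kb per million library reads


def quantify_regions(
    asite: ASiteCountMatrix,
    transcript_id: str,
    regions: dict[str, Interval],
    library_size: float,
    transcript_length: int | None = None,
    overlap: str = "uorf2",
) -> RegionQuant:
    """Count A-site positions per leader region of one transcript.

    A position in the uORF2/CDS overlap counts toward uORF2 only (a
    ribosome that initiated at uORF2 reads through the CDS start out of
    frame); set ``overlap="both"`` to credit both regions. Densities are
    count / region length (kb) / library size (millions).
    """
    if overlap not in ("uorf2", "both"):
        raise ValueError("overlap must be 'uorf2' or 'both'")
    missing = [r for r in REGIONS if r not in regions]
    if missing:
        raise ValueError(f"annotation lacks regions {missing} for {transcript_id}")
    if transcript_length is not None:
        for name, iv in regions.items():
            if iv.end > transcript_length:
                raise ValueError(f"{transcript_id}: region {name} [{iv.start}, {iv.end}) outside transcript bounds")
    counts = dict.fromkeys(REGIONS, 0.0)
    for (tid, pos), n in asite.positions.items():
        if tid != transcript_id:
            continue
        in_uorf2 = regions["uORF2"].contains(pos)
        if regions["uORF1"].contains(pos):
            counts["uORF1"] += n
        elif in_uorf2:
            counts["uORF2"] += n
            if overlap == "both" and regions["CDS"].contains(pos):
                counts["CDS"] += n
        elif regions["CDS"].contains(pos):
            counts["CDS"] += n
    lengths = {r: len(regions[r]) for r in REGIONS}
    density = {
        r: counts[r] / (lengths[r] / 1000.0) / (library_size / 1e6) if library_size > 0 else float("nan")
        for r in REGIONS
    }
    return RegionQuant(transcript_id=transcript_id, counts=counts, lengths=lengths, density=density)


@dataclass
class ReleaseResult:
    """Main-CDS translational release of the null genotype relative to WT."""

    release: float
    p: float | None
    undefined: bool
    wt_ratios: list[float]
    null_ratios: list[float]


def cds_release(wt: list[RegionQuant], null: list[RegionQuant]) -> ReleaseResult:
    """release = (CDS density / uORF1 density)_null / (CDS density / uORF1 density)_WT.

    Per-replicate CDS/uORF1 density ratios are averaged within genotype;
    a Welch p across replicate ratios is attached when both groups have
    >= 2 replicates. Zero uORF1 density makes the statistic undefined.
    """
    if not wt or not null:
        raise ValueError("need >= 1 replicate per genotype")

    def ratios(quants: list[RegionQuant]) -> tuple[list[float], bool]:
        out, bad = [], False
        for rq in quants:
            if rq.density["uORF1"] == 0:
                bad = True
            else:
                out.append(rq.density["CDS"] / rq.density["uORF1"])
        return out, bad

    wt_r, wt_bad = ratios(wt)
    null_r, null_bad = ratios(null)
    if wt_bad or null_bad or not wt_r or not null_r:
        return ReleaseResult(release=float("nan"), p=None, undefined=True, wt_ratios=wt_r, null_ratios=null_r)
    release = float(np.mean(null_r) / np.mean(wt_r)) if np.mean(wt_r) > 0 else float("nan")
    p = None
    if len(wt_r) >= 2 and len(null_r) >= 2:
        if wt_r.count(wt_r[0]) == len(wt_r) and null_r.count(null_r[0]) == len(null_r):
            p = 1.0  # constant replicates in both groups
        else:
            p = float(stats.ttest_ind(null_r, wt_r, equal_var=False).pvalue)
    return ReleaseResult(release=release, p=p, undefined=not np.isfinite(release), wt_ratios=wt_r, null_ratios=null_r)


@dataclass
class FitResult:
    q_hat: float
    log_likelihood: float
    ci_low: float
    ci_high: float
    boundary: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_hat <= 1.0:
            raise ValueError("q_hat outside [0, 1]")
        if not self.ci_low - 1e-12 <= self.q_hat <= self.ci_high + 1e-12:
            raise ValueError("confidence interval does not contain q_hat")


def scanning_log_likelihood(q: np.ndarray | float, counts: InitiationCounts, d1: int, d2: int) -> np.ndarray | float:
    """Multinomial log-likelihood of outcome counts at reacquisition prob q."""
    q = np.asarray(q, dtype=float)
    s1 = (1.0 - q) ** d1
    s2 = (1.0 - q) ** d2
    return (
        special.xlogy(counts.uorf2, 1.0 - s1)
        + special.xlogy(counts.cds, s1 * (1.0 - s2))
        + special.xlogy(counts.none, s1 * s2)
    )


def fit_reacquisition(counts: InitiationCounts, d1: int, d2: int) -> FitResult:
    """Maximum-likelihood q from scanning outcome counts.

    1-D bounded optimization of the multinomial likelihood; the 95% CI is
    the chi-square(1) profile-likelihood interval. All-uORF2 counts drive
    q to the upper boundary, all-none counts to the lower boundary.
    """
    if counts.total < 1:
        raise ValueError("need at least one counted ribosome")
    ScanningParams(q=0.5, d1=d1, d2=d2)  # validate spacer lengths
    if counts.cds == 0 and counts.none == 0:
        q_hat, boundary = 1.0, True
    elif counts.uorf2 == 0 and counts.cds == 0:
        q_hat, boundary = 0.0, True
    else:
        res = optimize.minimize_scalar(
            lambda q: -scanning_log_likelihood(q, counts, d1, d2),
            bounds=(1e-12, 1.0 - 1e-12),
            method="bounded",
            options={"xatol": 1e-10},
        )
        q_hat, boundary = float(res.x), False
    ll_max = float(scanning_log_likelihood(q_hat, counts, d1, d2))
    threshold = ll_max - stats.chi2.ppf(0.95, df=1) / 2.0

    def deficit(q: float) -> float:
        return float(scanning_log_likelihood(q, counts, d1, d2)) - threshold

    lo, hi = 0.0, 1.0
    if q_hat > 0 and deficit(max(1e-15, lo)) < 0:
        lo = float(optimize.brentq(deficit, 1e-15, q_hat, xtol=1e-12))
    if q_hat < 1 and deficit(min(1.0 - 1e-15, hi)) < 0:
        hi = float(optimize.brentq(deficit, q_hat, 1.0 - 1e-15, xtol=1e-12))
    return FitResult(q_hat=q_hat, log_likelihood=ll_max, ci_low=lo, ci_high=hi, boundary=boundary)
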