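"""Translational efficiency (TE): counting, normalization, testing, labels.

TE is footprint abundance normalized to mRNA abundance. The genotype
contrast is a Welch-style four-group comparison on log2 size-factor
normalized counts:

    log2FC_TE = (mean fp_null - mean fp_WT) - (mean rna_null - mean rna_WT)

with the standard error summing the four variance-of-mean terms and a
Welch-Satterthwaite degrees-of-freedom. Footprint and RNA replicates are
unpaired (they may differ in number), which this contrast handles without
forming per-sample ratios. By default the gene-wise group variances are
moderated toward an empirical-Bayes prior shared across genes (the same
information borrowing that makes dispersion-sharing count models usable
at 3-5 replicates); ``moderate_var=False`` gives the plain gene-wise
Welch contrast. Classification uses raw p < 0.05 and |log2FC_TE| > 0.5
(strict); BH q-values are emitted alongside for the record but do not
enter the labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import Alignment, Interval
from .occupancy import OffsetTable


@dataclass
class CountMatrix:
    """Genes x samples integer counts for one assay plus the genotype design."""

    assay: str  # "footprint" | "rna"
    counts: pd.DataFrame
    genotype: dict[str, str]  # sample -> "WT" | "null"

    def __post_init__(self) -> None:
        if self.assay not in ("footprint", "rna"):
            raise ValueError("assay must be 'footprint' or 'rna'")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def samples(self, genotype: str) -> list[str]:
        return [s for s in self.counts.columns if self.genotype[s] == genotype]


def count_cds(
    alignments_by_sample: dict[str, list[Alignment]],
    annotation: dict[str, dict[str, Interval]],
    assay: str = "footprint",
    offsets: OffsetTable | None = None,
    genotype: dict[str, str] | None = None,
) -> CountMatrix:
    """Per-gene read counting.

    A footprint counts toward a gene iff its A-site nucleotide
    (5' position + offset(length)) lies inside the CDS; an RNA-seq read
    counts iff its 5' end lies in the transcript. Multimapped reads are
    split 1/k across their hits and the matrix is rounded to integers at
    the end.
    """
    if assay == "footprint" and offsets is None:
        raise ValueError("footprint counting requires an OffsetTable")
    genes = sorted(annotation)
    cols = {}
    for sample, alns in alignments_by_sample.items():
        counts = dict.fromkeys(genes, 0.0)
        for a in alns:
            feats = annotation.get(a.reference_id)
            if feats is None:
                continue
            if assay == "footprint":
                if a.length not in offsets:
                    continue
                a_site = a.position + offsets[a.length]
                if "CDS" not in feats or not feats["CDS"].contains(a_site):
                    continue
            counts[a.reference_id] += 1.0 / a.multiplicity
        cols[sample] = pd.Series(counts)
    matrix = pd.DataFrame(cols).round().astype(int)
    genotype = genotype or {s: "WT" for s in matrix.columns}
    return CountMatrix(assay=assay, counts=matrix, genotype=genotype)


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Genes with a zero in any sample are excluded from the geometric-mean
    reference; if no gene survives, falls back to total-count scaling
    (normalized to geometric mean 1) with a warning.
    """
    m = counts.counts if isinstance(counts, CountMatrix) else counts
    x = m.to_numpy(dtype=float)
    all_nonzero = (x > 0).all(axis=1)
    if not all_nonzero.any():
        warnings.warn("no gene with nonzero counts in all samples; using total-count scaling")
        totals = x.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(factors, index=m.columns)
    lx = np.log(x[all_nonzero])
    log_gm = lx.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(lx - log_gm, axis=0))
    return pd.Series(factors, index=m.columns)


def _group_stats(log_counts: pd.DataFrame, samples: list[str]) -> tuple[np.ndarray, np.ndarray, int]:
    sub = log_counts[samples].to_numpy()
    n = sub.shape[1]
    return sub.mean(axis=1), sub.var(axis=1, ddof=1), n


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    from scipy.special import polygamma

    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of gene-wise variances toward a common prior.

    Fits a scaled inverse-chi-square prior (prior df d0, prior value s0^2)
    to the observed variances by matching the moments of log(s^2), then
    returns the posterior variances (d0*s0^2 + df*s^2) / (d0 + df) and d0.
    Genes with zero observed variance receive the prior-only component.
    """
    from scipy.special import digamma, polygamma

    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0
    z = np.log(s2[ok])
    e = z - float(digamma(df / 2.0)) + np.log(df / 2.0)
    ev = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if ev <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e.mean()))
        return np.full_like(s2, s0_2), d0
    d0 = 2.0 * _trigamma_inverse(ev)
    s0_2 = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return (d0 * s0_2 + df * s2) / (d0 + df), d0


def te_table(
    fp: CountMatrix,
    rna: CountMatrix,
    pseudocount: float = 0.5,
    moderate_var: bool = True,
) -> pd.DataFrame:
    """Per-gene TE change table (gene universe = intersection of assays)."""
    for cm, need in ((fp, "footprint"), (rna, "rna")):
        if cm.assay != need:
            raise ValueError(f"expected a {need} CountMatrix")
        for g in ("WT", "null"):
            if len(cm.samples(g)) < 2:
                raise ValueError(f"{need} assay needs >= 2 {g} replicates")
    genes = fp.counts.index.intersection(rna.counts.index)
    fp_counts = fp.counts.loc[genes]
    rna_counts = rna.counts.loc[genes]
    fp_log = np.log2(fp_counts / size_factors(fp_counts) + pseudocount)
    rna_log = np.log2(rna_counts / size_factors(rna_counts) + pseudocount)
    means, variances, ns = {}, {}, {}
    for key, logc, cm in (
        ("fp_wt", fp_log, fp), ("fp_null", fp_log, fp),
        ("rna_wt", rna_log, rna), ("rna_null", rna_log, rna),
    ):
        geno = "null" if key.endswith("null") else "WT"
        means[key], variances[key], ns[key] = _group_stats(logc, cm.samples(geno))
    dfs = {k: float(ns[k] - 1) for k in variances}
    if moderate_var:
        for k in variances:
            variances[k], d0 = moderate_variances(variances[k], ns[k] - 1)
            dfs[k] = min(dfs[k] + d0, 1e6)
    lfc = (means["fp_null"] - means["fp_wt"]) - (means["rna_null"] - means["rna_wt"])
    vom = {k: variances[k] / ns[k] for k in variances}  # variance of the mean
    se2 = sum(vom.values())
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
        df = se2**2 / sum(vom[k] ** 2 / dfs[k] for k in vom)
    # All-zero in any group: no usable evidence for that gene.
    zero_flag = np.zeros(len(genes), dtype=bool)
    for cm, counts in ((fp, fp_counts), (rna, rna_counts)):
        for g in ("WT", "null"):
            zero_flag |= (counts[cm.samples(g)].to_numpy() == 0).all(axis=1)
    p = np.where(np.isfinite(t) & np.isfinite(df), 2 * stats.t.sf(np.abs(t), df), 1.0)
    p = np.where(zero_flag, 1.0, p)
    t = np.where(np.isfinite(t), t, 0.0)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc_te": lfc,
            "se": se,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "all_zero_group": zero_flag,
        },
        index=genes,
    )


def classify_te(results: pd.DataFrame, p_threshold: float = 0.05, lfc_threshold: float = 0.5) -> pd.DataFrame:
    """Attach up/down/unchanged labels at the volcano thresholds (strict >)."""
    out = results.copy()
    up = (out["p"] < p_threshold) & (out["log2fc_te"] > lfc_threshold)
    down = (out["p"] < p_threshold) & (out["log2fc_te"] < -lfc_threshold)
    out["label"] = np.where(up, "up", np.where(down, "down", "unchanged"))
    return out


def gene_lists(classified: pd.DataFrame) -> dict[str, list[str]]:
    """Up/down gene id lists (inputs to codon statistics and GO tools)."""
    return {
        "up": list(classified.index[classified["label"] == "up"]),
        "down": list(classified.index[classified["label"] == "down"]),
    }
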