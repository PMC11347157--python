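"""Per-gene codon composition and group comparisons.

Computes the percentage of a target codon (CAG by default downstream)
among the CDS codons of each gene, and compares gene groups — e.g. the
TE-down vs TE-up sets — with a Mann-Whitney U test that is exact
(full enumeration) at small sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .codons import CODON_TO_AA, STOP_CODONS, codons_of

EXACT_MAX_N = 8


def codon_fraction(
    cds_sequences: dict[str, str],
    codon: str,
    include_stop: bool = False,
    of_amino_acid: bool = False,
) -> pd.Series:
    """Percentage of ``codon`` among each gene's CDS codons.

    The final stop codon is excluded from the denominator unless
    ``include_stop``. With ``of_amino_acid`` the denominator is restricted
    to synonymous codons of the target codon's amino acid (e.g. CAG as a
    fraction of Gln codons).
    """
    codon = codon.upper()
    if codon not in CODON_TO_AA:
        raise ValueError(f"{codon} is not a sense codon")
    out = {}
    for gene, seq in cds_sequences.items():
        seq = seq.upper()
        if len(seq) % 3:
            raise ValueError(f"gene {gene}: CDS length {len(seq)} not divisible by 3")
        if seq[-3:] not in STOP_CODONS:
            raise ValueError(f"gene {gene}: CDS does not end in a stop codon")
        cs = codons_of(seq)
        if not include_stop:
            cs = cs[:-1]
        if of_amino_acid:
            aa = CODON_TO_AA[codon]
            denom = sum(1 for c in cs if CODON_TO_AA.get(c) == aa)
        else:
            denom = len(cs)
        out[gene] = 100.0 * sum(1 for c in cs if c == codon) / denom if denom else 0.0
    return pd.Series(out, name=f"pct_{codon}")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x against y with tie-aware half counting."""
    greater = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(greater + 0.5 * ties)


def mannwhitney_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of group assignments.

    Enumerates all C(n1+n2, n1) splits of the pooled values and reports
    the fraction with |U - n1*n2/2| at least as extreme as observed.
    Correct under ties (the permutation null conditions on the pooled
    values).
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    extreme = 0
    idx = np.arange(n1 + n2)
    for chosen in combinations(idx, n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(chosen)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return u_obs, extreme / comb(n1 + n2, n1)


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u: float
    p: float
    method: str


def compare_groups(
    table: pd.Series,
    group_a: list[str],
    group_b: list[str],
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Mann-Whitney comparison of codon fractions between two gene groups.

    Exact enumeration when min(n1, n2) <= 8, otherwise the normal
    approximation with tie correction and continuity correction.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    missing = sorted((set(group_a) | set(group_b)) - set(table.index))
    if missing:
        raise ValueError(f"genes missing from the codon-fraction table: {missing}")
    x = table.loc[group_a].to_numpy(dtype=float)
    y = table.loc[group_b].to_numpy(dtype=float)
    if min(len(x), len(y)) <= EXACT_MAX_N:
        u, p = mannwhitney_exact(x, y)
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"
    return GroupComparison(
        group_a=labels[0],
        group_b=labels[1],
        n_a=len(x),
        n_b=len(y),
        median_a=float(np.median(x)),
        median_b=float(np.median(y)),
        u=u,
        p=min(1.0, p),
        method=method,
    )
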