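"""Mature tRNA reference construction, isodecoder quantification and end profiles.

Isodecoders (tRNA genes sharing an anticodon but differing in body
sequence) are quantified from tRNA-seq alignments with an explicit
multimapping policy: uniform 1/k splitting by default, or an EM that
re-allocates shared reads in proportion to current abundance estimates.
Genotype comparisons use per-isodecoder Welch t-tests with a Sidak
family-wise adjustment, plus an optional two-way ANOVA omnibus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .mapping import ReferenceIndex, build_index, map_reads
from .models import Alignment, Read, ReadSet


@dataclass
class TRNAReference:
    """Mature tRNA sequences (introns removed, CCA 3' end) by isodecoder id.

    ``family`` maps each isodecoder to its isoacceptor family
    (amino acid + anticodon); ``copies`` counts collapsed identical gene
    copies behind each record.
    """

    records: dict[str, str]
    family: dict[str, str] = field(default_factory=dict)
    copies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty tRNA reference")
        for name, seq in self.records.items():
            if not seq.endswith("CCA"):
                raise ValueError(f"{name}: mature tRNA must end in CCA")
        for name in self.records:
            self.family.setdefault(name, _family_of(name))
            self.copies.setdefault(name, 1)

    def __len__(self) -> int:
        return len(self.records)


def _family_of(isodecoder_id: str) -> str:
    parts = isodecoder_id.replace("tRNA-", "").split("-")
    return "-".join(parts[:2]) if len(parts) >= 2 else isodecoder_id


def build_mature_reference(
    raw_sequences: dict[str, str],
    intron_annotations: dict[str, tuple[int, int]] | None = None,
) -> TRNAReference:
    """Build mature isodecoder records from genomic tRNA sequences.

    Annotated introns are spliced out, a 3' CCA is appended when absent and
    a G-1 is prepended to His tRNAs lacking it (both are added
    post-transcriptionally and present on mature molecules). Genes with
    identical mature sequences are collapsed into one record whose
    ``copies`` entry counts the members.
    """
    if not raw_sequences:
        raise ValueError("empty tRNA input")
    intron_annotations = intron_annotations or {}
    mature: dict[str, str] = {}
    for name, seq in raw_sequences.items():
        seq = seq.upper().replace("U", "T")
        if set(seq) - set("ACGT"):
            raise ValueError(f"{name}: non-ACGT characters")
        if name in intron_annotations:
            s, e = intron_annotations[name]
            seq = seq[:s] + seq[e:]
        if not seq.endswith("CCA"):
            seq = seq + "CCA"
        if _family_of(name).startswith("His") and not seq.startswith("G"):
            seq = "G" + seq
        mature[name] = seq
    records: dict[str, str] = {}
    copies: dict[str, int] = {}
    seen: dict[str, str] = {}  # sequence -> first id
    for name, seq in mature.items():
        if seq in seen:
            copies[seen[seq]] += 1
        else:
            seen[seq] = name
            records[name] = seq
            copies[name] = 1
    return TRNAReference(records=records, copies=copies)


def build_trna_index(reference: TRNAReference, k: int = 12) -> ReferenceIndex:
    return build_index(reference.records, k=k)


def map_trna_reads(
    reads: ReadSet | list[Read],
    reference: TRNAReference,
    max_mismatches: int = 0,
    k: int = 12,
    index: ReferenceIndex | None = None,
) -> list[Alignment]:
    """Map tRNA-seq reads, allowing one non-templated 5' nucleotide.

    A read that fails to map full-length is retried with its first
    nucleotide soft-clipped (the extra 5' nt added by the terminal
    transferase activity of the reverse transcriptase); such alignments
    carry ``soft5 = 1``.
    """
    index = index or build_trna_index(reference, k=k)
    result = map_reads(reads, index, max_mismatches=max_mismatches)
    alignments = list(result.alignments)
    unmapped_ids = set(result.unmapped)
    retry = [
        Read(id=r.id, sequence=r.sequence[1:], origin=r.origin)
        for r in reads
        if r.id in unmapped_ids and len(r.sequence) > index.k
    ]
    if retry:
        second = map_reads(retry, index, max_mismatches=max_mismatches)
        for a in second.alignments:
            alignments.append(
                Alignment(
                    read_id=a.read_id,
                    reference_id=a.reference_id,
                    position=a.position,
                    length=a.length,
                    mismatches=a.mismatches,
                    multiplicity=a.multiplicity,
                    soft5=1,
                )
            )
    return alignments


@dataclass
class IsodecoderAbundanceTable:
    """Fractional multimap-resolved counts and relative abundances per sample."""

    counts: pd.DataFrame  # isodecoder x sample, fractional counts
    genotype: dict[str, str]  # sample -> "WT" | "null"

    @property
    def relative_abundance(self) -> pd.DataFrame:
        return self.counts / self.counts.sum(axis=0)

    def samples(self, genotype: str) -> list[str]:
        return [s for s, g in self.genotype.items() if g == genotype]


def group_by_hit_set(alignments: list[Alignment]) -> dict[tuple[str, ...], int]:
    """Aggregate reads by their (sorted) set of hit isodecoders."""
    by_read: dict[str, set[str]] = {}
    for a in alignments:
        by_read.setdefault(a.read_id, set()).add(a.reference_id)
    groups: dict[tuple[str, ...], int] = {}
    for hits in by_read.values():
        key = tuple(sorted(hits))
        groups[key] = groups.get(key, 0) + 1
    return groups


def multimap_log_likelihood(groups: dict[tuple[str, ...], int], theta: dict[str, float] | pd.Series) -> float:
    """Multimap mixture log-likelihood: sum over reads of log(sum of theta over hits)."""
    ll = 0.0
    for hits, n in groups.items():
        s = float(sum(theta[h] for h in hits))
        ll += n * (np.log(s) if s > 0 else -np.inf)
    return ll


def em_allocate(
    groups: dict[tuple[str, ...], int],
    isodecoders: list[str],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[pd.Series, list[float]]:
    """EM reallocation of multimapped reads; returns (counts, log-lik trajectory).

    E-step: each read is split across its hits in proportion to current
    abundance estimates; M-step: abundances are the normalized fractional
    counts. Iterated until the largest count change falls below ``tol``.
    """
    total = sum(groups.values())
    theta = pd.Series(1.0 / len(isodecoders), index=isodecoders)
    prev = None
    trajectory: list[float] = []
    counts = pd.Series(0.0, index=isodecoders)
    for _ in range(max_iter):
        counts = pd.Series(0.0, index=isodecoders)
        for hits, n in groups.items():
            th = theta[list(hits)]
            s = th.sum()
            if s == 0:
                counts[list(hits)] += n / len(hits)
            else:
                counts[list(hits)] += n * th / s
        theta = counts / total
        trajectory.append(multimap_log_likelihood(groups, theta))
        if prev is not None and (counts - prev).abs().max() < tol:
            break
        prev = counts
    return counts, trajectory


def _quantify_one(alignments: list[Alignment], isodecoders: list[str], mode: str) -> pd.Series:
    if not alignments:
        raise ValueError("zero mapped tRNA reads")
    groups = group_by_hit_set(alignments)
    if mode == "uniform":
        counts = pd.Series(0.0, index=isodecoders)
        for hits, n in groups.items():
            share = n / len(hits)
            for ref in hits:
                counts[ref] += share
        return counts
    if mode != "em":
        raise ValueError("mode must be 'uniform' or 'em'")
    counts, _ = em_allocate(groups, isodecoders)
    return counts


def quantify_isodecoders(
    alignments_by_sample: dict[str, list[Alignment]],
    reference: TRNAReference,
    genotype: dict[str, str] | None = None,
    mode: str = "uniform",
) -> IsodecoderAbundanceTable:
    """Fractional per-isodecoder counts per sample.

    uniform: a read with k equally-best hits contributes 1/k to each.
    em: iterative reallocation proportional to current abundance estimates,
    run to a 1e-8 fixed point (max 100 iterations). Both modes conserve the
    mapped-read total exactly.
    """
    isodecoders = list(reference.records)
    cols = {}
    for sample, alns in alignments_by_sample.items():
        cols[sample] = _quantify_one(alns, isodecoders, mode)
    counts = pd.DataFrame(cols)
    genotype = genotype or {s: "WT" for s in counts.columns}
    return IsodecoderAbundanceTable(counts=counts, genotype=genotype)


def similar_isodecoders(reference: TRNAReference, max_edit_distance: int = 1) -> list[tuple[str, str, int]]:
    """Isodecoder pairs within ``max_edit_distance`` edits (cross-hybridization risk)."""
    names = list(reference.records)
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = edlib.align(reference.records[a], reference.records[b], k=max_edit_distance)["editDistance"]
            if 0 <= d <= max_edit_distance:
                out.append((a, b, d))
    return out


def compare_abundance(table: IsodecoderAbundanceTable, adjust: str = "sidak") -> pd.DataFrame:
    """Per-isodecoder WT-vs-null comparison of relative abundances.

    Welch t on per-sample relative abundances, Sidak family-wise
    adjustment p_adj = 1 - (1 - p)^m over the m isodecoders tested.
    """
    if adjust != "sidak":
        raise ValueError("only the Sidak adjustment is implemented")
    rel = table.relative_abundance
    wt_s, null_s = table.samples("WT"), table.samples("null")
    if len(wt_s) < 2 or len(null_s) < 2:
        raise ValueError("compare_abundance needs >= 2 replicates per genotype")
    m = len(rel.index)
    rows = []
    for iso in rel.index:
        x = rel.loc[iso, wt_s].to_numpy(dtype=float)
        y = rel.loc[iso, null_s].to_numpy(dtype=float)
        degenerate = bool((x == x[0]).all() and (y == y[0]).all())
        if degenerate:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(y, x, equal_var=False)
        rows.append(
            {
                "isodecoder": iso,
                "family": table_family(table, iso),
                "mean_wt": x.mean(),
                "mean_null": y.mean(),
                "ratio": y.mean() / x.mean() if x.mean() > 0 else np.nan,
                "p": float(p),
                "p_adj": float(min(1.0, 1.0 - (1.0 - p) ** m)),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("isodecoder")


def table_family(table: IsodecoderAbundanceTable, isodecoder: str) -> str:
    return _family_of(isodecoder)


def abundance_anova(table: IsodecoderAbundanceTable) -> pd.DataFrame:
    """Two-way ANOVA omnibus (genotype x isodecoder) on relative abundances."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rel = table.relative_abundance
    long = rel.reset_index(names="isodecoder").melt(id_vars="isodecoder", var_name="sample", value_name="rel")
    long["genotype"] = long["sample"].map(table.genotype)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ols("rel ~ C(genotype) * C(isodecoder)", data=long).fit()
        return sm.stats.anova_lm(model, typ=2)


@dataclass
class EndProfile:
    """Distributions of read end positions relative to the mature termini.

    5' categories: -1 one extra (non-templated) nucleotide, 0 mature start,
    +k a k-nt 5' truncation. 3' categories: 0 full CCA, -1 missing the
    terminal A, and so on. Each distribution sums to 1 over observed
    categories; the -1 extra-nucleotide row is always reported.
    """

    isodecoder: str
    five_prime: dict[int, float]
    three_prime: dict[int, float]


def end_profiles(alignments: list[Alignment], reference: TRNAReference) -> dict[str, EndProfile]:
    """Tally 5'/3' read-end categories per isodecoder from ungapped alignments."""
    five: dict[str, dict[int, float]] = {}
    three: dict[str, dict[int, float]] = {}
    for a in alignments:
        ref_len = len(reference.records[a.reference_id])
        cat5 = -1 if a.soft5 > 0 else a.position
        cat3 = (a.position + a.length) - ref_len
        w = 1.0 / a.multiplicity
        five.setdefault(a.reference_id, {})[cat5] = five.setdefault(a.reference_id, {}).get(cat5, 0.0) + w
        three.setdefault(a.reference_id, {})[cat3] = three.setdefault(a.reference_id, {}).get(cat3, 0.0) + w
    out: dict[str, EndProfile] = {}
    for iso in five:
        f, t3 = five[iso], three[iso]
        f.setdefault(-1, 0.0)  # always report the extra-nucleotide category
        fs, ts = sum(f.values()), sum(t3.values())
        out[iso] = EndProfile(
            isodecoder=iso,
            five_prime={k: v / fs for k, v in sorted(f.items())},
            three_prime={k: v / ts for k, v in sorted(t3.items())},
        )
    return out
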