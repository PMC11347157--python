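"""Synthetic tRNA reference and tRNA-seq read simulation.

The synthetic reference (labelled synthetic: sequences are random-bodied,
not real gene sequences) carries an isodecoder roster shaped like a
mammalian cytoplasmic set — including the initiator tRNA (iMet-CAT) and
both Gln isodecoders, with Gln-TTG one substitution away from Gln-CTG to
mirror the cross-hybridization caveat of real anticodon neighbours. Reads
are full-length mature molecules subject to a simple end-variation model:
one non-templated 5' nucleotide with probability p_extra5 (reverse
transcriptase terminal transferase activity) and loss of the terminal A of
the CCA with probability p_trunc3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..models import Read, ReadOrigin, ReadSet
from ..trna import TRNAReference

_NT = np.array(list("ACGT"))

# amino acid / anticodon roster (40 isodecoders including iMet and both Gln)
_ROSTER = [
    "iMet-CAT", "Met-CAT", "Gln-CTG", "Gln-TTG", "Glu-CTC", "Glu-TTC",
    "Gly-GCC", "Gly-CCC", "Ala-AGC", "Ala-CGC", "Val-AAC", "Val-CAC",
    "Leu-CAG", "Leu-AAG", "Leu-TAA", "Ile-AAT", "Ile-TAT", "Pro-AGG",
    "Pro-TGG", "Thr-AGT", "Thr-TGT", "Ser-AGA", "Ser-GCT", "Arg-ACG",
    "Arg-TCT", "Lys-CTT", "Lys-TTT", "Asn-GTT", "Asp-GTC", "Phe-GAA",
    "Tyr-GTA", "Cys-GCA", "Trp-CCA", "His-GTG", "Sec-TCA", "Gly-TCC",
    "Val-TAC", "Ser-TGA", "Arg-CCT", "Thr-CGT",
]


@dataclass(frozen=True)
class EndModel:
    """Non-templated end-variation probabilities."""

    p_extra5: float = 0.0
    p_trunc3: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_extra5", "p_trunc3"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def synthetic_trna_reference(body_length: int = 73, seed: int = 0) -> TRNAReference:
    """Generate the 40-isodecoder synthetic reference, deterministic under seed.

    Bodies are random (hence mutually distant and uniquely mappable),
    except Gln-TTG which is constructed one substitution away from Gln-CTG.
    """
    rng = np.random.default_rng(seed)
    records: dict[str, str] = {}
    for name in _ROSTER:
        iso = f"tRNA-{name}-1"
        if name == "Gln-TTG":
            base = records["tRNA-Gln-CTG-1"][:-3]
            pos = 34  # anticodon wobble position
            old = base[pos]
            new = str(rng.choice([n for n in "ACGT" if n != old]))
            records[iso] = base[:pos] + new + base[pos + 1 :] + "CCA"
        else:
            body = "".join(_NT[rng.integers(0, 4, size=body_length)])
            records[iso] = body + "CCA"
    return TRNAReference(records=records)


def dirichlet_abundances(reference: TRNAReference, alpha: float = 5.0, seed: int = 0) -> dict[str, float]:
    """Dirichlet-drawn relative abundances over the reference isodecoders."""
    rng = np.random.default_rng(seed)
    names = list(reference.records)
    w = rng.dirichlet(np.full(len(names), alpha))
    return dict(zip(names, w))


def simulate_trna_reads(
    reference: TRNAReference,
    abundances: dict[str, float],
    end_model: EndModel | None = None,
    depth: int = 100_000,
    seed: int = 0,
) -> ReadSet:
    """Draw ``depth`` full-length mature tRNA reads with end variation.

    The recorded origin refers to the pre-edit mature sequence (position 0,
    full length); end edits are applied afterwards.
    """
    end_model = end_model or EndModel()
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return ReadSet(reads=[], format="fastq")
    names = list(reference.records)
    w = np.array([float(abundances.get(n, 0.0)) for n in names])
    if (w < 0).any():
        raise ValueError("abundances must be non-negative")
    if w.sum() <= 0:
        raise ValueError("all abundances are zero")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(names), size=depth, p=w / w.sum())
    extra5 = rng.random(depth) < end_model.p_extra5
    trunc3 = rng.random(depth) < end_model.p_trunc3
    extra_nt = _NT[rng.integers(0, 4, size=depth)]
    reads: list[Read] = []
    for i in range(depth):
        name = names[picks[i]]
        seq = reference.records[name]
        origin = ReadOrigin(name, 0, len(seq))
        if trunc3[i]:
            seq = seq[:-1]
        if extra5[i]:
            seq = extra_nt[i] + seq
        reads.append(Read(id=f"trna{i}", sequence=seq, origin=origin))
    return ReadSet(reads=reads, format="fastq")
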