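#!/usr/bin/env python
"""Generate the synthetic study data for the whole analysis.

Emulates the brain ribosome-profiling / RNA-seq / tRNA-seq design of a
TRMT10A-null vs wild-type comparison with ground truth planted at every
stage:

* a 200-gene transcriptome plus one two-uORF (Atf4-like) transcript;
* 3 footprint replicates per genotype; the null genotype carries a 1.3x
  CAG dwell weight (the slow-Gln-decoding signature of a depleted
  tRNA-Gln(CUG) pool);
* Atf4-like footprints from the delayed-reinitiation model, with the
  ternary-complex reacquisition probability q dropping from 0.02 (WT) to
  0.005 (null) to mimic initiator-tRNA depletion;
* 4 tRNA-seq replicates per genotype with iMet and Gln-CUG halved in the
  null, plus a 30% extra-5'-nucleotide rate from reverse transcription.

Reads and references are written under scratch/data (FASTA/FASTQ); a
manifest JSON records paths and the planted truth for downstream scripts.
"""

from __future__ import annotations

import json
from pathlib import Path

from ribodwell import io
from ribodwell.models import DwellModel, ScanningParams
from ribodwell.simulate import (
    EndModel,
    UorfSpec,
    dirichlet_abundances,
    generate_transcriptome,
    simulate_footprints,
    simulate_rnaseq,
    simulate_trna_reads,
    simulate_uorf_footprints,
    synthetic_trna_reference,
    write_transcriptome,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
SEED = 20_240_601
FOOTPRINT_DEPTH = 300_000
RNA_DEPTH = 200_000
TRNA_DEPTH = 200_000
CAG_WEIGHT_NULL = 1.3
Q_WT, Q_NULL = 0.02, 0.005
ATF4_SPEC = UorfSpec(uorf1_len=9, d1=87, d2=100, uorf2_len=180)


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    transcripts = generate_transcriptome(200, uorf_spec=ATF4_SPEC, seed=SEED)
    atf4 = transcripts[0]
    fasta, annot = write_transcriptome(transcripts, DATA)
    manifest: dict = {
        "fasta": str(fasta),
        "annotation": str(annot),
        "atf4_id": atf4.id,
        "truth": {
            "cag_weight_null": CAG_WEIGHT_NULL,
            "q_wt": Q_WT,
            "q_null": Q_NULL,
            "d1": ATF4_SPEC.d1,
            "d2": ATF4_SPEC.d2,
        },
        "footprints": {},
        "rnaseq": {},
        "trnaseq": {},
    }

    dwell = {"WT": DwellModel(), "null": DwellModel({"CAG": CAG_WEIGHT_NULL})}
    q = {"WT": Q_WT, "null": Q_NULL}
    for g_i, genotype in enumerate(("WT", "null")):
        for rep in range(3):
            seed = SEED + 100 * g_i + rep
            reads = simulate_footprints(transcripts, dwell[genotype], depth=FOOTPRINT_DEPTH, seed=seed)
            uorf_reads = simulate_uorf_footprints(
                atf4, ScanningParams(q[genotype], ATF4_SPEC.d1, ATF4_SPEC.d2), n_ribosomes=20_000, seed=seed + 50
            )
            path = DATA / f"footprints_{genotype}{rep + 1}.fastq"
            io.write_fastq(list(reads) + list(uorf_reads), path)
            manifest["footprints"][f"{genotype}{rep + 1}"] = {"path": str(path), "genotype": genotype}
            rna = simulate_rnaseq(transcripts, depth=RNA_DEPTH, read_length=50, seed=seed + 70)
            rpath = DATA / f"rnaseq_{genotype}{rep + 1}.fastq"
            io.write_fastq(rna, rpath)
            manifest["rnaseq"][f"{genotype}{rep + 1}"] = {"path": str(rpath), "genotype": genotype}

    reference = synthetic_trna_reference(seed=0)
    io.write_fasta(reference.records, DATA / "trna_reference.fa")
    manifest["trna_reference"] = str(DATA / "trna_reference.fa")
    base = dirichlet_abundances(reference, alpha=5.0, seed=SEED + 900)
    targets = [n for n in base if "iMet" in n or "Gln-CTG" in n]
    manifest["trna_targets"] = targets
    for g_i, genotype in enumerate(("WT", "null")):
        ab = dict(base)
        if genotype == "null":
            for t in targets:
                ab[t] *= 0.5
        for rep in range(4):
            reads = simulate_trna_reads(
                reference, ab, EndModel(p_extra5=0.3, p_trunc3=0.05),
                depth=TRNA_DEPTH, seed=SEED + 1000 + 10 * g_i + rep,
            )
            path = DATA / f"trnaseq_{genotype}{rep + 1}.fastq"
            io.write_fastq(reads, path)
            manifest["trnaseq"][f"{genotype}{rep + 1}"] = {"path": str(path), "genotype": genotype}

    (DATA / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    n_fq = len(manifest["footprints"]) + len(manifest["rnaseq"]) + len(manifest["trnaseq"])
    print(f"wrote {n_fq} FASTQ libraries plus reference files under {DATA}")
    print(f"planted truth: CAG dwell x{CAG_WEIGHT_NULL} (null), q {Q_WT}->{Q_NULL}, iMet/Gln-CUG x0.5")


if __name__ == "__main__":
    main()
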