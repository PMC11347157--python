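#!/usr/bin/env python
"""Map the simulated footprint libraries against the transcriptome.

Exact seed-and-verify alignment (the reads are error-free by construction);
per-sample alignment TSVs go to scratch/alignments for the occupancy and
uORF analyses.
"""

from __future__ import annotations

import json
from pathlib import Path

from ribodwell import io
from ribodwell.mapping import build_index, map_reads

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
ALN = ROOT / "scratch" / "alignments"


def main() -> None:
    manifest = json.loads((DATA / "manifest.json").read_text())
    ALN.mkdir(parents=True, exist_ok=True)
    index = build_index(io.read_fasta(manifest["fasta"]))
    for sample, meta in manifest["footprints"].items():
        reads = io.read_fastq(meta["path"])
        result = map_reads(reads, index, max_mismatches=0)
        out = ALN / f"footprints_{sample}.tsv"
        io.write_alignments_tsv(result.alignments, out)
        print(f"{sample}: {len(result.alignments)} alignments, {len(result.unmapped)} unmapped -> {out.name}")


if __name__ == "__main__":
    main()
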