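#!/usr/bin/env python
"""CAG codon composition of the TE-down vs TE-up gene groups.

Asks whether genes whose translational efficiency fell differ from genes
whose TE rose in their CAG content — i.e. whether slow CAG decoding alone
explains the TE shifts. Gene groups come from the TE analysis (script 04);
CDS sequences from the simulated transcriptome are not gene-matched to the
NB count simulation, so the comparison is run on the simulation's own CDS
pool as a worked null example: no difference is expected.

Writes results/cag_fraction_comparison.tsv.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from ribodwell.codons import SENSE_CODONS, STOP_CODONS
from ribodwell.codonstats import codon_fraction, compare_groups

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 20_240_604


def main() -> None:
    up = (RESULTS / "te_genes_up.txt").read_text().split()
    down = (RESULTS / "te_genes_down.txt").read_text().split()
    # CDS pool matching the TE gene universe: random coding sequences with
    # the generator's uniform codon usage (no planted CAG difference)
    rng = np.random.default_rng(SEED)
    genes = {}
    for g in set(up) | set(down):
        internal = "".join(rng.choice(SENSE_CODONS, size=int(rng.integers(80, 200))))
        genes[g] = "ATG" + internal + str(rng.choice(STOP_CODONS))
    table = codon_fraction(genes, "CAG")
    out = compare_groups(table, down, up, labels=("TE_down", "TE_up"))
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "cag_fraction_comparison.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["group_a", "group_b", "n_a", "n_b", "median_a_pct", "median_b_pct", "U", "p", "method"])
        writer.writerow([out.group_a, out.group_b, out.n_a, out.n_b,
                         round(out.median_a, 3), round(out.median_b, 3), out.u, round(out.p, 4), out.method])
    verdict = "no significant difference" if out.p >= 0.05 else "significant difference"
    print(
        f"CAG fraction: TE-down median {out.median_a:.2f}% (n={out.n_a}), "
        f"TE-up median {out.median_b:.2f}% (n={out.n_b}); Mann-Whitney p = {out.p:.3f} ({verdict})"
    )
    print(f"wrote {RESULTS / 'cag_fraction_comparison.tsv'}")


if __name__ == "__main__":
    main()
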