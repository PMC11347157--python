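"""Negative-binomial replicate count simulation for TE calibration studies.

Counts are drawn NB with var = mu + dispersion * mu^2 (the standard
RNA-seq noise model). A per-gene true TE log2 fold change enters the
null-genotype footprint means only, leaving RNA abundance unchanged —
the pattern the TE contrast is built to detect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..te import CountMatrix

DEFAULT_DISPERSION = 0.05


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float, size: tuple[int, ...]) -> np.ndarray:
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_te_counts(
    n_genes: int = 2000,
    te_lfc: np.ndarray | float = 0.0,
    mean: np.ndarray | float = 500.0,
    dispersion: float = DEFAULT_DISPERSION,
    fp_replicates: tuple[int, int] = (3, 3),
    rna_replicates: tuple[int, int] = (5, 5),
    seed: int = 0,
) -> tuple[CountMatrix, CountMatrix]:
    """Simulate matched footprint and RNA count matrices.

    ``fp_replicates``/``rna_replicates`` are (n_WT, n_null); the defaults
    mirror a 3-footprint / 5-RNA replicate design per genotype. Returns
    (footprint CountMatrix, rna CountMatrix) with genes g0..g{n-1}.
    """
    rng = np.random.default_rng(seed)
    lfc = np.broadcast_to(np.asarray(te_lfc, dtype=float), (n_genes,))
    mu = np.broadcast_to(np.asarray(mean, dtype=float), (n_genes,))
    genes = [f"g{i}" for i in range(n_genes)]

    def matrix(assay: str, reps: tuple[int, int], null_mu: np.ndarray) -> CountMatrix:
        cols, genotype = {}, {}
        for j in range(reps[0]):
            name = f"{assay}_wt{j + 1}"
            cols[name] = _nb_draw(rng, mu, dispersion, (n_genes,))
            genotype[name] = "WT"
        for j in range(reps[1]):
            name = f"{assay}_null{j + 1}"
            cols[name] = _nb_draw(rng, null_mu, dispersion, (n_genes,))
            genotype[name] = "null"
        frame = pd.DataFrame(cols, index=genes)
        return CountMatrix(assay=assay, counts=frame, genotype=genotype)

    fp = matrix("footprint", fp_replicates, mu * 2.0**lfc)
    rna = matrix("rna", rna_replicates, mu)
    return fp, rna
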