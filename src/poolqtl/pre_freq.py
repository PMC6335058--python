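"""Pre-ATAC allele-frequency inference from fitted pooling weights.

The pre-ATAC (expected, no-cis-effect) minor-allele frequency of SNP i is
p_pre_i = sum_j w_hat_j G_ij.  Its sampling variance follows from the
multivariate-normal approximation to the free fitted weights: with
d_j = G_ij - g_ref,i (g_ref = the reference-group dosage at SNP i),

    v_i = d' Sigma d

over the free individuals, which is algebraically identical to the expanded
three-term sum over Sigma entries but numerically better behaved.  When all
pooled genotypes at a SNP coincide the differences vanish and v_i = 0
exactly: the frequency would be the same for any weights, so weight
uncertainty contributes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix
from .pool_weights import PoolWeights

logger = logging.getLogger(__name__)

__all__ = ["PreFreq", "infer_pre_freq", "variance_triple_sum"]


@dataclass
class PreFreq:
    """Per-SNP inferred pre-ATAC frequency and its variance."""

    table: pd.DataFrame  # index snp_id; columns pre_freq, variance, pre_freq_raw

    @property
    def pre_freq(self) -> pd.Series:
        return self.table["pre_freq"]

    @property
    def variance(self) -> pd.Series:
        return self.table["variance"]


def infer_pre_freq(weights: PoolWeights, genotypes: GenotypeMatrix) -> PreFreq:
    """Pre-ATAC frequency and variance for every SNP in the matrix.

    Estimates outside [0, 1] (possible when fitted weights stray outside the
    simplex) are clipped, with the raw value retained in ``pre_freq_raw``.
    """
    sample_to_row = {s: i for i, s in enumerate(genotypes.samples)}
    missing = [s for s in weights.samples if s not in sample_to_row]
    if missing:
        raise ValueError(f"weights refer to samples absent from genotypes: {missing}")
    if len(weights.samples) != genotypes.n_individuals:
        raise ValueError("weights and genotypes cover different individuals")

    order = [sample_to_row[s] for s in weights.samples]
    G = genotypes.dosages[order]  # aligned with weights.samples
    p_raw = weights.weights @ G

    if weights.covariance.size:
        free_rows = [weights.samples.index(s) for s in weights.free_samples]
        ref_rows = [weights.samples.index(s) for s in weights.reference_group]
        g_ref = G[ref_rows].mean(axis=0)
        D = G[free_rows] - g_ref[None, :]  # n_free x n_snps
        v = np.einsum("is,ij,js->s", D, weights.covariance, D)
        v = np.maximum(v, 0.0)
    else:
        v = np.zeros(genotypes.n_snps)

    clipped = (p_raw < 0) | (p_raw > 1)
    if clipped.any():
        logger.info("infer_pre_freq: clipped %d estimates to [0, 1]", clipped.sum())
    table = pd.DataFrame(
        {
            "pre_freq": np.clip(p_raw, 0.0, 1.0),
            "variance": v,
            "pre_freq_raw": p_raw,
        },
        index=genotypes.snp_ids,
    )
    return PreFreq(table)


def variance_triple_sum(g: np.ndarray, g_ref: float, cov: np.ndarray) -> float:
    """Expanded three-term form of the pre-ATAC variance for one SNP.

    Literal term-by-term evaluation
    sum_jk g_j g_k S_jk + sum_jk g_ref^2 S_jk - 2 sum_jk g_j g_ref S_jk,
    kept as an independent cross-check of the quadratic form used in
    :func:`infer_pre_freq`.
    """
    total = 0.0
    k = len(g)
    for j in range(k):
        for l in range(k):
            total += g[j] * g[l] * cov[j, l]
            total += g_ref * g_ref * cov[j, l]
            total -= 2.0 * g[j] * g_ref * cov[j, l]
    return total
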