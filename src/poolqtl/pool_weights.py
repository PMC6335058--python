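"""Estimate pooling weights by constrained (weighted) linear regression.

The post-ATAC minor-allele frequency of a non-caQTL SNP is an unbiased
estimate of the pool frequency p_i = sum_j w_j G_ij, so with most SNPs
assumed null the weights w_j can be recovered by regressing the observed
frequencies on the genotype dosages.  The sum-to-one constraint is imposed
by substituting w_n = 1 - sum_{j<n} w_j, giving the intercept-free
differenced regression of (p_hat_i - G_in) on (G_ij - G_in), j = 1..n-1.
The regression also yields the covariance of the free weights, which feeds
the variance of the inferred pre-ATAC frequencies downstream.

The reference (substituted) individual is the last after a canonical sort by
sample ID, so results do not depend on input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import data_io
from .data_io import GenotypeMatrix, PoolCounts, merge_replicates

logger = logging.getLogger(__name__)

__all__ = ["PoolWeights", "estimate_weights", "effective_weights_note"]


@dataclass
class PoolWeights:
    """Fitted per-individual pool proportions.

    ``weights`` is aligned with ``samples`` (canonically sorted by ID) and
    sums to exactly 1 by construction.  ``covariance`` is the regression
    covariance of the free weights (all individuals except the reference
    group); ``free_samples`` names them in order.  ``reference_group``
    contains the reference individual plus any individuals genotypically
    indistinguishable from it over the SNPs used (their share of the
    leftover weight was split equally).
    """

    samples: list[str]
    weights: np.ndarray
    covariance: np.ndarray
    free_samples: list[str]
    reference_group: list[str]
    out_of_range: bool = False
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.samples, name="weight")


def _regression_weights(total_counts: np.ndarray, mode: str) -> np.ndarray | None:
    """WLS weights (inverse residual variance scale) for each SNP."""
    n = total_counts.astype(float)
    if mode == "variance":
        # binomial sampling variance of p_hat is proportional to 1/n
        return n
    if mode == "literal":
        return 1.0 / np.sqrt(n)
    if mode == "none":
        return None
    raise ValueError(f"unknown weighting_mode {mode!r}")


def estimate_weights(
    genotypes: GenotypeMatrix,
    counts: PoolCounts,
    snp_filter: np.ndarray | None = None,
    weighting_mode: str = "variance",
) -> PoolWeights:
    """Fit pooling weights for one pool.

    Parameters
    ----------
    genotypes : dosage matrix restricted to the pool's individuals.
    counts : counts for a single pool (replicates merged by summation if
        still present).
    snp_filter : boolean mask over ``genotypes.snp_ids`` selecting SNPs to
        use (default: all SNPs with nonzero depth present in the counts).
    weighting_mode : "variance" (regression weights proportional to read
        depth n_i, i.e. residual variance proportional to 1/n_i, the
        default), "literal" (weights proportional to n_i^{-1/2}), or "none"
        (ordinary least squares).
    """
    if counts.df["pool_id"].nunique() > 1:
        raise ValueError("estimate_weights expects counts for a single pool")
    merged = merge_replicates(counts, "sum")
    aligned = data_io.align_counts(genotypes, merged)

    mask = aligned["n"].to_numpy() > 0
    if snp_filter is not None:
        mask &= np.asarray(snp_filter, dtype=bool)
    cols = np.where(mask)[0]

    order = np.argsort(np.array(genotypes.samples))
    samples = [genotypes.samples[i] for i in order]
    G = genotypes.dosages[order][:, cols]  # n_individuals x n_used_snps
    n_ind = len(samples)

    n_reads = aligned["n"].to_numpy()[cols].astype(float)
    p_hat = aligned["m"].to_numpy()[cols] / n_reads

    if n_ind == 1:
        return PoolWeights(samples, np.array([1.0]), np.zeros((0, 0)), [], samples)

    ref = n_ind - 1  # canonical reference: last after sort
    X = (G[:ref] - G[ref]).T  # n_snps x (n_ind - 1)
    y = p_hat - G[ref]

    # individuals indistinguishable from the reference over the used SNPs
    zero_cols = np.where(np.abs(X).max(axis=0) == 0)[0] if X.size else np.arange(ref)
    free = [j for j in range(ref) if j not in set(zero_cols)]
    ref_group = [samples[ref]] + [samples[j] for j in zero_cols]

    if not free:
        logger.warning(
            "estimate_weights: all individuals genotypically identical over "
            "used SNPs; returning uniform weights"
        )
        w = np.full(n_ind, 1.0 / n_ind)
        return PoolWeights(
            samples, w, np.zeros((0, 0)), [], samples, fit_diagnostics={"n_snps": len(y)}
        )

    Xf = X[:, free]
    if len(y) < len(free):
        raise ValueError(
            f"only {len(y)} usable SNPs for {len(free)} free weights"
        )
    if np.linalg.matrix_rank(Xf) < len(free):
        # identify pairwise-identical non-reference individuals for the message
        dup = []
        for a in range(len(free)):
            for b in range(a + 1, len(free)):
                if np.array_equal(Xf[:, a], Xf[:, b]):
                    dup.append((samples[free[a]], samples[free[b]]))
        raise ValueError(
            f"design is rank deficient; indistinguishable individuals: {dup}"
        )

    w_reg = _regression_weights(n_reads, weighting_mode)
    model = (
        sm.WLS(y, Xf, weights=w_reg) if w_reg is not None else sm.OLS(y, Xf)
    )
    res = model.fit()
    w_free = res.params
    cov = np.asarray(res.cov_params())

    w = np.zeros(n_ind)
    for j, wj in zip(free, w_free):
        w[j] = wj
    leftover = 1.0 - w_free.sum()
    share = leftover / len(ref_group)
    for s in ref_group:
        w[samples.index(s)] = share
    if len(ref_group) > 1:
        logger.info(
            "estimate_weights: %d individuals collapsed with the reference",
            len(ref_group) - 1,
        )

    out_of_range = bool(((w < 0) | (w > 1)).any())
    if out_of_range:
        logger.warning("estimate_weights: fitted weights outside [0, 1]")
    diagnostics = {
        "n_snps": int(len(y)),
        "residual_scale": float(np.sqrt(res.scale)),
        "weighting_mode": weighting_mode,
    }
    return PoolWeights(
        samples,
        w,
        cov,
        [samples[j] for j in free],
        ref_group,
        out_of_range,
        diagnostics,
    )


def effective_weights_note(
    weights: PoolWeights, flag_fold: float = 3.0
) -> dict:
    """Compare fitted weights against nominal equal pooling.

    Because the regression absorbs global trans-acting differences (a sample
    with more open chromatin contributes more reads everywhere), fitted
    weights are *effective* proportions; large deviations from 1/n flag
    samples that were over- or under-represented.
    """
    n = len(weights.samples)
    w = np.clip(weights.weights, 0.0, None)
    nominal = 1.0 / n
    dev = weights.weights / nominal
    flagged = [
        s
        for s, r in zip(weights.samples, dev)
        if r > flag_fold or r < 1.0 / flag_fold
    ]
    wp = w / w.sum() if w.sum() > 0 else np.full(n, nominal)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-np.sum(np.where(wp > 0, wp * np.log(wp), 0.0)))
    return {
        "n_individuals": n,
        "max_deviation_fold": float(np.max(np.abs(dev))) if n else 0.0,
        "entropy": entropy,
        "max_entropy": float(np.log(n)),
        "flagged": flagged,
        "n_flagged": len(flagged),
    }
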