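"""Combining caQTL evidence across populations.

Populations differ in linkage disequilibrium, so a causal variant should
associate consistently across them while tag SNPs drop out wherever their
LD with the causal site breaks down.  Evidence is combined per SNP with
Fisher's method, X^2 = -2 sum_i ln p_i on 2k degrees of freedom, with
untested populations contributing p = 1 (ln 1 = 0).  SNPs below a combined
threshold are called shared; sharing between population pairs is summarized
with the Storey pi1 statistic on the cross-population p-value distribution.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_combined",
    "combine_populations",
    "call_shared",
    "direction_concordance",
    "pi1_sharing",
    "pi1_matrix",
    "enrichment_by_n_populations",
]

PER_POP_ALPHA = 5e-4
SHARED_ALPHA = 5e-6


def fisher_combined(
    pvals: np.ndarray,
    tested: np.ndarray | None = None,
    k_mode: str = "all",
) -> tuple[float, int, float]:
    """Fisher's combined statistic for one SNP.

    Parameters
    ----------
    pvals : per-population p-values (entries for untested populations are
        ignored and treated as p = 1).
    tested : boolean mask of populations in which the SNP was testable
        (default: all).
    k_mode : "all" counts every population toward the degrees of freedom
        (df = 2k with the p = 1 substitution, the default), "tested" counts
        only testable populations.

    Returns (X2, df, combined_p).
    """
    pvals = np.asarray(pvals, dtype=float)
    if tested is None:
        tested = np.ones(len(pvals), dtype=bool)
    tested = np.asarray(tested, dtype=bool)
    if len(pvals) == 0:
        raise ValueError("need at least one population")
    use = pvals[tested]
    if (use <= 0).any():
        raise ValueError("p-values must be strictly positive")
    if (use > 1).any():
        raise ValueError("p-values must be <= 1")
    x2 = float(-2.0 * np.sum(np.log(use)))
    if k_mode == "all":
        df = 2 * len(pvals)
    elif k_mode == "tested":
        df = 2 * int(tested.sum())
    else:
        raise ValueError(f"unknown k_mode {k_mode!r}")
    if df == 0:
        return 0.0, 0, 1.0
    return x2, df, float(chi2.sf(x2, df))


def combine_populations(
    results: dict[str, pd.DataFrame],
    k_mode: str = "all",
    per_pop_alpha: float = PER_POP_ALPHA,
) -> pd.DataFrame:
    """Per-SNP multi-population table from per-pool scan results.

    ``results`` maps population name to the per-pool table from
    :func:`poolqtl.caqtl_test.test_pool`.  Returns one row per SNP seen in
    any population with per-population p-values/directions, the Fisher
    statistic and combined p, the number of populations significant at
    ``per_pop_alpha``, and a majority-direction concordance flag.
    """
    pops = list(results)
    all_ids = pd.Index([])
    for df in results.values():
        all_ids = all_ids.union(df.index)

    pv = pd.DataFrame(1.0, index=all_ids, columns=pops)
    tested = pd.DataFrame(False, index=all_ids, columns=pops)
    direction = pd.DataFrame(0, index=all_ids, columns=pops)
    for pop, df in results.items():
        ok = df["testable"] & df["pv"].notna()
        pv.loc[df.index[ok], pop] = df.loc[ok, "pv"].to_numpy()
        tested.loc[df.index[ok], pop] = True
        direction.loc[df.index[ok], pop] = df.loc[ok, "direction"].to_numpy()

    pv_arr = pv.to_numpy()
    tested_arr = tested.to_numpy()
    # vectorized Fisher across SNPs
    logs = np.where(tested_arr, np.log(np.maximum(pv_arr, 1e-300)), 0.0)
    x2 = -2.0 * logs.sum(axis=1)
    k = len(pops) if k_mode == "all" else tested_arr.sum(axis=1)
    df_arr = 2 * np.broadcast_to(k, x2.shape).astype(int)
    with np.errstate(invalid="ignore"):
        combined = np.where(df_arr > 0, chi2.sf(x2, np.maximum(df_arr, 1)), 1.0)

    sig = tested_arr & (pv_arr < per_pop_alpha)
    n_sig = sig.sum(axis=1)

    dir_arr = direction.to_numpy()
    has_pos = (sig & (dir_arr > 0)).any(axis=1)
    has_neg = (sig & (dir_arr < 0)).any(axis=1)
    concordant = ~(has_pos & has_neg)

    out = pd.DataFrame(
        {
            "x2": x2,
            "df": df_arr,
            "combined_p": combined,
            "n_significant": n_sig,
            "n_tested": tested_arr.sum(axis=1),
            "concordant": concordant,
        },
        index=all_ids,
    )
    for pop in pops:
        out[f"pv_{pop}"] = pv[pop].where(tested[pop], np.nan)
        out[f"dir_{pop}"] = direction[pop]
    # pooled (majority) direction across significant populations
    signed = np.where(sig, dir_arr, 0).sum(axis=1)
    out["pooled_direction"] = np.sign(signed).astype(int)
    return out


def call_shared(results: pd.DataFrame, threshold: float = SHARED_ALPHA) -> pd.DataFrame:
    """SNPs with combined p strictly below the shared-caQTL threshold."""
    mask = (results["combined_p"] < threshold) & (results["n_tested"] >= 1)
    return results[mask]


def direction_concordance(results: pd.DataFrame) -> tuple[pd.Series, float]:
    """Concordance flags and the summary fraction among multi-population hits.

    A SNP is concordant when every population significant at the
    per-population threshold agrees on the more accessible allele.  The
    summary fraction is computed over shared caQTLs significant in at least
    two populations.
    """
    eligible = results[(results["n_significant"] >= 2)]
    frac = float(eligible["concordant"].mean()) if len(eligible) else np.nan
    return results["concordant"], frac


def pi1_sharing(pvals: np.ndarray, lam: float = 0.5) -> float:
    """Storey pi1 = 1 - pi0 with pi0 estimated at a single lambda.

    ``pvals`` are the p-values, in a replication population, of SNPs that
    were significant in a discovery population; pi1 estimates the fraction
    with a genuine effect in the replication population.
    """
    pvals = np.asarray(pvals, dtype=float)
    pvals = pvals[~np.isnan(pvals)]
    if len(pvals) == 0:
        raise ValueError("no p-values supplied")
    if len(pvals) < 100:
        warnings.warn("pi1 estimated from fewer than 100 p-values", stacklevel=2)
    pi0 = np.mean(pvals > lam) / (1.0 - lam)
    return float(np.clip(1.0 - pi0, 0.0, 1.0))


def pi1_matrix(
    results: dict[str, pd.DataFrame],
    alpha: float = PER_POP_ALPHA,
    lam: float = 0.5,
) -> pd.DataFrame:
    """Pairwise sharing: pi1 of population A's caQTLs evaluated in B."""
    pops = list(results)
    mat = pd.DataFrame(np.nan, index=pops, columns=pops)
    for disc in pops:
        d = results[disc]
        hits = d.index[(d["testable"]) & (d["pv"] < alpha)]
        for rep in pops:
            if rep == disc:
                mat.loc[disc, rep] = 1.0
                continue
            r = results[rep]
            common = hits.intersection(r.index[r["testable"]])
            if len(common) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mat.loc[disc, rep] = pi1_sharing(r.loc[common, "pv"].to_numpy(), lam)
    return mat


def enrichment_by_n_populations(
    results: pd.DataFrame, validation_set: set
) -> pd.DataFrame:
    """Validation-set fold enrichment stratified by n_significant.

    fold(stratum) = overlap fraction within the stratum divided by the
    overlap fraction among all SNPs in ``results``.  Empty strata are
    reported with fold NaN (missing, not zero).
    """
    ids = results.index
    in_val = ids.isin(validation_set)
    base = in_val.mean() if len(ids) else np.nan
    rows = []
    for k in range(int(results["n_significant"].max()) + 1 if len(results) else 0):
        stratum = results["n_significant"] == k
        n_k = int(stratum.sum())
        if n_k == 0 or base == 0:
            rows.append((k, n_k, np.nan))
        else:
            rows.append((k, n_k, float(in_val[stratum].mean() / base)))
    return pd.DataFrame(rows, columns=["n_significant", "n_snps", "fold"]).set_index(
        "n_significant"
    )
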