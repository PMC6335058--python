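"""Allele-specific long-range interaction analysis.

Chromosomal-contact (Hi-C) reads phased to the two alleles of a caQTL give
per-allele long-range contact counts.  A two-sided binomial test against
0.5 classifies each SNP as open_more / closed_more / no_bias; the ratio of
the first two classes measures whether the more accessible allele tends to
make more contacts.  Variants with clearly no allelic contact bias (binomial
p above a null floor, with a minimum read support) form the restriction set
for the proximal/distal eQTL enrichment contrast: if long-range interaction
changes mediate distal regulation, distal-eQTL enrichment should vanish
within that set while proximal enrichment persists.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import binomtest, fisher_exact

logger = logging.getLogger(__name__)

__all__ = [
    "allelic_bias_test",
    "directional_ratio",
    "no_effect_set",
    "classify_eqtl_proximity",
    "eqtl_enrichment_contrast",
    "split_bqtls_by_ca",
    "majority_direction_consistent",
]

DISTANCE_CLASSES = (">20kb", ">100kb", "inter")


def allelic_bias_test(contacts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-SNP allelic contact bias classification.

    ``contacts`` needs columns open_reads and closed_reads (indexed by
    snp_id).  SNPs with zero total reads are excluded (logged).  Adds
    columns total, binom_p and bias_class in
    {open_more, closed_more, no_bias}.
    """
    df = contacts.copy()
    total = df["open_reads"] + df["closed_reads"]
    zero = total == 0
    if zero.any():
        logger.info("allelic_bias_test: excluded %d SNPs with no reads", zero.sum())
        df = df[~zero]
        total = total[~zero]
    pvals = np.array(
        [
            binomtest(int(o), int(t), 0.5, alternative="two-sided").pvalue
            for o, t in zip(df["open_reads"], total)
        ]
    )
    cls = np.where(
        (pvals < alpha) & (df["open_reads"] > df["closed_reads"]),
        "open_more",
        np.where(
            (pvals < alpha) & (df["closed_reads"] > df["open_reads"]),
            "closed_more",
            "no_bias",
        ),
    )
    out = df.copy()
    out["total"] = total
    out["binom_p"] = pvals
    out["bias_class"] = cls
    return out


def directional_ratio(classified: pd.DataFrame) -> tuple[float, float, int, int]:
    """Open/closed class ratio with a two-sided binomial sign-test p.

    Returns (ratio, p, n_open_more, n_closed_more); ratio is inf when no SNP
    is closed_more but some are open_more.
    """
    n_open = int((classified["bias_class"] == "open_more").sum())
    n_closed = int((classified["bias_class"] == "closed_more").sum())
    if n_open + n_closed == 0:
        return np.nan, np.nan, 0, 0
    ratio = n_open / n_closed if n_closed else np.inf
    p = float(binomtest(n_open, n_open + n_closed, 0.5, alternative="two-sided").pvalue)
    return ratio, p, n_open, n_closed


def no_effect_set(
    classified: pd.DataFrame, min_reads: int = 100, p_floor: float = 0.5
) -> set:
    """SNPs with confidently no allelic contact bias.

    Requires binomial p strictly above ``p_floor`` and at least ``min_reads``
    long-range reads, so the absence of bias is well supported.
    """
    ok = (classified["binom_p"] > p_floor) & (classified["total"] >= min_reads)
    return set(classified.index[ok])


def classify_eqtl_proximity(
    eqtls: pd.DataFrame, proximal_bp: int = 10_000, distal_bp: int = 100_000
) -> pd.DataFrame:
    """Label eQTLs proximal (<10 kb to target TSS), distal (>100 kb), other."""
    dist = eqtls["tss_distance"].abs()
    cls = np.where(dist < proximal_bp, "proximal", np.where(dist > distal_bp, "distal", "other"))
    out = eqtls.copy()
    out["proximity_class"] = cls
    return out


def eqtl_enrichment_contrast(
    caqtls: set,
    non_caqtls: set,
    eqtls: pd.DataFrame,
    restriction_set: set | None = None,
) -> pd.DataFrame:
    """Proximal/distal eQTL enrichment of caQTLs over non-caQTLs.

    For each proximity class a 2x2 Fisher's exact test compares eQTL
    membership between caQTLs and non-caQTLs, optionally after intersecting
    both groups with ``restriction_set`` (e.g. the no-interaction-effect
    set).  Returns per class: counts, fold (ratio of eQTL fractions) and p.
    """
    if "proximity_class" not in eqtls.columns:
        eqtls = classify_eqtl_proximity(eqtls)
    ca = set(caqtls)
    non = set(non_caqtls)
    if restriction_set is not None:
        ca &= set(restriction_set)
        non &= set(restriction_set)
    rows = []
    for cls in ("proximal", "distal"):
        members = set(eqtls.index[eqtls["proximity_class"] == cls])
        a = len(ca & members)
        b = len(ca) - a
        c = len(non & members)
        d = len(non) - c
        if len(ca) == 0 or len(non) == 0:
            rows.append((cls, a, len(ca), c, len(non), np.nan, np.nan))
            continue
        f_ca = a / len(ca)
        f_non = c / len(non)
        fold = f_ca / f_non if f_non > 0 else np.inf if f_ca > 0 else np.nan
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((cls, a, len(ca), c, len(non), float(fold), float(p)))
    return pd.DataFrame(
        rows,
        columns=["class", "caqtl_eqtls", "n_caqtls", "control_eqtls", "n_controls", "fold", "pvalue"],
    ).set_index("class")


def split_bqtls_by_ca(
    bqtl_ids: list,
    combined_p: pd.Series,
    sig_threshold: float = 5e-6,
    null_floor: float = 0.5,
) -> tuple[set, set]:
    """Split binding QTLs by whether they also affect chromatin accessibility.

    affects_CA: combined caQTL p below ``sig_threshold``; no_CA: combined p
    above ``null_floor``; the intermediate band is excluded from both.
    """
    affects, no_ca = set(), set()
    for b in bqtl_ids:
        if b not in combined_p.index:
            continue
        p = combined_p[b]
        if p < sig_threshold:
            affects.add(b)
        elif p > null_floor:
            no_ca.add(b)
    return affects, no_ca


def majority_direction_consistent(results: pd.DataFrame) -> pd.Series:
    """Shared caQTLs whose allelic direction agrees across populations.

    True when strictly more than half of the populations in which the SNP
    was tested (with a defined direction) agree with the pooled direction;
    used to gate entry into the allelic Hi-C analysis.
    """
    dir_cols = [c for c in results.columns if c.startswith("dir_")]
    pv_cols = [c.replace("dir_", "pv_") for c in dir_cols]
    dirs = results[dir_cols].to_numpy()
    tested = results[pv_cols].notna().to_numpy()
    pooled = results["pooled_direction"].to_numpy()
    agree = ((dirs == pooled[:, None]) & tested & (dirs != 0)).sum(axis=1)
    n_tested = tested.sum(axis=1)
    ok = (pooled != 0) & (agree * 2 > n_tested)
    return pd.Series(ok, index=results.index, name="direction_consistent")
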