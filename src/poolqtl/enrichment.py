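"""Validation and annotation analyses for called caQTLs.

Overlap fold-enrichment against external QTL sets, allelic-direction
agreement, effect-size correlation, chromatin-state enrichment with
read-depth-matched controls, motif position-wise caQTL density versus
information content, minor-allele-frequency contrasts, LD expansion for
GWAS intersection, and the paired allelic-difference comparison harness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu, pearsonr

from .data_io import AnnotationTrack, GenotypeMatrix
from ._rng import split_rng

logger = logging.getLogger(__name__)

__all__ = [
    "fold_enrichment",
    "directionality_agreement",
    "effect_size_correlation",
    "match_backgrounds",
    "state_enrichment",
    "motif_information_content",
    "motif_position_density",
    "maf_comparison",
    "ld_r2",
    "ld_expand",
    "paired_allelic_difference_test",
]


@dataclass
class MatchedPair:
    caqtl_id: str
    control_id: str
    caqtl_reads: float
    control_reads: float


def fold_enrichment(query: set, reference: set, universe: set):
    """Fold enrichment of a reference set within a query set.

    fold = (|query & reference| / |query|) / (|reference| / |universe|),
    with a two-sided Fisher's exact p on the 2x2 membership table.  Returns
    (fold, p); (nan, nan) when query or reference is empty.
    """
    query, reference, universe = set(query), set(reference), set(universe)
    if not query <= universe or not reference <= universe:
        raise ValueError("query and reference must be subsets of the universe")
    if not query or not reference:
        return np.nan, np.nan
    overlap = len(query & reference)
    base = len(reference) / len(universe)
    fold = (overlap / len(query)) / base
    a = overlap
    b = len(query) - overlap
    c = len(reference) - overlap
    d = len(universe) - len(query) - c
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(fold), float(p)


def directionality_agreement(
    caqtls: pd.DataFrame,
    external: pd.DataFrame,
    cutoffs: list[float] = (5e-2, 5e-3, 5e-4),
) -> pd.DataFrame:
    """Fraction of overlapping SNPs whose more-accessible allele matches.

    ``caqtls`` needs columns pv and direction (sign, +1 = minor allele more
    accessible); ``external`` needs a direction column on the same allele
    orientation.  Agreement is reported at each caQTL p-value cutoff.
    """
    common = caqtls.index.intersection(external.index)
    rows = []
    for cut in cutoffs:
        sub = caqtls.loc[common]
        sub = sub[(sub["pv"] < cut) & (sub["direction"] != 0)]
        ext = external.loc[sub.index, "direction"]
        ok = ext != 0
        n = int(ok.sum())
        agree = float((sub.loc[ok, "direction"] == ext[ok]).mean()) if n else np.nan
        rows.append((cut, n, agree))
    return pd.DataFrame(rows, columns=["cutoff", "n_overlap", "agreement"]).set_index(
        "cutoff"
    )


def effect_size_correlation(
    caqtl_shift: pd.Series, external_effect: pd.Series, harmonize: bool = True
) -> float:
    """Pearson correlation of signed effect sizes on overlapping SNPs.

    With ``harmonize`` the external effects are flipped to the orientation
    that refers to the same allele as the caQTL shift (sign convention
    agreement by majority); set False to correlate raw signs.
    """
    common = caqtl_shift.index.intersection(external_effect.index)
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping SNPs")
    x = caqtl_shift.loc[common].to_numpy(dtype=float)
    y = external_effect.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    if harmonize:
        agree = np.sign(x) == np.sign(y)
        if agree.mean() < 0.5:
            y = -y
    return float(pearsonr(x, y)[0])


def match_backgrounds(
    caqtl_reads: pd.Series,
    control_reads: pd.Series,
    tolerance_log2: float = 0.5,
    seed: int = 0,
) -> list[MatchedPair]:
    """Greedy one-to-one read-depth matching of caQTLs to control SNPs.

    For each caQTL (visited in seeded-random order) the first unused control
    with |log2(caQTL reads) - log2(control reads)| < tolerance is taken;
    caQTLs with no remaining match are dropped (counted in the log).
    """
    rng = split_rng(seed, "match_backgrounds")
    ca_ids = list(caqtl_reads.index)
    rng.shuffle(ca_ids)
    ctrl = control_reads.copy()
    ctrl_log = np.log2(ctrl.to_numpy(dtype=float))
    order = np.argsort(ctrl_log)
    ctrl_ids = np.array(ctrl.index)[order]
    ctrl_log = ctrl_log[order]
    used = np.zeros(len(ctrl_ids), dtype=bool)

    pairs = []
    dropped = 0
    for cid in ca_ids:
        target = np.log2(float(caqtl_reads[cid]))
        lo = np.searchsorted(ctrl_log, target - tolerance_log2, side="right")
        hi = np.searchsorted(ctrl_log, target + tolerance_log2, side="left")
        window = np.where(~used[lo:hi])[0]
        # strict inequality at the tolerance boundary
        window = window[np.abs(ctrl_log[lo:hi][window] - target) < tolerance_log2]
        if len(window) == 0:
            dropped += 1
            continue
        # closest available control
        j = lo + window[np.argmin(np.abs(ctrl_log[lo:hi][window] - target))]
        used[j] = True
        pairs.append(
            MatchedPair(
                cid,
                str(ctrl_ids[j]),
                float(caqtl_reads[cid]),
                float(control_reads[ctrl_ids[j]]),
            )
        )
    if dropped:
        logger.info("match_backgrounds: dropped %d unmatched caQTLs", dropped)
    return pairs


def state_enrichment(
    snps: pd.DataFrame,
    annotation: AnnotationTrack,
    control_snps: pd.DataFrame,
) -> pd.DataFrame:
    """Chromatin-state composition of caQTLs with a matched-control fold.

    ``snps`` and ``control_snps`` need chrom/pos columns (1-based).  Returns
    per state: raw fraction among the SNPs, fraction among controls, and the
    read-density-controlled fold (caQTL fraction / control fraction).
    """
    states = annotation.state_at(snps["chrom"].to_numpy(), snps["pos"].to_numpy())
    ctl_states = annotation.state_at(
        control_snps["chrom"].to_numpy(), control_snps["pos"].to_numpy()
    )
    all_states = sorted(set(states) | set(ctl_states) | set(annotation.states))
    rows = []
    for st in all_states:
        f_ca = float(np.mean(states == st)) if len(states) else np.nan
        f_ct = float(np.mean(ctl_states == st)) if len(ctl_states) else np.nan
        fold = f_ca / f_ct if f_ct and f_ct > 0 else np.nan
        rows.append((st, f_ca, f_ct, fold))
    return pd.DataFrame(
        rows, columns=["state", "caqtl_fraction", "control_fraction", "controlled_fold"]
    ).set_index("state")


def motif_information_content(pwm: np.ndarray) -> np.ndarray:
    """Per-position information content in bits: 2 + sum_b f_b log2 f_b.

    ``pwm`` is positions x 4 with probability rows; zero frequencies
    contribute nothing.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("pwm must be positions x 4")
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("pwm rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pwm > 0, pwm * np.log2(pwm), 0.0)
    return 2.0 + terms.sum(axis=1)


def orient_offsets(offsets: np.ndarray, strands: np.ndarray, motif_len: int) -> np.ndarray:
    """Map genomic motif offsets to motif orientation (minus strand flips)."""
    offsets = np.asarray(offsets)
    strands = np.asarray(strands)
    return np.where(strands == "-", motif_len - 1 - offsets, offsets)


def motif_position_density(
    offsets: np.ndarray, pwm: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """caQTL counts per motif position against the position's information.

    ``offsets`` are 0-based positions of caQTLs within the motif (already in
    motif orientation).  Returns (counts, information content, Pearson r).
    """
    ic = motif_information_content(pwm)
    L = len(ic)
    offsets = np.asarray(offsets, dtype=int)
    if ((offsets < 0) | (offsets >= L)).any():
        raise ValueError("caQTL offset outside the motif")
    counts = np.bincount(offsets, minlength=L).astype(float)
    r = float(pearsonr(counts, ic)[0]) if np.std(counts) > 0 and np.std(ic) > 0 else np.nan
    return counts, ic, r


def maf_comparison(
    groups: dict[str, np.ndarray], contrasts: list[tuple[str, str]]
) -> pd.DataFrame:
    """Median MAF per group with Wilcoxon rank-sum p per named contrast.

    Medians use the lower-interpolation convention (the reported median is
    an observed value).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    med = {
        name: float(np.quantile(np.asarray(v, float), 0.5, method="lower"))
        for name, v in groups.items()
    }
    rows = []
    for a, b in contrasts:
        stat = mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append((a, b, med[a], med[b], float(stat.pvalue)))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "median_a", "median_b", "pvalue"]
    )


def ld_r2(genotypes: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of dosage vectors (genotype-based r^2)."""
    ja = genotypes.snp_ids.get_loc(snp_a)
    jb = genotypes.snp_ids.get_loc(snp_b)
    a = genotypes.dosages[:, ja]
    b = genotypes.dosages[:, jb]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_expand(
    lead_snps: list[str],
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.8,
    window: int = 1_000_000,
) -> set:
    """Leads plus every SNP in strong LD (r^2 strictly above threshold).

    Only SNPs on the same chromosome within ``window`` bp of the lead are
    considered; monomorphic leads contribute only themselves.
    """
    snps = genotypes.snps
    expanded = set()
    for lead in lead_snps:
        if lead not in genotypes.snp_ids:
            continue
        expanded.add(lead)
        jl = genotypes.snp_ids.get_loc(lead)
        a = genotypes.dosages[:, jl]
        if np.std(a) == 0:
            continue
        lead_chrom = snps["chrom"].iloc[jl]
        lead_pos = snps["pos"].iloc[jl]
        near = (snps["chrom"] == lead_chrom) & (
            (snps["pos"] - lead_pos).abs() <= window
        )
        cols = np.where(near.to_numpy())[0]
        B = genotypes.dosages[:, cols]
        sd = B.std(axis=0)
        ok = sd > 0
        if not ok.any():
            continue
        ac = a - a.mean()
        r = (ac @ (B[:, ok] - B[:, ok].mean(axis=0))) / (
            len(a) * a.std() * sd[ok]
        )
        r = np.clip(r, -1.0, 1.0)
        hits = cols[ok][r**2 > r2_threshold]
        expanded.update(genotypes.snp_ids[hits])
    return expanded


def paired_allelic_difference_test(
    case_diffs: np.ndarray,
    control_diffs: np.ndarray,
    n_parameters: int = 4,
) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of two allelic-difference distributions.

    Returns (raw two-sided p, Bonferroni-adjusted p = raw * n_parameters,
    capped at 1).  The default correction of 4 matches simultaneous testing
    of four DNA-shape parameters.
    """
    case_diffs = np.asarray(case_diffs, dtype=float)
    control_diffs = np.asarray(control_diffs, dtype=float)
    if len(case_diffs) == 0 or len(control_diffs) == 0:
        raise ValueError("both samples must be nonempty")
    raw = float(mannwhitneyu(case_diffs, control_diffs, alternative="two-sided").pvalue)
    return raw, float(min(1.0, raw * n_parameters))
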