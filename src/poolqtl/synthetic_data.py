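"""Synthetic pooled ATAC-seq data with known ground truth.

The generator emulates the statistical structure of a pooled
chromatin-accessibility QTL experiment: population-structured genotypes
(Balding-Nichols divergence from a shared ancestral frequency,
Hardy-Weinberg sampling within populations), Dirichlet pooling weights,
per-individual multiplicative trans (global open-chromatin) scalars,
Poisson read depth per SNP, and binomial sampling of minor-allele reads
whose success probability comes from a haplotype-mixture model:

    p_post,i = sum_h u_h a_h x_h / sum_h u_h a_h

over the 2N haplotypes h of a pool, where u_h = w_j(h) * t_j(h) / 2 combines
the pooling weight and trans scalar of the carrying individual, x_h indicates
the minor allele, and allelic accessibility a_h equals the allelic
fold-change rho_i on minor-allele haplotypes and 1 otherwise.  Under the null
(rho = 1, t = 1) this reduces exactly to the pre-ATAC frequency
sum_j w_j G_ij, and a heterozygote in isolation shows allelic ratio
rho/(1+rho).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._rng import split_rng
from .data_io import COUNT_COLUMNS, GenotypeMatrix, PoolCounts, snp_id_from_fields

__all__ = [
    "SimScenario",
    "SimTruth",
    "simulate_genotypes",
    "simulate_pool_counts",
    "simulate_study",
    "post_atac_freq",
    "write_truth",
]


@dataclass
class SimScenario:
    """Study conditions for one synthetic experiment.

    Defaults mirror a single-population pooled experiment of ~100 cell lines
    at ~100x read depth per SNP with two replicates.
    """

    n_populations: int = 1
    n_individuals_per_pop: int = 100
    n_snps: int = 2000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.5)
    divergence: float = 0.05  # Balding-Nichols F_ST-like parameter
    weight_concentration: float = 50.0  # Dirichlet concentration per individual
    trans_effect_sd: float = 0.0  # sd of log trans scalar
    mean_depth: float = 100.0
    caqtl_fraction: float = 0.0
    effect_model: dict = field(default_factory=lambda: {"kind": "fixed", "rho": 3.0})
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_populations, self.n_individuals_per_pop, self.n_snps) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.caqtl_fraction <= 1.0:
            raise ValueError("caqtl_fraction must be in [0, 1]")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("ancestral_freq_range must be within [0, 1]")

    @property
    def pool_ids(self) -> list[str]:
        return [f"pop{k}" for k in range(self.n_populations)]


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    true_weights: dict[str, np.ndarray]  # per pool, sums to 1
    true_rho: np.ndarray  # per SNP allelic fold-change (1 = null)
    trans_scalars: dict[str, np.ndarray]  # per pool, per individual
    true_pre_freq: dict[str, np.ndarray]  # per pool, per SNP

    def __post_init__(self):
        for pool, w in self.true_weights.items():
            if abs(w.sum() - 1.0) > 1e-12:
                raise ValueError(f"weights for {pool} do not sum to 1")
        for pool, p in self.true_pre_freq.items():
            if ((p < 0) | (p > 1)).any():
                raise ValueError(f"pre-ATAC frequencies for {pool} outside [0, 1]")

    def is_caqtl(self) -> np.ndarray:
        return self.true_rho != 1.0


def _draw_rho(rng: np.random.Generator, scenario: SimScenario) -> np.ndarray:
    """Per-SNP allelic fold-change; rho = 1 at null SNPs."""
    rho = np.ones(scenario.n_snps)
    n_effects = int(round(scenario.caqtl_fraction * scenario.n_snps))
    if n_effects == 0:
        return rho
    idx = rng.choice(scenario.n_snps, size=n_effects, replace=False)
    model = scenario.effect_model
    kind = model.get("kind", "fixed")
    if kind == "fixed":
        vals = np.full(n_effects, float(model.get("rho", 3.0)))
    elif kind == "lognormal":
        vals = np.exp(rng.normal(0.0, float(model.get("sdlog", 0.5)), size=n_effects))
    else:
        raise ValueError(f"unknown effect model {kind!r}")
    if (vals <= 0).any():
        raise ValueError("allelic fold-change must be positive")
    # randomly orient which allele is the more accessible one
    flip = rng.random(n_effects) < 0.5
    vals[flip] = 1.0 / vals[flip]
    rho[idx] = vals
    return rho


def simulate_genotypes(scenario: SimScenario) -> GenotypeMatrix:
    """Population-structured Hardy-Weinberg genotypes, dosage-coded.

    A shared ancestral frequency per SNP is drawn uniformly from
    ``ancestral_freq_range``; each population's frequency is a
    Balding-Nichols draw Beta(f(1-F)/F, (1-f)(1-F)/F) around it (identical
    to f when F = 0).  Genotypes are Binomial(2, f_pop)/2 per individual.
    """
    rng = split_rng(scenario.seed, "genotypes")
    lo, hi = scenario.ancestral_freq_range
    f_anc = rng.uniform(lo, hi, size=scenario.n_snps)
    F = scenario.divergence
    pops = scenario.pool_ids
    dosage_blocks = []
    populations = []
    samples = []
    for pool in pops:
        if F == 0.0:
            f_pop = f_anc
        else:
            a = f_anc * (1.0 - F) / F
            b = (1.0 - f_anc) * (1.0 - F) / F
            # guard the degenerate Beta endpoints f in {0, 1}
            f_pop = np.where(
                (f_anc <= 0) | (f_anc >= 1), f_anc, rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))
            )
        g = rng.binomial(2, f_pop, size=(scenario.n_individuals_per_pop, scenario.n_snps))
        dosage_blocks.append(g / 2.0)
        populations.extend([pool] * scenario.n_individuals_per_pop)
        samples.extend(
            f"{pool}_s{i:04d}" for i in range(scenario.n_individuals_per_pop)
        )
    dosages = np.vstack(dosage_blocks)
    pos = np.arange(1, scenario.n_snps + 1) * 1000
    snps = pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "ref": "A", "alt": "G"},
    )
    snps.index = pd.Index(
        [snp_id_from_fields("chr1", p, "A", "G") for p in pos], name="snp_id"
    )
    return GenotypeMatrix(snps, dosages, samples, populations)


def sample_truth(genotypes: GenotypeMatrix, scenario: SimScenario) -> SimTruth:
    """Draw pooling weights, trans scalars and cis effects for each pool."""
    rng = split_rng(scenario.seed, "truth")
    rho = _draw_rho(rng, scenario)
    weights, trans, pre = {}, {}, {}
    pop_arr = np.array(genotypes.populations)
    for pool in scenario.pool_ids:
        members = pop_arr == pool
        n = int(members.sum())
        w = rng.dirichlet(np.full(n, scenario.weight_concentration))
        w = w / w.sum()  # exact sum-to-one
        t = (
            np.exp(rng.normal(0.0, scenario.trans_effect_sd, size=n))
            if scenario.trans_effect_sd > 0
            else np.ones(n)
        )
        weights[pool] = w
        trans[pool] = t
        pre[pool] = w @ genotypes.dosages[members]
    return SimTruth(weights, rho, trans, pre)


def post_atac_freq(
    dosages: np.ndarray,
    weights: np.ndarray,
    trans: np.ndarray,
    rho: np.ndarray,
) -> np.ndarray:
    """Expected post-ATAC minor-allele read fraction per SNP.

    Haplotype-mixture model: each of an individual's two haplotypes carries
    weight w_j t_j / 2 and accessibility rho (minor) or 1 (major); reads are
    sampled proportionally to weight x accessibility.
    """
    u = weights * trans  # per-individual haplotype-pair weight
    minor = u @ (dosages * rho[None, :])  # sum_j u_j G_ij rho_i
    major = u @ (1.0 - dosages)  # sum_j u_j (1 - G_ij)
    return minor / (minor + major)


def simulate_pool_counts(
    genotypes: GenotypeMatrix, truth: SimTruth, scenario: SimScenario
) -> PoolCounts:
    """Poisson depth and binomial minor-allele reads per SNP x pool x replicate."""
    rng = split_rng(scenario.seed, "counts")
    pop_arr = np.array(genotypes.populations)
    records = []
    snps = genotypes.snps
    for pool in scenario.pool_ids:
        members = pop_arr == pool
        p_post = post_atac_freq(
            genotypes.dosages[members],
            truth.true_weights[pool],
            truth.trans_scalars[pool],
            truth.true_rho,
        )
        for rep in range(scenario.n_replicates):
            n = rng.poisson(scenario.mean_depth, size=genotypes.n_snps)
            m = rng.binomial(n, p_post)
            records.append(
                pd.DataFrame(
                    {
                        "chrom": snps["chrom"].to_numpy(),
                        "pos": snps["pos"].to_numpy(),
                        "ref": snps["ref"].to_numpy(),
                        "alt": snps["alt"].to_numpy(),
                        "pool_id": pool,
                        "replicate": rep,
                        "minor_count": m,
                        "total_count": n,
                    }
                )
            )
    df = pd.concat(records, ignore_index=True)
    return PoolCounts(df[COUNT_COLUMNS])


def simulate_study(scenario: SimScenario) -> tuple[GenotypeMatrix, SimTruth, PoolCounts]:
    """Genotypes, ground truth and pooled counts for one scenario."""
    genotypes = simulate_genotypes(scenario)
    truth = sample_truth(genotypes, scenario)
    counts = simulate_pool_counts(genotypes, truth, scenario)
    return genotypes, truth, counts


def write_truth(truth: SimTruth, scenario: SimScenario, path) -> None:
    """JSON ground-truth file (weights, effects, trans scalars, scenario)."""
    payload = {
        "scenario": asdict(scenario),
        "true_rho": truth.true_rho.tolist(),
        "true_weights": {k: v.tolist() for k, v in truth.true_weights.items()},
        "trans_scalars": {k: v.tolist() for k, v in truth.trans_scalars.items()},
        "true_pre_freq": {k: v.tolist() for k, v in truth.true_pre_freq.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
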