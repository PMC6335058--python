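"""End-to-end orchestration: simulate/load -> weights -> test -> combine.

Every run is a pure function of (inputs, config, seed): stage seeds are
derived from the master seed, the full configuration is serialized into the
run manifest together with per-stage row counts, and output tables are
written deterministically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import data_io
from .caqtl_test import call_caqtls, test_pool
from .multipop import call_shared, combine_populations, pi1_matrix
from .pool_weights import estimate_weights
from .synthetic_data import SimScenario, simulate_study, write_truth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``scenario`` (synthetic run) or ``vcf_path`` + ``counts_path`` +
    ``populations_path`` (real inputs) must be provided.
    """

    scenario: SimScenario | None = None
    vcf_path: str | None = None
    counts_path: str | None = None
    populations_path: str | None = None  # TSV: sample <tab> population
    min_reads: int = 20
    min_maf: float = 0.01
    per_pop_alpha: float = 5e-4
    combined_alpha: float = 5e-6
    weighting_mode: str = "variance"
    k_mode: str = "all"
    seed: int = 0

    def validate(self) -> None:
        if self.scenario is None:
            for p in (self.vcf_path, self.counts_path, self.populations_path):
                if p is None:
                    raise ValueError(
                        "either a scenario or vcf/counts/populations paths are required"
                    )
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        for name in ("min_reads", "min_maf", "per_pop_alpha", "combined_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _load_inputs(config: RunConfig, out: Path):
    if config.scenario is not None:
        scenario = dataclasses.replace(config.scenario, seed=config.seed)
        genotypes, truth, counts = simulate_study(scenario)
        data_io.write_vcf(genotypes, out / "genotypes.vcf")
        data_io.write_counts(counts, out / "counts.tsv")
        write_truth(truth, scenario, out / "truth.json")
        return genotypes, counts
    pops = pd.read_csv(
        config.populations_path, sep="\t", header=None, names=["sample", "population"]
    )
    population_map = dict(zip(pops["sample"], pops["population"]))
    genotypes = data_io.read_genotypes(
        config.vcf_path, list(pops["sample"]), population_map
    )
    counts = data_io.read_counts(config.counts_path)
    return genotypes, counts


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run all stages, writing tables and a manifest under ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_rows: dict[str, int] = {}

    genotypes, counts = _load_inputs(config, out)
    stage_rows["genotype_snps"] = genotypes.n_snps
    stage_rows["count_rows"] = len(counts.df)

    pools = sorted(counts.df["pool_id"].unique())
    results: dict[str, pd.DataFrame] = {}
    for pool in pools:
        members = [
            s for s, p in zip(genotypes.samples, genotypes.populations) if p == pool
        ]
        if not members:
            raise ValueError(f"stage weights[{pool}]: no genotyped individuals")
        gm = genotypes.subset_samples(members)
        pc = counts.for_pool(pool)
        try:
            res = test_pool(
                gm,
                pc,
                min_reads=config.min_reads,
                min_maf=config.min_maf,
                weighting_mode=config.weighting_mode,
            )
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"stage test[{pool}] failed: {exc}") from exc
        results[pool] = res
        res.to_csv(out / f"caqtl_{pool}.tsv", sep="\t")
        called = call_caqtls(res, config.per_pop_alpha)
        stage_rows[f"tested_{pool}"] = int(res["testable"].sum())
        stage_rows[f"caqtls_{pool}"] = len(called)

    combined = combine_populations(
        results, k_mode=config.k_mode, per_pop_alpha=config.per_pop_alpha
    )
    combined.to_csv(out / "combined.tsv", sep="\t")
    shared = call_shared(combined, config.combined_alpha)
    shared.to_csv(out / "shared_caqtls.tsv", sep="\t")
    stage_rows["combined"] = len(combined)
    stage_rows["shared_caqtls"] = len(shared)

    if len(pools) > 1:
        pi1 = pi1_matrix(results, alpha=config.per_pop_alpha)
        pi1.to_csv(out / "pi1_matrix.tsv", sep="\t")

    cfg = config.to_dict()
    data_io.write_manifest(out / "manifest.json", cfg, config.seed, stage_rows)
    return out
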