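"""Input/output and the core in-memory containers.

Genotypes are held as a minor-allele dosage matrix (individuals x SNPs,
entries in {0, 0.5, 1}); pooled ATAC-seq allele counts are held as a long
table with one row per SNP x pool x replicate.  VCF positions are 1-based
internally; BED intervals are converted from 0-based half-open at the
boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "pool_id",
    "replicate",
    "minor_count",
    "total_count",
]

DOSAGE_VALUES = (0.0, 0.5, 1.0)


def snp_id_from_fields(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix for the pooled individuals.

    Attributes
    ----------
    snps : DataFrame with columns chrom, pos (1-based), ref, alt, indexed by
        snp_id.  ``ref``/``alt`` are the VCF alleles; ``alt`` is oriented to
        the pool minor allele after :func:`orient_to_minor`.
    dosages : float array, shape (n_individuals, n_snps), entries in
        {0, 0.5, 1}.
    samples : sample identifiers, one per row of ``dosages``.
    populations : population label per sample.
    """

    snps: pd.DataFrame
    dosages: np.ndarray
    samples: list[str]
    populations: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if not np.isin(self.dosages, DOSAGE_VALUES).all():
            raise ValueError("dosages must be coded 0, 0.5 or 1")
        if self.snps.index.duplicated().any():
            raise ValueError("duplicate SNP identifiers")

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> pd.Index:
        return self.snps.index

    def minor_allele_freq(self) -> np.ndarray:
        """Pool allele frequency of the (oriented) minor allele per SNP."""
        return self.dosages.mean(axis=0)

    def subset_samples(self, samples: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in samples]
        return GenotypeMatrix(
            self.snps.copy(),
            self.dosages[idx],
            list(samples),
            [self.populations[i] for i in idx],
        )


@dataclass
class PoolCounts:
    """Per-SNP minor/total ATAC-seq read counts per pool and replicate."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        missing = [c for c in COUNT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        bad = self.df["minor_count"] > self.df["total_count"]
        if bad.any():
            rows = self.df.index[bad].tolist()[:5]
            raise ValueError(f"minor_count > total_count at rows {rows}")
        if (self.df["minor_count"] < 0).any() or (self.df["total_count"] < 0).any():
            raise ValueError("negative read counts")
        if "snp_id" not in self.df.columns:
            self.df = self.df.assign(
                snp_id=[
                    snp_id_from_fields(c, p, r, a)
                    for c, p, r, a in zip(
                        self.df["chrom"], self.df["pos"], self.df["ref"], self.df["alt"]
                    )
                ]
            )

    @property
    def post_freq(self) -> pd.Series:
        """Post-ATAC minor allele frequency m/n (NaN where n == 0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.df["minor_count"] / self.df["total_count"].replace(0, np.nan)

    def for_pool(self, pool_id) -> "PoolCounts":
        return PoolCounts(self.df[self.df["pool_id"] == pool_id].reset_index(drop=True))


@dataclass
class AnnotationTrack:
    """Chromatin-state intervals (0-based half-open converted on read)."""

    intervals: pd.DataFrame  # chrom, start, end, state (1-based inclusive internally)
    default_state: str = "quiescent"

    def __post_init__(self):
        if (self.intervals["start"] >= self.intervals["end"]).any():
            raise ValueError("annotation intervals must have start < end")

    @property
    def states(self) -> list[str]:
        return sorted(set(self.intervals["state"])) + [self.default_state]

    def state_at(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Chromatin state for 1-based positions; unannotated -> default."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        out = np.full(len(pos), self.default_state, dtype=object)
        for c, sub in self.intervals.groupby("chrom", sort=False):
            mask = chrom == c
            if not mask.any():
                continue
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            states = sub["state"].to_numpy()
            # BED half-open [start, end) on 0-based == (start, end] on 1-based
            idx = np.searchsorted(starts, pos[mask] - 1, side="right") - 1
            ok = (idx >= 0) & (pos[mask] - 1 < ends[np.clip(idx, 0, None)])
            vals = out[mask]
            vals[ok] = states[idx[ok]]
            out[mask] = vals
        return out


# ---------------------------------------------------------------------------
# VCF


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write dosages as an uncompressed VCF 4.2 with GT fields.

    Dosage 0 -> 0/0, 0.5 -> 0/1, 1 -> 1/1 with respect to the stored
    ref/alt orientation.
    """
    gt_code = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for j, (sid, row) in enumerate(genotypes.snps.iterrows()):
            gts = "\t".join(gt_code[d] for d in genotypes.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{sid}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genotypes(
    vcf_path,
    sample_list: list[str],
    population_map: dict[str, str],
    orient: bool = True,
) -> GenotypeMatrix:
    """Read biallelic SNP genotypes for the pooled samples from a VCF.

    Dosage is (number of minor alleles)/2 per individual.  The minor allele
    is defined from the pooled individuals themselves (mean dosage), with
    ties broken toward the VCF alternate allele.  Multiallelic sites and
    sites with missing genotypes in any pooled sample are skipped (counted
    in the log).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    available = set(vcf.samples)
    missing = [s for s in sample_list if s not in available]
    if missing:
        raise ValueError(f"samples absent from VCF: {missing}")
    vcf = VCF(str(vcf_path), samples=sample_list)
    # cyvcf2 returns samples in VCF order; map back to requested order
    order = [vcf.samples.index(s) for s in sample_list]

    rows = []
    dosage_cols = []
    n_multi = n_missing = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = np.array(var.gt_types)[order]  # 0=hom ref,1=het,2=unknown,3=hom alt
        if (gts == 2).any():
            n_missing += 1
            continue
        dos = np.where(gts == 0, 0.0, np.where(gts == 1, 0.5, 1.0))
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        dosage_cols.append(dos)
    if n_multi or n_missing:
        logger.info(
            "read_genotypes: skipped %d multiallelic and %d incomplete sites",
            n_multi,
            n_missing,
        )
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    snps.index = pd.Index(
        [snp_id_from_fields(*r) for r in rows], name="snp_id"
    )
    dosages = (
        np.column_stack(dosage_cols) if dosage_cols else np.zeros((len(sample_list), 0))
    )
    gm = GenotypeMatrix(
        snps,
        dosages,
        list(sample_list),
        [population_map.get(s, "pool") for s in sample_list],
    )
    return orient_to_minor(gm) if orient else gm


def orient_to_minor(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Flip sites where the alternate allele is the pool major allele.

    After orientation the dosage of every SNP has mean <= 0.5 among the
    pooled individuals, ref/alt are swapped at flipped sites, and dosages are
    complemented (d -> 1 - d).  Idempotent; ties (mean exactly 0.5) keep the
    alternate allele as minor.
    """
    freq = genotypes.dosages.mean(axis=0)
    flip = freq > 0.5
    if not flip.any():
        return genotypes
    dosages = genotypes.dosages.copy()
    dosages[:, flip] = 1.0 - dosages[:, flip]
    snps = genotypes.snps.copy()
    ref = snps["ref"].to_numpy().copy()
    alt = snps["alt"].to_numpy().copy()
    ref[flip], alt[flip] = alt[flip].copy(), ref[flip].copy()
    snps["ref"], snps["alt"] = ref, alt
    snps.index = pd.Index(
        [
            snp_id_from_fields(c, p, r, a)
            for c, p, r, a in zip(snps["chrom"], snps["pos"], snps["ref"], snps["alt"])
        ],
        name="snp_id",
    )
    logger.info("orient_to_minor: flipped %d sites", int(flip.sum()))
    return GenotypeMatrix(snps, dosages, genotypes.samples, genotypes.populations)


# ---------------------------------------------------------------------------
# Count tables


def write_counts(counts: PoolCounts, path) -> None:
    counts.df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(tsv_path) -> PoolCounts:
    df = pd.read_csv(tsv_path, sep="\t")
    return PoolCounts(df)


def align_counts(genotypes: GenotypeMatrix, counts: PoolCounts) -> pd.DataFrame:
    """Per-SNP (m, n) aligned to the genotype matrix's allele orientation.

    Counts are matched by (chrom, pos, ref, alt); a count row whose alleles
    are swapped relative to the oriented genotypes is complemented
    (m -> n - m).  SNPs with no counts get n = 0.  ``counts`` must be
    replicate-merged for a single pool.
    """
    key = counts.df.set_index("snp_id")[["minor_count", "total_count"]]
    key = key[~key.index.duplicated()]
    snps = genotypes.snps
    flipped_ids = [
        snp_id_from_fields(c, p, a, r)
        for c, p, r, a in zip(snps["chrom"], snps["pos"], snps["ref"], snps["alt"])
    ]
    direct = key.reindex(genotypes.snp_ids)
    swapped = key.reindex(flipped_ids)
    swapped.index = genotypes.snp_ids
    n = direct["total_count"].fillna(swapped["total_count"])
    m = direct["minor_count"].fillna(swapped["total_count"] - swapped["minor_count"])
    out = pd.DataFrame(
        {"m": m.fillna(0).astype(int), "n": n.fillna(0).astype(int)},
        index=genotypes.snp_ids,
    )
    return out


def merge_replicates(counts: PoolCounts, mode: str = "sum") -> PoolCounts:
    """Combine replicate rows per pool.

    mode "sum" adds minor and total counts over replicates (the default used
    for caQTL calling); "separate" passes replicates through unchanged (for
    reproducibility analyses on individual replicates).
    """
    if mode == "separate":
        return counts
    if mode != "sum":
        raise ValueError(f"unknown merge mode {mode!r}")
    df = (
        counts.df.groupby(
            ["chrom", "pos", "ref", "alt", "pool_id"], sort=False, as_index=False
        )
        .agg(minor_count=("minor_count", "sum"), total_count=("total_count", "sum"))
        .assign(replicate=0)
    )
    return PoolCounts(df[COUNT_COLUMNS])


# ---------------------------------------------------------------------------
# Annotations and small tables


def read_bed(path, default_state: str = "quiescent") -> AnnotationTrack:
    """Read a BED file of chromatin-state intervals (name column = state)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "state"],
    )
    return AnnotationTrack(df, default_state=default_state)


def write_manifest(path, config: dict, seed: int, stage_rows: dict[str, int]) -> None:
    """JSON run manifest: config hash, seed and per-stage row counts."""
    import hashlib

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": int(seed),
        "stage_rows": {k: int(v) for k, v in stage_rows.items()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
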