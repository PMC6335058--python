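import numpy as np
import pandas as pd
import pytest

from poolqtl.data_io import COUNT_COLUMNS, GenotypeMatrix, PoolCounts


def make_genotypes(dosages, samples=None, populations=None, chrom="chr1"):
    """GenotypeMatrix from a raw dosage array (individuals x SNPs)."""
    dosages = np.asarray(dosages, dtype=float)
    n_ind, n_snp = dosages.shape
    if samples is None:
        samples = [f"s{i:03d}" for i in range(n_ind)]
    if populations is None:
        populations = ["pop0"] * n_ind
    pos = np.arange(1, n_snp + 1) * 100
    snps = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"})
    snps.index = pd.Index([f"{chrom}:{p}:A:G" for p in pos], name="snp_id")
    return GenotypeMatrix(snps, dosages, list(samples), list(populations))


def make_counts(genotypes, minor, total, pool_id="pop0", replicate=0):
    """PoolCounts aligned with a GenotypeMatrix's SNPs."""
    snps = genotypes.snps
    df = pd.DataFrame(
        {
            "chrom": snps["chrom"].to_numpy(),
            "pos": snps["pos"].to_numpy(),
            "ref": snps["ref"].to_numpy(),
            "alt": snps["alt"].to_numpy(),
            "pool_id": pool_id,
            "replicate": replicate,
            "minor_count": np.asarray(minor, dtype=int),
            "total_count": np.asarray(total, dtype=int),
        }
    )
    return PoolCounts(df[COUNT_COLUMNS])


@pytest.fixture
def rng(request):
    # per-test deterministic stream, independent of execution order
    import zlib

    return np.random.default_rng(zlib.crc32(request.node.nodeid.encode()))
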