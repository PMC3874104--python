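import numpy as np
import pytest

from lincscreen.io_formats import DiffRecord, GenomicInterval
from lincscreen import synthetic


@pytest.fixture(scope="session")
def small_genome():
    """Two-chromosome genome with a 300-gene catalog."""
    sizes, catalog = synthetic.gen_genome(
        n_chroms=2, mean_length=30_000_000, n_genes=300, seed=11
    )
    return sizes, catalog


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def pick_focal_with_neighbours(catalog, need: int, half_width: int = 1_000_000):
    """First catalog gene with >= ``need`` genes within +-half_width of its TSS."""
    by_chrom = {}
    for g in catalog:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for genes in by_chrom.values():
        tss = np.sort(np.array([g.tss for g in genes]))
        for g in genes:
            n = int(
                np.searchsorted(tss, g.tss + half_width, side="right")
                - np.searchsorted(tss, g.tss - half_width, side="left")
                - 1
            )
            if n >= need:
                return g
    raise ValueError("no gene has enough neighbours")


def make_diff_record(
    gene_id: str,
    chrom: str = "chr1",
    start: int = 100,
    end: int = 200,
    stat: float = 0.0,
    q: float = 1.0,
    p: float | None = None,
    status: str = "OK",
    strand: str = ".",
) -> DiffRecord:
    return DiffRecord(
        gene_id=gene_id,
        locus=GenomicInterval(chrom, start, end, strand),
        test_statistic=stat,
        log2fc=0.0,
        p=min(q, 1.0) if p is None else p,
        q=q,
        status=status,
    )
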