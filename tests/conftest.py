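import numpy as np
import pandas as pd
import pytest

from hijackscan import (
    Breakpoint,
    CountMatrix,
    GenomicInterval,
    PromoterInteraction,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_counts():
    """4 genes x 6 donors, all reference-eligible."""
    data = np.array(
        [
            [10, 20, 15, 12, 18, 25],
            [100, 210, 160, 130, 170, 240],
            [5, 9, 7, 6, 8, 11],
            [50, 95, 80, 60, 90, 120],
        ]
    )
    return CountMatrix(
        counts=pd.DataFrame(
            data,
            index=[f"G{i}" for i in range(4)],
            columns=[f"D{j}" for j in range(6)],
        )
    )


def random_interval(rng, max_coord=10_000, chroms=("chr1", "chr2", "chr3")):
    start = int(rng.integers(0, max_coord - 1))
    end = int(rng.integers(start + 1, max_coord))
    return GenomicInterval(str(rng.choice(chroms)), start, end)


def random_interactions(rng, n, max_coord=10_000):
    out = []
    for i in range(n):
        chrom = str(rng.choice(["chr1", "chr2"]))
        b0 = int(rng.integers(0, max_coord - 10))
        bait = GenomicInterval(chrom, b0, b0 + int(rng.integers(1, 200)))
        p0 = int(rng.integers(0, max_coord - 10))
        pir = GenomicInterval(chrom, p0, p0 + int(rng.integers(1, 200)))
        out.append(
            PromoterInteraction(
                interaction_id=f"I{i:03d}",
                gene_ids=(f"G{i:03d}", f"H{i:03d}")[: int(rng.integers(1, 3))],
                bait=bait,
                pir=pir,
                score=float(rng.uniform(0, 10)),
            )
        )
    return out


def random_breakpoints(rng, n, max_coord=10_000):
    return [
        Breakpoint(
            donor_id=f"D{int(rng.integers(0, 20)):02d}",
            chrom=str(rng.choice(["chr1", "chr2", "chr3"])),
            pos=int(rng.integers(0, max_coord)),
        )
        for _ in range(n)
    ]
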