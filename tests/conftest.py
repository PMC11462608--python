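import numpy as np
import pandas as pd
import pytest

from sweepscan.genotype_io import (
    HaplotypeMatrix,
    Polarity,
    PopulationPanel,
    SiteRecord,
)


def make_matrix(counts, n=4, spacing=100, polarity=Polarity.ALT_IS_DERIVED,
                chrom="chr1", start=100):
    """Matrix with given per-site 1-counts; first ``count`` rows carry the 1."""
    sites, cols = [], []
    for k, x in enumerate(counts):
        aa = None
        if polarity is Polarity.ALT_IS_DERIVED:
            aa = "A"
        elif polarity is Polarity.REF_IS_DERIVED:
            aa = "C"
        sites.append(
            SiteRecord(chrom=chrom, pos=start + spacing * k, ref="A", alt="C",
                       variant_id=f"v{k}", ancestral=aa, polarity=polarity)
        )
        col = np.zeros(n, dtype=np.int8)
        col[:x] = 1
        cols.append(col)
    calls = np.stack(cols, axis=1) if cols else np.empty((n, 0), dtype=np.int8)
    return HaplotypeMatrix(
        sites=sites, calls=calls, sample_ids=[f"s{i}" for i in range(n // 2)]
    )


def matrix_from_calls(calls, positions=None, polarity=Polarity.ALT_IS_DERIVED,
                      chrom="chr1"):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = 100 * (np.arange(m) + 1)
    aa = "A" if polarity is Polarity.ALT_IS_DERIVED else (
        "C" if polarity is Polarity.REF_IS_DERIVED else None)
    sites = [
        SiteRecord(chrom=chrom, pos=int(p), ref="A", alt="C", variant_id=f"v{k}",
                   ancestral=aa, polarity=polarity)
        for k, p in enumerate(positions)
    ]
    return HaplotypeMatrix(
        sites=sites, calls=calls, sample_ids=[f"s{i}" for i in range(n // 2)]
    )


def random_matrix(rng, n_hap, n_sites, polymorphic=True):
    """Random polarized matrix; optionally guarantee every site polymorphic."""
    while True:
        calls = (rng.random((n_hap, n_sites)) < rng.uniform(0.1, 0.9, n_sites))
        calls = calls.astype(np.int8)
        if not polymorphic:
            break
        counts = calls.sum(axis=0)
        if ((counts > 0) & (counts < n_hap)).all():
            break
    return matrix_from_calls(calls)


@pytest.fixture
def toy_panel():
    return PopulationPanel(
        table=pd.DataFrame(
            {
                "sample": ["s0", "s1", "s2", "s3"],
                "pop": ["YRI", "YRI", "CEU", "CEU"],
                "super_pop": ["AFR", "AFR", "EUR", "EUR"],
                "gender": ["male", "female", "male", "female"],
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
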