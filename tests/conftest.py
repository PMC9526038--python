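import numpy as np
import pytest

from impmkt import GeneVariationRecord, SiteFrequencySpectrum


def make_record(
    gene_id="g",
    n=20,
    sfs_n=None,
    sfs_s=None,
    dn=15,
    ds=8,
    mn=500.0,
    ms=200.0,
    folded=False,
):
    k = n // 2 if folded else n - 1
    if sfs_n is None:
        sfs_n = np.zeros(k)
    if sfs_s is None:
        sfs_s = np.zeros(k)
    return GeneVariationRecord(
        gene_id=gene_id,
        sfs_n=SiteFrequencySpectrum(n, np.asarray(sfs_n, dtype=float), folded),
        sfs_s=SiteFrequencySpectrum(n, np.asarray(sfs_s, dtype=float), folded),
        dn=dn,
        ds=ds,
        mn=mn,
        ms=ms,
    )


@pytest.fixture
def worked_example():
    """The worked-example gene: P_N=11 (7 below 15%), P_S=17 (6 below 15%),
    D_N=15, D_S=8, n=20."""
    return make_record(
        gene_id="example",
        sfs_n=[4, 3, 2, 1, 1] + [0] * 14,
        sfs_s=[4, 2, 3, 3, 2, 2, 1] + [0] * 12,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
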