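"""Site-frequency-spectrum containers and manipulations.

The central objects are :class:`SiteFrequencySpectrum` (counts of segregating
sites per allele-frequency class at a fixed sample size) and
:class:`GeneVariationRecord` (one gene's paired nonsynonymous/synonymous SFS
plus fixed-difference and site counts).  All downstream McDonald-Kreitman
machinery consumes these objects; no genomic coordinates are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import hypergeom


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """Counts of segregating sites per allele-frequency class.

    Parameters
    ----------
    sample_size
        Number of sampled haploid sequences ``n``.
    counts
        Non-negative counts indexed by derived-allele count ``i = 1..n-1``
        (unfolded) or minor-allele count ``i = 1..floor(n/2)`` (folded).
        Real-valued counts are allowed (expected spectra, projections).
    folded
        Whether ``counts`` is indexed by minor-allele count.
    """

    sample_size: int
    counts: np.ndarray
    folded: bool = False

    def __post_init__(self) -> None:
        n = int(self.sample_size)
        if n < 2:
            raise ValueError(f"sample_size must be >= 2, got {n}")
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        expected = n // 2 if self.folded else n - 1
        if counts.shape[0] != expected:
            raise ValueError(
                f"counts length {counts.shape[0]} does not match "
                f"{'folded' if self.folded else 'unfolded'} SFS at n={n} "
                f"(expected {expected})"
            )
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and non-negative")
        counts.setflags(write=False)
        object.__setattr__(self, "sample_size", n)
        object.__setattr__(self, "counts", counts)

    @property
    def frequencies(self) -> np.ndarray:
        """Allele frequency of each class, ``i / n``."""
        k = self.counts.shape[0]
        return np.arange(1, k + 1) / self.sample_size

    def total(self) -> float:
        return float(self.counts.sum())

    def __add__(self, other: "SiteFrequencySpectrum") -> "SiteFrequencySpectrum":
        if (self.sample_size, self.folded) != (other.sample_size, other.folded):
            raise ValueError("cannot add SFS with different sample size or folding")
        return replace(self, counts=self.counts + other.counts)


def total(sfs: SiteFrequencySpectrum) -> float:
    """Total number of segregating sites in the spectrum."""
    return sfs.total()


def fold(sfs: SiteFrequencySpectrum) -> SiteFrequencySpectrum:
    """Fold an unfolded SFS onto minor-allele-count classes.

    ``f'(i) = f(i) + f(n-i)`` for ``i < n/2``; the middle class ``i = n/2``
    (even ``n``) is carried over unchanged.  The total is conserved exactly.
    """
    if sfs.folded:
        raise ValueError("SFS is already folded")
    n = sfs.sample_size
    k = n // 2
    out = np.zeros(k)
    f = sfs.counts
    for i in range(1, k + 1):
        if i == n - i:
            out[i - 1] = f[i - 1]
        else:
            out[i - 1] = f[i - 1] + f[n - i - 1]
    return SiteFrequencySpectrum(n, out, folded=True)


def project(
    sfs: SiteFrequencySpectrum,
    m: int,
    *,
    round_stochastic: bool = False,
    rng: np.random.Generator | None = None,
) -> SiteFrequencySpectrum:
    """Hypergeometric projection of an unfolded SFS down to ``m`` samples.

    Each class ``i`` at sample size ``n`` contributes
    ``f_n(i) * P(j derived | draw m of n without replacement)`` to class
    ``j`` at size ``m``.  Mass that becomes monomorphic after downsampling
    (``j = 0`` or ``j = m``) is dropped, mirroring observable data.  Counts
    are expectations (real-valued) by default; with ``round_stochastic`` each
    class is rounded to an adjacent integer with probability equal to its
    fractional part.
    """
    if sfs.folded:
        raise ValueError("projection requires an unfolded SFS")
    n = sfs.sample_size
    if not 2 <= m <= n:
        raise ValueError(f"projection size must satisfy 2 <= m <= n, got m={m}, n={n}")
    if m == n and not round_stochastic:
        return sfs
    out = np.zeros(m - 1)
    for i in range(1, n):
        c = sfs.counts[i - 1]
        if c == 0:
            continue
        j = np.arange(1, m)
        # hypergeom(M=n, n=i, N=m): j successes when drawing m from n with i marked
        out += c * hypergeom.pmf(j, n, i, m)
    if round_stochastic:
        if rng is None:
            rng = np.random.default_rng()
        frac, base = np.modf(out)
        out = base + (rng.random(out.shape) < frac)
    return SiteFrequencySpectrum(m, out, folded=False)


@dataclass(frozen=True)
class GeneVariationRecord:
    """One gene's polymorphism and divergence summary.

    ``pn``/``ps`` (total nonsynonymous / synonymous segregating sites) are
    derived from the spectra and never stored independently.
    """

    gene_id: str
    sfs_n: SiteFrequencySpectrum
    sfs_s: SiteFrequencySpectrum
    dn: float
    ds: float
    mn: float = 1.0
    ms: float = 1.0

    def __post_init__(self) -> None:
        a, b = self.sfs_n, self.sfs_s
        if (a.sample_size, a.folded) != (b.sample_size, b.folded):
            raise ValueError(
                f"gene {self.gene_id!r}: nonsynonymous and synonymous SFS must "
                "share sample size and folding"
            )
        if self.dn < 0 or self.ds < 0:
            raise ValueError(f"gene {self.gene_id!r}: divergence counts must be >= 0")
        if self.mn <= 0 or self.ms <= 0:
            raise ValueError(f"gene {self.gene_id!r}: site counts must be positive")

    @property
    def sample_size(self) -> int:
        return self.sfs_n.sample_size

    @property
    def folded(self) -> bool:
        return self.sfs_n.folded

    @property
    def pn(self) -> float:
        return self.sfs_n.total()

    @property
    def ps(self) -> float:
        return self.sfs_s.total()

    def folded_copy(self) -> "GeneVariationRecord":
        return replace(self, sfs_n=fold(self.sfs_n), sfs_s=fold(self.sfs_s))


@dataclass(frozen=True)
class BandCounts:
    """Segregating-site counts split at a frequency cutoff.

    ``*_low`` counts sites strictly below the cutoff, ``*_high`` at or above
    it (derived-allele frequency for unfolded spectra, minor-allele frequency
    for folded ones).
    """

    pn_low: float
    pn_high: float
    ps_low: float
    ps_high: float
    cutoff: float

    @property
    def pn(self) -> float:
        return self.pn_low + self.pn_high

    @property
    def ps(self) -> float:
        return self.ps_low + self.ps_high


def _split(sfs: SiteFrequencySpectrum, cutoff: float) -> tuple[float, float]:
    low = sfs.frequencies < cutoff
    return float(sfs.counts[low].sum()), float(sfs.counts[~low].sum())


def band_counts(record: GeneVariationRecord, cutoff: float) -> BandCounts:
    """Split both spectra of a gene at a frequency cutoff.

    A class ``i`` is below the cutoff iff ``i/n < cutoff`` (strict), so at
    ``n = 20`` a 15% cutoff puts classes 1-2 below and class 3 (frequency
    exactly 0.15) above.  On a folded SFS the split is on minor-allele
    frequency, which removes both the ``DAF < c`` and ``DAF > 1-c`` tails.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    pn_low, pn_high = _split(record.sfs_n, cutoff)
    ps_low, ps_high = _split(record.sfs_s, cutoff)
    return BandCounts(pn_low, pn_high, ps_low, ps_high, cutoff)


def three_band_counts(
    record: GeneVariationRecord, low: float, high: float
) -> tuple[np.ndarray, np.ndarray]:
    """(low, mid, high) band totals for each spectrum at two cutoffs.

    Low is ``freq < low``, mid is ``low <= freq < high``, high is
    ``freq >= high``.  Requires an unfolded SFS (the high band is a
    derived-allele-frequency concept).
    """
    if record.folded:
        raise ValueError("three-band splits require an unfolded SFS")
    if not 0.0 < low < high < 1.0:
        raise ValueError(f"cutoffs must satisfy 0 < low < high < 1, got {low}, {high}")

    def bands(sfs: SiteFrequencySpectrum) -> np.ndarray:
        f = sfs.frequencies
        return np.array(
            [
                sfs.counts[f < low].sum(),
                sfs.counts[(f >= low) & (f < high)].sum(),
                sfs.counts[f >= high].sum(),
            ]
        )

    return bands(record.sfs_n), bands(record.sfs_s)
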