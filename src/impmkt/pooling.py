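"""Gene pooling and bootstrap resampling.

Pooling sums polymorphism and divergence over genes to build a single
high-count record, trading per-gene resolution for statistical power.  The
bootstrap machinery resamples genes with replacement to chart how alpha
estimates stabilise as pools grow -- the procedure used to determine the
minimum data requirements of each MKT variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .sfs import GeneVariationRecord

#: Pool-size grid used in the gene-pooling analyses.
DEFAULT_POOL_SIZES = (1, 2, 5, 10, 25, 50, 75, 100, 250, 500, 750, 1000)


def pool_records(
    records: Sequence[GeneVariationRecord], gene_id: str | None = None
) -> GeneVariationRecord:
    """Sum polymorphism and divergence across genes into one pooled record."""
    if not records:
        raise ValueError("cannot pool an empty record list")
    first = records[0]
    if len(records) == 1:
        return first if gene_id is None else replace(first, gene_id=gene_id)
    sizes = {(r.sample_size, r.folded) for r in records}
    if len(sizes) > 1:
        raise ValueError(f"cannot pool records with mixed sample sizes/folding: {sorted(sizes)}")
    sfs_n = first.sfs_n
    sfs_s = first.sfs_s
    for r in records[1:]:
        sfs_n = sfs_n + r.sfs_n
        sfs_s = sfs_s + r.sfs_s
    if gene_id is None:
        gene_id = f"pool[{first.gene_id}+{len(records) - 1}]"
    return GeneVariationRecord(
        gene_id=gene_id,
        sfs_n=sfs_n,
        sfs_s=sfs_s,
        dn=sum(r.dn for r in records),
        ds=sum(r.ds for r in records),
        mn=sum(r.mn for r in records),
        ms=sum(r.ms for r in records),
    )


@dataclass(frozen=True)
class PoolSpec:
    """Configuration for a bootstrap gene-pooling run."""

    pool_sizes: tuple[int, ...] = DEFAULT_POOL_SIZES
    replicates: int = 1000
    seed: int = 0
    method: str = "imp"
    cutoff: float = 0.15
    high_cutoff: float = 0.85

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.pool_sizes):
            raise ValueError("pool sizes must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "pool_sizes", tuple(int(s) for s in self.pool_sizes))


@dataclass(frozen=True)
class PoolResult:
    """Summary of one pool size over all bootstrap replicates."""

    pool_size: int
    alpha_mean: float
    alpha_p2_5: float
    alpha_p97_5: float
    fraction_analyzable: float
    mean_pn: float
    mean_ps: float


def bootstrap_pools(
    records: Sequence[GeneVariationRecord], spec: PoolSpec
) -> list[PoolResult]:
    """Bootstrap alpha over pools of increasing size.

    For every pool size, genes are drawn with replacement ``spec.replicates``
    times, pooled, and the configured MKT variant is run on the pool.
    Unanalyzable replicates are counted (``fraction_analyzable``) but
    excluded from the mean and the 2.5/97.5 empirical percentiles.  Per
    (pool size, replicate) random streams are derived from the master seed,
    so output is bit-reproducible and order-independent.
    """
    from .mkt import run_method  # local import to avoid a cycle

    if not records:
        raise ValueError("cannot bootstrap an empty record list")
    results = []
    for size_idx, pool_size in enumerate(spec.pool_sizes):
        alphas = np.empty(spec.replicates)
        pns = np.empty(spec.replicates)
        pss = np.empty(spec.replicates)
        ok = np.zeros(spec.replicates, dtype=bool)
        for rep in range(spec.replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence(spec.seed, spawn_key=(size_idx, rep))
            )
            idx = rng.integers(0, len(records), pool_size)
            pooled = pool_records([records[i] for i in idx], gene_id=f"pool{pool_size}r{rep}")
            res = run_method(pooled, spec.method, spec.cutoff, spec.high_cutoff)
            pns[rep], pss[rep] = pooled.pn, pooled.ps
            if res.analyzable:
                ok[rep] = True
                alphas[rep] = res.alpha
        a = alphas[ok]
        if a.size:
            lo, hi = np.percentile(a, [2.5, 97.5])
            mean = float(a.mean())
        else:
            lo = hi = mean = float("nan")
        results.append(
            PoolResult(
                pool_size=pool_size,
                alpha_mean=mean,
                alpha_p2_5=float(lo),
                alpha_p97_5=float(hi),
                fraction_analyzable=float(ok.mean()),
                mean_pn=float(pns.mean()),
                mean_ps=float(pss.mean()),
            )
        )
    return results


def pool_results_frame(results: Sequence[PoolResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
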