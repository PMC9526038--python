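"""Synthetic gene-variation data with known ground-truth alpha.

The generator is a Poisson-Random-Field (PRF) sampler: sites evolve
independently, the expected sampled SFS of a mutation class with scaled
selection coefficient gamma = 2*Ne*s follows the standard diffusion sojourn
density, and per-gene counts are Poisson draws around those expectations.
Nonsynonymous mutations are a mixture of a Gamma-distributed deleterious
class (shape ``beta``, mean ``|gamma_del|``) and point-mass beneficial
classes; every nonsynonymous fixation is drawn from an explicitly labelled
class, so the realized adaptive fraction alpha is known exactly by
construction rather than estimated.

The recombination rate ``rho`` is accepted and recorded for configuration
parity with forward-simulation studies but is UNUSED: the PRF model assumes
free recombination (independent sites), so linkage effects such as
background selection or Hill-Robertson interference are not emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from .sfs import GeneVariationRecord, SiteFrequencySpectrum

#: Harmonic-number helper for the neutral SFS total.
def _harmonic(k: int) -> float:
    return float(np.sum(1.0 / np.arange(1, k + 1)))


def _sojourn_ratio(q: np.ndarray, gamma: float) -> np.ndarray:
    """(1 - exp(-gamma*(1-q))) / (1 - exp(-gamma)), stable for large |gamma|.

    This is the selected sojourn density relative to 1/(q(1-q)); it tends to
    (1-q) as gamma -> 0, recovering the neutral 1/q density.
    """
    q = np.asarray(q, dtype=float)
    if abs(gamma) < 1e-8:
        return 1.0 - q
    if gamma > 0:
        return np.expm1(-gamma * (1.0 - q)) / math.expm1(-gamma)
    g = -gamma

    def log_expm1(x):
        x = np.asarray(x, dtype=float)
        out = np.where(x > 30.0, x, np.log(np.expm1(np.minimum(x, 30.0))))
        return out

    return np.exp(log_expm1(g * (1.0 - q)) - log_expm1(g))


def sojourn_density(q: np.ndarray, gamma: float) -> np.ndarray:
    """Expected density of segregating sites at population frequency q
    for scaled selection gamma, normalised so that gamma = 0 gives 1/q."""
    q = np.asarray(q, dtype=float)
    return _sojourn_ratio(q, gamma) / (q * (1.0 - q))


@lru_cache(maxsize=4096)
def _expected_sfs_cached(gamma: float, n: int) -> tuple[float, ...]:
    out = np.empty(n - 1)
    log_binom = [
        math.lgamma(n + 1) - math.lgamma(i + 1) - math.lgamma(n - i + 1)
        for i in range(n + 1)
    ]
    for i in range(1, n):
        def integrand(q, i=i):
            # binomial sampling kernel times the sojourn density, with the
            # q(1-q) denominator folded in analytically
            lb = log_binom[i] + (i - 1) * math.log(q) + (n - i - 1) * math.log(1.0 - q)
            return math.exp(lb) * float(_sojourn_ratio(q, gamma))

        pts = [1e-6, 1e-4, 1e-2, 0.1, 0.5, 0.9, 0.99]
        val, _err = quad(integrand, 0.0, 1.0, points=pts, limit=200)
        out[i - 1] = val
    return tuple(out)


def expected_sfs_selected(gamma: float, n: int) -> np.ndarray:
    """Expected sampled SFS (relative class densities) under selection.

    Class ``i`` (of ``n`` sampled haploids) has expected density

        S_i(gamma) = integral  f(q; gamma) * Binomial(i; n, q)  dq

    with the sojourn density ``f`` of :func:`sojourn_density`.  The
    normalisation is per unit theta: at gamma = 0, ``S_i = 1/i``, so the
    expected count in class i of a neutral locus is ``theta_locus / i``.
    """
    if n < 2:
        raise ValueError("sample size must be >= 2")
    return np.array(_expected_sfs_cached(float(gamma), int(n)))


def relative_fixation_rate(gamma: float) -> float:
    """Fixation probability of a new mutation relative to neutral,
    u(gamma) = gamma / (1 - exp(-gamma)), with u(0) = 1."""
    if abs(gamma) < 1e-8:
        return 1.0
    if gamma > 0:
        return gamma / (1.0 - math.exp(-gamma))
    g = -gamma
    if g > 700.0:  # expm1 overflows; the rate is numerically zero anyway
        return 0.0
    return g / math.expm1(g)  # == gamma/(1-e^-gamma) for gamma<0, underflow-safe


def discretize_dfe(gamma_del: float, beta: float, k: int = 24) -> np.ndarray:
    """Equal-probability midpoint discretisation of the deleterious DFE.

    Scaled coefficients are drawn as ``-Gamma(shape=beta, mean=|gamma_del|)``;
    returns ``k`` negative support points with weight 1/k each.  A zero mean
    collapses to the neutral point mass.
    """
    if beta <= 0:
        raise ValueError("DFE shape beta must be positive")
    mean = abs(gamma_del)
    if mean == 0:
        return np.zeros(k)
    probs = (np.arange(k) + 0.5) / k
    return -gamma_dist.ppf(probs, a=beta, scale=mean / beta)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the PRF generator (scaled-selection convention 2*Ne*s).

    Defaults mirror the baseline forward-simulation scenario: per-site
    theta = rho = 0.001, Gamma-deleterious DFE with shape 0.3 and mean scaled
    strength 2000, point-mass beneficials at 2Nes = 250 arising at proportion
    p_a = 2.1e-4 of nonsynonymous mutations, total adaptive substitution
    fraction 0.4, samples of 20 haploids, and a gene model of five 300-bp
    exons split 0.75/0.25 into nonsynonymous/synonymous sites.
    """

    theta: float = 0.001
    rho: float = 0.001  # recorded only; sites are unlinked
    gamma_del: float = -2000.0
    beta: float = 0.3
    gamma_ben: float = 250.0
    gamma_weak: float = 5.0
    p_a: float = 0.00021
    alpha_target: float = 0.4
    alpha_weak_fraction: float = 0.0
    sample_size: int = 20
    n_genes: int = 14000
    mn_per_gene: float = 1125.0  # 5 exons x 300 bp x 0.75
    ms_per_gene: float = 375.0
    divergence_time_scale: float = 3.5
    dfe_points: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0.0 <= self.p_a <= 1.0:
            raise ValueError("p_a must lie in [0, 1]")
        if not 0.0 <= self.alpha_target < 1.0:
            raise ValueError("alpha_target must lie in [0, 1)")
        if self.sample_size < 4:
            raise ValueError("sample_size must be >= 4")
        if self.gamma_del > 0:
            raise ValueError("gamma_del is a deleterious strength and must be <= 0")


#: Scenario presets mirroring the forward-simulation parameter grid.
PRESETS: dict[str, dict] = {
    "baseline": {},
    "ben500": {"gamma_ben": 500.0, "p_a": 0.00012},
    "ben100": {"gamma_ben": 100.0, "p_a": 0.00048},
    "del1000": {"gamma_del": -1000.0},
    "del500": {"gamma_del": -500.0},
    "beta0.1": {"beta": 0.1, "p_a": 0.00115},
    "beta0.2": {"beta": 0.2, "p_a": 0.00048},
    "genes28000": {"n_genes": 28000},
    "genes2000": {"n_genes": 2000},
    "rho0.01": {"rho": 0.01},
    "rho0.0001": {"rho": 0.0001},
    "theta0.01": {"theta": 0.01},
    "theta0.0001": {"theta": 0.0001},
    "alpha0.1": {"alpha_target": 0.1, "p_a": 0.000036},
    "alpha0.7": {"alpha_target": 0.7, "p_a": 0.00075},
    "neutral": {"p_a": 0.0, "gamma_del": 0.0, "alpha_target": 0.0},
}


def preset_config(name: str, **overrides) -> SyntheticConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; valid: {', '.join(sorted(PRESETS))}")
    return SyntheticConfig(**{**PRESETS[name], **overrides})


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded while generating a dataset.

    ``realized_alpha`` is the exact fraction of nonsynonymous fixations that
    were drawn from a beneficial class.  ``expected_del_sfs`` is the per-gene
    expected count of deleterious-origin segregating sites in each frequency
    class, from which the expected below-cutoff SDM load follows.
    """

    realized_alpha: float
    n_fixations_beneficial: int
    n_fixations_total: int
    per_gene_dn_beneficial: np.ndarray
    per_gene_dn_background: np.ndarray
    expected_del_sfs: np.ndarray
    sample_size: int

    def expected_pwd_below_cutoff(self, cutoff: float) -> float:
        """Per-gene expected deleterious segregating sites below the cutoff."""
        freqs = np.arange(1, len(self.expected_del_sfs) + 1) / self.sample_size
        return float(self.expected_del_sfs[freqs < cutoff].sum())


def _class_expectations(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Per-unit-theta expected SFS for each mutation class."""
    n = config.sample_size
    neutral = expected_sfs_selected(0.0, n)
    dfe = discretize_dfe(config.gamma_del, config.beta, config.dfe_points)
    del_avg = np.mean([expected_sfs_selected(g, n) for g in dfe], axis=0)
    out = {"neutral": neutral, "deleterious": del_avg, "dfe": dfe}
    if config.p_a > 0:
        out["beneficial"] = expected_sfs_selected(config.gamma_ben, n)
        out["weak_beneficial"] = (
            expected_sfs_selected(config.gamma_weak, n)
            if config.alpha_weak_fraction > 0
            else None
        )
    return out


def simulate_dataset(
    config: SyntheticConfig,
) -> tuple[list[GeneVariationRecord], SyntheticTruth]:
    """Generate a gene set with recorded ground truth.

    Synonymous sites are neutral; nonsynonymous mutations are beneficial with
    probability ``p_a`` (split between strong and weak classes by
    ``alpha_weak_fraction``) and Gamma-deleterious otherwise.  Divergence is
    drawn per class: background (neutral leak through the DFE plus weak/strong
    beneficial sojourn is not modelled separately -- fixations of deleterious
    alleles use the diffusion fixation rate) and an adaptive class scaled so
    the beneficial share of nonsynonymous fixations is ``alpha_target`` in
    expectation.  Every fixation carries its class label, so the realized
    alpha is exact.
    """
    n = config.sample_size
    rng = np.random.default_rng(config.seed)
    exp = _class_expectations(config)

    theta_s = config.theta * config.ms_per_gene
    theta_n = config.theta * config.mn_per_gene

    syn_expect = theta_s * exp["neutral"]
    del_expect = theta_n * (1.0 - config.p_a) * exp["deleterious"]
    nonsyn_expect = del_expect.copy()
    if config.p_a > 0:
        w = config.alpha_weak_fraction
        ben_expect = theta_n * config.p_a * (1.0 - w) * exp["beneficial"]
        nonsyn_expect = nonsyn_expect + ben_expect
        if w > 0:
            nonsyn_expect = nonsyn_expect + theta_n * config.p_a * w * exp["weak_beneficial"]

    # divergence expectations per gene
    t_scale = config.divergence_time_scale
    ds_expect = theta_s * t_scale
    u_bg = float(np.mean([relative_fixation_rate(g) for g in exp["dfe"]]))
    dn_bg_expect = theta_n * t_scale * (1.0 - config.p_a) * u_bg
    if config.alpha_target > 0 and dn_bg_expect > 0:
        dn_ben_expect = dn_bg_expect * config.alpha_target / (1.0 - config.alpha_target)
    else:
        dn_ben_expect = 0.0

    g = config.n_genes
    syn_counts = rng.poisson(np.broadcast_to(syn_expect, (g, n - 1)))
    nonsyn_counts = rng.poisson(np.broadcast_to(nonsyn_expect, (g, n - 1)))
    ds_draw = rng.poisson(ds_expect, g)
    dn_bg_draw = rng.poisson(dn_bg_expect, g)
    dn_ben_draw = rng.poisson(dn_ben_expect, g)

    records = [
        GeneVariationRecord(
            gene_id=f"g{i:05d}",
            sfs_n=SiteFrequencySpectrum(n, nonsyn_counts[i]),
            sfs_s=SiteFrequencySpectrum(n, syn_counts[i]),
            dn=int(dn_bg_draw[i] + dn_ben_draw[i]),
            ds=int(ds_draw[i]),
            mn=config.mn_per_gene,
            ms=config.ms_per_gene,
        )
        for i in range(g)
    ]
    n_ben = int(dn_ben_draw.sum())
    n_tot = int(dn_bg_draw.sum() + dn_ben_draw.sum())
    truth = SyntheticTruth(
        realized_alpha=n_ben / n_tot if n_tot else 0.0,
        n_fixations_beneficial=n_ben,
        n_fixations_total=n_tot,
        per_gene_dn_beneficial=dn_ben_draw,
        per_gene_dn_background=dn_bg_draw,
        expected_del_sfs=del_expect,
        sample_size=n,
    )
    return records, truth
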