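# Methods

## Data model and conventions

A gene is summarised by paired site frequency spectra (SFS) for
nonsynonymous and synonymous segregating sites at a fixed sample size `n`
(haploid sequences), fixed-difference counts `D_N`, `D_S`, and analysed
site counts `m_N`, `m_S`.  No genomic coordinates are modelled.

* **Frequency convention.**  Class `i` of an unfolded SFS has derived-allele
  frequency `i/n`; a class is *below* a cutoff `c` iff `i/n < c` (strict).
  At `n = 20` and `c = 0.15`, classes 1–2 are below and class 3 (frequency
  exactly 0.15) is above.  On a folded SFS the same rule applies to
  minor-allele frequency, which removes both the `DAF < c` and `DAF > 1−c`
  tails at once.
* **Analyzability.**  A gene is not analyzable when `P_S`, `D_N` or `D_S`
  is zero, or when the above-cutoff synonymous band needed by a cutoff
  method is empty.  Such genes are reported with NaN statistics and counted
  separately; pooled analyses track the analyzable fraction per replicate.
* **Rounding.**  Imputed (real-valued) quantities enter the Fisher 2×2
  table rounded half-away-from-zero; alpha and the DFE fractions always use
  the unrounded values, keeping the estimators continuous in the data.
* **Projection.**  Downsampling an SFS to `m < n` uses the hypergeometric
  expectation; mass that becomes monomorphic is dropped, mirroring what a
  smaller sample would observe.  Expectations are real-valued; an optional
  seeded stochastic rounding produces integer spectra.

## The test family

All methods share the 2×2 contingency test (two-sided Fisher exact, via
`scipy.stats.fisher_exact`; empty margins yield P = 1 with a flag) and the
estimator `alpha = 1 − (P_N/P_S)(D_S/D_N)` applied to their adjusted
polymorphism cells:

* **Standard MKT** — no adjustment.
* **fwwMKT(c)** — drops all polymorphism below `c` from both classes.
* **eMKT(c)** — scales `P_N` by the synonymous below-cutoff fraction
  `f_neutral = P_S(<c)/P_S`: `P_N_neutral = P_N·f_neutral + P_N(≥c)`.  The
  published description is ambiguous about whether the total or the
  below-cutoff `P_N` is scaled; the total is used here, with the
  alternative reading available via `neutral_from_low_band=True`.
* **impMKT(c)** — imputes `P_wd = P_N(<c) − P_N(≥c)·P_S(<c)/P_S(≥c)`,
  clamped to `[0, P_N(<c)]` (a negative imputation — more constraint below
  the cutoff than above — is treated as 0 and flagged rather than allowed
  to inflate `P_N`), and removes only `P_wd` from the nonsynonymous cell.
  Note the identity `(P_N − P_wd)/P_S = P_N(≥c)/P_S(≥c)` (when unclamped):
  impMKT and fwwMKT give the *same* alpha point estimate and differ in the
  power of the 2×2 test, which is the point of the imputation.
* **impMKT-high(l, h)** — for spectra distorted by slightly beneficial
  alleles accumulating at high frequency: the mid band `l ≤ x < h` provides
  the neutral ratio; the low-frequency SDM are removed as above, while the
  high-frequency excess `X = max(0, P_N(≥h) − r·P_S(≥h))` is *moved* into
  the nonsynonymous divergence cell (near-fixed adaptive alleles are
  incipient substitutions).  Requires an unfolded SFS.
* **DFE fractions** — `d = 1 − (P_N/P_S)(m_S/m_N)` (strongly deleterious,
  absent from polymorphism), `d_w = (P_wd/P_S)(m_S/m_N)` (segregating SDM),
  `d_0 = 1 − d − d_w`; they sum to one by construction.

The orientation of the divergence ratio in the imputed-alpha expression is
taken as `D_S/D_N` (the published typesetting is ambiguous); this is the
only orientation consistent with the standard alpha definition and with the
sign of the reported gene-level estimates.

Exclusion bookkeeping reports, for every method, the share of the gene's
polymorphic sites (`P_N + P_S`) removed from the test: 0 for the standard
MKT, `(P_N(<c)+P_S(<c))/(P_N+P_S)` for fwwMKT, `round(P_wd)/(P_N+P_S)` for
impMKT.  On the worked example these are 46% and 18% respectively (the
latter is sometimes quoted as 15% with an unreconstructible denominator;
the total-polymorphism denominator is used consistently here).

Batch output reports raw P-values; Benjamini–Hochberg adjustment is
available as an opt-in extra column and never drives the classification
(positive / negative / non-significant at a caller-chosen significance
level, defaulting to 0.05).

## Asymptotic MKT

`alpha(x_i) = 1 − (D_S/D_N)·(P_N(i)/P_S(i))` per frequency bin (cumulative
variant optional), with empty synonymous bins masked.  The exponential
`a + b·e^(−cx)` is fitted by bounded least squares (`c ∈ (0, 100]`,
multi-start from three decay rates — the model is ill-conditioned when
alpha(x) is near-linear) on bins inside a trim interval, default
`[0.1, 0.9]`: the lowest bins are SDM-dominated and the highest are prone
to polarization error.  The exact published trim values are not stated
anywhere reproducible; these defaults are declared choices and
configurable.  `alpha(1) = a + b·e^(−c)` is reported with a percentile
bootstrap CI over resampled bins (500 replicates by default, seeded); if
the exponential fails to converge a linear fit is used and flagged.

## Pooling

Pooling sums both spectra and all scalar counts across genes.  The
bootstrap design draws genes with replacement for each pool size on the
grid `1, 2, 5, 10, 25, 50, 75, 100, 250, 500, 750, 1000` (1,000 replicates
by default), runs one configured method per pooled record, and reports the
mean, the empirical 2.5/97.5 percentiles (linear interpolation), and the
analyzable fraction.  Per-(pool size, replicate) RNG streams are spawned
from the master seed, so results are bit-reproducible and independent of
evaluation order.  Pooling heterogeneous genes can reverse the sign of
alpha relative to every per-gene estimate (Simpson's paradox, driven by
unequal divergence margins); the test suite constructs such a case.

## Synthetic data generator

A Poisson-Random-Field sampler stands in for forward simulation: sites are
independent, and a mutation class with scaled selection coefficient
`gamma = 2·Ne·s` contributes an expected sampled SFS

    S_i(gamma) = ∫ f(q; gamma) · Binomial(i; n, q) dq,
    f(q; gamma) = (1 − e^(−gamma(1−q))) / (q(1−q)(1 − e^(−gamma))),

normalised so the neutral limit is `S_i = 1/i` per unit locus theta
(verified to 1e−6 in the tests; the strong-purifying limit concentrates
more than 99% of mass in singletons at n = 20).  Relative fixation rates
are `u(gamma) = gamma/(1 − e^(−gamma))`.  Both integrals are evaluated with
adaptive quadrature on overflow-safe forms and cached per `(gamma, n)`.

Per gene: synonymous counts are Poisson around `theta·m_S·S_i(0)`;
nonsynonymous mutations are beneficial with probability `p_a` (point mass
at `gamma_ben`, optionally split with a weak class at `gamma_weak` by
`alpha_weak_fraction`) and otherwise deleterious with `gamma` drawn from
`−Gamma(shape β, mean |gamma_del|)`, discretised into 24 equal-probability
support points.  Divergence: `D_S` is Poisson around
`theta·m_S·T`, where `T` (`divergence_time_scale`, default 3.5) is the
expected number of neutral substitutions per site over the divergence
period in units of theta — chosen so per-gene `D_S` is of the same order as
`P_S`, keeping the 2×2 tables balanced.  Background nonsynonymous
fixations are Poisson around `theta·m_N·T·(1−p_a)·E[u(gamma)]` over the
DFE; adaptive fixations are a separate Poisson stream scaled so their
expected share is `alpha_target`.  Because every fixation is drawn from a
labelled stream, the **realized** adaptive fraction is recorded exactly,
and estimator validation compares against it rather than the nominal
target.

Defaults are the baseline scenario of the simulation study the generator
emulates: `theta = rho = 0.001` per site, `gamma_del = −2000`, `β = 0.3`,
`gamma_ben = 250`, `p_a = 2.1e−4`, `alpha_target = 0.4`, `n = 20`,
five 300-bp exons per gene split 0.75/0.25 into nonsynonymous/synonymous
sites (m_N = 1125, m_S = 375), 14,000 genes; named presets cover the
parameter grid (selection strengths, DFE shapes, theta, gene counts,
adaptation rates).  A consistency check on these defaults: with the
package's fixation rates, `p_a = 2.1e−4` at `gamma_ben = 250` implies an
adaptive fraction `0.385 ≈ 0.4`, matching the nominal target of the
emulated study.

**What the generator does not emulate.**  `rho` is recorded but unused:
sites are unlinked, so background selection, Hill–Robertson interference
and hitchhiking are absent.  This matters for estimator validation: in the
free-recombination PRF, deleterious alleles with `gamma` between roughly
−20 and −1 carry about 17% more above-35%-frequency SFS mass than their
share of fixations, so the imputation's neutral ratio slightly over-counts
neutral polymorphism and `alpha_imp(0.35)` retains a residual downward
bias of ≈ 0.10 at the baseline DFE (the corresponding figure under linked
forward simulation is smaller).  Passing recovery tests therefore
demonstrate the estimator ordering and approximate recovery under
independent sites, not linkage robustness.  Demography is stationary;
ancestral-state misidentification is not modelled (folded-mode analysis is
supported for data where polarization is unreliable).

## Evaluation sizes and numerical choices

Recovery checks run on 2,000–3,000 genes (pooled ≈ 4,000–6,000 segregating
sites), neutral-limit checks on 500 genes with a 200-replicate gene
bootstrap for the standard error — sizes at which Monte-Carlo error is a
few hundredths of an alpha unit while the full suite stays fast.  Fisher
exactness is verified against exhaustive fixed-margin enumeration in exact
rational arithmetic for every table with grand total ≤ 40 (18,215 distinct
tables after symmetry reduction; worst relative deviation < 1e−9).
Degenerate inputs (zero margins, empty bands, refolding, mixed sample
sizes) raise explicit errors or return flagged unanalyzable results rather
than propagating NaNs silently.

## Known limitations

* The imputation assumes SDM segregate only below the cutoff; when
  constraint is strong and SDM are rare, the imputation removes real
  neutral data and the standard MKT can be preferable (the clamp flag marks
  imputations driven to the boundary).
* Heuristic cutoff methods cannot correct weak adaptation spread across
  the whole spectrum; `imp_mkt_high` handles only a high-frequency excess.
* The generator's truth-by-construction design records the adaptive share
  of fixations directly; it does not reproduce any analytical
  fixation-probability pipeline, and its divergence clock ignores ancestral
  polymorphism.
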