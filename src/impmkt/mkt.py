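"""The 2x2 McDonald-Kreitman test family.

The McDonald-Kreitman test contrasts the nonsynonymous/synonymous ratio in
polymorphism (P_N/P_S) with the same ratio in divergence (D_N/D_S); an excess
of the divergence ratio signals recurrent positive selection, quantified by
the adaptive-substitution fraction

    alpha = 1 - (P_N / P_S) * (D_S / D_N).

Slightly deleterious mutations (SDM) segregate at low frequencies, inflate
P_N and bias alpha downward.  The variants implemented here differ in how
they handle that low-frequency band:

* ``standard_mkt``   -- no correction;
* ``fww_mkt``        -- drop every polymorphic site below a frequency cutoff;
* ``emkt``           -- decompose P_N into neutral and deleterious parts using
                        the synonymous spectrum's below-cutoff fraction;
* ``imp_mkt``        -- impute the SDM count P_wd from the above-cutoff
                        P_N/P_S ratio and remove only that many sites (the
                        imputed MKT);
* ``imp_mkt_high``   -- additionally move an imputed high-frequency
                        nonsynonymous excess (slightly beneficial alleles)
                        into the divergence cell.

All tests report a two-sided Fisher exact P-value on the integer-rounded
contingency table; alpha and the DFE fractions use unrounded quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control
from scipy.stats import fisher_exact as _scipy_fisher

from .sfs import BandCounts, GeneVariationRecord, band_counts, three_band_counts

METHODS = ("mkt", "fww", "emkt", "imp", "imp_high")

#: Frequency cutoffs explored in practice; 0.15 is the conventional default,
#: larger cutoffs (0.25, 0.35) handle heavier SDM loads.
DEFAULT_CUTOFF = 0.15
CUTOFF_PRESETS = (0.05, 0.15, 0.25, 0.35)


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (4.5 -> 5, -4.5 -> -5)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 MKT table: polymorphism column (pn, ps), divergence column (dn, ds)."""

    pn_cell: int
    ps_cell: int
    dn_cell: int
    ds_cell: int

    def __post_init__(self) -> None:
        for v in (self.pn_cell, self.ps_cell, self.dn_cell, self.ds_cell):
            if v < 0 or int(v) != v:
                raise ValueError(f"contingency cells must be non-negative integers, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.pn_cell, self.dn_cell], [self.ps_cell, self.ds_cell]], dtype=int
        )


class GeneClass(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NON_SIGNIFICANT = "non-significant"
    NON_ANALYZABLE = "non-analyzable"


@dataclass(frozen=True)
class MKTResult:
    """Outcome of one MKT variant on one gene (or gene pool)."""

    method: str
    gene_id: str
    table: ContingencyTable | None
    alpha: float
    p_value: float
    cutoff: float | None = None
    high_cutoff: float | None = None
    pwd: float = 0.0
    pneut: float = float("nan")
    f_neutral: float = float("nan")
    excluded_fraction: float = 0.0
    analyzable: bool = True
    pwd_clamped: bool = False
    zero_margin: bool = False

    def classify(self, significance: float = 0.05) -> GeneClass:
        return classify_gene(self, significance)


def fisher_exact(table: ContingencyTable) -> tuple[float, bool]:
    """Two-sided Fisher exact P-value for a 2x2 table.

    Returns ``(p, zero_margin)``; a table with an empty row or column carries
    no information about association and is reported as ``p = 1`` with the
    flag set.
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        return 1.0, True
    return float(_scipy_fisher(arr, alternative="two-sided").pvalue), False


def _alpha(pn: float, ps: float, dn: float, ds: float) -> float:
    return 1.0 - (pn / ps) * (ds / dn)


def _not_analyzable(method: str, record: GeneVariationRecord, **kw) -> MKTResult:
    return MKTResult(
        method=method,
        gene_id=record.gene_id,
        table=None,
        alpha=float("nan"),
        p_value=float("nan"),
        analyzable=False,
        **kw,
    )


def _base_analyzable(record: GeneVariationRecord) -> bool:
    # genes with zero divergence or zero polymorphism cannot be tested
    return record.ps > 0 and record.dn > 0 and record.ds > 0


def _finish(
    method: str,
    record: GeneVariationRecord,
    pn_cell_raw: float,
    ps_cell_raw: float,
    dn_cell_raw: float,
    ds_cell_raw: float,
    alpha: float,
    **kw,
) -> MKTResult:
    table = ContingencyTable(
        round_half_away(pn_cell_raw),
        round_half_away(ps_cell_raw),
        round_half_away(dn_cell_raw),
        round_half_away(ds_cell_raw),
    )
    p, zero_margin = fisher_exact(table)
    return MKTResult(
        method=method,
        gene_id=record.gene_id,
        table=table,
        alpha=alpha,
        p_value=p,
        zero_margin=zero_margin,
        **kw,
    )


def standard_mkt(record: GeneVariationRecord) -> MKTResult:
    """Original MKT: full polymorphism counts against divergence counts."""
    if not _base_analyzable(record) or record.pn + record.ps == 0:
        return _not_analyzable("mkt", record)
    alpha = _alpha(record.pn, record.ps, record.dn, record.ds)
    return _finish("mkt", record, record.pn, record.ps, record.dn, record.ds, alpha)


def fww_mkt(record: GeneVariationRecord, cutoff: float = DEFAULT_CUTOFF) -> MKTResult:
    """Fay-Wyckoff-Wu MKT: drop all polymorphism below the frequency cutoff."""
    if not _base_analyzable(record):
        return _not_analyzable("fww", record, cutoff=cutoff)
    b = band_counts(record, cutoff)
    if b.ps_high == 0:
        return _not_analyzable("fww", record, cutoff=cutoff)
    alpha = _alpha(b.pn_high, b.ps_high, record.dn, record.ds)
    excluded = (b.pn_low + b.ps_low) / (record.pn + record.ps)
    return _finish(
        "fww",
        record,
        b.pn_high,
        b.ps_high,
        record.dn,
        record.ds,
        alpha,
        cutoff=cutoff,
        excluded_fraction=excluded,
    )


def emkt(
    record: GeneVariationRecord,
    cutoff: float = DEFAULT_CUTOFF,
    *,
    neutral_from_low_band: bool = False,
) -> MKTResult:
    """Extended MKT: estimate the neutral share of P_N from the synonymous SFS.

    ``f_neutral = P_S(<c)/P_S`` is the synonymous below-cutoff fraction; the
    neutral nonsynonymous count is ``P_N * f_neutral + P_N(>=c)``.  With
    ``neutral_from_low_band`` the below-cutoff nonsynonymous count is scaled
    instead of the total (an alternative reading of the estimator).
    """
    if not _base_analyzable(record):
        return _not_analyzable("emkt", record, cutoff=cutoff)
    b = band_counts(record, cutoff)
    f_neutral = b.ps_low / record.ps
    base = b.pn_low if neutral_from_low_band else record.pn
    pn_neutral = base * f_neutral + b.pn_high
    alpha = _alpha(pn_neutral, record.ps, record.dn, record.ds)
    excluded = max(record.pn - pn_neutral, 0.0) / (record.pn + record.ps)
    return _finish(
        "emkt",
        record,
        pn_neutral,
        record.ps,
        record.dn,
        record.ds,
        alpha,
        cutoff=cutoff,
        f_neutral=f_neutral,
        pneut=pn_neutral,
        excluded_fraction=excluded,
    )


def impute_pwd(bands: BandCounts) -> tuple[float, float, bool]:
    """Impute the slightly-deleterious count P_wd from band counts.

    Under neutrality the below-cutoff P_N/P_S ratio matches the above-cutoff
    one; any excess of nonsynonymous sites below the cutoff is attributed to
    SDM::

        P_wd = P_N(<c) - P_N(>=c) * P_S(<c) / P_S(>=c)

    Returns ``(pwd, pwd_raw, clamped)`` where ``pwd`` is clamped to
    ``[0, P_N(<c)]`` and ``pwd_raw`` is the unclamped value.
    """
    if bands.ps_high == 0:
        raise ValueError("P_S at or above the cutoff is zero; imputation ratio undefined")
    raw = bands.pn_low - bands.pn_high * bands.ps_low / bands.ps_high
    clamped_val = min(max(raw, 0.0), bands.pn_low)
    return clamped_val, raw, clamped_val != raw


def imp_mkt(record: GeneVariationRecord, cutoff: float = DEFAULT_CUTOFF) -> MKTResult:
    """Imputed MKT: remove only the imputed SDM count from P_N.

    The synonymous cell is left untouched, so far less data is discarded than
    under the frequency-cutoff approach; alpha uses the unrounded P_wd while
    the Fisher table uses integer cells.
    """
    if not _base_analyzable(record):
        return _not_analyzable("imp", record, cutoff=cutoff)
    b = band_counts(record, cutoff)
    if b.ps_high == 0:
        return _not_analyzable("imp", record, cutoff=cutoff)
    pwd, _raw, clamped = impute_pwd(b)
    pneut = record.pn - pwd
    alpha = _alpha(pneut, record.ps, record.dn, record.ds)
    excluded = round_half_away(pwd) / (record.pn + record.ps)
    return _finish(
        "imp",
        record,
        pneut,
        record.ps,
        record.dn,
        record.ds,
        alpha,
        cutoff=cutoff,
        pwd=pwd,
        pneut=pneut,
        excluded_fraction=excluded,
        pwd_clamped=clamped,
    )


def imp_mkt_high(
    record: GeneVariationRecord,
    low_cutoff: float = DEFAULT_CUTOFF,
    high_cutoff: float = 0.85,
) -> MKTResult:
    """Imputed MKT with a high-frequency correction for slightly beneficial alleles.

    The mid band ``low <= freq < high`` provides the expected neutral
    P_N/P_S ratio ``r``.  Low-frequency SDM are imputed and removed as in
    :func:`imp_mkt`; the high-frequency nonsynonymous excess
    ``X = max(0, P_N(>=h) - r * P_S(>=h))`` is not removed but moved into the
    nonsynonymous divergence cell (these near-fixed alleles are treated as
    incipient substitutions).
    """
    if not _base_analyzable(record):
        return _not_analyzable("imp_high", record, cutoff=low_cutoff, high_cutoff=high_cutoff)
    bn, bs = three_band_counts(record, low_cutoff, high_cutoff)
    if bs[1] == 0:
        return _not_analyzable("imp_high", record, cutoff=low_cutoff, high_cutoff=high_cutoff)
    r = bn[1] / bs[1]
    x_high = max(0.0, bn[2] - r * bs[2])
    raw = bn[0] - r * bs[0]
    pwd = min(max(raw, 0.0), float(bn[0]))
    pneut = record.pn - pwd - x_high
    dn_adj = record.dn + x_high
    alpha = _alpha(pneut, record.ps, dn_adj, record.ds)
    excluded = round_half_away(pwd) / (record.pn + record.ps)
    return _finish(
        "imp_high",
        record,
        pneut,
        record.ps,
        dn_adj,
        record.ds,
        alpha,
        cutoff=low_cutoff,
        high_cutoff=high_cutoff,
        pwd=pwd,
        pneut=pneut,
        excluded_fraction=excluded,
        pwd_clamped=pwd != raw,
    )


@dataclass(frozen=True)
class DStats:
    """Heuristic DFE fractions at nonsynonymous sites.

    ``d``: strongly deleterious (missing from polymorphism entirely),
    ``dw``: slightly deleterious (the imputed segregating SDM),
    ``d0``: effectively neutral (the remainder); they sum to one by
    construction.
    """

    d: float
    dw: float
    d0: float


def d_stats(record: GeneVariationRecord, cutoff: float = DEFAULT_CUTOFF) -> DStats:
    """Estimate the strongly deleterious / SDM / neutral fractions.

    d  = 1 - (P_N/P_S) * (m_S/m_N)
    dw = (P_wd/P_S) * (m_S/m_N)         (unrounded P_wd)
    d0 = 1 - d - dw
    """
    if record.ps <= 0:
        raise ValueError("d statistics require synonymous polymorphism (P_S > 0)")
    b = band_counts(record, cutoff)
    pwd, _, _ = impute_pwd(b)
    ratio = record.ms / record.mn
    d = 1.0 - (record.pn / record.ps) * ratio
    dw = (pwd / record.ps) * ratio
    return DStats(d=d, dw=dw, d0=1.0 - d - dw)


def classify_gene(result: MKTResult, significance: float = 0.05) -> GeneClass:
    """Label a gene by its MKT outcome at the given significance level."""
    if not result.analyzable:
        return GeneClass.NON_ANALYZABLE
    if result.p_value < significance and result.alpha > 0:
        return GeneClass.POSITIVE
    if result.p_value < significance and result.alpha < 0:
        return GeneClass.NEGATIVE
    return GeneClass.NON_SIGNIFICANT


def run_method(
    record: GeneVariationRecord,
    method: str,
    cutoff: float = DEFAULT_CUTOFF,
    high_cutoff: float = 0.85,
) -> MKTResult:
    """Dispatch a single MKT variant by name."""
    if method == "mkt":
        return standard_mkt(record)
    if method == "fww":
        return fww_mkt(record, cutoff)
    if method == "emkt":
        return emkt(record, cutoff)
    if method == "imp":
        return imp_mkt(record, cutoff)
    if method == "imp_high":
        return imp_mkt_high(record, cutoff, high_cutoff)
    raise ValueError(f"unknown MKT method {method!r}; valid methods: {', '.join(METHODS)}")


def run_batch(
    records: Iterable[GeneVariationRecord],
    methods: Sequence[str] = ("mkt", "imp"),
    cutoff: float = DEFAULT_CUTOFF,
    high_cutoff: float = 0.85,
    significance: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Run one or more MKT variants over a gene set.

    Returns one row per gene per method with the contingency cells, alpha,
    raw P-value and classification.  With ``bh_correction`` a
    Benjamini-Hochberg adjusted column (per method, over analyzable genes)
    is appended; classification always uses raw P-values.
    """
    rows = []
    for rec in records:
        for method in methods:
            res = run_method(rec, method, cutoff, high_cutoff)
            t = res.table
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "method": method,
                    "cutoff": res.cutoff if res.cutoff is not None else float("nan"),
                    "pn_cell": t.pn_cell if t else float("nan"),
                    "ps_cell": t.ps_cell if t else float("nan"),
                    "dn": t.dn_cell if t else float("nan"),
                    "ds": t.ds_cell if t else float("nan"),
                    "pwd": res.pwd,
                    "alpha": res.alpha,
                    "p_value": res.p_value,
                    "class": classify_gene(res, significance).value,
                }
            )
    df = pd.DataFrame(rows)
    if bh_correction and not df.empty:
        df["p_bh"] = float("nan")
        for method in df["method"].unique():
            mask = (df["method"] == method) & df["p_value"].notna()
            if mask.any():
                df.loc[mask, "p_bh"] = false_discovery_control(
                    df.loc[mask, "p_value"].to_numpy(), method="bh"
                )
    return df
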