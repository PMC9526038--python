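"""Readers and writers for the gene-table formats.

Two dialects are supported:

* the primary gene-table TSV, one row per gene::

      gene_id  n  folded  sfs_n  sfs_s  dn  ds  mn  ms

  where ``sfs_n``/``sfs_s`` are comma-separated counts of length ``n-1``
  (unfolded) or ``floor(n/2)`` (folded);

* the two-file DAF/DIV dialect: a DAF file with header ``daf Pi P0``
  (per-bin derived-allele frequency, nonsynonymous count, synonymous count)
  and a DIV file with header ``mi Di m0 D0``, one gene per file pair or many
  genes with a leading ``gene_id`` column.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sfs import GeneVariationRecord, SiteFrequencySpectrum

log = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = ["gene_id", "n", "folded", "sfs_n", "sfs_s", "dn", "ds", "mn", "ms"]


class GeneTableError(ValueError):
    """Malformed gene table; message carries the offending line number."""


def _parse_counts(text: str, what: str, line: int) -> np.ndarray:
    try:
        vals = np.array([float(x) for x in str(text).split(",")])
    except ValueError as exc:
        raise GeneTableError(f"line {line}: cannot parse {what}: {exc}") from None
    if np.any(vals < 0):
        raise GeneTableError(f"line {line}: negative counts in {what}")
    return vals


def read_gene_table(path: str | Path) -> list[GeneVariationRecord]:
    """Read the primary gene-table TSV into records.

    Raises :class:`GeneTableError` with a line number on malformed rows;
    an empty file yields an empty list with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise GeneTableError(f"{path}: missing column(s): {', '.join(missing)}")
    if df.empty:
        log.warning("%s: gene table is empty", path)
        return []
    records: list[GeneVariationRecord] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        if row.isna().any():
            bad = ", ".join(row.index[row.isna()])
            raise GeneTableError(f"line {line}: missing value(s) in column(s): {bad}")
        try:
            n = int(row["n"])
            folded = _parse_bool(row["folded"], line)
            sfs_n = SiteFrequencySpectrum(n, _parse_counts(row["sfs_n"], "sfs_n", line), folded)
            sfs_s = SiteFrequencySpectrum(n, _parse_counts(row["sfs_s"], "sfs_s", line), folded)
            rec = GeneVariationRecord(
                gene_id=str(row["gene_id"]),
                sfs_n=sfs_n,
                sfs_s=sfs_s,
                dn=float(row["dn"]),
                ds=float(row["ds"]),
                mn=float(row["mn"]),
                ms=float(row["ms"]),
            )
        except GeneTableError:
            raise
        except (ValueError, TypeError) as exc:
            raise GeneTableError(f"line {line}: {exc}") from None
        records.append(rec)
    sizes = {(r.sample_size, r.folded) for r in records}
    if len(sizes) > 1:
        log.warning("%s: mixed sample sizes/folding across genes: %s", path, sorted(sizes))
    return records


def _parse_bool(text: str, line: int) -> bool:
    t = str(text).strip().lower()
    if t in {"1", "true", "t", "yes"}:
        return True
    if t in {"0", "false", "f", "no"}:
        return False
    raise GeneTableError(f"line {line}: cannot parse folded flag {text!r}")


def _fmt_counts(counts: np.ndarray) -> str:
    out = []
    for v in counts:
        out.append(str(int(v)) if float(v).is_integer() else f"{v:.6g}")
    return ",".join(out)


def _fmt_num(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:.6g}"


def write_gene_table(path: str | Path, records: Iterable[GeneVariationRecord]) -> None:
    """Write records to the primary gene-table TSV (lossless for integers)."""
    rows = [
        {
            "gene_id": r.gene_id,
            "n": r.sample_size,
            "folded": int(r.folded),
            "sfs_n": _fmt_counts(r.sfs_n.counts),
            "sfs_s": _fmt_counts(r.sfs_s.counts),
            "dn": _fmt_num(r.dn),
            "ds": _fmt_num(r.ds),
            "mn": _fmt_num(r.mn),
            "ms": _fmt_num(r.ms),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_daf_div(
    daf_path: str | Path, div_path: str | Path, *, folded: bool = False
) -> list[GeneVariationRecord]:
    """Read the two-file DAF/DIV dialect.

    The DAF file carries per-bin frequencies and counts (``daf Pi P0``,
    nonsynonymous then synonymous); the DIV file carries totals
    (``mi Di m0 D0``).  The sample size is inferred from the frequency grid,
    which must equal ``i/n`` for consecutive ``i``.  A ``gene_id`` column in
    both files encodes multiple genes; without it each file pair is one gene.
    """
    daf = pd.read_csv(daf_path, sep=r"\s+")
    div = pd.read_csv(div_path, sep=r"\s+")
    for col in ("daf", "Pi", "P0"):
        if col not in daf.columns:
            raise GeneTableError(f"{daf_path}: missing column {col!r}")
    for col in ("mi", "Di", "m0", "D0"):
        if col not in div.columns:
            raise GeneTableError(f"{div_path}: missing column {col!r}")
    has_id = "gene_id" in daf.columns
    if has_id != ("gene_id" in div.columns):
        raise GeneTableError("gene_id column must appear in both files or neither")
    if not has_id:
        daf = daf.assign(gene_id="gene")
        div = div.assign(gene_id="gene")
    records = []
    div = div.set_index("gene_id")
    for gid, grp in daf.groupby("gene_id", sort=False):
        freqs = grp["daf"].to_numpy(dtype=float)
        k = len(freqs)
        n = k * 2 if folded else k + 1
        expected = (np.arange(1, k + 1)) / n
        if not np.allclose(np.sort(freqs), expected, atol=1e-6):
            raise GeneTableError(
                f"gene {gid!r}: daf grid is not i/n for consecutive i "
                f"(got {np.sort(freqs)!r})"
            )
        order = np.argsort(freqs)
        sfs_n = SiteFrequencySpectrum(n, grp["Pi"].to_numpy(dtype=float)[order], folded)
        sfs_s = SiteFrequencySpectrum(n, grp["P0"].to_numpy(dtype=float)[order], folded)
        if gid not in div.index:
            raise GeneTableError(f"gene {gid!r}: present in DAF file but not DIV file")
        d = div.loc[gid]
        records.append(
            GeneVariationRecord(
                gene_id=str(gid),
                sfs_n=sfs_n,
                sfs_s=sfs_s,
                dn=float(d["Di"]),
                ds=float(d["D0"]),
                mn=float(d["mi"]),
                ms=float(d["m0"]),
            )
        )
    return records


def write_results(path: str | Path, results: pd.DataFrame | Sequence[dict]) -> None:
    """Write a result table as TSV with floats at 6 significant digits."""
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(list(results))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
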