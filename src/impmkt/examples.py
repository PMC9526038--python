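"""Packaged example data.

The worked example is a hypothetical gene with 11 nonsynonymous and 17
synonymous segregating sites (7 and 6 of them below 15% derived-allele
frequency), 15 nonsynonymous and 8 synonymous fixed differences, sampled at
n = 20.  The per-class SFS layout inside each frequency band is a synthetic
reconstruction (only the band totals are determined); every statistic the
package computes from it depends on the band totals alone.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import read_gene_table
from .sfs import GeneVariationRecord


def worked_example_path() -> Path:
    """Path of the packaged worked-example gene table."""
    return Path(resources.files("impmkt").joinpath("data/worked_example.tsv"))


def worked_example() -> GeneVariationRecord:
    """The worked-example gene as a record."""
    return read_gene_table(worked_example_path())[0]
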