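"""qPCR gene-copy to cell-abundance conversion.

qPCR yields marker-gene copies per gram (wet weight) of sample. Cell
densities follow by dividing by the average gene copy number per genome:
multi-copy rrn operons for 16S (defaults: 3.6 for bacteria, 1.2 for
archaea), single copy for the functional markers mcrA and dsrB. Domain
and guild fractions (archaea among prokaryotes, methanogens among
archaea, sulfate reducers among bacteria) are ratios of those densities.

All arithmetic is done on unrounded intermediates; rounding (2 significant
figures on densities, 1 decimal on percentages) happens only at report
time so printed roundings do not compound.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "QpcrMeasurement",
    "GenomeCopyModel",
    "CellEstimate",
    "cells_from_copies",
    "domain_fraction",
    "guild_fraction",
    "round_sig",
    "cell_table",
]

#: Average marker copies per genome. 16S counts are rrn-operon averages
#: from genome surveys; mcrA and dsrB are taken as single-copy.
DEFAULT_COPIES_PER_GENOME = {
    "16S-bacteria": 3.6,
    "16S-archaea": 1.2,
    "mcrA": 1.0,
    "dsrB": 1.0,
}


@dataclass(frozen=True)
class QpcrMeasurement:
    target: str
    copies_per_gww: float
    sd: float = 0.0
    year: int = 0

    def __post_init__(self) -> None:
        if self.copies_per_gww < 0 or self.sd < 0:
            raise ValueError("copies_per_gww and sd must be >= 0")


@dataclass(frozen=True)
class GenomeCopyModel:
    copies_per_genome: dict = field(
        default_factory=lambda: dict(DEFAULT_COPIES_PER_GENOME)
    )

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.copies_per_genome.values()):
            raise ValueError("copies per genome must be >= 1")

    def for_target(self, target: str) -> float:
        try:
            return self.copies_per_genome[target]
        except KeyError:
            raise KeyError(f"no copy number for target {target!r}") from None


@dataclass(frozen=True)
class CellEstimate:
    """Cell density derived from a copy density.

    `sd` is the linearly propagated uncertainty (copy sd scaled by the
    copy number); `sd_unscaled` carries the copy-density sd through
    unchanged, a reporting convention some tables use.
    """

    target: str
    cells_per_gww: float
    sd: float = 0.0
    sd_unscaled: float = 0.0
    year: int = 0


def round_sig(x: float, sig: int = 2) -> float:
    """Round to `sig` significant figures; exact halves round toward zero.

    The value is first quantized to 12 significant digits so binary float
    noise (e.g. 4.5e6/1.2 = 3750000.0000000005) cannot tip a half-way
    case. Half-toward-zero matches the reporting convention of qPCR
    summary tables in this domain (2.75 -> 2.7 at 2 s.f.).
    """
    if x == 0:
        return 0.0
    d = decimal.Decimal(f"{x:.12g}")
    exp = d.adjusted()  # position of the leading digit
    quantum = decimal.Decimal(1).scaleb(exp - sig + 1)
    return float(d.quantize(quantum, rounding=decimal.ROUND_HALF_DOWN))


def cells_from_copies(m: QpcrMeasurement, model: GenomeCopyModel | None = None) -> CellEstimate:
    """cells/gww = copies/gww divided by the per-genome copy number."""
    model = model or GenomeCopyModel()
    cpg = model.for_target(m.target)
    return CellEstimate(
        target=m.target,
        cells_per_gww=m.copies_per_gww / cpg,
        sd=m.sd / cpg,
        sd_unscaled=m.sd,
        year=m.year,
    )


def _cells(x) -> float:
    return x.cells_per_gww if isinstance(x, CellEstimate) else float(x)


def domain_fraction(arch, bact) -> float:
    """Archaeal share of prokaryotic cells: 100 * A / (A + B), 1 dp."""
    a, b = _cells(arch), _cells(bact)
    if a < 0 or b < 0:
        raise ValueError("cell densities must be >= 0")
    if a + b == 0:
        raise ValueError("both cell densities are zero")
    return round(100.0 * a / (a + b), 1)


def guild_fraction(func: QpcrMeasurement, host_cells) -> float:
    """Guild share of its host domain, assuming one functional-gene copy
    per guild cell: 100 * copies / host cells, 1 dp."""
    h = _cells(host_cells)
    if h <= 0:
        raise ValueError("host cell density must be > 0")
    return round(100.0 * func.copies_per_gww / h, 1)


def cell_table(measurements, model: GenomeCopyModel | None = None) -> pd.DataFrame:
    """Report table of copy and derived cell densities, 2 significant
    figures, with both uncertainty conventions."""
    model = model or GenomeCopyModel()
    rows = []
    for m in measurements:
        est = cells_from_copies(m, model)
        rows.append({
            "year": m.year,
            "target": m.target,
            "copies_per_gww": round_sig(m.copies_per_gww),
            "copies_sd": round_sig(m.sd),
            "cells_per_gww": round_sig(est.cells_per_gww),
            "cells_sd": round_sig(est.sd),
            "cells_sd_unscaled": round_sig(est.sd_unscaled),
        })
    return pd.DataFrame(rows)
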