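"""Counseling tables and rate-curve exports.

The central artifact is a prediction table: for each number of embryos a
clinic might transfer, the total delivery rate and the percentages of
deliveries that are multiples, twins, and triplets-or-more, with a color
band on the multiples percentage (0-9% green, 10-19% yellow, 20-29% red,
>=30% gray) to flag the risk of a multiple gestation at a glance.
Percentages are carried at full precision and rounded only for display;
the band is always computed on the unrounded value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimation import LbrTable
from .model import Cycle, TransferSpec, delivery_rate, multiples_fractions

__all__ = [
    "risk_band",
    "PredictionRow",
    "PredictionTable",
    "build_prediction_table",
    "build_clinic_tables",
    "simplified_reference_table",
    "lbr_curve_frame",
]

#: (upper bound of percent-multiples, band name); bands are half-open
_BANDS = ((10.0, "green"), (20.0, "yellow"), (30.0, "red"))


def risk_band(pct_multiples: float) -> str:
    """Color band for a percent-of-deliveries-that-are-multiples value."""
    if not np.isfinite(pct_multiples) or pct_multiples < 0:
        raise ValueError(f"pct_multiples must be a non-negative percent, got {pct_multiples}")
    for upper, name in _BANDS:
        if pct_multiples < upper:
            return name
    return "gray"


@dataclass
class PredictionRow:
    """Predicted outcomes for transferring ``n_embryos`` embryos."""

    n_embryos: int
    delivery_rate: float
    pct_multiples: float  # percent of deliveries, 0-100; NaN when undefined
    pct_twins: float
    pct_triplet_or_more: float
    band: Optional[str]  # None when percentages are undefined (no deliveries)


@dataclass
class PredictionTable:
    """Counseling table for one (rate, uni) combination, rows by embryo count."""

    lbr: float
    uni: float
    rows: List[PredictionRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_embryos": r.n_embryos,
                    "delivery_rate": r.delivery_rate,
                    "pct_multiples": r.pct_multiples,
                    "pct_twins": r.pct_twins,
                    "pct_triplet_or_more": r.pct_triplet_or_more,
                    "risk_band": r.band,
                }
                for r in self.rows
            ]
        )

    def render_text(self, title: Optional[str] = None) -> str:
        """Plain-text table with whole-percent rounding for quick clinic use."""
        lines = []
        if title:
            lines.append(title)
        lines.append(
            f"{'n':>2}  {'LBR':>5}  {'% mult.':>8}  {'% twins':>8}  "
            f"{'% trip. or >':>12}  band"
        )
        for r in self.rows:
            if r.band is None:
                lines.append(
                    f"{r.n_embryos:>2}  {100 * r.delivery_rate:>4.0f}%  "
                    f"{'--':>8}  {'--':>8}  {'--':>12}  --"
                )
            else:
                lines.append(
                    f"{r.n_embryos:>2}  {100 * r.delivery_rate:>4.0f}%  "
                    f"{r.pct_multiples:>7.0f}%  {r.pct_twins:>7.0f}%  "
                    f"{r.pct_triplet_or_more:>11.0f}%  {r.band}"
                )
        return "\n".join(lines)


def build_prediction_table(
    lbr: float, uni: float, max_embryos: int = 4
) -> PredictionTable:
    """Predicted outcomes for 1..max_embryos embryos sharing one rate.

    Rows with a zero delivery rate have undefined multiples percentages and
    carry ``band=None`` rather than a fabricated 0.
    """
    if max_embryos < 1:
        raise ValueError("max_embryos must be >= 1")
    rows = []
    for n in range(1, max_embryos + 1):
        spec = TransferSpec.homogeneous(lbr, n, uni)  # validates lbr <= uni
        rate = delivery_rate(spec)
        if rate <= 0.0:
            rows.append(
                PredictionRow(n, 0.0, float("nan"), float("nan"), float("nan"), None)
            )
            continue
        mult, twin, trip = multiples_fractions(spec)
        rows.append(
            PredictionRow(
                n_embryos=n,
                delivery_rate=rate,
                pct_multiples=100.0 * mult,
                pct_twins=100.0 * twin,
                pct_triplet_or_more=100.0 * trip,
                band=risk_band(100.0 * mult),
            )
        )
    return PredictionTable(lbr=float(lbr), uni=float(uni), rows=rows)


def build_clinic_tables(
    lbr_table: LbrTable,
    uni_fresh: float,
    uni_frozen: float,
    max_embryos: int = 4,
) -> Tuple[Dict[Tuple[str, "object"], PredictionTable], List[str]]:
    """One prediction table per populated rate cell.

    Fresh cells use ``uni_fresh``, frozen cells ``uni_frozen``.  Cells whose
    fitted rate exceeds the applicable uni cannot be combined with it into a
    well-formed model; these produce a warning entry instead of a table.
    """
    tables: Dict[Tuple[str, object], PredictionTable] = {}
    warnings: List[str] = []
    for (label, cat), cell in sorted(
        lbr_table.cells.items(), key=lambda kv: (kv[0][1], kv[0][0])
    ):
        uni = uni_fresh if cat.cycle == Cycle.FRESH else uni_frozen
        if cell.lbr > uni + 1e-12:
            warnings.append(
                f"cell ({label}, {cat.label}): fitted rate {cell.lbr:.3f} "
                f"exceeds uni {uni:.2f}; table not emitted (identifiability "
                "warning)"
            )
            continue
        tables[(label, cat)] = build_prediction_table(cell.lbr, uni, max_embryos)
    return tables, warnings


def simplified_reference_table(
    uni: float = 0.70,
    lbr_grid: Optional[Sequence[float]] = None,
    max_embryos: int = 4,
) -> pd.DataFrame:
    """Reference lookup over (average rate per embryo, embryos transferred).

    A clinic that only computes its average live-birth rate per embryo
    (births divided by embryos transferred, the simplified estimator) can
    read predicted outcomes off this grid; 0.70 is a serviceable universal
    factors fraction for both fresh and frozen transfers.  Grid entries
    whose rate exceeds uni are flagged rather than silently dropped.
    """
    if lbr_grid is None:
        lbr_grid = np.round(np.arange(0.05, 0.71, 0.05), 10)
    rows = []
    for lbr in lbr_grid:
        if lbr > uni + 1e-12:
            for n in range(1, max_embryos + 1):
                rows.append(
                    {
                        "lbr_per_embryo": float(lbr),
                        "n_embryos": n,
                        "delivery_rate": float("nan"),
                        "pct_multiples": float("nan"),
                        "pct_twins": float("nan"),
                        "pct_triplet_or_more": float("nan"),
                        "risk_band": None,
                        "flag": "lbr exceeds uni",
                    }
                )
            continue
        table = build_prediction_table(float(lbr), uni, max_embryos)
        for r in table.rows:
            rows.append(
                {
                    "lbr_per_embryo": float(lbr),
                    "n_embryos": r.n_embryos,
                    "delivery_rate": r.delivery_rate,
                    "pct_multiples": r.pct_multiples,
                    "pct_twins": r.pct_twins,
                    "pct_triplet_or_more": r.pct_triplet_or_more,
                    "risk_band": r.band,
                    "flag": None if r.band is not None else "no deliveries",
                }
            )
    return pd.DataFrame(rows)


def lbr_curve_frame(lbr_table: LbrTable) -> pd.DataFrame:
    """Rate-by-age curve export: one row per (age group, category) cell."""
    return lbr_table.to_frame()
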