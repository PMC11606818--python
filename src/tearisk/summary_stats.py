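"""Leaf-to-infusion transfer ratios and descriptive statistics.

The transfer percentage is the source survey's own definition: 100 × the
infusion concentration (µg/L) over the leaf concentration (µg/kg). The
ratio is dimensionally naive — it ignores the 1 g : 45 mL brewing ratio —
so it is not a mass-balance transfer fraction and can exceed 100%; we
reproduce the printed definition and flag such values rather than
reinterpret them.

Group summaries are arithmetic mean ± sample standard deviation (n−1
denominator). The combined "total" summary over the two origin groups is
the mean ± sample SD *of the two group means* (computed from the
2-decimal rounded group means), not the pooled per-sample mean — a
statistically unusual convention, but the one the survey tables use, kept
here so the package regenerates those tables cell for cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tea_data import ConcentrationRecord, Metal, Origin, records_to_frame

__all__ = [
    "SummaryStat",
    "TransferRecord",
    "UndefinedTransferError",
    "round_half_away",
    "transfer_percent",
    "transfer_table",
    "group_summary",
    "overall_summary",
    "reproduce_summary_tables",
]


class UndefinedTransferError(ZeroDivisionError):
    """Transfer ratio is undefined: zero in leaves but metal in infusion."""


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (display convention).

    Matches the survey tables' display rounding (e.g. 3.105 → 3.11),
    unlike Python's built-in banker's rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SummaryStat:
    """Mean ± sample SD over n values; sd is None when n < 2."""

    mean: float
    sd: float | None
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n >= 2 and (self.sd is None or self.sd < 0):
            raise ValueError("sd must be >= 0 for n >= 2")

    def display(self, ndigits: int = 2) -> str:
        mean = round_half_away(self.mean, ndigits)
        if self.sd is None:
            return f"{mean:.{ndigits}f}"
        return f"{mean:.{ndigits}f} ± {round_half_away(self.sd, ndigits):.{ndigits}f}"


@dataclass(frozen=True)
class TransferRecord:
    """Transfer percentage for one sample × metal; >100% values are flagged."""

    sample_id: str
    origin: Origin
    metal: Metal
    transfer_pct: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.transfer_pct) or self.transfer_pct < 0:
            raise ValueError(f"transfer_pct must be finite and >= 0, got {self.transfer_pct!r}")

    @property
    def exceeds_100(self) -> bool:
        return self.transfer_pct > 100.0


def transfer_percent(
    infusion_conc: float, leaves_conc: float, ndigits: int | None = 2
) -> float:
    """100 × infusion (µg/L) / leaves (µg/kg), the survey's transfer ratio.

    Both zero → 0 (no metal anywhere). Zero leaves with metal in the
    infusion is undefined and raises. ``ndigits`` applies the 2-decimal
    display rounding; pass ``None`` for the exact ratio.
    """
    if leaves_conc < 0 or infusion_conc < 0:
        raise ValueError("concentrations must be >= 0")
    if leaves_conc == 0:
        if infusion_conc == 0:
            return 0.0
        raise UndefinedTransferError(
            f"leaves 0 but infusion {infusion_conc!r}: transfer undefined"
        )
    pct = 100.0 * infusion_conc / leaves_conc
    return pct if ndigits is None else round_half_away(pct, ndigits)


def transfer_table(
    records: Iterable[ConcentrationRecord], ndigits: int | None = None
) -> list[TransferRecord]:
    """Transfer ratios for every record, in input order."""
    return [
        TransferRecord(
            sample_id=r.sample_id,
            origin=r.origin,
            metal=r.metal,
            transfer_pct=transfer_percent(r.infusion_conc, r.leaves_conc, ndigits),
        )
        for r in records
    ]


def _select(
    records: Iterable[ConcentrationRecord], origin: Origin, metal: Metal, matrix: str
) -> np.ndarray:
    if matrix not in ("leaves", "infusion"):
        raise ValueError(f"matrix must be 'leaves' or 'infusion', got {matrix!r}")
    attr = "leaves_conc" if matrix == "leaves" else "infusion_conc"
    values = [getattr(r, attr) for r in records if r.origin is Origin(origin) and r.metal is Metal(metal)]
    if not values:
        raise ValueError(f"no records for origin={origin}, metal={metal}")
    return np.asarray(values, dtype=float)


def group_summary(
    records: Iterable[ConcentrationRecord], origin: Origin, metal: Metal, matrix: str
) -> SummaryStat:
    """Mean ± sample SD of one origin × metal × matrix selection."""
    values = _select(list(records), origin, metal, matrix)
    n = values.size
    sd = float(np.std(values, ddof=1)) if n >= 2 else None
    return SummaryStat(mean=float(np.mean(values)), sd=sd, n=n)


def overall_summary(
    group_stats: Sequence[SummaryStat], from_rounded: bool = True
) -> SummaryStat:
    """Combined summary over exactly two origin groups.

    Mean of the two group means ± their sample SD; by default computed
    from the 2-decimal rounded group means, matching the printed tables.
    """
    if len(group_stats) != 2:
        raise ValueError(f"expected exactly 2 group summaries, got {len(group_stats)}")
    means = [s.mean for s in group_stats]
    if from_rounded:
        means = [round_half_away(m, 2) for m in means]
    arr = np.asarray(means, dtype=float)
    return SummaryStat(mean=float(arr.mean()), sd=float(np.std(arr, ddof=1)), n=2)


def reproduce_summary_tables(records: Iterable[ConcentrationRecord]) -> dict[str, pd.DataFrame]:
    """Regenerate the survey's summary tables from concentration records.

    Returns ``{"transfer": ..., "group_summary": ...}``: per-sample
    transfer percentages alongside the concentrations, and the
    mean ± SD table per metal × matrix with per-origin columns plus the
    combined column. Values are full precision; display rounding is left
    to the caller (``SummaryStat.display`` / ``round_half_away``).
    """
    records = list(records)
    origins = {r.origin for r in records}
    metals = {r.metal for r in records}
    if origins != set(Origin) or metals != set(Metal):
        raise ValueError("records must cover both origins and all three metals")

    frame = records_to_frame(records)
    frame["transfer_pct"] = [
        transfer_percent(r.infusion_conc, r.leaves_conc, ndigits=None) for r in records
    ]
    frame["exceeds_100"] = frame["transfer_pct"] > 100.0

    rows = []
    for metal in Metal:
        for matrix in ("leaves", "infusion"):
            per_origin = {
                origin: group_summary(records, origin, metal, matrix)
                for origin in (Origin.IRANIAN, Origin.FOREIGN)
            }
            total = overall_summary(
                [per_origin[Origin.IRANIAN], per_origin[Origin.FOREIGN]]
            )
            row: dict[str, object] = {"metal": metal.value, "matrix": matrix}
            for origin, stat in per_origin.items():
                row[f"{origin.value}_mean"] = stat.mean
                row[f"{origin.value}_sd"] = stat.sd
                row[f"{origin.value}_n"] = stat.n
            row["total_mean"] = total.mean
            row["total_sd"] = total.sd
            rows.append(row)

    return {"transfer": frame, "group_summary": pd.DataFrame(rows)}
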