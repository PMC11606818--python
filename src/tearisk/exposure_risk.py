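"""Deterministic exposure and risk indices for metals in tea infusion.

The chain is the standard oral-route screening arithmetic:

    EDI  = DC × Cm / BW          (µg/kg bw/day)
    HQ   = (EDI / 1000) / RfD    (dimensionless; µg→mg conversion internal)
    HI   = Σ HQ                  (over metals sharing the oral route)
    ILCR = (EDI / 1000) × CSF    (dimensionless excess lifetime cancer risk)

where DC is daily infusion consumption (L/day), Cm the metal concentration
in the infusion (µg/L), BW body weight (kg), RfD the oral reference dose
(mg/kg bw/day) and CSF the carcinogenic slope factor ((mg/kg bw/day)^-1).
Exposure duration/frequency/averaging-time factors common in regulatory
ILCR practice are deliberately not applied: the model is the plain
EDI × CSF (an ``edi_scale`` hook exists for users who need such factors).

Classification follows the regulatory cut-offs: ILCR ≤ 1e-6 acceptable
(US EPA), 1e-5 the WHO working cut-off, > 1e-4 critical; noncarcinogenic
concern starts at HQ (or HI) of exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .summary_stats import group_summary
from .tea_data import (
    ConcentrationRecord,
    Metal,
    Origin,
    PopulationGroup,
    ToxicologyParams,
)

__all__ = [
    "UG_PER_MG",
    "RiskThresholds",
    "ExposureResult",
    "RiskResult",
    "PointRiskReport",
    "estimate_edi",
    "hazard_quotient",
    "hazard_index",
    "ilcr",
    "classify_ilcr",
    "classify_noncarcinogenic",
    "point_risk_pipeline",
]

UG_PER_MG = 1000.0


@dataclass(frozen=True)
class RiskThresholds:
    """Regulatory cut-offs for the risk indices (all dimensionless)."""

    ilcr_safe: float = 1e-6
    ilcr_who: float = 1e-5
    ilcr_critical: float = 1e-4
    noncarc_limit: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.ilcr_safe < self.ilcr_who < self.ilcr_critical):
            raise ValueError("need 0 < ilcr_safe < ilcr_who < ilcr_critical")


@dataclass(frozen=True)
class ExposureResult:
    metal: Metal
    group: str
    edi: float  # µg/kg bw/day


@dataclass(frozen=True)
class RiskResult:
    """Risk indices for one metal × consumer group.

    ``ilcr`` is None exactly when the metal has no slope factor
    (not applicable, distinct from zero risk).
    """

    metal: Metal
    group: str
    origin: Origin | None
    edi: float
    hq: float
    ilcr: float | None
    hq_label: str
    ilcr_label: str | None


def estimate_edi(dc: float, cm, bw: float):
    """Estimated daily intake, µg/kg bw/day. Accepts scalar or array Cm."""
    if not dc > 0:
        raise ValueError(f"dc must be > 0, got {dc!r}")
    if not bw > 0:
        raise ValueError(f"bw must be > 0, got {bw!r}")
    cm = np.asarray(cm, dtype=float)
    if np.any(cm < 0):
        raise ValueError("cm must be >= 0")
    out = dc * cm / bw
    return float(out) if out.ndim == 0 else out


def hazard_quotient(edi, rfd: float):
    """HQ = (EDI µg → mg) / RfD. The 1000× unit conversion is internal."""
    if not rfd > 0:
        raise ValueError(f"rfd must be > 0, got {rfd!r}")
    edi = np.asarray(edi, dtype=float)
    if np.any(edi < 0):
        raise ValueError("edi must be >= 0")
    out = (edi / UG_PER_MG) / rfd
    return float(out) if out.ndim == 0 else out


def hazard_index(hqs: Iterable):
    """HI = Σ HQ. Element-wise over vectors; errors on an empty collection."""
    hqs = [np.asarray(h, dtype=float) for h in hqs]
    if not hqs:
        raise ValueError("hazard_index needs at least one HQ")
    for h in hqs:
        if np.any(h < 0):
            raise ValueError("HQ values must be >= 0")
    out = sum(hqs[1:], start=hqs[0].copy())
    return float(out) if out.ndim == 0 else out


def ilcr(edi, csf: float):
    """ILCR = (EDI µg → mg) × CSF, dimensionless lifetime excess risk."""
    if csf is None:
        raise ValueError("csf is absent: ILCR not applicable for this metal")
    if not csf > 0:
        raise ValueError(f"csf must be > 0, got {csf!r}")
    edi = np.asarray(edi, dtype=float)
    if np.any(edi < 0):
        raise ValueError("edi must be >= 0")
    out = (edi / UG_PER_MG) * csf
    return float(out) if out.ndim == 0 else out


def classify_ilcr(x: float, thresholds: RiskThresholds = RiskThresholds()) -> str:
    """Map an ILCR value onto the regulatory bands (boundaries closed below)."""
    if not (math.isfinite(x) and x >= 0):
        raise ValueError(f"ILCR must be finite and >= 0, got {x!r}")
    if x <= thresholds.ilcr_safe:
        return "acceptable"
    if x <= thresholds.ilcr_who:
        return "tolerable_below_who"
    if x <= thresholds.ilcr_critical:
        return "tolerable_above_who"
    return "critical"


def classify_noncarcinogenic(x: float, thresholds: RiskThresholds = RiskThresholds()) -> str:
    """"no_concern" strictly below the HQ/HI limit of 1, else "concern"."""
    if not (math.isfinite(x) and x >= 0):
        raise ValueError(f"HQ/HI must be finite and >= 0, got {x!r}")
    return "no_concern" if x < thresholds.noncarc_limit else "concern"


@dataclass(frozen=True)
class PointRiskReport:
    """Point-estimate risk table plus per-group hazard indices."""

    risk: pd.DataFrame
    hazard_index: pd.DataFrame
    dc_used: Mapping[str, float] = field(default_factory=dict)


def point_risk_pipeline(
    records: Iterable[ConcentrationRecord],
    toxicology: Mapping[Metal, ToxicologyParams],
    populations: Mapping[str, PopulationGroup],
    thresholds: RiskThresholds = RiskThresholds(),
    edi_scale: float = 1.0,
) -> PointRiskReport:
    """Point-estimate risk for each origin × metal × group.

    EDI is computed from the group-mean infusion concentration per
    origin × metal; HQ always, ILCR where a slope factor exists, and HI
    per origin × group (sum over the three metals). ``edi_scale`` is a
    hook for exposure-duration style factors and defaults to 1 (none).
    """
    records = list(records)
    rows = []
    hi_rows = []
    for origin in Origin:
        for pop in populations.values():
            hqs = []
            for metal in Metal:
                cm = group_summary(records, origin, metal, "infusion").mean
                edi = estimate_edi(pop.dc, cm, pop.bw) * edi_scale
                tox = toxicology[metal]
                hq = hazard_quotient(edi, tox.rfd)
                hqs.append(hq)
                metal_ilcr = ilcr(edi, tox.csf) if tox.csf is not None else None
                rows.append(
                    {
                        "origin": origin.value,
                        "group": pop.name,
                        "metal": metal.value,
                        "edi_ug_per_kg_bw_day": edi,
                        "hq": hq,
                        "hq_label": classify_noncarcinogenic(hq, thresholds),
                        "ilcr": metal_ilcr,
                        "ilcr_label": (
                            classify_ilcr(metal_ilcr, thresholds)
                            if metal_ilcr is not None
                            else None
                        ),
                    }
                )
            hi = hazard_index(hqs)
            hi_rows.append(
                {
                    "origin": origin.value,
                    "group": pop.name,
                    "hi": hi,
                    "hi_label": classify_noncarcinogenic(hi, thresholds),
                }
            )
    return PointRiskReport(
        risk=pd.DataFrame(rows),
        hazard_index=pd.DataFrame(hi_rows),
        dc_used={name: pop.dc for name, pop in populations.items()},
    )
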