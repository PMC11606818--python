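"""Data model and packaged study data for heavy metals in black tea.

The underlying survey measured arsenic, cadmium and lead by ICP-MS in 23
packaged black teas from the Tehran market (16 foreign brands, 7 Iranian),
in both the dry leaves (µg/kg) and the infusion brewed from them (µg/L).
This module defines the record types used throughout the package, ships the
survey tables as packaged fixtures, reads and writes the package's CSV
concentration format, and provides the toxicological constants (oral
reference doses and carcinogenic slope factors) and consumer-group
parameters (body weight, daily consumption) used by the risk engine.

Units are fixed at module boundaries: leaf concentrations are µg/kg,
infusion concentrations are µg/L, reference doses and slope factors are on
the mg/kg bw/day scale. Conversions happen inside the risk formulas, never
in the data layer.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "Metal",
    "Origin",
    "ConcentrationRecord",
    "ToxicologyParams",
    "PopulationGroup",
    "DetectionLimits",
    "FixtureIntegrityError",
    "ValidationError",
    "load_fixture_tables",
    "load_printed_transfer",
    "read_concentration_table",
    "write_concentration_table",
    "records_to_frame",
    "default_toxicology",
    "default_populations",
    "default_detection_limits",
    "apply_detection_limit_policy",
]


class Metal(str, enum.Enum):
    """The three metals assessed: a closed set."""

    ARSENIC = "arsenic"
    CADMIUM = "cadmium"
    LEAD = "lead"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Origin(str, enum.Enum):
    """Provenance of the tea brand: a closed set."""

    IRANIAN = "iranian"
    FOREIGN = "foreign"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ValidationError(ValueError):
    """Raised when input data violate the concentration-record invariants."""


class FixtureIntegrityError(RuntimeError):
    """Raised when a packaged fixture fails its checksum."""


def _check_conc(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValidationError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class ConcentrationRecord:
    """One sample × metal observation: leaf and infusion concentration.

    ``leaves_conc`` is in µg/kg dry leaves; ``infusion_conc`` in µg/L of
    the brewed infusion (1 g leaves per 45 mL water, 90 °C, 10 min).
    """

    sample_id: str
    origin: Origin
    metal: Metal
    leaves_conc: float
    infusion_conc: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", Origin(self.origin))
        object.__setattr__(self, "metal", Metal(self.metal))
        object.__setattr__(self, "leaves_conc", _check_conc("leaves_conc", self.leaves_conc))
        object.__setattr__(self, "infusion_conc", _check_conc("infusion_conc", self.infusion_conc))


@dataclass(frozen=True)
class ToxicologyParams:
    """Per-metal toxicological constants.

    ``rfd`` — oral reference dose, mg/kg bw/day. ``csf`` — carcinogenic
    slope factor, (mg/kg bw/day)^-1, or ``None`` where no oral slope
    factor has been published (cadmium).
    """

    metal: Metal
    rfd: float
    csf: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "metal", Metal(self.metal))
        if not self.rfd > 0:
            raise ValidationError(f"rfd must be > 0, got {self.rfd!r}")
        if self.csf is not None and not self.csf > 0:
            raise ValidationError(f"csf must be > 0 when present, got {self.csf!r}")


@dataclass(frozen=True)
class PopulationGroup:
    """A consumer group: body weight (kg) and daily consumption (L/day)."""

    name: str
    bw: float
    dc: float

    def __post_init__(self) -> None:
        if not self.bw > 0:
            raise ValidationError(f"bw must be > 0, got {self.bw!r}")
        if not self.dc > 0:
            raise ValidationError(f"dc must be > 0, got {self.dc!r}")


@dataclass(frozen=True)
class DetectionLimits:
    """Analytical detection/quantification limits of the ICP-MS method, µg/kg."""

    lod: float
    loq: float

    def __post_init__(self) -> None:
        if not (0 < self.lod <= self.loq):
            raise ValidationError(f"need 0 < lod <= loq, got lod={self.lod!r} loq={self.loq!r}")


# --------------------------------------------------------------------------
# Packaged fixtures
# --------------------------------------------------------------------------

_FIXTURE_FILES = {
    Origin.FOREIGN: "table2_foreign.csv",
    Origin.IRANIAN: "table3_iranian.csv",
}

# Column sums of the packaged survey tables, established once by hand from
# the printed values.  Any drift in the fixture files is a fatal error.
_FIXTURE_CHECKSUMS: dict[tuple[Origin, str], float] = {
    (Origin.FOREIGN, "arsenic_leaves_ug_per_kg"): 21.95,
    (Origin.FOREIGN, "arsenic_infusion_ug_per_L"): 3.75,
    (Origin.FOREIGN, "cadmium_leaves_ug_per_kg"): 56.90,
    (Origin.FOREIGN, "cadmium_infusion_ug_per_L"): 4.55,
    (Origin.FOREIGN, "lead_leaves_ug_per_kg"): 77.16,
    (Origin.FOREIGN, "lead_infusion_ug_per_L"): 45.35,
    (Origin.IRANIAN, "arsenic_leaves_ug_per_kg"): 3.90,
    (Origin.IRANIAN, "arsenic_infusion_ug_per_L"): 0.84,
    (Origin.IRANIAN, "cadmium_leaves_ug_per_kg"): 25.90,
    (Origin.IRANIAN, "cadmium_infusion_ug_per_L"): 2.00,
    (Origin.IRANIAN, "lead_leaves_ug_per_kg"): 34.52,
    (Origin.IRANIAN, "lead_infusion_ug_per_L"): 23.66,
}


def _fixture_frame(origin: Origin) -> pd.DataFrame:
    ref = resources.files("tearisk.fixtures") / _FIXTURE_FILES[origin]
    with ref.open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh, dtype={"sample_id": str})
    for (chk_origin, column), expected in _FIXTURE_CHECKSUMS.items():
        if chk_origin is not origin:
            continue
        total = float(frame[column].sum())
        if abs(total - expected) > 1e-9:
            raise FixtureIntegrityError(
                f"fixture {_FIXTURE_FILES[origin]} column {column}: "
                f"sum {total!r} != expected {expected!r}"
            )
    return frame


def load_fixture_tables() -> list[ConcentrationRecord]:
    """Load the packaged survey tables as 69 concentration records.

    Returns 23 samples × 3 metals (16 foreign + 7 Iranian samples), with
    values matching the printed survey tables digit for digit. Column
    checksums guard against fixture corruption.
    """
    records: list[ConcentrationRecord] = []
    for origin in (Origin.FOREIGN, Origin.IRANIAN):
        frame = _fixture_frame(origin)
        for row in frame.itertuples(index=False):
            for metal in Metal:
                records.append(
                    ConcentrationRecord(
                        sample_id=str(row.sample_id),
                        origin=origin,
                        metal=metal,
                        leaves_conc=getattr(row, f"{metal.value}_leaves_ug_per_kg"),
                        infusion_conc=getattr(row, f"{metal.value}_infusion_ug_per_L"),
                    )
                )
    return records


def load_printed_transfer() -> dict[tuple[Origin, str, Metal], float]:
    """Leaf-to-infusion transfer percentages as printed in the survey tables.

    Keyed by (origin, sample_id, metal). These are the source's displayed
    values, kept verbatim for cross-checking the recomputed ratios.
    """
    printed: dict[tuple[Origin, str, Metal], float] = {}
    for origin in (Origin.FOREIGN, Origin.IRANIAN):
        frame = _fixture_frame(origin)
        for row in frame.itertuples(index=False):
            for metal in Metal:
                printed[(origin, str(row.sample_id), metal)] = float(
                    getattr(row, f"{metal.value}_transfer_pct")
                )
    return printed


# --------------------------------------------------------------------------
# CSV interchange format (long): sample_id, origin, metal,
# leaves_ug_per_kg, infusion_ug_per_L
# --------------------------------------------------------------------------

_CSV_COLUMNS = ["sample_id", "origin", "metal", "leaves_ug_per_kg", "infusion_ug_per_L"]


def read_concentration_table(
    source: str | Path | IO[str], origin: Origin | None = None
) -> list[ConcentrationRecord]:
    """Read concentration records from the package's long CSV format.

    ``origin`` overrides/supplies the origin column. Raises
    :class:`ValidationError` on negative or missing values (naming the
    offending row) and on unknown metal names; values are never imputed.
    """
    frame = pd.read_csv(source, dtype={"sample_id": str})
    missing_cols = [c for c in _CSV_COLUMNS if c not in frame.columns and c != "origin"]
    if missing_cols:
        raise ValidationError(f"missing required columns: {missing_cols}")
    if origin is None and "origin" not in frame.columns:
        raise ValidationError("no origin column and no origin argument given")

    records: list[ConcentrationRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header is line 1
        metal_raw = row.metal
        try:
            metal = Metal(str(metal_raw).strip().lower())
        except ValueError:
            raise ValidationError(f"row {i}: unknown metal {metal_raw!r}") from None
        row_origin = origin if origin is not None else Origin(str(row.origin).strip().lower())
        leaves = row.leaves_ug_per_kg
        infusion = row.infusion_ug_per_L
        if pd.isna(leaves) or pd.isna(infusion):
            raise ValidationError(f"row {i}: missing concentration value")
        try:
            records.append(
                ConcentrationRecord(
                    sample_id=str(row.sample_id),
                    origin=row_origin,
                    metal=metal,
                    leaves_conc=float(leaves),
                    infusion_conc=float(infusion),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None

    seen: set[tuple[Origin, str, Metal]] = set()
    for rec in records:
        key = (rec.origin, rec.sample_id, rec.metal)
        if key in seen:
            raise ValidationError(f"duplicate record for {key}")
        seen.add(key)
    return records


def records_to_frame(records: Iterable[ConcentrationRecord]) -> pd.DataFrame:
    """Concentration records as a tidy DataFrame in the CSV column layout."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "origin": r.origin.value,
                "metal": r.metal.value,
                "leaves_ug_per_kg": r.leaves_conc,
                "infusion_ug_per_L": r.infusion_conc,
            }
            for r in records
        ],
        columns=_CSV_COLUMNS,
    )


def write_concentration_table(
    records: Iterable[ConcentrationRecord], target: str | Path | IO[str]
) -> None:
    """Write records in the long CSV format (lossless round trip)."""
    records_to_frame(records).to_csv(target, index=False)


# --------------------------------------------------------------------------
# Parameter registries
# --------------------------------------------------------------------------


def default_toxicology() -> dict[Metal, ToxicologyParams]:
    """Per-metal RfD/CSF registry from the packaged toxicology fixture."""
    ref = resources.files("tearisk.fixtures") / "toxicology.yaml"
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return {
        Metal(name): ToxicologyParams(metal=Metal(name), rfd=entry["rfd"], csf=entry.get("csf"))
        for name, entry in raw.items()
    }


def default_populations() -> dict[str, PopulationGroup]:
    """Consumer groups (children/adults) from the packaged population fixture."""
    ref = resources.files("tearisk.fixtures") / "populations.yaml"
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return {
        name: PopulationGroup(name=name, bw=entry["bw"], dc=entry["dc"])
        for name, entry in raw.items()
    }


def default_detection_limits() -> DetectionLimits:
    """LOD/LOQ of the ICP-MS method (µg/kg), carried as metadata."""
    return DetectionLimits(lod=0.0003, loq=0.001)


def apply_detection_limit_policy(
    records: Iterable[ConcentrationRecord],
    policy: str = "as_is",
    limits: DetectionLimits | None = None,
) -> list[ConcentrationRecord]:
    """Substitute zero concentrations per a censoring policy.

    ``as_is`` keeps literal zeros (the default: the source tables print
    zeros), ``half_lod`` substitutes LOD/2, ``lod`` substitutes LOD.
    Censoring treatment is an analyst choice; none is silently applied.
    """
    if policy == "as_is":
        return list(records)
    if policy not in ("half_lod", "lod"):
        raise ValueError(f"unknown detection-limit policy {policy!r}")
    limits = limits or default_detection_limits()
    sub = limits.lod / 2 if policy == "half_lod" else limits.lod
    out = []
    for rec in records:
        out.append(
            ConcentrationRecord(
                sample_id=rec.sample_id,
                origin=rec.origin,
                metal=rec.metal,
                leaves_conc=rec.leaves_conc if rec.leaves_conc > 0 else sub,
                infusion_conc=rec.infusion_conc if rec.infusion_conc > 0 else sub,
            )
        )
    return out
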