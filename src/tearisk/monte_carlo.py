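"""Seeded Monte Carlo propagation of the exposure/risk chain.

Uncertain inputs — infusion concentration per metal, daily consumption and
body weight per consumer group — are described declaratively by
:class:`DistributionSpec` and propagated through the EDI/HQ/HI/ILCR
formulas by repeated sampling (default 10,000 iterations). The engine
replaces the spreadsheet add-in workflow (Crystal Ball) with a seedable,
reproducible implementation: a single named NumPy generator, variables
sampled in a fixed documented order (metals alphabetically, then per
group — sorted by name — daily consumption then body weight), so that
identical (seed, config, data) gives bit-identical results.

Outputs are full per-iteration vectors plus the derived summaries the
probabilistic assessment reads off them: percentiles (linear-interpolation
convention), cumulative / reverse-cumulative frequency tables, and
threshold-exceedance fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import exposure_risk as er
from .tea_data import (
    ConcentrationRecord,
    Metal,
    Origin,
    PopulationGroup,
    ToxicologyParams,
    default_populations,
    default_toxicology,
)

__all__ = [
    "DistributionSpec",
    "SimulationConfig",
    "SimulationResult",
    "FrequencyTable",
    "ExceedanceResult",
    "sample_distribution",
    "fit_spec_from_records",
    "run_simulation",
    "config_from_records",
    "percentile",
    "cumulative_frequency",
    "exceedance_fraction",
]

_FAMILIES = {
    "point": ("value",),
    "normal": ("mean", "sd"),
    "lognormal": ("meanlog", "sdlog"),
    "uniform": ("low", "high"),
    "triangular": ("low", "mode", "high"),
    "empirical": ("values",),
}

_TRUNCATION_BATCHES = 1000  # resampling rounds before declaring the bounds empty


@dataclass(frozen=True)
class DistributionSpec:
    """Declarative description of an uncertain model input.

    ``family`` is one of point, normal, lognormal, uniform, triangular or
    empirical; ``params`` the family's parameters (lognormal takes the
    log-scale ``meanlog``/``sdlog``); ``truncation`` optional [low, high]
    bounds enforced by resampling.
    """

    family: str
    params: Mapping[str, object]
    truncation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {sorted(_FAMILIES)}")
        missing = [k for k in _FAMILIES[self.family] if k not in self.params]
        if missing:
            raise ValueError(f"{self.family} spec missing params {missing}")
        p = self.params
        if self.family == "normal" and p["sd"] < 0:
            raise ValueError("normal sd must be >= 0")
        if self.family == "lognormal" and p["sdlog"] < 0:
            raise ValueError("lognormal sdlog must be >= 0")
        if self.family == "uniform" and not p["low"] < p["high"]:
            raise ValueError("uniform needs low < high")
        if self.family == "triangular" and not p["low"] <= p["mode"] <= p["high"]:
            raise ValueError("triangular needs low <= mode <= high")
        if self.family == "triangular" and not p["low"] < p["high"]:
            raise ValueError("triangular needs low < high")
        if self.family == "empirical":
            values = tuple(float(v) for v in p["values"])  # type: ignore[arg-type]
            if len(values) < 1:
                raise ValueError("empirical needs at least one value")
            object.__setattr__(self, "params", {"values": values})
        if self.truncation is not None:
            low, high = self.truncation
            if not low < high:
                raise ValueError(f"truncation needs low < high, got {self.truncation!r}")
            object.__setattr__(self, "truncation", (float(low), float(high)))

    @staticmethod
    def point(value: float) -> "DistributionSpec":
        return DistributionSpec("point", {"value": float(value)})

    def analytic_mean(self) -> float:
        """Closed-form mean of the *untruncated* distribution."""
        p = self.params
        if self.family == "point":
            return float(p["value"])  # type: ignore[arg-type]
        if self.family == "normal":
            return float(p["mean"])  # type: ignore[arg-type]
        if self.family == "lognormal":
            return math.exp(float(p["meanlog"]) + float(p["sdlog"]) ** 2 / 2)  # type: ignore[arg-type]
        if self.family == "uniform":
            return (float(p["low"]) + float(p["high"])) / 2  # type: ignore[arg-type]
        if self.family == "triangular":
            return (float(p["low"]) + float(p["mode"]) + float(p["high"])) / 3  # type: ignore[arg-type]
        return float(np.mean(p["values"]))  # empirical


def _draw(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    p = spec.params
    if spec.family == "point":
        return np.full(n, float(p["value"]))  # type: ignore[arg-type]
    if spec.family == "normal":
        return rng.normal(float(p["mean"]), float(p["sd"]), size=n)  # type: ignore[arg-type]
    if spec.family == "lognormal":
        return rng.lognormal(float(p["meanlog"]), float(p["sdlog"]), size=n)  # type: ignore[arg-type]
    if spec.family == "uniform":
        return rng.uniform(float(p["low"]), float(p["high"]), size=n)  # type: ignore[arg-type]
    if spec.family == "triangular":
        return rng.triangular(float(p["low"]), float(p["mode"]), float(p["high"]), size=n)  # type: ignore[arg-type]
    values = np.asarray(p["values"], dtype=float)
    return rng.choice(values, size=n, replace=True)


def sample_distribution(
    spec: DistributionSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from ``spec``; truncation is enforced by resampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec.truncation is None:
        return _draw(spec, n, rng)
    low, high = spec.truncation
    out = np.empty(n)
    filled = 0
    for _ in range(_TRUNCATION_BATCHES):
        batch = _draw(spec, n, rng)
        keep = batch[(batch >= low) & (batch <= high)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
        if filled == n:
            return out
    raise RuntimeError(
        f"truncation {spec.truncation} holds (almost) no probability mass for {spec.family}"
    )


def fit_spec_from_records(
    records: Iterable[ConcentrationRecord],
    origin: Origin,
    metal: Metal,
    family: str = "lognormal",
    truncate_at_zero: bool = True,
) -> DistributionSpec:
    """Moment-match a concentration spec to observed infusion values.

    ``normal`` matches the sample mean/SD; ``lognormal`` moment-matches
    mean/SD of the positive values (zeros are censored observations, not
    part of a lognormal's support); ``empirical`` resamples the observed
    values. Concentrations are non-negative, so fitted normals are
    truncated at zero by default.
    """
    values = np.asarray(
        [
            r.infusion_conc
            for r in records
            if r.origin is Origin(origin) and r.metal is Metal(metal)
        ],
        dtype=float,
    )
    if values.size < 2:
        raise ValueError("need at least 2 records to fit a distribution")
    if family == "empirical":
        return DistributionSpec("empirical", {"values": tuple(values)})
    if family == "normal":
        spec_trunc = (0.0, float("inf")) if truncate_at_zero else None
        return DistributionSpec(
            "normal",
            {"mean": float(values.mean()), "sd": float(values.std(ddof=1))},
            truncation=spec_trunc,
        )
    if family != "lognormal":
        raise ValueError(f"unsupported family {family!r}")
    positive = values[values > 0]
    if positive.size < 2:
        raise ValueError(
            "all (or all but one) values are zero: a lognormal cannot represent "
            "this group — use family='empirical' or 'normal'"
        )
    m = float(positive.mean())
    s = float(positive.std(ddof=1))
    if s == 0:
        return DistributionSpec.point(m)
    sdlog = math.sqrt(math.log(1 + (s / m) ** 2))
    meanlog = math.log(m) - sdlog**2 / 2
    return DistributionSpec("lognormal", {"meanlog": meanlog, "sdlog": sdlog})


@dataclass(frozen=True)
class SimulationConfig:
    """Inputs of one Monte Carlo run.

    ``concentration`` maps each metal to the spec of its infusion
    concentration (µg/L); ``dc``/``bw`` map each consumer-group name to
    daily consumption (L/day) and body weight (kg) specs.
    """

    concentration: Mapping[Metal, DistributionSpec]
    dc: Mapping[str, DistributionSpec]
    bw: Mapping[str, DistributionSpec]
    toxicology: Mapping[Metal, ToxicologyParams]
    thresholds: er.RiskThresholds = er.RiskThresholds()
    n_iter: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        missing = [m.value for m in self.concentration if m not in self.toxicology]
        if missing:
            raise ValueError(f"no toxicology parameters for metals {missing}")
        if set(self.dc) != set(self.bw):
            raise ValueError("dc and bw must cover the same consumer groups")


@dataclass(frozen=True)
class SimulationResult:
    """Per-iteration vectors and provenance of one simulation run.

    ``edi``/``hq`` are keyed by (group, metal); ``ilcr`` only for metals
    with a slope factor; ``hi`` per group. All vectors have length
    ``config.n_iter`` and HI[i] equals the sum of that iteration's HQs.
    """

    config: SimulationConfig
    samples: Mapping[str, np.ndarray]  # raw input draws by variable name
    edi: Mapping[tuple[str, Metal], np.ndarray]
    hq: Mapping[tuple[str, Metal], np.ndarray]
    ilcr: Mapping[tuple[str, Metal], np.ndarray]
    hi: Mapping[str, np.ndarray]

    def summary(self, quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.DataFrame:
        """Long summary table: mean, sd and the requested percentiles."""
        rows = []
        def add(index: str, group: str, metal: str, vec: np.ndarray) -> None:
            row = {
                "index": index,
                "group": group,
                "metal": metal,
                "mean": float(vec.mean()),
                "sd": float(vec.std(ddof=1)) if vec.size > 1 else float("nan"),
            }
            for q in quantiles:
                row[f"p{100 * q:g}"] = percentile(vec, q)
            rows.append(row)

        for (group, metal), vec in self.edi.items():
            add("edi", group, metal.value, vec)
        for (group, metal), vec in self.hq.items():
            add("hq", group, metal.value, vec)
        for (group, metal), vec in self.ilcr.items():
            add("ilcr", group, metal.value, vec)
        for group, vec in self.hi.items():
            add("hi", group, "all", vec)
        return pd.DataFrame(rows)


def run_simulation(
    config: SimulationConfig,
    records: Iterable[ConcentrationRecord] | None = None,
    origin: Origin | None = None,
) -> SimulationResult:
    """Propagate sampled inputs through the risk chain.

    Missing concentration specs may be fitted on the fly from ``records``
    (lognormal moment match for the given ``origin``); a metal referenced
    by the toxicology registry but lacking both a spec and records is a
    configuration error. One concentration draw per metal is shared
    across groups (both groups drink the same tea).
    """
    conc_specs = dict(config.concentration)
    for metal in config.toxicology:
        if metal not in conc_specs:
            if records is None or origin is None:
                raise ValueError(
                    f"no concentration spec for {metal.value} and no records/origin to fit one"
                )
            conc_specs[metal] = fit_spec_from_records(records, origin, metal)

    rng = np.random.default_rng(config.seed)
    n = config.n_iter
    samples: dict[str, np.ndarray] = {}
    # Fixed sampling order: metals alphabetically, then groups by name (dc, bw).
    for metal in sorted(conc_specs, key=lambda m: m.value):
        samples[f"concentration[{metal.value}]"] = sample_distribution(conc_specs[metal], n, rng)
    for group in sorted(config.dc):
        samples[f"dc[{group}]"] = sample_distribution(config.dc[group], n, rng)
        samples[f"bw[{group}]"] = sample_distribution(config.bw[group], n, rng)

    edi: dict[tuple[str, Metal], np.ndarray] = {}
    hq: dict[tuple[str, Metal], np.ndarray] = {}
    ilcr_v: dict[tuple[str, Metal], np.ndarray] = {}
    hi: dict[str, np.ndarray] = {}
    for group in sorted(config.dc):
        dc_draw = samples[f"dc[{group}]"]
        bw_draw = samples[f"bw[{group}]"]
        hqs = []
        for metal in sorted(conc_specs, key=lambda m: m.value):
            cm = samples[f"concentration[{metal.value}]"]
            e = dc_draw * cm / bw_draw
            edi[(group, metal)] = e
            tox = config.toxicology[metal]
            hq[(group, metal)] = er.hazard_quotient(e, tox.rfd)
            hqs.append(hq[(group, metal)])
            if tox.csf is not None:
                ilcr_v[(group, metal)] = er.ilcr(e, tox.csf)
        hi[group] = er.hazard_index(hqs)
    return SimulationResult(
        config=config, samples=samples, edi=edi, hq=hq, ilcr=ilcr_v, hi=hi
    )


def config_from_records(
    records: Iterable[ConcentrationRecord],
    origin: Origin,
    populations: Mapping[str, PopulationGroup] | None = None,
    toxicology: Mapping[Metal, ToxicologyParams] | None = None,
    family: str = "lognormal",
    n_iter: int = 10_000,
    seed: int = 0,
) -> SimulationConfig:
    """Build a simulation config for one origin from observed records.

    Concentrations get ``family`` specs fitted to the origin's infusion
    values; DC and BW default to point values from the population
    registry (the conventional choice when no consumption survey
    distribution is available).
    """
    records = list(records)
    populations = populations or default_populations()
    toxicology = toxicology or default_toxicology()
    conc = {
        metal: fit_spec_from_records(records, origin, metal, family=family)
        for metal in Metal
        if metal in toxicology
    }
    dc = {name: DistributionSpec.point(p.dc) for name, p in populations.items()}
    bw = {name: DistributionSpec.point(p.bw) for name, p in populations.items()}
    return SimulationConfig(
        concentration=conc, dc=dc, bw=bw, toxicology=toxicology, n_iter=n_iter, seed=seed
    )


# --------------------------------------------------------------------------
# Distribution read-outs
# --------------------------------------------------------------------------


def percentile(values, q: float) -> float:
    """Linear-interpolation quantile (the numpy default convention)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile of empty vector")
    if not 0 <= q <= 1:
        raise ValueError(f"q must be in [0, 1], got {q!r}")
    return float(np.quantile(values, q, method="linear"))


@dataclass(frozen=True)
class FrequencyTable:
    """Cumulative and reverse-cumulative frequency over equal-width bins.

    ``cumulative[j]`` is the fraction of values at or below ``edges[j]``
    (0 at the left edge, 1 at the right); ``reverse`` its complement.
    """

    edges: np.ndarray
    cumulative: np.ndarray
    reverse: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"edge": self.edges, "cumulative": self.cumulative, "reverse": self.reverse}
        )


def cumulative_frequency(values, n_bins: int = 20) -> FrequencyTable:
    """Equal-width frequency table spanning [min, max] of ``values``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cumulative_frequency of empty vector")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    counts, edges = np.histogram(values, bins=n_bins)
    cumulative = np.concatenate([[0.0], np.cumsum(counts) / values.size])
    return FrequencyTable(edges=edges, cumulative=cumulative, reverse=1.0 - cumulative)


@dataclass(frozen=True)
class ExceedanceResult:
    """Fraction of iterations strictly above a threshold, and its complement."""

    threshold: float
    fraction_above: float
    fraction_at_or_below: float


def exceedance_fraction(values, threshold: float) -> ExceedanceResult:
    """P(X > threshold) over the sampled vector, with the ≤ complement."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("exceedance_fraction of empty vector")
    above = float(np.mean(values > threshold))
    return ExceedanceResult(
        threshold=float(threshold),
        fraction_above=above,
        fraction_at_or_below=1.0 - above,
    )
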