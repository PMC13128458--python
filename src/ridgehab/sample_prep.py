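"""Measurement-level corrections and per-compartment aggregation.

Raw field measurements need three kinds of handling before they can enter
the standing-stock budget:

* a multiplicative recovery correction for chlorophyll-a filters that
  were oven-dried before extraction (dried filters yield 1.8x less);
* conversion of ³H-leucine incorporation rates to bacterial carbon
  production via the standard 1.5 kg C per mol leucine factor;
* separation of biogenic from lithogenic silica in a time-course
  alkaline digestion, where mineral dissolution is linear in time and
  the biogenic pool appears as the y-intercept of the trailing linear
  phase;
* aggregation of per-sample values into mean ± SE per compartment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DRIED_CHLA_FACTOR, LEUCINE_TO_CARBON_KG_PER_MOL
from .stock_budget import ConcentrationEstimate

__all__ = [
    "SampleRecord",
    "DigestionTimeCourse",
    "correct_dried_chla",
    "leucine_to_carbon",
    "bsi_lsi_split",
    "aggregate_compartment",
    "read_samples",
    "read_timecourse",
]


@dataclass(frozen=True)
class SampleRecord:
    """One field measurement of one variable in one habitat compartment."""

    variable: str
    ice_type: str
    compartment: str
    date: str  # ISO-8601
    value: float
    dried_flag: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"concentration value must be >= 0, got {self.value}")


@dataclass(frozen=True)
class DigestionTimeCourse:
    """Cumulative Si liberated by alkaline digestion, plus the HF phase.

    ``timepoints`` (hours) must be strictly increasing and the cumulative
    ``alkaline_liberated_si`` (µmol L⁻¹) non-decreasing; ``hf_phase_si``
    is the Si solubilized afterwards by hydrofluoric acid.
    """

    timepoints: tuple[float, ...]
    alkaline_liberated_si: tuple[float, ...]
    hf_phase_si: float

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        si = np.asarray(self.alkaline_liberated_si, dtype=float)
        if t.size != si.size:
            raise ValueError("timepoints and Si series differ in length")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if si.size and not np.all(np.diff(si) >= -1e-12):
            raise ValueError("cumulative Si series must be non-decreasing")
        if self.hf_phase_si < 0:
            raise ValueError("HF-phase Si must be >= 0")


def correct_dried_chla(value: float, factor: float = DRIED_CHLA_FACTOR) -> float:
    """Scale a dried-filter Chl-a concentration up by the recovery factor.

    Dried filters retain ``factor`` times less Chl-a than standard-treated
    ones, so the measured value is multiplied by the factor (default 1.8).
    """
    if value < 0:
        raise ValueError(f"Chl-a concentration must be >= 0, got {value}")
    if factor <= 0:
        raise ValueError(f"correction factor must be > 0, got {factor}")
    return value * factor


def leucine_to_carbon(
    leu_incorporation: float, cf: float = LEUCINE_TO_CARBON_KG_PER_MOL
) -> float:
    """Convert leucine incorporation (nmol L⁻¹ d⁻¹) to bacterial carbon
    production (mg C m⁻³ d⁻¹).

    With cf in kg C per mol leucine, the unit algebra collapses to a pure
    scaling: 1 nmol L⁻¹ d⁻¹ x cf = cf mg C m⁻³ d⁻¹ (1e-9 mol x 1e6 mg/kg
    ... x 1e3 L/m³ cancel).  Incubation-time normalization to per-day is
    assumed done upstream; no isotope dilution is applied.
    """
    if leu_incorporation < 0:
        raise ValueError(
            f"leucine incorporation must be >= 0, got {leu_incorporation}"
        )
    return leu_incorporation * cf


def bsi_lsi_split(
    tc: DigestionTimeCourse, linear_window: int = 3
) -> tuple[float, float]:
    """Split a digestion time-course into biogenic and lithogenic silica.

    Biogenic silica dissolves quickly; the slow linear tail of the
    cumulative curve is mineral dissolution.  An ordinary least-squares
    line through the trailing ``linear_window`` points is extrapolated to
    t = 0: its intercept is BSi, and LSi is the remaining alkaline-phase
    Si (final cumulative minus BSi) plus the HF phase.

    Returns ``(bsi, lsi)`` in µmol L⁻¹.  A negative fitted intercept is
    clipped to 0 with a warning.
    """
    t = np.asarray(tc.timepoints, dtype=float)
    si = np.asarray(tc.alkaline_liberated_si, dtype=float)
    if linear_window < 2:
        raise ValueError(f"linear window must be >= 2 points, got {linear_window}")
    if t.size < linear_window + 1:
        raise ValueError(
            f"need at least {linear_window + 1} timepoints for a "
            f"{linear_window}-point trailing fit, got {t.size}"
        )
    slope, intercept = np.polyfit(t[-linear_window:], si[-linear_window:], 1)
    bsi = float(intercept)
    if bsi < 0:
        warnings.warn(
            f"fitted BSi intercept {bsi:.3g} µmol/L is negative; clipping to 0",
            stacklevel=2,
        )
        bsi = 0.0
    lsi = (float(si[-1]) - bsi) + tc.hf_phase_si
    return bsi, lsi


def aggregate_compartment(samples: Sequence[SampleRecord]) -> ConcentrationEstimate:
    """Collapse per-sample values into a mean ± SE concentration estimate.

    SE is the sample standard deviation (ddof=1) over sqrt(n).  Dried
    Chl-a samples are corrected before averaging.  A single-sample
    compartment has no defined SE; it is reported as 0 with the
    ``degenerate`` flag set (single-core sampling does occur in the
    field).
    """
    if len(samples) == 0:
        raise ValueError("cannot aggregate an empty sample list")
    keys = {(s.variable, s.ice_type, s.compartment) for s in samples}
    if len(keys) != 1:
        raise ValueError(f"samples span multiple compartments: {sorted(keys)}")
    variable, ice_type, compartment = keys.pop()
    values = np.array(
        [
            correct_dried_chla(s.value) if s.dried_flag and s.variable == "chla"
            else s.value
            for s in samples
        ]
    )
    n = values.size
    if n == 1:
        return ConcentrationEstimate(
            variable, ice_type, compartment,
            float(values[0]), 0.0, 1, degenerate=True,
        )
    se = float(values.std(ddof=1) / np.sqrt(n))
    return ConcentrationEstimate(
        variable, ice_type, compartment, float(values.mean()), se, int(n)
    )


def read_samples(path, sep: str = ",") -> list[SampleRecord]:
    """Read sample records from delimited text with columns variable,
    ice_type, compartment, date, value, dried_flag."""
    df = pd.read_csv(path, sep=sep)
    required = ["variable", "ice_type", "compartment", "date", "value", "dried_flag"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample file {path} missing columns: {missing}")
    return [
        SampleRecord(
            r.variable, r.ice_type, r.compartment, str(r.date),
            float(r.value), bool(r.dried_flag),
        )
        for r in df.itertuples()
    ]


def read_timecourse(path, hf_phase_si: float, sep: str = ",") -> DigestionTimeCourse:
    """Read a digestion time-course (columns time_h, si_umol_l)."""
    df = pd.read_csv(path, sep=sep)
    for col in ("time_h", "si_umol_l"):
        if col not in df.columns:
            raise ValueError(f"time-course file {path} missing column {col}")
    return DigestionTimeCourse(
        tuple(df.time_h), tuple(df.si_umol_l), hf_phase_si
    )
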