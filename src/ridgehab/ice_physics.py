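"""Brine volume fraction and permeability of sea ice.

Sea ice is a mushy two-phase medium: the liquid brine fraction, a function
of bulk salinity S (PSS-78, dimensionless) and ice temperature T (°C),
controls whether the pore space is connected and therefore habitable and
permeable to nutrient exchange.  The conventional connectivity threshold
for columnar ice is a brine volume fraction of 5%; ice above it is treated
as permeable.

Two published parameterizations are provided:

* ``brine_fraction_fg`` — the closed form of Frankenstein & Garner (1967),
  V_b/V = S (0.532 + 49.185/|T|) / 1000, valid for −22.9 °C ≤ T ≤ −0.5 °C.
* ``brine_fraction_cw`` — the phase relations of Cox & Weeks (1983) with
  the warm-ice (−2 °C < T < 0 °C) extension of Leppäranta & Manninen
  (1988), assuming air-free ice.

Both are monotonically increasing in S at fixed T and increasing toward
the melting point at fixed S; they agree to within a few percent over the
salinities and temperatures typical of Arctic first-year ice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .constants import (
    CW_COLD,
    CW_MAIN,
    LM_WARM,
    FG_T_MIN,
    FG_T_MAX,
    PERMEABILITY_THRESHOLD,
    SEAWATER_FREEZING_POINT_C,
)

__all__ = [
    "IceSection",
    "BrineState",
    "brine_fraction_fg",
    "brine_fraction_cw",
    "classify_permeability",
    "profile_brine_fractions",
    "level_ice_temperature",
    "scenario_brine_fractions",
    "read_profile",
    "write_profile_with_brine",
]


@dataclass(frozen=True)
class IceSection:
    """A depth interval of an ice core with its bulk salinity and temperature.

    Depths are meters below the reference (upper) surface, so
    ``depth_bottom > depth_top``.  Temperature must be at or below 0 °C for
    the section to enter brine-physics calculations.
    """

    depth_top: float
    depth_bottom: float
    bulk_salinity: float
    temperature: float

    def validate(self) -> None:
        if not self.depth_bottom > self.depth_top:
            raise ValueError(
                f"depth_bottom ({self.depth_bottom}) must exceed depth_top "
                f"({self.depth_top})"
            )
        if self.bulk_salinity < 0:
            raise ValueError(f"bulk salinity must be >= 0, got {self.bulk_salinity}")
        if self.temperature > 0:
            raise ValueError(
                f"ice temperature must be <= 0 °C for brine calculations, "
                f"got {self.temperature}"
            )


@dataclass(frozen=True)
class BrineState:
    """Brine volume fraction of a section and its permeability class."""

    brine_volume_fraction: float
    permeable: bool


def _check_inputs(bulk_salinity: float, temperature: float) -> None:
    if bulk_salinity < 0:
        raise ValueError(f"bulk salinity must be >= 0, got {bulk_salinity}")
    if temperature >= 0:
        raise ValueError(
            f"brine fraction is undefined at T >= 0 °C (got {temperature})"
        )


def brine_fraction_fg(bulk_salinity: float, temperature: float) -> float:
    """Frankenstein–Garner closed-form brine volume fraction.

    V_b/V = S (0.532 + 49.185/|T|) / 1000, valid on [−22.9, −0.5] °C.

    Raises
    ------
    ValueError
        If the temperature is positive or outside the closed form's
        validity range.
    """
    _check_inputs(bulk_salinity, temperature)
    if not (FG_T_MIN <= temperature <= FG_T_MAX):
        raise ValueError(
            f"temperature {temperature} °C outside Frankenstein–Garner "
            f"validity range [{FG_T_MIN}, {FG_T_MAX}] °C"
        )
    frac = bulk_salinity * (0.532 + 49.185 / abs(temperature)) / 1000.0
    return min(frac, 1.0)


def _poly3(coeffs: Sequence[float], t: float) -> float:
    a0, a1, a2, a3 = coeffs
    return a0 + a1 * t + a2 * t * t + a3 * t * t * t


def _ice_density(t: float) -> float:
    # pure-ice density, g cm^-3 (Pounder 1965)
    return 0.917 - 1.403e-4 * t


def brine_fraction_cw(bulk_salinity: float, temperature: float) -> float:
    """Cox–Weeks / Leppäranta–Manninen brine volume fraction (air-free ice).

    Uses the phase-relation polynomials F1(T), F2(T) with the bulk density
    of gas-free ice, rho = rho_i F1 / (F1 − rho_i S F2):

        V_b/V = rho S / F1(T)

    Coefficient sets (see :mod:`ridgehab.constants`): Cox & Weeks for
    −30 ≤ T ≤ −22.9 and −22.9 < T ≤ −2 °C; Leppäranta & Manninen for
    −2 < T < 0 °C.  The piece boundary at −2 °C is continuous to about
    2e-4 per salinity unit (the two publications fitted F1/F2
    independently).
    """
    _check_inputs(bulk_salinity, temperature)
    if temperature < -30.0:
        raise ValueError(
            f"temperature {temperature} °C below phase-relation validity (−30 °C)"
        )
    if temperature <= -22.9:
        coeffs = CW_COLD
    elif temperature <= -2.0:
        coeffs = CW_MAIN
    else:
        coeffs = LM_WARM
    f1 = _poly3(coeffs.f1, temperature)
    f2 = _poly3(coeffs.f2, temperature)
    rho_i = _ice_density(temperature)
    rho = rho_i * f1 / (f1 - rho_i * bulk_salinity * f2)
    return min(rho * bulk_salinity / f1, 1.0)


def classify_permeability(
    brine_volume_fraction: float, threshold: float = PERMEABILITY_THRESHOLD
) -> BrineState:
    """Classify a brine volume fraction against the permeability threshold.

    Permeable means *strictly* above the threshold (default 5%); ice at
    exactly the threshold is classified impermeable.
    """
    if not 0.0 <= brine_volume_fraction <= 1.0:
        raise ValueError(
            f"brine volume fraction must lie in [0, 1], got {brine_volume_fraction}"
        )
    return BrineState(brine_volume_fraction, brine_volume_fraction > threshold)


_METHODS = {"fg": brine_fraction_fg, "cw": brine_fraction_cw}


def profile_brine_fractions(
    sections: Sequence[IceSection],
    method: Literal["fg", "cw"] = "cw",
    threshold: float = PERMEABILITY_THRESHOLD,
) -> list[BrineState]:
    """Apply a brine parameterization to every section of a core profile."""
    if len(sections) == 0:
        raise ValueError("empty ice profile")
    try:
        func = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown brine method {method!r}; use 'fg' or 'cw'")
    states = []
    for i, sec in enumerate(sections):
        try:
            sec.validate()
            frac = func(sec.bulk_salinity, sec.temperature)
        except ValueError as exc:
            raise ValueError(f"section {i}: {exc}") from exc
        states.append(classify_permeability(frac, threshold))
    return states


def level_ice_temperature(
    surface_t: float,
    freezing_point: float = SEAWATER_FREEZING_POINT_C,
    convention: Literal["mid", "surface", "bottom"] = "mid",
) -> float:
    """Representative level-ice temperature for bulk brine estimates.

    Level ice spans a near-linear gradient from the (cold) surface to the
    seawater freezing point at the bottom; the default convention evaluates
    brine volume at the mid-depth mean of the two.
    """
    if convention == "mid":
        return 0.5 * (surface_t + freezing_point)
    if convention == "surface":
        return surface_t
    if convention == "bottom":
        return freezing_point
    raise ValueError(f"unknown temperature convention {convention!r}")


def scenario_brine_fractions(
    rubble_salinity: float = 4.0,
    level_salinity: float = 5.0,
    surface_t: float = -10.0,
    freezing_point: float = SEAWATER_FREEZING_POINT_C,
    method: Literal["fg", "cw"] = "fg",
    level_convention: Literal["mid", "surface", "bottom"] = "mid",
) -> tuple[float, float]:
    """Winter-scenario brine fractions for ridge rubble and level ice.

    Submerged keel rubble sits at the seawater freezing point; level ice is
    evaluated at the temperature convention of
    :func:`level_ice_temperature`.  With the defaults (rubble S = 4, level
    S = 5, surface −10 °C) the Frankenstein–Garner form gives roughly 10%
    brine in rubble and 5% in level ice.

    Returns ``(vb_rubble, vb_level)``.
    """
    func = _METHODS[method]
    vb_rbl = func(rubble_salinity, freezing_point)
    vb_li = func(
        level_salinity, level_ice_temperature(surface_t, freezing_point, level_convention)
    )
    return vb_rbl, vb_li


_PROFILE_COLUMNS = ["depth_top_m", "depth_bottom_m", "bulk_salinity", "temperature_c"]


def read_profile(path, sep: str = ",") -> list[IceSection]:
    """Read a core profile from delimited text.

    Expects columns depth_top_m, depth_bottom_m, bulk_salinity,
    temperature_c.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile file {path} missing columns: {missing}")
    return [
        IceSection(r.depth_top_m, r.depth_bottom_m, r.bulk_salinity, r.temperature_c)
        for r in df.itertuples()
    ]


def write_profile_with_brine(
    sections: Iterable[IceSection],
    states: Iterable[BrineState],
    path,
    sep: str = ",",
) -> pd.DataFrame:
    """Write a profile with brine fraction and permeability columns added."""
    rows = [
        {
            "depth_top_m": s.depth_top,
            "depth_bottom_m": s.depth_bottom,
            "bulk_salinity": s.bulk_salinity,
            "temperature_c": s.temperature,
            "brine_volume_fraction": b.brine_volume_fraction,
            "permeable": b.permeable,
        }
        for s, b in zip(sections, states, strict=True)
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep=sep, index=False)
    return df
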