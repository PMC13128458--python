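"""Seeded synthetic field data with the statistical structure the
budget analysis assumes.

The generator stands in for the deposited field observations: it draws
per-compartment concentration samples whose summary statistics emulate
the July campaign table (means, SEs and sample counts), simulates
drill-line void/ice logs through a keel with a stated macroporosity, and
builds ice-core temperature/salinity profiles for the brine physics.
Everything is bit-reproducible given (spec, seed).

Concentration draws come from a zero-truncated normal by default —
concentrations are non-negative, and several compartments have SEs of
the same order as the mean, so an untruncated normal would go negative.
The distribution is parameterized by its *parent* (pre-truncation)
mean and sd; the realized population mean of the truncated law
(:meth:`CompartmentSpec.population_mean`) is therefore larger whenever
truncation bites, and parameter-recovery experiments must compare
against the truncated moments, not the parent ones.  A moment-matched
lognormal is available as an alternative for strongly skewed
compartments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ice_physics import IceSection
from .ridge_geometry import RidgeMorphology
from .sample_prep import SampleRecord
from .uncert import Measurement

__all__ = [
    "CompartmentSpec",
    "DrillSpec",
    "gen_samples",
    "gen_drill_profiles",
    "estimate_macroporosity",
    "gen_ice_profile",
]

_DISTRIBUTIONS = ("truncated_normal_at_zero", "lognormal")


@dataclass(frozen=True)
class CompartmentSpec:
    """Sampling law for one (variable, ice type, compartment) cell.

    ``true_mean``/``true_sd`` parameterize the generating distribution:
    for the truncated normal they are the parent normal's parameters; for
    the lognormal they are matched exactly to the distribution's mean and
    sd.
    """

    variable: str
    ice_type: str
    compartment: str
    true_mean: float
    true_sd: float
    n: int
    distribution: str = "truncated_normal_at_zero"

    def __post_init__(self) -> None:
        if self.true_mean < 0 or self.true_sd < 0:
            raise ValueError("true_mean and true_sd must be >= 0")
        if self.n < 1:
            raise ValueError(f"sample count must be >= 1, got {self.n}")
        if self.distribution not in _DISTRIBUTIONS:
            raise ValueError(
                f"unsupported distribution {self.distribution!r}; "
                f"choose one of {_DISTRIBUTIONS}"
            )

    def _frozen(self):
        m, s = self.true_mean, self.true_sd
        if self.distribution == "truncated_normal_at_zero":
            a = (0.0 - m) / s  # truncation point in parent sigma units
            return stats.truncnorm(a, np.inf, loc=m, scale=s)
        # lognormal moment-matched to (m, s)
        if m == 0:
            raise ValueError("lognormal requires true_mean > 0")
        sigma2 = math.log(1.0 + (s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        return stats.lognorm(math.sqrt(sigma2), scale=math.exp(mu))

    def population_mean(self) -> float:
        """Analytic mean of the generating distribution (post-truncation)."""
        if self.true_sd == 0:
            return self.true_mean
        return float(self._frozen().mean())

    def population_sd(self) -> float:
        """Analytic standard deviation of the generating distribution."""
        if self.true_sd == 0:
            return 0.0
        return float(self._frozen().std())


def gen_samples(spec: CompartmentSpec, seed: int) -> list[SampleRecord]:
    """Draw ``spec.n`` sample records from the compartment's law."""
    rng = np.random.default_rng(seed)
    if spec.true_sd == 0:
        values = np.full(spec.n, spec.true_mean)
    else:
        dist = spec._frozen()
        values = dist.ppf(rng.uniform(size=spec.n))
    return [
        SampleRecord(
            spec.variable, spec.ice_type, spec.compartment,
            date="2020-07-01", value=float(max(v, 0.0)),
        )
        for v in values
    ]


@dataclass(frozen=True)
class DrillSpec:
    """Drilling survey through a keel: line count and vertical resolution."""

    morphology: RidgeMorphology
    n_drill_lines: int
    vertical_resolution: float

    def __post_init__(self) -> None:
        if self.n_drill_lines < 1:
            raise ValueError("need at least one drill line")
        if self.vertical_resolution <= 0:
            raise ValueError("vertical resolution must be > 0")


def gen_drill_profiles(spec: DrillSpec, seed: int) -> list[np.ndarray]:
    """Simulate drill-line void/ice logs through the rubble layer.

    Each log covers the rubble (consolidated base to keel bottom) at the
    stated resolution; each cell is void (True) independently with
    probability equal to the macroporosity.  The consolidated layer is
    all ice and is not logged.  Cell independence is a simplification —
    real voids are spatially correlated — but only the porosity
    estimator, not void geometry, rests on these logs.
    """
    morph = spec.morphology
    h_rbl = morph.rubble_thickness
    if spec.vertical_resolution > h_rbl:
        raise ValueError(
            f"vertical resolution {spec.vertical_resolution} m exceeds the "
            f"rubble thickness {h_rbl} m"
        )
    n_cells = int(round(h_rbl / spec.vertical_resolution))
    rng = np.random.default_rng(seed)
    return [
        rng.uniform(size=n_cells) < morph.macroporosity
        for _ in range(spec.n_drill_lines)
    ]


def estimate_macroporosity(logs: list[np.ndarray]) -> Measurement:
    """Estimate rubble macroporosity from drill logs.

    Point estimate: pooled void-cell fraction over all rubble cells.
    SE: spread of the per-line void fractions (sd / sqrt(lines)), which
    captures line-to-line heterogeneity.  A single line has no defined
    SE and is flagged degenerate.
    """
    if len(logs) == 0:
        raise ValueError("no drill logs supplied")
    per_line = np.array([np.mean(log) for log in logs], dtype=float)
    pooled = float(np.concatenate(logs).mean())
    if len(logs) == 1:
        return Measurement(pooled, 0.0, degenerate=True)
    se = float(per_line.std(ddof=1) / np.sqrt(len(logs)))
    return Measurement(pooled, se)


def gen_ice_profile(
    surface_t: float,
    bottom_t: float,
    salinity_profile: list[float],
    seed: int = 0,
    total_depth: float = 1.4,
    temperature_jitter: float = 0.0,
) -> list[IceSection]:
    """Build an ice-core profile with linear temperature interpolation.

    One section per salinity entry, equally thick over ``total_depth``;
    each section's temperature is the linear surface-to-bottom gradient
    evaluated at the section midpoint, plus optional seeded Gaussian
    jitter (clipped at 0 °C).
    """
    if len(salinity_profile) == 0:
        raise ValueError("empty salinity profile")
    if any(s < 0 for s in salinity_profile):
        raise ValueError("salinities must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(salinity_profile)
    dz = total_depth / n
    sections = []
    for i, s in enumerate(salinity_profile):
        mid = (i + 0.5) / n
        t = surface_t + (bottom_t - surface_t) * mid
        if temperature_jitter > 0:
            t = min(t + rng.normal(0.0, temperature_jitter), 0.0)
        sections.append(IceSection(i * dz, (i + 1) * dz, s, t))
    return sections
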