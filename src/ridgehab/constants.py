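"""Physical constants and published coefficient tables.

Phase-relation coefficients are pinned here in one place, with citation
strings, so that tests can assert against the published values and the
CLI can echo the provenance of every constant it uses.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhaseCoefficients:
    """Cubic F1/F2 phase-relation coefficients over one temperature range."""

    t_min: float
    t_max: float
    f1: tuple[float, float, float, float]
    f2: tuple[float, float, float, float]
    citation: str


# Cox, G.F.N. & Weeks, W.F. (1983), J. Glaciol. 29(102), 306-316:
# equations for determining the gas and brine volumes in sea-ice samples.
CW_COLD = PhaseCoefficients(
    t_min=-30.0,
    t_max=-22.9,
    f1=(9899.0, 1309.0, 55.27, 0.7160),
    f2=(8.547, 1.089, 0.04518, 5.819e-4),
    citation="Cox & Weeks (1983), J. Glaciol. 29(102), Table 1, -30 <= T <= -22.9 C",
)

CW_MAIN = PhaseCoefficients(
    t_min=-22.9,
    t_max=-2.0,
    f1=(-4.732, -22.45, -0.6397, -0.01074),
    f2=(8.903e-2, -1.763e-2, -5.33e-4, -8.801e-6),
    citation="Cox & Weeks (1983), J. Glaciol. 29(102), Table 1, -22.9 < T <= -2 C",
)

# Leppäranta, M. & Manninen, T. (1988), Finnish Inst. Marine Res. Internal
# Report 88-2: brine and gas content of sea ice with attention to low
# salinities and high temperatures (warm-ice extension, -2 < T < 0 C).
LM_WARM = PhaseCoefficients(
    t_min=-2.0,
    t_max=0.0,
    f1=(-0.041221, -18.407, 0.58402, 0.21454),
    f2=(0.090312, -0.016111, 1.2291e-4, 1.3603e-4),
    citation="Leppäranta & Manninen (1988), FIMR Internal Report 88-2, -2 < T < 0 C",
)

# Frankenstein & Garner (1967), J. Glaciol. 6(48), 943-944: closed-form
# brine volume valid for -22.9 <= T <= -0.5 C.
FG_T_MIN = -22.9
FG_T_MAX = -0.5
FG_CITATION = "Frankenstein & Garner (1967), J. Glaciol. 6(48), 943-944"

#: Conventional brine-connectivity (permeability) threshold for columnar ice,
#: brine volume fraction; ice strictly above it is treated as permeable.
PERMEABILITY_THRESHOLD = 0.05

#: Freezing point of Arctic surface seawater, °C (configurable; no
#: salinity-dependent formula is applied).
SEAWATER_FREEZING_POINT_C = -1.9

#: Default ice block length : thickness aspect ratio for ridge rubble.
BLOCK_ASPECT_RATIO = 3.5

#: Submerged fraction of level ice (ice/seawater density ratio) used to
#: convert total thickness to draft when only thickness is known.
SUBMERGED_FRACTION = 0.9

#: Multiplicative correction for chlorophyll-a measured on filters that
#: were oven-dried before extraction (dried filters retain 1.8x less).
DRIED_CHLA_FACTOR = 1.8

#: Leucine-to-carbon conversion for bacterial production, kg C per mol of
#: incorporated leucine.  Derived from 1797 g protein per mol leucine and
#: 0.86 g C per g protein (Simon & Azam 1989), assuming no isotope
#: dilution; the two underlying constants are provenance only and are
#: never re-multiplied.
LEUCINE_TO_CARBON_KG_PER_MOL = 1.5
LEUCINE_PROTEIN_G_PER_MOL = 1797.0
CARBON_PER_PROTEIN_G_PER_G = 0.86

CITATIONS = {
    "brine_fg": FG_CITATION,
    "brine_cw_cold": CW_COLD.citation,
    "brine_cw_main": CW_MAIN.citation,
    "brine_lm_warm": LM_WARM.citation,
    "permeability_threshold": "Golden et al. (1998) percolation threshold, ~5%",
    "dried_chla_factor": "paired dried/non-dried filter comparison, factor 1.8",
    "leucine_to_carbon": "Simon & Azam (1989): 1797 g protein/mol leu x 0.86 g C/g protein",
}
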