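"""Geometric model of pressure-ridge keels and level ice.

A ridge keel of depth ``h_k`` below the waterline consists of a
consolidated layer (thickness ``h_c``, blocks frozen together) underlain
by unconsolidated rubble of loose ice blocks with water-filled voids
occupying a macroporosity fraction ``mu``.  Treating the rubble as a
stack of blocks of thickness ``h_b`` and length ``l_b``, the model yields

* the ratio of total ice-block surface area in the rubble to the
  horizontal keel footprint (:func:`surface_area_ratio`),
* the ratio of total brine volume in the ridge to that in level ice
  (:func:`brine_volume_ratio`), and
* per-compartment *unit volumes* — m³ of compartment per m² of the ice
  type's areal footprint, i.e. meters (:func:`ridge_unit_volumes`,
  :func:`level_unit_volumes`).

Compartments partition each ice type into the habitats sampled in the
field: for ridges, the water-filled voids, a 10-cm *exterior* skin on the
upper and lower faces of each rubble block, the remaining block +
consolidated *interior*, and a 10-cm *bottom* layer; for level ice, the
interior and the bottom 10 cm.  Only the submerged part (draft/keel) is
counted: the sail and freeboard are not algal habitat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .constants import BLOCK_ASPECT_RATIO, SUBMERGED_FRACTION

__all__ = [
    "RidgeMorphology",
    "LevelIceMorphology",
    "CompartmentVolumes",
    "IceTypeCover",
    "surface_area_ratio",
    "brine_volume_ratio",
    "ridge_unit_volumes",
    "level_unit_volumes",
    "thickness_to_draft",
    "volume_fractions",
    "habitable_ice_volume_per_type",
]


@dataclass(frozen=True)
class RidgeMorphology:
    """Keel geometry: depths in m below the waterline, fractions in [0, 1].

    ``block_length`` defaults to 3.5 x ``block_thickness`` (typical rubble
    block aspect ratio) when not given.
    """

    keel_depth: float
    consolidated_thickness: float
    macroporosity: float
    block_thickness: float
    block_length: float | None = None
    exterior_skin: float = 0.1
    bottom_layer: float = 0.1

    def __post_init__(self) -> None:
        if self.block_length is None:
            object.__setattr__(
                self, "block_length", BLOCK_ASPECT_RATIO * self.block_thickness
            )
        if not 0 < self.consolidated_thickness <= self.keel_depth:
            raise ValueError(
                f"need 0 < consolidated thickness ({self.consolidated_thickness}) "
                f"<= keel depth ({self.keel_depth})"
            )
        if not 0 <= self.macroporosity <= 1:
            raise ValueError(f"macroporosity must be in [0, 1], got {self.macroporosity}")
        if self.block_thickness <= 0:
            raise ValueError(f"block thickness must be > 0, got {self.block_thickness}")
        if self.block_length < self.block_thickness:
            raise ValueError(
                f"block length ({self.block_length}) must be >= thickness "
                f"({self.block_thickness})"
            )
        if self.exterior_skin > self.block_thickness / 2:
            raise ValueError(
                f"exterior skin ({self.exterior_skin}) cannot exceed half the "
                f"block thickness ({self.block_thickness / 2})"
            )

    @property
    def rubble_thickness(self) -> float:
        """Unconsolidated rubble thickness h_k − h_c, m."""
        return self.keel_depth - self.consolidated_thickness


@dataclass(frozen=True)
class LevelIceMorphology:
    """Level-ice draft (m below the waterline) and bottom-layer thickness."""

    draft: float
    bottom_layer: float = 0.1

    def __post_init__(self) -> None:
        if not self.draft > self.bottom_layer:
            raise ValueError(
                f"draft ({self.draft}) must exceed the bottom layer "
                f"({self.bottom_layer})"
            )


@dataclass(frozen=True)
class CompartmentVolumes:
    """Unit volumes (m³ per m² of the ice type's footprint) by compartment.

    Level ice has zero voids and exterior; ridge compartments follow the
    block-stack construction.  ``total_ice`` is always derived from the
    components (never a separate closed form), and ``total`` additionally
    includes the water-filled voids.
    """

    interior: float
    bottom: float
    exterior: float = 0.0
    voids: float = 0.0

    def __post_init__(self) -> None:
        for name in ("interior", "bottom", "exterior", "voids"):
            if getattr(self, name) < 0:
                raise ValueError(f"compartment volume {name} must be >= 0")

    @property
    def total_ice(self) -> float:
        """Ice-only unit volume: interior + exterior + bottom, m."""
        return self.interior + self.exterior + self.bottom

    @property
    def total(self) -> float:
        """Total habitat unit volume including voids, m."""
        return self.total_ice + self.voids

    def as_dict(self) -> dict[str, float]:
        d = {"interior": self.interior, "bottom": self.bottom}
        if self.exterior or self.voids:
            d["exterior"] = self.exterior
            d["voids"] = self.voids
        return d

    def __getitem__(self, compartment: str) -> float:
        try:
            return getattr(self, compartment)
        except AttributeError:
            raise KeyError(compartment)


@dataclass(frozen=True)
class IceTypeCover:
    """Areal fractions of ridges, first- and second-year level ice."""

    ridge: float
    fyi: float
    syi: float

    def __post_init__(self) -> None:
        for name in ("ridge", "fyi", "syi"):
            f = getattr(self, name)
            if not 0 <= f <= 1:
                raise ValueError(f"areal fraction {name}={f} outside [0, 1]")
        if self.ridge + self.fyi + self.syi > 1 + 1e-9:
            raise ValueError("areal fractions sum above 1")

    def __getitem__(self, ice_type: str) -> float:
        try:
            return getattr(self, ice_type)
        except AttributeError:
            raise KeyError(ice_type)


def surface_area_ratio(
    morph: RidgeMorphology, rubble_thickness_override: float | None = None
) -> float:
    """Ice-block surface area in the rubble per m² of keel footprint,
    relative to the same for level ice.

    S_rbl / S_li = h_rbl (1 − mu) / (h_b l_b) · (l_b + 2 h_b)

    Counts the top, bottom and two end faces of each block in a stack of
    h_rbl (1 − mu) / h_b blocks per unit footprint.  Young unconsolidated
    keels typically come out 20–30x level ice, so even a few percent
    ridge coverage can double the ice–water interface of a floe.
    """
    h_rbl = (
        rubble_thickness_override
        if rubble_thickness_override is not None
        else morph.rubble_thickness
    )
    if h_rbl < 0:
        raise ValueError(f"rubble thickness must be >= 0, got {h_rbl}")
    h_b, l_b = morph.block_thickness, morph.block_length
    if h_b * l_b == 0:
        raise ValueError("block dimensions must be positive")
    return h_rbl * (1 - morph.macroporosity) / (h_b * l_b) * (l_b + 2 * h_b)


def brine_volume_ratio(
    h_cl: float,
    h_rbl: float,
    h_li: float,
    mu: float,
    vb_rbl: float,
    vb_li: float,
) -> float:
    """Total ridge brine volume relative to level ice of thickness h_li.

    V_b,rdg / V_b,li = h_cl/h_li + h_rbl (1 − mu)/h_li · (v_b,rbl / v_b,li)

    The consolidated layer is assumed to hold brine like level ice, while
    submerged rubble blocks near the freezing point are far more porous
    (v_b,rbl / v_b,li ≈ 2 in winter), which is what makes ridges
    disproportionately habitable.
    """
    if h_cl <= 0 or h_li <= 0:
        raise ValueError("consolidated and level-ice thicknesses must be > 0")
    if h_rbl < 0:
        raise ValueError(f"rubble thickness must be >= 0, got {h_rbl}")
    if vb_li <= 0:
        raise ValueError("level-ice brine fraction must be > 0")
    return h_cl / h_li + h_rbl * (1 - mu) / h_li * (vb_rbl / vb_li)


def ridge_unit_volumes(morph: RidgeMorphology) -> CompartmentVolumes:
    """Per-compartment unit volumes of a ridge keel, m³ per m² footprint.

    voids    = h_rbl · mu
    exterior = h_rbl (1 − mu)/h_b · 2 δ_ext        (skin on both block faces)
    interior = h_c + h_rbl (1 − mu)/h_b · (h_b − 2 δ_ext)
    bottom   = δ_bot

    Total ice volume is the sum of the ice components; it is not computed
    from a separate closed form.
    """
    h_rbl = morph.rubble_thickness
    if h_rbl < 0:
        raise ValueError(f"rubble thickness must be >= 0, got {h_rbl}")
    mu = morph.macroporosity
    n_blocks = h_rbl * (1 - mu) / morph.block_thickness  # blocks per m² footprint
    return CompartmentVolumes(
        voids=h_rbl * mu,
        exterior=n_blocks * 2 * morph.exterior_skin,
        interior=morph.consolidated_thickness
        + n_blocks * (morph.block_thickness - 2 * morph.exterior_skin),
        bottom=morph.bottom_layer,
    )


def level_unit_volumes(level: LevelIceMorphology) -> CompartmentVolumes:
    """Unit volumes of level ice: interior (draft minus bottom layer) and
    the bottom layer itself."""
    return CompartmentVolumes(
        interior=level.draft - level.bottom_layer, bottom=level.bottom_layer
    )


def thickness_to_draft(
    thickness: float, submerged_fraction: float = SUBMERGED_FRACTION
) -> float:
    """Convert total level-ice thickness to draft via the submerged fraction
    (ice/seawater density ratio, default 0.9)."""
    if thickness <= 0:
        raise ValueError(f"thickness must be > 0, got {thickness}")
    if not 0 < submerged_fraction <= 1:
        raise ValueError(
            f"submerged fraction must be in (0, 1], got {submerged_fraction}"
        )
    return thickness * submerged_fraction


def volume_fractions(
    vols_by_type: Mapping[str, CompartmentVolumes], cover: IceTypeCover
) -> dict[tuple[str, str], float]:
    """Fraction of the total ice-covered volume held by each
    (ice type, compartment) cell, coverage-weighted and normalized to 1."""
    weighted = {
        (ice_type, comp): vol * cover[ice_type]
        for ice_type, vols in vols_by_type.items()
        for comp, vol in vols.as_dict().items()
    }
    total = sum(weighted.values())
    if total <= 0:
        raise ValueError("total coverage-weighted volume is zero")
    return {key: v / total for key, v in weighted.items()}


def habitable_ice_volume_per_type(
    vols_by_type: Mapping[str, CompartmentVolumes], cover: IceTypeCover
) -> dict[str, float]:
    """Ice-only unit volume of each ice type per m² of *total* sea-ice area
    (coverage-weighted; water-filled voids excluded)."""
    return {
        ice_type: vols.total_ice * cover[ice_type]
        for ice_type, vols in vols_by_type.items()
    }
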