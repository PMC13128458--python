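"""Run configuration: YAML parsing and the packaged MOSAiC fixture.

A run configuration bundles the keel morphology, level-ice geometry,
areal coverages, concentration estimates (or synthetic sampling specs)
and reporting precision.  :func:`mosaic_config` loads the packaged July
drifting-station configuration that the worked examples and the
reference budget use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .ridge_geometry import (
    CompartmentVolumes,
    IceTypeCover,
    LevelIceMorphology,
    RidgeMorphology,
    level_unit_volumes,
    ridge_unit_volumes,
    thickness_to_draft,
)
from .stock_budget import ConcentrationEstimate

__all__ = ["RunConfig", "ConfigError", "load_config", "mosaic_config"]


class ConfigError(ValueError):
    """Raised when a run configuration is incomplete or inconsistent."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run the geometry + budget pipeline."""

    morphology: RidgeMorphology
    fyi: LevelIceMorphology
    syi: LevelIceMorphology
    cover: IceTypeCover
    concentrations: tuple[ConcentrationEstimate, ...] = ()
    precision: int = 2
    seed: int | None = None
    source: str = "<in-memory>"

    def __post_init__(self) -> None:
        if self.precision < 1:
            raise ConfigError("reporting precision must be >= 1 significant figure")

    def unit_volumes(self) -> dict[str, CompartmentVolumes]:
        """Compartment unit volumes for all three ice types."""
        return {
            "ridge": ridge_unit_volumes(self.morphology),
            "fyi": level_unit_volumes(self.fyi),
            "syi": level_unit_volumes(self.syi),
        }

    def echo(self) -> dict:
        """Plain-dict snapshot of the configuration for run logs."""
        return {
            "source": self.source,
            "morphology": vars(self.morphology).copy(),
            "fyi_draft_m": self.fyi.draft,
            "syi_draft_m": self.syi.draft,
            "cover": vars(self.cover).copy(),
            "n_concentration_cells": len(self.concentrations),
            "precision": self.precision,
            "seed": self.seed,
        }


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"missing key {key!r} in {context}")
    return mapping[key]


def _build(raw: dict, source: str, seed: int | None = None) -> RunConfig:
    problems: list[str] = []
    try:
        m = _require(raw, "morphology", source)
        morph = RidgeMorphology(
            keel_depth=_require(m, "keel_depth", "morphology"),
            consolidated_thickness=_require(m, "consolidated_thickness", "morphology"),
            macroporosity=_require(m, "macroporosity", "morphology"),
            block_thickness=_require(m, "block_thickness", "morphology"),
            block_length=m.get("block_length"),
            exterior_skin=m.get("exterior_skin", 0.1),
            bottom_layer=m.get("bottom_layer", 0.1),
        )
    except (ConfigError, ValueError) as exc:
        problems.append(f"morphology: {exc}")
        morph = None
    level = raw.get("level_ice", {})
    sub = level.get("submerged_fraction", 0.9)
    bottom = level.get("bottom_layer", 0.1)
    fyi = syi = None
    try:
        if "fyi_draft" in level:
            fyi = LevelIceMorphology(level["fyi_draft"], bottom)
        else:
            fyi = LevelIceMorphology(
                thickness_to_draft(_require(level, "fyi_thickness", "level_ice"), sub),
                bottom,
            )
        if "syi_draft" in level:
            syi = LevelIceMorphology(level["syi_draft"], bottom)
        else:
            syi = LevelIceMorphology(
                thickness_to_draft(_require(level, "syi_thickness", "level_ice"), sub),
                bottom,
            )
    except (ConfigError, ValueError) as exc:
        problems.append(f"level_ice: {exc}")
    try:
        c = _require(raw, "cover", source)
        cover = IceTypeCover(
            _require(c, "ridge", "cover"), _require(c, "fyi", "cover"),
            _require(c, "syi", "cover"),
        )
    except (ConfigError, ValueError) as exc:
        problems.append(f"cover: {exc}")
        cover = None
    concs = []
    for i, row in enumerate(raw.get("concentrations", [])):
        try:
            concs.append(
                ConcentrationEstimate(
                    row["variable"], row["ice_type"], row["compartment"],
                    float(row["mean"]), float(row["se"]), int(row["n"]),
                )
            )
        except (KeyError, ValueError) as exc:
            problems.append(f"concentrations[{i}]: {exc}")
    if problems:
        raise ConfigError("; ".join(problems))
    return RunConfig(
        morphology=morph,
        fyi=fyi,
        syi=syi,
        cover=cover,
        concentrations=tuple(concs),
        precision=int(raw.get("reporting", {}).get("precision", 2)),
        seed=seed,
        source=source,
    )


def load_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Load a run configuration from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} is not a mapping")
    return _build(raw, str(path), seed)


def mosaic_config(seed: int | None = None) -> RunConfig:
    """The packaged MOSAiC July configuration (keel morphology, coverages
    and per-compartment concentration estimates)."""
    ref = resources.files("ridgehab").joinpath("data/mosaic.yaml")
    raw = yaml.safe_load(ref.read_text())
    return _build(raw, "packaged:mosaic.yaml", seed)
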