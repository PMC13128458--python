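"""Standing-stock accounting: concentrations x volumes -> areal budgets.

Given per-compartment concentration estimates (mean ± SE, mg m⁻³) and the
compartment unit volumes from :mod:`ridgehab.ridge_geometry`, this module
builds the habitat budget of an ice pack:

* per-compartment stock, mg per m² of total sea-ice area;
* per-ice-type stock per m² of that type's own footprint (``per_area``);
* the same weighted by areal coverage (``per_coverage``), i.e. the
  contribution per m² of total sea ice;
* relative contributions (%) of ridge / FYI / SYI to the total stock.

SEs propagate to first order assuming independent compartment errors and
exact volumes and coverages: constants scale SE linearly, sums add SEs in
quadrature, and percentage shares use the delta method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ridge_geometry import CompartmentVolumes, IceTypeCover
from .uncert import Measurement, combine_sum, round_sig, share_percent

__all__ = [
    "ConcentrationEstimate",
    "StockTable",
    "compartment_stock",
    "per_area_stock",
    "per_volume_stock",
    "per_coverage_stock",
    "relative_fractions",
    "build_budget",
    "c_to_chla_ratio",
    "read_concentrations",
]

ICE_TYPES = ("ridge", "fyi", "syi")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Mean ± SE concentration (mg m⁻³) of one variable in one compartment."""

    variable: str
    ice_type: str
    compartment: str
    mean: float
    se: float
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError(f"mean concentration must be >= 0, got {self.mean}")
        if self.se < 0:
            raise ValueError(f"SE must be >= 0, got {self.se}")
        if self.n < 1:
            raise ValueError(f"sample count must be >= 1, got {self.n}")

    @property
    def measurement(self) -> Measurement:
        return Measurement(self.mean, self.se, self.degenerate)


@dataclass(frozen=True)
class StockTable:
    """Machine twin of the budget tables.

    ``compartments`` mirrors the per-compartment table (unit volume,
    volume fraction, concentration, coverage-weighted stock per cell);
    ``ice_types`` mirrors the per-ice-type summary (per-volume, per-area,
    per-coverage and relative stocks).  Values are unrounded; use
    :meth:`rounded` for display at a chosen number of significant figures.
    """

    compartments: pd.DataFrame
    ice_types: pd.DataFrame

    def rounded(self, sig: int = 2) -> "StockTable":
        def _round(df: pd.DataFrame) -> pd.DataFrame:
            out = df.copy()
            for col in out.columns:
                if out[col].dtype.kind == "f":
                    out[col] = out[col].map(lambda x: round_sig(x, sig))
            return out

        return StockTable(_round(self.compartments), _round(self.ice_types))

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "compartments": self.compartments.to_dict(orient="records"),
                "ice_types": self.ice_types.to_dict(orient="records"),
            },
            **kwargs,
        )


def compartment_stock(
    conc: ConcentrationEstimate, unit_volume: float, areal_fraction: float
) -> Measurement:
    """Stock of one compartment per m² of total sea ice:
    mean x unit volume x areal coverage, SE scaled identically."""
    if unit_volume < 0:
        raise ValueError(f"unit volume must be >= 0, got {unit_volume}")
    if not 0 <= areal_fraction <= 1:
        raise ValueError(f"areal fraction must be in [0, 1], got {areal_fraction}")
    return conc.measurement.scaled(unit_volume * areal_fraction)


def _match_compartments(
    concs: Sequence[ConcentrationEstimate], vols: CompartmentVolumes
) -> list[tuple[ConcentrationEstimate, float]]:
    vol_map = vols.as_dict()
    have = {c.compartment for c in concs}
    missing_vol = sorted(have - vol_map.keys())
    missing_conc = sorted(vol_map.keys() - have)
    if missing_vol or missing_conc:
        raise ValueError(
            "compartment mismatch: concentrations without a volume "
            f"{missing_vol}, volumes without a concentration {missing_conc}"
        )
    return [(c, vol_map[c.compartment]) for c in concs]


def per_area_stock(
    concs: Sequence[ConcentrationEstimate], vols: CompartmentVolumes
) -> Measurement:
    """Depth-integrated stock per m² of the ice type's own footprint:
    sum of mean_i x v_i over compartments, SEs in quadrature."""
    pairs = _match_compartments(concs, vols)
    return combine_sum(c.measurement.scaled(v) for c, v in pairs)


def per_volume_stock(per_area: Measurement, total_unit_volume: float) -> Measurement:
    """Mean concentration over the whole ice-type column (stock / volume)."""
    if total_unit_volume <= 0:
        raise ValueError(f"total unit volume must be > 0, got {total_unit_volume}")
    return per_area.scaled(1.0 / total_unit_volume)


def per_coverage_stock(per_area: Measurement, areal_fraction: float) -> Measurement:
    """Contribution of the ice type per m² of total sea ice."""
    if not 0 <= areal_fraction <= 1:
        raise ValueError(f"areal fraction must be in [0, 1], got {areal_fraction}")
    return per_area.scaled(areal_fraction)


def relative_fractions(
    per_coverage_by_type: Mapping[str, Measurement],
) -> dict[str, Measurement]:
    """Percent share of each ice type in the total stock (sums to 100).

    SEs come from the first-order delta method with independent inputs.
    """
    if all(m.value == 0 for m in per_coverage_by_type.values()):
        raise ValueError("all per-coverage stocks are zero; shares undefined")
    out = {}
    for ice_type, m in per_coverage_by_type.items():
        others = [v for k, v in per_coverage_by_type.items() if k != ice_type]
        out[ice_type] = share_percent(m, others)
    return out


def build_budget(
    concs: Iterable[ConcentrationEstimate],
    vols_by_type: Mapping[str, CompartmentVolumes],
    cover: IceTypeCover,
) -> dict[str, StockTable]:
    """Assemble the full budget, one :class:`StockTable` per variable.

    Every (variable, ice type) pair present must cover all compartments of
    that ice type's :class:`CompartmentVolumes`; missing cells raise with
    an enumeration of what is absent.
    """
    concs = list(concs)
    if not concs:
        raise ValueError("no concentration estimates supplied")
    variables = sorted({c.variable for c in concs})
    # coverage-weighted volume fractions, shared across variables
    from .ridge_geometry import volume_fractions

    vfrac = volume_fractions(vols_by_type, cover)

    tables: dict[str, StockTable] = {}
    for var in variables:
        rows = []
        per_area: dict[str, Measurement] = {}
        per_cov: dict[str, Measurement] = {}
        missing: list[tuple[str, str, str]] = []
        for ice_type, vols in vols_by_type.items():
            sub = [c for c in concs if c.variable == var and c.ice_type == ice_type]
            have = {c.compartment for c in sub}
            absent = [
                (var, ice_type, comp) for comp in vols.as_dict() if comp not in have
            ]
            if absent:
                missing += absent
                continue
            pa = per_area_stock(sub, vols)
            pc = per_coverage_stock(pa, cover[ice_type])
            # internal consistency: per-coverage equals the compartment sum
            direct = combine_sum(
                compartment_stock(c, vols[c.compartment], cover[ice_type]) for c in sub
            )
            assert abs(direct.value - pc.value) < 1e-9
            per_area[ice_type] = pa
            per_cov[ice_type] = pc
            for c in sub:
                stock = compartment_stock(c, vols[c.compartment], cover[ice_type])
                rows.append(
                    {
                        "ice_type": ice_type,
                        "compartment": c.compartment,
                        "unit_volume_m": vols[c.compartment],
                        "areal_coverage": cover[ice_type],
                        "volume_fraction": vfrac[(ice_type, c.compartment)],
                        "n": c.n,
                        "conc_mean_mg_m3": c.mean,
                        "conc_se_mg_m3": c.se,
                        "stock_mg_m2": stock.value,
                        "stock_se_mg_m2": stock.se,
                    }
                )
        if missing:
            raise ValueError(f"missing concentration cells: {missing}")
        rel = relative_fractions(per_cov)
        type_rows = []
        for ice_type in vols_by_type:
            pv = per_volume_stock(per_area[ice_type], vols_by_type[ice_type].total)
            type_rows.append(
                {
                    "ice_type": ice_type,
                    "per_volume_mg_m3": pv.value,
                    "per_volume_se": pv.se,
                    "per_area_mg_m2": per_area[ice_type].value,
                    "per_area_se": per_area[ice_type].se,
                    "per_coverage_mg_m2": per_cov[ice_type].value,
                    "per_coverage_se": per_cov[ice_type].se,
                    "relative_pct": rel[ice_type].value,
                    "relative_se_pct": rel[ice_type].se,
                }
            )
        tables[var] = StockTable(pd.DataFrame(rows), pd.DataFrame(type_rows))
    return tables


def c_to_chla_ratio(
    poc_stock: Measurement, chla_stock: Measurement, basis: str
) -> dict[str, object]:
    """POC : Chl-a ratio on a stated basis ('per_volume' or 'per_area').

    The ratio is a diagnostic of stored versus actively growing biomass
    (high values indicate detrital/stored carbon).  The computation basis
    is recorded alongside the number because the ratio is not invariant to
    it once stocks are rounded.
    """
    if basis not in ("per_volume", "per_area"):
        raise ValueError(f"basis must be 'per_volume' or 'per_area', got {basis!r}")
    if chla_stock.value <= 0:
        raise ValueError("Chl-a stock must be > 0 for a C:Chl-a ratio")
    return {"ratio": poc_stock.value / chla_stock.value, "basis": basis}


def read_concentrations(path, sep: str = ",") -> list[ConcentrationEstimate]:
    """Read concentration estimates from delimited text with columns
    variable, ice_type, compartment, mean, se, n."""
    df = pd.read_csv(path, sep=sep)
    required = ["variable", "ice_type", "compartment", "mean", "se", "n"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"concentration file {path} missing columns: {missing}")
    return [
        ConcentrationEstimate(
            r.variable, r.ice_type, r.compartment, r.mean, r.se, int(r.n)
        )
        for r in df.itertuples()
    ]
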