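"""Standing-stock accounting and error propagation."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ridgehab.ridge_geometry import CompartmentVolumes, IceTypeCover
from ridgehab.stock_budget import (
    ConcentrationEstimate,
    build_budget,
    c_to_chla_ratio,
    compartment_stock,
    per_area_stock,
    per_coverage_stock,
    per_volume_stock,
    relative_fractions,
    read_concentrations,
)
from ridgehab.uncert import Measurement

RIDGE_VOLS = CompartmentVolumes(interior=2.67, bottom=0.1, exterior=0.94, voids=0.29)
FYI_VOLS = CompartmentVolumes(interior=1.2, bottom=0.1)
SYI_VOLS = CompartmentVolumes(interior=1.3, bottom=0.1)
COVER = IceTypeCover(0.22, 0.50, 0.28)


def _conc(var, ice_type, comp, mean, se=0.0, n=3):
    return ConcentrationEstimate(var, ice_type, comp, mean, se, n)


RIDGE_CHLA = [
    _conc("chla", "ridge", "interior", 2.6, 0.9, 23),
    _conc("chla", "ridge", "exterior", 19.0, 9.0, 16),
    _conc("chla", "ridge", "voids", 3.0, 1.0, 3),
    _conc("chla", "ridge", "bottom", 1.2, 0.2, 5),
]


class TestCompartmentStock:
    def test_ridge_interior_chla(self):
        m = compartment_stock(RIDGE_CHLA[0], 2.67, 0.22)
        assert m.value == pytest.approx(1.5, abs=0.05)

    def test_ridge_interior_poc(self):
        m = compartment_stock(_conc("poc", "ridge", "interior", 420, 60, 21), 2.67, 0.22)
        assert m.value == pytest.approx(250, abs=5)

    def test_se_scales_exactly_with_constants(self):
        m = compartment_stock(RIDGE_CHLA[0], 2.67, 0.22)
        assert m.se == pytest.approx(0.9 * 2.67 * 0.22)
        assert m.se == pytest.approx(0.5, abs=0.03)

    def test_zero_concentration(self):
        m = compartment_stock(_conc("chla", "fyi", "interior", 0.0), 1.2, 0.5)
        assert m == Measurement(0.0, 0.0)


class TestPerAreaStock:
    def test_ridge_chla_table_values(self):
        m = per_area_stock(RIDGE_CHLA, RIDGE_VOLS)
        assert m.value == pytest.approx(25.8, abs=0.05)

    def test_fyi_chla(self):
        concs = [
            _conc("chla", "fyi", "interior", 0.9, 0.1, 60),
            _conc("chla", "fyi", "bottom", 3.9, 0.9, 5),
        ]
        assert per_area_stock(concs, FYI_VOLS).value == pytest.approx(1.47)

    def test_all_zero_concentrations(self):
        concs = [
            _conc("chla", "fyi", "interior", 0.0),
            _conc("chla", "fyi", "bottom", 0.0),
        ]
        assert per_area_stock(concs, FYI_VOLS) == Measurement(0.0, 0.0)

    def test_compartment_mismatch_is_enumerated(self):
        with pytest.raises(ValueError, match="bottom"):
            per_area_stock([RIDGE_CHLA[0]], FYI_VOLS)

    def test_matches_exact_rational_summation(self):
        """Brute-force oracle: the volume-weighted sum over <=4 compartments
        agrees with exact rational arithmetic on integer-scaled inputs."""
        exact = sum(
            Fraction(m) * Fraction(v)
            for m, v in [("2.6", "2.67"), ("19", "0.94"), ("3", "0.29"), ("1.2", "0.1")]
        )
        m = per_area_stock(RIDGE_CHLA, RIDGE_VOLS)
        assert m.value == pytest.approx(float(exact), abs=1e-12)


class TestRescalings:
    def test_per_volume(self):
        assert per_volume_stock(Measurement(25.8, 5.0), 4.0).value == pytest.approx(
            6.45
        )
        assert per_volume_stock(Measurement(1035.0, 90.0), 1.4).value == pytest.approx(
            739.3, abs=0.05
        )

    def test_per_volume_rejects_zero_volume(self):
        with pytest.raises(ValueError):
            per_volume_stock(Measurement(25.8, 5.0), 0.0)

    def test_per_coverage(self):
        m = per_coverage_stock(Measurement(25.8, 9.0), 0.22)
        assert m.value == pytest.approx(5.68, abs=0.005)
        assert m.se == pytest.approx(9.0 * 0.22)
        assert per_coverage_stock(Measurement(431.0, 0.0), 0.5).value == pytest.approx(
            215.5
        )

    def test_per_coverage_identity_at_full_cover(self):
        m = Measurement(25.8, 9.0)
        assert per_coverage_stock(m, 1.0) == m


class TestRelativeFractions:
    def test_chla_shares(self):
        rel = relative_fractions(
            {
                "ridge": Measurement(5.68, 1.9),
                "fyi": Measurement(0.735, 0.07),
                "syi": Measurement(0.378, 0.04),
            }
        )
        assert rel["ridge"].value == pytest.approx(84, abs=1)
        assert 60 <= rel["ridge"].value <= 100  # the ~80 +/- 20 % band
        assert sum(m.value for m in rel.values()) == pytest.approx(100.0)

    def test_poc_shares(self):
        rel = relative_fractions(
            {
                "ridge": Measurement(346.0, 41.0),
                "fyi": Measurement(215.5, 21.0),
                "syi": Measurement(289.8, 26.0),
            }
        )
        assert rel["ridge"].value == pytest.approx(41, abs=0.5)

    def test_single_nonzero_type_gets_everything(self):
        rel = relative_fractions(
            {"ridge": Measurement(5.0, 1.0), "fyi": Measurement(0.0, 0.0)}
        )
        assert rel["ridge"].value == 100.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            relative_fractions({"ridge": Measurement(0.0, 0.0)})


class TestBuildBudget:
    def test_mosaic_headline_numbers(self, mosaic_cfg, mosaic_vols):
        tables = build_budget(mosaic_cfg.concentrations, mosaic_vols, mosaic_cfg.cover)
        poc = tables["poc"].ice_types.set_index("ice_type")
        assert poc.loc["ridge", "per_area_mg_m2"] == pytest.approx(1570, abs=10)
        assert poc.loc["syi", "per_area_mg_m2"] == pytest.approx(1035, abs=1)
        chla = tables["chla"].ice_types.set_index("ice_type")
        assert chla.loc["ridge", "relative_pct"] == pytest.approx(84, abs=1)

    def test_relative_shares_sum_to_100(self, mosaic_cfg, mosaic_vols):
        tables = build_budget(mosaic_cfg.concentrations, mosaic_vols, mosaic_cfg.cover)
        for table in tables.values():
            assert table.ice_types.relative_pct.sum() == pytest.approx(100.0, abs=0.5)

    def test_per_coverage_equals_compartment_sum(self, mosaic_cfg, mosaic_vols):
        tables = build_budget(mosaic_cfg.concentrations, mosaic_vols, mosaic_cfg.cover)
        for table in tables.values():
            by_type = table.compartments.groupby("ice_type").stock_mg_m2.sum()
            summary = table.ice_types.set_index("ice_type").per_coverage_mg_m2
            for ice_type in by_type.index:
                assert by_type[ice_type] == pytest.approx(summary[ice_type], abs=1e-9)

    def test_missing_cells_are_enumerated(self, mosaic_cfg, mosaic_vols):
        concs = [c for c in mosaic_cfg.concentrations
                 if not (c.variable == "poc" and c.ice_type == "syi")]
        with pytest.raises(ValueError, match="syi"):
            build_budget(concs, mosaic_vols, mosaic_cfg.cover)

    def test_empty_input_rejected(self, mosaic_vols, mosaic_cfg):
        with pytest.raises(ValueError, match="no concentration"):
            build_budget([], mosaic_vols, mosaic_cfg.cover)

    @settings(max_examples=20, deadline=None)
    @given(k=st.floats(0.1, 10.0))
    def test_scale_equivariance(self, mosaic_cfg, mosaic_vols, k):
        """Multiplying all concentrations by k scales every stock by k and
        leaves the relative shares unchanged."""
        base = build_budget(mosaic_cfg.concentrations, mosaic_vols, mosaic_cfg.cover)
        scaled_concs = [
            ConcentrationEstimate(
                c.variable, c.ice_type, c.compartment, c.mean * k, c.se * k, c.n
            )
            for c in mosaic_cfg.concentrations
        ]
        scaled = build_budget(scaled_concs, mosaic_vols, mosaic_cfg.cover)
        for var in base:
            b = base[var].ice_types.set_index("ice_type")
            s = scaled[var].ice_types.set_index("ice_type")
            for ice_type in b.index:
                assert s.loc[ice_type, "per_area_mg_m2"] == pytest.approx(
                    k * b.loc[ice_type, "per_area_mg_m2"]
                )
                assert s.loc[ice_type, "relative_pct"] == pytest.approx(
                    b.loc[ice_type, "relative_pct"]
                )


class TestCarbonChlaRatio:
    def test_per_area_basis_is_recorded(self):
        out = c_to_chla_ratio(Measurement(1574.0), Measurement(25.8), "per_area")
        assert out["basis"] == "per_area"
        assert out["ratio"] == pytest.approx(61, abs=0.5)

    def test_per_volume_basis(self):
        out = c_to_chla_ratio(Measurement(739.0), Measurement(0.96), "per_volume")
        assert out["ratio"] == pytest.approx(770, abs=1)

    def test_equal_stocks_ratio_one(self):
        assert c_to_chla_ratio(Measurement(5.0), Measurement(5.0), "per_area")[
            "ratio"
        ] == 1.0

    def test_zero_chla_rejected(self):
        with pytest.raises(ValueError):
            c_to_chla_ratio(Measurement(5.0), Measurement(0.0), "per_area")


def test_read_concentrations_roundtrip(tmp_path):
    path = tmp_path / "concs.csv"
    path.write_text(
        "variable,ice_type,compartment,mean,se,n\n"
        "chla,ridge,interior,2.6,0.9,23\n"
        "poc,fyi,bottom,950,220,5\n"
    )
    concs = read_concentrations(path)
    assert concs[0].mean == 2.6 and concs[0].n == 23
    assert concs[1].variable == "poc"
    with pytest.raises(ValueError, match="missing columns"):
        bad = tmp_path / "bad.csv"
        bad.write_text("variable,mean\nchla,1\n")
        read_concentrations(bad)
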