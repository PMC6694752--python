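"""Unit and property tests for the hydraulic pedo-transfer functions."""

import math

import numpy as np
import pytest
from ptf_oracle import (
    oracle_KS,
    oracle_theta33,
    oracle_theta1500,
    oracle_thetaS,
)

from gridsol.ptf import (
    FLAG_OK,
    InvalidSoilInputError,
    OrganicContent,
    TextureComposition,
    derive_hydraulics_grid,
    derive_layer_hydraulics,
    field_capacity,
    organic_carbon_to_matter,
    saturated_conductivity,
    saturation,
    wilting_point,
)


def sweep_points(step_pct=2, om_values=(0.0, 2.0, 4.0, 8.0)):
    pts = []
    for s in range(0, 101, step_pct):
        for c in range(0, 101 - s, step_pct):
            for om in om_values:
                pts.append((s / 100.0, c / 100.0, om))
    return pts


class TestOrganicCarbonToMatter:
    @pytest.mark.parametrize(
        "oc_g_kg, oc_pct, om_pct",
        [(10.0, 1.0, 2.0), (0.0, 0.0, 0.0), (17.24, 1.724, 3.448)],
    )
    def test_conversion_uses_factor_two(self, oc_g_kg, oc_pct, om_pct):
        out = organic_carbon_to_matter(oc_g_kg)
        assert out.organic_carbon_pct == pytest.approx(oc_pct)
        assert out.organic_matter_pct == pytest.approx(om_pct)
        if oc_pct > 0:
            # explicitly not the conventional van-Bemmelen factor
            assert out.organic_matter_pct != pytest.approx(1.724 * oc_pct, rel=1e-6)

    def test_negative_input_rejected(self):
        with pytest.raises(InvalidSoilInputError):
            organic_carbon_to_matter(-1.0)


class TestTextureInvariants:
    def test_components_must_close(self):
        with pytest.raises(InvalidSoilInputError):
            TextureComposition(50.0, 30.0, 30.0)

    def test_components_must_be_in_range(self):
        with pytest.raises(InvalidSoilInputError):
            TextureComposition(120.0, -10.0, -10.0)

    def test_fraction_accessors(self):
        t = TextureComposition(40.0, 20.0, 40.0)
        assert t.sand_frac == 0.4 and t.clay_frac == 0.2

    def test_percent_scale_rejected_at_equation_boundary(self):
        # sand/clay must enter the regressions as fractions, not percent
        with pytest.raises(InvalidSoilInputError):
            wilting_point((40.0, 20.0), 2.0)


class TestRetentionEquations:
    def test_zero_input_corner(self):
        # hand evaluation at S = C = OM = 0
        assert wilting_point((0.0, 0.0), 0.0) == pytest.approx(0.01534, abs=1e-12)
        t33t = 0.299
        expected = t33t + (1.283 * t33t**2 - 0.374 * t33t - 0.015)
        assert field_capacity((0.0, 0.0), 0.0) == pytest.approx(expected, abs=1e-12)

    def test_reference_loam_point(self):
        om = OrganicContent(1.0, 2.0)
        tex = TextureComposition(20.0, 30.0, 50.0)
        assert wilting_point(tex, om) == pytest.approx(0.188, abs=5e-4)
        assert field_capacity(tex, om) == pytest.approx(0.350, abs=5e-4)
        assert saturation(tex, om) > field_capacity(tex, om)

    def test_pure_sand_corner_is_direct_substitution(self):
        s, c, om = 1.0, 0.0, 0.0
        expected = oracle_theta33(s, c, om) + (
            oracle_thetaS(s, c, om) - oracle_theta33(s, c, om))
        assert saturation((s, c), om) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("func, oracle", [
        (wilting_point, oracle_theta1500),
        (field_capacity, oracle_theta33),
        (saturation, oracle_thetaS),
    ])
    def test_matches_independent_transcription(self, func, oracle):
        for s, c, om in sweep_points():
            assert func((s, c), om) == pytest.approx(oracle(s, c, om), rel=1e-12, abs=1e-15)

    def test_wilting_point_increases_with_clay(self):
        # partial derivative wrt C is 0.487 + 0.068 S - 0.013 OM > 0 on the
        # agricultural domain, so theta1500 must rise with clay
        for s in (0.0, 0.2, 0.5):
            for om in (0.0, 3.0, 8.0):
                vals = [wilting_point((s, c / 100.0), om)
                        for c in range(0, int((1 - s) * 100), 5)]
                assert all(b > a for a, b in zip(vals, vals[1:]))


class TestSaturatedConductivity:
    def test_reference_point(self):
        # B = ln(1500/33)/ln(3), lambda = 1/B, KS = 1930 * 0.15^(3-lambda)
        b = math.log(1500.0 / 33.0) / math.log(3.0)
        expected = 1930.0 * 0.15 ** (3.0 - 1.0 / b)
        ks = saturated_conductivity(0.10, 0.30, 0.45)
        assert ks == pytest.approx(expected, rel=1e-12)
        assert ks == pytest.approx(11.2, abs=0.2)  # hand evaluation

    def test_zero_base(self):
        assert saturated_conductivity(0.10, 0.30, 0.30) == 0.0

    def test_monotone_in_moisture_difference(self):
        ks = [saturated_conductivity(0.10, 0.30, 0.30 + d)
              for d in (0.05, 0.10, 0.20)]
        assert ks[0] < ks[1] < ks[2]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidSoilInputError):
            saturated_conductivity(0.30, 0.30, 0.45)
        with pytest.raises(InvalidSoilInputError):
            saturated_conductivity(0.30, 0.10, 0.45)


class TestDeriveLayerHydraulics:
    def test_loam_layer_bundle(self):
        tex = TextureComposition(40.0, 20.0, 40.0)
        h = derive_layer_hydraulics(tex, 15.0)
        s, c, om = 0.4, 0.2, 3.0
        assert h.theta1500 == pytest.approx(oracle_theta1500(s, c, om), rel=1e-12)
        assert h.theta33 == pytest.approx(oracle_theta33(s, c, om), rel=1e-12)
        assert h.thetaS == pytest.approx(oracle_thetaS(s, c, om), rel=1e-12)
        assert h.ks_mm_h == pytest.approx(
            oracle_KS(h.theta1500, h.theta33, h.thetaS), rel=1e-12)
        assert 0 < h.theta1500 < h.theta33 < h.thetaS < 1
        assert h.flags == FLAG_OK
        assert h.ks_cm_h == h.ks_mm_h / 10.0

    def test_missing_oc_is_an_error(self):
        tex = TextureComposition(40.0, 20.0, 40.0)
        with pytest.raises(InvalidSoilInputError, match="incomplete"):
            derive_layer_hydraulics(tex, float("nan"))

    def test_determinism(self):
        tex = TextureComposition(33.0, 27.0, 40.0)
        a = derive_layer_hydraulics(tex, 12.5)
        b = derive_layer_hydraulics(tex, 12.5)
        assert a == b

    def test_out_of_domain_is_flagged_never_silent(self):
        # an extreme sandy, OM-rich corner drives the regressions out of
        # their fitted domain; output must be clamped and flagged
        flagged = 0
        for s in (0.9, 0.95, 1.0):
            h = derive_layer_hydraulics(
                TextureComposition(s * 100, 0.0, 100 - s * 100), 80.0)
            assert 0 < h.theta1500 < h.theta33 < h.thetaS <= 0.60
            flagged += h.flags != FLAG_OK
        assert flagged > 0

    def test_sweep_ordering_and_flags(self):
        for s, c, om in sweep_points(step_pct=4):
            sp, cp = round(s * 100), round(c * 100)
            h = derive_layer_hydraulics(
                TextureComposition(sp, cp, 100 - sp - cp), om * 5.0)
            assert 0 < h.theta1500 < h.theta33 < h.thetaS < 1
            raw_ok = (
                oracle_theta1500(s, c, om) >= 0.01
                and oracle_theta33(s, c, om) - oracle_theta1500(s, c, om) >= 0.01
                and oracle_thetaS(s, c, om) <= 0.60
                and oracle_thetaS(s, c, om) > oracle_theta33(s, c, om) + 2e-3
            )
            if raw_ok:
                assert h.flags == FLAG_OK
            else:
                assert h.flags != FLAG_OK


class TestVectorisedGrid:
    def test_matches_scalar_path(self):
        sand = np.array([[20.0, 40.0], [60.0, 80.0]])
        clay = np.array([[30.0, 20.0], [15.0, 8.0]])
        oc = np.array([[10.0, 15.0], [5.0, 2.0]])
        g = derive_hydraulics_grid(sand, clay, oc)
        for i in range(2):
            for j in range(2):
                tex = TextureComposition(
                    sand[i, j], clay[i, j], 100 - sand[i, j] - clay[i, j])
                h = derive_layer_hydraulics(tex, oc[i, j])
                assert g["theta1500"][i, j] == pytest.approx(h.theta1500, rel=1e-14)
                assert g["theta33"][i, j] == pytest.approx(h.theta33, rel=1e-14)
                assert g["thetaS"][i, j] == pytest.approx(h.thetaS, rel=1e-14)
                assert g["ks_mm_h"][i, j] == pytest.approx(h.ks_mm_h, rel=1e-14)

    def test_nan_propagates(self):
        g = derive_hydraulics_grid(
            np.array([np.nan, 40.0]), np.array([20.0, 20.0]),
            np.array([10.0, np.nan]))
        assert np.isnan(g["theta1500"][0]) and np.isnan(g["theta33"][1])
        assert g["flags"][0] == 0
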