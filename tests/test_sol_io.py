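"""Round-trip and robustness tests for the *.SOL reader/writer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridsol.sol import (
    LAYER_FIELDS,
    MISSING,
    STANDARD_SLB,
    STANDARD_SLMH,
    SoilLayerRecord,
    SoilProfile,
    SolFormatError,
    SolParseError,
    SurfaceParameters,
    format_profile,
    read_sol,
    write_sol,
)

_PRECISION = {name: dec for name, kind, dec in LAYER_FIELDS if kind == "float"}


def make_profile(rng: np.random.Generator, pid="TS00000001") -> SoilProfile:
    """A randomized valid six-layer profile."""
    layers = []
    for slb, slmh in zip(STANDARD_SLB, STANDARD_SLMH):
        slll = rng.uniform(0.05, 0.25)
        sdul = slll + rng.uniform(0.02, 0.2)
        ssat = sdul + rng.uniform(0.01, 0.2)
        clay = rng.uniform(5, 55)
        silt = rng.uniform(5, 90 - clay)
        layers.append(SoilLayerRecord(
            slb=slb, slmh=slmh,
            slll=slll, sdul=sdul, ssat=ssat,
            srgf=rng.uniform(0, 1),
            ssks=rng.uniform(0.01, 80),
            sbdm=rng.uniform(0.9, 1.8),
            sloc=rng.uniform(0, 6),
            slcl=clay, slsi=silt,
            slcf=MISSING,
            slni=rng.uniform(0, 0.4),
            slhw=rng.uniform(4, 9),
            slhb=MISSING,
            scec=rng.uniform(1, 60),
        ))
    return SoilProfile(
        profile_id=pid, country="KE",
        lat=rng.uniform(-90, 90), lon=rng.uniform(-180, 180),
        description="randomized test profile",
        surface=SurfaceParameters(
            salb=round(rng.uniform(0.05, 0.3), 2),
            slu1=round(rng.uniform(5, 12), 1),
            sldr=round(rng.uniform(0.1, 0.85), 2),
            slro=round(rng.uniform(60, 95), 1),
        ),
        layers=layers,
    )


def assert_profiles_equal_at_precision(a: SoilProfile, b: SoilProfile):
    assert a.profile_id == b.profile_id
    assert a.country == b.country
    assert abs(a.lat - b.lat) <= 5e-4 and abs(a.lon - b.lon) <= 5e-4
    for f in ("scom", "smhb", "smpx", "smke"):
        assert getattr(a.surface, f) == getattr(b.surface, f)
    for f, dec in (("salb", 2), ("slu1", 1), ("sldr", 2), ("slro", 1),
                   ("slnf", 2), ("slpf", 2)):
        assert abs(getattr(a.surface, f) - getattr(b.surface, f)) <= 0.5 * 10 ** -dec
    assert len(a.layers) == len(b.layers)
    for la, lb in zip(a.layers, b.layers):
        assert la.slb == lb.slb and la.slmh == lb.slmh
        for name, dec in _PRECISION.items():
            va, vb = getattr(la, name.lower()), getattr(lb, name.lower())
            if va == MISSING or vb == MISSING:
                assert va == vb
            else:
                assert abs(va - vb) <= 0.5 * 10 ** -dec + 1e-12, name


class TestWriteRead:
    def test_roundtrip_randomized_profiles(self, tmp_path):
        rng = np.random.default_rng(23)
        profiles = [make_profile(rng, pid=f"TS{i:08d}") for i in range(50)]
        path = write_sol(profiles, tmp_path / "RT.SOL")
        back = read_sol(path)
        assert len(back) == len(profiles)
        for a, b in zip(profiles, back):
            assert_profiles_equal_at_precision(a, b)

    def test_strict_mode_parses_own_output(self, tmp_path):
        rng = np.random.default_rng(3)
        p = make_profile(rng)
        path = write_sol([p], tmp_path / "S.SOL")
        strict = read_sol(path, strict=True)
        tolerant = read_sol(path)
        assert_profiles_equal_at_precision(strict[0], tolerant[0])

    def test_fixed_columns_and_sentinels(self, tmp_path):
        rng = np.random.default_rng(4)
        p = make_profile(rng)
        p.layers[0].slll = 0.188
        text = format_profile(p)
        layer_line = text.splitlines()[6]
        # SLLL is the third 6-char column of the layer line
        assert layer_line[12:18] == " 0.188"
        # SLCF (-99) is column 12, SLHB column 15
        assert layer_line[66:72] == "   -99"
        assert layer_line[84:90] == "   -99"

    def test_byte_identical_reruns(self, tmp_path):
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        a = write_sol([make_profile(rng1)], tmp_path / "A.SOL").read_bytes()
        b = write_sol([make_profile(rng2)], tmp_path / "B.SOL").read_bytes()
        assert a == b
        assert b"\r" not in a
        assert not any(line != line.rstrip() for line in a.split(b"\n"))

    def test_overflowing_field_is_named(self, tmp_path):
        rng = np.random.default_rng(6)
        p = make_profile(rng)
        p.layers[0].scec = 12345678.9
        with pytest.raises(SolFormatError, match="SCEC"):
            write_sol([p], tmp_path / "O.SOL")


class TestValidation:
    def test_inverted_water_contents_rejected(self):
        rng = np.random.default_rng(8)
        p = make_profile(rng)
        p.layers[2].sdul = p.layers[2].slll - 0.01
        with pytest.raises(SolFormatError, match="SLLL < SDUL < SSAT"):
            p.validate()

    def test_layer_depths_must_increase(self):
        rng = np.random.default_rng(8)
        p = make_profile(rng)
        p.layers[3].slb = 15
        with pytest.raises(SolFormatError, match="strictly increasing"):
            p.validate()

    def test_standard_layer_contract(self):
        rng = np.random.default_rng(8)
        p = make_profile(rng)
        p.validate_standard_layers()
        p.layers = p.layers[:5]
        with pytest.raises(SolFormatError, match="layer bottoms"):
            p.validate_standard_layers()


class TestReaderRobustness:
    def test_truncated_layer_line_errors_with_line_number(self, tmp_path):
        rng = np.random.default_rng(10)
        text = format_profile(make_profile(rng))
        lines = text.splitlines()
        lines[-1] = lines[-1][:30]          # chop the final layer record
        bad = tmp_path / "T.SOL"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(SolParseError, match=rf"line {len(lines)}"):
            read_sol(bad)

    def test_non_numeric_field_names_column(self, tmp_path):
        rng = np.random.default_rng(10)
        text = format_profile(make_profile(rng))
        text = text.replace(" 0.188", " x.188") if " 0.188" in text else text
        lines = text.splitlines()
        lines[6] = lines[6][:12] + " abcde" + lines[6][18:]
        bad = tmp_path / "N.SOL"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(SolParseError, match="SLLL"):
            read_sol(bad)

    def test_malformed_header_errors(self, tmp_path):
        bad = tmp_path / "H.SOL"
        bad.write_text("*X\n")
        with pytest.raises(SolParseError):
            read_sol(bad)

    def test_unknown_trailing_columns_preserved(self, tmp_path):
        rng = np.random.default_rng(12)
        p = make_profile(rng)
        text = format_profile(p)
        lines = text.splitlines()
        lines[5] = lines[5] + "  SADC"
        for i in range(6, len(lines)):
            lines[i] = lines[i] + "   -99"
        f = tmp_path / "E.SOL"
        f.write_text("\n".join(lines) + "\n")
        back = read_sol(f)
        assert back[0].layers[0].extras == {"SADC": "-99"}


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    slll=st.floats(0.02, 0.3),
    spread=st.floats(0.011, 0.2),
    sat_extra=st.floats(0.005, 0.2),
    srgf=st.floats(0, 1),
    ssks=st.floats(0.01, 99),
)
def test_roundtrip_property(tmp_path_factory, slll, spread, sat_extra, srgf, ssks):
    """Any physically ordered layer survives write -> read at precision."""
    tmp = tmp_path_factory.mktemp("hyp")
    layers = [
        SoilLayerRecord(
            slb=slb, slmh=slmh,
            slll=slll, sdul=slll + spread, ssat=slll + spread + sat_extra,
            srgf=srgf, ssks=ssks, sbdm=1.4, sloc=1.0, slcl=20.0, slsi=40.0,
            slcf=MISSING, slni=0.1, slhw=6.5, slhb=MISSING, scec=15.0,
        )
        for slb, slmh in zip(STANDARD_SLB, STANDARD_SLMH)
    ]
    p = SoilProfile(profile_id="HYP0000001", layers=layers)
    path = write_sol([p], tmp / "X.SOL")
    back = read_sol(path)
    assert_profiles_equal_at_precision(p, back[0])
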