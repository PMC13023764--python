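"""Cross-section tables, interpolation and the mixture rule."""

import importlib.resources

import numpy as np
import pytest
from hypothesis import given, strategies as st

from xpdtsim.materials import (
    ATOMIC_MASS,
    CHANNELS,
    MaterialComposition,
    XsecRangeError,
    builtin_material,
    interpolate_xsec,
    load_element_table,
    mixture_mu,
    nanoparticle_composition,
    np_suspension_composition,
    water,
)

ALL_ELEMENTS = sorted(ATOMIC_MASS)


@pytest.mark.parametrize("symbol", ALL_ELEMENTS)
def test_table_invariants(symbol):
    """Grid strictly increasing over [1, 200] keV, positive coefficients,
    total consistent with the channel sum, mu_en <= mu_total."""
    t = load_element_table(symbol)
    assert np.all(np.diff(t.energies) > 0)
    assert t.energies[0] <= 1.0 + 1e-9 and t.energies[-1] >= 200.0 - 1e-9
    for ch in CHANNELS:
        assert np.all(t.channel(ch) > 0)
    s = t.mu_rho_photoelectric + t.mu_rho_incoherent + t.mu_rho_coherent
    assert np.all(np.abs(t.mu_rho_total - s) / t.mu_rho_total <= 0.02)
    assert np.all(t.mu_en_rho <= t.mu_rho_total * (1 + 1e-12))


def test_interpolation_exact_at_grid_points():
    t = load_element_table("O")
    for idx in (0, 17, 53, len(t.energies) - 1):
        e = t.energies[idx]
        assert interpolate_xsec(t, e, "total") == pytest.approx(
            t.mu_rho_total[idx], rel=1e-12)


def _independent_loglog_lookup(symbol, energy, column):
    """Oracle: re-read the bundled text table and interpolate log-log with
    code independent of the package's interpolation path."""
    ref = importlib.resources.files("xpdtsim").joinpath(f"data/xsec/{symbol}.txt")
    rows = [list(map(float, ln.split()))
            for ln in ref.read_text().splitlines() if not ln.startswith("#")]
    rows.sort()
    below = max(r for r in rows if r[0] <= energy)
    above = min(r for r in rows if r[0] >= energy)
    if below[0] == above[0]:
        return below[column]
    f = (np.log(energy) - np.log(below[0])) / (np.log(above[0]) - np.log(below[0]))
    return np.exp((1 - f) * np.log(below[column]) + f * np.log(above[column]))


def test_lutetium_60kev_against_independent_lookup():
    t = load_element_table("Lu")
    got = interpolate_xsec(t, 60.0, "total")
    assert got == pytest.approx(_independent_loglog_lookup("Lu", 60.0, 1), rel=0.01)


def test_out_of_range_energy_raises():
    t = load_element_table("O")
    with pytest.raises(XsecRangeError, match="O"):
        interpolate_xsec(t, 0.5, "total")
    with pytest.raises(XsecRangeError):
        interpolate_xsec(t, 250.0, "total")


def test_unknown_channel_rejected():
    t = load_element_table("O")
    with pytest.raises(ValueError, match="channel"):
        interpolate_xsec(t, 30.0, "pair_production")


def test_mixture_water_is_hand_weighted_sum(tables):
    w = water()
    m_h, m_o = 2 * ATOMIC_MASS["H"], ATOMIC_MASS["O"]
    wh, wo = m_h / (m_h + m_o), m_o / (m_h + m_o)
    for e in (10.0, 30.0, 80.0):
        expected = (wh * interpolate_xsec(tables["H"], e, "total")
                    + wo * interpolate_xsec(tables["O"], e, "total"))
        mass, lin = mixture_mu(w, tables, e, "total")
        assert mass == pytest.approx(expected, rel=1e-12)
        assert lin == pytest.approx(expected * w.density, rel=1e-12)


def test_mixture_degenerate_and_symmetric(tables):
    pure = MaterialComposition("pure_O", (("O", 1.0),), 1.4)
    assert mixture_mu(pure, tables, 25.0, "incoherent")[0] == pytest.approx(
        interpolate_xsec(tables["O"], 25.0, "incoherent"), rel=1e-12)
    half = MaterialComposition("HO_5050", (("H", 0.5), ("O", 0.5)), 1.0)
    mean = 0.5 * (interpolate_xsec(tables["H"], 40.0, "total")
                  + interpolate_xsec(tables["O"], 40.0, "total"))
    assert mixture_mu(half, tables, 40.0, "total")[0] == pytest.approx(mean, rel=1e-12)


def test_mixture_missing_element_table(tables):
    sub = {k: v for k, v in tables.items() if k != "O"}
    with pytest.raises(KeyError, match="O"):
        mixture_mu(water(), sub, 30.0, "total")


def test_water_reference_attenuation(tables):
    """Assembled water coefficients agree with standard published values
    (NIST mass attenuation for liquid water) to a few percent."""
    reference = {10.0: 5.329, 20.0: 0.8096, 30.0: 0.3756, 60.0: 0.2059, 100.0: 0.1707}
    for e, ref in reference.items():
        got = mixture_mu(water(), tables, e, "total")[0]
        assert got == pytest.approx(ref, rel=0.04), f"water at {e} keV"


def test_suspension_zero_concentration_is_water():
    assert np_suspension_composition(0.0) == water()


def test_suspension_10mgml_composition():
    s = np_suspension_composition(10.0)
    w_np = 10.0 / 1010.0
    assert s.density == pytest.approx(1.010)
    fr = dict(s.constituents)
    comp = dict(nanoparticle_composition().constituents)
    for el in ("Na", "Lu", "Gd", "Tb"):
        assert fr[el] == pytest.approx(w_np * comp[el], rel=1e-12)
    # expanded from molar masses by hand
    m = {"Na": 22.98977, "Lu": 174.9668, "Gd": 157.25, "Tb": 158.92534,
         "F": 18.998403}
    total = m["Na"] + 0.65 * m["Lu"] + 0.2 * m["Gd"] + 0.15 * m["Tb"] + 4 * m["F"]
    assert fr["Lu"] == pytest.approx(w_np * 0.65 * m["Lu"] / total, rel=1e-9)


def test_nanoparticle_stoichiometric_fractions_sum_to_one():
    assert sum(w for _, w in nanoparticle_composition().constituents) == pytest.approx(1.0, abs=1e-12)


def test_negative_concentration_rejected():
    with pytest.raises(ValueError):
        np_suspension_composition(-1.0)


def test_builtin_registry():
    assert builtin_material("water") == water()
    with pytest.raises(KeyError):
        builtin_material("kryptonite")


@pytest.mark.parametrize("name", ["water", "np_suspension_10mgml", "lutetium"])
def test_energy_absorption_below_total_for_builtins(name, tables):
    mat = builtin_material(name)
    for e in np.geomspace(5.0, 160.0, 40):
        tot = mixture_mu(mat, tables, e, "total")[0]
        en = mixture_mu(mat, tables, e, "energy_absorption")[0]
        assert en <= tot * (1 + 1e-12)


def test_suspension_monotone_in_concentration(tables):
    """Above the Lu L edges the suspension coefficient grows with
    concentration."""
    e = 15.0
    prev = None
    for c in (0.0, 5.0, 10.0, 20.0, 50.0):
        mu = mixture_mu(np_suspension_composition(c), tables, e, "total")[0]
        if prev is not None:
            assert mu > prev
        prev = mu


@given(st.floats(0.05, 0.95))
def test_composition_renormalization_roundtrip(w_h):
    mat = MaterialComposition("mix", (("H", w_h), ("O", 1.0 - w_h)), 1.0)
    total = sum(w for _, w in mat.constituents)
    renorm = MaterialComposition(
        "mix", tuple((s, w / total) for s, w in mat.constituents), 1.0)
    for (s1, a), (s2, b) in zip(mat.constituents, renorm.constituents):
        assert s1 == s2 and abs(a - b) <= 1e-12


def test_invalid_compositions_rejected():
    with pytest.raises(ValueError):
        MaterialComposition("bad", (("H", 0.5), ("O", 0.6)), 1.0)
    with pytest.raises(ValueError):
        MaterialComposition("bad", (("H", 1.0),), -1.0)
    with pytest.raises(ValueError):
        MaterialComposition("bad", (("H", 0.0), ("O", 1.0)), 1.0)
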