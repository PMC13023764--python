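"""Monte Carlo transport: analytic oracles, sampler distributions,
conservation, uncertainty scaling and determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import integrate, stats

from xpdtsim.analysis import aad, depth_dose
from xpdtsim.materials import mixture_mu, water
from xpdtsim.phantoms import build_model, depth_layers
from xpdtsim.spectra import Spectrum
from xpdtsim.transport import (
    ELECTRON_REST_KEV,
    KEV_TO_J,
    TransportConfig,
    convert_to_dose,
    kn_sample,
    kn_sample_many,
    run_transport,
)


def _mono(e_kev):
    return Spectrum(np.array([e_kev]), np.array([1.0]))


def test_pure_photoelectric_slab_matches_beer_lambert(tables):
    """With only the photoelectric channel enabled, the per-layer energy
    deposition in a water cube follows the closed-form Beer-Lambert
    layer-absorption law within 3 standard errors."""
    ph = build_model("C")
    e = 12.0  # keV; photoelectric-dominated regime anyway
    n = 200_000
    cfg = TransportConfig(n_photons=n, seed=42, incoherent=False,
                          coherent_scatter=False)
    grid = run_transport(ph, _mono(e), cfg, tables)
    mu_mm = mixture_mu(water(), tables, e, "photoelectric")[1] / 10.0
    depths, z_indices = depth_layers(ph)
    dz = ph.voxel_size_mm
    for k, z in enumerate(z_indices):
        observed = grid.energy_dep[:, :, z].sum()
        p_layer = np.exp(-mu_mm * k * dz) - np.exp(-mu_mm * (k + 1) * dz)
        expected = n * e * p_layer
        se = e * np.sqrt(n * p_layer * (1 - p_layer))
        assert abs(observed - expected) <= 3 * se, f"layer {k}"


def test_beam_missing_phantom_deposits_nothing(tables):
    ph = build_model("C")
    beam = dataclasses.replace(ph.beam, x_min_mm=50.0, x_max_mm=55.0)
    ph = dataclasses.replace(ph, beam=beam)
    grid = run_transport(ph, _mono(30.0), TransportConfig(n_photons=100, seed=1), tables)
    assert np.all(grid.energy_dep == 0)
    assert grid.meta["escaped_kev"] == pytest.approx(100 * 30.0)


def test_kn_energy_bounds():
    rng = np.random.default_rng(0)
    for e in (5.0, 60.0, 160.0):
        a = e / ELECTRON_REST_KEV
        emin = e / (1 + 2 * a)
        es, cs = kn_sample_many(e, 5000, seed=3)
        assert np.all(es <= e + 1e-12) and np.all(es >= emin - 1e-12)
        assert np.all(np.abs(cs) <= 1.0)
        e1, c1 = kn_sample(e, rng)
        assert emin - 1e-12 <= e1 <= e + 1e-12 and -1 <= c1 <= 1


def _kn_density(e_kev, cos_t):
    a = e_kev / ELECTRON_REST_KEV
    kp = 1.0 / (1.0 + a * (1.0 - cos_t))
    return kp**2 * (kp + 1.0 / kp - (1.0 - cos_t**2))


def test_kn_angular_distribution_chi_square():
    """Sampled polar-cosine histogram at 10 keV vs the numerically
    integrated Klein-Nishina density (1e6 samples, fixed seed)."""
    e, n = 10.0, 1_000_000
    _, cs = kn_sample_many(e, n, seed=12345)
    edges = np.linspace(-1, 1, 41)
    observed, _ = np.histogram(cs, bins=edges)
    probs = np.array([integrate.quad(lambda c: _kn_density(e, c), lo, hi)[0]
                      for lo, hi in zip(edges[:-1], edges[1:])])
    probs /= probs.sum()
    res = stats.chisquare(observed, f_exp=probs * n)
    assert res.pvalue > 0.01


def test_kn_mean_energy_transfer_matches_quadrature():
    """Mean transferred-energy fraction at 60 keV vs the quadrature of
    the energy-weighted Klein-Nishina integrand, within 1%."""
    e, n = 60.0, 1_000_000
    es, _ = kn_sample_many(e, n, seed=999)
    got = np.mean(1.0 - es / e)
    a = e / ELECTRON_REST_KEV
    num = integrate.quad(
        lambda c: _kn_density(e, c) * (1 - 1 / (1 + a * (1 - c))), -1, 1)[0]
    den = integrate.quad(lambda c: _kn_density(e, c), -1, 1)[0]
    assert got == pytest.approx(num / den, rel=0.01)


def test_convert_to_dose_unit_arithmetic(tables):
    ph = build_model("C")
    grid = run_transport(ph, _mono(30.0), TransportConfig(n_photons=100, seed=2), tables)
    grid.energy_dep[:] = 0.0
    grid.energy_dep[3, 4, 5] = 1.0  # 1 keV in one 0.2 mm water voxel
    dosed = convert_to_dose(grid, ph)
    mass_kg = 1.0 * (0.02**3) * 1e-3  # g/cm^3 * cm^3 -> kg
    assert mass_kg == pytest.approx(8e-9)
    assert dosed.dose[3, 4, 5] == pytest.approx(KEV_TO_J / 8e-9, rel=1e-12)
    assert dosed.dose[0, 0, 0] == 0.0


def test_dose_inversely_proportional_to_density(tables):
    phc = build_model("C")
    phd = build_model("D", np_concentration_mg_ml=1000.0)  # density 2.0
    assert phd.materials[1].density == pytest.approx(2.0)
    doses = []
    for ph in (phc, phd):
        grid = run_transport(ph, _mono(30.0), TransportConfig(n_photons=50, seed=3), tables)
        grid.energy_dep[:] = 1.0  # fixed energy everywhere
        dosed = convert_to_dose(grid, ph)
        rho = ph.materials[1].density
        assert np.allclose(dosed.dose, KEV_TO_J / (rho * 8e-9))
        doses.append(dosed.dose[0, 0, 0])
    assert doses[0] == pytest.approx(2.0 * doses[1], rel=1e-12)


def test_energy_conservation_per_history(tables, spec60):
    ph = build_model("C")
    grid = run_transport(ph, spec60, TransportConfig(n_photons=50_000, seed=8), tables)
    assert grid.meta["max_conservation_err_kev"] < 1e-9
    total_dep = grid.energy_dep.sum()
    assert total_dep + grid.meta["escaped_kev"] == pytest.approx(
        grid.meta["emitted_kev"], rel=1e-12)
    assert total_dep <= grid.meta["emitted_kev"]


def test_determinism_fixed_seed(tables, spec60):
    ph = build_model("C")
    cfg = TransportConfig(n_photons=20_000, seed=77)
    g1 = run_transport(ph, spec60, cfg, tables)
    g2 = run_transport(ph, spec60, cfg, tables)
    assert np.array_equal(g1.energy_dep, g2.energy_dep)
    assert np.array_equal(g1.rel_uncertainty, g2.rel_uncertainty)
    g3 = run_transport(ph, spec60, TransportConfig(n_photons=20_000, seed=78), tables)
    assert not np.array_equal(g1.energy_dep, g3.energy_dep)


def test_uncertainty_scales_inverse_sqrt_n(tables, spec60):
    """Quadrupling histories halves the median relative uncertainty
    (within 10%)."""
    ph = build_model("C")
    meds = []
    for n in (300_000, 1_200_000):
        g = run_transport(ph, spec60, TransportConfig(n_photons=n, seed=31), tables)
        rel = g.rel_uncertainty[ph.tumor_mask]
        meds.append(np.median(rel[rel > 0]))
    ratio = meds[0] / meds[1]
    assert ratio == pytest.approx(2.0, rel=0.10)


def test_der_identity_same_model(tables, spec60):
    """Model A against itself (different seeds) gives depth-DER = 1
    within statistical error at every layer."""
    ph = build_model("C")
    curves = []
    for seed in (1001, 2002):
        g = convert_to_dose(
            run_transport(ph, spec60, TransportConfig(n_photons=400_000, seed=seed), tables), ph)
        curves.append(depth_dose(g, ph))
    ratio = curves[0].values / curves[1].values
    sigma = ratio * np.sqrt((curves[0].uncertainties / curves[0].values) ** 2
                            + (curves[1].uncertainties / curves[1].values) ** 2)
    assert np.all(np.abs(ratio - 1.0) <= 4.0 * sigma)
    assert np.median(np.abs(ratio - 1.0)) < 0.05


def test_radiosensitization_b_exceeds_a(pair60):
    """Tumor AAD with the nanoprobe exceeds the water-only tumor."""
    ph_a, grid_a = pair60["A"]
    ph_b, grid_b = pair60["B"]
    assert aad(grid_b, ph_b) > 1.1 * aad(grid_a, ph_a)


def test_config_validation():
    with pytest.raises(ValueError):
        TransportConfig(n_photons=5, n_batches=10)
    with pytest.raises(ValueError):
        TransportConfig(n_photons=100, energy_cutoff_kev=0.1)
    with pytest.raises(ValueError):
        TransportConfig(n_photons=100, photoelectric=False, incoherent=False,
                        coherent_scatter=False)


def test_zero_fluence_spectrum_rejected(tables):
    with pytest.raises(ValueError):
        Spectrum(np.array([30.0]), np.array([0.0]))
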