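"""Monte Carlo photon transport with voxel dose scoring.

The transport engine follows photons only; all energy transferred to
electrons is deposited in the voxel where the interaction happened
(kerma approximation).  At the tube potentials considered here
(20-160 kVp) CSDA electron ranges in water stay below ~0.35 mm, close
to the 0.2 mm voxel size, which is the principal physics simplification
of this package relative to a condensed-history code.

Statistical uncertainty is estimated by batch means: the requested
histories are split into ``n_batches`` equal batches with sub-seeds
derived deterministically from the master seed, and the per-voxel
relative standard error of the batch mean is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .materials import element_tables, interpolate_xsec, mixture_mu
from .phantoms import VoxelPhantom
from .spectra import Spectrum

__all__ = ["TransportConfig", "DoseGrid", "run_transport", "convert_to_dose",
           "kn_sample", "kn_sample_many"]

KEV_TO_J = 1.602176634e-16
ELECTRON_REST_KEV = 510.99895

#: in-kernel lookup grid (uniform in log energy)
LOOKUP_E_MIN, LOOKUP_E_MAX, LOOKUP_N = 1.0, 200.0, 2048

#: K-shell data for the high-Z elements that can fluoresce in this
#: energy range: (K edge keV, fluorescence yield omega_K, mean emitted
#: K-line energy keV, line-weighted over K-alpha1/2 and K-beta)
K_SHELL = {
    "Gd": (50.2391, 0.930, 43.9),
    "Tb": (51.9957, 0.933, 45.4),
    "Lu": (63.3138, 0.950, 55.2),
    "W": (69.5250, 0.958, 60.5),
}


@dataclass(frozen=True)
class TransportConfig:
    """Settings for one transport run."""

    n_photons: int
    seed: int = 0
    n_batches: int = 10
    energy_cutoff_kev: float = 1.0
    photoelectric: bool = True
    incoherent: bool = True
    coherent_scatter: bool = True
    #: emit and transport K-fluorescence photons after photoelectric
    #: absorption on K shells of high-Z constituents
    k_fluorescence: bool = True
    max_scatters: int = 1000

    def __post_init__(self) -> None:
        if self.n_photons < self.n_batches or self.n_batches < 2:
            raise ValueError("need n_photons >= n_batches >= 2")
        if self.energy_cutoff_kev < LOOKUP_E_MIN:
            raise ValueError(f"energy cutoff below table minimum {LOOKUP_E_MIN} keV")
        if not (self.photoelectric or self.incoherent or self.coherent_scatter):
            raise ValueError("at least one interaction channel must be enabled")


@dataclass
class DoseGrid:
    """Per-voxel deposited energy / absorbed dose with uncertainties."""

    energy_dep: np.ndarray  # keV, shape = phantom.shape
    rel_uncertainty: np.ndarray  # relative standard error of the mean
    dose: np.ndarray | None = None  # Gy, filled by convert_to_dose
    meta: dict = field(default_factory=dict)

    def scaled(self, factor: float) -> "DoseGrid":
        """Globally rescaled copy (relative uncertainties unchanged)."""
        return DoseGrid(
            energy_dep=self.energy_dep * factor,
            rel_uncertainty=self.rel_uncertainty.copy(),
            dose=None if self.dose is None else self.dose * factor,
            meta={**self.meta, "scale_applied": factor * self.meta.get("scale_applied", 1.0)},
        )


def _material_lookup_arrays(phantom: VoxelPhantom, config: TransportConfig,
                            tables: dict):
    """Per-material linear attenuation and cumulative channel fractions
    on the in-kernel log-energy grid."""
    egrid = np.geomspace(LOOKUP_E_MIN, LOOKUP_E_MAX, LOOKUP_N)
    n_mat = len(phantom.materials)
    mu_tot = np.zeros((n_mat, LOOKUP_N))
    cum_pe = np.zeros((n_mat, LOOKUP_N))
    cum_inc = np.zeros((n_mat, LOOKUP_N))
    p_kfluor = np.zeros((n_mat, LOOKUP_N))
    e_kfluor = np.zeros((n_mat, LOOKUP_N))
    for m, mat in enumerate(phantom.materials):
        if mat is None:
            continue
        mu_pe = mixture_mu(mat, tables, egrid, "photoelectric")[1] if config.photoelectric else 0.0
        mu_in = mixture_mu(mat, tables, egrid, "incoherent")[1] if config.incoherent else 0.0
        mu_co = mixture_mu(mat, tables, egrid, "coherent")[1] if config.coherent_scatter else 0.0
        tot = mu_pe + mu_in + mu_co
        if np.any(~np.isfinite(tot)) or np.any(tot <= 0):
            raise ValueError(f"non-finite or vanishing cross section for material {mat.name}")
        mu_tot[m] = tot
        cum_pe[m] = np.asarray(mu_pe) / tot
        cum_inc[m] = (np.asarray(mu_pe) + np.asarray(mu_in)) / tot
        if config.photoelectric and config.k_fluorescence:
            p_kfluor[m], e_kfluor[m] = _k_fluorescence_arrays(
                mat, tables, egrid, np.asarray(mu_pe))
    loge0 = np.log(LOOKUP_E_MIN)
    dloge = (np.log(LOOKUP_E_MAX) - loge0) / (LOOKUP_N - 1)
    return mu_tot, cum_pe, cum_inc, p_kfluor, e_kfluor, loge0, dloge


def _k_fluorescence_arrays(mat, tables, egrid, mu_pe_lin):
    """Per-energy probability that a photoelectric event emits a
    K-fluorescence photon, and the mean emitted line energy.

    For each fluorescing constituent: its share of the photoelectric
    cross section, times the K-shell fraction (from the table's edge
    jump), times the fluorescence yield.
    """
    p = np.zeros_like(egrid)
    pe_sum = np.zeros_like(egrid)
    for sym, w in mat.constituents:
        if sym not in K_SHELL:
            continue
        edge, omega, e_line = K_SHELL[sym]
        t = tables[sym]
        jump = (interpolate_xsec(t, edge + 0.006, "photoelectric")
                / interpolate_xsec(t, edge - 0.006, "photoelectric"))
        f_k = 1.0 - 1.0 / jump
        above = egrid > edge
        mu_el = w * interpolate_xsec(t, egrid, "photoelectric") * mat.density
        contrib = np.where(above, mu_el * f_k * omega, 0.0)
        p += contrib
        pe_sum += contrib * e_line
    with np.errstate(invalid="ignore", divide="ignore"):
        e_mean = np.where(p > 0, pe_sum / np.where(p > 0, p, 1.0), 0.0)
        prob = np.where(mu_pe_lin > 0, p / np.where(mu_pe_lin > 0, mu_pe_lin, 1.0), 0.0)
    return np.clip(prob, 0.0, 1.0), e_mean


def run_transport(phantom: VoxelPhantom, spectrum: Spectrum,
                  config: TransportConfig, tables: dict | None = None) -> DoseGrid:
    """Transport photons through the phantom and score deposited energy.

    Deterministic for a fixed ``config.seed``.  The returned grid holds
    total deposited energy (keV) for all histories run; call
    :func:`convert_to_dose` for Gy.
    """
    tables = tables if tables is not None else element_tables()
    if spectrum.energies.max() > LOOKUP_E_MAX or spectrum.energies.min() < LOOKUP_E_MIN:
        raise ValueError("spectrum extends beyond the cross-section lookup range")
    (mu_tot, cum_pe, cum_inc, p_kfluor, e_kfluor,
     loge0, dloge) = _material_lookup_arrays(phantom, config, tables)

    fl = spectrum.fluence
    cdf = np.cumsum(fl)
    cdf /= cdf[-1]

    nx, ny, nz = phantom.shape
    n_per = config.n_photons // config.n_batches
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_batches)
    mat_flat = np.ascontiguousarray(phantom.material_id, dtype=np.uint8).ravel()

    total = np.zeros(nx * ny * nz)
    total_sq = np.zeros(nx * ny * nz)
    escaped = 0.0
    max_err = 0.0
    beam = phantom.beam
    for b in range(config.n_batches):
        edep, esc, err = _kernels.run_batch(
            mat_flat, nx, ny, nz, phantom.voxel_size_mm,
            np.ascontiguousarray(spectrum.energies), np.ascontiguousarray(cdf),
            mu_tot, cum_pe, cum_inc, p_kfluor, e_kfluor, loge0, dloge,
            beam.x_min_mm, beam.x_max_mm, beam.y_min_mm, beam.y_max_mm,
            beam.entry_z_mm,
            n_per, int(seeds[b]), config.energy_cutoff_kev, config.max_scatters,
        )
        total += edep
        total_sq += edep * edep
        escaped += esc
        max_err = max(max_err, err)

    nb = config.n_batches
    mean = total / nb
    var = np.maximum(total_sq - nb * mean**2, 0.0) / (nb - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, np.sqrt(var / nb) / np.where(mean > 0, mean, 1.0), 0.0)
    histories = n_per * nb
    return DoseGrid(
        energy_dep=total.reshape(phantom.shape),
        rel_uncertainty=rel.reshape(phantom.shape),
        meta={
            "model": phantom.model, "histories": histories,
            "n_batches": nb, "seed": config.seed,
            "escaped_kev": escaped, "max_conservation_err_kev": max_err,
            "emitted_kev": float(total.sum() + escaped),
            "spectrum_mean_kev": spectrum.mean_energy,
            "config": config,
        },
    )


def convert_to_dose(grid: DoseGrid, phantom: VoxelPhantom) -> DoseGrid:
    """Convert deposited energy to absorbed dose, Gy = J/kg per voxel."""
    dens = phantom.density_by_id()[phantom.material_id]  # g/cm^3
    mass_kg = dens * phantom.voxel_volume_cm3() * 1e-3
    vacuum = mass_kg == 0
    if np.any(grid.energy_dep[vacuum] > 0):
        raise ValueError("energy deposited in a zero-density voxel")
    dose = np.zeros_like(grid.energy_dep)
    dose[~vacuum] = grid.energy_dep[~vacuum] * KEV_TO_J / mass_kg[~vacuum]
    return DoseGrid(energy_dep=grid.energy_dep, rel_uncertainty=grid.rel_uncertainty,
                    dose=dose, meta=dict(grid.meta))


def save_dose_grid(grid: DoseGrid, path) -> None:
    """Persist a dose grid (.npz with a JSON metadata string)."""
    import json

    meta = {k: v for k, v in grid.meta.items() if isinstance(v, (int, float, str, bool))}
    np.savez_compressed(
        path, energy_dep=grid.energy_dep, rel_uncertainty=grid.rel_uncertainty,
        dose=grid.dose if grid.dose is not None else np.array([]),
        meta_json=np.array(json.dumps(meta)),
    )


def load_dose_grid(path) -> DoseGrid:
    import json

    with np.load(path) as d:
        dose = d["dose"]
        return DoseGrid(
            energy_dep=d["energy_dep"], rel_uncertainty=d["rel_uncertainty"],
            dose=None if dose.size == 0 else dose,
            meta=json.loads(str(d["meta_json"])),
        )


def kn_sample(energy_kev: float, rng: np.random.Generator):
    """One Klein-Nishina sample: (scattered energy keV, polar cosine).

    Free-electron Klein-Nishina with the Compton relation
    E' = E / (1 + (E/m_e c^2)(1 - cos theta)); rejection sampling with
    the same envelope as the transport kernel.
    """
    a = energy_kev / ELECTRON_REST_KEV
    while True:
        c = 1.0 - 2.0 * rng.random()
        kp = 1.0 / (1.0 + a * (1.0 - c))
        p = kp * kp * (kp + 1.0 / kp - (1.0 - c * c))
        if 2.0 * rng.random() <= p:
            return energy_kev * kp, c


def kn_sample_many(energy_kev: float, n: int, seed: int):
    """Vectorized Klein-Nishina sampling via the compiled kernel."""
    return _kernels.kn_sample_batch(float(energy_kev), int(n), int(seed))
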