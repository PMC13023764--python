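"""Filtered tungsten-anode kVp spectra and spectrum summaries.

The tube model is semi-empirical, not an electron-in-target Monte Carlo:

* bremsstrahlung continuum N(E) ~ (E0 - E)/E**p, where p = 1 is the
  thin-target Kramers photon-fluence law and the calibrated default
  p = 0.79 lumps anode self-absorption of soft photons into the
  energy weighting;
* anode self-filtration through an effective tungsten path derived
  from the Katz-Penfold CSDA electron range (production depth grows
  with tube potential) projected along the 20 degree take-off
  direction, capped at a calibrated 8.9 um;
* Beer-Lambert attenuation through each external filter (0.8 mm Be by
  default);
* tungsten characteristic lines added as narrow single-bin peaks -
  L series (~8.4/9.7/10.0 keV) above the L3 edge and K series
  (~58-69 keV) above the K edge (69.525 keV) - with line-to-continuum
  amplitudes that are fixed, documented model constants, and the total
  line share of fluence saturating at a configurable cap (0.55).

The continuum exponent, self-filtration scale/cap and line amplitudes
were calibrated once against the mean energies of the reference tube
(see docs/methods.md and scripts/calibrate_tube_model.py) and are
never fitted per run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .materials import (
    MaterialComposition,
    beryllium,
    element_tables,
    interpolate_xsec,
    mixture_mu,
    tungsten,
)

__all__ = [
    "TubeConfig",
    "Spectrum",
    "generate_spectrum",
    "apply_filter",
    "mean_energy",
    "read_spectrum",
    "write_spectrum",
]

W_L3_EDGE_KEV = 10.2068
W_K_EDGE_KEV = 69.525
#: tungsten L-series lines as (energy keV, relative branching)
W_L_LINES = ((8.398, 0.60), (9.672, 0.25), (9.963, 0.15))
#: tungsten K-series lines as (energy keV, relative branching)
W_K_LINES = ((57.982, 0.29), (59.318, 0.50), (67.15, 0.17), (69.067, 0.04))

W_DENSITY = 19.25  # g/cm^3


def _csda_range_mm_w(e0_kev: float) -> float:
    """Katz-Penfold CSDA electron range in tungsten, mm."""
    e_mev = e0_kev / 1000.0
    r_gcm2 = 0.412 * e_mev ** (1.265 - 0.0954 * np.log(e_mev))
    return r_gcm2 / W_DENSITY * 10.0


@dataclass(frozen=True)
class TubeConfig:
    """Tungsten-anode tube settings and spectrum-model constants."""

    kvp: float
    anode: str = "W"
    anode_angle_deg: float = 20.0
    target_thickness_mm: float = 0.2
    #: effective tungsten self-filtration path in mm; None (default)
    #: derives it from the electron production depth (CSDA/2) projected
    #: at the take-off angle, scaled by ``selffilter_scale`` and capped
    #: at ``selffilter_cap_mm``
    target_selffilter_mm: float | None = None
    #: upper bound of the derived self-filtration path (calibrated)
    selffilter_cap_mm: float = 0.0089
    #: filters as (material name or composition, thickness mm)
    filters: tuple = (("beryllium", 0.8),)
    bin_width: float = 0.5
    min_energy: float = 1.0
    #: continuum shape N(E) ~ (E0 - E) / E**p.  p = 1 is the thin-target
    #: Kramers photon-fluence law; smaller p suppresses the soft-photon
    #: divergence, standing in for anode self-absorption in a thick
    #: target.  The default was calibrated once (docs/methods.md).
    continuum_exponent: float = 0.79
    #: calibrated model constants (see module docstring); do not fit per run
    selffilter_scale: float = 2.13
    l_line_scale: float = 200.0
    l_line_exponent: float = -4.4
    k_line_scale: float = 0.2
    k_line_exponent: float = 4.5
    #: characteristic lines never exceed this share of the total
    #: fluence (saturation of the line-to-continuum ratio)
    line_fraction_cap: float = 0.55
    include_lines: bool = True

    def __post_init__(self) -> None:
        if not 10.0 <= self.kvp <= 200.0:
            raise ValueError(f"kvp {self.kvp} outside supported range [10, 200] kV")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.kvp <= self.min_energy:
            raise ValueError("kvp must exceed min_energy")
        if any(t < 0 for _, t in self.filters):
            raise ValueError("filter thicknesses must be non-negative")
        if self.anode != "W":
            raise ValueError("only a tungsten anode is modelled")
        if not 0.0 <= self.continuum_exponent <= 1.5:
            raise ValueError("continuum_exponent must lie in [0, 1.5]")

    @property
    def selffilter_mm(self) -> float:
        """Effective tungsten self-filtration path, mm."""
        if self.target_selffilter_mm is not None:
            return self.target_selffilter_mm
        depth = 0.5 * _csda_range_mm_w(self.kvp)  # mean production depth
        path = depth / np.sin(np.radians(self.anode_angle_deg))
        return float(min(self.selffilter_scale * path, self.selffilter_cap_mm))


@dataclass(frozen=True)
class Spectrum:
    """Binned relative photon fluence N_i at bin-center energies E_i."""

    energies: np.ndarray  # keV, strictly increasing bin centers
    fluence: np.ndarray  # relative photons per bin, >= 0

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        n = np.asarray(self.fluence, dtype=float)
        if e.shape != n.shape or e.ndim != 1:
            raise ValueError("energies and fluence must be equal-length 1-D arrays")
        if not np.all(np.diff(e) > 0):
            raise ValueError("spectrum energies must be strictly increasing")
        if np.any(n < 0):
            raise ValueError("spectrum fluence must be non-negative")
        if not np.any(n > 0):
            raise ValueError("spectrum must contain some fluence")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "fluence", n)

    def normalized(self) -> "Spectrum":
        return Spectrum(self.energies, self.fluence / self.fluence.sum())

    @property
    def mean_energy(self) -> float:
        return mean_energy(self)

    @property
    def total_energy(self) -> float:
        """sum N_i E_i (keV per unit total fluence metric)."""
        return float(np.sum(self.energies * self.fluence))


def _resolve_material(mat) -> MaterialComposition:
    if isinstance(mat, MaterialComposition):
        return mat
    from .materials import builtin_material

    return builtin_material(mat)


def generate_spectrum(config: TubeConfig, tables: dict | None = None) -> Spectrum:
    """Generate the filtered anode spectrum for one tube setting."""
    tables = tables if tables is not None else element_tables()
    e0 = config.kvp
    edges = np.arange(config.min_energy, e0 + config.bin_width, config.bin_width)
    if edges[-1] > e0:
        edges[-1] = e0
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    # continuum (per-bin photon count), N(E) ~ (E0 - E)/E**p
    cont = (e0 - centers) / centers**config.continuum_exponent * widths
    cont[cont < 0] = 0.0
    phi_unfiltered = float(cont.sum())

    # anode self-filtration + external filters
    trans = np.ones_like(centers)
    t_w_cm = config.selffilter_mm / 10.0
    if t_w_cm > 0:
        mu_w = interpolate_xsec(tables["W"], centers, "total") * W_DENSITY
        trans *= np.exp(-mu_w * t_w_cm)
    for mat, t_mm in config.filters:
        if t_mm <= 0:
            continue
        material = _resolve_material(mat)
        _, mu_lin = mixture_mu(material, tables, centers, "total")
        trans *= np.exp(-mu_lin * t_mm / 10.0)
    fluence = cont * trans

    if config.include_lines:
        def line_transmission(e_line: float) -> float:
            t = 1.0
            if t_w_cm > 0:
                t *= np.exp(-interpolate_xsec(tables["W"], e_line, "total") * W_DENSITY * t_w_cm)
            for mat, t_mm in config.filters:
                if t_mm <= 0:
                    continue
                material = _resolve_material(mat)
                _, mu_lin = mixture_mu(material, tables, e_line, "total")
                t *= np.exp(-mu_lin * t_mm / 10.0)
            return float(t)

        line_fluence = np.zeros_like(fluence)
        for lines, edge, scale, expo in (
            (W_L_LINES, W_L3_EDGE_KEV, config.l_line_scale, config.l_line_exponent),
            (W_K_LINES, W_K_EDGE_KEV, config.k_line_scale, config.k_line_exponent),
        ):
            if e0 <= edge or scale <= 0:
                continue
            u = e0 / edge
            intensity = scale * (u - 1.0) ** expo * phi_unfiltered
            for e_line, branch in lines:
                if e_line >= e0:
                    continue
                idx = int(np.clip(np.searchsorted(edges, e_line) - 1, 0, len(centers) - 1))
                line_fluence[idx] += intensity * branch * line_transmission(e_line)
        # saturate the line share of the total fluence
        cap = config.line_fraction_cap
        cont_total, line_total = fluence.sum(), line_fluence.sum()
        if cap < 1.0 and line_total > 0 and cont_total > 0:
            limit = cap / (1.0 - cap) * cont_total
            if line_total > limit:
                line_fluence *= limit / line_total
        fluence = fluence + line_fluence

    total = fluence.sum()
    if total <= 0:
        raise ValueError("generated spectrum has zero fluence; check filtration")
    return Spectrum(centers, fluence / total)


def apply_filter(spectrum: Spectrum, material, thickness_mm: float,
                 tables: dict | None = None) -> Spectrum:
    """Attenuate a spectrum by one filter: N_i' = N_i exp(-mu(E_i) t)."""
    if thickness_mm < 0:
        raise ValueError("filter thickness must be non-negative")
    if thickness_mm == 0:
        return Spectrum(spectrum.energies.copy(), spectrum.fluence.copy())
    tables = tables if tables is not None else element_tables()
    mat = _resolve_material(material)
    _, mu_lin = mixture_mu(mat, tables, spectrum.energies, "total")
    return Spectrum(spectrum.energies, spectrum.fluence * np.exp(-mu_lin * thickness_mm / 10.0))


def mean_energy(spectrum: Spectrum) -> float:
    """Fluence-weighted mean energy, sum(N_i E_i) / sum(N_i), keV."""
    total = spectrum.fluence.sum()
    if total <= 0:
        raise ValueError("mean energy undefined for all-zero fluence")
    return float(np.sum(spectrum.energies * spectrum.fluence) / total)


def write_spectrum(spectrum: Spectrum, path, header: str | None = None) -> None:
    """Write a two-column text spectrum (energy_keV <TAB> relative_fluence)."""
    with open(path, "w") as fh:
        fh.write("# xpdtsim spectrum\n")
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# energy_keV\trelative_fluence\n")
        for e, n in zip(spectrum.energies, spectrum.fluence):
            fh.write(f"{e:.9g}\t{n:.9e}\n")


def read_spectrum(path) -> Spectrum:
    """Read a two-column text spectrum ('#' comments allowed)."""
    energies, fluence = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed spectrum line {lineno}: {raw.rstrip()!r}")
            try:
                e, n = float(parts[0]), float(parts[1])
            except ValueError:
                raise ValueError(f"{path}: malformed spectrum line {lineno}: {raw.rstrip()!r}") from None
            energies.append(e)
            fluence.append(n)
    e = np.array(energies)
    n = np.array(fluence)
    if np.any(n < 0):
        raise ValueError(f"{path}: negative fluence values")
    order = np.argsort(e)
    if not np.array_equal(order, np.arange(len(e))):
        warnings.warn(f"{path}: spectrum energies were unsorted; sorting ascending")
        e, n = e[order], n[order]
    return Spectrum(e, n)
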