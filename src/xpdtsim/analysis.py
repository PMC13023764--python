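"""Dosimetric endpoints: depth dose, PDD, DER, AAD and normalizations.

DER (dose enhancement ratio) is the depth dose with the nanoprobe
divided by the depth dose at the same point without it; "a point" is
implemented as the tumor-layer mean over the beam cross-section, with a
per-voxel central-axis variant available.  AAD is the average absorbed
dose over all tumor voxels.  PDD normalizes a depth-dose curve to its
maximum in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import VoxelPhantom, depth_layers
from .transport import DoseGrid

__all__ = ["DepthCurve", "depth_dose", "pdd", "der_curve", "aad", "aad_der",
           "normalize_to_surface_dose", "peak", "max_rel_uncertainty",
           "extrapolate_rel_uncertainty", "summarize_pair", "plot_depth_curves"]


@dataclass(frozen=True)
class DepthCurve:
    """1-D dosimetric endpoint along the beam axis."""

    depths_mm: np.ndarray
    values: np.ndarray  # Gy, % (PDD) or ratio (DER)
    uncertainties: np.ndarray | None = None  # absolute, same shape

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_mm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if d.shape != v.shape or d.ndim != 1:
            raise ValueError("depths and values must be equal-length 1-D arrays")
        if not np.all(np.diff(d) > 0):
            raise ValueError("depths must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("curve values must be finite")
        object.__setattr__(self, "depths_mm", d)
        object.__setattr__(self, "values", v)
        if self.uncertainties is not None:
            u = np.asarray(self.uncertainties, dtype=float)
            if u.shape != v.shape:
                raise ValueError("uncertainties shape mismatch")
            object.__setattr__(self, "uncertainties", u)


def _require_dose(grid: DoseGrid) -> np.ndarray:
    if grid.dose is None:
        raise ValueError("DoseGrid has no dose yet; call convert_to_dose first")
    return grid.dose


def depth_dose(grid: DoseGrid, phantom: VoxelPhantom,
               central_axis: bool = False) -> DepthCurve:
    """Mean dose per tumor layer along the beam axis.

    Layer uncertainty assumes independent voxels:
    SE_layer = sqrt(sum sigma_v^2) / n_voxels.  With ``central_axis``
    only the voxel column nearest the field center is used.
    """
    dose = _require_dose(grid)
    depths, z_indices = depth_layers(phantom)
    values = np.empty(len(z_indices))
    uncs = np.empty(len(z_indices))
    mask2d = None
    if central_axis:
        beam = phantom.beam
        icx = int(0.5 * (beam.x_min_mm + beam.x_max_mm) / phantom.voxel_size_mm)
        icy = int(0.5 * (beam.y_min_mm + beam.y_max_mm) / phantom.voxel_size_mm)
    for k, z in enumerate(z_indices):
        layer = phantom.tumor_mask[:, :, z]
        if not layer.any():
            raise ValueError(f"tumor layer at z={z} is empty")
        if central_axis:
            sel_dose = np.array([dose[icx, icy, z]])
            sel_rel = np.array([grid.rel_uncertainty[icx, icy, z]])
        else:
            sel_dose = dose[:, :, z][layer]
            sel_rel = grid.rel_uncertainty[:, :, z][layer]
        values[k] = sel_dose.mean()
        sigma = sel_dose * sel_rel
        uncs[k] = np.sqrt(np.sum(sigma**2)) / sel_dose.size
    return DepthCurve(depths, values, uncs)


def pdd(curve: DepthCurve) -> DepthCurve:
    """Percentage depth dose: values scaled to percent of the maximum."""
    peak_val = curve.values.max()
    if peak_val <= 0:
        raise ValueError("PDD undefined for an all-zero depth-dose curve")
    unc = None if curve.uncertainties is None else curve.uncertainties / peak_val * 100.0
    return DepthCurve(curve.depths_mm, curve.values / peak_val * 100.0, unc)


def der_curve(with_probe: DepthCurve, without_probe: DepthCurve) -> DepthCurve:
    """Pointwise DER: with-probe / without-probe depth dose."""
    if not np.allclose(with_probe.depths_mm, without_probe.depths_mm):
        raise ValueError("DER requires identical depth grids")
    denom = without_probe.values
    bad = np.nonzero(denom == 0)[0]
    if bad.size:
        raise ZeroDivisionError(f"zero reference dose at layer index {bad[0]} "
                                f"(depth {with_probe.depths_mm[bad[0]]} mm)")
    ratio = with_probe.values / denom
    unc = None
    if with_probe.uncertainties is not None and without_probe.uncertainties is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_w = np.where(with_probe.values != 0,
                             with_probe.uncertainties / with_probe.values, 0.0)
            rel_o = without_probe.uncertainties / denom
        unc = ratio * np.sqrt(rel_w**2 + rel_o**2)
    return DepthCurve(with_probe.depths_mm, ratio, unc)


def aad(grid: DoseGrid, phantom: VoxelPhantom) -> float:
    """Average absorbed dose over all tumor voxels, Gy."""
    if not phantom.tumor_mask.any():
        raise ValueError("phantom has an empty tumor mask")
    return float(_require_dose(grid)[phantom.tumor_mask].mean())


def aad_der(grid_with: DoseGrid, grid_without: DoseGrid,
            phantom: VoxelPhantom) -> float:
    """Enhancement ratio of the tumor average absorbed dose."""
    denom = aad(grid_without, phantom)
    if denom == 0:
        raise ZeroDivisionError("reference tumor AAD is zero")
    return aad(grid_with, phantom) / denom


def normalize_to_surface_dose(grid: DoseGrid, phantom: VoxelPhantom,
                              target_gy: float) -> DoseGrid:
    """Rescale the grid so the tumor entry-layer mean dose equals target.

    Dose is linear in fluence, so a global scale factor is exact; PDD
    and every DER are invariant under it.
    """
    if target_gy <= 0:
        raise ValueError("target surface dose must be positive")
    dose = _require_dose(grid)
    z_entry = depth_layers(phantom)[1][0]
    surface = dose[:, :, z_entry][phantom.tumor_mask[:, :, z_entry]].mean()
    if surface <= 0:
        raise ValueError("entry-layer mean dose is zero; cannot normalize")
    return grid.scaled(target_gy / surface)


def peak(curve: DepthCurve):
    """(peak value, peak depth mm); ties resolve to the shallower depth."""
    i = int(np.argmax(curve.values))
    return float(curve.values[i]), float(curve.depths_mm[i])


def max_rel_uncertainty(grid: DoseGrid, phantom: VoxelPhantom,
                        dose_fraction: float = 0.5) -> float:
    """Maximum per-voxel relative standard error over the reporting
    region: tumor voxels receiving more than ``dose_fraction`` of the
    peak tumor voxel dose (low-dose voxels excluded)."""
    dose = _require_dose(grid)
    tum_dose = dose[phantom.tumor_mask]
    tum_rel = grid.rel_uncertainty[phantom.tumor_mask]
    peak_dose = tum_dose.max()
    if peak_dose <= 0:
        raise ValueError("no dose recorded in the tumor")
    sel = tum_dose > dose_fraction * peak_dose
    return float(tum_rel[sel].max())


def extrapolate_rel_uncertainty(value: float, n_run: int, n_target: int) -> float:
    """1/sqrt(N) scaling of a relative statistical uncertainty."""
    return value * np.sqrt(n_run / n_target)


def summarize_pair(grid_with: DoseGrid, grid_without: DoseGrid,
                   phantom_with: VoxelPhantom, phantom_without: VoxelPhantom,
                   kvp: float | None = None) -> dict:
    """Per-setting summary of the with/without-probe comparison."""
    curve_w = depth_dose(grid_with, phantom_with)
    curve_o = depth_dose(grid_without, phantom_without)
    der = der_curve(curve_w, curve_o)
    peak_der, peak_der_depth = peak(der)
    _, peak_dose_depth = peak(curve_w)
    return {
        "kvp": kvp,
        "aad_with": aad(grid_with, phantom_with),
        "aad_without": aad(grid_without, phantom_without),
        "aad_der": aad_der(grid_with, grid_without, phantom_with),
        "peak_der": peak_der,
        "peak_der_depth_mm": peak_der_depth,
        "peak_dose_depth_mm": peak_dose_depth,
        "max_rel_uncertainty": max_rel_uncertainty(grid_with, phantom_with),
    }


def plot_depth_curves(curves: dict, path, ylabel: str = "dose (Gy)",
                      title: str | None = None) -> None:
    """Plot labelled depth curves to a file (matplotlib, Agg backend)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, c in curves.items():
        ax.errorbar(c.depths_mm, c.values, yerr=c.uncertainties, label=str(label))
    ax.set_xlabel("depth (mm)")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
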