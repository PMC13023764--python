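"""Voxelized phantoms for the four simulation geometries.

Model A: a 5 mm water cube (the tumor) sitting centered and flush on the
top 6 x 3 cm face of a 6 x 3 x 3 cm water slab (the mouse body), with a
parallel beam entering vertically through the cube's top face and
covering it exactly.  Model B: identical, but the tumor cube is filled
with the 10 mg/mL nanoparticle suspension.  Models C and D are the bare
tumor cubes (water / suspension) with the same beam and no surrounding
slab.

Coordinates: voxel indices are 0-based, voxel i spans
[i*voxel_size, (i+1)*voxel_size) mm; z is vertical with index 0 at the
slab bottom, and the beam travels along -z so depth is measured downward
from the tumor's top (entry) face.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .materials import MaterialComposition, np_suspension_composition, water

__all__ = ["Beam", "VoxelPhantom", "build_model", "depth_layers",
           "save_phantom", "load_phantom"]

TUMOR_SIDE_MM = 5.0
SLAB_X_MM, SLAB_Y_MM, SLAB_Z_MM = 60.0, 30.0, 30.0

GRID_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Beam:
    """Parallel rectangular beam, direction -z, covering the tumor face."""

    direction: tuple = (0.0, 0.0, -1.0)
    x_min_mm: float = 0.0
    x_max_mm: float = TUMOR_SIDE_MM
    y_min_mm: float = 0.0
    y_max_mm: float = TUMOR_SIDE_MM
    entry_z_mm: float = TUMOR_SIDE_MM  # entry plane (top of grid)

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("beam direction must be a unit vector")
        if self.x_max_mm <= self.x_min_mm or self.y_max_mm <= self.y_min_mm:
            raise ValueError("beam field extent must be positive")


@dataclass(frozen=True)
class VoxelPhantom:
    """3-D material-id grid plus beam definition.

    ``materials[0]`` is always vacuum (None); ``material_id`` indexes
    into ``materials``.
    """

    model: str
    shape: tuple  # (nx, ny, nz)
    voxel_size_mm: float
    material_id: np.ndarray  # uint8, shape (nx, ny, nz)
    materials: tuple  # (None, MaterialComposition, ...)
    tumor_mask: np.ndarray  # bool, same shape
    beam: Beam

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.material_id.shape != self.shape or self.tumor_mask.shape != self.shape:
            raise ValueError("grid arrays inconsistent with declared shape")
        if self.material_id.max() >= len(self.materials):
            raise ValueError("material id out of range of the material list")
        if self.materials[0] is not None:
            raise ValueError("materials[0] must be vacuum (None)")

    @property
    def n_tumor_layers(self) -> int:
        return round(TUMOR_SIDE_MM / self.voxel_size_mm)

    @property
    def tumor_top_z(self) -> int:
        """z-index of the tumor entry layer (beam side)."""
        return self.shape[2] - 1

    def voxel_volume_cm3(self) -> float:
        return (self.voxel_size_mm / 10.0) ** 3

    def density_by_id(self) -> np.ndarray:
        """Mass density per material id (vacuum -> 0), g/cm^3."""
        return np.array([0.0 if m is None else m.density for m in self.materials])

    def total_mass_g(self) -> float:
        counts = np.bincount(self.material_id.ravel(), minlength=len(self.materials))
        return float(np.sum(counts * self.density_by_id()) * self.voxel_volume_cm3())


def _check_divides(voxel_size: float, length_mm: float, what: str) -> int:
    n = length_mm / voxel_size
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"voxel size {voxel_size} mm does not divide {what} ({length_mm} mm)")
    return round(n)


def build_model(model: str, tumor_material: MaterialComposition | None = None,
                body_material: MaterialComposition | None = None,
                voxel_size_mm: float = 0.2,
                np_concentration_mg_ml: float = 10.0) -> VoxelPhantom:
    """Build one of the four phantoms (A, B, C or D).

    A/C use water in the tumor cube, B/D the nanoparticle suspension
    (10 mg/mL by default).  A/B place the cube on the water slab; C/D
    are the isolated cube with the identical beam.
    """
    model = model.upper()
    if model not in "ABCD" or len(model) != 1:
        raise ValueError(f"model must be one of A, B, C, D; got {model!r}")
    nt = _check_divides(voxel_size_mm, TUMOR_SIDE_MM, "the 5 mm tumor cube")
    if body_material is None:
        body_material = water()
    if tumor_material is None:
        tumor_material = (water() if model in "AC"
                          else np_suspension_composition(np_concentration_mg_ml))

    if model in "AB":
        nx = _check_divides(voxel_size_mm, SLAB_X_MM, "the slab x extent")
        ny = _check_divides(voxel_size_mm, SLAB_Y_MM, "the slab y extent")
        nz_slab = _check_divides(voxel_size_mm, SLAB_Z_MM, "the slab z extent")
        shape = (nx, ny, nz_slab + nt)
        ids = np.zeros(shape, dtype=np.uint8)
        ids[:, :, :nz_slab] = 1  # body slab
        x0, y0 = (nx - nt) // 2, (ny - nt) // 2
        tumor = np.zeros(shape, dtype=bool)
        tumor[x0:x0 + nt, y0:y0 + nt, nz_slab:] = True
        ids[tumor] = 2
        materials = (None, body_material, tumor_material)
        beam = Beam(
            x_min_mm=x0 * voxel_size_mm, x_max_mm=(x0 + nt) * voxel_size_mm,
            y_min_mm=y0 * voxel_size_mm, y_max_mm=(y0 + nt) * voxel_size_mm,
            entry_z_mm=shape[2] * voxel_size_mm,
        )
    else:
        shape = (nt, nt, nt)
        tumor = np.ones(shape, dtype=bool)
        ids = np.ones(shape, dtype=np.uint8)
        materials = (None, tumor_material)
        beam = Beam(x_min_mm=0.0, x_max_mm=TUMOR_SIDE_MM,
                    y_min_mm=0.0, y_max_mm=TUMOR_SIDE_MM,
                    entry_z_mm=shape[2] * voxel_size_mm)
    return VoxelPhantom(model=model, shape=shape, voxel_size_mm=voxel_size_mm,
                        material_id=ids, materials=materials,
                        tumor_mask=tumor, beam=beam)


def depth_layers(phantom: VoxelPhantom):
    """Tumor voxel layers ordered along the beam (entry face first).

    Returns ``(depths_mm, z_indices)`` where layer k collects the tumor
    voxels with z-index ``z_indices[k]`` and its center depth is
    ``depths_mm[k] = (k + 0.5) * voxel_size`` below the entry face.
    """
    nt = phantom.n_tumor_layers
    nz = phantom.shape[2]
    z_indices = np.arange(nz - 1, nz - 1 - nt, -1)
    depths = (np.arange(nt) + 0.5) * phantom.voxel_size_mm
    return depths, z_indices


def save_phantom(phantom: VoxelPhantom, path) -> None:
    """Write the documented grid file: JSON header line, then the raw
    material-id bytes (C order, uint8, little-endian irrelevant)."""
    header = {
        "format": "xpdtsim-grid", "version": GRID_FORMAT_VERSION,
        "model": phantom.model, "shape": list(phantom.shape),
        "voxel_size_mm": phantom.voxel_size_mm,
        "materials": [None if m is None else
                      {"name": m.name, "density": m.density,
                       "constituents": list(map(list, m.constituents))}
                      for m in phantom.materials],
        "beam": {"direction": list(phantom.beam.direction),
                 "x_mm": [phantom.beam.x_min_mm, phantom.beam.x_max_mm],
                 "y_mm": [phantom.beam.y_min_mm, phantom.beam.y_max_mm],
                 "entry_z_mm": phantom.beam.entry_z_mm},
    }
    with open(path, "wb") as fh:
        fh.write((json.dumps(header) + "\n").encode())
        fh.write(np.ascontiguousarray(phantom.material_id, dtype=np.uint8).tobytes())


def load_phantom(path) -> VoxelPhantom:
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        if header.get("format") != "xpdtsim-grid":
            raise ValueError(f"{path}: not an xpdtsim grid file")
        shape = tuple(header["shape"])
        ids = np.frombuffer(fh.read(), dtype=np.uint8).reshape(shape).copy()
    materials = tuple(
        None if m is None else MaterialComposition(
            m["name"], tuple((s, w) for s, w in m["constituents"]), m["density"])
        for m in header["materials"]
    )
    tumor_id = len(materials) - 1
    beam = Beam(direction=tuple(header["beam"]["direction"]),
                x_min_mm=header["beam"]["x_mm"][0], x_max_mm=header["beam"]["x_mm"][1],
                y_min_mm=header["beam"]["y_mm"][0], y_max_mm=header["beam"]["y_mm"][1],
                entry_z_mm=header["beam"]["entry_z_mm"])
    return VoxelPhantom(model=header["model"], shape=shape,
                        voxel_size_mm=header["voxel_size_mm"],
                        material_id=ids, materials=materials,
                        tumor_mask=ids == tumor_id, beam=beam)
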