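"""Elemental photon cross sections and the mixture rule.

Element tables are shipped as plain-text files (one per element) on a
log-energy grid with absorption edges represented by duplicated grid
energies, and are interpolated log-log linearly.  Compound coefficients
follow the standard mixture rule  (mu/rho)_mix = sum_i w_i (mu/rho)_i,
with the linear coefficient obtained by multiplying with the mass
density.

Built-in materials cover liquid water and the aqueous suspension of the
Tb/Gd-doped sodium lutetium fluoride nanocrystal used as an X-PDT
radiosensitizer, Na(Lu0.65 Gd0.20 Tb0.15)F4, at a configurable
concentration (10 mg/mL by default).
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CHANNELS",
    "ElementXsecTable",
    "MaterialComposition",
    "load_element_table",
    "element_tables",
    "interpolate_xsec",
    "mixture_mu",
    "np_suspension_composition",
    "nanoparticle_composition",
    "water",
    "builtin_material",
]

#: coefficient channels, in table column order
CHANNELS = ("total", "photoelectric", "incoherent", "coherent", "energy_absorption")

#: atomic masses (g/mol) of the elements with bundled tables
ATOMIC_MASS = {
    "H": 1.008, "Be": 9.0122, "O": 15.999, "F": 18.998403, "Na": 22.98977,
    "Gd": 157.25, "Tb": 158.92534, "Lu": 174.9668, "W": 183.84,
}

ATOMIC_NUMBER = {
    "H": 1, "Be": 4, "O": 8, "F": 9, "Na": 11,
    "Gd": 64, "Tb": 65, "Lu": 71, "W": 74,
}

WATER_DENSITY = 1.0  # g/cm^3 (simulation convention)
LU_DENSITY = 9.841  # g/cm^3, elemental lutetium


class XsecRangeError(ValueError):
    """Requested energy falls outside an element table's grid."""


@dataclass(frozen=True)
class ElementXsecTable:
    """Mass attenuation coefficients of one element on a log-energy grid."""

    symbol: str
    Z: int
    energies: np.ndarray  # keV, strictly increasing (edges duplicated +/- 5 eV)
    mu_rho_total: np.ndarray  # cm^2/g
    mu_rho_photoelectric: np.ndarray
    mu_rho_incoherent: np.ndarray
    mu_rho_coherent: np.ndarray
    mu_en_rho: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.energies) > 0):
            raise ValueError(f"{self.symbol}: energy grid not strictly increasing")
        for ch in CHANNELS:
            if np.any(self.channel(ch) <= 0):
                raise ValueError(f"{self.symbol}: non-positive {ch} coefficient")

    def channel(self, name: str) -> np.ndarray:
        try:
            return {
                "total": self.mu_rho_total,
                "photoelectric": self.mu_rho_photoelectric,
                "incoherent": self.mu_rho_incoherent,
                "coherent": self.mu_rho_coherent,
                "energy_absorption": self.mu_en_rho,
            }[name]
        except KeyError:
            raise ValueError(f"unknown channel {name!r}; expected one of {CHANNELS}") from None

    def interpolate(self, energy, channel: str = "total"):
        return interpolate_xsec(self, energy, channel)


@functools.lru_cache(maxsize=None)
def load_element_table(symbol: str) -> ElementXsecTable:
    """Load the bundled table for one element (cached)."""
    if symbol not in ATOMIC_MASS:
        raise KeyError(f"no bundled cross-section table for element {symbol!r}")
    ref = importlib.resources.files("xpdtsim").joinpath(f"data/xsec/{symbol}.txt")
    with ref.open("r") as fh:
        data = np.loadtxt(fh)
    return ElementXsecTable(
        symbol=symbol,
        Z=ATOMIC_NUMBER[symbol],
        energies=np.ascontiguousarray(data[:, 0]),
        mu_rho_total=np.ascontiguousarray(data[:, 1]),
        mu_rho_photoelectric=np.ascontiguousarray(data[:, 2]),
        mu_rho_incoherent=np.ascontiguousarray(data[:, 3]),
        mu_rho_coherent=np.ascontiguousarray(data[:, 4]),
        mu_en_rho=np.ascontiguousarray(data[:, 5]),
    )


def element_tables(symbols=None) -> dict:
    """Tables for the requested elements (all bundled ones by default)."""
    if symbols is None:
        symbols = tuple(ATOMIC_MASS)
    return {s: load_element_table(s) for s in symbols}


def interpolate_xsec(table: ElementXsecTable, energy, channel: str = "total"):
    """Log-log linear interpolation of a mass coefficient (cm^2/g).

    Exact at grid points; absorption-edge discontinuities are preserved
    because edges appear twice in the grid.  Raises :class:`XsecRangeError`
    for energies outside the tabulated range.
    """
    e = np.asarray(energy, dtype=float)
    lo, hi = table.energies[0], table.energies[-1]
    if np.any(e < lo) or np.any(e > hi):
        raise XsecRangeError(
            f"energy outside {table.symbol} table range [{lo:.4g}, {hi:.4g}] keV"
        )
    vals = np.exp(
        np.interp(np.log(e), np.log(table.energies), np.log(table.channel(channel)))
    )
    return float(vals) if np.isscalar(energy) else vals


@dataclass(frozen=True)
class MaterialComposition:
    """A homogeneous material: elemental mass fractions plus density."""

    name: str
    constituents: tuple  # ((symbol, mass_fraction), ...)
    density: float  # g/cm^3

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        ws = np.array([w for _, w in self.constituents], dtype=float)
        if len(ws) == 0 or np.any(ws <= 0) or np.any(ws > 1):
            raise ValueError(f"{self.name}: mass fractions must lie in (0, 1]")
        if abs(ws.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: mass fractions sum to {ws.sum()!r}, not 1")
        object.__setattr__(self, "constituents", tuple((s, float(w)) for s, w in self.constituents))

    def elements(self):
        return tuple(s for s, _ in self.constituents)


def mixture_mu(material: MaterialComposition, tables: dict, energy, channel: str = "total"):
    """Mixture-rule coefficients: (mass cm^2/g, linear 1/cm)."""
    missing = [s for s in material.elements() if s not in tables]
    if missing:
        raise KeyError(f"no cross-section table for element(s) {missing} in {material.name}")
    mass = None
    for sym, w in material.constituents:
        v = w * interpolate_xsec(tables[sym], energy, channel)
        mass = v if mass is None else mass + v
    return mass, mass * material.density


def _merge(fracs: dict) -> tuple:
    return tuple(sorted(fracs.items()))


# molar stoichiometry of the doped nanocrystal Na(Lu0.65 Gd0.20 Tb0.15)F4;
# the 20%/15% Gd/Tb doping substitutes Lu sites (standard doped-crystal usage)
NP_STOICHIOMETRY = (("Na", 1.0), ("Lu", 0.65), ("Gd", 0.20), ("Tb", 0.15), ("F", 4.0))
NP_DENSITY = 6.0  # g/cm^3, bulk crystal; only used if the pure compound is built


def nanoparticle_composition(stoichiometry=NP_STOICHIOMETRY, density: float = NP_DENSITY,
                             name: str = "nalufgdtb") -> MaterialComposition:
    """Pure doped-nanocrystal compound from its molar stoichiometry."""
    masses = {sym: n * ATOMIC_MASS[sym] for sym, n in stoichiometry}
    total = sum(masses.values())
    return MaterialComposition(
        name=name,
        constituents=_merge({s: m / total for s, m in masses.items()}),
        density=density,
    )


def water(name: str = "water") -> MaterialComposition:
    """Liquid water, 2H + O by stoichiometry."""
    m_h, m_o = 2 * ATOMIC_MASS["H"], ATOMIC_MASS["O"]
    tot = m_h + m_o
    return MaterialComposition(name, (("H", m_h / tot), ("O", m_o / tot)), WATER_DENSITY)


def np_suspension_composition(concentration_mg_ml: float,
                              stoichiometry=NP_STOICHIOMETRY,
                              water_density: float = WATER_DENSITY) -> MaterialComposition:
    """Aqueous nanoparticle suspension at a given concentration.

    Volume-additive convention: 1 mL of suspension holds ``c`` mg of
    nanocrystal plus 1 mL of water, so the nanoparticle mass fraction is
    c / (1000 * rho_water + c) and the suspension density is
    rho_water + c/1000 (1.010 g/cm^3 at 10 mg/mL).
    """
    c = float(concentration_mg_ml)
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if c == 0:
        return water()
    w_np = c / (water_density * 1000.0 + c)
    np_mat = nanoparticle_composition(stoichiometry)
    wat = water()
    fracs: dict = {}
    for sym, w in np_mat.constituents:
        fracs[sym] = fracs.get(sym, 0.0) + w_np * w
    for sym, w in wat.constituents:
        fracs[sym] = fracs.get(sym, 0.0) + (1.0 - w_np) * w
    return MaterialComposition(
        name=f"np_suspension_{c:g}mgml",
        constituents=_merge(fracs),
        density=water_density + c / 1000.0,
    )


def lutetium() -> MaterialComposition:
    """Elemental lutetium at its standard density (analytic-oracle slab)."""
    return MaterialComposition("Lu", (("Lu", 1.0),), LU_DENSITY)


def beryllium() -> MaterialComposition:
    return MaterialComposition("Be", (("Be", 1.0),), 1.848)


def tungsten() -> MaterialComposition:
    return MaterialComposition("W", (("W", 1.0),), 19.25)


_BUILTINS = {
    "water": water,
    "np_suspension_10mgml": lambda: np_suspension_composition(10.0),
    "lutetium": lutetium,
    "beryllium": beryllium,
    "tungsten": tungsten,
}


def builtin_material(name: str) -> MaterialComposition:
    """Look up a built-in material by name."""
    try:
        return _BUILTINS[name]()
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; built-ins: {sorted(_BUILTINS)}"
        ) from None
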