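"""Numba kernels for voxel photon transport (kerma approximation).

All kernels are deterministic for a fixed seed and run single-threaded;
the batch layer in :mod:`xpdtsim.transport` derives per-batch sub-seeds
from one master seed, so results are independent of how batches are
grouped.

Physics per history: energy sampled from the binned spectrum; free path
sampled from the local linear attenuation coefficient with an exact
voxel-boundary (DDA) walk; interaction channel sampled from the partial
cross sections; photoelectric absorbs the photon locally; Compton
deposits E - E' locally with the scattered photon sampled from the
free-electron Klein-Nishina law; Rayleigh redirects via the Thomson
angular law without energy deposit.  All electron energy stays in the
interaction voxel (kerma approximation).  Photoelectric events on
K shells of high-Z constituents re-emit the K-fluorescence photon
isotropically (probability and mean line energy precomputed per
material and energy) and transport it; without this the centimetre-
range 43-61 keV fluorescence of Gd/Tb/Lu would be deposited locally
and the enhancement above the K edges grossly overestimated.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1.0e30


@njit(cache=True, inline="always")
def _lookup(grid_vals, mat, loge, loge0, dloge, ng):
    """Linear interpolation of a per-material log-energy lookup table."""
    t = (loge - loge0) / dloge
    if t <= 0.0:
        return grid_vals[mat, 0]
    if t >= ng - 1:
        return grid_vals[mat, ng - 1]
    i = int(t)
    f = t - i
    return grid_vals[mat, i] * (1.0 - f) + grid_vals[mat, i + 1] * f


@njit(cache=True, inline="always")
def _sample_kn_cos(e_kev):
    """Klein-Nishina polar scattering cosine by rejection (envelope 2)."""
    a = e_kev / 510.99895
    while True:
        c = 1.0 - 2.0 * np.random.random()
        kp = 1.0 / (1.0 + a * (1.0 - c))
        p = kp * kp * (kp + 1.0 / kp - (1.0 - c * c))
        if 2.0 * np.random.random() <= p:
            return c, kp


@njit(cache=True, inline="always")
def _sample_thomson_cos():
    """Thomson angular law ~ (1 + cos^2)."""
    while True:
        c = 1.0 - 2.0 * np.random.random()
        if 2.0 * np.random.random() <= 1.0 + c * c:
            return c


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cos_t, phi):
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.999999:
        sign = 1.0 if uz > 0.0 else -1.0
        return sin_t * cp, sin_t * sp, sign * cos_t
    den = np.sqrt(1.0 - uz * uz)
    nx = ux * cos_t + sin_t * (ux * uz * cp - uy * sp) / den
    ny = uy * cos_t + sin_t * (uy * uz * cp + ux * sp) / den
    nz = uz * cos_t - sin_t * den * cp
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def run_batch(mat_ids, nx, ny, nz, voxel_mm,
              spec_e, spec_cdf,
              mu_tot, cum_pe, cum_inc, p_kfluor, e_kfluor, loge0, dloge,
              bx0, bx1, by0, by1, z_top,
              n_hist, seed, e_cutoff, max_scatters):
    """Transport one batch of histories.

    Returns (edep keV per flat voxel index, escaped keV total, max
    per-history energy-conservation error keV)."""
    np.random.seed(seed)
    edep = np.zeros(nx * ny * nz, dtype=np.float64)
    ng = mu_tot.shape[1]
    escaped_total = 0.0
    max_err = 0.0
    nbins = spec_cdf.shape[0]
    for _ in range(n_hist):
        u = np.random.random()
        lo, hi = 0, nbins - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if spec_cdf[mid] < u:
                lo = mid + 1
            else:
                hi = mid
        e = spec_e[lo]
        e0 = e
        x = bx0 + np.random.random() * (bx1 - bx0)
        y = by0 + np.random.random() * (by1 - by0)
        z = z_top - 1.0e-9
        ux, uy, uz = 0.0, 0.0, -1.0
        ix = int(x / voxel_mm)
        iy = int(y / voxel_mm)
        iz = int(z / voxel_mm)
        deposited = 0.0
        escaped = 0.0
        n_scat = 0
        alive = not (ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz)
        if not alive:
            escaped = e
        while alive:
            tau = -np.log(1.0 - np.random.random())
            while True:
                mat = mat_ids[(ix * ny + iy) * nz + iz]
                mu_mm = 0.0
                loge = np.log(e)
                if mat > 0:
                    mu_mm = _lookup(mu_tot, mat, loge, loge0, dloge, ng) * 0.1
                if ux > 0.0:
                    tx = ((ix + 1) * voxel_mm - x) / ux
                elif ux < 0.0:
                    tx = (ix * voxel_mm - x) / ux
                else:
                    tx = BIG
                if uy > 0.0:
                    ty = ((iy + 1) * voxel_mm - y) / uy
                elif uy < 0.0:
                    ty = (iy * voxel_mm - y) / uy
                else:
                    ty = BIG
                if uz > 0.0:
                    tz = ((iz + 1) * voxel_mm - z) / uz
                elif uz < 0.0:
                    tz = (iz * voxel_mm - z) / uz
                else:
                    tz = BIG
                d = min(tx, ty, tz)
                if d < 0.0:
                    d = 0.0
                if mu_mm > 0.0 and mu_mm * d >= tau:
                    # interaction inside this voxel
                    s = tau / mu_mm
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    vox = (ix * ny + iy) * nz + iz
                    c_pe = _lookup(cum_pe, mat, loge, loge0, dloge, ng)
                    c_inc = _lookup(cum_inc, mat, loge, loge0, dloge, ng)
                    r = np.random.random()
                    if r < c_pe:
                        # photoelectric; possibly re-emit K fluorescence
                        p_fl = _lookup(p_kfluor, mat, loge, loge0, dloge, ng)
                        e_fl = _lookup(e_kfluor, mat, loge, loge0, dloge, ng)
                        if p_fl > 0.0 and e_fl < e and np.random.random() < p_fl:
                            edep[vox] += e - e_fl
                            deposited += e - e_fl
                            e = e_fl
                            cos_t = 1.0 - 2.0 * np.random.random()  # isotropic
                            phi = 2.0 * np.pi * np.random.random()
                            ux, uy, uz = _rotate(ux, uy, uz, cos_t, phi)
                            n_scat += 1
                        else:
                            edep[vox] += e
                            deposited += e
                            alive = False
                    elif r < c_inc:
                        cos_t, kp = _sample_kn_cos(e)
                        e_new = e * kp
                        edep[vox] += e - e_new
                        deposited += e - e_new
                        e = e_new
                        if e <= e_cutoff:
                            edep[vox] += e
                            deposited += e
                            alive = False
                        else:
                            phi = 2.0 * np.pi * np.random.random()
                            ux, uy, uz = _rotate(ux, uy, uz, cos_t, phi)
                            n_scat += 1
                    else:
                        cos_t = _sample_thomson_cos()
                        phi = 2.0 * np.pi * np.random.random()
                        ux, uy, uz = _rotate(ux, uy, uz, cos_t, phi)
                        n_scat += 1
                    if alive and n_scat >= max_scatters:
                        escaped = e
                        alive = False
                    break
                # advance to the nearest boundary and cross it
                tau -= mu_mm * d
                x += ux * d
                y += uy * d
                z += uz * d
                if d == tx:
                    if ux > 0.0:
                        ix += 1
                        x = ix * voxel_mm
                    else:
                        x = ix * voxel_mm
                        ix -= 1
                elif d == ty:
                    if uy > 0.0:
                        iy += 1
                        y = iy * voxel_mm
                    else:
                        y = iy * voxel_mm
                        iy -= 1
                else:
                    if uz > 0.0:
                        iz += 1
                        z = iz * voxel_mm
                    else:
                        z = iz * voxel_mm
                        iz -= 1
                if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                    escaped = e
                    alive = False
                    break
        escaped_total += escaped
        err = abs(e0 - deposited - escaped)
        if err > max_err:
            max_err = err
    return edep, escaped_total, max_err


@njit(cache=True)
def kn_sample_batch(e_kev, n, seed):
    """Sample n Klein-Nishina scatters at one energy (test/diagnostic).

    Returns (scattered energies keV, polar cosines)."""
    np.random.seed(seed)
    es = np.empty(n, dtype=np.float64)
    cs = np.empty(n, dtype=np.float64)
    for i in range(n):
        c, kp = _sample_kn_cos(e_kev)
        cs[i] = c
        es[i] = e_kev * kp
    return es, cs
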