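"""Numba kernels: straight-track CSDA voxel traversal with energy scoring.

A track starts at its emission point with energy E0 and CSDA range R0 and
walks the voxel grid with the Amanatides–Woo stepping scheme.  The energy
deposited in a voxel is the residual-energy difference across the voxel's
chord, E(R0−s_in) − E(R0−s_out), evaluated on the log–log range↔energy
knots, so the per-history total telescopes exactly to the energy spent
inside the grid.  Each straight track visits a voxel at most once, which
makes per-history squared deposits a single in-place update.
"""

import numpy as np
from numba import njit

__all__ = ["transport_voxel"]

_INF = 1e30


@njit(cache=False)
def _interp_lin(x, xs, ys):
    """Piecewise-linear interpolation with edge clamping (xs ascending)."""
    n = xs.shape[0]
    if x <= xs[0]:
        return ys[0]
    if x >= xs[n - 1]:
        return ys[n - 1]
    i = np.searchsorted(xs, x) - 1
    t = (x - xs[i]) / (xs[i + 1] - xs[i])
    return ys[i] + t * (ys[i + 1] - ys[i])


@njit(cache=False)
def _energy_at_range(r, log_r, log_e):
    """Residual energy at residual range r [µm]; 0 below the table floor."""
    if r <= 0.0:
        return 0.0
    lr = np.log(r)
    if lr <= log_r[0]:
        return 0.0
    return np.exp(_interp_lin(lr, log_r, log_e))


@njit(cache=False)
def transport_voxel(
    origins, directions, energies, recoil,
    log_e, log_r,
    energy_sum, energy_sumsq, mask,
    grid_min, edge,
):
    """Transport straight CSDA tracks, scoring energy per voxel.

    origins, directions : (n, 3) float64 [µm, unit vectors]
    energies, recoil    : (n,) float64 [MeV]; recoil deposits at the start voxel
    log_e, log_r        : log–log knots of the stopping table (E [MeV], R [µm])
    energy_sum/sumsq    : (nx, ny, nz) accumulators, updated in place
    mask                : (nx, ny, nz) uint8 region membership for the
                          per-history region tally

    Returns (region_sum, region_sumsq): Σh and Σh² of the per-history energy
    [MeV] deposited inside the masked region.
    """
    nx, ny, nz = energy_sum.shape
    region_sum = 0.0
    region_sumsq = 0.0
    n = origins.shape[0]
    for h in range(n):
        E0 = energies[h]
        if E0 <= 0.0:
            continue
        x = origins[h, 0] - grid_min[0]
        y = origins[h, 1] - grid_min[1]
        z = origins[h, 2] - grid_min[2]
        ix = int(np.floor(x / edge))
        iy = int(np.floor(y / edge))
        iz = int(np.floor(z / edge))
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            continue
        dx = directions[h, 0]
        dy = directions[h, 1]
        dz = directions[h, 2]
        R0 = np.exp(_interp_lin(np.log(E0), log_e, log_r))

        # Amanatides–Woo initialisation
        if dx > 0.0:
            sx, tmx, tdx = 1, ((ix + 1) * edge - x) / dx, edge / dx
        elif dx < 0.0:
            sx, tmx, tdx = -1, (ix * edge - x) / dx, -edge / dx
        else:
            sx, tmx, tdx = 0, _INF, _INF
        if dy > 0.0:
            sy, tmy, tdy = 1, ((iy + 1) * edge - y) / dy, edge / dy
        elif dy < 0.0:
            sy, tmy, tdy = -1, (iy * edge - y) / dy, -edge / dy
        else:
            sy, tmy, tdy = 0, _INF, _INF
        if dz > 0.0:
            sz, tmz, tdz = 1, ((iz + 1) * edge - z) / dz, edge / dz
        elif dz < 0.0:
            sz, tmz, tdz = -1, (iz * edge - z) / dz, -edge / dz
        else:
            sz, tmz, tdz = 0, _INF, _INF

        E_prev = E0
        pending = recoil[h]  # recoil energy deposits in the start voxel
        region_h = 0.0
        while True:
            s_next = tmx
            axis = 0
            if tmy < s_next:
                s_next = tmy
                axis = 1
            if tmz < s_next:
                s_next = tmz
                axis = 2
            stopped = s_next >= R0
            if stopped:
                E_next = 0.0
            else:
                E_next = _energy_at_range(R0 - s_next, log_r, log_e)
            dep = E_prev - E_next + pending
            pending = 0.0
            if dep > 0.0:
                energy_sum[ix, iy, iz] += dep
                energy_sumsq[ix, iy, iz] += dep * dep
                if mask[ix, iy, iz]:
                    region_h += dep
            if stopped:
                break
            E_prev = E_next
            if axis == 0:
                ix += sx
                tmx += tdx
                if ix < 0 or ix >= nx:
                    break
            elif axis == 1:
                iy += sy
                tmy += tdy
                if iy < 0 or iy >= ny:
                    break
            else:
                iz += sz
                tmz += tdz
                if iz < 0 or iz >= nz:
                    break
        region_sum += region_h
        region_sumsq += region_h * region_h
    return region_sum, region_sumsq
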