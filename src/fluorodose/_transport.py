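"""Numba transport kernels: Woodcock tracking in the voxel phantom and
analytic-path transport through the room's homogeneous regions.

Everything here works in mm for geometry and keV for energy; linear
attenuation coefficients are 1/cm (hence the factor 10 on sampled path
lengths).  All randomness flows through numba's internal ``np.random``
state, seeded once per kernel call, so a (seed, config) pair fixes every
output bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MEC2_KEV = 510.99895
_EPS_MM = 1.0e-4
_MAX_EVENTS = 100_000


@njit(cache=True, inline="always")
def _eindex(e_keV, e0, inv_de, n_e):
    i = int((e_keV - e0) * inv_de + 0.5)
    if i < 0:
        i = 0
    elif i >= n_e:
        i = n_e - 1
    return i


@njit(cache=True)
def _kn_scatter(e_keV):
    """Kahn's rejection sampling of the Klein-Nishina distribution.

    Returns (scattered energy keV, cos(theta)); E' = E/(1 + a(1-cos t)).
    """
    a = e_keV / MEC2_KEV
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (1.0 + 2.0 * a) / (9.0 + 2.0 * a):
            eta = 1.0 + 2.0 * a * r2
            if r3 <= 4.0 * (1.0 / eta - 1.0 / (eta * eta)):
                break
        else:
            eta = (1.0 + 2.0 * a) / (1.0 + 2.0 * a * r2)
            cost = 1.0 - (eta - 1.0) / a
            if r3 <= 0.5 * (cost * cost + 1.0 / eta):
                break
    cost = 1.0 - (eta - 1.0) / a
    return e_keV / eta, cost


@njit(cache=True)
def _rayleigh_cost():
    """Thomson-form coherent scattering angle, pdf ∝ 1 + cos²θ."""
    while True:
        c = 2.0 * np.random.random() - 1.0
        if 2.0 * np.random.random() <= 1.0 + c * c:
            return c


@njit(cache=True, inline="always")
def _rotate(dx, dy, dz, cost, phi):
    """Rotate direction by polar angle arccos(cost), azimuth phi."""
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(dz) > 0.99999:
        ux = sint * cosp
        uy = sint * sinp
        uz = cost * (1.0 if dz > 0.0 else -1.0)
        return ux, uy, uz
    rho = np.sqrt(dx * dx + dy * dy)
    ux = cost * dx + sint * (cosp * dx * dz - sinp * dy) / rho
    uy = cost * dy + sint * (cosp * dy * dz + sinp * dx) / rho
    uz = cost * dz - sint * cosp * rho
    n = np.sqrt(ux * ux + uy * uy + uz * uz)
    return ux / n, uy / n, uz / n


@njit(cache=True, inline="always")
def _ray_box(px, py, pz, dx, dy, dz, lo, hi):
    """Entry/exit distances (t0, t1) of a ray with an AABB; t1 < t0 => miss."""
    t0 = -1.0e30
    t1 = 1.0e30
    for k in range(3):
        if k == 0:
            p = px
            d = dx
        elif k == 1:
            p = py
            d = dy
        else:
            p = pz
            d = dz
        if abs(d) < 1.0e-12:
            if p < lo[k] or p >= hi[k]:
                return 1.0, -1.0
        else:
            ta = (lo[k] - p) / d
            tb = (hi[k] - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    return t0, t1


@njit(cache=True, inline="always")
def _inside(px, py, pz, lo, hi):
    return (lo[0] <= px < hi[0]) and (lo[1] <= py < hi[1]) and (lo[2] <= pz < hi[2])


@njit(cache=True)
def _sample_source(src, e1v, e2v, det, half_mm, isotropic):
    """Initial direction: through the collimated detector square, or isotropic."""
    if isotropic:
        cost = 2.0 * np.random.random() - 1.0
        phi = 2.0 * np.pi * np.random.random()
        sint = np.sqrt(1.0 - cost * cost)
        return sint * np.cos(phi), sint * np.sin(phi), cost
    u = (2.0 * np.random.random() - 1.0) * half_mm
    v = (2.0 * np.random.random() - 1.0) * half_mm
    dx = det[0] + u * e1v[0] + v * e2v[0] - src[0]
    dy = det[1] + u * e1v[1] + v * e2v[1] - src[1]
    dz = det[2] + u * e1v[2] + v * e2v[2] - src[2]
    n = np.sqrt(dx * dx + dy * dy + dz * dz)
    return dx / n, dy / n, dz / n


@njit(cache=True)
def skin_dose_kernel(seed, n_photons,
                     src, e1v, e2v, det, half_mm,
                     cdf, ebins,
                     mat, rho, grid_lo, spacing,
                     mu_rho, f_pe, f_co,
                     mu_maj, e0, inv_de,
                     cutoff_keV, rayleigh_on,
                     edep, mutr_rho, kscore, firstcol, fc_bin_mm):
    """Woodcock transport in the phantom grid with two dose estimators.

    ``edep`` (flattened C-order, keV) accumulates analog energy deposits;
    ``kscore`` accumulates the collision-density kerma estimator
    E·(μ_tr/ρ)/μ_maj (keV·cm³/g) at every Woodcock collision, real or
    virtual.  ``firstcol`` histograms the path length from phantom entry to
    the first *real* collision in ``fc_bin_mm`` bins (overflow in the last
    bin) for primary-transmission checks.  Returns (emitted, deposited,
    escaped) energies in keV.
    """
    np.random.seed(seed)
    nx, ny, nz = mat.shape
    n_e = mu_maj.shape[0]
    grid_hi = np.empty(3)
    for k in range(3):
        grid_hi[k] = grid_lo[k] + spacing[k] * mat.shape[k]
    emitted = 0.0
    escaped = 0.0
    deposited = 0.0
    for _ in range(n_photons):
        u = np.random.random()
        b = np.searchsorted(cdf, u)
        if b >= ebins.shape[0]:
            b = ebins.shape[0] - 1
        e = ebins[b]
        emitted += e
        dx, dy, dz = _sample_source(src, e1v, e2v, det, half_mm, False)
        px, py, pz = src[0], src[1], src[2]
        t0, t1 = _ray_box(px, py, pz, dx, dy, dz, grid_lo, grid_hi)
        if t1 <= max(t0, 0.0):
            escaped += e
            continue
        t0 = max(t0, 0.0) + _EPS_MM
        px += t0 * dx
        py += t0 * dy
        pz += t0 * dz
        alive = True
        ie = _eindex(e, e0, inv_de, n_e)
        events = 0
        plen = 0.0
        no_real_yet = True
        while alive:
            events += 1
            if events > _MAX_EVENTS:
                escaped += e
                break
            step = -np.log(np.random.random()) * 10.0 / mu_maj[ie]
            px += step * dx
            py += step * dy
            pz += step * dz
            if no_real_yet:
                plen += step
            if not _inside(px, py, pz, grid_lo, grid_hi):
                escaped += e
                if no_real_yet:
                    firstcol[firstcol.shape[0] - 1] += 1  # left uncollided
                    no_real_yet = False
                break
            ix = int((px - grid_lo[0]) / spacing[0])
            iy = int((py - grid_lo[1]) / spacing[1])
            iz = int((pz - grid_lo[2]) / spacing[2])
            m = mat[ix, iy, iz]
            mu = mu_rho[m, ie] * rho[ix, iy, iz]
            vox = (ix * ny + iy) * nz + iz
            # collision-density kerma estimator at every Woodcock collision
            kscore[vox] += e * mutr_rho[m, ie] / mu_maj[ie]
            if np.random.random() * mu_maj[ie] >= mu:
                continue  # virtual collision
            if no_real_yet:
                no_real_yet = False
                fb = int(plen / fc_bin_mm)
                if fb >= firstcol.shape[0] - 1:
                    fb = firstcol.shape[0] - 1
                firstcol[fb] += 1
            fpe = f_pe[m, ie]
            fco = f_co[m, ie]
            if rayleigh_on:
                norm = 1.0
            else:
                norm = fpe + fco
            xi = np.random.random() * norm
            if xi < fpe:
                edep[vox] += e
                deposited += e
                alive = False
            elif xi < fpe + fco:
                e2, cost = _kn_scatter(e)
                edep[vox] += e - e2
                deposited += e - e2
                e = e2
                if e < cutoff_keV:
                    edep[vox] += e
                    deposited += e
                    alive = False
                else:
                    dx, dy, dz = _rotate(dx, dy, dz, cost,
                                         2.0 * np.pi * np.random.random())
                    ie = _eindex(e, e0, inv_de, n_e)
            else:
                cost = _rayleigh_cost()
                dx, dy, dz = _rotate(dx, dy, dz, cost,
                                     2.0 * np.pi * np.random.random())
    return emitted, deposited, escaped


@njit(cache=True, inline="always")
def _score_segment(px, py, pz, dx, dy, dz, length_mm, weight,
                   lat_lo, lat_sp, lat_shape, accum):
    """Track-length scoring: add weight × ℓ_cm to each lattice cell crossed."""
    lat_hi0 = lat_lo[0] + lat_sp[0] * lat_shape[0]
    lat_hi1 = lat_lo[1] + lat_sp[1] * lat_shape[1]
    lat_hi2 = lat_lo[2] + lat_sp[2] * lat_shape[2]
    hi = np.empty(3)
    hi[0] = lat_hi0
    hi[1] = lat_hi1
    hi[2] = lat_hi2
    t0, t1 = _ray_box(px, py, pz, dx, dy, dz, lat_lo, hi)
    t0 = max(t0, 0.0)
    t1 = min(t1, length_mm)
    if t1 <= t0:
        return
    t = t0 + _EPS_MM
    qx = px + t * dx
    qy = py + t * dy
    qz = pz + t * dz
    ix = int((qx - lat_lo[0]) / lat_sp[0])
    iy = int((qy - lat_lo[1]) / lat_sp[1])
    iz = int((qz - lat_lo[2]) / lat_sp[2])
    if ix < 0 or iy < 0 or iz < 0 or ix >= lat_shape[0] or iy >= lat_shape[1] or iz >= lat_shape[2]:
        return
    # Amanatides-Woo traversal
    stepx = 1 if dx > 0 else -1
    stepy = 1 if dy > 0 else -1
    stepz = 1 if dz > 0 else -1
    offx = 1 if stepx > 0 else 0
    offy = 1 if stepy > 0 else 0
    offz = 1 if stepz > 0 else 0
    big = 1.0e30
    tmaxx = big if dx == 0.0 else ((lat_lo[0] + (ix + offx) * lat_sp[0]) - px) / dx
    tmaxy = big if dy == 0.0 else ((lat_lo[1] + (iy + offy) * lat_sp[1]) - py) / dy
    tmaxz = big if dz == 0.0 else ((lat_lo[2] + (iz + offz) * lat_sp[2]) - pz) / dz
    tdx = big if dx == 0.0 else abs(lat_sp[0] / dx)
    tdy = big if dy == 0.0 else abs(lat_sp[1] / dy)
    tdz = big if dz == 0.0 else abs(lat_sp[2] / dz)
    tcur = t0
    ny = lat_shape[1]
    nz = lat_shape[2]
    while tcur < t1:
        tnext = min(min(tmaxx, tmaxy), min(tmaxz, t1))
        seg = tnext - tcur
        if seg > 0.0:
            accum[(ix * ny + iy) * nz + iz] += seg * 0.1 * weight  # mm -> cm
        if tnext >= t1:
            break
        if tmaxx <= tmaxy and tmaxx <= tmaxz:
            ix += stepx
            tmaxx += tdx
            if ix < 0 or ix >= lat_shape[0]:
                break
        elif tmaxy <= tmaxz:
            iy += stepy
            tmaxy += tdy
            if iy < 0 or iy >= ny:
                break
        else:
            iz += stepz
            tmaxz += tdz
            if iz < 0 or iz >= nz:
                break
        tcur = tnext


# region codes for the room flight loop
_R_ESCAPED = 0
_R_AIR = 1
_R_PHANTOM = 2
_R_TABLE = 3
_R_WALL = 4


@njit(cache=True, inline="always")
def _classify(px, py, pz, inner_lo, inner_hi, outer_lo, outer_hi,
              ph_lo, ph_hi, tb_lo, tb_hi, has_phantom, has_table, has_walls):
    if _inside(px, py, pz, inner_lo, inner_hi):
        if has_phantom and _inside(px, py, pz, ph_lo, ph_hi):
            return _R_PHANTOM
        if has_table and _inside(px, py, pz, tb_lo, tb_hi):
            return _R_TABLE
        return _R_AIR
    if has_walls and _inside(px, py, pz, outer_lo, outer_hi):
        return _R_WALL
    return _R_ESCAPED


@njit(cache=True, inline="always")
def _boundary_distance(px, py, pz, dx, dy, dz, region,
                       inner_lo, inner_hi, outer_lo, outer_hi,
                       ph_lo, ph_hi, tb_lo, tb_hi,
                       has_phantom, has_table):
    """Distance to the nearest region change from a homogeneous region."""
    if region == _R_AIR:
        t0, t1 = _ray_box(px, py, pz, dx, dy, dz, inner_lo, inner_hi)
        b = t1
        if has_phantom:
            t0, t1 = _ray_box(px, py, pz, dx, dy, dz, ph_lo, ph_hi)
            if t1 > t0 and t0 > 0.0 and t0 < b:
                b = t0
        if has_table:
            t0, t1 = _ray_box(px, py, pz, dx, dy, dz, tb_lo, tb_hi)
            if t1 > t0 and t0 > 0.0 and t0 < b:
                b = t0
        return b
    if region == _R_TABLE:
        t0, t1 = _ray_box(px, py, pz, dx, dy, dz, tb_lo, tb_hi)
        return t1
    # wall shell: leave through the outer box or re-enter the inner box
    t0, t1 = _ray_box(px, py, pz, dx, dy, dz, outer_lo, outer_hi)
    b = t1
    t0, t1 = _ray_box(px, py, pz, dx, dy, dz, inner_lo, inner_hi)
    if t1 > t0 and t0 > 0.0 and t0 < b:
        b = t0
    return b


@njit(cache=True)
def air_kerma_kernel(seed, n_photons,
                     src, e1v, e2v, det, half_mm, isotropic,
                     cdf, ebins,
                     mat, rho, ph_lo, ph_spacing, has_phantom,
                     mu_rho, f_pe, f_co,
                     mu_maj, e0, inv_de,
                     inner_lo, inner_hi, outer_lo, outer_hi, has_walls,
                     wall_mat, wall_rho,
                     tb_lo, tb_hi, has_table, table_mat, table_rho,
                     air_rho,
                     mutr_air, cutoff_keV, rayleigh_on,
                     lat_lo, lat_sp, lat_shape, accum):
    """Room transport with track-length air-kerma scoring.

    ``accum`` (flattened air lattice) collects ℓ_cm × E_keV × (μ_tr/ρ)_air;
    the caller converts to Gy per source photon.  Phantom voxels use
    Woodcock tracking; table, walls and air use analytic free paths.
    """
    np.random.seed(seed)
    n_e = mu_maj.shape[0]
    ph_hi = np.empty(3)
    for k in range(3):
        ph_hi[k] = ph_lo[k] + ph_spacing[k] * mat.shape[k]
    for _ in range(n_photons):
        u = np.random.random()
        b = np.searchsorted(cdf, u)
        if b >= ebins.shape[0]:
            b = ebins.shape[0] - 1
        e = ebins[b]
        dx, dy, dz = _sample_source(src, e1v, e2v, det, half_mm, isotropic)
        px, py, pz = src[0], src[1], src[2]
        ie = _eindex(e, e0, inv_de, n_e)
        events = 0
        while True:
            events += 1
            if events > _MAX_EVENTS:
                break
            region = _classify(px, py, pz, inner_lo, inner_hi, outer_lo, outer_hi,
                               ph_lo, ph_hi, tb_lo, tb_hi,
                               has_phantom, has_table, has_walls)
            if region == _R_ESCAPED:
                break
            if region == _R_PHANTOM:
                # one Woodcock step inside the phantom grid, truncated at the
                # grid boundary (valid by memorylessness of the free path)
                step = -np.log(np.random.random()) * 10.0 / mu_maj[ie]
                t0, t1 = _ray_box(px, py, pz, dx, dy, dz, ph_lo, ph_hi)
                if step >= t1:
                    t = t1 + _EPS_MM
                    px += t * dx
                    py += t * dy
                    pz += t * dz
                    continue
                px += step * dx
                py += step * dy
                pz += step * dz
                if not _inside(px, py, pz, ph_lo, ph_hi):
                    continue
                ix = int((px - ph_lo[0]) / ph_spacing[0])
                iy = int((py - ph_lo[1]) / ph_spacing[1])
                iz = int((pz - ph_lo[2]) / ph_spacing[2])
                m = mat[ix, iy, iz]
                mu = mu_rho[m, ie] * rho[ix, iy, iz]
                if np.random.random() * mu_maj[ie] >= mu:
                    continue
            else:
                if region == _R_AIR:
                    m = 0  # Material.AIR
                    mu = mu_rho[m, ie] * air_rho
                elif region == _R_TABLE:
                    m = table_mat
                    mu = mu_rho[m, ie] * table_rho
                else:
                    m = wall_mat
                    mu = mu_rho[m, ie] * wall_rho
                s = -np.log(np.random.random()) * 10.0 / mu
                bdist = _boundary_distance(px, py, pz, dx, dy, dz, region,
                                           inner_lo, inner_hi, outer_lo, outer_hi,
                                           ph_lo, ph_hi, tb_lo, tb_hi,
                                           has_phantom, has_table)
                travel = min(s, bdist)
                if region == _R_AIR:
                    _score_segment(px, py, pz, dx, dy, dz, travel,
                                   e * mutr_air[ie], lat_lo, lat_sp, lat_shape,
                                   accum)
                if s >= bdist:
                    t = bdist + _EPS_MM
                    px += t * dx
                    py += t * dy
                    pz += t * dz
                    continue
                px += s * dx
                py += s * dy
                pz += s * dz
            # real interaction at (px, py, pz) in material m
            fpe = f_pe[m, ie]
            fco = f_co[m, ie]
            if rayleigh_on:
                norm = 1.0
            else:
                norm = fpe + fco
            xi = np.random.random() * norm
            if xi < fpe:
                break
            elif xi < fpe + fco:
                e2, cost = _kn_scatter(e)
                e = e2
                if e < cutoff_keV:
                    break
                dx, dy, dz = _rotate(dx, dy, dz, cost,
                                     2.0 * np.pi * np.random.random())
                ie = _eindex(e, e0, inv_de, n_e)
            else:
                cost = _rayleigh_cost()
                dx, dy, dz = _rotate(dx, dy, dz, cost,
                                     2.0 * np.pi * np.random.random())
    return 0
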