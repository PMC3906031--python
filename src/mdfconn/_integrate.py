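"""Numba kernels for the overlap integrals.

The bilinear (r, z) sampling here must stay numerically identical to
``mdf.sample_density``: values interpolated between bin centres, radius
clamped to the innermost centre, zero beyond the outermost centres plus
one bin width.
"""

import numpy as np
from numba import njit


@njit(inline="always", cache=True)
def _bilinear(vals, h, z0, x, y, z):  # pragma: no cover - numba
    nr, nz = vals.shape
    r = (x * x + y * y) ** 0.5
    fr = r / h - 0.5
    fz = (z - z0) / h - 0.5
    if fr >= nr or fz <= -1.0 or fz >= nz:
        return 0.0
    if fr < 0.0:
        fr = 0.0
    k0 = int(np.floor(fr))
    m0 = int(np.floor(fz))
    tr = fr - k0
    tz = fz - m0
    v00 = vals[k0, m0] if (0 <= k0 < nr and 0 <= m0 < nz) else 0.0
    v10 = vals[k0 + 1, m0] if (k0 + 1 < nr and 0 <= m0 < nz) else 0.0
    v01 = vals[k0, m0 + 1] if (0 <= k0 < nr and m0 + 1 < nz) else 0.0
    v11 = vals[k0 + 1, m0 + 1] if (k0 + 1 < nr and m0 + 1 < nz) else 0.0
    return ((1 - tr) * (1 - tz) * v00 + tr * (1 - tz) * v10
            + (1 - tr) * tz * v01 + tr * tz * v11)


@njit(cache=True)
def product_sum(vals_a, h_a, z0_a, vals_d, h_d, z0_d,
                rho, zeta, x0, y0, zlo, nx, ny, nzp, step):  # pragma: no cover
    """sum over the lattice of rho_a(x) * rho_d(x - d)."""
    total = 0.0
    for ix in range(nx):
        x = x0 + (ix + 0.5) * step
        for iy in range(ny):
            y = y0 + (iy + 0.5) * step
            for iz in range(nzp):
                z = zlo + (iz + 0.5) * step
                va = _bilinear(vals_a, h_a, z0_a, x, y, z)
                if va == 0.0:
                    continue
                vd = _bilinear(vals_d, h_d, z0_d, x - rho, y, z - zeta)
                total += va * vd
    return total


@njit(cache=True)
def template_sum(vals_a, h_a, z0_a, vals_d, h_d, z0_d, axes,
                 rho, zeta, x0, y0, zlo, nx, ny, nzp, step):  # pragma: no cover
    """sum over the lattice of sum_ij |sin theta_ij| T_a_i(x) T_d_j(x - d),
    with channel axes rotated into the global frame by each field's local
    azimuth at the evaluation point."""
    nch = vals_a.shape[0]
    ta = np.empty(nch)
    td = np.empty(nch)
    rax = np.empty((nch, 3))
    total = 0.0
    for ix in range(nx):
        x = x0 + (ix + 0.5) * step
        for iy in range(ny):
            y = y0 + (iy + 0.5) * step
            for iz in range(nzp):
                z = zlo + (iz + 0.5) * step
                sa = 0.0
                for i in range(nch):
                    ta[i] = _bilinear(vals_a[i], h_a, z0_a, x, y, z)
                    sa += ta[i]
                if sa == 0.0:
                    continue
                sd = 0.0
                for j in range(nch):
                    td[j] = _bilinear(vals_d[j], h_d, z0_d, x - rho, y, z - zeta)
                    sd += td[j]
                if sd == 0.0:
                    continue
                phi_a = np.arctan2(y, x)
                phi_d = np.arctan2(y, x - rho)
                dphi = phi_a - phi_d
                c = np.cos(dphi)
                s = np.sin(dphi)
                for i in range(nch):
                    rax[i, 0] = c * axes[i, 0] - s * axes[i, 1]
                    rax[i, 1] = s * axes[i, 0] + c * axes[i, 1]
                    rax[i, 2] = axes[i, 2]
                for i in range(nch):
                    if ta[i] == 0.0:
                        continue
                    for j in range(nch):
                        if td[j] == 0.0:
                            continue
                        dot = (rax[i, 0] * axes[j, 0] + rax[i, 1] * axes[j, 1]
                               + rax[i, 2] * axes[j, 2])
                        sin2 = 1.0 - dot * dot
                        if sin2 < 0.0:
                            sin2 = 0.0
                        total += np.sqrt(sin2) * ta[i] * td[j]
    return total
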