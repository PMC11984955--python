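"""Fused per-cell kernels for the expensive inner loop (numba-accelerated).

The production stepper spends nearly all of its time in three places:
evaluating chemical potentials (logs + Laplacians), assembling the
per-cell 4x4 friction matrix and solving ``A v = -grad(mu)``, and the
upwinded flux divergence.  Batched LAPACK and whole-array numpy
temporaries dominate a single-core budget, so these are fused into
single-pass kernels here.  Pure-numpy reference implementations of the
same operations live in :mod:`tmemix.spatial` and the two paths are
cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _mu_kernel(
    phi, d, d0, lcc, lct, lcf, kappa, dx, phi_floor, phi0_floor
):  # pragma: no cover
    """Chemical potentials mu_i = df/dphi_i - kappa lap(phi_i).

    Mirror (no-flux) ghost cells for the 5-point Laplacian; log
    arguments floored.  Returns (mu, n_floor_phi, n_floor_phi0).
    """
    ny, nx = phi.shape[1], phi.shape[2]
    mu = np.empty((4, ny, nx))
    n_floor = 0
    n_floor0 = 0
    inv_dx2 = 1.0 / (dx * dx)
    for iy in range(ny):
        for ix in range(nx):
            p0 = 1.0 - (
                phi[0, iy, ix] + phi[1, iy, ix] + phi[2, iy, ix] + phi[3, iy, ix]
            )
            if p0 < phi0_floor:
                p0 = phi0_floor
                n_floor0 += 1
            common = -d0 * (1.0 + np.log(p0))
            ym = iy - 1 if iy > 0 else 0
            yp = iy + 1 if iy < ny - 1 else ny - 1
            xm = ix - 1 if ix > 0 else 0
            xp = ix + 1 if ix < nx - 1 else nx - 1
            for i in range(4):
                pi = phi[i, iy, ix]
                if pi < phi_floor:
                    pi = phi_floor
                    n_floor += 1
                lap = (
                    phi[i, ym, ix]
                    + phi[i, yp, ix]
                    + phi[i, iy, xm]
                    + phi[i, iy, xp]
                    - 4.0 * phi[i, iy, ix]
                ) * inv_dx2
                mu[i, iy, ix] = d[i] * (1.0 + np.log(pi)) + common - kappa * lap
            c = phi[0, iy, ix]
            t = phi[1, iy, ix]
            na = phi[2, iy, ix]
            a = phi[3, iy, ix]
            mu[0, iy, ix] -= 2.0 * lcc * c + lct * t + lcf * (na + a)
            mu[1, iy, ix] -= lct * c
            mu[2, iy, ix] -= lcf * c
            mu[3, iy, ix] -= lcf * c
    return mu, n_floor, n_floor0


@njit(cache=True)
def _velocity_kernel(
    phi, mu, dx, xi0, xi1, phi0_floor, reg_eps, phi_weight
):  # pragma: no cover
    """Assemble the friction matrix and solve the velocity system cell-wise.

    The right-hand side is ``-grad(mu_i)`` or, with ``phi_weight`` set,
    the force density ``-phi_i grad(mu_i)`` (degenerate mobility: empty
    cells have zero velocity).  Gradients are central differences,
    one-sided at boundaries.  Returns (v, n_reg, vmax) with v of shape
    (4, 2, ny, nx); near-singular pivots get a Tikhonov diagonal shift
    ``reg_eps`` (counted).
    """
    ny, nx = phi.shape[1], phi.shape[2]
    v = np.empty((4, 2, ny, nx))
    n_reg = 0
    vmax = 0.0
    a = np.empty((4, 4))
    b = np.empty((4, 2))
    phit = np.empty(4)
    xi_i0 = np.empty(4)
    inv_2dx = 0.5 / dx
    inv_dx = 1.0 / dx
    for iy in range(ny):
        for ix in range(nx):
            p0 = 1.0 - (
                phi[0, iy, ix] + phi[1, iy, ix] + phi[2, iy, ix] + phi[3, iy, ix]
            )
            if p0 < phi0_floor:
                p0 = phi0_floor
            for i in range(4):
                phit[i] = phi[i, iy, ix] / p0
            xi_a = xi0 + xi1 * phi[3, iy, ix]
            xi_i0[0] = xi0
            xi_i0[1] = xi0
            xi_i0[2] = xi0
            xi_i0[3] = xi_a
            cross = 0.0
            for k in range(4):
                cross += xi_i0[k] * phit[k]
            for i in range(4):
                diag = xi_i0[i] * (1.0 + phit[i]) * (1.0 + phit[i])
                for j in range(4):
                    if j == i:
                        continue
                    xi_ij = xi_a if (i == 3 or j == 3) else xi0
                    diag += (xi_ij + xi_i0[j] * phit[i]) * phi[j, iy, ix]
                    a[i, j] = phi[j, iy, ix] * (
                        -xi_ij + xi_i0[i] + xi_i0[j] + cross
                    )
                a[i, i] = diag
                # -grad(mu_i): central, one-sided at the boundary
                if 0 < ix < nx - 1:
                    b[i, 0] = -(mu[i, iy, ix + 1] - mu[i, iy, ix - 1]) * inv_2dx
                elif ix == 0:
                    b[i, 0] = -(mu[i, iy, 1] - mu[i, iy, 0]) * inv_dx
                else:
                    b[i, 0] = -(mu[i, iy, nx - 1] - mu[i, iy, nx - 2]) * inv_dx
                if 0 < iy < ny - 1:
                    b[i, 1] = -(mu[i, iy + 1, ix] - mu[i, iy - 1, ix]) * inv_2dx
                elif iy == 0:
                    b[i, 1] = -(mu[i, 1, ix] - mu[i, 0, ix]) * inv_dx
                else:
                    b[i, 1] = -(mu[i, ny - 1, ix] - mu[i, ny - 2, ix]) * inv_dx
                if phi_weight[i]:
                    b[i, 0] *= phi[i, iy, ix]
                    b[i, 1] *= phi[i, iy, ix]
            # Gaussian elimination with partial pivoting, 2 right-hand sides
            for k in range(3):
                piv = abs(a[k, k])
                pr = k
                for r in range(k + 1, 4):
                    if abs(a[r, k]) > piv:
                        piv = abs(a[r, k])
                        pr = r
                if piv < reg_eps:
                    for dd in range(4):
                        a[dd, dd] += reg_eps
                    n_reg += 1
                if pr != k:
                    for cc in range(4):
                        tmp = a[k, cc]
                        a[k, cc] = a[pr, cc]
                        a[pr, cc] = tmp
                    for cc in range(2):
                        tmp = b[k, cc]
                        b[k, cc] = b[pr, cc]
                        b[pr, cc] = tmp
                for r in range(k + 1, 4):
                    f = a[r, k] / a[k, k]
                    for cc in range(k + 1, 4):
                        a[r, cc] -= f * a[k, cc]
                    b[r, 0] -= f * b[k, 0]
                    b[r, 1] -= f * b[k, 1]
            for i in range(3, -1, -1):
                x0 = b[i, 0]
                x1 = b[i, 1]
                for j in range(i + 1, 4):
                    x0 -= a[i, j] * v[j, 0, iy, ix]
                    x1 -= a[i, j] * v[j, 1, iy, ix]
                x0 /= a[i, i]
                x1 /= a[i, i]
                v[i, 0, iy, ix] = x0
                v[i, 1, iy, ix] = x1
                if abs(x0) > vmax:
                    vmax = abs(x0)
                if abs(x1) > vmax:
                    vmax = abs(x1)
    return v, n_reg, vmax


@njit(cache=True)
def _upwind_div_kernel(phi, v, dx):  # pragma: no cover
    """div(phi v) for all four species, conservative upwinded flux form.

    Face velocities are averages of adjacent centers; boundary faces
    carry zero flux.
    """
    ny, nx = phi.shape[1], phi.shape[2]
    div = np.zeros((4, ny, nx))
    inv_dx = 1.0 / dx
    for i in range(4):
        for iy in range(ny):
            for ix in range(nx - 1):
                vf = 0.5 * (v[i, 0, iy, ix] + v[i, 0, iy, ix + 1])
                up = phi[i, iy, ix] if vf > 0 else phi[i, iy, ix + 1]
                flux = up * vf * inv_dx
                div[i, iy, ix] += flux
                div[i, iy, ix + 1] -= flux
        for iy in range(ny - 1):
            for ix in range(nx):
                vf = 0.5 * (v[i, 1, iy, ix] + v[i, 1, iy + 1, ix])
                up = phi[i, iy, ix] if vf > 0 else phi[i, iy + 1, ix]
                flux = up * vf * inv_dx
                div[i, iy, ix] += flux
                div[i, iy + 1, ix] -= flux
    return div


def transport_rate(
    phi: np.ndarray,
    dx: float,
    d: np.ndarray,
    d0: float,
    lcc: float,
    lct: float,
    lcf: float,
    kappa: float,
    xi0: float,
    xi1: float,
    phi_floor: float,
    phi0_floor: float,
    reg_eps: float,
    phi_weight: np.ndarray | None = None,
) -> tuple[np.ndarray, float, dict]:
    """Fused transport term -div(phi_i v_i); returns (rate, vmax, counters).

    ``phi_weight`` is a per-species boolean array: species with True use
    the degenerate force-density right-hand side -phi_i grad(mu_i),
    species with False the bare -grad(mu_i).
    """
    if phi_weight is None:
        phi_weight = np.ones(4, dtype=np.bool_)
    phi = np.ascontiguousarray(phi)
    mu, n_floor, n_floor0 = _mu_kernel(
        phi, np.ascontiguousarray(d), d0, lcc, lct, lcf, kappa, dx,
        phi_floor, phi0_floor,
    )
    v, n_reg, vmax = _velocity_kernel(
        phi, mu, dx, xi0, xi1, phi0_floor, reg_eps,
        np.ascontiguousarray(phi_weight, dtype=np.bool_),
    )
    div = _upwind_div_kernel(phi, v, dx)
    counters = {"phi": n_floor, "phi0": n_floor0, "reg": n_reg}
    return -div, float(vmax), counters
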