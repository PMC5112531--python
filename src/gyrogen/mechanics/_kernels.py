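"""Numba inner loops for the explicit quasi-static relaxation solver.

The 2D plane-strain kernel is hand-unrolled (2x2 tensor algebra as scalar
arithmetic) because batch experiments integrate tens of thousands of
central-difference steps per run.  The 3D kernel is written generically;
it is intended for small demonstration meshes.

Element technology: selective reduced integration.  The isochoric
neo-Hookean term is integrated at the full Gauss set (4 points for quads,
8 for hexes), the volumetric penalty at the element center only, which
avoids volumetric locking at high bulk penalty while the full-order
deviatoric quadrature suppresses hourglass modes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the kernels
OK = -1  # completed all requested steps


@njit(cache=True, fastmath=True)
def relax2d(x, v, conn, gradN0, wdet, gmul, mu0, smul, bulk, mass,
            damping, dt, t0, n_steps, ramp_time, stiff_ramp_time, g_max,
            free_x, free_y):
    """Advance the damped central-difference dynamics ``n_steps`` steps.

    Growth ramps linearly in time to ``g_max`` over ``ramp_time``; element
    growth is ``1 + gmul[e] * (g_base - 1)`` and the element shear modulus
    ``mu0[e] * (1 + (smul[e] - 1) * ramp_fraction)``.  Returns the step
    index at which an element inverted, or -1 on success.  ``x`` and ``v``
    are updated in place.
    """
    nE = conn.shape[0]
    nN = x.shape[0]
    f = np.zeros((nN, 2))
    c1 = 1.0 - 0.5 * damping * dt
    c2 = 1.0 / (1.0 + 0.5 * damping * dt)
    for step in range(n_steps):
        t = t0 + (step + 1) * dt
        frac = t / ramp_time
        if frac > 1.0:
            frac = 1.0
        sfrac = t / stiff_ramp_time
        if sfrac > 1.0:
            sfrac = 1.0
        gb = 1.0 + (g_max - 1.0) * frac
        for n in range(nN):
            f[n, 0] = 0.0
            f[n, 1] = 0.0
        for e in range(nE):
            ge = 1.0 + gmul[e] * (gb - 1.0)
            mu_e = mu0[e] * (1.0 + (smul[e] - 1.0) * sfrac)
            n0 = conn[e, 0]
            n1 = conn[e, 1]
            n2 = conn[e, 2]
            n3 = conn[e, 3]
            x0 = x[n0, 0]
            y0 = x[n0, 1]
            x1 = x[n1, 0]
            y1 = x[n1, 1]
            x2 = x[n2, 0]
            y2 = x[n2, 1]
            x3 = x[n3, 0]
            y3 = x[n3, 1]
            for q in range(5):
                g0x = gradN0[e, q, 0, 0]
                g0y = gradN0[e, q, 0, 1]
                g1x = gradN0[e, q, 1, 0]
                g1y = gradN0[e, q, 1, 1]
                g2x = gradN0[e, q, 2, 0]
                g2y = gradN0[e, q, 2, 1]
                g3x = gradN0[e, q, 3, 0]
                g3y = gradN0[e, q, 3, 1]
                F11 = x0 * g0x + x1 * g1x + x2 * g2x + x3 * g3x
                F12 = x0 * g0y + x1 * g1y + x2 * g2y + x3 * g3y
                F21 = y0 * g0x + y1 * g1x + y2 * g2x + y3 * g3x
                F22 = y0 * g0y + y1 * g1y + y2 * g2y + y3 * g3y
                A11 = F11 / ge
                A12 = F12 / ge
                A21 = F21 / ge
                A22 = F22 / ge
                J = A11 * A22 - A12 * A21
                if J <= 1e-12:
                    return step
                iJ = 1.0 / J
                if q < 4:
                    P11 = mu_e * (A11 - A22 * iJ)
                    P12 = mu_e * (A12 + A21 * iJ)
                    P21 = mu_e * (A21 + A12 * iJ)
                    P22 = mu_e * (A22 - A11 * iJ)
                else:
                    c0 = bulk * (J - 1.0)
                    P11 = c0 * A22
                    P12 = -c0 * A21
                    P21 = -c0 * A12
                    P22 = c0 * A11
                w = wdet[e, q] * ge  # ge^(d-1) with d = 2
                f[n0, 0] -= w * (P11 * g0x + P12 * g0y)
                f[n0, 1] -= w * (P21 * g0x + P22 * g0y)
                f[n1, 0] -= w * (P11 * g1x + P12 * g1y)
                f[n1, 1] -= w * (P21 * g1x + P22 * g1y)
                f[n2, 0] -= w * (P11 * g2x + P12 * g2y)
                f[n2, 1] -= w * (P21 * g2x + P22 * g2y)
                f[n3, 0] -= w * (P11 * g3x + P12 * g3y)
                f[n3, 1] -= w * (P21 * g3x + P22 * g3y)
        for n in range(nN):
            vx = (c1 * v[n, 0] + dt * f[n, 0] / mass[n]) * c2
            vy = (c1 * v[n, 1] + dt * f[n, 1] / mass[n]) * c2
            if not free_x[n]:
                vx = 0.0
            if not free_y[n]:
                vy = 0.0
            v[n, 0] = vx
            v[n, 1] = vy
            x[n, 0] += vx * dt
            x[n, 1] += vy * dt
    return OK


@njit(cache=True, fastmath=True)
def relax3d(x, v, conn, gradN0, wdet, gmul, mu0, smul, bulk, mass,
            damping, dt, t0, n_steps, ramp_time, stiff_ramp_time, g_max, free):
    """3D counterpart of :func:`relax2d` (trilinear hexes, 8+1 points)."""
    nE = conn.shape[0]
    nN = x.shape[0]
    nQ = gradN0.shape[1]
    f = np.zeros((nN, 3))
    F = np.empty((3, 3))
    A = np.empty((3, 3))
    P = np.empty((3, 3))
    c1 = 1.0 - 0.5 * damping * dt
    c2 = 1.0 / (1.0 + 0.5 * damping * dt)
    for step in range(n_steps):
        t = t0 + (step + 1) * dt
        frac = t / ramp_time
        if frac > 1.0:
            frac = 1.0
        sfrac = t / stiff_ramp_time
        if sfrac > 1.0:
            sfrac = 1.0
        gb = 1.0 + (g_max - 1.0) * frac
        for n in range(nN):
            for i in range(3):
                f[n, i] = 0.0
        for e in range(nE):
            ge = 1.0 + gmul[e] * (gb - 1.0)
            mu_e = mu0[e] * (1.0 + (smul[e] - 1.0) * sfrac)
            for q in range(nQ):
                for i in range(3):
                    for j in range(3):
                        s = 0.0
                        for a in range(8):
                            s += x[conn[e, a], i] * gradN0[e, q, a, j]
                        F[i, j] = s
                for i in range(3):
                    for j in range(3):
                        A[i, j] = F[i, j] / ge
                # cofactors / inverse-transpose of A
                C11 = A[1, 1] * A[2, 2] - A[1, 2] * A[2, 1]
                C12 = A[1, 2] * A[2, 0] - A[1, 0] * A[2, 2]
                C13 = A[1, 0] * A[2, 1] - A[1, 1] * A[2, 0]
                C21 = A[0, 2] * A[2, 1] - A[0, 1] * A[2, 2]
                C22 = A[0, 0] * A[2, 2] - A[0, 2] * A[2, 0]
                C23 = A[0, 1] * A[2, 0] - A[0, 0] * A[2, 1]
                C31 = A[0, 1] * A[1, 2] - A[0, 2] * A[1, 1]
                C32 = A[0, 2] * A[1, 0] - A[0, 0] * A[1, 2]
                C33 = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
                J = A[0, 0] * C11 + A[0, 1] * C12 + A[0, 2] * C13
                if J <= 1e-12:
                    return step
                iJ = 1.0 / J
                if q < nQ - 1:
                    P[0, 0] = mu_e * (A[0, 0] - C11 * iJ)
                    P[0, 1] = mu_e * (A[0, 1] - C12 * iJ)
                    P[0, 2] = mu_e * (A[0, 2] - C13 * iJ)
                    P[1, 0] = mu_e * (A[1, 0] - C21 * iJ)
                    P[1, 1] = mu_e * (A[1, 1] - C22 * iJ)
                    P[1, 2] = mu_e * (A[1, 2] - C23 * iJ)
                    P[2, 0] = mu_e * (A[2, 0] - C31 * iJ)
                    P[2, 1] = mu_e * (A[2, 1] - C32 * iJ)
                    P[2, 2] = mu_e * (A[2, 2] - C33 * iJ)
                else:
                    c0 = bulk * (J - 1.0)
                    P[0, 0] = c0 * C11
                    P[0, 1] = c0 * C12
                    P[0, 2] = c0 * C13
                    P[1, 0] = c0 * C21
                    P[1, 1] = c0 * C22
                    P[1, 2] = c0 * C23
                    P[2, 0] = c0 * C31
                    P[2, 1] = c0 * C32
                    P[2, 2] = c0 * C33
                w = wdet[e, q] * ge * ge  # ge^(d-1) with d = 3
                for a in range(8):
                    na = conn[e, a]
                    for i in range(3):
                        f[na, i] -= w * (P[i, 0] * gradN0[e, q, a, 0]
                                         + P[i, 1] * gradN0[e, q, a, 1]
                                         + P[i, 2] * gradN0[e, q, a, 2])
        for n in range(nN):
            for i in range(3):
                vi = (c1 * v[n, i] + dt * f[n, i] / mass[n]) * c2
                if not free[n, i]:
                    vi = 0.0
                v[n, i] = vi
                x[n, i] += vi * dt
    return OK
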