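"""Numba kernels for the hot Langevin/ABF inner loop (direct-CV tier).

These mirror the reference numpy implementations in :mod:`codonpmf.system`
(tested against them) and exist purely for speed: the desk-scale study runs
millions of sequential overdamped steps per trial.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def energy_cv(d, eps, a, d0, j12, j23, sigma, kappa, dw, wall_on):
    """U(d1,d2,d3), kJ/mol, boundary restraints excluded."""
    u = 0.0
    for i in range(3):
        e = np.exp(-a[i] * (d[i] - d0[i]))
        u += eps[i] * ((1.0 - e) * (1.0 - e) - 1.0)
    s2 = 2.0 * sigma * sigma
    x1 = d[0] - d0[0]
    x2 = d[1] - d0[1]
    x3 = d[2] - d0[2]
    u -= j12 * np.exp(-(x1 * x1 + x2 * x2) / s2)
    u -= j23 * np.exp(-(x2 * x2 + x3 * x3) / s2)
    for i in range(3):
        if wall_on[i] and d[i] < dw:
            u += kappa * (dw - d[i]) * (dw - d[i])
    return u


@njit(cache=True)
def gradient_cv(d, eps, a, d0, j12, j23, sigma, kappa, dw, wall_on, g):
    """Analytic gradient dU/dd_i into ``g`` (length-3 scratch array)."""
    sig2 = sigma * sigma
    for i in range(3):
        e = np.exp(-a[i] * (d[i] - d0[i]))
        g[i] = 2.0 * eps[i] * (1.0 - e) * a[i] * e
    x1 = d[0] - d0[0]
    x2 = d[1] - d0[1]
    x3 = d[2] - d0[2]
    e12 = np.exp(-(x1 * x1 + x2 * x2) / (2.0 * sig2))
    e23 = np.exp(-(x2 * x2 + x3 * x3) / (2.0 * sig2))
    g[0] += j12 * e12 * x1 / sig2
    g[1] += j12 * e12 * x2 / sig2 + j23 * e23 * x2 / sig2
    g[2] += j23 * e23 * x3 / sig2
    for i in range(3):
        if wall_on[i] and d[i] < dw:
            g[i] += -2.0 * kappa * (dw - d[i])


@njit(cache=True)
def abf_chunk(
    pos, noise,
    eps, a, d0, j12, j23, sigma, kappa, dw, wall_on,
    jac_on, kt, mob, noise_scale,
    blo, bhi, bk,
    glo, gw, nb,
    counts, force_sum,
    bias_on, acc_on,
    n_full, cv_out, stride, step0,
    discard, prev_noise,
):
    """Advance overdamped Langevin dynamics by ``noise.shape[0]`` steps.

    Uses the Leimkuhler-Matthews averaged-noise scheme
    ``x' = x + mob*F + noise_scale*(xi_n + xi_{n+1})/2`` whose stationary
    density error is O(dt^2) (plain Euler-Maruyama is O(dt)); ``prev_noise``
    carries xi_n across chunk boundaries and is updated in place.

    Updates ``pos`` (the CV triple), the ABF accumulators ``counts`` /
    ``force_sum`` and the discard counter in place; records CV frames into
    ``cv_out`` (columns step, d1, d2, d3, U) every ``stride`` steps.  Returns
    the global step index at which a coordinate went non-finite, or -1.
    """
    n = noise.shape[0]
    g = np.empty(3)
    f = np.empty(3)
    for t in range(n):
        step = step0 + t
        gradient_cv(pos, eps, a, d0, j12, j23, sigma, kappa, dw, wall_on, g)
        in_range = True
        i0 = 0
        i1 = 0
        i2 = 0
        for i in range(3):
            f[i] = -g[i]
            if jac_on:
                f[i] += 2.0 * kt / pos[i]
            x = pos[i]
            if x < glo or x > glo + gw * nb:
                in_range = False
        if in_range:
            i0 = min(int((pos[0] - glo) / gw), nb - 1)
            i1 = min(int((pos[1] - glo) / gw), nb - 1)
            i2 = min(int((pos[2] - glo) / gw), nb - 1)
        if step % stride == 0:
            k = step // stride
            cv_out[k, 0] = step
            cv_out[k, 1] = pos[0]
            cv_out[k, 2] = pos[1]
            cv_out[k, 3] = pos[2]
            cv_out[k, 4] = energy_cv(pos, eps, a, d0, j12, j23, sigma, kappa, dw, wall_on)
        if acc_on:
            if in_range:
                counts[i0, i1, i2] += 1
                for i in range(3):
                    force_sum[i0, i1, i2, i] += f[i]
            else:
                discard[0] += 1
        for i in range(3):
            tot = f[i]
            if pos[i] < blo:
                tot += 2.0 * bk * (blo - pos[i])
            elif pos[i] > bhi:
                tot -= 2.0 * bk * (pos[i] - bhi)
            if bias_on and in_range:
                nbv = counts[i0, i1, i2]
                if nbv > 0:
                    ramp = nbv / n_full
                    if ramp > 1.0:
                        ramp = 1.0
                    tot -= ramp * force_sum[i0, i1, i2, i] / nbv
            pos[i] = pos[i] + mob * tot + 0.5 * noise_scale * (prev_noise[i] + noise[t, i])
            prev_noise[i] = noise[t, i]
            if not np.isfinite(pos[i]):
                return step
    return -1
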