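"""Numba kernels for Brownian propagation and dipolar correlation sums.

All kernels are sequential (no threading) so results are bit-reproducible
for a fixed random stream. Lengths in nm, times in ps.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def propagate_free(u, steps, b, box, r_edges, d_scales):
    """Advance unwrapped positions ``u`` (n_mol, 3) through Gaussian substeps.

    ``steps``: (n_sub, n_mol, 3) pre-drawn displacements for unit D-scale.
    Reflection off the solute sphere of radius ``b`` (centred on the nearest
    periodic image of the box centre, here the origin of the relative frame)
    is radial: r -> 2b - r. ``r_edges``/``d_scales`` give an optional
    piecewise-constant diffusion scale by distance (empty arrays = scale 1).
    """
    n_sub, n_mol, _ = steps.shape
    n_seg = r_edges.shape[0]
    for s in range(n_sub):
        for m in range(n_mol):
            x = u[m, 0]
            y = u[m, 1]
            z = u[m, 2]
            scale = 1.0
            if n_seg > 0:
                wx = x - box * np.round(x / box)
                wy = y - box * np.round(y / box)
                wz = z - box * np.round(z / box)
                r = np.sqrt(wx * wx + wy * wy + wz * wz)
                for k in range(n_seg):
                    if r < r_edges[k]:
                        scale = d_scales[k]
                        break
            rt = np.sqrt(scale)
            x += steps[s, m, 0] * rt
            y += steps[s, m, 1] * rt
            z += steps[s, m, 2] * rt
            wx = x - box * np.round(x / box)
            wy = y - box * np.round(y / box)
            wz = z - box * np.round(z / box)
            r = np.sqrt(wx * wx + wy * wy + wz * wz)
            if r < b:
                if r < 1e-12:
                    r = 1e-12
                    wx = r
                    wy = 0.0
                    wz = 0.0
                fac = (2.0 * b - r) / r - 1.0
                x += wx * fac
                y += wy * fac
                z += wz * fac
            u[m, 0] = x
            u[m, 1] = y
            u[m, 2] = z


# sticky-mode particle states
STATE_FREE = 0
STATE_BOUND = 1
STATE_REFRACTORY = 2  # unbound but must leave the capture shell to rebind


@njit(cache=True)
def propagate_sticky(
    u,
    steps,
    unif,
    state,
    bind_start,
    b,
    box,
    capture,
    d_scale_bound,
    p_off,
    t0_sub,
    dt_sub,
    ev_mol,
    ev_start,
    ev_end,
    ev_count,
):
    """Sticky-surface propagation with a Poisson unbinding clock.

    A free molecule whose centre enters the capture shell (r <= capture)
    binds: its diffusion is scaled by ``d_scale_bound`` and it is confined
    between the solute sphere and the capture shell (reflecting at both)
    until a per-substep Bernoulli trial with probability ``p_off`` releases
    it. Released molecules are refractory until they leave the shell.
    Completed bound intervals are appended to the event buffers (times in
    ps from trajectory start). Returns the updated event count.
    """
    n_sub, n_mol, _ = steps.shape
    rt_b = np.sqrt(d_scale_bound)
    n_ev = ev_count
    for s in range(n_sub):
        for m in range(n_mol):
            bound = state[m] == STATE_BOUND
            rt = rt_b if bound else 1.0
            x = u[m, 0] + steps[s, m, 0] * rt
            y = u[m, 1] + steps[s, m, 1] * rt
            z = u[m, 2] + steps[s, m, 2] * rt
            wx = x - box * np.round(x / box)
            wy = y - box * np.round(y / box)
            wz = z - box * np.round(z / box)
            r = np.sqrt(wx * wx + wy * wy + wz * wz)
            if r < b:
                if r < 1e-12:
                    r = 1e-12
                    wx = r
                    wy = 0.0
                    wz = 0.0
                fac = (2.0 * b - r) / r
                x += wx * (fac - 1.0)
                y += wy * (fac - 1.0)
                z += wz * (fac - 1.0)
                wx *= fac
                wy *= fac
                wz *= fac
                r = 2.0 * b - r
            if bound and r > capture:
                # confinement at the outer capture boundary while bound
                fac = (2.0 * capture - r) / r - 1.0
                x += wx * fac
                y += wy * fac
                z += wz * fac
                r = 2.0 * capture - r
            u[m, 0] = x
            u[m, 1] = y
            u[m, 2] = z
            t_now = t0_sub + (s + 1) * dt_sub
            if bound:
                if unif[s, m] < p_off:
                    state[m] = STATE_REFRACTORY
                    ev_mol[n_ev] = m
                    ev_start[n_ev] = bind_start[m]
                    ev_end[n_ev] = t_now
                    n_ev += 1
            elif state[m] == STATE_REFRACTORY:
                if r > capture:
                    state[m] = STATE_FREE
            else:
                if r <= capture:
                    # bind; the unbinding clock starts immediately, so an
                    # infinite k_off degenerates exactly to free dynamics
                    if unif[s, m] < p_off:
                        ev_mol[n_ev] = m
                        ev_start[n_ev] = t_now
                        ev_end[n_ev] = t_now
                        n_ev += 1
                        state[m] = STATE_REFRACTORY
                    else:
                        state[m] = STATE_BOUND
                        bind_start[m] = t_now
    return n_ev


@njit(cache=True)
def dipolar_correlation_sums(rel_uw, box, lags, stride, shell_edges):
    """Shell-routed dipolar correlation accumulation.

    Parameters
    ----------
    rel_uw:
        (n_frames, n_sel, 3) unwrapped solvent-spin positions relative to the
        reference hydrogen (float32). The origin-frame vector is taken as the
        minimum image; the lagged vector is origin + unwrapped displacement.
    lags:
        increasing int64 lag indices, lags[0] == 0.
    stride:
        origin spacing in frames.
    shell_edges:
        increasing radial bin edges starting at 0; the last edge is the
        origin-inclusion cutoff. Contributions are routed by origin shell.

    Returns
    -------
    g_sum: (n_shell, n_lag) accumulated P2(cos theta)/(r0^3 r1^3), nm^-6
    pair_count: (n_shell, n_lag) number of (origin, spin) pairs
    n_origins: (n_lag,) origins evaluated per lag
    tot_sum, tot_sq: (n_lag,) per-origin totals (all shells) and their
        squares, for standard errors over origins.
    """
    n_frames, n_sel, _ = rel_uw.shape
    n_lag = lags.shape[0]
    n_shell = shell_edges.shape[0] - 1
    cutoff2 = shell_edges[n_shell] * shell_edges[n_shell]
    g_sum = np.zeros((n_shell, n_lag))
    pair_count = np.zeros((n_shell, n_lag), np.int64)
    n_origins = np.zeros(n_lag, np.int64)
    tot_sum = np.zeros(n_lag)
    tot_sq = np.zeros(n_lag)
    max_lag = lags[n_lag - 1]
    origin_tot = np.zeros(n_lag)
    for t0 in range(0, n_frames - max_lag, stride):
        for il in range(n_lag):
            origin_tot[il] = 0.0
        for k in range(n_sel):
            ux = rel_uw[t0, k, 0]
            uy = rel_uw[t0, k, 1]
            uz = rel_uw[t0, k, 2]
            x0 = ux - box * np.round(ux / box)
            y0 = uy - box * np.round(uy / box)
            z0 = uz - box * np.round(uz / box)
            r02 = x0 * x0 + y0 * y0 + z0 * z0
            if r02 > cutoff2 or r02 < 1e-24:
                continue
            r0 = np.sqrt(r02)
            ishell = 0
            while shell_edges[ishell + 1] < r0:
                ishell += 1
            r03 = r02 * r0
            for il in range(n_lag):
                lag = lags[il]
                x1 = x0 + (rel_uw[t0 + lag, k, 0] - ux)
                y1 = y0 + (rel_uw[t0 + lag, k, 1] - uy)
                z1 = z0 + (rel_uw[t0 + lag, k, 2] - uz)
                r12 = x1 * x1 + y1 * y1 + z1 * z1
                r1 = np.sqrt(r12)
                c = (x0 * x1 + y0 * y1 + z0 * z1) / (r0 * r1)
                p2 = 1.5 * c * c - 0.5
                val = p2 / (r03 * r12 * r1)
                g_sum[ishell, il] += val
                pair_count[ishell, il] += 1
                origin_tot[il] += val
        for il in range(n_lag):
            n_origins[il] += 1
            tot_sum[il] += origin_tot[il]
            tot_sq[il] += origin_tot[il] * origin_tot[il]
    return g_sum, pair_count, n_origins, tot_sum, tot_sq
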