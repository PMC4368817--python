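"""Brute-force reference solver for validating the ADI transport scheme.

A deliberately simple, self-contained explicit (forward-Euler, FTCS)
finite-volume solver on its own rasterization of the same physical
problem: capillary disks in a box, Dirichlet lumen, wall ring with a
time-dependent coefficient, zero-flux outer boundaries. Face
diffusivities are harmonic path averages obtained by dense numeric
sampling of 1/D along each centre-to-centre segment — independent of the
analytic circle-clipping used by the production grid builder. Run at a
few-fold finer resolution and a stability-limited time step, it serves as
the independent oracle for the implicit production scheme.
"""

from __future__ import annotations

import numpy as np

__all__ = ["explicit_reference_mev"]

_N_SAMPLES = 96  # 1/D path-sampling density per face segment


def _path_fractions(p1, p2, centers, r, w):
    """Fraction of each segment lying in the wall annulus and in tissue."""
    frac = (np.arange(_N_SAMPLES) + 0.5) / _N_SAMPLES
    pts = p1[..., None, :] + frac[None, :, None] * (p2 - p1)[..., None, :]
    d = np.full(pts.shape[:-1], np.inf)
    for cx, cz in centers:
        d = np.minimum(d, np.hypot(pts[..., 0] - cx, pts[..., 1] - cz))
    wall_frac = ((d > r) & (d <= r + w)).mean(axis=-1)
    tiss_frac = (d > r + w).mean(axis=-1)
    return wall_frac, tiss_frac


def _face_diffusivity(wall_frac, tiss_frac, d_wall, d_tiss):
    """Harmonic path average; lumen portions contribute no resistance."""
    with np.errstate(divide="ignore"):
        inv = np.where(
            (wall_frac > 0) & (d_wall <= 0), np.inf, wall_frac / max(d_wall, 1e-300)
        ) + tiss_frac / d_tiss
        out = 1.0 / inv
    out[~np.isfinite(out)] = 0.0
    return out


def explicit_reference_mev(
    width: float,
    height: float,
    centers,
    r: float,
    w: float,
    d_wall_of_t,
    d_tiss: float,
    c_iv_of_t,
    t_end: float,
    resolution: float,
    *,
    safety: float = 0.4,
    record_times=None,
):
    """Integrate the diffusion problem with explicit FTCS; return m_ev.

    Returns ``(times, m_ev)`` where m_ev is the area integral of
    concentration over tissue cells at ``record_times`` (default: only
    ``t_end``). The time step is ``safety * dx^2 / (4 * D_max)``.
    """
    dx = float(resolution)
    nx = max(1, round(width / dx))
    nz = max(1, round(height / dx))
    x = (np.arange(nx) + 0.5) * dx
    z = (np.arange(nz) + 0.5) * dx
    X, Z = np.meshgrid(x, z)

    dist = np.full((nz, nx), np.inf)
    for cx, cz in centers:
        dist = np.minimum(dist, np.hypot(X - cx, Z - cz))
    lumen = dist <= r
    tissue = dist > r + w

    P = np.stack([X, Z], axis=-1)
    wf_h, tf_h = _path_fractions(P[:, :-1], P[:, 1:], centers, r, w)  # (nz, nx-1)
    wf_v, tf_v = _path_fractions(P[:-1, :], P[1:, :], centers, r, w)  # (nz-1, nx)

    d_max = max(d_tiss, float(np.max(d_wall_of_t(np.linspace(0.0, t_end, 64)))), 1e-12)
    dt = safety * dx * dx / (4.0 * d_max)
    nsteps = int(np.ceil(t_end / dt))
    dt = t_end / nsteps

    record_times = np.atleast_1d(np.asarray(record_times if record_times is not None else [t_end], float))
    rec_steps = np.clip(np.round(record_times / dt).astype(int), 1, nsteps)

    c = np.zeros((nz, nx))
    out = np.empty(record_times.size)
    r_coef = dt / (dx * dx)

    rec_i = 0
    last_dw = None
    Dh = Dv = None
    for step in range(1, nsteps + 1):
        t_prev = (step - 1) * dt
        dw = float(np.asarray(d_wall_of_t(np.array([t_prev + 0.5 * dt])))[0])
        if dw != last_dw:
            Dh = _face_diffusivity(wf_h, tf_h, dw, d_tiss)
            Dv = _face_diffusivity(wf_v, tf_v, dw, d_tiss)
            last_dw = dw
        c[lumen] = float(np.asarray(c_iv_of_t(np.array([t_prev])))[0])
        fh = Dh * (c[:, 1:] - c[:, :-1])
        fv = Dv * (c[1:, :] - c[:-1, :])
        lap = np.zeros_like(c)
        lap[:, :-1] += fh
        lap[:, 1:] -= fh
        lap[:-1, :] += fv
        lap[1:, :] -= fv
        c = c + r_coef * lap
        c[lumen] = float(np.asarray(c_iv_of_t(np.array([step * dt])))[0])
        while rec_i < rec_steps.size and step == rec_steps[rec_i]:
            out[rec_i] = c[tissue].sum() * dx * dx
            rec_i += 1
    while rec_i < record_times.size:
        out[rec_i] = c[tissue].sum() * dx * dx
        rec_i += 1
    return record_times, out
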