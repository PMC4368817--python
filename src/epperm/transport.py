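"""Forward model: 2-D Fickian transport on a capillary unit cell.

The skin layer under the window chamber is idealized as an infinite array
of parallel capillaries (radius ``r``, wall thickness ``w``) arranged on an
equilateral-triangle lattice in four horizontal layers centred in a slab of
thickness ``H``. Because capillaries are long and parallel, transport is
solved on a 2-D cross-section; by periodicity it suffices to solve on a
half-spacing-wide unit cell with symmetry (zero-flux) side walls. Lattice
points fall on those side walls, so capillaries appear as half cross
sections.

Fick's second law with a space- and time-dependent coefficient,

    dc/dt = div( D(x, t) grad c ),

is discretized by a conservative finite-volume scheme on a regular grid and
advanced with Peaceman-Rachford ADI (implicit alternating directions,
unconditionally stable, second order in time). Face transmissibilities are
exact line integrals of 1/D along the segment joining the two cell centres,
using the analytic circle geometry, so the wall's diffusive resistance
(thickness w at coefficient D_wall) is honoured independently of how the
thin wall ring happens to rasterize. The lumen is a Dirichlet region held
at the well-mixed plasma concentration c_iv(t); the wall carries the time
ramp D_wall(t): zero before a delay ``t_del``, linear up to ``t_sat``,
constant ``d_sat`` after. Extravascular tissue has constant ``d_tiss``. The
wall coefficient is "apparent": convective leakage is lumped into it.

Units: lengths in micrometres, times in seconds, diffusivities in um^2/s.
Amounts are per unit capillary length (area integrals of concentration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "UnitCellGeometry",
    "WallPermeabilityFunction",
    "TransportParams",
    "Grid",
    "ForwardSolution",
    "dwall_at",
    "build_grid",
    "build_box_grid",
    "solve_forward",
    "signal_model",
    "evolve",
    "TransportError",
]

# cell tags
TISSUE, WALL, LUMEN = 0, 1, 2


class TransportError(RuntimeError):
    """Forward-solver failure; carries a diagnostic field snapshot."""

    def __init__(self, message: str, field_snapshot: "np.ndarray | None" = None):
        super().__init__(message)
        self.field_snapshot = field_snapshot


@dataclass(frozen=True)
class UnitCellGeometry:
    """Dimensions of the capillary lattice unit cell (micrometres).

    Defaults are the histology-derived values: slab thickness ``H`` = 300,
    capillary radius ``r`` = 3.5, first/last layer depth ``h`` = 72 from
    either surface, centre-to-centre spacing ``a`` = 60, wall thickness
    ``w`` = 1, four layers. ``d_electrodes`` (mm) is carried as metadata
    for config validation only.
    """

    H: float = 300.0
    r: float = 3.5
    h: float = 72.0
    a: float = 60.0
    w: float = 1.0
    n_layers: int = 4
    d_electrodes: float = 6.0

    def __post_init__(self) -> None:
        for name in ("H", "r", "h", "a", "w"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not self.H > 2 * self.h:
            raise ValueError(f"slab too thin: H={self.H} must exceed 2h={2 * self.h}")
        if not self.r + self.w < self.a / 2:
            raise ValueError(f"capillaries overlap: r+w={self.r + self.w} must be < a/2={self.a / 2}")
        # equilateral-triangle packing consistency: last layer sits at depth H-h
        span = self.h + (self.n_layers - 1) * self.layer_spacing
        if abs(span - (self.H - self.h)) > 0.05 * self.H:
            raise ValueError(
                f"layer packing inconsistent with slab: last layer at {span:.1f} um, expected {self.H - self.h:.1f} um"
            )

    @property
    def layer_spacing(self) -> float:
        """Vertical distance between capillary layers, a*sqrt(3)/2."""
        return self.a * math.sqrt(3.0) / 2.0

    @property
    def layer_depths(self) -> np.ndarray:
        return self.h + self.layer_spacing * np.arange(self.n_layers)

    def capillary_centers(self) -> list[tuple[float, float]]:
        """(x, z) centres within the half-spacing unit cell [0, a/2] x [0, H].

        Layers alternate between the left (x = 0) and right (x = a/2)
        symmetry walls, so each appears as a half cross-section.
        """
        centers = []
        for k, z in enumerate(self.layer_depths):
            x = 0.0 if k % 2 == 0 else self.a / 2.0
            centers.append((x, float(z)))
        return centers


@dataclass(frozen=True)
class WallPermeabilityFunction:
    """Time ramp of the apparent wall diffusion coefficient D_wall(t).

    Zero until ``t_del`` (>= the pulse time ``t_ep``), then linear up to
    the saturated value ``d_sat`` (um^2/s) reached at ``t_sat``, constant
    afterwards. A control experiment is ``d_sat = 0``.
    """

    t_ep: float
    t_del: float
    t_sat: float
    d_sat: float

    def __post_init__(self) -> None:
        if not 0 <= self.t_ep <= self.t_del:
            raise ValueError(f"need 0 <= t_ep <= t_del, got t_ep={self.t_ep}, t_del={self.t_del}")
        if not self.t_del < self.t_sat:
            raise ValueError(f"need t_del < t_sat, got {self.t_del} >= {self.t_sat}")
        if self.d_sat < 0:
            raise ValueError(f"d_sat must be non-negative, got {self.d_sat}")

    def __call__(self, t):
        return dwall_at(t, self)


def dwall_at(t, wall: WallPermeabilityFunction):
    """Evaluate the wall-coefficient ramp at time(s) ``t`` (um^2/s)."""
    t = np.asarray(t, dtype=float)
    frac = np.clip((t - wall.t_del) / (wall.t_sat - wall.t_del), 0.0, 1.0)
    out = wall.d_sat * frac
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TransportParams:
    """Extravascular diffusivity plus the wall ramp.

    ``d_tiss`` is 30 um^2/s for 70 kDa dextran (literature value for
    tissue), 5 um^2/s for 2000 kDa.
    """

    d_tiss: float
    wall: WallPermeabilityFunction

    def __post_init__(self) -> None:
        if not self.d_tiss > 0:
            raise ValueError(f"d_tiss must be positive, got {self.d_tiss}")


@dataclass(frozen=True)
class Grid:
    """Tagged finite-volume discretization of a rectangular domain.

    ``len_wall_*`` / ``len_tiss_*`` hold, per interior face, the length of
    the centre-to-centre segment lying in wall and in tissue material
    (analytic circle geometry); the lumen portion has no resistance.
    Boundary and deactivated faces carry zero flux.
    """

    cell_type: np.ndarray  # (nz, nx) int8, TISSUE/WALL/LUMEN
    resolution: float  # um per cell (square cells)
    len_wall_x: np.ndarray  # (nz, nx+1)
    len_tiss_x: np.ndarray
    len_wall_z: np.ndarray  # (nz+1, nx)
    len_tiss_z: np.ndarray
    active_x: np.ndarray  # (nz, nx+1) bool
    active_z: np.ndarray  # (nz+1, nx) bool
    width: float
    height: float
    n_capillary_sections: int  # count of (half) cross-sections placed

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_type.shape

    @property
    def cell_area(self) -> float:
        return self.resolution ** 2

    @property
    def lumen_area(self) -> float:
        return float(np.count_nonzero(self.cell_type == LUMEN)) * self.cell_area

    @property
    def wall_area(self) -> float:
        return float(np.count_nonzero(self.cell_type == WALL)) * self.cell_area

    @property
    def tissue_area(self) -> float:
        return float(np.count_nonzero(self.cell_type == TISSUE)) * self.cell_area

    @property
    def lumen_area_per_capillary(self) -> float:
        """Rasterized lumen area of one full capillary cross-section."""
        if self.n_capillary_sections == 0:
            return 0.0
        return self.lumen_area / (self.n_capillary_sections / 2.0)

    def sealed(self) -> "Grid":
        """Copy with all lumen-adjacent faces closed (zero flux).

        Used for discrete mass-conservation checks: with the lumen sealed
        the wall+tissue amount must be exactly conserved by the scheme.
        """
        lum = self.cell_type == LUMEN
        ax = self.active_x.copy()
        az = self.active_z.copy()
        ax[:, 1:-1] &= ~(lum[:, :-1] | lum[:, 1:])
        az[1:-1, :] &= ~(lum[:-1, :] | lum[1:, :])
        return replace(self, active_x=ax, active_z=az)


def _segment_disk_lengths(p1x, p1z, p2x, p2z, cx, cz, radius):
    """Length of each segment (p1->p2) lying inside the disk (cx, cz, radius).

    All segment arrays share a shape; the segments have equal length.
    """
    ux, uz = p2x - p1x, p2z - p1z
    L = np.hypot(ux, uz)
    ux, uz = ux / L, uz / L
    tc = (cx - p1x) * ux + (cz - p1z) * uz
    d2 = (cx - p1x) ** 2 + (cz - p1z) ** 2 - tc ** 2
    half2 = radius ** 2 - d2
    half = np.sqrt(np.clip(half2, 0.0, None))
    enter = np.clip(tc - half, 0.0, L)
    exit_ = np.clip(tc + half, 0.0, L)
    return np.where(half2 > 0.0, exit_ - enter, 0.0)


def build_box_grid(
    width: float,
    height: float,
    centers: "list[tuple[float, float]]",
    r: float,
    w: float,
    resolution: float,
) -> Grid:
    """Tag a ``width x height`` box containing circular capillaries.

    Cells are tagged lumen (centre within ``r`` of a capillary centre),
    wall (within ``r + w``) or tissue; per-face wall/tissue path lengths
    are computed from the analytic circles.
    """
    if not resolution > 0:
        raise ValueError("resolution must be positive")
    if resolution > w + 1e-12:
        raise ValueError(
            f"resolution {resolution} um does not resolve the {w} um wall; use resolution <= w"
        )
    nx = max(1, round(width / resolution))
    nz = max(1, round(height / resolution))
    dx = float(resolution)
    x = (np.arange(nx) + 0.5) * dx
    z = (np.arange(nz) + 0.5) * dx
    X, Z = np.meshgrid(x, z)

    ctype = np.full((nz, nx), TISSUE, dtype=np.int8)
    for cx, cz in centers:
        d = np.hypot(X - cx, Z - cz)
        ctype[(d <= r + w) & (ctype == TISSUE)] = WALL
        ctype[d <= r] = LUMEN

    def face_lengths(p1x, p1z, p2x, p2z):
        lum = np.zeros(p1x.shape)
        ann = np.zeros(p1x.shape)
        for cx, cz in centers:
            lum += _segment_disk_lengths(p1x, p1z, p2x, p2z, cx, cz, r)
            ann += _segment_disk_lengths(p1x, p1z, p2x, p2z, cx, cz, r + w)
        lw = ann - lum
        lt = dx - ann
        return np.clip(lw, 0.0, dx), np.clip(lt, 0.0, dx)

    # x faces: between (iz, ix-1) and (iz, ix); interior faces ix = 1..nx-1
    lw_x = np.zeros((nz, nx + 1))
    lt_x = np.zeros((nz, nx + 1))
    act_x = np.zeros((nz, nx + 1), dtype=bool)
    if nx > 1:
        p1x, p2x = X[:, :-1], X[:, 1:]
        p1z = p2z = Z[:, :-1]
        lw, lt = face_lengths(p1x, p1z, p2x, p2z)
        lw_x[:, 1:-1], lt_x[:, 1:-1] = lw, lt
        act_x[:, 1:-1] = True

    # z faces: between (iz-1, ix) and (iz, ix); interior faces iz = 1..nz-1
    lw_z = np.zeros((nz + 1, nx))
    lt_z = np.zeros((nz + 1, nx))
    act_z = np.zeros((nz + 1, nx), dtype=bool)
    if nz > 1:
        p1z, p2z = Z[:-1, :], Z[1:, :]
        p1x = p2x = X[:-1, :]
        lw, lt = face_lengths(p1x, p1z, p2x, p2z)
        lw_z[1:-1, :], lt_z[1:-1, :] = lw, lt
        act_z[1:-1, :] = True

    return Grid(
        cell_type=ctype,
        resolution=dx,
        len_wall_x=lw_x,
        len_tiss_x=lt_x,
        len_wall_z=lw_z,
        len_tiss_z=lt_z,
        active_x=act_x,
        active_z=act_z,
        width=nx * dx,
        height=nz * dx,
        n_capillary_sections=len(centers),
    )


def build_grid(geometry: UnitCellGeometry, resolution: float = 1.0) -> Grid:
    """Discretize the half-spacing unit cell of ``geometry``."""
    return build_box_grid(
        geometry.a / 2.0,
        geometry.H,
        geometry.capillary_centers(),
        geometry.r,
        geometry.w,
        resolution,
    )


@njit(cache=True)
def _face_diff(lw, lt, active, dw, dtiss, dx, out):  # pragma: no cover
    n0, n1 = lw.shape
    for i in range(n0):
        for j in range(n1):
            if not active[i, j]:
                out[i, j] = 0.0
                continue
            w_ = lw[i, j]
            t_ = lt[i, j]
            if w_ > 0.0 and dw <= 0.0:
                out[i, j] = 0.0
                continue
            denom = 0.0
            if w_ > 0.0:
                denom += w_ / dw
            if t_ > 0.0:
                denom += t_ / dtiss
            out[i, j] = dx / denom if denom > 0.0 else 0.0


@njit(cache=True)
def _adi_run(  # pragma: no cover
    c,
    dirichlet,
    mass_mask,
    lw_x,
    lt_x,
    act_x,
    lw_z,
    lt_z,
    act_z,
    dtiss,
    dwall_half,
    civ_half,
    civ_new,
    dt,
    dx,
):
    nz, nx = c.shape
    nsteps = dwall_half.size
    rr = dt / (2.0 * dx * dx)
    mev = np.empty(nsteps)

    Dx = np.empty((nz, nx + 1))
    Dz = np.empty((nz + 1, nx))
    rhs = np.empty((nz, nx))
    cstar = np.empty((nz, nx))

    n_buf = max(nx, nz)
    cp = np.empty(n_buf)
    dp = np.empty(n_buf)

    for n in range(nsteps):
        dw = dwall_half[n]
        _face_diff(lw_x, lt_x, act_x, dw, dtiss, dx, Dx)
        _face_diff(lw_z, lt_z, act_z, dw, dtiss, dx, Dz)

        cmid = civ_half[n]
        cnew = civ_new[n]

        # rhs = c + (dt/2) Lz c ; Dirichlet cells pinned at c_iv(t + dt/2)
        for iz in range(nz):
            for ix in range(nx):
                if dirichlet[iz, ix]:
                    rhs[iz, ix] = cmid
                else:
                    acc = 0.0
                    if iz > 0:
                        acc += Dz[iz, ix] * (c[iz - 1, ix] - c[iz, ix])
                    if iz < nz - 1:
                        acc += Dz[iz + 1, ix] * (c[iz + 1, ix] - c[iz, ix])
                    rhs[iz, ix] = c[iz, ix] + rr * acc

        # implicit x sweep: (I - dt/2 Lx) c* = rhs, row by row (Thomas)
        for iz in range(nz):
            if dirichlet[iz, 0]:
                b0, c0, d0 = 1.0, 0.0, cmid
            else:
                b0 = 1.0 + rr * (Dx[iz, 0] + Dx[iz, 1])
                c0 = -rr * Dx[iz, 1]
                d0 = rhs[iz, 0]
            cp[0] = c0 / b0
            dp[0] = d0 / b0
            for ix in range(1, nx):
                if dirichlet[iz, ix]:
                    ai, bi, ci, di = 0.0, 1.0, 0.0, cmid
                else:
                    ai = -rr * Dx[iz, ix]
                    ci = -rr * Dx[iz, ix + 1]
                    bi = 1.0 + rr * (Dx[iz, ix] + Dx[iz, ix + 1])
                    di = rhs[iz, ix]
                m = bi - ai * cp[ix - 1]
                cp[ix] = ci / m
                dp[ix] = (di - ai * dp[ix - 1]) / m
            cstar[iz, nx - 1] = dp[nx - 1]
            for ix in range(nx - 2, -1, -1):
                cstar[iz, ix] = dp[ix] - cp[ix] * cstar[iz, ix + 1]

        # rhs = c* + (dt/2) Lx c* ; Dirichlet cells pinned at c_iv(t + dt)
        for iz in range(nz):
            for ix in range(nx):
                if dirichlet[iz, ix]:
                    rhs[iz, ix] = cnew
                else:
                    acc = 0.0
                    if ix > 0:
                        acc += Dx[iz, ix] * (cstar[iz, ix - 1] - cstar[iz, ix])
                    if ix < nx - 1:
                        acc += Dx[iz, ix + 1] * (cstar[iz, ix + 1] - cstar[iz, ix])
                    rhs[iz, ix] = cstar[iz, ix] + rr * acc

        # implicit z sweep: (I - dt/2 Lz) c = rhs, column by column
        for ix in range(nx):
            if dirichlet[0, ix]:
                b0, c0, d0 = 1.0, 0.0, cnew
            else:
                b0 = 1.0 + rr * (Dz[0, ix] + Dz[1, ix])
                c0 = -rr * Dz[1, ix]
                d0 = rhs[0, ix]
            cp[0] = c0 / b0
            dp[0] = d0 / b0
            for iz in range(1, nz):
                if dirichlet[iz, ix]:
                    ai, bi, ci, di = 0.0, 1.0, 0.0, cnew
                else:
                    ai = -rr * Dz[iz, ix]
                    ci = -rr * Dz[iz + 1, ix]
                    bi = 1.0 + rr * (Dz[iz, ix] + Dz[iz + 1, ix])
                    di = rhs[iz, ix]
                m = bi - ai * cp[iz - 1]
                cp[iz] = ci / m
                dp[iz] = (di - ai * dp[iz - 1]) / m
            c[nz - 1, ix] = dp[nz - 1]
            for iz in range(nz - 2, -1, -1):
                c[iz, ix] = dp[iz] - cp[iz] * c[iz + 1, ix]

        s = 0.0
        for iz in range(nz):
            for ix in range(nx):
                if mass_mask[iz, ix]:
                    s += c[iz, ix]
        mev[n] = s * dx * dx

    return mev


def evolve(
    grid: Grid,
    d_tiss: float,
    dwall_of_t,
    c_iv,
    t0: float,
    t_end: float,
    dt: float,
    *,
    c0: "np.ndarray | None" = None,
    dirichlet_lumen: bool = True,
    mass_over: str = "tissue",
):
    """Low-level time integration from ``t0`` to ``t_end``.

    Returns ``(step_times, mass_series, final_field)`` where ``mass_series``
    is the area integral of concentration over ``mass_over`` cells
    ("tissue" or "wall+tissue") after each step. ``dwall_of_t`` and
    ``c_iv`` are callables of time. With ``dirichlet_lumen=False`` lumen
    cells are left free (used together with :meth:`Grid.sealed` for
    conservation checks).
    """
    if t_end <= t0:
        return np.array([t0]), np.zeros(1), np.zeros(grid.shape)
    nsteps = max(1, int(math.ceil((t_end - t0) / dt - 1e-9)))
    dt_eff = (t_end - t0) / nsteps
    t_half = t0 + (np.arange(nsteps) + 0.5) * dt_eff
    t_new = t0 + (np.arange(nsteps) + 1.0) * dt_eff

    dwall_half = np.asarray(dwall_of_t(t_half), dtype=float)
    civ_half = np.asarray(c_iv(t_half), dtype=float)
    civ_new = np.asarray(c_iv(t_new), dtype=float)

    c = np.zeros(grid.shape) if c0 is None else np.array(c0, dtype=float)
    dirichlet = (grid.cell_type == LUMEN) if dirichlet_lumen else np.zeros(grid.shape, dtype=bool)
    if dirichlet_lumen:
        c[dirichlet] = float(np.asarray(c_iv(t0), dtype=float))
    if mass_over == "tissue":
        mass_mask = grid.cell_type == TISSUE
    elif mass_over == "wall+tissue":
        mass_mask = grid.cell_type != LUMEN
    else:
        raise ValueError(f"unknown mass_over {mass_over!r}")

    mass = _adi_run(
        c,
        dirichlet,
        mass_mask,
        grid.len_wall_x,
        grid.len_tiss_x,
        grid.active_x,
        grid.len_wall_z,
        grid.len_tiss_z,
        grid.active_z,
        float(d_tiss),
        dwall_half,
        civ_half,
        civ_new,
        float(dt_eff),
        grid.resolution,
    )
    if not np.all(np.isfinite(mass)) or not np.all(np.isfinite(c)):
        raise TransportError(
            f"forward solve diverged (non-finite field) between t={t0} and t={t_end}", field_snapshot=c
        )
    return t_new, mass, c


@dataclass(frozen=True)
class ForwardSolution:
    """Modeled amounts in the unit cell, per unit capillary length.

    ``m_iv`` is the intravascular amount (c_iv times rasterized lumen
    area), ``m_ev`` the area integral of tissue concentration, ``m_total``
    their sum — the model counterpart of the measured trace: intravascular
    only before the pulses, intra- plus extravascular after.
    """

    times: np.ndarray
    m_iv: np.ndarray
    m_ev: np.ndarray
    m_total: np.ndarray
    final_field: "np.ndarray | None" = None
    meta: dict = field(default_factory=dict)


def solve_forward(
    grid: Grid,
    params: TransportParams,
    c_iv,
    t_eval,
    *,
    dt: float = 10.0,
    keep_field: bool = False,
) -> ForwardSolution:
    """Run the forward model and report amounts at ``t_eval`` (seconds).

    Before ``t_del`` the wall coefficient is zero and the tissue starts
    empty, so the extravascular field is identically zero there; time
    stepping begins at ``t_del``. ``m_ev`` is linearly interpolated from
    the step grid onto ``t_eval``.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    wall = params.wall
    t_end = float(t_eval.max())

    m_iv = np.asarray(c_iv(t_eval), dtype=float) * grid.lumen_area
    if wall.d_sat == 0.0 or wall.t_del >= t_end:
        m_ev = np.zeros_like(t_eval)
        final = np.zeros(grid.shape) if keep_field else None
    else:
        step_t, step_mev, c = evolve(
            grid, params.d_tiss, lambda t: dwall_at(t, wall), c_iv, wall.t_del, t_end, dt
        )
        knots_t = np.concatenate([[wall.t_del], step_t])
        knots_m = np.concatenate([[0.0], step_mev])
        m_ev = np.interp(t_eval, knots_t, knots_m, left=0.0)
        final = c if keep_field else None

    return ForwardSolution(
        times=t_eval,
        m_iv=m_iv,
        m_ev=m_ev,
        m_total=m_iv + m_ev,
        final_field=final,
        meta={"scheme": "finite-volume Peaceman-Rachford ADI", "dt": dt, "resolution": grid.resolution},
    )


def signal_model(solution: ForwardSolution, t_ep: float) -> np.ndarray:
    """Normalized model trace, comparable to a normalized measured trace.

    Divides ``m_total`` by its maximum over the pre-pulse samples
    (t < ``t_ep``), mirroring the normalization applied to measured
    fluorescence.
    """
    pre = solution.times < t_ep
    if not np.any(pre):
        raise ValueError("solution does not span the pre-pulse normalization window")
    peak = float(solution.m_total[pre].max())
    if peak <= 0:
        raise ValueError(f"non-positive pre-pulse maximum ({peak}); cannot normalize")
    return solution.m_total / peak
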