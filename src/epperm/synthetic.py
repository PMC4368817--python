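"""Synthetic data with known ground truth.

Generates fluorescence traces (and optional image stacks) with the
statistical and kinetic structure the analysis assumes: Bateman
intravascular kinetics after the bolus, delayed post-pulse extravascular
accumulation from the forward transport model, a constant background, and
multiplicative Gaussian measurement noise. Every random draw comes from a
single seeded generator, so identical (schedule, truth, seed) inputs give
bitwise-identical outputs.

The measured signal model is

    F(t) = background + gain * m(t),      noisy F = F * (1 + cv * eps),

with m(t) the unit-cell amount from the forward model (m_iv before the
pulses, m_iv + m_ev after) and eps ~ N(0, 1). The gain is arbitrary — the
pipeline normalizes it away — and is recorded in the truth for oracle
tests only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pk import PKParams, civ_profile
from .schedule import AcquisitionSchedule, make_schedule
from .trace import FluorescenceTrace
from .transport import (
    Grid,
    TransportParams,
    UnitCellGeometry,
    WallPermeabilityFunction,
    build_grid,
    solve_forward,
)

__all__ = ["GroundTruth", "SyntheticDataset", "VesselLayout", "default_truth", "simulate_trace", "render_image_stack"]


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    pk: PKParams
    wall: WallPermeabilityFunction
    d_tiss: float = 30.0
    background: float = 100.0
    noise_cv: float = 0.03
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be non-negative, got {self.noise_cv}")
        if self.background < 0:
            raise ValueError(f"background must be non-negative, got {self.background}")
        if not self.gain > 0:
            raise ValueError(f"gain must be positive, got {self.gain}")


def default_truth(
    schedule: "AcquisitionSchedule | None" = None,
    *,
    d_sat: float = 0.008,
    delay: float = 60.0,
    ramp: float = 300.0,
    d_tiss: float = 30.0,
    noise_cv: float = 0.03,
    background: float = 100.0,
    seed: int = 0,
) -> GroundTruth:
    """Study-condition ground truth tied to a schedule's landmarks.

    Defaults: saturated wall coefficient 0.008 um^2/s reached 60 s + 300 s
    after the pulses (a Table-1-scale permeabilization), tissue coefficient
    30 um^2/s (70 kDa), 3% multiplicative noise.
    """
    schedule = schedule or make_schedule()
    t_ep = schedule.t_ep if schedule.t_ep is not None else schedule.total_span
    wall = WallPermeabilityFunction(t_ep=t_ep, t_del=t_ep + delay, t_sat=t_ep + delay + ramp, d_sat=d_sat)
    return GroundTruth(
        pk=PKParams(), wall=wall, d_tiss=d_tiss, background=background, noise_cv=noise_cv, seed=seed
    )


@dataclass(frozen=True)
class SyntheticDataset:
    trace: FluorescenceTrace
    truth: GroundTruth
    schedule: AcquisitionSchedule
    clean_values: np.ndarray  # noise-free F(t), for oracle tests
    m_total: np.ndarray  # unit-cell amount m(t) at the frame times
    images: "np.ndarray | None" = None  # optional (n_frames, h, w) stack
    true_mask: "np.ndarray | None" = None
    meta: dict = field(default_factory=dict)


def _model_amounts(schedule, truth, geometry, grid, resolution, dt):
    times = schedule.frame_times()
    if grid is None:
        grid = build_grid(geometry or UnitCellGeometry(), resolution)
    c_iv = civ_profile(truth.pk, schedule.t_fd)
    sol = solve_forward(grid, TransportParams(truth.d_tiss, truth.wall), c_iv, times, dt=dt)
    return times, sol, grid, c_iv


def simulate_trace(
    schedule: "AcquisitionSchedule | None" = None,
    truth: "GroundTruth | None" = None,
    geometry: "UnitCellGeometry | None" = None,
    *,
    grid: "Grid | None" = None,
    resolution: float = 1.0,
    dt: float = 10.0,
) -> SyntheticDataset:
    """Simulate a trace sampled at the schedule's frame times.

    Phase I frames carry background plus noise only; later frames add
    ``gain * m(t)`` with m(t) from the forward transport model (a control
    trace is simply ``truth.wall.d_sat = 0``, for which m = m_iv).
    """
    schedule = schedule or make_schedule()
    truth = truth or default_truth(schedule)
    times, sol, grid, _ = _model_amounts(schedule, truth, geometry, grid, resolution, dt)

    clean = truth.background + truth.gain * sol.m_total
    rng = np.random.default_rng(truth.seed)
    noisy = clean * (1.0 + truth.noise_cv * rng.standard_normal(times.size))
    trace = FluorescenceTrace(
        times=times,
        values=noisy,
        t_fd=schedule.t_fd,
        t_ep=schedule.t_ep,
        dextran_kda=70.0 if truth.d_tiss >= 15 else 2000.0,
        meta={"synthetic": True, "seed": truth.seed},
    )
    return SyntheticDataset(
        trace=trace,
        truth=truth,
        schedule=schedule,
        clean_values=clean,
        m_total=sol.m_total.copy(),
        meta={"gain": truth.gain, "resolution": grid.resolution, "dt": dt},
    )


@dataclass(frozen=True)
class VesselLayout:
    """Raster layout for synthetic image stacks.

    Vertical large-vessel stripes (x offset, width in pixels) on a diffuse
    microvascular background field. Stripe widths are far above the ~1 px
    capillary scale, mimicking the large vessels that must be masked out.
    """

    shape: tuple[int, int] = (96, 128)  # (height, width)
    stripes: tuple[tuple[int, int], ...] = ((30, 12), (80, 12))
    vessel_gain: float = 4.0  # fluorescence gain of large-vessel pixels over c_iv

    def __post_init__(self) -> None:
        h, w = self.shape
        for x0, width in self.stripes:
            if width <= 0:
                raise ValueError(f"stripe width must be positive, got {width}")
            if x0 < 0 or x0 + width > w:
                raise ValueError(f"stripe [{x0}, {x0 + width}) exceeds frame width {w}")

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for x0, width in self.stripes:
            m[:, x0 : x0 + width] = True
        return m


def render_image_stack(
    schedule: "AcquisitionSchedule | None" = None,
    truth: "GroundTruth | None" = None,
    layout: "VesselLayout | None" = None,
    *,
    geometry: "UnitCellGeometry | None" = None,
    resolution: float = 1.0,
    dt: float = 10.0,
    noise: str = "gaussian",
) -> SyntheticDataset:
    """Render a per-frame image stack plus its ground-truth vessel mask.

    Large-vessel pixels track the plasma concentration c_iv(t) (times
    ``layout.vessel_gain``); all other pixels track the region-of-interest
    mean ``background + gain * m(t)``. Pixel noise is multiplicative
    Gaussian (sigma = noise_cv * signal) or Poisson.
    """
    schedule = schedule or make_schedule()
    truth = truth or default_truth(schedule)
    layout = layout or VesselLayout()
    times, sol, grid, c_iv = _model_amounts(schedule, truth, geometry, None, resolution, dt)

    mask = layout.mask()
    roi_mean = truth.background + truth.gain * sol.m_total
    vessel_mean = truth.background + layout.vessel_gain * truth.gain * np.asarray(c_iv(times)) * grid.lumen_area

    rng = np.random.default_rng(truth.seed)
    frames = np.empty((times.size,) + layout.shape)
    for k in range(times.size):
        frame = np.where(mask, vessel_mean[k], roi_mean[k]).astype(float)
        if truth.noise_cv > 0:
            if noise == "gaussian":
                frame = frame * (1.0 + truth.noise_cv * rng.standard_normal(layout.shape))
            elif noise == "poisson":
                # Poisson with mean chosen so the CV at the background level is noise_cv
                scale = 1.0 / (truth.noise_cv ** 2 * max(truth.background, 1e-12))
                frame = rng.poisson(np.clip(frame, 0, None) * scale) / scale
            else:
                raise ValueError(f"unknown noise model {noise!r}")
        frames[k] = frame

    trace = FluorescenceTrace(
        times=times,
        values=roi_mean,  # noise-free ROI mean: generator ground truth for extraction
        t_fd=schedule.t_fd,
        t_ep=schedule.t_ep,
        meta={"synthetic": True, "seed": truth.seed},
    )
    return SyntheticDataset(
        trace=trace,
        truth=truth,
        schedule=schedule,
        clean_values=roi_mean,
        m_total=sol.m_total.copy(),
        images=frames,
        true_mask=mask,
        meta={"gain": truth.gain, "vessel_gain": layout.vessel_gain, "noise": noise},
    )


def write_image_stack(dataset: SyntheticDataset, path, *, mask_path=None) -> None:
    """Write the rendered stack as a multi-page 16-bit TIFF (mask as single page)."""
    import tifffile

    if dataset.images is None:
        raise ValueError("dataset has no rendered images")
    lo, hi = float(dataset.images.min()), float(dataset.images.max())
    span = hi - lo if hi > lo else 1.0
    u16 = np.clip((dataset.images - lo) / span * 65535.0, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, u16)
    if mask_path is not None and dataset.true_mask is not None:
        tifffile.imwrite(mask_path, dataset.true_mask.astype(np.uint8) * 255)
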