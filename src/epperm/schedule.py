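"""Image-acquisition schedule for dorsal-window-chamber experiments.

The experiment is sampled in five consecutive intervals (A-E) with
interval-specific frame rates. The tracer bolus is injected at the end of
interval A (``t_fd``) and the electroporation pulses, when present, are
delivered at the end of interval C (``t_ep``). Interval B starts a short
acquisition gap after the injection (the stage is restarted once the bolus
has been delivered), so intervals carry explicit start times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Interval", "AcquisitionSchedule", "make_schedule", "DEFAULT_INTERVALS"]


@dataclass(frozen=True)
class Interval:
    """One constant-rate acquisition block.

    Frames are acquired at ``start + k * period`` for ``k = 0, 1, ...``
    while strictly inside ``[start, start + duration)``.
    """

    label: str
    start: float
    duration: float
    period: float

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"interval {self.label!r}: duration must be positive, got {self.duration}")
        if not self.period > 0:
            raise ValueError(f"interval {self.label!r}: frame period must be positive, got {self.period}")
        if self.start < 0:
            raise ValueError(f"interval {self.label!r}: negative start time {self.start}")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def n_frames(self) -> int:
        return int(np.ceil(self.duration / self.period - 1e-12))

    def frame_times(self) -> np.ndarray:
        return self.start + self.period * np.arange(self.n_frames)


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Ordered acquisition intervals plus the injection/pulse landmarks.

    ``t_fd`` is the tracer-injection time (end of interval A) and ``t_ep``
    the pulse-delivery time (end of interval C); ``t_ep`` is ``None`` for
    control experiments.
    """

    intervals: tuple[Interval, ...]
    t_fd: float
    t_ep: float | None = None

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("schedule needs at least one interval")
        for prev, nxt in zip(self.intervals, self.intervals[1:]):
            if nxt.start < prev.end - 1e-9:
                raise ValueError(f"intervals {prev.label!r} and {nxt.label!r} overlap")
        if self.t_ep is not None and not self.t_fd < self.t_ep:
            raise ValueError(f"t_fd ({self.t_fd}) must precede t_ep ({self.t_ep})")

    @property
    def total_span(self) -> float:
        """End of the last interval, in seconds from the start of interval A."""
        return float(self.intervals[-1].end)

    def interval(self, label: str) -> Interval:
        for iv in self.intervals:
            if iv.label == label:
                return iv
        raise KeyError(f"no interval labelled {label!r}")

    def frame_times(self) -> np.ndarray:
        """All frame timestamps in seconds, strictly increasing."""
        t = np.concatenate([iv.frame_times() for iv in self.intervals])
        if np.any(np.diff(t) <= 0):
            raise ValueError("overlapping intervals: frame times are not strictly increasing")
        return t

    def phase_of(self, times: np.ndarray) -> np.ndarray:
        """Phase label per sample: I before injection, II before the pulses, III after.

        Half-open convention: a sample at exactly ``t_fd`` is Phase II, one
        at exactly ``t_ep`` is Phase III. Control schedules have no Phase III.
        """
        times = np.asarray(times, dtype=float)
        phases = np.full(times.shape, "I", dtype="<U3")
        phases[times >= self.t_fd] = "II"
        if self.t_ep is not None:
            phases[times >= self.t_ep] = "III"
        return phases


#: Protocol-default blocks: (label, duration s, frame period s).
DEFAULT_INTERVALS = (
    ("A", 300.0, 20.0),
    ("B", 120.0, 5.0),
    ("C", 600.0, 20.0),
    ("D", 600.0, 20.0),
    ("E", 1800.0, 120.0),
)

#: Acquisition restart gap between the injection and the first interval-B frame.
DEFAULT_B_GAP = 10.0


def make_schedule(
    intervals: "list[tuple[str, float, float]] | None" = None,
    *,
    b_gap: float = DEFAULT_B_GAP,
    control: bool = False,
) -> AcquisitionSchedule:
    """Build an :class:`AcquisitionSchedule`.

    With no arguments this reproduces the experimental protocol: A at one
    frame per 20 s for 5 min (injection at its end), B at one frame per 5 s
    for 2 min starting ``b_gap`` = 10 s after the injection, C at one frame
    per 20 s for 10 min (pulses at its end), D likewise for 10 min, and E at
    one frame per 2 min for 30 min. Custom interval lists use the same
    (label, duration, period) convention; the injection lands at the end of
    interval A and the pulses at the end of interval C when those labels are
    present.

    Parameters
    ----------
    intervals : list of (label, duration_s, period_s), optional
    b_gap : float
        Dead time in seconds between the injection and the start of
        interval B (0 disables it).
    control : bool
        If True the schedule carries no pulse time (``t_ep`` is None).
    """
    blocks = list(intervals) if intervals is not None else [tuple(x) for x in DEFAULT_INTERVALS]
    if b_gap < 0:
        raise ValueError("b_gap must be non-negative")

    built: list[Interval] = []
    t = 0.0
    for label, duration, period in blocks:
        if str(label) == "B":
            t += b_gap
        iv = Interval(str(label), t, float(duration), float(period))
        built.append(iv)
        t = iv.end

    labels = [iv.label for iv in built]
    t_fd = built[labels.index("A")].end if "A" in labels else 0.0
    t_ep = None
    if not control and "C" in labels:
        t_ep = built[labels.index("C")].end
    return AcquisitionSchedule(tuple(built), t_fd=t_fd, t_ep=t_ep)
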