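"""Fluorescence time courses and their preprocessing.

A trace is the mean fluorescence F(t) of the microcirculatory region of
interest, labelled by experimental phase: Phase I before tracer injection
(background only), Phase II between injection and pulse delivery
(intravascular signal only — dextrans of 70 kDa and larger do not
extravasate in homeostatic skin), Phase III after the pulses (intra- plus
extravascular). Preprocessing subtracts the mean Phase I background and
normalizes by the pre-pulse Phase II maximum; everything downstream works
on normalized traces, which makes the pipeline invariant to the arbitrary
fluorescence gain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["FluorescenceTrace", "subtract_background", "normalize_trace", "read_trace", "write_trace"]


@dataclass(frozen=True)
class FluorescenceTrace:
    """Time-stamped mean fluorescence with phase labels.

    ``t_ep`` is ``None`` for control experiments (no Phase III). The
    dextran size (kDa) rides along as metadata.
    """

    times: np.ndarray
    values: np.ndarray
    t_fd: float
    t_ep: float | None = None
    dextran_kda: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def phases(self) -> np.ndarray:
        """Per-sample phase labels, half-open convention [start, end)."""
        ph = np.full(self.times.shape, "I", dtype="<U3")
        ph[self.times >= self.t_fd] = "II"
        if self.t_ep is not None:
            ph[self.times >= self.t_ep] = "III"
        return ph

    def phase(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.phases == label
        return self.times[m], self.values[m]

    def __len__(self) -> int:
        return self.times.size


def subtract_background(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Subtract the mean Phase I fluorescence from every sample."""
    _, bg = trace.phase("I")
    if bg.size == 0:
        raise ValueError("cannot subtract background: trace has no Phase I samples")
    b = float(bg.mean())
    return replace(trace, values=trace.values - b, meta={**trace.meta, "background_subtracted": b})


def normalize_trace(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Divide by the maximum over pre-pulse Phase II samples.

    The reference is the maximum reached before pulse delivery (all of
    Phase II for control traces); that maximum maps to 1. The trace should
    be background-subtracted first.
    """
    _, ph2 = trace.phase("II")
    if ph2.size == 0:
        raise ValueError("cannot normalize: trace has no Phase II samples")
    peak = float(ph2.max())
    if peak <= 0:
        raise ValueError(f"cannot normalize: non-positive pre-pulse maximum ({peak})")
    return replace(trace, values=trace.values / peak, meta={**trace.meta, "normalization_peak": peak})


def write_trace(trace: FluorescenceTrace, path: "str | Path", sidecar: bool = True) -> Path:
    """Write a two-column (time_s, intensity_au) text file plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, np.column_stack([trace.times, trace.values]), fmt="%.10g", header="time_s intensity_au")
    if sidecar:
        meta = {
            "t_fd": trace.t_fd,
            "t_ep": trace.t_ep,
            "dextran_kda": trace.dextran_kda,
            **{k: v for k, v in trace.meta.items() if _json_safe(v)},
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
    return path


def read_trace(path: "str | Path", t_fd: "float | None" = None, t_ep: "float | None" = None) -> FluorescenceTrace:
    """Read a two-column text trace; landmarks come from the JSON sidecar unless given."""
    path = Path(path)
    data = np.loadtxt(path)
    meta: dict = {}
    side = Path(str(path) + ".json")
    if side.exists():
        meta = json.loads(side.read_text())
    if t_fd is None:
        t_fd = meta.get("t_fd")
    if t_ep is None:
        t_ep = meta.get("t_ep")
    if t_fd is None:
        raise ValueError(f"no injection time for {path}: pass t_fd or provide a sidecar")
    return FluorescenceTrace(
        times=data[:, 0],
        values=data[:, 1],
        t_fd=float(t_fd),
        t_ep=None if t_ep is None else float(t_ep),
        dextran_kda=meta.get("dextran_kda"),
        meta={k: v for k, v in meta.items() if k not in ("t_fd", "t_ep", "dextran_kda")},
    )


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
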