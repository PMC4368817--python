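"""Sensitivity of the fitted wall coefficient to the tissue coefficient.

The extravascular diffusivity ``d_tiss`` is a literature value, not a
measurement, so the whole inverse problem is repeated over a grid of
``d_tiss`` values (default 2-70 um^2/s, the span of published estimates)
to check how much the fitted ``d_sat`` moves. In the wall-limited regime
(``d_sat`` three orders of magnitude below ``d_tiss``) the wall is the
rate-limiting resistance and the fitted ``d_sat`` should move far less
than the grid itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fitting import FitContext, GAConfig, ga_optimize
from .trace import FluorescenceTrace

__all__ = ["SensitivityCurve", "dtiss_sweep", "DEFAULT_DTISS_GRID"]

#: Default sweep grid in um^2/s: covers the published 2-70 range at desk scale.
DEFAULT_DTISS_GRID = (2.0, 5.0, 10.0, 30.0, 50.0, 70.0)


@dataclass(frozen=True)
class SensitivityCurve:
    """Fitted d_sat (and objective) per tissue-coefficient grid point.

    Failed grid points carry NaN and are listed in ``failed``.
    """

    d_tiss_grid: np.ndarray
    d_sat: np.ndarray
    objective: np.ndarray
    failed: list = field(default_factory=list)

    def __post_init__(self) -> None:
        g = np.asarray(self.d_tiss_grid, dtype=float)
        if g.size == 0:
            raise ValueError("sensitivity grid is empty")
        if np.any(np.diff(g) <= 0):
            raise ValueError("sensitivity grid must be strictly increasing")
        object.__setattr__(self, "d_tiss_grid", g)
        object.__setattr__(self, "d_sat", np.asarray(self.d_sat, dtype=float))
        object.__setattr__(self, "objective", np.asarray(self.objective, dtype=float))

    @property
    def spread_ratio(self) -> float:
        """max/min of the fitted d_sat over the successful grid points."""
        ok = self.d_sat[np.isfinite(self.d_sat)]
        if ok.size == 0 or ok.min() <= 0:
            return np.inf
        return float(ok.max() / ok.min())


def dtiss_sweep(
    trace: FluorescenceTrace,
    context: FitContext,
    grid=DEFAULT_DTISS_GRID,
    config: "GAConfig | None" = None,
) -> SensitivityCurve:
    """Refit the wall ramp at each tissue coefficient on ``grid``.

    Each grid point runs a full genetic-algorithm fit with the same seed
    policy (identical ``config``); per-point failures are recorded and the
    curve is returned with NaN gaps rather than aborting the sweep.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("sensitivity grid is empty")
    d_sat = np.full(grid.size, np.nan)
    obj = np.full(grid.size, np.nan)
    failed: list = []
    for i, dt in enumerate(grid):
        ctx = replace(context, d_tiss=float(dt), grid=context.grid, _cache={}, failures=[])
        try:
            res = ga_optimize(trace, ctx, config)
            d_sat[i] = res.d_sat
            obj[i] = res.objective
        except Exception as err:  # noqa: BLE001 - gaps are flagged, sweep continues
            failed.append({"d_tiss": float(dt), "error": str(err)})
    return SensitivityCurve(d_tiss_grid=grid, d_sat=d_sat, objective=obj, failed=failed)
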