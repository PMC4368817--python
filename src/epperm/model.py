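"""Model/Results interface to the full permeability analysis.

:class:`MicrovascularPermeabilityModel` bundles a fluorescence trace with
the unit-cell geometry and tissue diffusivity; :meth:`fit` runs the
two-stage estimation (pharmacokinetic rates on the pre-pulse window, then
the genetic-algorithm search for the wall ramp) and returns a
:class:`PermeabilityResults` carrying the estimates, fit diagnostics, a
``summary()`` table and prediction/plot helpers.

    >>> model = MicrovascularPermeabilityModel(trace, d_tiss=30.0)
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import FitContext, FitResult, GAConfig, ga_optimize
from .pk import PKParams, fit_pk
from .report import PermeabilityReport, postep_linearity, pwall_from_dwall
from .sensitivity import DEFAULT_DTISS_GRID, SensitivityCurve, dtiss_sweep
from .trace import FluorescenceTrace, normalize_trace, subtract_background
from .transport import TransportParams, UnitCellGeometry, signal_model, solve_forward

__all__ = ["MicrovascularPermeabilityModel", "PermeabilityResults"]


class MicrovascularPermeabilityModel:
    """Estimate the apparent wall diffusion coefficient from one trace.

    Parameters
    ----------
    trace : FluorescenceTrace
        Raw or preprocessed trace with injection/pulse landmarks. With
        ``preprocess=True`` (default) the Phase I mean background is
        subtracted and the trace is normalized by its pre-pulse maximum;
        pass ``preprocess=False`` for a trace that is already normalized.
    d_tiss : float
        Extravascular diffusion coefficient in um^2/s (30 for 70 kDa
        dextran, 5 for 2000 kDa).
    geometry : UnitCellGeometry, optional
        Capillary lattice dimensions; defaults to the histology values.
    resolution, dt : float
        Forward-solver grid spacing (um) and time step (s).
    """

    def __init__(
        self,
        trace: FluorescenceTrace,
        *,
        d_tiss: float = 30.0,
        geometry: "UnitCellGeometry | None" = None,
        resolution: float = 1.0,
        dt: float = 10.0,
        preprocess: bool = True,
    ) -> None:
        if trace.t_ep is None:
            raise ValueError("trace has no pulse time; permeability estimation needs an EP trace")
        self.raw_trace = trace
        self.endog = normalize_trace(subtract_background(trace)) if preprocess else trace
        self.d_tiss = float(d_tiss)
        self.geometry = geometry or UnitCellGeometry()
        self.resolution = float(resolution)
        self.dt = float(dt)

    @classmethod
    def from_dataframe(cls, df, *, t_fd: float, t_ep: float, time_col: str = "time_s",
                       value_col: str = "intensity_au", **kwargs) -> "MicrovascularPermeabilityModel":
        """Build from a DataFrame with time and intensity columns."""
        trace = FluorescenceTrace(
            times=np.asarray(df[time_col], dtype=float),
            values=np.asarray(df[value_col], dtype=float),
            t_fd=t_fd,
            t_ep=t_ep,
        )
        return cls(trace, **kwargs)

    def _pk(self, init: "PKParams | None" = None) -> tuple[PKParams, float]:
        t2, y2 = self.endog.phase("II")
        return fit_pk(t2, y2, self.endog.t_fd, init=init)

    def make_context(self, pk: PKParams) -> FitContext:
        return FitContext(
            pk=pk,
            t_fd=self.endog.t_fd,
            t_ep=float(self.endog.t_ep),
            d_tiss=self.d_tiss,
            geometry=self.geometry,
            resolution=self.resolution,
            dt=self.dt,
        )

    def fit(self, ga_config: "GAConfig | None" = None, *, seed: "int | None" = None,
            pk_init: "PKParams | None" = None) -> "PermeabilityResults":
        """Two-stage estimation; ``seed`` overrides the GA config seed."""
        pk, pk_resid = self._pk(init=pk_init)
        config = ga_config or GAConfig()
        if seed is not None:
            config = GAConfig(**{**config.__dict__, "seed": int(seed)})
        context = self.make_context(pk)
        fit = ga_optimize(self.endog, context, config)
        return PermeabilityResults(model=self, pk=pk, pk_residual=pk_resid, fit=fit, context=context)


@dataclass
class PermeabilityResults:
    """Estimates, diagnostics and derived quantities of one fitted trace."""

    model: MicrovascularPermeabilityModel
    pk: PKParams
    pk_residual: float
    fit: FitResult
    context: FitContext
    wall_thickness_um: float = field(init=False)

    def __post_init__(self) -> None:
        self.wall_thickness_um = self.model.geometry.w

    # -- primary estimates -------------------------------------------------
    @property
    def d_wall(self) -> float:
        """Saturated apparent wall diffusion coefficient, um^2/s."""
        return self.fit.d_sat

    @property
    def delay(self) -> float:
        """Onset delay t_del - t_ep, s."""
        return self.fit.delay

    @property
    def ramp(self) -> float:
        """Ramp duration t_sat - t_del, s."""
        return self.fit.ramp

    @property
    def p_wall(self) -> float:
        """Apparent permeability coefficient D_wall / wall thickness, cm/s."""
        return pwall_from_dwall(self.d_wall, self.wall_thickness_um)

    @property
    def params(self) -> dict:
        return {"d_wall": self.d_wall, "delay": self.delay, "ramp": self.ramp,
                "k_a": self.pk.k_a, "k_e": self.pk.k_e}

    # -- diagnostics -------------------------------------------------------
    @property
    def objective(self) -> float:
        return self.fit.objective

    def r2_phase3(self) -> float:
        """Linearity of the post-pulse accumulation (R^2 of an OLS line)."""
        return postep_linearity(self.model.endog)

    def predict(self, times=None) -> np.ndarray:
        """Normalized model trace at ``times`` (default: the data's times)."""
        trace = self.model.endog
        times = trace.times if times is None else np.asarray(times, dtype=float)
        sol = solve_forward(
            self.context.grid,
            TransportParams(self.context.d_tiss, self.fit.wall),
            self.context._c_iv,
            times,
            dt=self.context.dt,
        )
        return signal_model(sol, self.context.t_ep)

    def sensitivity(self, grid=DEFAULT_DTISS_GRID, config: "GAConfig | None" = None) -> SensitivityCurve:
        """Refit over a d_tiss grid (same GA settings unless overridden)."""
        return dtiss_sweep(self.model.endog, self.context, grid, config or self.fit.config)

    def to_report(self, dextran_kda: "float | None" = None) -> PermeabilityReport:
        kda = dextran_kda if dextran_kda is not None else (self.model.endog.dextran_kda or 70.0)
        return PermeabilityReport(
            dextran_kda=float(kda),
            d_wall=(self.d_wall,),
            wall_thickness_um=self.wall_thickness_um,
            d_tiss=self.context.d_tiss,
            r2_phase3=(self.r2_phase3(),),
        )

    def summary(self) -> str:
        lines = [
            "Microvascular permeability estimate (apparent wall coefficient)",
            "=" * 64,
            f"{'samples (phase II/III)':<34}{np.count_nonzero(self.model.endog.phases != 'I'):>10d}",
            f"{'tissue coefficient D_tiss':<34}{self.context.d_tiss:>10.3g}  um^2/s",
            f"{'uptake rate k_a':<34}{self.pk.k_a:>10.4g}  1/s",
            f"{'clearance rate k_e':<34}{self.pk.k_e:>10.4g}  1/s",
            "-" * 64,
            f"{'wall coefficient D_wall':<34}{self.d_wall:>10.4g}  um^2/s",
            f"{'permeability P_wall':<34}{self.p_wall:>10.4g}  cm/s",
            f"{'onset delay T_del - T_EP':<34}{self.delay:>10.4g}  s",
            f"{'ramp duration T_sat - T_del':<34}{self.ramp:>10.4g}  s",
            "-" * 64,
            f"{'objective (SSR)':<34}{self.objective:>10.4g}",
            f"{'GA generations':<34}{self.fit.generations:>10d}",
            f"{'converged':<34}{str(self.fit.converged):>10}",
            f"{'phase III linearity R^2':<34}{self.r2_phase3():>10.4f}",
            "=" * 64,
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Data vs fitted model, normalized scale; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        tr = self.model.endog
        sel = tr.times >= tr.t_fd
        ax.plot(tr.times[sel] / 60.0, tr.values[sel], ".", ms=4, color="0.4", label="data")
        ax.plot(tr.times[sel] / 60.0, self.predict(tr.times[sel])[...], "-", color="crimson",
                label=f"model (D_wall={self.d_wall:.2g} um$^2$/s)")
        ax.axvline(self.context.t_ep / 60.0, color="k", ls=":", lw=1, label="EP pulses")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("normalized fluorescence")
        ax.legend(frameon=False)
        return ax
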