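"""Two-compartment pharmacokinetics of the dextran bolus.

The tracer is injected into the orbital sinus (compartment 1) and is taken
up into the systemic blood (compartment 2) with first-order rate ``k_a``;
it is cleared from blood (kidneys) with first-order rate ``k_e``:

    dm_orb/dt = -k_a * m_orb,        m_orb(T_FD) = dose
    dm_iv/dt  =  k_a * m_orb - k_e * m_iv,   m_iv(T_FD) = 0

The intravascular amount is the Bateman function

    m_iv(tau) = dose * k_a / (k_e - k_a) * (exp(-k_a tau) - exp(-k_e tau)),

with tau = t - T_FD, and the capillary concentration driving the transport
model is c_iv = m_iv / v_blood. Because the downstream pipeline normalizes
every trace by its pre-pulse maximum, v_blood (and any fluorescence gain)
is unidentifiable and is fixed to 1 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = ["PKParams", "PKSolution", "PKFitError", "bateman", "solve_two_compartment", "fit_pk", "civ_profile"]

#: Relative |k_a - k_e| below which the confluent (k_a == k_e) limit is used
#: to avoid catastrophic cancellation in the Bateman difference of exponentials.
CONFLUENT_RTOL = 1e-9


@dataclass(frozen=True)
class PKParams:
    """Uptake/clearance rates and scale of the two-compartment cascade.

    k_a, k_e in 1/s; ``dose`` is the orbital-sinus amount at injection and
    ``v_blood`` the effective blood volume (both in arbitrary units — only
    the shape of c_iv(t) matters once traces are normalized).
    """

    k_a: float = 0.02
    k_e: float = 5e-4
    dose: float = 1.0
    v_blood: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_a", "k_e", "dose", "v_blood"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite, got {getattr(self, name)}")
        if not self.k_a > 0:
            raise ValueError(f"k_a must be positive, got {self.k_a}")
        if self.k_e < 0:
            raise ValueError(f"k_e must be non-negative, got {self.k_e}")
        if not self.dose > 0:
            raise ValueError(f"dose must be positive, got {self.dose}")
        if not self.v_blood > 0:
            raise ValueError(f"v_blood must be positive, got {self.v_blood}")

    @property
    def t_peak(self) -> float:
        """Time after injection at which m_iv peaks (inf when k_e == 0)."""
        if self.k_e == 0:
            return np.inf
        if abs(self.k_a - self.k_e) < CONFLUENT_RTOL * self.k_a:
            return 1.0 / self.k_a
        return float(np.log(self.k_a / self.k_e) / (self.k_a - self.k_e))


@dataclass(frozen=True)
class PKSolution:
    times: np.ndarray
    m_iv: np.ndarray
    c_iv: np.ndarray


def bateman(tau: np.ndarray, params: PKParams) -> np.ndarray:
    """Intravascular amount m_iv as a function of time-after-injection tau.

    Negative tau maps to 0. Uses the confluent limit
    ``dose * k_a * tau * exp(-k_a tau)`` when k_a and k_e coincide to
    within :data:`CONFLUENT_RTOL`.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    tp = tau[pos]
    ka, ke = params.k_a, params.k_e
    if abs(ka - ke) < CONFLUENT_RTOL * ka:
        out[pos] = params.dose * ka * tp * np.exp(-ka * tp)
    else:
        out[pos] = params.dose * ka / (ke - ka) * (np.exp(-ka * tp) - np.exp(-ke * tp))
    return out


def solve_two_compartment(params: PKParams, times: np.ndarray, t_fd: float) -> PKSolution:
    """Closed-form solution of the cascade on ``times`` (seconds).

    Times earlier than the injection map to zero amounts.
    """
    times = np.asarray(times, dtype=float)
    m_iv = bateman(times - t_fd, params)
    return PKSolution(times=times, m_iv=m_iv, c_iv=m_iv / params.v_blood)


def civ_profile(params: PKParams, t_fd: float):
    """Return the capillary concentration c_iv(t) as a callable.

    Evaluable on arbitrary times (closed form, no interpolation error);
    zero before the injection. This is the Dirichlet boundary input of the
    transport model.
    """

    def c_iv(t):
        return bateman(np.asarray(t, dtype=float) - t_fd, params) / params.v_blood

    return c_iv


class PKFitError(RuntimeError):
    """Fit failure carrying the best parameters seen so far."""

    def __init__(self, message: str, best: "PKParams | None" = None, residual: float = np.nan):
        super().__init__(message)
        self.best = best
        self.residual = residual


def _shape(t: np.ndarray, t_fd: float, ka: float, ke: float) -> np.ndarray:
    return bateman(t - t_fd, PKParams(k_a=ka, k_e=ke, dose=1.0, v_blood=1.0))


def fit_pk(times, values, t_fd: float, init: "PKParams | None" = None, *, min_rise: int = 6, min_post_peak: int = 3):
    """Fit (k_a, k_e) to a normalized pre-pulse intravascular trace.

    ``times``/``values`` are the Phase II samples (background-subtracted;
    normalized or raw — the fit carries a free amplitude, so the overall
    gain never influences the recovered rates, and pinning the model to
    the noisy sample maximum is avoided). Optimized in log-space with
    ``scipy.optimize.least_squares`` from a small multistart.

    Raises
    ------
    ValueError
        If the samples do not cover the rise (≥ ``min_rise`` points) and the
        decay (≥ ``min_post_peak`` points past the empirical peak).
    PKFitError
        On non-convergence, carrying the best parameters seen.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < min_rise + min_post_peak:
        raise ValueError(f"need at least {min_rise + min_post_peak} samples, got {t.size}")
    i_peak = int(np.argmax(y))
    if i_peak < min_rise - 1:
        raise ValueError(f"need >= {min_rise} samples spanning the rise, got {i_peak + 1}")
    if t.size - 1 - i_peak < min_post_peak:
        raise ValueError(f"need >= {min_post_peak} samples past the peak, got {t.size - 1 - i_peak}")

    starts = []
    if init is not None:
        starts.append((init.k_a, init.k_e))
    starts += [(0.02, 5e-4), (0.005, 2e-3), (0.05, 1e-4)]

    ymax = float(y.max())
    if ymax <= 0:
        raise ValueError("Phase II samples have non-positive maximum; subtract background first")

    def resid(p):
        ka, ke, amp = np.exp(p)
        return amp * _shape(t, t_fd, ka, ke) - y

    best = None
    for ka0, ke0 in starts:
        shape0 = _shape(t, t_fd, ka0, ke0)
        amp0 = max(ymax / max(shape0.max(), 1e-300), 1e-300)
        try:
            sol = least_squares(resid, x0=np.log([ka0, ke0, amp0]), method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise PKFitError("pharmacokinetic fit failed for every start point")
    ka, ke = np.exp(best.x[:2])
    params = PKParams(k_a=float(ka), k_e=float(ke), dose=1.0, v_blood=1.0)
    rnorm = float(np.sqrt(2.0 * best.cost))
    if not best.success:
        raise PKFitError(f"pharmacokinetic fit did not converge: {best.message}", best=params, residual=rnorm)
    return params, rnorm


def with_rates(params: PKParams, k_a: float, k_e: float) -> PKParams:
    """Copy of ``params`` with replaced rates (dose/volume preserved)."""
    return replace(params, k_a=k_a, k_e=k_e)
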