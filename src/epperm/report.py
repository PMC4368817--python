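"""Derived quantities and serialized summaries.

Converts fitted wall diffusion coefficients to permeability coefficients
(P_wall = D_wall / d_wall, with d_wall the microvessel wall thickness),
computes group medians and the cross-study ratios used to place the
results in context, and writes the per-mouse/median tables as JSON + CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PermeabilityReport",
    "pwall_from_dwall",
    "stokes_einstein_ratio",
    "coefficient_ratio",
    "postep_linearity",
    "write_report",
    "HYDRODYNAMIC_RADIUS_NM",
]

#: Hydrodynamic radii of the two dextran tracers (literature values, nm).
HYDRODYNAMIC_RADIUS_NM = {70: 6.49, 2000: 26.89}

#: Micrometre -> centimetre conversion for the permeability coefficient.
_UM_TO_CM = 1e-4


def pwall_from_dwall(d_wall: float, thickness_um: float = 1.0) -> float:
    """Apparent permeability coefficient in cm/s.

    ``P_wall = D_wall / d_wall``: a wall diffusion coefficient in um^2/s
    divided by the wall thickness in um gives um/s, converted to cm/s.
    With the default 1 um wall, 0.0086 um^2/s maps to 8.6e-7 cm/s.
    """
    if not thickness_um > 0:
        raise ValueError(f"wall thickness must be positive, got {thickness_um}")
    return d_wall / thickness_um * _UM_TO_CM


def stokes_einstein_ratio(radius_large_nm: float, radius_small_nm: float) -> float:
    """Free-diffusion coefficient ratio implied by Stokes-Einstein.

    D scales inversely with hydrodynamic radius, so the expected ratio of
    free diffusion coefficients of a small over a large tracer is
    ``radius_large / radius_small``.
    """
    if not (radius_large_nm > 0 and radius_small_nm > 0):
        raise ValueError("hydrodynamic radii must be positive")
    return radius_large_nm / radius_small_nm


def coefficient_ratio(d_a: float, d_b: float) -> float:
    """Plain ratio ``d_a / d_b`` of two diffusion coefficients."""
    if d_b == 0:
        raise ValueError("denominator coefficient is zero")
    return d_a / d_b


def postep_linearity(trace) -> float:
    """R^2 of an ordinary least-squares line through the Phase III samples.

    Diagnostic for the near-linear post-pulse accumulation seen once the
    wall coefficient saturates. A constant trace has zero variance; its
    R^2 is defined as 0.
    """
    t, y = trace.phase("III")
    if t.size < 3:
        raise ValueError(f"need >= 3 Phase III samples, got {t.size}")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    slope, intercept = np.polyfit(t, y, 1)
    ss_res = float(np.sum((y - (slope * t + intercept)) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class PermeabilityReport:
    """Per-mouse and median wall coefficients for one dextran size."""

    dextran_kda: float
    d_wall: tuple  # per-mouse, um^2/s
    wall_thickness_um: float = 1.0
    d_tiss: float | None = None
    hydrodynamic_radius_nm: float | None = None
    r2_phase3: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.d_wall) == 0:
            raise ValueError("report needs at least one fitted d_wall")
        if self.hydrodynamic_radius_nm is None:
            object.__setattr__(
                self,
                "hydrodynamic_radius_nm",
                HYDRODYNAMIC_RADIUS_NM.get(int(self.dextran_kda)),
            )

    @property
    def median_d_wall(self) -> float:
        return float(np.median(self.d_wall))

    @property
    def p_wall(self) -> tuple:
        return tuple(pwall_from_dwall(d, self.wall_thickness_um) for d in self.d_wall)

    @property
    def median_p_wall(self) -> float:
        return float(np.median(self.p_wall))

    def table(self) -> pd.DataFrame:
        """Per-mouse rows plus a median row, Table-1 layout."""
        rows = [
            {
                "subject": f"mouse {i + 1}",
                "d_wall_um2_s": d,
                "p_wall_cm_s": p,
                "p_wall_1e-7_cm_s": p / 1e-7,
            }
            for i, (d, p) in enumerate(zip(self.d_wall, self.p_wall))
        ]
        rows.append(
            {
                "subject": "median",
                "d_wall_um2_s": self.median_d_wall,
                "p_wall_cm_s": self.median_p_wall,
                "p_wall_1e-7_cm_s": self.median_p_wall / 1e-7,
            }
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        # consistency of the stored conversion, checked on every write
        assert np.isclose(
            self.median_p_wall, pwall_from_dwall(self.median_d_wall, self.wall_thickness_um)
        ), "P_wall and D_wall medians inconsistent with P = D/d"
        return {
            "dextran_kda": self.dextran_kda,
            "d_tiss_um2_s": self.d_tiss,
            "wall_thickness_um": self.wall_thickness_um,
            "hydrodynamic_radius_nm": self.hydrodynamic_radius_nm,
            "d_wall_um2_s": list(self.d_wall),
            "median_d_wall_um2_s": self.median_d_wall,
            "p_wall_cm_s": list(self.p_wall),
            "median_p_wall_cm_s": self.median_p_wall,
            "r2_phase3": list(self.r2_phase3),
            **({"meta": self.meta} if self.meta else {}),
        }


def write_report(reports, out_dir, *, sweeps=None, config=None) -> Path:
    """Serialize one or more :class:`PermeabilityReport` objects.

    Writes ``report.json`` (all groups, plus optional sensitivity sweeps
    and run config) and one ``table_<size>kda.csv`` per group mirroring
    the per-mouse/median table layout. Returns the JSON path.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no fit results to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    payload: dict = {"groups": [r.to_dict() for r in reports]}
    if len(reports) == 2:
        a, b = sorted(reports, key=lambda r: r.dextran_kda)
        payload["ratio_small_over_large"] = coefficient_ratio(a.median_d_wall, b.median_d_wall)
        if a.hydrodynamic_radius_nm and b.hydrodynamic_radius_nm:
            payload["stokes_einstein_expected_ratio"] = stokes_einstein_ratio(
                b.hydrodynamic_radius_nm, a.hydrodynamic_radius_nm
            )
    if sweeps is not None:
        payload["sensitivity"] = [
            {
                "d_tiss_um2_s": list(map(float, s.d_tiss_grid)),
                "d_sat_um2_s": [None if not np.isfinite(v) else float(v) for v in s.d_sat],
                "spread_ratio": None if not np.isfinite(s.spread_ratio) else float(s.spread_ratio),
            }
            for s in sweeps
        ]
    if config is not None:
        payload["config"] = config

    json_path = out_dir / "report.json"
    try:
        json_path.write_text(json.dumps(payload, indent=2))
        for r in reports:
            r.table().to_csv(out_dir / f"table_{int(r.dextran_kda)}kda.csv", index=False)
    except OSError as err:
        raise OSError(f"failed to write report under {out_dir}: {err}") from err
    return json_path


def read_report(path) -> dict:
    """Re-parse a written ``report.json``."""
    return json.loads(Path(path).read_text())
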