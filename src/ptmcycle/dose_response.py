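"""Steady-state dose–response scans over any scalar parameter axis.

The dose grid is geometric: successive doses differ by a fixed relative
increment (default 1%), i.e. ``lower * (1 + step_percent/100)**i`` truncated
at ``upper``.  A multiplicative grid is the natural choice here because the
response curves are analysed on log axes and the local response coefficient
is a log–log derivative; it makes the finite-difference stencil uniform in
log-dose.

Readouts are named R, Rp, Rtot_free (= R + Rp), total_substrate
(= R + Rp + RX + RpY, full model only) and the four fluxes flux_k1..flux_k4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .models import FullParameters, FullState, MMParameters, MMState
from .models import full_fluxes, mm_fluxes
from .steady_state import (
    ModelVariant,
    SteadyStateError,
    initial_condition,
    solve_steady_state,
    _is_closed_cycle,
)

__all__ = [
    "DoseGrid", "DoseResponseCurve", "scan_dose_response",
    "scan_until_saturated", "flux_profile", "rtot_linearity_check",
    "MM_READOUTS", "FULL_READOUTS",
]

MM_READOUTS = ("R", "Rp", "Rtot_free", "flux_k1", "flux_k2", "flux_k3", "flux_k4")
FULL_READOUTS = ("R", "Rp", "Rtot_free", "total_substrate",
                 "flux_k1", "flux_k2", "flux_k3", "flux_k4")


@dataclass(frozen=True)
class DoseGrid:
    """Geometric dose grid along one parameter axis."""

    axis_name: str
    lower: float
    upper: float
    step_percent: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError("require 0 < lower < upper")
        if self.step_percent <= 0:
            raise ValueError("step_percent must be > 0")

    def values(self) -> np.ndarray:
        """Grid points lower*(1+s/100)^i truncated at upper (inclusive, with
        a small tolerance so an exact multiple of the ratio is kept)."""
        ratio = 1.0 + self.step_percent / 100.0
        n = int(np.floor(np.log(self.upper / self.lower) / np.log(ratio) + 1e-9)) + 1
        pts = self.lower * ratio ** np.arange(n + 1)
        return pts[pts <= self.upper * (1.0 + 1e-9)]


def _extract_readouts(state, params, model_variant: ModelVariant) -> dict[str, float]:
    if model_variant == "mm":
        fx = mm_fluxes(state, params)
        out = {"R": state.R, "Rp": state.Rp, "Rtot_free": state.Rtot}
    else:
        fx = full_fluxes(state, params)
        out = {"R": state.R, "Rp": state.Rp, "Rtot_free": state.Rtot_free,
               "total_substrate": state.total_substrate}
    out.update(fx._asdict())
    return out


@dataclass
class DoseResponseCurve:
    """Steady-state responses over a dose grid, with basal reference values.

    ``background`` holds the readouts at the documented basal condition: the
    axis value 0 when the dose axis is the kinase level (X / Xtot), otherwise
    the grid's lower bound (recorded in ``background_at_zero``).
    """

    doses: np.ndarray
    outputs: dict[str, np.ndarray]
    background: dict[str, float]
    params_used: MMParameters | FullParameters
    model_variant: ModelVariant
    grid: DoseGrid
    background_at_zero: bool = True
    total: float | None = None  # conserved total in closed-cycle mode

    def __post_init__(self) -> None:
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")

    @classmethod
    def from_arrays(
        cls,
        doses: Iterable[float],
        outputs: Mapping[str, Iterable[float]],
        background: Mapping[str, float] | None = None,
        model_variant: ModelVariant = "mm",
        params: MMParameters | FullParameters | None = None,
        background_at_zero: bool = True,
    ) -> "DoseResponseCurve":
        """Build a curve from plain arrays (used for synthetic test curves and
        for curves re-read from CSV).  Missing backgrounds default to the
        first point of each readout."""
        doses = np.asarray(list(doses), dtype=float)
        outputs = {k: np.asarray(list(v), dtype=float) for k, v in outputs.items()}
        if background is None:
            background = {k: float(v[0]) for k, v in outputs.items()}
            background_at_zero = False
        grid = DoseGrid("dose", float(doses[0]), float(doses[-1]),
                        step_percent=100.0 * (doses[1] / doses[0] - 1.0)
                        if len(doses) > 1 else 1.0)
        if params is None:
            params = MMParameters() if model_variant == "mm" else FullParameters()
        return cls(doses=doses, outputs=outputs, background=dict(background),
                   params_used=params, model_variant=model_variant, grid=grid,
                   background_at_zero=background_at_zero)

    @property
    def readouts(self) -> tuple[str, ...]:
        return tuple(self.outputs)

    def to_dataframe(self) -> pd.DataFrame:
        order = [c for c in ("dose",) + FULL_READOUTS if c == "dose" or c in self.outputs]
        df = pd.DataFrame({"dose": self.doses, **self.outputs})
        return df[order]


def _dose_axis_is_enzyme(axis: str) -> bool:
    return axis in ("X", "Xtot")


def scan_dose_response(
    params,
    model_variant: ModelVariant,
    grid: DoseGrid,
    readouts: Iterable[str] | None = None,
    total: float | None = None,
) -> DoseResponseCurve:
    """One steady state per grid point, warm-started from the previous point.

    The background is evaluated at axis value 0 when the axis is the kinase
    level (X or Xtot); for other axes it is the response at the grid's lower
    bound, and the curve records that convention.
    """
    axis = grid.axis_name
    if axis not in params.field_names():
        raise ValueError(f"unknown dose axis {axis!r} for {type(params).__name__}")
    all_readouts = MM_READOUTS if model_variant == "mm" else FULL_READOUTS
    if readouts is None:
        readouts = all_readouts
    else:
        readouts = tuple(readouts)
        unknown = set(readouts) - set(all_readouts)
        if unknown:
            raise ValueError(f"unknown readout(s): {sorted(unknown)}")

    doses = grid.values()
    columns = {name: np.empty(len(doses)) for name in readouts}
    prev_state = None
    for i, d in enumerate(doses):
        p_i = params.with_(**{axis: float(d)})
        try:
            res = solve_steady_state(p_i, model_variant, total=total,
                                     initial_state=prev_state)
        except SteadyStateError as err:
            raise SteadyStateError(
                f"no steady state at {axis}={d:g}: {err}", residual=err.residual
            ) from err
        if not res.converged:
            raise SteadyStateError(
                f"steady state did not converge at {axis}={d:g} "
                f"(residual {res.residual_norm:.3g})", residual=res.residual_norm)
        vals = _extract_readouts(res.state, p_i, model_variant)
        for name in readouts:
            columns[name][i] = vals[name]
        prev_state = res.state

    bg_at_zero = _dose_axis_is_enzyme(axis)
    p_bg = params.with_(**{axis: 0.0 if bg_at_zero else float(doses[0])})
    bg_state = solve_steady_state(p_bg, model_variant, total=total).state
    background = {name: _extract_readouts(bg_state, p_bg, model_variant)[name]
                  for name in readouts}

    return DoseResponseCurve(
        doses=doses, outputs=columns, background=background,
        params_used=params, model_variant=model_variant, grid=grid,
        background_at_zero=bg_at_zero, total=total,
    )


def scan_until_saturated(
    params,
    model_variant: ModelVariant,
    grid: DoseGrid,
    readout: str,
    readouts: Iterable[str] | None = None,
    total: float | None = None,
    max_upper: float = 1e8,
) -> DoseResponseCurve:
    """Scan, extending the upper dose bound tenfold at a time until the given
    readout saturates (see :func:`ptmcycle.metrics.plateau_check`) or the
    bound ``max_upper`` is reached.

    Used for responses whose transition region moves far to the right (e.g.
    large Michaelis constants), where a fixed dose range would truncate the
    curve before its plateau.
    """
    from .metrics import plateau_check  # local import to avoid a cycle

    g = grid
    while True:
        curve = scan_dose_response(params, model_variant, g,
                                   readouts=readouts, total=total)
        saturated, _ = plateau_check(curve, readout)
        if saturated or g.upper >= max_upper:
            return curve
        g = DoseGrid(g.axis_name, g.lower, min(g.upper * 10.0, max_upper),
                     g.step_percent)


def flux_profile(curve: DoseResponseCurve) -> pd.DataFrame:
    """Per-dose table of the four named fluxes.

    For the MM model the turnover fluxes are checked against the steady-state
    balance flux_k3 + flux_k4 = k0 at every dose.
    """
    flux_names = ("flux_k1", "flux_k2", "flux_k3", "flux_k4")
    missing = [n for n in flux_names if n not in curve.outputs]
    if missing:
        raise ValueError(f"curve lacks flux readouts: {missing}")
    df = pd.DataFrame({"dose": curve.doses,
                       **{n: curve.outputs[n] for n in flux_names}})
    if curve.model_variant == "mm" and not _is_closed_cycle(curve.params_used):
        balance = df["flux_k3"] + df["flux_k4"] - curve.params_used.k0
        if np.max(np.abs(balance)) > 1e-6:
            raise AssertionError(
                "steady-state turnover balance violated: "
                f"max |flux_k3 + flux_k4 - k0| = {np.max(np.abs(balance)):.3g}")
    return df


@dataclass(frozen=True)
class RtotLinearityResult:
    """Residuals of the linear Rtot–Rp and Rtot–R steady-state relations."""

    eq_rp_residuals: np.ndarray | None  # Rtot - [k0/k3 + (1 - k4/k3) Rp]
    eq_r_residuals: np.ndarray | None   # Rtot - [k0/k4 + (1 - k3/k4) R]
    max_abs_residual: float
    skipped: tuple[str, ...]


def rtot_linearity_check(curve: DoseResponseCurve, params: MMParameters | None = None
                         ) -> RtotLinearityResult:
    """Check the closed-form linear dependence of total substrate on Rp / R.

    At steady state the turnover balance k0 = k3 R + k4 Rp implies
    ``Rtot = k0/k3 + (1 - k4/k3) Rp`` and symmetric relation in R; when
    k3 = k4 both collapse to the constant Rtot = k0/k3.
    """
    if curve.model_variant != "mm":
        raise ValueError("Rtot linearity relations apply to the MM model")
    p = params or curve.params_used
    need = {"R", "Rp"}
    if not need <= set(curve.outputs):
        raise ValueError("curve must contain R and Rp readouts")
    R, Rp = curve.outputs["R"], curve.outputs["Rp"]
    Rtot = R + Rp
    skipped = []
    eq_rp = eq_r = None
    if p.k3 > 0:
        eq_rp = Rtot - (p.k0 / p.k3 + (1.0 - p.k4 / p.k3) * Rp)
    else:
        skipped.append("eq_rp (k3=0)")
    if p.k4 > 0:
        eq_r = Rtot - (p.k0 / p.k4 + (1.0 - p.k3 / p.k4) * R)
    else:
        skipped.append("eq_r (k4=0)")
    max_abs = max((float(np.max(np.abs(e))) for e in (eq_rp, eq_r)
                   if e is not None), default=0.0)
    return RtotLinearityResult(eq_rp, eq_r, max_abs, tuple(skipped))
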