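"""Ultrasensitivity metrics of steady-state dose–response curves.

Two complementary measures are computed:

* **Hill coefficient** ``n_H = ln(81) / ln(X_90 / X_10)`` where ``X_10`` and
  ``X_90`` are the doses producing 10% and 90% of the maximal response after
  subtracting the basal (background) response.  ``n_H`` captures the global
  steepness of the curve; it is signed, negative for decreasing (inhibitory)
  responses, for which the response is measured as the decrease from the
  basal level.
* **Local response coefficient** ``LRC = d ln(response) / d ln(dose)``, the
  log–log slope, estimated by centered finite differences on the geometric
  dose grid (one-sided at the endpoints).  ``|LRC|max`` is the curve's
  maximal amplification capacity.

The two need not agree: a curve with a large basal level can have a high
``|n_H|`` yet amplify weakly (``|LRC|max`` small), and vice versa.

``n_H`` is well defined only for monotone curves that saturate at the
high-dose end; for non-saturating or nonmonotonic curves the metric object
carries a NaN value and an explanatory flag instead of raising, so scenario
tables can contain "not evaluated" cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_response import DoseResponseCurve

__all__ = [
    "UltrasensitivityMetrics", "hill_coefficient",
    "local_response_coefficients", "lrc_max", "plateau_check",
    "evaluate_curve",
]

#: a readout saturates if its change over the last half-decade of doses is
#: below this fraction of the total response swing
PLATEAU_THRESHOLD = 1e-2
#: responses below this value are masked before taking logs
RESPONSE_FLOOR = 1e-12
#: relative tolerance for monotonicity (absorbs solver rounding noise)
MONOTONE_RTOL = 1e-9


@dataclass
class UltrasensitivityMetrics:
    """Hill coefficient, LRC profile and diagnostics for one readout."""

    readout: str
    n_H: float                 # NaN when undefined; see n_H_reason
    X_10: float
    X_90: float
    lrc: np.ndarray            # per-dose LRC, aligned with lrc_doses
    lrc_doses: np.ndarray
    lrc_max_abs: float
    lrc_max_location: float    # dose at which |LRC| peaks (ties -> lower dose)
    lrc_extremum: float        # signed LRC of largest magnitude
    saturated: bool
    monotone: bool
    plateau: float
    background: float
    n_H_reason: str | None = None

    @property
    def n_H_defined(self) -> bool:
        return np.isfinite(self.n_H)


def _direction(values: np.ndarray) -> int:
    """+1 monotone increasing, -1 decreasing, 0 flat, None nonmonotone."""
    tol = MONOTONE_RTOL * max(float(np.max(np.abs(values))), 1e-300)
    d = np.diff(values)
    up, down = np.any(d > tol), np.any(d < -tol)
    if up and down:
        return None
    if up:
        return 1
    if down:
        return -1
    return 0


def plateau_check(curve: DoseResponseCurve, readout: str,
                  threshold: float = PLATEAU_THRESHOLD) -> tuple[bool, float]:
    """Saturation flag and plateau value of a readout.

    The curve is deemed saturated when the readout changes by less than
    ``threshold`` times its total swing over the last half-decade of doses
    (an exactly constant readout is trivially saturated).  The plateau value
    is the readout at the highest dose.
    """
    r = np.asarray(curve.outputs[readout], dtype=float)
    if len(r) < 10:
        raise ValueError("plateau detection requires at least 10 grid points")
    doses = curve.doses
    window = doses >= doses[-1] / np.sqrt(10.0)
    tail_change = float(np.max(r[window]) - np.min(r[window]))
    swing = float(np.max(r) - np.min(r))
    if swing <= MONOTONE_RTOL * max(float(np.max(np.abs(r))), 1e-300):
        return True, float(r[-1])
    return tail_change <= threshold * swing, float(r[-1])


def _crossing(log_doses: np.ndarray, f: np.ndarray, level: float) -> float | None:
    """Dose (not log) of the first upward crossing of ``f`` through ``level``
    by piecewise-linear interpolation in (log-dose, f) space."""
    above = f >= level
    if above[0]:
        return None  # crossing lies below the scanned range
    if not above.any():
        return None
    i = int(np.argmax(above))
    f0, f1 = f[i - 1], f[i]
    if f1 == f0:
        return float(np.exp(log_doses[i]))
    t = (level - f0) / (f1 - f0)
    return float(np.exp(log_doses[i - 1] + t * (log_doses[i] - log_doses[i - 1])))


def local_response_coefficients(curve: DoseResponseCurve, readout: str) -> np.ndarray:
    """Per-dose LRC via centered log–log finite differences.

    Responses below ``RESPONSE_FLOOR`` are masked (NaN in the output):
    log-slopes of effectively extinct responses are numerically meaningless.
    """
    if len(curve.doses) < 3:
        raise ValueError("LRC estimation requires at least 3 grid points")
    if np.any(curve.doses <= 0):
        raise ValueError("doses must be positive")
    r = np.asarray(curve.outputs[readout], dtype=float)
    lrc = np.full_like(r, np.nan)
    valid = r > RESPONSE_FLOOR
    if valid.sum() >= 3:
        # operate on the contiguous valid block (masking only trims the ends)
        idx = np.flatnonzero(valid)
        sl = slice(idx[0], idx[-1] + 1)
        lrc[sl] = np.gradient(np.log(r[sl]), np.log(curve.doses[sl]))
    return lrc


def lrc_max(lrc_values: np.ndarray, doses: np.ndarray) -> tuple[float, float]:
    """Maximal |LRC| and the dose where it occurs (ties -> lower dose)."""
    lrc_values = np.asarray(lrc_values, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if lrc_values.size == 0 or doses.size == 0:
        raise ValueError("empty LRC input")
    if np.all(np.isnan(lrc_values)):
        return float("nan"), float("nan")
    i = int(np.nanargmax(np.abs(lrc_values)))
    return float(abs(lrc_values[i])), float(doses[i])


def evaluate_curve(curve: DoseResponseCurve, readout: str,
                   plateau_threshold: float = PLATEAU_THRESHOLD
                   ) -> UltrasensitivityMetrics:
    """All ultrasensitivity metrics of one readout of a dose–response curve."""
    if readout not in curve.outputs:
        raise ValueError(f"curve has no readout {readout!r}")
    r = np.asarray(curve.outputs[readout], dtype=float)
    doses = curve.doses
    bg = float(curve.background[readout])

    direction = _direction(r)
    monotone = direction is not None
    saturated, plateau = plateau_check(curve, readout, plateau_threshold)

    lrc = local_response_coefficients(curve, readout)
    lmax, lloc = lrc_max(lrc, doses)
    lext = float("nan")
    if np.isfinite(lmax):
        i = int(np.nanargmax(np.abs(lrc)))
        lext = float(lrc[i])

    n_H = float("nan")
    x10 = x90 = float("nan")
    reason = None
    if not monotone:
        reason = "nonmonotonic response"
    elif direction == 0:
        reason = "flat response"
    elif not saturated:
        reason = "response does not saturate"
    else:
        span = plateau - bg
        if abs(span) <= MONOTONE_RTOL * max(abs(bg), abs(plateau), 1e-300):
            reason = "no dynamic range above background"
        else:
            # fractional response, measured downward from basal for
            # inhibitory curves so that f rises monotonically 0 -> 1
            f = (r - bg) / span
            log_doses = np.log(doses)
            c10 = _crossing(log_doses, f, 0.1)
            c90 = _crossing(log_doses, f, 0.9)
            if c10 is None or c90 is None:
                reason = "10%/90% crossing outside the scanned dose range"
            else:
                x10, x90 = c10, c90
                n_H = direction * float(np.log(81.0) / np.log(x90 / x10))

    return UltrasensitivityMetrics(
        readout=readout, n_H=n_H, X_10=x10, X_90=x90,
        lrc=lrc, lrc_doses=doses, lrc_max_abs=lmax, lrc_max_location=lloc,
        lrc_extremum=lext, saturated=saturated, monotone=monotone,
        plateau=plateau, background=bg, n_H_reason=reason,
    )


def hill_coefficient(curve: DoseResponseCurve, readout: str) -> float:
    """Signed Hill coefficient of one readout (NaN when undefined)."""
    return evaluate_curve(curve, readout).n_H
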