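"""Optional plotting helpers (matplotlib); numeric outputs never depend on these."""

from __future__ import annotations

from .dose_response import DoseResponseCurve
from .metrics import evaluate_curve
from .steady_state import TimeCourse

__all__ = ["plot_dose_response", "plot_lrc", "plot_time_course"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_dose_response(curve: DoseResponseCurve, readouts=("R", "Rp"),
                       loglog: bool = True, ax=None, **kwargs):
    """Dose-response curves, linear or log-log."""
    ax = _ax(ax)
    for r in readouts:
        ax.plot(curve.doses, curve.outputs[r], label=r, **kwargs)
    if loglog:
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel(curve.grid.axis_name)
    ax.set_ylabel("steady-state response")
    ax.legend()
    return ax


def plot_lrc(curve: DoseResponseCurve, readouts=("R", "Rp"), ax=None, **kwargs):
    """Local response coefficient against dose, with the n_H level lines."""
    ax = _ax(ax)
    for r in readouts:
        m = evaluate_curve(curve, r)
        (line,) = ax.plot(m.lrc_doses, m.lrc, label=f"LRC {r}", **kwargs)
        if m.n_H_defined:
            ax.axhline(m.n_H, linestyle="--", color=line.get_color(),
                       alpha=0.5, label=f"n_H {r}")
    ax.set_xscale("log")
    ax.set_xlabel(curve.grid.axis_name)
    ax.set_ylabel("LRC")
    ax.legend()
    return ax


def plot_time_course(tc: TimeCourse, ax=None, **kwargs):
    """Species trajectories over time."""
    ax = _ax(ax)
    df = tc.to_dataframe()
    for col in df.columns[1:]:
        ax.plot(df["time"], df[col], label=col, **kwargs)
    ax.set_xlabel("time")
    ax.set_ylabel("concentration")
    if tc.input_description:
        ax.set_title(tc.input_description)
    ax.legend()
    return ax
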