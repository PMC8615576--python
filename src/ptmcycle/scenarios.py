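"""Declarative scenario runner for the standard simulation experiments.

A :class:`ScenarioConfig` names a model variant, parameter overrides (scalar,
or a list to produce one curve per value), a dose axis with range and step,
and the readouts to evaluate.  :func:`run_scenario` produces one
dose–response curve and one set of ultrasensitivity metrics per
(override value x readout) and can write them as CSV files plus a JSON run
manifest from which every number can be regenerated.

The built-in scenarios cover the canonical experiments: the baseline cycle,
stability (k4) sweeps in both model variants, emergence of ultrasensitivity
at high Michaelis constants, Km1 sweeps under destabilization and
stabilization, synthesis-driven (k0) dose responses, the closed cycle
without turnover, and the large-k4 asymptote.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import (
    FULL_READOUTS,
    MM_READOUTS,
    DoseGrid,
    DoseResponseCurve,
    scan_dose_response,
)
from .metrics import UltrasensitivityMetrics, evaluate_curve
from .models import FullParameters, MMParameters
from .steady_state import RESIDUAL_TOL, RTOL, ATOL

__all__ = [
    "ScenarioConfig", "ScenarioResult", "BUILTIN_SCENARIOS", "get_scenario",
    "run_scenario", "table3_summary", "load_config", "save_config",
]

METRIC_COLUMNS = ["scenario", "readout", "override_param", "override_value",
                  "n_H", "X_10", "X_90", "lrc_max_abs", "lrc_max_location",
                  "saturated", "monotone"]


def _package_version() -> str:
    from . import __version__

    return __version__


def _fmt(x: float) -> str:
    """Full-precision plain decimal representation (no scientific notation)."""
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    xf = float(x)
    if np.isnan(xf):
        return "NA"
    return np.format_float_positional(xf, unique=True, trim="0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Declarative description of one dose–response experiment."""

    name: str
    model_variant: str = "mm"                       # "mm" | "full"
    overrides: Mapping[str, float | Sequence[float]] = field(default_factory=dict)
    dose_axis: str = "X"
    dose_lower: float = 1e-2
    dose_upper: float = 1e2
    step_percent: float = 1.0
    readouts: Sequence[str] | None = None           # None -> all for the variant
    total: float | None = None                      # closed-cycle conserved total

    def __post_init__(self) -> None:
        if self.model_variant not in ("mm", "full"):
            raise ValueError(f"model_variant must be 'mm' or 'full', got "
                             f"{self.model_variant!r}")
        cls = MMParameters if self.model_variant == "mm" else FullParameters
        valid = set(cls.field_names())
        unknown = set(self.overrides) - valid
        if unknown:
            raise ValueError(f"unknown override parameter(s): {sorted(unknown)}")
        if self.dose_axis not in valid:
            raise ValueError(f"unknown dose axis {self.dose_axis!r}")
        allowed = MM_READOUTS if self.model_variant == "mm" else FULL_READOUTS
        if self.readouts is not None:
            bad = set(self.readouts) - set(allowed)
            if bad:
                raise ValueError(f"unknown readout(s): {sorted(bad)}")
        n_lists = sum(1 for v in self.overrides.values()
                      if isinstance(v, (list, tuple)))
        if n_lists > 1:
            raise ValueError("at most one override may be list-valued")

    @property
    def sweep_param(self) -> str | None:
        for k, v in self.overrides.items():
            if isinstance(v, (list, tuple)):
                return k
        return None

    def parameter_sets(self):
        """Yield (override_value, params) pairs, one per curve."""
        cls = MMParameters if self.model_variant == "mm" else FullParameters
        scalar = {k: float(v) for k, v in self.overrides.items()
                  if not isinstance(v, (list, tuple))}
        sweep = self.sweep_param
        if sweep is None:
            yield None, cls(**scalar)
        else:
            for v in self.overrides[sweep]:
                yield float(v), cls(**scalar, **{sweep: float(v)})

    def grid(self) -> DoseGrid:
        return DoseGrid(self.dose_axis, self.dose_lower, self.dose_upper,
                        self.step_percent)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["overrides"] = {k: (list(v) if isinstance(v, (list, tuple)) else v)
                          for k, v in self.overrides.items()}
        if d["readouts"] is not None:
            d["readouts"] = list(d["readouts"])
        return d


@dataclass
class ScenarioResult:
    """Curves and metrics of one scenario run."""

    config: ScenarioConfig
    curves: dict[float | None, DoseResponseCurve]
    metrics: dict[tuple[float | None, str], UltrasensitivityMetrics]

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for (value, readout), m in self.metrics.items():
            rows.append({
                "scenario": self.config.name, "readout": readout,
                "override_param": self.config.sweep_param or "",
                "override_value": value if value is not None else np.nan,
                "n_H": m.n_H, "X_10": m.X_10, "X_90": m.X_90,
                "lrc_max_abs": m.lrc_max_abs,
                "lrc_max_location": m.lrc_max_location,
                "saturated": m.saturated, "monotone": m.monotone,
            })
        return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def run_scenario(config: ScenarioConfig, outdir: str | Path | None = None
                 ) -> ScenarioResult:
    """Run one scenario; optionally write CSV outputs and a run manifest."""
    grid = config.grid()
    curves: dict[float | None, DoseResponseCurve] = {}
    metrics: dict[tuple[float | None, str], UltrasensitivityMetrics] = {}
    metric_readouts = ("R", "Rp", "Rtot_free") if config.model_variant == "mm" \
        else ("R", "Rp", "Rtot_free", "total_substrate")
    if config.readouts is not None:
        metric_readouts = tuple(r for r in metric_readouts
                                if r in config.readouts)
    for value, params in config.parameter_sets():
        curve = scan_dose_response(params, config.model_variant, grid,
                                   readouts=config.readouts, total=config.total)
        curves[value] = curve
        for readout in metric_readouts:
            metrics[(value, readout)] = evaluate_curve(curve, readout)
    result = ScenarioResult(config, curves, metrics)
    if outdir is not None:
        write_scenario_outputs(result, Path(outdir))
    return result


def _curve_csv(curve: DoseResponseCurve) -> str:
    df = curve.to_dataframe()
    lines = [",".join(df.columns)]
    for row in df.itertuples(index=False):
        lines.append(",".join(_fmt(v) for v in row))
    return "\n".join(lines) + "\n"


def write_scenario_outputs(result: ScenarioResult, outdir: Path) -> list[Path]:
    """Write curve/LRC/metrics CSVs and the JSON manifest; returns the paths."""
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    written = []

    def tag(value):
        return "" if value is None else f"_{cfg.sweep_param}={_fmt(value)}"

    for value, curve in result.curves.items():
        p = outdir / f"{cfg.name}{tag(value)}_curve.csv"
        p.write_text(_curve_csv(curve))
        written.append(p)
    for (value, readout), m in result.metrics.items():
        p = outdir / f"{cfg.name}{tag(value)}_{readout}_lrc.csv"
        lines = ["dose,lrc"] + [f"{_fmt(d)},{_fmt(l)}"
                                for d, l in zip(m.lrc_doses, m.lrc)]
        p.write_text("\n".join(lines) + "\n")
        written.append(p)

    mt = result.metrics_table()
    p = outdir / f"{cfg.name}_metrics.csv"
    lines = [",".join(METRIC_COLUMNS)]
    for row in mt.itertuples(index=False):
        lines.append(",".join(_fmt(v) if isinstance(v, (int, float, np.floating,
                                                        bool, np.bool_))
                              else str(v) for v in row))
    p.write_text("\n".join(lines) + "\n")
    written.append(p)

    manifest = {
        "package_version": _package_version(),
        "config": cfg.to_dict(),
        "grid": {"axis": cfg.dose_axis, "lower": cfg.dose_lower,
                 "upper": cfg.dose_upper, "step_percent": cfg.step_percent,
                 "n_points": int(len(next(iter(result.curves.values())).doses))},
        "tolerances": {"steady_state_residual": RESIDUAL_TOL,
                       "integration_rtol": RTOL, "integration_atol": ATOL},
        "parameters": {(_fmt(v) if v is not None else "default"):
                       params.as_dict()
                       for v, params in
                       ((val, c.params_used) for val, c in result.curves.items())},
    }
    p = outdir / f"{cfg.name}_manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(p)
    return written


# ---------------------------------------------------------------------------
# Config file I/O (YAML mirroring ScenarioConfig field names)
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> ScenarioConfig:
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"malformed scenario config: {path}")
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return ScenarioConfig(**data)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Built-in scenarios
# ---------------------------------------------------------------------------

BUILTIN_SCENARIOS: dict[str, ScenarioConfig] = {
    # baseline cycle: equal turnover of both substrate forms
    "fig2_baseline": ScenarioConfig(name="fig2_baseline"),
    # stability sweep of the modified form
    "fig3_k4_sweep": ScenarioConfig(
        name="fig3_k4_sweep",
        overrides={"k4": [0.0001, 0.001, 0.01, 0.1, 1.0]}),
    # full model with phosphatase comparable to substrate
    "fig4_full_ytot100": ScenarioConfig(
        name="fig4_full_ytot100", model_variant="full", dose_axis="Xtot",
        overrides={"Ytot": 100.0, "k4": [0.0001, 0.001, 0.01, 0.1, 1.0]}),
    # emergence of ultrasensitivity at high Michaelis constants
    "fig5_emergence": ScenarioConfig(
        name="fig5_emergence",
        overrides={"Km1": 100.0, "Km2": 100.0,
                   "k4": [0.0001, 0.001, 0.01, 0.1]}),
    "fig5_emergence_full": ScenarioConfig(
        name="fig5_emergence_full", model_variant="full", dose_axis="Xtot",
        overrides={"k1b": 990.0, "k2b": 990.0,
                   "k4": [0.0001, 0.001, 0.01, 0.1]}),
    # Michaelis-constant sweeps under destabilization / stabilization
    "fig6_km1_destab": ScenarioConfig(
        name="fig6_km1_destab",
        overrides={"k4": 0.1, "Km1": [0.1, 1.0, 10.0, 100.0, 1000.0]}),
    "fig7_km1_stab": ScenarioConfig(
        name="fig7_km1_stab",
        overrides={"k4": 0.001, "Km1": [0.1, 1.0, 10.0, 100.0, 1000.0]}),
    # synthesis-rate-driven dose response at intermediate kinase activity
    "fig8_k0_sweep": ScenarioConfig(
        name="fig8_k0_sweep", dose_axis="k0",
        overrides={"X": 1.0, "k4": [0.001, 0.01, 0.1, 1.0]}),
    "fig8_k0_sweep_k2zero": ScenarioConfig(
        name="fig8_k0_sweep_k2zero", dose_axis="k0",
        overrides={"X": 1.0, "k2": 0.0, "k4": 1.0}),
    # classical cycle without synthesis or turnover
    "closed_cycle": ScenarioConfig(
        name="closed_cycle", overrides={"k0": 0.0, "k3": 0.0, "k4": 0.0},
        total=100.0),
    # limit of strong destabilization of the modified form
    "large_k4_asymptote": ScenarioConfig(
        name="large_k4_asymptote", overrides={"k4": [1.0, 10.0, 100.0]}),
}


def get_scenario(name: str) -> ScenarioConfig:
    try:
        return BUILTIN_SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: "
            f"{', '.join(sorted(BUILTIN_SCENARIOS))}") from None


# ---------------------------------------------------------------------------
# Direction-of-change summary of |LRC|max under parameter variations
# ---------------------------------------------------------------------------

#: each row: (label, axis, base overrides, varied overrides, condition label)
#: the sweeps for k4 itself move from within one stability regime 10x further
#: into it for the synthesis-driven (k0) block, and from the default value
#: 10x into the regime for the kinase-driven block, mirroring how the sweeps
#: are presented in the figures.
_TABLE3_ROWS: list[tuple[str, str, dict, dict, str]] = [
    ("down k4", "X", {}, {"k4": 0.001}, "k3 > k4"),
    ("up k4", "X", {}, {"k4": 0.1}, "k3 < k4"),
    ("down Km1, down Km2", "X", {"k4": 0.001},
     {"k4": 0.001, "Km1": 1.0, "Km2": 1.0}, "k3 > k4"),
    ("down Km1, down Km2", "X", {"k4": 0.1},
     {"k4": 0.1, "Km1": 1.0, "Km2": 1.0}, "k3 < k4"),
    ("up Km1, up Km2", "X", {"k4": 0.001},
     {"k4": 0.001, "Km1": 100.0, "Km2": 100.0}, "k3 > k4"),
    ("up Km1, up Km2", "X", {"k4": 0.1},
     {"k4": 0.1, "Km1": 100.0, "Km2": 100.0}, "k3 < k4"),
    ("up k1", "X", {"k4": 0.001}, {"k4": 0.001, "k1": 100.0}, "k3 > k4"),
    ("up k1", "X", {"k4": 0.1}, {"k4": 0.1, "k1": 100.0}, "k3 < k4"),
    ("down k1", "X", {"k4": 0.001}, {"k4": 0.001, "k1": 1.0}, "k3 > k4"),
    ("down k1", "X", {"k4": 0.1}, {"k4": 0.1, "k1": 1.0}, "k3 < k4"),
    ("up k2", "X", {"k4": 0.001}, {"k4": 0.001, "k2": 100.0}, "k3 > k4"),
    ("up k2", "X", {"k4": 0.1}, {"k4": 0.1, "k2": 100.0}, "k3 < k4"),
    ("down k4", "k0", {"X": 1.0, "k4": 0.001},
     {"X": 1.0, "k4": 0.0001}, "k3 > k4"),
    ("up k4", "k0", {"X": 1.0, "k4": 0.1}, {"X": 1.0, "k4": 1.0}, "k3 < k4"),
]

#: change in |LRC|max below this fraction counts as "no effect" (-)
TABLE3_FLAT_THRESHOLD = 0.05


def _lrc_max_for(overrides: dict, axis: str) -> dict[str, float]:
    params = MMParameters(**overrides)
    grid = DoseGrid(axis, 1e-2, 1e2, 1.0)
    curve = scan_dose_response(params, "mm", grid,
                               readouts=("R", "Rp", "Rtot_free"))
    return {r: evaluate_curve(curve, r).lrc_max_abs
            for r in ("R", "Rp", "Rtot_free")}


def table3_summary() -> pd.DataFrame:
    """Direction of change of |LRC|max under 10x parameter variations.

    For every row the MM model is scanned at a base and a varied parameter
    set over the kinase axis (or the synthesis axis with X = 1), and the
    direction of change of |LRC|max is reported per readout: "up", "down",
    or "-" when the relative change is below 5% (changes from an exactly
    flat base curve count as "up").
    """
    rows = []
    cache: dict[tuple, dict[str, float]] = {}

    def lrc(overrides: dict, axis: str) -> dict[str, float]:
        key = (axis, tuple(sorted(overrides.items())))
        if key not in cache:
            cache[key] = _lrc_max_for(overrides, axis)
        return cache[key]

    for label, axis, base_ov, var_ov, condition in _TABLE3_ROWS:
        base = lrc(base_ov, axis)
        varied = lrc(var_ov, axis)
        row = {"parameter": label, "axis": axis, "condition": condition}
        for readout in ("R", "Rp", "Rtot_free"):
            b, v = base[readout], varied[readout]
            if b < 1e-6:  # flat base curve: any appreciable LRC is a gain
                row[readout] = "up" if v > 1e-3 else "-"
                continue
            rel = (v - b) / b
            if abs(rel) < TABLE3_FLAT_THRESHOLD:
                row[readout] = "-"
            else:
                row[readout] = "up" if rel > 0 else "down"
        rows.append(row)
    return pd.DataFrame(rows,
                        columns=["parameter", "axis", "condition",
                                 "R", "Rp", "Rtot_free"])
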