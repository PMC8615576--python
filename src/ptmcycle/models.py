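"""Parameter/state containers and right-hand sides of both cycle models.

The MM model describes a substrate ``R`` that is synthesized at constant rate
``k0``, phosphorylated into ``Rp`` by a kinase ``X`` (Michaelis–Menten, with
maximal velocity ``k1*X`` and Michaelis constant ``Km1``), dephosphorylated
back by a phosphatase ``Y`` (``k2*Y``, ``Km2``), and degraded first-order:
``R`` with rate constant ``k3`` and ``Rp`` with ``k4``::

    dR/dt  = k0 - k1*X*R/(Km1+R) + k2*Y*Rp/(Km2+Rp) - k3*R
    dRp/dt =      k1*X*R/(Km1+R) - k2*Y*Rp/(Km2+Rp) - k4*Rp

The full model replaces the two Michaelis–Menten steps by explicit mass-action
binding (``k1f``/``k1b``, ``k2f``/``k2b``) and catalysis (``k1c``, ``k2c``)
with enzyme–substrate complexes ``RX`` and ``RpY`` as state variables.
Substrate in a complex is degraded at the same rate constant as the matching
free form (``k3`` for R/RX, ``k4`` for Rp/RpY) and the enzyme is released
intact and recycled; free enzyme is therefore the algebraic quantity
``Xtot - RX`` (resp. ``Ytot - RpY``), never an ODE variable, so enzyme
conservation holds by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "MMParameters", "FullParameters", "MMState", "FullState", "Fluxes",
    "mm_rhs", "full_rhs", "mm_fluxes", "full_fluxes", "apparent_km",
]


def apparent_km(kb: float, kc: float, kf: float) -> float:
    """Apparent Michaelis constant (kb + kc) / kf of a mass-action enzyme step.

    With the default full-model constants (kb=90, kc=10, kf=10) this equals
    the MM-model Michaelis constant of 10, which makes the two variants
    directly comparable.
    """
    if kf <= 0:
        raise ZeroDivisionError("association rate constant kf must be > 0")
    return (kb + kc) / kf


class _ParamsBase:
    """Shared helpers for the immutable parameter records."""

    def with_(self, **overrides: float):
        """Return a copy with the given fields replaced (validates anew)."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))


@dataclass(frozen=True)
class MMParameters(_ParamsBase):
    """Kinetic constants of the MM model (defaults: the baseline parameter set).

    Units are arbitrary concentration/time units; ``k3`` and ``k4`` default to
    1/100 of the pseudo-first-order modification rates ``k1/Km1`` and
    ``k2/Km2``, reflecting that protein turnover (hours) is much slower than
    covalent modification (seconds to minutes).
    """

    k0: float = 1.0     # synthesis rate of R (conc/time)
    k1: float = 10.0    # catalytic rate constant, phosphorylation (1/time)
    Km1: float = 10.0   # Michaelis constant, phosphorylation (conc)
    X: float = 0.0      # kinase level (conc); the canonical dose axis
    k2: float = 10.0    # catalytic rate constant, dephosphorylation (1/time)
    Km2: float = 10.0   # Michaelis constant, dephosphorylation (conc)
    k3: float = 0.01    # degradation rate constant of R (1/time)
    k4: float = 0.01    # degradation rate constant of Rp (1/time)
    Y: float = 1.0      # phosphatase level (conc)

    def __post_init__(self) -> None:
        for name in self.field_names():
            v = getattr(self, name)
            if not (v >= 0):  # also catches NaN
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.Km1 <= 0 or self.Km2 <= 0:
            raise ValueError("Michaelis constants Km1 and Km2 must be > 0")


@dataclass(frozen=True)
class FullParameters(_ParamsBase):
    """Kinetic constants of the full mass-action model.

    Defaults are chosen so that the apparent Michaelis constants
    ``(k1b+k1c)/k1f`` and ``(k2b+k2c)/k2f`` both equal 10, matching the MM
    model baseline.
    """

    k0: float = 1.0     # synthesis rate of R (conc/time)
    k1f: float = 10.0   # association rate, R + X -> RX (1/conc/time)
    k1b: float = 90.0   # dissociation rate, RX -> R + X (1/time)
    k1c: float = 10.0   # catalysis, RX -> Rp + X (1/time)
    Xtot: float = 0.0   # total kinase (conc); the canonical dose axis
    k2f: float = 10.0   # association rate, Rp + Y -> RpY (1/conc/time)
    k2b: float = 90.0   # dissociation rate, RpY -> Rp + Y (1/time)
    k2c: float = 10.0   # catalysis, RpY -> R + Y (1/time)
    k3: float = 0.01    # degradation rate constant of R and RX (1/time)
    k4: float = 0.01    # degradation rate constant of Rp and RpY (1/time)
    Ytot: float = 1.0   # total phosphatase (conc)

    def __post_init__(self) -> None:
        for name in self.field_names():
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.k1f <= 0 or self.k2f <= 0:
            raise ValueError("association rate constants k1f and k2f must be > 0")

    @property
    def apparent_km1(self) -> float:
        """(k1b + k1c) / k1f — apparent Michaelis constant of the kinase step."""
        return apparent_km(self.k1b, self.k1c, self.k1f)

    @property
    def apparent_km2(self) -> float:
        """(k2b + k2c) / k2f — apparent Michaelis constant of the phosphatase step."""
        return apparent_km(self.k2b, self.k2c, self.k2f)


@dataclass(frozen=True)
class MMState:
    """Concentrations of the two substrate forms in the MM model."""

    R: float
    Rp: float

    def __post_init__(self) -> None:
        if not (self.R >= 0 and self.Rp >= 0):
            raise ValueError(f"concentrations must be >= 0, got {self}")

    @property
    def Rtot(self) -> float:
        """Total substrate R + Rp."""
        return self.R + self.Rp

    def as_tuple(self) -> tuple[float, float]:
        return (self.R, self.Rp)


@dataclass(frozen=True)
class FullState:
    """Concentrations of free substrate forms and enzyme complexes (full model)."""

    R: float
    Rp: float
    RX: float
    RpY: float

    def __post_init__(self) -> None:
        if not (self.R >= 0 and self.Rp >= 0 and self.RX >= 0 and self.RpY >= 0):
            raise ValueError(f"concentrations must be >= 0, got {self}")

    @property
    def Rtot_free(self) -> float:
        """Free substrate R + Rp (excluding enzyme-bound forms)."""
        return self.R + self.Rp

    @property
    def total_substrate(self) -> float:
        """All substrate, free plus enzyme-bound: R + Rp + RX + RpY."""
        return self.R + self.Rp + self.RX + self.RpY

    def free_X(self, params: FullParameters) -> float:
        """Free kinase Xtot - RX (conservation holds by construction)."""
        return params.Xtot - self.RX

    def free_Y(self, params: FullParameters) -> float:
        """Free phosphatase Ytot - RpY."""
        return params.Ytot - self.RpY

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.R, self.Rp, self.RX, self.RpY)


class Fluxes(NamedTuple):
    """Steady-state (or instantaneous) fluxes named by their rate constant."""

    flux_k1: float  # phosphorylation
    flux_k2: float  # dephosphorylation
    flux_k3: float  # degradation of R (plus RX in the full model)
    flux_k4: float  # degradation of Rp (plus RpY in the full model)


def _check_full_state(state: FullState, params: FullParameters) -> None:
    tol = 1e-9 * max(1.0, params.Xtot, params.Ytot)
    if state.RX > params.Xtot + tol:
        raise ValueError(f"RX={state.RX} exceeds total kinase Xtot={params.Xtot}")
    if state.RpY > params.Ytot + tol:
        raise ValueError(f"RpY={state.RpY} exceeds total phosphatase Ytot={params.Ytot}")


def mm_rhs(state: MMState, params: MMParameters) -> tuple[float, float]:
    """Time derivatives (dR/dt, dRp/dt) of the MM model."""
    p = params
    phos = p.k1 * p.X * state.R / (p.Km1 + state.R)
    dephos = p.k2 * p.Y * state.Rp / (p.Km2 + state.Rp)
    dR = p.k0 - phos + dephos - p.k3 * state.R
    dRp = phos - dephos - p.k4 * state.Rp
    return (dR, dRp)


def mm_fluxes(state: MMState, params: MMParameters) -> Fluxes:
    """The four named fluxes of the MM model at the given state.

    At any steady state the turnover fluxes balance synthesis:
    flux_k3 + flux_k4 = k0.
    """
    p = params
    return Fluxes(
        flux_k1=p.k1 * p.X * state.R / (p.Km1 + state.R),
        flux_k2=p.k2 * p.Y * state.Rp / (p.Km2 + state.Rp),
        flux_k3=p.k3 * state.R,
        flux_k4=p.k4 * state.Rp,
    )


def full_rhs(state: FullState, params: FullParameters) -> tuple[float, float, float, float]:
    """Time derivatives (dR, dRp, dRX, dRpY) of the full mass-action model.

    Complex degradation (-k3*RX, -k4*RpY) removes substrate from the complex
    pool only and returns the enzyme to the free pool; no substrate is
    recovered.
    """
    p = params
    _check_full_state(state, params)
    X_free = p.Xtot - state.RX
    Y_free = p.Ytot - state.RpY
    bind1 = p.k1f * state.R * X_free
    bind2 = p.k2f * state.Rp * Y_free
    dR = p.k0 - bind1 + p.k1b * state.RX + p.k2c * state.RpY - p.k3 * state.R
    dRp = p.k1c * state.RX - bind2 + p.k2b * state.RpY - p.k4 * state.Rp
    dRX = bind1 - (p.k1b + p.k1c + p.k3) * state.RX
    dRpY = bind2 - (p.k2b + p.k2c + p.k4) * state.RpY
    return (dR, dRp, dRX, dRpY)


def full_fluxes(state: FullState, params: FullParameters) -> Fluxes:
    """Named fluxes of the full model, defined on the lumped substrate pools.

    flux_k1 is the catalytic phosphorylation flux k1c*RX, flux_k2 the
    dephosphorylation flux k2c*RpY; the turnover fluxes sum the free and
    complexed forms, so that flux_k3 + flux_k4 = k0 at steady state, as in
    the MM model.
    """
    p = params
    _check_full_state(state, params)
    return Fluxes(
        flux_k1=p.k1c * state.RX,
        flux_k2=p.k2c * state.RpY,
        flux_k3=p.k3 * (state.R + state.RX),
        flux_k4=p.k4 * (state.Rp + state.RpY),
    )
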