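# Methods

## Models

Two deterministic descriptions of a phosphorylation–dephosphorylation cycle
with protein turnover are implemented.

The **MM model** treats both modification reactions with Michaelis–Menten
kinetics:

    dR/dt  = k0 − k1·X·R/(Km1+R) + k2·Y·Rp/(Km2+Rp) − k3·R
    dRp/dt =      k1·X·R/(Km1+R) − k2·Y·Rp/(Km2+Rp) − k4·Rp

The **full model** resolves the enzyme–substrate complexes RX and RpY with
mass-action kinetics:

    dR/dt   = k0 − k1f·R·(Xtot−RX) + k1b·RX + k2c·RpY − k3·R
    dRp/dt  = k1c·RX − k2f·Rp·(Ytot−RpY) + k2b·RpY − k4·Rp
    dRX/dt  = k1f·R·(Xtot−RX) − (k1b + k1c + k3)·RX
    dRpY/dt = k2f·Rp·(Ytot−RpY) − (k2b + k2c + k4)·RpY

Assumptions: substrate bound in a complex is degraded with the same rate
constant as the matching free form (k3 for R/RX, k4 for Rp/RpY), the enzyme
being released intact and recycled; only the equal-rate case is implemented
— differing complex stabilities are a known unknown and out of scope. Free
enzyme is the algebraic quantity Xtot − RX (resp. Ytot − RpY), never a
state variable, so enzyme conservation holds identically. Degrading a
complex removes substrate only; no free substrate is returned.

## Parameters

All quantities are in arbitrary concentration/time units; no unit layer is
provided. Defaults (MM model): k0 = 1, k1 = k2 = 10, Km1 = Km2 = 10,
k3 = k4 = 0.01, Y = 1, X = 0. The turnover constants are 1/100 of the
pseudo-first-order modification rates k1/Km1 and k2/Km2, encoding the
two-orders-of-magnitude separation between modification (seconds–minutes)
and protein half-lives (hours). Full-model defaults k1f = k2f = 10,
k1b = k2b = 90, k1c = k2c = 10 reproduce the MM Michaelis constants through
the apparent Km = (kb + kc)/kf = 10, which makes the two variants directly
comparable; `apparent_km` exposes this mapping. The stability contrast that
drives most results is the ratio k4/k3: k4 < k3 means the modification
stabilizes the substrate, k4 > k3 destabilizes it.

Parameter records are immutable; scenario overrides build new records, so
scans can never contaminate each other.

## Steady states

Dose–response points are steady states reachable from the basal state (the
X = 0 steady state R = k0/k3, all modified species zero). The solver
reduces each algebraic system before root finding:

* MM model: the turnover balance k0 = k3·R + k4·Rp eliminates R, leaving a
  scalar monotone equation in Rp on [0, k0/k4] solved by Brent's method to
  near machine precision. The degenerate cases k3 = 0 or k4 = 0 are solved
  in closed form where a finite steady state exists and raise a structured
  error ("grows without bound") where it does not.
* Full model: at steady state the complex equations give exactly
  RX = Xtot·k1f·R/(k1f·R + k1b + k1c + k3) (and the RpY analogue), reducing
  the system to two equations in (R, Rp) solved with MINPACK hybr, warm
  started from the previous scan point. Convergence is judged by the actual
  derivative residual, not the solver's step-size diagnostics.
* Closed cycle (k0 = k3 = k4 = 0): the substrate total is conserved and
  must be supplied; the flux balance is again a bracketed scalar equation.

A solution is accepted when max |dy/dt| ≤ 1e-8 (derivative units);
otherwise the solver falls back to stiff integration (LSODA, rtol 1e-9,
atol 1e-12 — rate constants span 1e-3 to 1e3) over doubling time horizons
until max |dy/dt| / max(state, 1) < 1e-10, which selects the biologically
reachable branch by construction. The tight tolerances matter because the
metrics finite-difference the curves on a 1% grid, amplifying solver noise
roughly 100-fold. Time courses use the same integrator and tolerances.

## Dose–response protocol

Dose grids are geometric: lower·(1 + s/100)^i truncated at the upper bound,
with s = 1% by default. The relative increment was chosen (over an additive
one) because the curves are analysed on log axes and the LRC is a log–log
derivative; a geometric grid makes the finite-difference stencil uniform in
log-dose. Default ranges: kinase (X/Xtot) and synthesis (k0) axes span
[1e-2, 1e2]. Because large Michaelis constants push the transition region
to arbitrarily high kinase levels, `scan_until_saturated` extends the upper
bound tenfold at a time until the chosen readout passes the plateau check;
the large-Km and full-model fold-rise results use this extension (reaching
upper bounds near 1e5 and 1e4 respectively).

The basal reference (background) is the response at axis value 0 when the
dose axis is the kinase level, and the response at the grid's lower bound
for other axes (recorded in the curve metadata).

## Ultrasensitivity metrics

* **n_H** = ln 81 / ln(X_90/X_10). The response is first mapped to
  f = (r − background)/(plateau − background), which rises 0 → 1 for both
  stimulatory and inhibitory curves (for the latter the response is
  measured as the decrease from basal — the only convention that yields the
  expected negative n_H for R). X_10 and X_90 are located by monotone
  piecewise-linear interpolation in (log dose, f); on a 1% grid
  higher-order interpolation is unnecessary. n_H is signed by the direction
  of the response.
* **LRC** is estimated by centered finite differences of ln r against
  ln D (one-sided at the endpoints, `numpy.gradient`); responses below
  1e-12 are masked. Spline or smoothing estimators were rejected to avoid
  smoothing-parameter choices; grid-refinement stability is itself a tested
  property (halving the step changes n_H and |LRC|max by < 0.5%).
* **Plateau check**: a readout is saturated when its change over the last
  half-decade of doses is below 1% of its total swing over the scan.
  Normalizing by the swing (rather than by the local value) lets inhibitory
  curves that decay toward zero saturate, while responses that keep growing
  (the synthesis-driven R and Rtot curves) are correctly flagged as
  non-saturating. The 1% level cleanly separates the two regimes: the
  saturating curves here fall below 0.3%, the non-saturating ones stay
  above 10%.
* Undefined metrics (non-saturating or nonmonotonic curves, flat curves)
  are values-with-flags, not exceptions, so scenario tables can contain
  "not evaluated" cells.

n_H needs both crossings inside the scanned range and a genuine plateau;
|LRC|max is reported regardless. Ties in |LRC| break toward the lower dose.

## Scenarios and outputs

`ScenarioConfig` validates model variant, overrides, axis and readouts
before any computation; at most one override may be list-valued and
produces one curve per value. Outputs are curve, LRC and metrics CSVs
(plain full-precision decimals, fixed column order: dose, R, Rp, Rtot_free,
total_substrate (full model), flux_k1..flux_k4) plus a JSON manifest with
all parameters, grid metadata and solver tolerances — sufficient to
regenerate every number, which a test verifies byte-for-byte. The pipeline
contains no randomness, so repeated runs are byte-identical.

`table3_summary` reports the direction of change of |LRC|max under tenfold
parameter variations ("up"/"down"/"-", with "-" meaning < 5% relative
change; a gain from an exactly flat base curve counts as "up"). The table
is silent on where each variation is anchored: kinase-axis k4 rows vary k4
from its default tenfold into the stated stability regime (0.01 → 0.001 and
0.01 → 0.1), mirroring the stability sweeps; synthesis-axis rows vary k4
within the regime (0.001 → 0.0001 and 0.1 → 1), since the default point
k3 = k4 belongs to neither regime and the k0-driven responses change
qualitatively across it.

## Design notes and limitations

* The models are monostable here, so warm-started and cold-started scans
  agree (tested); the scan machinery is not a bistability detector.
* In the MM model the steady-state relation k0 = k3·R + k4·Rp makes R, Rp
  and Rtot exact affine transforms of one another, so their |n_H| values
  coincide after background subtraction; they genuinely differ only in the
  full model or in LRC terms.
* Problem sizes: a default scan is ~930 steady states; the asymptote
  procedures (parameter tenfold per step until metrics change < 1%) use
  3–6 scans each, with adaptively extended ranges up to ~1900 points. The
  entire headline-results script runs in a few seconds on one CPU.
* Fixed-range scans truncate slowly-saturating curves: with Ytot = 100 and
  k4 = 0.001 the free-substrate minimum sits near Xtot ≈ 110 and the
  total-substrate plateau near Xtot ≈ 3e3, both beyond the default range —
  analyses of such regimes must use (and here do use) the adaptive
  extension.
* No parameter fitting, stochastic simulation, multi-substrate/shared-
  ligase models, or bistability/oscillation analysis; plotting helpers are
  a convenience layer with no influence on numeric outputs.
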