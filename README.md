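# ptmcycle

Steady-state analysis of covalent modification cycles with protein turnover.

## The problem

A covalent modification cycle (CMC) — e.g. a kinase X phosphorylating a
protein substrate R into Rp, opposed by a phosphatase Y — is a canonical
signal-amplifying motif: when the substrate saturates both enzymes, the
steady-state fraction of Rp switches sharply with kinase activity
(zero-order ultrasensitivity, the Goldbeter–Koshland mechanism). The
classical treatment holds total substrate constant, but real signaling
proteins are continuously synthesized and degraded, and the modification
itself often changes the substrate's stability (p53 is stabilized by
phosphorylation, BCL6 destabilized). `ptmcycle` is a small toolkit for
exploring what this turnover layer does to ultrasensitivity: when it erodes
the switch, when it creates one de novo, and when it produces qualitatively
new behavior such as nonmonotonic dose–responses of the free substrate.

It is aimed at systems-biology modelers who want reproducible steady-state
dose–response scans and ultrasensitivity metrics, from a library API or the
command line.

## Models and metrics

**MM model** (Michaelis–Menten rate laws, two ODEs):

    dR/dt  = k0 − k1·X·R/(Km1+R) + k2·Y·Rp/(Km2+Rp) − k3·R
    dRp/dt =      k1·X·R/(Km1+R) − k2·Y·Rp/(Km2+Rp) − k4·Rp

R is synthesized at rate k0 and degraded with rate constant k3; the modified
form Rp is degraded with k4, so k4 < k3 means the modification *stabilizes*
the protein and k4 > k3 *destabilizes* it. Defaults: k0=1, k1=k2=10,
Km1=Km2=10, k3=k4=0.01, Y=1 (arbitrary concentration/time units; turnover is
100-fold slower than modification, as for proteins with hour-scale
half-lives).

**Full model** (mass action, four ODEs) adds explicit enzyme–substrate
complexes RX and RpY with association/dissociation/catalysis constants
(k1f, k1b, k1c and k2f, k2b, k2c; apparent Km = (kb+kc)/kf = 10 at
defaults). Substrate in a complex is degraded at the same rate constant as
the matching free form and the enzyme is recycled intact. With substrate in
excess it reduces to the MM model; with enzymes at comparable levels it
additionally captures molecular titration.

**Metrics** of a steady-state dose–response curve r(D):

* Hill coefficient `n_H = ln 81 / ln(X_90/X_10)`, where X_10/X_90 produce
  10%/90% of the maximal response after subtracting the basal level
  (negative for inhibitory responses) — global steepness;
* local response coefficient `LRC = d ln r / d ln D`, whose extremum
  `|LRC|max` is the maximal amplification capacity — a curve is
  ultrasensitive where |LRC| > 1.

The two deliberately disagree on curves with large basal levels, and the
package reports both.

## Worked example

```python
from ptmcycle import MMParameters, DoseGrid, scan_dose_response, evaluate_curve

params = MMParameters()                      # baseline cycle, X is the dose
curve = scan_dose_response(params, "mm", DoseGrid("X", 1e-2, 1e2, 1.0))
for readout in ("R", "Rp"):
    m = evaluate_curve(curve, readout)
    print(f"{readout:>2}: n_H = {m.n_H:+.2f}  |LRC|max = {m.lrc_max_abs:.2f} "
          f"at X = {m.lrc_max_location:.2f}  saturated = {m.saturated}")

stab = scan_dose_response(params.with_(k4=0.001), "mm",
                          DoseGrid("X", 1e-2, 1e2, 1.0))
m = evaluate_curve(stab, "Rp")
print(f"stabilized Rp: n_H = {m.n_H:+.2f}  |LRC|max = {m.lrc_max_abs:.2f}  "
      f"plateau = {m.plateau:.0f}")
```

prints

```
 R: n_H = -3.52  |LRC|max = 3.06 at X = 1.20  saturated = True
Rp: n_H = +3.52  |LRC|max = 3.05 at X = 0.93  saturated = True
stabilized Rp: n_H = +5.91  |LRC|max = 10.59  plateau = 999
```

The baseline cycle is a sharp, symmetric switch (|n_H| = 3.52 for both
forms, local amplification ~3 peaking mid-curve). Stabilizing the modified
form tenfold (k4: 0.01 → 0.001) lets the substrate pool grow with the
signal, driving both enzymes deeper into saturation: the Rp plateau rises
tenfold to k0/k4 ≈ 1000 and amplification roughly triples.

The same scans are available from the shell:

```
ptmcycle dr-scan --model mm --set k4=0.001 --axis X --from 0.01 --to 100 \
    --step-pct 1 --readout Rp --out curve.csv
ptmcycle metrics --in curve.csv --readout Rp
ptmcycle scenario --name fig5_emergence --out results/
ptmcycle table3
```

Built-in scenarios (`ptmcycle scenario --name ...`, YAML examples under
`configs/`) cover the baseline cycle, stability sweeps in both model
variants, emergence of ultrasensitivity at high Michaelis constants,
synthesis-driven responses and the closed cycle without turnover. Each run
writes curve/LRC/metrics CSVs plus a JSON manifest from which every number
can be regenerated.

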