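# hemesam

Analysis toolkit for electron transport through **heme-binding peptide
self-assembled monolayers** (SAMs). Short helical peptides anchored to
gold through an N-terminal cysteine form ~3 nm monolayers; adding heme
(an iron metalloporphyrin that coordinates to histidine side chains)
raises the junction current density by roughly three orders of
magnitude. This package provides, for researchers working with such
molecular-junction and monolayer data, the full computational chain
behind that kind of study:

* **Single-level transport models.** Hopping current from Marcus
  electrode kinetics: the electrode-to-level rate is

  `R = (γ/ħ) (4πλkT)^(-1/2) ∫ dE f(E, μ) exp(-(ε₀ + λ - E)²/4λkT)`

  with level offset ε₀ = Δε, reorganization energy λ, coupling γ and the
  bias divided by a fraction η between the contacts; the steady-state
  one-level master equation combines the forward and backward rates at
  both electrodes (at large bias it reduces to the series form
  `I = q R_in^l R_out^r / (R_in^l + R_out^r)`). Tunneling current from
  the Landauer formula,
  `I = (2q/h) ∫ T(E) [f(E, μ_l) - f(E, μ_r)] dE` with a Lorentzian
  transmission `T(E) = γ_l γ_r / ((E - Δε)² + Γ²)`, `Γ = (γ_l + γ_r)/2`.
* **J–V ensemble analysis.** Median/quartile summaries of log₁₀|J| over
  scans, log-space least-squares fits of both models, AIC mechanism
  selection, the current-spread heuristic (hopping ensembles span far
  more decades), and enhancement-vs-heme-loading curves.
* **Binding titration.** Continuous two-segment regression of Soret
  (413 nm) absorbance vs hemin:peptide ratio; the breakpoint estimates
  the saturation binding stoichiometry (~0.4 per single histidine,
  ~0.9 for two), with bootstrap confidence intervals.
* **Surface metrology.** AFM scratch-step thickness by two-Gaussian
  height-histogram fits with plane detrending; XPS peak areas (linear or
  Shirley background) and the S 2p : Au 4f packing-density proxy;
  amide-I secondary-structure classification.
* **Height–density regression.** Weighted least squares of monolayer
  height on packing density and inverse prediction of density from a
  measured height, with delta-method uncertainty.
* **Coarse-grained heme permeation.** A 1-D overdamped Langevin model
  of heme infiltration along the membrane normal with a depth-increasing
  crowding barrier, reflecting walls, and reversible histidine
  coordination through a Morse potential — the sequence analogs PHH,
  PAH, PHA, PAA differ only in site depths.
* **Synthetic data + pipeline.** Seeded generators for every input the
  analyses consume, and a YAML-driven pipeline producing a consolidated
  JSON/Markdown report.

## Worked example

Fit both transport models to a synthetic 70-scan ensemble generated by
the hopping reference junction (`examples/mechanism_discrimination.py`):

```
hopping fit:   RMSE 0.0082 decades, AIC -376.5
  level offset 0.149 eV, lambda 0.303 eV, gamma_l 5.57e-03 eV
tunneling fit: RMSE 0.1309 decades, AIC -156.7
preferred mechanism: hopping (delta AIC -219.8)
```

The hopping fit recovers the generating energetics (level offset
0.15 eV, λ = 0.30 eV) to within a few percent and beats the tunneling
model by ΔAIC ≈ −220: the tunneling model cannot reproduce the
thermally broadened current rise. The other scripts in `examples/` walk
through the loading enhancement (≈909-fold at ratio 8, CI [813, 1016]),
titration breakpoints, AFM/XPS metrology (3.00 ± 0.01 nm, S:Au 0.0061),
the WLS height–density line and the permeation model; each prints its
numbers with a one-line interpretation.

A thin CLI mirrors the library (`hemesam summarize|fit|titration|
afm-thickness|xps-ratio|amide1|wls-height|permeate|run|make-synthetic`),
and `hemesam run --config pipeline_demo.yaml` executes the shipped
end-to-end demo.

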