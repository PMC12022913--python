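# Methods

This note documents the models, estimators and numerical choices behind
`hemesam`, what the synthetic-data generators do and do not emulate, and
the limits of what the test suite demonstrates.

## Single-level transport models

Both mechanisms treat the junction as one molecular level at energy
Δε above the common zero-bias Fermi level, coupled to a left and right
electrode with strengths γ_l, γ_r (eV). The applied bias V is divided
between the contacts: μ_l = +ηV, μ_r = −(1−η)V in eV, with η = 0.5 by
default (a symmetric drop; nothing in the data constrains η, so it is
exposed but fixed during fitting). The level itself does not shift with
bias beyond this division; Stark shifts and image-charge corrections
are out of scope. All energies are carried in eV; conversion to SI
amperes happens only in the current expressions (CODATA constants in
`constants.py`).

**Hopping (Marcus electrode kinetics).** The electrode-to-level rate is
the Marcus–Hush–Chidsey expression: a Gaussian kernel of width
√(4λkT) centred λ above (into the level) or below (out of the level)
the level energy, integrated against the electrode's Fermi
distribution, scaled by γ/ħ. These rates satisfy detailed balance,
which a test verifies directly. The current comes from the steady state
of the one-level master equation with all four rates (in/out at each
contact):

    P = R_in/(R_in+R_out),   I = q (R_out^r P − R_in^r (1−P)).

The four-rate form is what guarantees I(0) = 0 exactly; when the
backward rates are negligible (|eV| a few kT beyond the activated
regime) it reduces to the familiar two-rate series expression
q R_in^l R_out^r/(R_in^l + R_out^r), and a test pins that limit.

**Tunneling (Landauer).** Lorentzian transmission of half-width
Γ = (γ_l+γ_r)/2 centred at Δε, integrated between the Fermi windows,
spin degeneracy factor 2. Three evaluation routes: adaptive quadrature
(default), the arctangent antiderivative in the T→0 limit, and the
exact finite-T digamma closed form

    ∫ f(E,μ) Γ dE /((E−ε)²+Γ²) = π/2 − Im ψ(½ + (Γ + i(ε−μ))/2πkT),

which is vectorised and machine-accurate at any temperature; the test
suite checks all three against each other. The zero-T and finite-T
forms agree to 1e−5 only where kT ≪ Γ — at 1 K that means couplings
above ~10 meV; for weaker couplings the residual difference is real
physics (thermal smearing of the resonance edge), not quadrature error.

**Numerics.** Adaptive quadrature works on the dimensionless integrand
in the Gauss-substituted variable with the Fermi edge registered as a
breakpoint, and the integrand is rescaled to its probed maximum first:
deep-tail rates are exponentially small and a fixed absolute tolerance
would otherwise destroy their relative accuracy. The fast path used
inside fitting loops replaces the adaptive rule with a uniform
trapezoid on x ∈ [−12, 12] at spacing 0.05; for this analytic,
Gaussian-decaying integrand the trapezoid converges geometrically and
stays within ~1e−9 relative of the adaptive result up to λ = 2 eV at
room temperature (asserted in tests).

## J–V ensemble analysis

Junction scans disperse log-normally with occasional shorts, so
summaries are the median and 25–75 percentiles of log₁₀|J| per voltage;
exact zeros (e.g. the V = 0 point) are excluded from the quantiles and
counted as censored rather than dropped silently. Traces are aligned by
linear interpolation onto the first trace's grid, never extrapolated.

Fits minimise log₁₀|J| residuals of the median curve (currents span
decades; linear residuals would see only the largest values) by
trust-region least squares with couplings and λ on a log₁₀ scale,
bounds Δε ∈ [0.05, 1.5] eV, γ ∈ [10⁻⁴·⁵, 10⁻⁰·⁵] eV,
λ ∈ [0.1, 2] eV (reorganization energies below ~0.1 eV are not
physical for condensed-phase outer-sphere transfer), and a small
multistart grid over the level offset. Free parameters: 3 for
tunneling (Δε, γ_l, γ_r), 4 for hopping (adds λ); η is fixed. AIC uses
the Gaussian log-space likelihood, n ln(RSS/n) + 2k. Fitting the median
curve (rather than pooling scans) is the default; the scan-level
spread enters through the summary quantiles.

Because γ_l and γ_r enter off-resonant currents essentially through
their product, only the geometric mean √(γ_l γ_r) is sharply
identified; recovery statements are made for Δε and that mean. The
reference synthetic junctions place the hopping resonance well inside
the ±1 V sweep (Δε = 0.15 eV, λ = 0.3 eV, γ = 5 meV — a redox level
near the electrode Fermi energy in a dry, low-water environment) so
that the curve's activated rise and saturation pin all parameters; with
a far-off-resonance level the λ–γ likelihood direction is genuinely
flat and no fitter can resolve it. The tunneling reference sits
off-resonance at Δε = 0.4 eV with the same coupling.

The spread statistic is the 5–95 inter-quantile range of log₁₀|J|
across scans at a query voltage. Site-energy disorder of 0.05 eV SD
translates into ~1.5 decades of spread for the thermally activated
hopping ensemble but only ~0.6 decades for tunneling — the mechanism
heuristic the statistic serves.

The enhancement ratio is 10^(Δ median log₁₀|J|) at −1 V with an
interval from the quartile-based standard error of each median;
reciprocity ratio(a,b)·ratio(b,a) = 1 holds exactly. Loading curves
get an optional saturating Hill-type summary fit (plateau fold, half
saturation, Hill exponent bounded [0.5, 6]).

## Titration breakpoints

The two-segment model A(r) = b₀ + b₁r + b₂(r−c)₊ is continuous at the
breakpoint c (the data show a slope change, not a jump). For each
candidate c — midpoints of consecutive ratios plus 50 uniform points,
restricted so ≥2 points fall on each side — the linear coefficients are
solved in closed form; the best candidate is then refined by bounded
scalar minimisation within its bracketing interval, which is what makes
noiseless kinks exact to 1e−6 rather than grid-limited. Model selection
against a single line uses AIC with 4 vs 2 parameters (the breakpoint
counts as one); the RSS is floored at numerical-noise scale
(n·(1e−10·range)²) so that noiseless data resolve to the simpler
model. The confidence interval is a seeded pairs bootstrap (default
1000 resamples) solved in batched normal equations. Saturable specific
binding requires both the segmented preference and a *decreased* upper
slope; a linear series or an upward kink classifies as nonspecific.

## Surface metrology

**AFM thickness.** The map is plane-detrended by default (scanner tilt
is ubiquitous), with the plane fitted outside the scratch so the step
does not bias it. Thickness is the separation of the two modes of the
pooled height histogram from a two-Gaussian fit (80 bins), falling back
to the difference of region medians when the fit degenerates; the SE is
a pixel bootstrap of the region medians. With no scratch rectangle
given, the lowest-median window (size ¼ of each dimension) is used,
and an effectively unimodal histogram raises an error asking for an
explicit region rather than guessing.

**XPS.** Peak areas are background-subtracted trapezoids. The linear
background is anchored on strip averages (~5% of the window per end,
≥3 points) at their centroid energies — unbiased for a linear
background and robust to Poisson noise, where single-sample anchors
bias areas by several percent at realistic counting statistics. A
Shirley background (iterated to 1e−6 relative) is available. The S:Au
packing proxy integrates the full S 2p window, deliberately covering
both the gold-bound and disulfide doublet components. Negative net
areas are returned with a warning, not clipped. Absolute quantification
with sensitivity factors and attenuation modelling is out of scope.

**Amide I.** Helical: (1648, 1670] cm⁻¹; unordered/β: [1625, 1648].
The shared 1648 endpoint is assigned to the unordered class — a
declared tie rule, since the band limits overlap.

## Height–density regression

Weights are the inverse of the reported height variance per observation
(the variance of frame heights in the terminal simulation window; an
SEM-weighted variant would only rescale the weights uniformly if frame
counts are equal). Closed-form weighted normal equations give the line
and its parameter covariance assuming the weights are true inverse
variances — the generator contract. Inverse prediction uses the delta
method including the slope–intercept covariance and refuses slopes
within 3 SE of zero. The monolayer height estimator is the 98th
percentile of particle z minus the substrate plane — an upper-edge
measure insensitive to a few protruding chains; a density-threshold
alternative (highest bin above half the interior plateau density)
agrees within 0.1 nm on slab-like distributions and is kept as a
cross-check.

## Coarse-grained permeation model

The observables of interest are z-distributions over time, so the model
resolves only the membrane normal: a deliberate dimensional reduction.
Lateral crowding inside the monolayer becomes a piecewise-linear
barrier rising from 0 at the monolayer top (3 nm) to 4 kT at the
substrate. Both excluded-volume walls are reflecting boundaries at
z = 0 and the box top (6 nm). Particles are strictly independent — the
anti-aggregation control (heme–heme attraction switched off) made
structural — so the particle count is conserved exactly and trivially.

Histidine coordination is a Morse well D_e[(1−e^(−a(r−r_e)))²−1] on
r = |z − z_site| with defaults D_e = 6 kT, a = 20 nm⁻¹, r_e = 0. In
this 1-D coordinate the 3-D Fe–N bond length collapses into the site
position: a nonzero r_e would put a steep repulsive spike exactly at
the site (the repulsive branch at r = 0 scales like D_e e^(2a r_e)),
which both breaks the integrator and misrepresents the physics. Site
depths: PHH 2.5 and 1.0 nm, PAH 2.5, PHA 1.0, PAA none.

Dynamics are overdamped Langevin, z ← z + dtF/ζ + √(2kT dt/ζ)ξ, with
kT = ζ = 1 (so D = 1 nm²/time-unit), dt = 10⁻⁴ by default. Construction
rejects time steps whose maximal drift exceeds a quarter of the Morse
width, reporting a suggested dt. Each replica (default 3) draws from
its own seed-sequence stream; the Gaussian increments are pre-generated
in chunks so results do not depend on the compiled integrator's
internals, and every seeded run is byte-identical. Times are reported
in simulation units only — no mapping to experimental hours or
atomistic microseconds is claimed; the separation between those scales
is many orders of magnitude.

Bond bookkeeping is hysteretic: a free particle binds an unoccupied
site (one heme per histidine, first come) when |z − z_site| < 0.3 nm
and releases beyond 0.5 nm, which suppresses chattering in event
counts. Profiles are time-windowed z-histograms averaged over replicas
(mean ± SD, counts per frame summing to the particle number);
nonspecific contacts count in-slab particles not bound to any site.

Verification leans on statistical mechanics rather than trajectories:
long-run z-densities must match exp(−U/kT)/Z from independent
quadrature (total-variation distance < 0.05 at the reference sampling),
positional site occupancy matches the two-state Boltzmann ratio within
Monte-Carlo error, formation and rupture counts balance at equilibrium,
and equilibrium sampling tests thin frames past the slowest diffusive
relaxation (~L²/π²D) before applying distributional tests — frame-level
samples are strongly autocorrelated and would otherwise invalidate the
p-values. Terminal bound fractions increase with well depth only in an
unsaturated regime (few hemes per site); with 30 hemes competing for
one site the occupancy pins at 1 for any plausible depth, so the
monotonicity check deliberately uses 5 hemes.

## Synthetic data: what it does and does not emulate

Generators draw from named substreams of one master seed (seed sequence
keyed by a CRC of the generator name), so stages are independently
reproducible. Noise models are the simplest consistent with how the
data present: log-normal scan dispersion with a scan-level offset
(SD = the quoted noise, in decades) plus pointwise noise (variance a
fixed fraction, 0.25, of the scan variance); Gaussian absorbance,
roughness and height noise; Poisson X-ray counts. Study conditions
follow the protocol scale: 70 scans per ensemble, ±1 V sweeps, loading
ratios {0, 0.5, 1, 2, 4, 8} with a 1000-fold saturating multiplier,
titration designs of 12 points with ~1% of dynamic-range noise,
10–30 chains per 10×10 nm cell with variance decreasing in density,
30 hemes over 3 replicas.

Not emulated: instrument artifacts (EGaIn oxide layers, AFM tip
convolution, XPS charging), temperature-dependent transport protocols,
spectral deconvolution of Soret shifts, peptide internal dynamics or
explicit solvent in the permeation model. Passing tests therefore
demonstrate that the estimators recover the truth of *these* idealised
generating processes at the stated noise — they do not certify accuracy
against systematic errors real instruments add.

## Problem sizes

The default test and acceptance runs use 70-scan ensembles (50–100
replicate ensembles in the simulation studies), 1000-resample
bootstraps (500 in the replicated coverage studies), 128×128 height
maps, and permeation runs of 0.8–1.5×10⁵ steps with 3 replicas — sizes
chosen so the full suite completes in a few minutes while leaving the
statistical margins (≥90–95% pass fractions) far from their thresholds.

## Known limitations

* Individual couplings γ_l, γ_r are only weakly identified from J–V
  shape off resonance; report √(γ_l γ_r).
* The AFM auto-detector assumes one rectangular scratch well inside
  the field; exotic scratch geometries need an explicit region.
* The permeation model's barrier and Morse parameters are order-of-
  magnitude choices that produce reversible binding on simulable
  scales; they are not calibrated to any specific force field.
* AIC-based mechanism selection assumes the median curve's residuals
  are approximately Gaussian in log space; heavy contamination (many
  shorted scans) should be screened beforehand.
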