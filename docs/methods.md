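# Methods

## Scope and model

`polydfs` analyses constant-velocity retraction experiments in which a
semiflexible polymer tethers an AFM tip to a bond on a surface. Three
ingredients define the model:

1. **Tether mechanics** — the worm-like chain (WLC) interpolation
   formula relates force to extension through the apparent persistence
   length `l_app` and contour length `L`. `l_app = l_p/N` for `N`
   identical chains sharing the load, which is what makes the fitted
   `l_app` a chain counter and the basis of single-molecule selection.
   The formula is used exactly as written (no stretch-modulus or
   higher-order corrections).
2. **Bond kinetics** — a single barrier with Bell force dependence,
   `k_u(f) = k_off·exp(f·x_t/k_BT)`. The mean rupture force at loading
   rate `r` is `⟨f⟩ = f_eq + f_β e^{1/R} E1(1/R)`,
   `R = r/(k_u(f_eq) f_β)`; this expression is exact for rupture under
   a constant loading rate starting from zero force (verified in the
   tests against quadrature of the survival integral).
3. **Equilibrium thermodynamics** — the plateau force `f_eq` maps to an
   adhesion free energy per length `γ_adh = (k_BT/b)·ln(4π sinh y / y)`
   with `y = f_eq b/k_BT`, `b = 2 l_p`, and to a per-monomer binding
   free energy `ΔG_bu = γ_adh·l_mono`. The exact expression is the
   default; the strong-binding shortcut `γ_adh ≈ f_eq` is reported
   alongside with its relative deviation. Note that the relative gap
   `|ln(2π/y)|/y` is not monotone — it peaks near `y = 2πe ≈ 17` at
   about 6% and only falls below 5% beyond `y ≈ 40`. ΔG_bu is reported
   as a positive stabilisation energy.

Units are fixed package-wide: pN, nm, s, pN·nm, K;
`k_B = 0.01380649 pN·nm/K` exactly, default temperature 293.15 K
(20 °C), giving `k_BT = 4.0474 pN·nm`.

## Numerical choices

- **WLC inversion** `x(f)`: Brent root bracketing on
  `[0, (1−10⁻¹²)L]`, absolute tolerance `10⁻¹⁰·L`. The force is
  strictly monotone on the bracket, so convergence is guaranteed.
- **Stable kernel** `g(z) = e^z E1(z)`: direct product for `z ≤ 30`,
  modified-Lentz continued fraction above (the two branches agree to
  `10⁻¹²` at the switch point). This keeps the mean-force model usable
  from the deep equilibrium regime (`1/R ~ 10⁶`) to the deep kinetic
  regime without overflow.
- **Spectrum fit**: weighted least squares (weights `1/SEM²` when every
  point carries one) in `(f_eq, log₁₀ x_t, log₁₀ k_off)`, bounds
  `f_eq ∈ [0, max⟨f⟩]`, `x_t ∈ [10⁻³, 10²] nm`,
  `k_off ∈ [10⁻⁸, 10⁴] /s`. The model is stiff in `k_off`, so the fit
  multi-starts: `f_eq` from the smallest mean force, `x_t` from the
  force-vs-ln(rate) slope over the upper half of rates, `k_off` over a
  log grid. Uncertainties come from the Jacobian covariance at the
  optimum (95% intervals); a point-bootstrap is available via
  `n_bootstrap`. Fits need ≥ 4 points and warn below 1.5 decades of
  rate span.
- **Monte Carlo stepping**: the per-step rule `P_u = k_u(f)·Δt > ξ` is
  implemented literally (uniform draws each step, vectorised in
  chunks); a Δt-robust variant `P_u = 1 − exp(−k_uΔt)` sits behind
  `robust_probability` (default off). Per-velocity RNG substreams are
  spawned from one seed, so ensembles are reproducible and adding a
  velocity never perturbs the others. A run aborts with an explicit
  error if the tether reaches 0.9999·L unruptured, and warns when the
  per-step probability at rupture exceeds 0.1.
- **First-passage oracle**: survival integrated in force coordinates,
  `S(f) = exp(−∫ k_u/(vκ) df')` with κ the tether stiffness; the grid
  is extended internally down to zero force so no hazard is missed, and
  a coverage warning fires if more than 10⁻³ of the mass lies outside
  the requested grid.

## Curve processing

The detection criterion (the instrument literature fixes none) is: a
force decrease of at least 5σ within ≤ 3 samples, starting from a force
at least 5σ above baseline, whose following five samples stay (in
median) 4σ below the pre-drop force; the last such drop is the terminal
rupture and the pre-drop force is `f_r`. The baseline is the median of
the final 10% of samples and σ = 1.4826·MAD of that tail unless
supplied. The two sustained-drop guards keep the false-positive rate of
the bare pair-difference test negligible (a lone noise spike otherwise
steals "last rupture" roughly once per few hundred noisy curves). The
flip side is a detection floor: ruptures below ≈ 5σ (25 pN at the
default 5 pN noise) are unmeasurable, so retraction speeds should be
chosen to keep rupture forces comfortably above it — the slowest group
in the bundled end-to-end studies is set by the rule "mean rupture
force ≳ 2× the detection floor".

The last-event WLC fit spans from the previous rupture (or the force
onset, the last sample below 3σ) to the rupture index, needs ≥ 8
samples, and fits `(l_app, L)` with bounds `l_app ∈ [0.01, 100] nm`,
`L ∈ (x_max, 10⁴·x_max]`, multi-starting over contour-length seeds.
Noiseless segments recover parameters to < 1%; at 5 pN noise the median
`l_app` error on 200-sample segments is below 1.5%.

Per-event loading rate defaults to the slope of a linear fit to `f(t)`
over the last 10% of pre-rupture samples (≥ 8), matching the
operational definition "dF/dt from the force–time trace"; the analytic
route `r = v·κ(x(f_r))` is available (`rate_method="analytic"`) and is
exact for simulated events. The windowed slope reads below the
instantaneous rate wherever the stiffness varies across the window —
a few percent at small extension, tens of percent near full extension.

Filtering keeps events with
`0.7·l_p ≤ l_app ≤ 2.0·l_p` (both fractions configurable; the
literature says only "near the single-polymer persistence length").
With `l_app = l_p/N` scattered by 10%, this keeps > 90% of N = 1 and
< 5% of N ≥ 2 events. Spectrum points are arithmetic means of `r` and
`f_r` per recorded nominal velocity (no clustering; the protocol sets
discrete speeds), with the SEM of `f_r`; groups under 5 events are
flagged.

## Synthetic data generator

`GeneratorConfig` emulates the acquisition protocol: seven speeds
log-spaced over 5 nm/s–10 μm/s, speed changed every five curves, 100
curves per speed (≥ 700 curves per dataset). Each curve draws `N`
chains (default mostly 1, occasionally up to 5), per-chain contour
lengths (default lognormal, median 150 nm, σ_ln 0.3 — polysaccharides
are polydisperse), and ruptures each chain independently by inverting
its continuous cumulative Bell hazard along the pull (the Δt → 0 limit
of per-step thinning, which keeps 30-second slow pulls exact without
microsecond stepping). White Gaussian force noise (default 5 pN) and a
linear baseline drift (default 2 pN per curve) are added; curves are
recorded at 10 kHz but decimated to at most 4096 samples, mimicking an
instrument's fixed points-per-curve. Defaults for the bond are
`k_off = 0.5 /s`, `x_t = 0.3 nm`, `l_p = 0.4 nm` (typical
polysaccharide scale).

What the generator does *not* emulate: 1/f and instrument-resonance
noise, contact-region adhesion peaks, cantilever-spring compliance in
series with the tether, rebinding, and tip chemistry. Passing the
end-to-end tests therefore demonstrates the pipeline's correctness on
idealised curves, not robustness to every artefact of real data.

## Known limitation: k_off under variable-rate loading

The mean-force model assumes a constant loading rate, but a WLC tether
loads the bond at a rate that grows roughly as `f^{3/2}` along the
pull. Pairing the mean rupture force with the mean *at-rupture* rate
therefore overstates the rate the bond actually experienced, and the
fitted `k_off` — exponentially sensitive to that pairing — comes out
high by ~+50% even deep in the kinetic regime (and up to ~3× at
moderate rates); the windowed numerical dF/dt instead reads low and
drags `k_off` the other way (−30% to −50% under the bundled end-to-end
conditions). Deterministic oracle-mean scans across
`x_t ∈ [0.2, 2] nm`, `k_off ∈ [10⁻³, 1] /s` show no regime or window
choice that removes the bias for both parameters at once. In contrast,
`x_t` (the slope of force vs ln rate) is robust, recovering within
5–20% everywhere scanned, and the mean *force* itself agrees with the
constant-rate model to within 2% deep in the kinetic regime. Fitted
`k_off` values from this protocol should accordingly be read as
order-of-magnitude estimates unless the loading-rate variation across
the rupture window is independently shown to be small.

The irreversible simulator and generator produce no equilibrium
plateau, so `f_eq` recovery is validated only on spectra generated from
the closed-form model (where all three parameters return to 0.1%).

## Problem sizes

The bundled studies use: 300 events/velocity × 4 velocities for the
standard Monte Carlo ensemble; 2000 events for distributional checks
(KS against the first-passage oracle, exponential-limit mean); 150
curves/velocity × 5 velocities (geomspace 0.2–20 μm/s) for the
end-to-end recovery study; 100 curves for two-sample fidelity checks.
These sizes put Monte Carlo standard errors well below the tolerances
they are checked against.
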