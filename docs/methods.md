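# Methods

## Forward model

Skin is treated as a semi-infinite homogeneous solid, initially at the
uniform baseline temperature T₀, heated through a Dirichlet boundary at the
surface.  For a constant surface temperature T_s the temperature at depth x
after time t is the first-order Henriques solution

    T(x, t) = T₀ + (T_s − T₀) · erfc( x / (2√(αt)) ),

with α = k/(ρc) the thermal diffusivity (conductivity k, density ρ, specific
heat c).  Because depth and diffusivity enter only through the combination
γ = x/(2√α) (units s^½), γ is the natural inference coordinate; physical
depth is recovered afterwards as D = 2γ√α.

**Diffusivity conventions.**  Two bookkeeping conventions are supported
behind one flag.  Under `standard`, α = k/(ρc) and the heat equation reads
∂T/∂t = α ∂²T/∂x².  Under `paper_sqrt` (the default), α = √(k/(ρc)) and the
equation reads ∂T/∂t = α² ∂²T/∂x².  These describe identical physics: the
effective diffusivity entering every temperature and depth formula is k/(ρc)
either way, so estimates are convention-invariant.  The square-root form is
kept only because parts of the bio-heat literature quote diffusivity that
way; `alpha_from_krc` returns the literal value per convention and
`effective_diffusivity` maps it to k/(ρc).

**Time-varying stimuli.**  Ramped stimuli are handled quasi-statically:
the erfc expression is evaluated with the instantaneous surface temperature.
This is exact for steps and accurate when conduction to the receptor depth is
fast relative to the ramp.  A finite-difference solver of the full diffusion
PDE (explicit scheme, stability-checked, far boundary at ≥8 diffusion
lengths) quantifies the error; it is used only as a test oracle.  Measured
against it on the 16 s ramp, the quasi-static temperature at depth is within
5 % of the instantaneous rise for γ ≤ 0.05 s^½ (t ≥ 2 s) and the error grows
roughly linearly with γ (about 15 % of the rise at γ = 0.2, about 30 % at
γ = 0.5 early in the ramp).  Two consequences are worth noting: (i) the
simulator and all estimators share this approximation, so parameter-recovery
results validate the inference machinery, not the quasi-static step itself;
(ii) under quasi-static evaluation the temperature at depth during the hold
phase depends only on elapsed time and the (common) hold temperature, so two
stimuli whose crossings both fall in the hold produce *identical* consistency
curves.  The classical estimator treats such pairs as uninformative rather
than as intersections.

**Threshold-crossing times.**  t*(T, γ) is the first time the quasi-static
temperature at depth reaches T: located by scanning a grid (trace samples
plus geometric refinement near onset, where erfc varies fastest) and refined
by Brent's method to 1e−9 s.  "Never crossed within the trace" is an explicit
sentinel (`inf`), not an exception, because the likelihood must handle such
parameter regions.  Batched variants interpolate crossings linearly on the
scan grid (~millisecond accuracy), which suffices for likelihood surfaces;
scalar refinement is used wherever microsecond accuracy matters.

## Classical intersection method

For stimulus i with latency τᵢ, every consistent (γ, T) pair lies on the
curve T(γ) = T₀ + (T_s(τᵢ) − T₀)·erfc(γ/√τᵢ).  Curves are evaluated on a
2000-point geometric γ grid spanning depths to 5 mm, pairwise crossings are
located by sign change and refined with a root finder, and ties at the
common T₀ asymptote (erfc underflow at large γ) are rejected as
non-intersections.  Outcomes:

- `single` — all pairwise intersections exist and coincide within
  (0.2 °C, 0.02 mm); estimate = mean of the points.
- `triangle` — three stimuli, all three intersections exist with diameter
  within (1.0 °C, 0.1 mm); estimate = centroid.  The triangle tolerance is
  deliberately looser than the coincidence tolerance, otherwise the two
  outcomes would be indistinguishable; both are configurable.
- `partial` — exactly one pairwise intersection; it is reported as a
  provisional point, not as a final estimate.
- `none` — anything else (including widely spread intersections).

## Delay-model maximum likelihood

Latencies decompose as τᵢ = t*ᵢ(T, γ) + Δᵢ with Δᵢ ≥ 0 i.i.d.
Exponential(λ).  The log likelihood is Σᵢ[log λ − λΔᵢ], −∞ wherever any
delay is negative or a threshold is never crossed.  λ defaults to 1 and is a
configuration constant; it rescales the objective monotonically and does not
move the optimizer.

Maximizing the likelihood is minimizing the total delay, and every t*ᵢ is
strictly increasing in γ, so the optimum lies on the feasibility boundary
where the smallest delay is exactly zero.  For monotone (ramp/step) stimuli
the boundary depth at threshold T has the closed form
γ_b(T) = minᵢ √τᵢ·erfcinv((T − T₀)/(T_s(τᵢ) − T₀)), reducing the fit to one
dimension: a dense 400-point grid in T over the feasible range
(T₀, minᵢ max_{t≤τᵢ} T_s(t)], followed by bounded Brent refinement (xatol
1e−7 °C) of the best grid cell.  Ties resolve toward smaller γ.  Non-monotone
traces fall back to bisection for the boundary depth.  An empty feasible
range (e.g. a spike during a flat baseline segment) returns a structured
failure with diagnostics instead of raising.

The estimator is deterministic, matches the classical solution to <0.02 °C
with sub-millisecond delays on noise-free data, and dominates dense
brute-force likelihood grids (asserted in tests).  Note its sampling
behavior under heavy delay noise: with only three stimuli and mean delays of
1 s the boundary attracts the fit, biasing γ upward (deeper) and T downward —
the same pathology that motivates the outlier-rejection layer, which the
paper-level validation reproduces (see "Validation" below).

## Priors and depth conversion

- Threshold: Normal(38, 2) °C.
- Depth: Beta(4.75, 2.25) scaled to [0, D_max]; D_max defaults to 600 μm,
  covering reported C-fiber ending depths of 20–570 μm.  The mode sits at
  0.75·D_max with the heavier tail toward zero.  D_max is an assumption
  exposed in configuration, and Uniform and Weibull alternatives are
  available for sensitivity analysis (shape 2, scale 350 μm — arbitrary but
  spanning the same range).
- Thermal parameters: k ~ U(0.05, 0.14) W/(m·K), ρ ~ U(1116, 1200) kg/m³,
  c ~ U(700, 950) J/(kg·K).

The γ prior induced by these has no closed form; it is approximated by a
Gaussian mixture fitted by EM to Monte-Carlo samples, with the component
count chosen by BIC over 1–5 (recorded in the result's metadata; 3 is
selected at the default 10⁵ samples, and can be forced).  γ → depth
conversion averages D = 2γ√(k/(ρc)) over thermal-parameter draws (10⁵ by
default; the Monte-Carlo standard error scales as n^{−1/2} and is ~0.1 μm at
the default size, so larger sample counts buy nothing at the reported
precision).  If an estimated depth exceeds the epidermal thickness, a
two-layer decomposition γ = D_e/(2√α_e) + D_d/(2√α_d) solves for the dermal
remainder, falling back to the single-layer reading when the remainder is
negative.

## Model selection

Candidates are the full model M₁ and the single-stimulus exclusions M₂,ᵢ
(multi-stimulus exclusion is deliberately not enumerated; with three stimuli
the retained pair is the minimum that still defines an intersection).  Each
evidence is the likelihood integrated against p(T)·p(γ) by the trapezoidal
rule on a 150×150 grid over (T₀, T_max] × [0, γ_max], γ_max defaulting to
twice an assumed 1 mm skin thickness.  The likelihood is discontinuous
across the feasibility boundary and maximal on it, which would make plain
trapezoid first-order inaccurate; each threshold slice therefore appends the
exact boundary depth γ_b(T) as an integration node, restoring second-order
behavior (halving the spacing moves the evidence by <1 %).  Per-stimulus
crossing-time lookup tables (400×320, bilinear interpolation) keep the grid
evaluation fast; log terms are max-shifted before exponentiation.

The excluded spike is treated as a fixed observation (Dirac likelihood
component), so its factor separates: the expectation of λ_s·exp(−λ_s·τᵢ)
under the λ_s prior.  The spontaneous-rate prior is Uniform(0.01, 2) s⁻¹ —
an assumption (sparse spontaneous C-fiber discharge), flagged in the output
metadata, integrated by 200-point trapezoid, and covered by the sensitivity
tests.  Evidences are normalized to weights summing to 1; the maximum is
selected, and the reported parameters are the MLE under the retained
stimuli (posterior summaries are deliberately not used, keeping the three
methods comparable).

## Simulator

`make_protocol` reproduces the stimulation protocol: linear ramps 32→48 °C
over 16, 4 and 2 s, each followed by a 10 s hold (traces sampled at 20 ms).
For each stimulus the simulator computes t* under the same quasi-static
model, adds an Exponential(delay_rate) delay, and (if an outlier process is
active) races it against an independent Exponential(outlier_rate)
spontaneous spike time — the earlier event is recorded and flagged.  The
race is the simplest generative reading of "not triggered by the stimulus";
an `inject_outlier` helper instead *replaces* one latency for controlled
detection studies.  Delay draws that would land beyond the trace end are
redrawn, i.e. recorded delays follow a truncated exponential; cohort draws
reject (depth, threshold) pairs whose threshold is not crossed at least 1 s
before every trace ends, so every simulated neuron is responsive to all
stimuli.  All randomness flows from explicit seeds.

What the simulator does **not** emulate: spike-generation biophysics,
adaptation or fatigue across the stimulus sequence, multi-layer skin with
distinct layer diffusivities, trial-to-trial threshold drift, and
measurement noise on the surface-temperature traces.  Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
stated generative model, not robustness to real-tissue deviations from it.

## Validation and problem sizes

The test suite validates, at sizes chosen to keep the full run within a few
minutes: the worked example (four step stimuli against a 0.3 mm / 38.8 °C
neuron; classical estimate correct to 0.1 °C and 0.01 mm); zero-delay
boundary consistency on 10 prior-drawn neurons; parameter recovery on 100
neurons per delay rate across rates {1, 10, 100} s⁻¹; outlier detection on
50 outlier/control pairs; and the oracle equivalences (PDE vs analytic step
solution within 1 %, MLE dominance over brute-force grids, prior properness,
evidence normalization).

Measured behavior worth recording: recovery error shrinks monotonically as
delays vanish, but at delay rate 1 s⁻¹ (mean delay 1 s, comparable to the
short-ramp crossing times) the three-stimulus MLE carries substantial bias —
median absolute errors ≈ 0.15 mm in depth and ≈ 0.7 °C in threshold under
the default priors.  This is a property of the estimator under heavy delay
noise (boundary attraction, three observations), not an optimization defect:
the fitted optimum dominates exhaustive likelihood grids, and the likelihood
at the truth is genuinely lower than at the fit.  The evidence layer is the
remedy: with one spontaneous outlier injected, the correct exclusion model
wins in well over 80 % of replicates and the normalized full-model weight
cleanly separates outlier neurons from clean controls.

## Known limitations

- The quasi-static forward model degrades with depth on fast ramps (see
  bound above); a full PDE-based likelihood would remove this at
  considerable cost.
- Evidence values depend on the assumed λ_s prior family and range; the
  selected model is insensitive across the tested alternatives, but the
  absolute weights are not.
- The classical tolerances (coincidence, triangle) are qualitative choices;
  cohort-level outcome counts shift with them.
- Recordings with all crossings in the hold phase carry little depth
  information (identical consistency curves); estimates there lean almost
  entirely on the priors.
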