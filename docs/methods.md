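# Methods

## The measurement problem

`fdgflux` quantifies myocardial and skeletal-muscle glucose metabolism from
dynamic [18F]FDG PET acquired under a slow constant-infusion protocol with a
mid-scan normoxia→hypoxia gas switch (21% → 12% inspired O₂). The subject
breathes room air for the first 15 minutes of a 60-minute scan; FDG is
infused at a constant rate throughout (10 mCi total, preceded by a small
line-priming bolus), and one-minute frames are reconstructed. The analysis
produces a net influx rate Ki and a glucose metabolic rate per tissue and
per gas condition, then group-level contrasts between term-born and
preterm-born cohorts.

## Kinetic model

The two-tissue (3-compartment) FDG model with plasma concentration Cp(t),
free tissue FDG Ce(t) and phosphorylated FDG-6-P Cm(t):

    dCe/dt = K1·Cp − (k2 + k3)·Ce + k4·Cm
    dCm/dt = k3·Ce − k4·Cm

Units are kBq/mL and minutes throughout; K1 in mL/mL/min, k2–k4 in 1/min.
k4 = 0 (irreversible trapping) by default — the fit windows are too short
to identify dephosphorylation — with a config switch to free it. The
macro-parameter of interest is the net influx rate

    Ki = K1·k3 / (k2 + k3)        [mL/mL/min]

and the glucose metabolic rate

    MRglc = Ki·[glc] / LC         [μmol/mL/min]

with [glc] the trapezoidal time-average of serum glucose over the condition
window (mg/dL ÷ 18.016 → μmol/mL) and lumped constant LC = 1.44
(myocardium) or 1.16 (skeletal muscle).

### Solution method

The system is linear, so it is solved by closed-form diagonalisation: the
two macro rates a₁ ≥ a₂ ≥ 0 are the eigenvalues of the rate matrix, and
Ce, Cm are linear combinations of exponential convolutions
E_λ(t) = ∫₀ᵗ e^(−λ(t−s)) Cp(s) ds. Both supported input representations
evaluate E_λ, ∫Cp and ∫∫Cp exactly: the parametric
bolus-plus-saturating-plateau form analytically, and measured (sampled)
curves by exact per-segment recursions over their piecewise-linear
representation. Modeled ROI signals are integrated over each frame interval
and divided by frame duration, matching the scanner's frame-integrating
measurement. Near-degenerate eigenvalue pairs (only possible with k4 > 0)
are nudged apart by one part in 10⁷. Accuracy against high-order adaptive
ODE integration is at the 1e−10 relative level (tested at 1e−6).

A condition change mid-scan is handled by re-solving from the switch time
with the compartment contents at the switch as the initial state, so tracer
accumulated before the switch is conserved.

### ROI model and spillover

Limited PET resolution mixes the myocardial and LV blood-pool signals. At
the ROI level this is modeled as mixing fractions rather than a
microvascular volume term:

    myocardium ROI:  M(t) = (1−α)·(Ce+Cm) + α·Cp
    blood-pool ROI:  B(t) = (1−β)·Cp + β·(Ce+Cm)

α, β ∈ [0, 1) subsume both resolution blurring and vascular fraction. For
the paraspinal-muscle ROI, which is remote from the cavity, spillover runs
only from blood into the muscle ROI (β ≡ 0). Whole-blood activity is used
as the plasma input (an optional multiplicative plasma/whole-blood
correction defaults to 1).

## TAC extraction

ROI masks are binary-eroded 3 iterations with the 6-connected
(face-adjacent) structuring element — a 3-voxel inward city-block margin —
before averaging, to limit partial-volume contamination; the connectivity
is configurable (26-connected available). An erosion that empties a mask is
an error reporting the surviving-voxel count per iteration. TAC values are
arithmetic means over surviving voxels per frame. Frames are assigned to a
condition window only when fully contained; a frame spanning a boundary is
dropped rather than split.

## Fitting

### Latent input and the joint myocardium/blood fit

The measured blood-pool TAC is itself spillover-contaminated, so the true
plasma curve is treated as latent with the parametric form

    Cp(t) = A·(1 − e^(−t/τ)) + D·t·e^(−t/λ)

(plateau A, saturation constant τ, bolus amplitude D, bolus constant λ).
The joint fit minimises the pooled squared residuals of the measured
myocardium and blood-pool TACs over the kinetic rates, both spillover
fractions and the four input parameters. The fitted parametric curve is the
spillover-corrected blood estimate, which then drives the skeletal-muscle
fit (K1, k2, k3 per condition, α; β fixed at 0).

### Condition handling

By default (`condition_mode="joint"`) the two condition windows are fitted
in a single model spanning the scan: transport (K1, k2), spillover (α, β)
and the input are shared, while the phosphorylation rate k3 takes separate
pre-switch and post-switch values, with compartment contents continuous at
the switch. The post-switch segment uses every frame from the gas switch
onward; the protocol's hypoxia window (default 25–60 min) remains the
reporting and glucose-averaging window. Rationale: at realistic noise the
15-minute pre-switch window alone cannot pin down the shared nuisance
parameters, and sequential per-window fits proved far less stable; sharing
them across the full curve anchors the per-condition k3 values. Two
alternatives remain available: `"continuation"` (sequential per-window
fits, hypoxia starting from the normoxia model state at the switch) and
`"independent"` (per-window fits with free initial amplitudes).

### Optimiser

Bounded nonlinear least squares (trust-region reflective,
`scipy.optimize.least_squares`) with bounds K1 ∈ [0, 2], k2 ∈ [10⁻³, 5],
k3 ∈ [0, 2], k4 ∈ [0, 0.1] (when freed), α, β ∈ [0, 0.8]; input amplitudes
bounded relative to the measured blood level, τ ∈ [1, 200] min,
λ ∈ [0.2, 10] min. Convergence tolerance 1e−10 on the relative SSE change.
The multistart is deterministic given the seed: one data-driven start
(plateau at the late blood level, mid-range kinetics), three structured
variants covering the normoxia/hypoxia k3 split, and scrambled-Sobol points
filling to 16 starts; all 16 are screened by a single residual evaluation
and the best 4 are polished. Best final SSE wins; ties break toward the
smaller parameter norm.

### Residual weighting

The generator's frame noise has SD proportional to frame activity, so the
default per-frame weighting is inverse-activity (approximate maximum
likelihood): weights 1/max(ref, 5% of peak), normalised to mean 1, where
`ref` is a 5-frame moving average of the measured TAC — weighting by the
raw noisy values would correlate weights with the noise and shrink the fit.
The myocardium and blood residual blocks are equally weighted. Uniform
weighting and a blood-block weight are configurable.

### Efflux regularisation

At realistic noise the likelihood admits a trapping alias: k2 → 0 makes the
free compartment itself behave irreversibly (Ce ≈ K1·∫Cp), fitting the data
as well as genuine phosphorylation while collapsing the formula Ki to 0.
Two weak penalty residuals guard the weakly-identified efflux rate, both
scaled by σ̂, the frame-noise level estimated from second differences of
the TACs (so both vanish for noiseless data and exact noiseless recovery is
untouched):

* a one-sided barrier `ridge_k2 · σ̂ · min(0, ln(k2/0.05))` that activates
  only below a physiological efflux floor of 0.05/min and suppresses the
  trapping alias;
* a weak symmetric prior `k2_prior · σ̂ · ln(k2/0.5)` centring k2 on a
  typical FDG efflux value, which counters the downward Ki shrinkage that
  the latent-input/spillover scale ridge otherwise induces.

Reported SSE and residuals always exclude the penalty terms; both weights
are configurable and 0 disables them.

### Identifiability guards

Fits refuse to run with ≤ 5 frames in a window, and the joint
myocardium/blood fit requires at least 8; identically-zero or non-finite
TACs are rejected as degenerate before optimisation.

## Group statistics

Per subject and tissue: Δrate = rate(hypoxia) − rate(normoxia), percent
change 100·Δ/rate(normoxia) (undefined when the normoxia rate is 0), and
ΔSpO₂ using the 55-minute measurement as the hypoxia value. The headline
group percent change is that of the group-mean rates (the ratio-of-means is
insensitive to per-subject input-scale errors, which cancel between
conditions); the mean of subject-level percent changes is available by
option but is heavy-tailed, since subject-level normoxia rates enter
denominators. Δrate-vs-ΔSpO₂ association is ordinary least squares with
Pearson R and a two-sided p from the t distribution on n−2 df, per group.
Mixed-effects modeling is deliberately out of scope: the tidy long-format
CSV (subject × tissue × condition) is the interface to external statistics
packages.

## Synthetic data generator

The generator emulates the acquisition end-to-end and exports ground truth
for every quantity it draws.

* Input: plateau from 10 mCi diluted in a nominal 5 L distribution volume
  (74 kBq/mL), τ = 20 min; bolus peak 25% of plateau, λ = 1.5 min.
* Tissue defaults: myocardium K1 = 0.6, k2 = 1.2, k3 = 0.0235 (Ki ≈ 0.0115
  mL/mL/min, i.e. a resting MMRglc ≈ 0.04 μmol/mL/min at 90 mg/dL — the
  dietary-suppression regime this protocol targets), α = 0.2, β = 0.1;
  skeletal muscle K1 = 0.1, k2 = 0.3, k3 = 0.02, α = 0.05.
* Hypoxia: at the gas switch k3 is rescaled so Ki changes by the group
  multiplier (myocardium 0.60 preterm / 0.75 term; skeletal muscle 0.48 /
  0.36), with compartment contents continuous across the switch. k3 is the
  lever because phosphorylation is the metabolic step; only the net Ki
  change matters for recovery tests.
* Serum: glucose 90 mg/dL, ramping from the switch to +5% (term) / +2%
  (preterm) at the 55-minute draw; lactate 1.0 mmol/L ramping +4% / +11%.
  Draws every 10 minutes plus the 55-minute draw.
* Noise: additive Gaussian per frame, SD = noise_cv × frame activity ×
  √(1 min / frame duration), independent across frames; noise_cv = 0.05.
  Post-reconstruction ROI-mean noise is approximately Gaussian with
  roughly activity-proportional SD; the √duration factor reflects count
  statistics (moot at the default equal 60-s frames).
* Cohorts: subject-level K1, k2, k3 drawn log-normally (CV 20%,
  mean-preserving) around the tissue defaults; default sizes 18 term / 28
  preterm. SpO₂ 98% at rest for both groups, falling to 85% (term) / 81%
  (preterm) at 55 min, with per-subject Gaussian jitter.
* Phantom: blood cylinder, concentric myocardial shell and two
  paraspinal blocks on a 48×48×24 grid of 3 mm voxels, carrying the pure
  (spillover-free) region curves; isotropic Gaussian blur of stated FWHM is
  the resolution/spillover surrogate, applied per frame, then voxel-level
  noise. Matching uneroded label masks are emitted.

What the generator does **not** emulate: cardiac and respiratory motion,
scanner-specific and anisotropic point-spread functions, sinogram-domain
(Poisson) noise and reconstruction artifacts, gradual physiological washin
of the hypoxic state (the simulated k3 switch is instantaneous at the gas
switch), plasma/whole-blood partitioning and metabolites, and inter-subject
variability of the input curve (all subjects share the protocol-determined
input). Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the stated noise model, not robustness to every
artifact of real cardiac PET.

## Statistical limits of per-condition Ki at study conditions

With the default (deliberately diet-suppressed) myocardial uptake, 5% frame
noise and a 15-minute pre-switch phase, the phosphorylated pool accumulated
under normoxia is only a few kBq/mL — a low-information regime. A local
Fisher-information analysis at the default parameters puts the per-subject
relative SD of the normoxia-phase Ki near 0.5 even for a maximum-likelihood
estimator with the model known exactly (the hypoxia-phase Ki, with 45
minutes of data, is near 0.15). Nonlinear least-squares point estimates in
this regime are also right-skewed: solutions with higher (k2, k3) can
genuinely attain the global minimum for a sizeable fraction of noise draws.
Group contrasts on n = 20 cohorts consequently carry a sampling SD of
several percentage points, and recovered percent decreases scatter
accordingly around the programmed effects; the package reports exactly what
the estimator produces, without post-hoc correction.

## Numerical choices and degenerate inputs

* Internal units fixed: kBq/mL, minutes, mg/dL at the serum boundary.
  Images are assumed decay-corrected to scan start by the reconstruction;
  no further decay handling is applied and the assumption is recorded in
  every run manifest.
* Glucose window averages interpolate the bounding samples at window edges;
  a single-sample series returns that sample; a window entirely outside the
  sampled range returns the nearest end value.
* Masks must be non-empty at construction and after erosion; label volumes
  must match the image grid exactly (no resampling is attempted).
* Frame timing must be strictly increasing and non-overlapping; a frame
  straddling the gas switch is an error for the generator and is dropped by
  window selection in the fitter.
* Multistart results are bit-reproducible for identical inputs and seed.

## Problem sizes

The shipped test suite and the acceptance script run simulation studies at
these sizes: the parameter-recovery surface uses a 3×3×3 grid of
(K1, k2, k3) with 20 noise replicates per point (540 fits of the full
60-frame scan); the effect-size recovery uses one simulated cohort of 20
subjects per birth group with every subject fitted end-to-end; the
regression-calibration check uses 1000 simulated null cohorts of 10
subjects; the digital phantom uses the default 48×48×24 grid over 60
frames.
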