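# Methods

`xcdyn` asks a single quantitative question of live-cell microscopy
data: does a nuclear RNA compartment (the Xist-coated X-chromosome
territory, "XC") physically exclude a diffusing protein such as RNA
polymerase II, or does the apparent depletion come from lost chromatin
binding? The package implements the three measurement channels that
answer it — FCS-calibrated concentration imaging, single-particle
tracking (SPT), and FRAP — plus a synthetic ground-truth generator so
that every estimator can be validated end to end without raw movies.

## Units and conventions

Lengths in μm, times in seconds, concentrations in nM. Frames are
0-based; the frame interval defaults to 5.477 ms and the pixel size to
0.106 μm. A localization at (x, y) belongs to pixel
`(row, col) = (floor(y/p), floor(x/p))` with the origin at the top-left
pixel corner; masks and trajectories are assumed co-registered under
this convention.

## Synthetic data generator

The generator (`xcdyn.simulate`) emulates the statistical structure the
analysis assumes, not the optics of a microscope.

**Trajectories.** Molecules perform 3D Brownian motion inside an
elliptical-cylinder nucleus: an ellipse in xy (default semi-axes
4 × 3 μm) and a reflecting slab of total depth 3 μm in z. Each molecule
is bound (D_bound, default 0.005 μm² s⁻¹) or free (D_free, default
3.8 μm² s⁻¹); the bound probability may differ between the XC and the
nucleoplasm, and first-order switching rates are available (0 = static
states). A molecule is localized only while |z| < dz/2 (dz = 0.7 μm);
observed positions add isotropic Gaussian localization error
(σ = 28 nm per coordinate). An out-of-focus frame ends the current
trajectory — there is no gap closing — and each maximal run of
consecutive detections of length ≥ 2 becomes one trajectory, as a
tracker links nothing from a single detection. Photobleaching is
geometric per frame with default probability 0.35, giving mean observed
tracks of ~3 localizations, typical of sparse photoactivation imaging
at full-power 1 ms excitation; activation is Poisson per frame. The XC
boundary can act as a partial barrier: each free-molecule step crossing
it is rejected with probability 1 − permeability (permeability 1 =
inert boundary, the regime the experimental evidence supports).

The generator does **not** model blinking photophysics, drift,
chromatic effects, anisotropic PSFs, heterogeneous chromatin density,
or localization-error correlations. Tests passing on it therefore show
that the estimators are correct under the stated model, not that the
model captures every property of real movies.

**FCS curves** are direct evaluations of the autocorrelation model
below on log-spaced lags plus iid Gaussian noise. **Calibration
stacks** invert the linear intensity–concentration map per voxel.
**FRAP traces** are simulated at the trace level: a plateau-recovery
model times global exponential acquisition bleaching, on a common
additive background shared by ROI, control and background traces (the
normalization subtracts a background estimate, so the generator must
include one for the correction to have something real to remove).

## FCS-calibrated imaging

The autocorrelation model is two-component anomalous diffusion with a
triplet-like blinking factor:

    G(τ) = (1 + T/(1−T)·e^(−τ/τ_T)) · (1/N) ·
           Σᵢ fᵢ (1 + (τ/τᵢ)^αᵢ)⁻¹ (1 + (τ/τᵢ)^αᵢ/κ²)^(−1/2)

fitted by bounded nonlinear least squares (lmfit), two optimizer runs —
the second from seed-perturbed initials — keeping the better solution.
One-component mode fixes f₁ = 1 (pure dye, freely diffusing control);
dye curves are truncated at lags ≤ 10 239 μs to avoid fitting the flat
tail. Any parameter can be held fixed; in practice κ and the triplet
are fixed when the data cannot constrain them — with all nine
parameters free the model is not identifiable and parameter recovery is
meaningless even on noiseless curves.

The confocal volume comes from pure-dye fits: w₀ = 2√(D_dye·τ_dye)
with D_dye = 521.46 μm² s⁻¹ (AF568 at 37 °C), V = π^{3/2}·κ·w₀³,
averaging w₀ and κ over all dye measurements of an experiment. Protein
diffusion coefficients are D = (w₀/2)²/τ, the *fastest* component
being the free fraction. Intensity calibration is ordinary least
squares of FCS concentration on background-corrected intensity,
established on freely diffusing control points only; the background is
the mean negative-control intensity. Per-region summaries report the
mean voxel concentration, region volume, a 95% normal-approximation CI
across voxels (spatial correlation between voxels is ignored — a
declared limitation), and the molecule count
C·10⁻⁹·N_A·V·10⁻¹⁵ (e.g. 207 nM over 9.34 μm³ → 1164 molecules).

## SPT statistics

**Jumps.** Displacements between frames n and n+dt for dt = 1…6 within
gap-free runs; at most 3 jumps per trajectory per dt (the earliest),
jumps > 2 μm discarded. **MSRD** is the mean single-frame jump length
per trajectory; > 0.2 μm classifies a trajectory free, < 0.1 μm bound.
**MSD** averages squared displacements over all (trajectory, start)
pairs; errors from 50 bootstrap resamples of 3000 trajectories. **VAC**
is ⟨v_n·v_{n+k}⟩/⟨|v|²⟩ on consecutive-frame displacement vectors.

**Angles.** For consecutive dt = 1 jump pairs with both lengths in
[0.2, 3] μm, the angle between jump vectors folded to [0°, 180°],
histogrammed in 10° bins. The forward/backward ratio divides window
counts by window width before taking the ratio — the default windows
(0–30° vs 160–180°) are 30° and 20° wide, so a raw count ratio would be
1.5 under isotropy; the density ratio is 1.0 under isotropy for any
windows and reduces to the count ratio for equal-width windows
(e.g. the alternative 150–180° backward window, which is exposed as an
option). Errors from 50 bootstrap resamples of the angle pairs.

**Flux.** A trajectory "enters" a region when a localization outside
is followed (first outside→inside transition between consecutive
localizations) by one inside; each trajectory counts once per region,
and only freely diffusing trajectories (MSRD > 0.2 μm) are scored.
Per-cell XC counts are compared against pooled shifted-control counts
with a two-sample two-sided Kolmogorov–Smirnov test. Note that on
count data the KS test is conservative: iid-Poisson simulations put
its true type-I rate near 3% at a nominal 5%, an intrinsic property of
ties, not of the p-value approximation.

**Control regions** are random shifted/rotated copies of the XC mask:
rotation uniform in [0°, 360°) about the XC centroid, centroid
translation uniform over the nuclear bounding box, re-rasterized by
*inverse* nearest-neighbor mapping (forward-mapping the pixel cloud
loses ~10% of pixels to rounding collisions and the resulting ragged
boundaries measurably inflate entering counts). A candidate is
accepted if (1) it lies entirely inside the nucleus, (2) its mean
Euclidean distance to the nuclear periphery (distance transform of the
nucleus mask, averaged over candidate pixels) is within ±50% of the
XC's, (3) nucleoli overlap ≤ 1% of its area, and (4) overlap with the
XC and each accepted control ≤ 10% of the respective areas; proposals
repeat until 10 controls or 500 000 iterations. Proposals are screened
in vectorized batches and every survivor is re-validated exactly.

Mask pairs taken before/after an acquisition are interpolated by
thresholding the linear blend of their signed Euclidean distance
transforms at zero — continuous, shape-aware, and exact at the
endpoints; trajectories are assigned with the mask interpolated at
their mid-time. Assignment rule "any": in-region iff ≥ 1 localization
inside; "none": out-region iff 0 inside.

**Two-state fit.** Jump lengths mix a bound and a free Rayleigh-type
component; with s = D·dt·Δt + σ²,

    CDF(r | dt) = [F_b·K(r; D_b) + (1−F_b)·Z(dt; D_f)·K(r; D_f)] /
                  [F_b + (1−F_b)·Z(dt; D_f)],   K = 1 − e^(−r²/4s)

fitted by least squares on empirical CDFs at dt = 1…6 stacked on one
shared r-grid (equal per-curve weight), with σ fixed at 28 nm and
bounds D_b ∈ [0, 0.02], D_f ∈ [0.1, 20] μm² s⁻¹. Z corrects for fast
molecules escaping the detection slab. Two implementations are
provided:

* `axial_escape_fraction` — the eigenfunction series for 1D diffusion
  in a slab with *continuously absorbing* walls from a uniform start
  (validated against a Brownian-bridge-corrected Monte Carlo to
  < 10⁻³);
* `detection_survival` (the fit's default) — the probability of being
  inside the window at each of the next dt *frame times*, computed by
  propagating the axial density (Gaussian step with reflection at the
  outer slab, truncation to the window at each frame).

The distinction matters: a tracker only checks detection at frame
times, so molecules that dip out of focus between frames and return
are *not* lost. The absorbing model underestimates the survival
(0.535 vs 0.77 at one 5.477 ms frame for D = 3.8), and using it in the
fit biases the bound fraction down by ~0.14 under the generator's own
conditions; the frame-wise survival removes that bias
(`z_correction="absorbing"` retains the absorbing variant for
comparison). A smaller negative bias (~0.03 on F_b) remains from the
3-jumps-per-trajectory cap, which truncates long bound tracks more
than short free ones; it shrinks as tracks get shorter and is within
the validation tolerance at the default bleaching rate. Bootstrap
errors: 50 resamples of 3000 trajectories, refitted from the point
estimate.

**Diffusion spectrum.** A deliberately simplified fixed-grid
estimator (not a posterior state-array inference): per trajectory the
sum of squared single-frame jumps is Gamma(shape = n jumps,
scale = 4(DΔt + σ²)); EM over a 40-point log-spaced D grid
(10⁻³…30 μm² s⁻¹) until the largest weight change < 10⁻⁶; weights are
then divided by the absorbing-slab escape factor and renormalized to
undo the defocalization bias.

**Delta method.** Concentration × fraction products carry variance
f²·var(C) + C²·var(f); 95% CI = ±1.96 sd.

## FRAP

Background and unbleached-control traces are replaced by least-squares
fits of A·e^(−kt) + C (offset included — the more general, nested
form; a raw-trace mode exists for diagnostics; a failed fit falls back
to a flat trace and is flagged). With prebleach means over all frames
before the bleach frame (default 80):

    Ic  = (ROI − bkg) / (⟨ROI⟩_pre − ⟨bkg⟩_pre)
    Icb = Ic / [(ctrl − bkg) / (⟨ctrl⟩_pre − ⟨bkg⟩_pre)]

Icb is 1 over the prebleach window by construction and invariant to
global intensity rescaling. Curves aggregate across cells as the
pointwise mean with a normal-approximation 95% band (≈93% true
pointwise coverage at n = 15). The recovered fraction at time t is
(Icb(t) − Icb(bleach)) / (1 − Icb(bleach)), undefined when nothing was
bleached.

## Validation battery and problem sizes

`xcdyn.validation` re-derives every stage from scratch
(`scripts/acceptance.py --seed S --out out.json` runs it all):
two-state recovery on 5000 trajectories; flux type-I calibration on
100 cohorts of 20 identical cells (~60 entering events per cell) plus
barrier detection at permeability 0.2; isotropy of the angle ratio on
10⁵ jump pairs; the confocal round-trip identity; the escape series vs
a 10⁶-walker Monte Carlo on a 5×5 (D, dt) grid; calibration-line
recovery at 200 points with 5% intensity noise; the MSD law over six
lags; FRAP flatness and plateau recovery; and a 50-geometry audit of
the control generator with independent rule re-checking and seed
reproducibility. In the flux null study the scored "XC" is drawn at
random from the generated region set per cell: with an inert boundary
the XC label has no dynamical meaning, while entering rates do depend
slightly on where a region sits relative to the nuclear wall, so the
random designation realizes exactly the exchangeable null the
calibration is meant to probe. With a real barrier the dynamically
distinguished XC mask is scored.

## Known limitations

* Region-mean CIs ignore voxel spatial correlation.
* The per-trajectory jump cap leaves a small (~0.03) negative bias on
  the fitted bound fraction; removing the cap removes the bias on
  synthetic data but departs from the standard analysis settings.
* The KS flux test is conservative on counts (true type-I ≈ 3% at
  nominal 5%); cohort-level rejection rates fluctuate accordingly.
* The diffusion spectrum's defocalization correction is per-step and
  approximate; weights at neighboring grid points trade off freely.
* FRAP is modeled at the trace level only; no reaction–diffusion
  (k_off) fitting.
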