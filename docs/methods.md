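# Methods

## Model

The recorded motion is modelled by the overdamped Langevin equation with
state-dependent noise amplitude, written as the generic SDE
`dX = a(X) dt + b(X) ∘ dW` with `b = √(2D)`.  When `D` varies in space the
noise term is only defined up to the stochastic-integration convention
λ ∈ [0, 1]; in the Itô form the total drift becomes

    α(x, λ) = a(x) + λ·b(x)∇b(x),

so the recorded (mesoscopic) drift α mixes the genuine non-diffusive force
per friction `a` with a convention-dependent spurious term.  The inverse
problem addressed here is whether a ≠ 0 is required by the data when λ is
unknown.

Within each spatial bin, drift and diffusivity are treated as constant, so
the displacements Δr over one frame interval Δt are i.i.d. Gaussian with
per-component mean αΔt and variance b²Δt.  The bin's sufficient statistics
are the count n, the mean displacement Δr̄ and the biased sample variance
V = Σᵢ|Δrᵢ − Δr̄|²/n (components summed).  Bins are assumed independent;
coupled-bin (regularized) inference is deliberately out of scope.

## Priors

The conjugate (normal–inverse-gamma-type) prior on (a, b²) carries an
effective number of prior observations n_π, is centred on *zero
non-diffusive force* (its drift mean follows the spurious drift λĝ), and
has prior jump variance V_π = u·V with u = 1 by default.  The prior is
proper only if the inverse-gamma shape m(d) = d(n_π−1)/2 − 1 is positive,
giving the least-constraining admissible choices n_π = 4 (1D) and n_π = 3
(2D); these are the defaults (`n_pi="auto"`).  `min_proper_n_pi` exposes
both the closed-form condition and a numeric normalizability scan.  The
convention parameter λ has a flat prior on [0, 1]; the diffusivity-gradient
parameter is fixed at its point estimate ĝ (a delta prior), which keeps the
evidences closed-form.

## Bayes factors

Both model evidences reduce to 1-d integrals over λ of
`[v + s·|ζ_t − λζ_sp|²]^{−κ}` with s = η² (H1) or 1 (H0), where

* ζ_t = Δr̄/√V_eff — total-drift signal-to-noise per jump,
* ζ_sp = ĝΔt/√V_eff — spurious-drift signal-to-noise per jump,
* η = √(n_π/(n+n_π)), v = 1 + n_π V_π/(n V_eff), κ = d(n+n_π−1)/2 − 1.

All normalization constants are common to the two hypotheses and are never
computed.  The fixed-λ factor K(λ) is fully closed-form; the marginalized
K^M is the ratio of the two λ-integrals times η^d and equals the
H0-integrand-weighted average of K(λ).  Its global minimum over the data,
attained at ζ_sp = 0 and ζ_∥ = 0, is η^d[(v+η²ζ⊥²)/(v+ζ⊥²)]^{−κ} — the
H0-favouring floor a bin can reach, ≈ (d/2)·log10(n_π/(n+n_π)) in log10
when ζ⊥ = 0.  Within the band 0 ≤ ζ_∥/ζ_sp ≤ 1 the factor varies little and
rises sharply outside it: configurations inside the band are intrinsically
undecidable no matter how much data accumulates, which is the honest answer
the marginalization is designed to give.

Bins are classified by log₁₀K^M against a symmetric threshold (default 1,
boundary values conclusive): `nonspurious`, `spurious_only` or
`inconclusive`.  No multiple-testing correction is applied across bins —
each bin is thresholded independently, so a small fraction of false calls
among many bins is expected and must be read accordingly.  When H0 is
preferred, the most efficient convention is reported as
λ* = clamp(ζ_∥/|ζ_sp|, 0, 1).

## Force posterior

Under H1 the posterior of the force signal-to-noise ζ_a = aΔt/√V_eff is the
λ-marginal of `[v + η²/(1−η²)·|ζ_a|² + |ζ_t − ζ_a − λζ_sp|²]^{−κ−d/2}`.  It
equals the evidence-weighted mixture of the fixed-λ posteriors, so it is
wider than any of them and generally skewed when ζ_sp ≠ 0.  Notably its
width does **not** shrink to zero with n at fixed ζ_sp: an irreducible
spread of order ζ_sp/√12 remains, the price of the unknown convention.  In
2D the density is evaluated in the frame aligned with ζ_sp (falling back to
the ζ_t direction when ζ_sp = 0); multiplying ζ_a by √V_eff/Δt converts to
physical drift units (force per friction, µm/s) — friction and force are
not separated because the model only constrains their ratio.

## Estimators

**Diffusivity.**  Integrating the drift out of likelihood × prior leaves an
inverse-gamma posterior for z = b²Δt with shape κ and scale S/2,
S = nV_eff(v + η²ζ_t²).  The reported `D_map = S/(2(κ+1))/(2Δt)` is the
posterior mode and converges to V_eff/(2dΔt); the 95% interval is the
equal-tailed posterior interval (scipy's inverse-gamma quantiles).  Bins
with n < n_π, or with exactly degenerate variance, are flagged rather than
estimated.

**Spurious-drift coefficient ĝ.**  ĝ is stored as the λ = 1 spurious drift
b∇b (units µm/s; for a smooth field ĝ = ∇D).  It is obtained per bin by a
weighted least-squares affine fit of b̂ = √(2D̂) over the bin and its
neighbors — non-empty bins whose centroids lie within 1.5× the local bin
pitch, the smallest symmetric stencil that over-determines a plane fit —
with weights equal to the per-bin counts, evaluated at the bin centroid.
The fit is exact on affine b-fields; bins with fewer than d+2 usable
neighbors are flagged and excluded from testing.

**Localization error.**  A static localization error σ_L inflates the
apparent jump variance by 2dσ_L²; the correction used throughout is
V_eff = max(V − 2dσ_L², εV) with ε = 10⁻⁶, and bins whose variance is
exhausted by the correction are flagged noise-dominated.  Motion blur and
the noise-induced correlation between consecutive displacements are not
modelled.

## Numerics

κ grows linearly with n (κ > 500 for a well-sampled 2D bin), so integrands
are never exponentiated un-shifted: all λ-integrals use trapezoid
quadrature on the log-integrand with per-integral max-subtraction, and the
node count is doubled (from 9) until the integral changes by < 10⁻⁹
relative.  A constant integrand (ζ_sp = 0) is evaluated at a single node,
making the λ-independence limit exact to machine precision.  The force
posterior uses a 257-node λ-grid and a 201-point ζ_a-grid per axis spanning
±6 approximate posterior widths plus the λ-shift range; the grid is
enlarged automatically while > 10⁻⁴ of the peak density sits on the
boundary.  The posterior MAP is the grid argmax refined by a local
quadratic fit.

## Tessellation and assignment

Two schemes: a regular half-open grid over the data bounding box (points on
interior edges belong to the higher-index cell, outer top faces closed),
and a count-balanced k-d tessellation for experiment-like occupancy
control.  The count-balanced scheme splits a node holding N points into
k ≈ round(N/target) leaves at rank N·⌊k/2⌋/k along alternating axes, so
every leaf holds ⌊N/k⌋ or ⌈N/k⌉ points; pure median halving could only
produce counts N/2^k and cannot meet a ±tolerance occupancy band in
general.  Displacements are assigned to bins by their start point — the
local jump law is attributed to the position the jump originates from; one
rule has to be fixed and the start point matches the Itô-form likelihood.
Empty bins are retained and flagged.  Trajectories recorded in a periodic
box are differenced with the minimal-image convention.

## Simulators

**Heterogeneous Langevin (`simulate_ole`).**  Euler–Maruyama in the Itô
form with the spurious drift λ_true·∇D injected explicitly, so the
generated data exhibit the convention dilemma by construction.  Defaults: a
1×1 µm² periodic box, triangular diffusivity profile along x rising from
0.05 to 0.3 µm²/s at the apex (both kinks on bin edges of the default
0.125 µm grid), Δt = 0.04 s and 10 substeps per frame so the
locally-constant-coefficient assumption holds at the recording scale
(substep noise stays below 10% of the profile scale; a warning fires
otherwise).  The drift is either a uniform total drift α or a pair
(a, λ_true).

**Bead crowding (`simulate_crowding`).**  Free microscopic diffusion
(D = 0.3 µm²/s) in a 10×10 µm² periodic box among impenetrable disks on a
0.1 µm lattice with radii growing linearly 0 → 0.04 µm in x; 1000 particles
× 1000 recorded jumps by default.  Proposed substeps whose segment enters a
disk are rejected and resampled (up to 100 tries, then the particle stays
put); rejection rather than reflection is used because it preserves the
uniform equilibrium measure in the accessible region and is unambiguous.
The segment test scans the 5×5 lattice nodes around the segment midpoint,
which covers every disk reachable by a ~4-standard-deviation substep at the
default parameters.  Crowding lowers the effective mesoscopic diffusivity
where beads are large, so the recorded data show a genuine diffusivity
gradient and a drift that is purely spurious — ground truth for H0.

**What the generators do not emulate.**  Localization noise and motion
blur, finite camera fields of view, trajectory linking errors, hydrodynamic
coupling, temperature gradients and intermittent trapping are absent.
Passing tests on these data therefore validate the statistics of the
method under its own model assumptions, not robustness to every
experimental artefact.

## Calibration protocol

`run_calibration` repeats simulate → tessellate → infer over independent
trials, cycling a set of uniform drift amplitudes (default 0–1.5 µm/s along
the gradient axis) so the expected Bayes factors span from the analytic
floor to strongly conclusive values.  Each tested bin contributes a pair
(expected log₁₀K^M, inferred log₁₀K̂^M), where the expected value is
computed from the true diffusivity profile, the injected drift, the bin's x
extent and its own occupancy.  The summary is a sliding average over a
window of constant width 0.5 in log₁₀ units together with the 2.5–97.5
percentile spread of the inferred values in the window; the method is
considered calibrated when the identity line lies inside that spread
wherever the window holds enough points.  The default validation scale
(20 trials of 40 particles × 250 steps on a 0.125 µm grid, ≈60 tested bins
per trial) keeps a full calibration under ten seconds while leaving ≥30
points per window over the sampled range.

## Known limitations

* The delta prior on ĝ ignores gradient-estimation uncertainty; very noisy
  diffusivity maps propagate bias into ζ_sp.
* The gradient stencil smooths across kinks of the true diffusivity field,
  biasing ĝ in bins adjacent to sharp features.
* Per-bin independence ignores that consecutive displacements of one
  trajectory can fall in the same bin.
* d = 3 data are not supported (κ, m and the properness thresholds are
  implemented for d ∈ {1, 2}).
* No multiple-testing control across bins; see above.
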