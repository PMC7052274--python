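# forcemap

Convention-robust detection and estimation of non-diffusive forces from
single-particle tracking data in heterogeneous-diffusivity environments.

## The problem

Trajectories of tracers governed by the overdamped Langevin equation

$$dX_t = \frac{f(X_t)}{\gamma(X_t)}\,dt + \sqrt{2D(X_t)}\circ dW_t$$

are ambiguous when the diffusivity `D(x)` varies in space: the stochastic
integral only becomes well defined once a convention λ ∈ [0, 1] is chosen
(λ = 0 Itô, 1/2 Stratonovich, 1 Hänggi–Klimontovich), and each convention
contributes a different "spurious" drift λ·b∇b (with b = √(2D)) to the
recorded motion.  An observed drift may therefore be a genuine interaction
(a non-diffusive force) or a pure convention artefact of the diffusivity
gradient — the Itô–Stratonovich dilemma for the *inverse* problem.

`forcemap` resolves this by testing, in each spatial bin, the nested
hypotheses

* **H0** — the drift is fully explained by some spurious contribution
  λ·b∇b, λ ∈ [0, 1];
* **H1** — an additional non-diffusive force is present;

via a Bayes factor in which λ is **marginalized** with a flat prior.  With a
conjugate prior of effective strength n_π on the local drift and squared
noise amplitude, the result is closed-form up to 1-d λ-integrals:

$$K^{\mathrm M} = \eta^{d}\,
\frac{\int_0^1 d\lambda\,[v+\eta^{2}(\zeta_{\mathrm t}-\lambda\zeta_{\mathrm{sp}})^{2}]^{-\kappa}}
     {\int_0^1 d\lambda\,[v+(\zeta_{\mathrm t}-\lambda\zeta_{\mathrm{sp}})^{2}]^{-\kappa}},
\qquad
K(\lambda)=\eta^{d}\Big[\tfrac{v+\eta^{2}(\zeta_{\mathrm t}-\lambda\zeta_{\mathrm{sp}})^{2}}
                              {v+(\zeta_{\mathrm t}-\lambda\zeta_{\mathrm{sp}})^{2}}\Big]^{-\kappa},$$

where ζ_t = Δr̄/√V and ζ_sp = ĝΔt/√V are per-jump signal-to-noise ratios of
the total and spurious drift, η = √(n_π/(n+n_π)), v = 1 + n_πV_π/(nV) and
κ = d(n+n_π−1)/2 − 1 are built from the per-bin sufficient statistics
(count n, mean displacement Δr̄, biased variance V).  Bins are coloured
non-spurious (log₁₀K ≥ 1), spurious-only (≤ −1) or inconclusive.  When H1
holds, the force posterior is likewise marginalized over λ, honestly
propagating the convention ambiguity into wider, generally skewed credible
intervals.

The package also ships the two validation simulators: heterogeneous
Langevin walkers with an explicit convention parameter, and free diffusion
among immobile beads whose growing radii create a purely spurious
mesoscopic drift.

## Worked example

Simulate crowding by a bead lattice (no microscopic force at all), run the
full pipeline, and inspect the map:

```python
import forcemap as fm

cfg  = fm.CrowdingSimConfig(n_particles=300, n_steps=300, substeps=5, seed=42)
ts   = fm.simulate_crowding(cfg)                      # 10×10 µm², bead radii grow with x
fmap = fm.run_inference(fm.RunConfig(bin_size=1.0), ts=ts)
print(fmap.table["classification"].value_counts().to_dict())
```

```
{'spurious_only': 86, 'inconclusive': 12, 'nonspurious': 2}
```

A few of the 100 bins (1×1 µm each):

```
 bin_id    n  D_map    g_x  log10_KM classification
      0 1631  0.279 -0.003    -2.178  spurious_only
      4 1172  0.300 -0.013    -2.351  spurious_only
     55  936  0.210 -0.012    -2.491  spurious_only
     99  469  0.166  0.003    -0.852   inconclusive
```

The inferred diffusivity `D_map` falls from ≈0.28 µm²/s on the open side to
≈0.17 µm²/s where beads are large, producing a genuine diffusivity-gradient
map `g_x` — yet 97.7% of the conclusive bins are correctly classified
`spurious_only`: the recorded drift never requires a non-diffusive force.
Injecting a uniform 1 µm/s drift into the same simulation flips the
majority to `nonspurious`.

The same workflow is available from the shell:

```sh
forcemap simulate crowding --seed 42 --out traj.csv
forcemap infer --input traj.csv --dt 0.04 --bin-size 1.0 --out map.csv
forcemap posterior --input traj.csv --dt 0.04 --bin 12 --out post.csv
forcemap calibrate --trials 20 --seed 1 --out calib.csv
```

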