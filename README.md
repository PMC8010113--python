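# silencemap

Localization of cortical **regions of silence** — contiguous patches of
brain tissue with no electrophysiological activity (surgical resections,
ischemic or lesional tissue) — from noninvasive scalp EEG.

Classical source localization treats background brain activity as noise
and averages it away; silence localization must do the opposite, because
the goal is to find where background activity is *absent*.  This package
implements a two-stage algorithm for that task:

1. **Contribution statistics.**  For each candidate source q with
   referenced lead-field column `ã_q`, the variance of the projection
   `μ_qt = ã_qᵀ y_t` measures the source's contribution to the recorded
   scalp power.  Noise-corrected and normalized by its silence-free value
   it gives a per-source score β_q ∈ [0, σ_s²] (coarse grid, uncorrelated
   sources) or β_q^high ∈ [0, 1] (fine grid, exponential-decay spatial
   covariance `c_ij = σ_s² e^{−γ‖f_i−f_j‖²}`).
2. **Hemispheric baseline.**  Healthy cortical power is approximately
   mirror-symmetric across the longitudinal fissure, so each source is
   judged against its contralateral twin, `β̃_q = min(β_q/β_{q_m}, 1)` —
   robust to spatially varying (but symmetric) source strength.
3. **Convex spectral clustering (CSpeC).**  The silent patch is selected
   by a relaxed indicator g ∈ [0,1]^p minimizing
   `β̃ᵀ(1−g) + λ(1−g)ᵀL(1−g)` s.t. `‖g‖₁ ≤ p−k`, where L is the Laplacian
   of the k-nearest-neighbor source graph — the quadratic term enforces
   contiguity.  λ and the patch size k are grid-tuned; a second,
   high-resolution pass iteratively refits the source covariance
   parameters (γ, σ_s) and adds per-electrode scalp-power constraints.
   The reference electrode (out of ten 10-5 midline candidates) with the
   smallest scalp power mismatch wins.

The package also ships the full synthetic study framework (symmetric
spherical-cap cortex, analytic dipole-in-sphere lead fields, spatially
correlated Gaussian sources with flat or 1/f-shaped PSD, SNR-calibrated
sensor noise), silence-adapted versions of **MNE**, **MUSIC**, and
**sLORETA** for comparison, and the evaluation metrics ΔCOM (center-of-
mass distance), JI (Jaccard index), Δk (relative size error), CR
(convergence rate), and the hemispheric MAD symmetry statistic.

Intended users: EEG methods researchers who want a reproducible,
dependency-light reference implementation of silence localization to
study, benchmark against, or extend.

## Worked example

```python
import silencemap as sm

# synthetic study instance: 300 sources, 48 electrodes, 15 silent
grid = sm.build_symmetric_grid(300, seed=0)
montage = sm.build_symmetric_montage(48)
lead = sm.synth_lead_field(grid, montage)
sim = sm.simulate_recording(grid, lead, k=15, T=20_000, seed=5,
                            references=("Cz",))

cfg = sm.SilenceMapConfig(max_iterations=4, lambda_points=6, n_k_points=8)
res = sm.run_silencemap(sim.recordings, lead, grid,
                        sim.noise_model.C_z, config=cfg)
rep = sm.evaluate(res.silent_set, sim.ground_truth, grid,
                  converged=res.converged)
print(f"k_hat={res.k_hat} converged={res.converged} "
      f"gamma_hat={res.gamma_hat:.3f}")
print(f"dCOM={rep.delta_com:.1f} mm  JI={rep.jaccard:.3f}  "
      f"dk={rep.delta_k:.2f}  (grid spacing {grid.spacing():.1f} mm)")
```

prints

```
k_hat=16 converged=True gamma_hat=0.485
dCOM=9.1 mm  JI=0.550  dk=0.07  (grid spacing 9.4 mm)
```

i.e. the recovered patch has 16 sources (truth: 15, a 7% size error), its
center of mass lands 9.1 mm from the true patch center — under one grid
spacing — and the two patches overlap with Jaccard index 0.55.  The
fitted spatial-decay coefficient overshoots the generating γ = 0.12 mm⁻²
(the scalp-power fit is flat in γ at this data length; localization is
driven by the mirrored contribution ratio and is insensitive to it).

The same pipeline is available from the shell:

```sh
silencemap simulate --seed 1 --p 500 --k 20 --snr 9 --out run.h5
silencemap localize --data run.h5 --baseline hemispheric --out report.txt
silencemap benchmark --n-regions 20 --seed 0 --out bench.tsv
```

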