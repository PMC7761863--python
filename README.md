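# cghbm — hierarchical Bayesian EEG/MEG source localization

`cghbm` implements distributed dipole source localization for EEG and MEG
with the **conditionally Gaussian hierarchical Bayesian model (CG-HBM)**,
aimed at researchers who need focal source estimates (e.g. of the P20/N20
somatosensory response) with a principled, transferable way of setting the
prior's scale.  The package provides:

* gamma (G) and inverse-gamma (IG) hyperpriors on the per-source prior
  variances, with densities, quantiles, conditional updates and samplers;
* **PM-SNR** (prior-over-measurement signal-to-noise ratio) calibration of
  the scale parameter, invariant to the noise level and source-space size;
* **IAS** (iterative alternating sequential) MAP estimation, with
  minimum-norm (MNE) and minimum-current (MCE) estimation recovered as its
  first and third iterates under the G hyperprior at β = 1.5;
* ROI-restricted blocked **Gibbs sampling** for conditional-mean (CM)
  estimation with credibility intervals of the posterior mass center;
* a synthetic **spherical-head forward simulator** (analytic EEG potential
  and Sarvas MEG field) so the entire pipeline is testable without MRI data,
  plus an HDF5 lead-field container that accepts external (e.g. FEM) forward
  models as drop-in replacements.

## Model

With lead field `L`, measurement `y` (one amplitude-normalized time slice)
and noise std `σ`, the posterior over source amplitudes `x` and their
variances `θ` is

    p(x, θ | y) ∝ p(θ) · N(x | 0, diag(θ)) · N(y | Lx, σ² I),

where `p(θ)` is G(θ | β, θ₀) or IG(θ | β, θ₀) per coordinate.  The shape
β = 3 makes the two families behave nearly identically; the scale θ₀ follows
from the PM-SNR

    PM-SNR = 10·log₁₀( θ₀ N A² / (σ² |J_p|²) ),

with `N` source positions, amplitude `A` (1 after normalization) and a
reference dipole strength `|J_p|` = 10 nAm.  0 dB means the prior's total
fluctuation matches the noise-induced level; latent (unmodeled) noise `s`
raises PM-SNR by `20·log₁₀ s`; epoch averaging of `n` of 1200 epochs raises
the noise amplitude by `10·log₁₀(1200/n)` dB.

## Worked example

```python
import cghbm as c

# canonical scenario: a 10 nAm normally-oriented superficial dipole,
# 128 EEG electrodes, 4000 source positions, 3% noise, 1200 epochs
sc = c.scenario_p20n20_like(n_dense=4000, seed=1)
lf = sc.normalized_leadfield()

theta0 = c.theta0_from_pm_snr(20.0, lf.source_space.n_positions,
                              c.NoiseModel(sigma_known=0.03))
res = c.ias_map(lf, sc.dataset.y_noisy, sc.dataset.sigma,
                c.HyperpriorSpec("G", 3.0, theta0))

roi = c.ROI("sphere", sc.roi_center_mm, sc.roi_diameter_mm)
ref = sc.dataset.truth[0]
rep = c.localization_report(res, lf.source_space, ref.position,
                            ref.orientation, roi=roi)
print(f"position error {rep.position_diff_mm:.2f} mm, "
      f"orientation error {rep.orientation_diff_deg:.1f} deg, "
      f"spread {rep.spread_mm2:.1f} mm^2")
```

prints

```
position error 2.21 mm, orientation error 15.1 deg, spread 14.4 mm^2
```

i.e. the three-step IAS MAP estimate localizes the synthetic source to
about 2 mm (the ROI-restricted mass center vs the planted dipole) with a
focal active area of one to two source-grid cells.

A command-line interface mirrors the library
(`cghbm simulate | invert | sample | metrics | presets | pipeline`); run
`cghbm pipeline --config run.yaml --out run/` for a fully logged
simulate → invert → metrics run with a provenance record.

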