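# Methods

This note documents the statistical model, the calibration conventions, the
synthetic forward simulator, and the numerical and design choices behind
`cghbm`.

## The conditionally Gaussian hierarchical model

The forward model is `y = Lx + n` with a known lead field `L`, a single
amplitude-normalized time slice `y` (‖y‖₂ = 1 after dividing by the signal
amplitude `A`) and i.i.d. Gaussian noise of std `σ` per channel.  Each source
amplitude `x_i` carries a zero-mean Gaussian prior with its own variance
`θ_i`, and the variances carry a heavy-tailed hyperprior — gamma
G(θ | β, θ₀) or inverse gamma IG(θ | β, θ₀).  The heavy tail makes large
variance outliers likely, i.e. the model expects a *sparse* source
configuration: a few strong dipoles on a weak background.  The shape β sets
the tail decay (smaller β, wider spread), the scale θ₀ the expected variance
per source.

Two posterior summaries are implemented:

* **IAS MAP** — coordinate ascent on p(x, θ | y): the x-step is the exact
  weighted Tikhonov solve `x = ΘLᵀ(LΘLᵀ + σ²I)⁻¹y`, the θ-step the closed
  form conditional maximizer, `(θ₀/2)[(β−3/2) + √((β−3/2)² + 2x²/θ₀)]` for G
  (clipped at 0) and `(θ₀ + x²/2)/(β + 3/2)` for IG.  The iteration starts
  at θ = θ₀ uniformly and runs a **fixed 3 steps** — the step count is part
  of the method definition, not a convergence criterion.  The iteration
  convention is: one step = one x-update followed by one θ-update, and the
  step-k iterate is the x after the k-th x-update.
* **MCMC CM** — blocked Gibbs on a region of interest: x | θ, y is drawn
  from its exact Gaussian conditional (precision `LᵀL/σ² + Θ⁻¹`, factorized
  densely; the ROI keeps the dimension small, capped at 600 components),
  θ | x elementwise from the conjugate IG(β+½, θ₀+x²/2) for IG, or from the
  generalized inverse Gaussian GIG(β−½, 2/θ₀, x²) for G.  Default chain
  length is 10,000 samples with 1,000 discarded as burn-in.

**MNE and MCE as special cases.**  With the G hyperprior at β = 1.5 the
first IAS iterate is exactly the Tikhonov-regularized minimum norm estimate
(regularization σ²/θ₀), and the third iterate is the minimum current
estimate.  At β = 1.5 the θ-maximizer at x = 0 is exactly 0 for G (the
boundary) and θ₀/3 for IG; the G boundary prunes weak coordinates, which is
the mechanism behind MCE's focality and its tendency to suppress weak deep
activity.  The θ-floor option defaults to exactly 0 to preserve this
equivalence.

**Choice of β.**  β = 3 is used as the default shape because it makes the
two hyperprior families behave nearly identically: their mean-normalized
10th/90th quantiles agree within 3% (0.37/1.77 for G vs 0.38/1.82 for IG),
and `match_beta` quantifies the discrepancy as a symmetrized KL divergence
between the unit-mean-rescaled densities (a pluggable surrogate criterion of
this package; any callable `beta -> discrepancy` can replace it).  At β = 3
the expected source strength √θ spans about 7 dB over the hyperprior's
interdecile range.

## PM-SNR calibration

The scale θ₀ is not transferable between forward models: the prior's weight
against the likelihood depends on the number of source positions N, the
noise variance σ² and the amplitude A.  The per-distribution total scale
`θ₀^tot = θ₀ N / (σ² A²)` is the transferable constant, and its power-dB is
the prior-over-measurement SNR:

    PM-SNR = 10·log₁₀(θ₀ N A² / (σ² |J_p|²)),   |J_p| = 10⁻⁸ Am.

0 dB is the matching point √θ₀ = σ|J_p|/(A√N).  Consequences (all exact and
tested): θ₀ ∝ 1/N at fixed PM-SNR (a 1/100 sparse space gets a 100× larger
θ₀), +10 dB ⇔ θ₀ × 10, and θ₀ ∝ σ̄².

**Decibel conventions.**  Amplitude-like quantities use 20·log₁₀, variance-
like quantities enter through their square root, i.e. 10·log₁₀ on the
variance.  The two helpers `db_amplitude` / `db_power` in
`cghbm.constants` are the single source of truth; every formula documents
which one it uses.  This convention is forced by internal consistency of the
reference values (+10 dB ⇔ ×10 θ₀; the mean-referenced correction +dB(β) =
+5 dB at β = 3 only holds as 10·log₁₀ 3).

**Three noise mechanisms** enter separately and are all logged per run:
the known per-channel std σ̄ (default 3%), the epoch-averaging factor
√(1200/n) (+6 dB at 300 epochs, +10.8 dB at 100), and the latent factor
s ≥ 1 for unmodeled errors (forward model, conductivities, segmentation),
which shifts PM-SNR by +20·log₁₀ s rather than entering the θ₀ conversion
directly — so "more latent noise" means "a stronger prior" at the same
measured data.  The PM-SNR ↔ θ₀ conversion therefore uses the known,
epoch-scaled noise std and excludes s; this is what makes the conversion an
exact round trip.

**Anchored presets vs the formula path.**  The package ships a reference
preset grid (PM-SNR per data type/modality/estimator/family, with
θ₀ = 10⁻¹⁴ dense and 10⁻¹² sparse at 0 dB) as literal data.  Plugging the
nominal constants (A = 10⁻⁶ V, σ = 0.03, |J_p| = 10⁻⁸ Am, N ≈ 7.6×10⁴) into
the formula gives ≈10⁻¹² at 0 dB, not 10⁻¹⁴ — a factor-~100 discrepancy in
the absolute anchor (the preset grid is consistent with A ≈ 10⁻⁵ V).  The
two paths are deliberately kept separate and never mixed; `preset_table`
uses the anchors, `theta0_from_pm_snr` the formula, and the provenance
record names which was used.

## Synthetic forward simulator

The simulator stands in for an FEM pipeline with a spherical head:

* **Geometry** (head-centered Cartesian, mm): a homogeneous conductor sphere
  of radius 90 mm (conductivity 0.33 S/m), a cortical shell at radii
  70–78 mm with radial outward "surface normals", and a deep central ball of
  radius 25 mm standing in for sub-cortical structures.  Source positions
  are drawn uniformly per region (three Cartesian source components each); a
  boundary margin — by default one nominal source spacing (V/N)^⅓, capped by
  the gap the shell already leaves — keeps sources off the conductor
  boundary, emulating the boundary-layer exclusion of FEM source spaces.
  The sparse space subsamples the dense one 1:100 with the same seed, so its
  positions are a strict subset.
* **EEG**: the closed-form potential of a current dipole in a homogeneous
  conducting sphere, obtained by summing the interior Neumann Legendre
  series with generating-function identities (the derivation is in the
  module docstring); rows are average-referenced.  The test oracle is the
  independently coded truncated multipole series (agreement ~10⁻¹⁰
  relative).
* **MEG**: the Sarvas closed form for a spherically symmetric conductor,
  projected on radial magnetometer axes.  Radial dipoles are exactly silent
  — which means a "normally-oriented" (radial) cortical source in this
  spherical cortex produces no MEG signal.  The canonical scenario therefore
  defaults to EEG; for MEG it orients the truth dipole tangentially
  (physiologically, a sulcal-wall source is tangential to the head surface).
  The test oracle is the Geselowitz surface-integral formula (primary field
  plus the volume-current term expressed through the series-verified surface
  potential, quadratured on an icosphere mesh; agreement ~0.5%).
* **Sensors**: Fibonacci-spiral caps covering the upper ~65% of the sphere,
  default 128 EEG electrodes on the conductor surface and 128 radial
  magnetometers at 110 mm.
* **Measurements**: the canonical scenario plants one 10 nAm
  normally-oriented superficial dipole (optionally plus a deep 10 nAm
  source), normalizes the clean signal to unit ℓ2-norm and adds i.i.d.
  Gaussian noise.  By default σ is the per-channel std on the ℓ2-normalized
  data ("l2" convention); the alternative "max" convention (σ relative to
  the maximal normalized amplitude) is available, and the choice is named in
  the dataset metadata.  Truth positions are snapped to the nearest source
  position with the offset logged.

What the simulator does *not* emulate: realistic cortical folding (normals
are radial, so orientation errors are optimistic), tissue inhomogeneity,
correlated sensor noise, temporal structure (a single time slice only), and
FEM discretization error.  Passing tests therefore demonstrate the
correctness and calibration behaviour of the inverse machinery, not
real-data localization accuracy.

## Evaluation metrics

Reconstructions are normally projected (signed normal component at cortical
positions, unprojected intensity at deep positions, where neurons are not
normally aligned).  The localization report gives the intensity-weighted
mass center and its distance to the reference dipole, the orientation
difference of the sign-aligned intensity-weighted mean moment (the
"orientation of a distributed estimate" has no canonical definition; this
weighted-mean construction is this package's documented choice, with a
sign-agnostic option), and the spread — the area where the normally
projected amplitude exceeds 80% of its maximum.  On the sphere the spread
uses per-position spherical-Voronoi area weights on the cortical mid-shell,
a proxy for the surface-mesh computation with the same relative threshold.
For global MAP estimates the mass center is evaluated ROI-restricted (24 mm
sphere around the reference), since the diffuse background of an ℓ2-type
estimate would otherwise dominate the centroid; the sampler is
ROI-restricted by construction.  Credibility intervals are equal-tailed 90%
intervals of the per-sample mass center, per Cartesian axis.

## Numerical choices

* MAP linear solves use the m×m sensor-space Cholesky factorization
  (`LΘLᵀ + σ²I`); θ = 0 columns prune exactly.  The Gibbs x-draw uses the
  d×d precision Cholesky on the ROI (no perturbation tricks).
* The G-family conditional θ-draw uses a vectorized ratio-of-uniforms
  sampler for the generalized inverse Gaussian in the standardized
  two-parameter form (mode-normalized density, acceptance bounded uniformly
  in the data weight ω = |x|√(2/θ₀)); below ω = 10⁻¹⁰ it switches to the
  exact x = 0 gamma limit Gamma(β−½, θ₀).  A slice-sampling fallback is
  provided and KS-tested against it, and both are tested against scipy's
  GIG generator and quadrature moments.
* IG quantiles use the reciprocal relation q_IG(p) = θ₀ / q_Γ(1−p; β).
* The IAS objective (negative log joint posterior) is tracked at every
  half-step and must be non-increasing (coordinate descent); at the G-family
  boundary θ_i = 0 with x_i = 0 the limiting value is used (finite exactly
  at β = 3/2, ±∞ otherwise), and non-finite values are excluded from the
  monotonicity check.
* Degenerate inputs fail loudly: non-positive θ in densities, IG means at
  β ≤ 1, empty ROIs, ROIs above the dense-factorization cap, singular
  sensor-space systems at σ = 0.

## Problem sizes

The canonical fixture uses 128 sensors and N = 4000 dense source positions
(nominal spacing ≈ 5.4 mm; sparse N = 40) — sizes chosen so a full
simulate → invert → metrics cycle takes well under a second and the complete
validation (including ten-seed invariance and depth studies and a
10,000-sample chain) completes in seconds; all sizes are configurable.
Behavioural claims (parametrization invariance, depth suppression ordering)
are asserted on medians over ≥10 simulation seeds.

## Known limitations

* The spherical geometry makes normally-constrained sources MEG-silent, so
  MEG pipelines must use the tangential scenario variant.
* The analytic EEG model is a single homogeneous sphere, not a multi-shell
  (skull/scalp) model; absolute amplitudes are optimistic for EEG, which
  mainly shifts the effective data SNR, not the calibration logic.
* `match_beta`'s symmetrized-KL criterion decreases monotonically in β on
  the default grid; it quantifies the G/IG discrepancy but is not a
  uniquely-minimizing objective.
* CM estimation requires an ROI; whole-brain sampling is out of scope.
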