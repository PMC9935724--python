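# Methods

## Signal model and estimation

The forward model is the three-compartment "standard model" adapted to
muscle: stick (intra-fiber, `v_intra`), axially symmetric zeppelin
(extra-fiber connective-tissue space, `v_extra`), and ball (free fluid,
`v_iso`), with fractions constrained to the unit simplex. Diffusivities are
fixed, not estimated: two shell means cannot identify three fractions *and*
three diffusivities. Defaults are `D_a = 1.7e-3`, `D_r = 0.7e-3`,
`D_iso = 3.0e-3` mm²/s — literature-typical values for muscle water and
free water at body temperature; all are configurable through
`TissueParams`, and the validity constraint `0 < D_r < D_a ≤ D_iso` is
enforced.

Estimation is orientation-invariant by construction. With 12 directions per
shell, full orientation-distribution modeling is not supportable, and the
fractions — the only outputs this analysis needs — do not require it. The
per-shell spherical mean of each compartment has a closed form
(`kernel_spherical_means`); stacking the two shells with the sum-to-one row
gives a square linear system whose inversion is the deterministic oracle
(`fit_fractions_linear`, simplex-projected when noise pushes the solution
outside). The system's condition number is checked (default ceiling 1e8)
and collapse of the shells or diffusivities raises a degenerate-model
error.

The production estimator (`fit_fractions_bayes`) approximates the posterior
mean under a flat simplex prior: draw M parameter sets (fractions uniform
on the simplex via a flat Dirichlet, orientations uniform on the sphere),
simulate them on the *actual* acquisition scheme, apply Rician noise at the
training SNR, reduce to normalized shell means, and fit a least-squares
polynomial regression (degree 3, all interaction monomials) from features
to true fractions. Training on noisy magnitudes lets the regression learn
the Rician bias instead of applying an analytic correction. Defaults:
M = 100,000 (hard floor 10,000), degree 3, training SNR 40. Predictions are
clipped to [0, 1] and renormalized to the simplex. Voxels whose mean b0
signal falls below 5× the estimated noise sigma (background magnitude mean
divided by √(π/2), taken from the darkest b0 decile) are masked invalid.

### Accuracy ceiling of the two-shell protocol

With shells at 600/1000 s/mm² and the default diffusivities, the stick and
zeppelin kernels are similar enough that the reduced 2×2 system has a small
determinant: shell-mean noise is amplified roughly 13-fold into `v_intra`
and 22-fold into `v_extra`. At SNR 40 with 12 directions per shell the
resulting posterior-mean RMSE over a flat simplex prior floors near 0.07
(`v_intra`), 0.12 (`v_extra`), and 0.05 (`v_iso`) for single-voxel
estimation; richer regressions (degree 5, M = 10⁶) do not improve it, so
this is an information limit of the protocol, not of the estimator. Two
consequences: (i) single-voxel recovery below 0.05 RMSE for all three
fractions is not attainable at these settings and the corresponding
acceptance check records that honestly; (ii) in actual use the pipeline
recovers VOI-level means far more accurately, because MP-PCA denoising and
averaging over hundreds of VOI voxels suppress the noise amplification (the
phantom driver measures VOI-mean errors of ~0.02–0.06 at SNR 40, and the
posterior-mean shrinkage toward 1/3 — about −0.03 at a true `v_intra` of
0.42 — is visible as a small systematic bias).

## Pre-processing

MP-PCA denoising operates on sliding cubic patches (radius 2, i.e. 5³,
shrunk at boundaries): eigenvalues of the patch voxel×volume covariance
that fit inside a Marchenko–Pastur bulk of width `4σ̂²√(k/n)` are
classified as noise and suppressed; overlapping reconstructions are
averaged and intensities clipped at zero. The per-patch σ̂ is also emitted
as a map. In the noiseless rank-1 limit the filter is exactly the identity.
Upsampling is trilinear onto an isotropic target grid (default 2.0 mm,
matching the analysis resolution) with voxel-center alignment, preserving
the field of view to within one voxel; trilinear (rather than spline)
interpolation is monotone and introduces no ringing. Order of operations:
denoise first (it assumes raw noise statistics), then upsample.

## Dixon fat fraction

Magnitude-based two-point separation under the water-dominant convention:
`water = (IP+OP)/2`, `fat = (IP−OP)/2`, with `OP > IP` voxels (noise)
clamped to zero fat and flagged. `FF = 100·fat/(fat+water)`; voxels whose
total signal is below 1% of the image's 99th-percentile intensity are
masked invalid (NaN). Magnitude-only separation caps FF at 50% physically;
fat–water swap resolution and multi-peak fat spectra are out of scope. Both
entry points exist: an echo pair, or pre-separated water/fat images.

## Synthetic data

The generator emulates the acquisition (1 b0 + 12 directions at each of
b = 600 and 1000 s/mm², 2.0×2.0×4.0 mm voxels; a frozen
electrostatic-repulsion direction set, since a poorly spread set leaves
orientation-dependent quadrature error above the noise floor) and the
two-point Dixon pair (in-phase = water+fat, opposed-phase = |water−fat|,
Gaussian noise — Dixon magnitudes are high-SNR). DWI noise is Rician
(magnitude of complex Gaussian), scale `s0/SNR`, default SNR 40 — a
plausible 3 T muscle protocol that keeps recovery testable. Phantom
subjects carry three disjoint ellipsoidal muscle VOIs on a zero-signal
background, within-muscle fraction jitter (SD 0.01, simplex-projected), and
a smoothly varying fiber-orientation field; the geometry is parametric and
can be re-rendered on any grid, which is how VOI masks stay aligned after
upsampling.

Cohorts default to 11 males + 11 females. Per-muscle `(v_intra, v_iso)`
pairs are drawn from the published sex-specific normals with
`v_extra = 1 − v_intra − v_iso` and off-simplex redraws; the published male
SSP V-ISO entry (0.53) is simplex-inconsistent and is replaced by its
simplex-consistent value 0.28, which also preserves the reported male <
female ordering. Fat fractions use moment-matched lognormals (the published
SDs exceed the means, ruling out normals on a positive quantity). Strength
tests map to their loaded muscle (IR→SSC, ER→ISP, Jobe/Starter→SSP) and are
linear in that muscle's `v_intra`:
`mean = α_sex + β(v_intra − μ_sex) + ε`, with residual SD chosen so the
group SDs match the published table and `max = mean·(γ_sex + η)` with γ
from the published max/mean ratios. The slope β = 8 kg per unit `v_intra`
was fixed by a one-off sweep so that the pooled r(SSC `v_intra`, max IR
strength) sits mid-band of the published 0.57–0.87 range (the sex gap alone
already produces r ≈ 0.75). What passing tests show is therefore that the
*pipeline* recovers and detects effects of the published size and
structure — not that real shoulders look like ellipsoids, nor that real
strength is linear in `v_intra`; relaxation effects, fat spectral
complexity, motion, and anatomical geometry are deliberately absent.

## Statistics

Pooled-variance Student's t (Welch behind a flag) accepting raw vectors or
printed `(n, mean, SD)` summaries, which is how the published table's
p-values are re-derived. Partial Spearman: average ranks, least-squares
residualization of x- and y-ranks on covariate ranks, Pearson on residuals,
t approximation with n−3 df; a constant covariate falls back to plain
Spearman with a flag. The two-way sex × ER/IR-group ANOVA uses an OLS fit
with Type II sums of squares — the conventional default for main-effect
testing in unbalanced designs without interaction priority (Type I/III
available via `typ=`); an empty cell drops the interaction with a flag.
p-values are never multiplicity-adjusted, matching the exploratory design,
and are reported at full precision (rounding happens only in display).
The ER/IR group split uses the mean-strength ratio at 0.95, ties assigned
to "high" so the cutoff is reproducible; which ratio (mean vs max) feeds
the split is not fixed by the study description, so it is configurable.

## Determinism and problem sizes

Every stochastic routine takes a seed or Generator; the pipeline fans one
global seed into per-stage child seeds through `numpy.random.SeedSequence`,
and identical config + seed reproduces outputs byte for byte. Default
problem sizes — 24×24×12 phantom grids, M = 100,000 prior draws, 1,000-rep
null calibrations, 100-seed power sweeps — were chosen so the full test
suite and the acceptance script each run in well under a minute on a
laptop-class machine while keeping Monte-Carlo error comfortably inside
the tolerances tested.

## Known limitations

* Two shells fix the diffusivities by assumption; misspecified `D_a`/`D_r`
  biases the fractions (no goodness-of-fit check is emitted).
* Single-voxel fraction precision is protocol-limited (see accuracy
  ceiling); interpret voxelwise maps qualitatively and VOI means
  quantitatively.
* The Dixon module is magnitude-only: FF > 50% aliases, and no T2*/T1 bias
  correction is applied.
* The reference Bayesian implementation this estimator class mirrors is not
  public; numeric agreement with it is not claimed, only the approach class
  (simulated-prior posterior-mean regression on shell means).
* Masks are inputs; no registration or resampling between mismatched grids
  is provided (phantom masks are re-rendered parametrically instead).
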