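# myodmi

Diffusion microstructure imaging (DMI) of skeletal muscle, packaged as a
tested analysis pipeline. The target application is quantitative MRI of the
rotator cuff — supraspinatus (SSP), infraspinatus (ISP), and subscapularis
(SSC) — where per-voxel compartment fractions and Dixon fat fraction are
related to isometric shoulder strength in a small two-sex cohort.

## The model

Each voxel's diffusion signal is a mixture of three water pools:

* **V-intra** — water inside muscle fibers, modeled as a *stick*:
  `S = exp(-b · D_a · (g·n)²)` with axial diffusivity `D_a` along the fiber
  axis `n`;
* **V-extra** — water in the endo-/perimysial space outside fibers, an
  axially symmetric *zeppelin*: `S = exp(-b · (D_r + (D_a − D_r)(g·n)²))`;
* **V-ISO** — free fluid, an isotropic *ball*: `S = exp(-b · D_iso)`.

The fractions live on the unit simplex (`V-intra + V-extra + V-ISO = 1`).
Because fractions are orientation-invariant, estimation uses **spherical
means**: averaging the signal over the 12 gradient directions of each shell
(b = 600 and 1000 s/mm²) cancels fiber orientation, and each compartment's
shell mean has a closed form, e.g.
`K_stick(b) = √(π/(4 b D_a)) · erf(√(b D_a))`. With one b0 and two shells
the three fractions are exactly determined — a deterministic linear oracle
(`fit_fractions_linear`). The production estimator
(`fit_fractions_bayes`) is a simulated-prior Bayesian posterior-mean
regression: simulate 100,000 parameter draws on the actual scheme with
matched Rician noise, reduce to shell means, and fit a degree-3 polynomial
regression from features to fractions, which both absorbs the Rician bias
and shrinks estimates optimally under noise.

Around the core fit the package provides MP-PCA denoising
(Marchenko–Pastur bulk-edge criterion on local patch PCA), trilinear
isotropic upsampling, magnitude two-point Dixon separation
(`water = (IP+OP)/2`, `fat = (IP−OP)/2`, `FF = 100·fat/(fat+water)`),
per-muscle VOI metrics with the derived ER/IR strength ratio (0.95 cutoff)
and ISP/SSC metric ratios, and the cohort battery: Student's t,
Pearson's r, partial Spearman's rho controlling for sex, Shapiro–Wilk, and
an unbalanced two-way (sex × ER/IR group) ANOVA with Type II sums of
squares. No subject images are distributed; a synthetic generator produces
phantoms and cohorts calibrated to the published per-sex summary table.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_phantom_recovery.py
python analysis/03_cohort_statistics.py
```

`01` writes `results/cohort.csv` (22 subjects). The generated SSC V-intra
comes out 0.428 ± 0.043 (male) vs 0.289 ± 0.054 (female) against published
anchors 0.42 ± 0.04 and 0.29 ± 0.05. `02` pushes one subject's phantom
through denoise → 2 mm upsampling → Bayesian fit → Dixon → VOI and prints
measured vs true per-muscle metrics (max VOI-mean fraction error 0.063 at
SNR 40; FF recovered to ~0.1 percentage points). `03` prints the battery:
the SSC V-intra sex difference is detected at p < 0.0001, the pooled
correlation of SSC V-intra with maximum internal-rotation strength is
r = +0.90 (partial Spearman ρ = +0.74 controlling for sex), and SSC V-ISO
correlates negatively (r = −0.66) — the study's qualitative pattern.

The same chain is scriptable: `myodmi simulate|preprocess|fit|dixon|voi|stats|run`
(see `myodmi run --config <yaml>` for the end-to-end pipeline with a single
seed fanned out per stage).

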