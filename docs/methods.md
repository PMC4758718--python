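# Methods

## Coordinate frame and montage construction

Each annotated pore contributes a rigid map from image pixels to the common
NPC frame: translate the pore center to the origin, rotate by minus the
NE-axis angle (plus an optional per-pore residual alignment angle,
default 0) so the NE plane lies along x, reflect across the x-axis when the
annotation marks the nucleoplasm on the positive side, and scale by the
annotation's nm-per-pixel factor. The map is an isometry up to the uniform
scale, so pairwise distances multiply by exactly that factor — a property
the test suite checks on random point pairs. "Superimposition" of excised
pore images is implemented as coordinate pooling: all particles of one
protein live in a single frame, since every downstream statistic consumes
coordinates, not gray values. Particles farther than the excision radius
(default 300 nm) from the pore center are discarded.

Axial histograms use half-open bins [k·w, (k+1)·w) with w = 10 nm by
default and edges anchored at integer multiples of w, so the NPC midplane
is always a bin boundary and counts above/below the midplane never share a
bin. Montage overlay figures draw one marker per particle, the midplane at
z = 0, the nucleoplasm label on the negative side, and graduation ticks
every 50 nm.

## Radial estimation

In a thin perpendicular section, epitopes on a ring of radius R about the
pore axis appear at x = R·cos φ with φ uniform: the arcsine (projected
ring) density 1/(π√(R²−x²)) on |x| < R, with integrable peaks at ±R.
Displacement by the antibody+gold linkage and alignment jitter convolve
this with an approximately Gaussian kernel. Two estimators are exposed:

- **KDE peak** (the default reported `R ave`): fold u = |x|, form a
  Gaussian KDE with the Silverman rule-of-thumb bandwidth
  0.9·min(sd, IQR/1.34)·n^(−1/5) (overridable by a fixed bandwidth),
  reflect the sample about 0 to remove the boundary deficit, and take the
  argmax on [0, excision radius] over a 1024-point grid. This estimates
  the mode of the *blurred* projection — the peak visible in the montage.
  With blur sd σ it sits systematically inside the true ring radius
  (measured ≈ 7 nm inward at R = 40, σ ≈ 8.6), a property of the
  observable density itself, not an estimator defect.
- **ML ring fit** (`fit_ring_model`): maximum likelihood over (R, σ) of the
  blurred arcsine model, evaluated by 96-node Gauss–Legendre quadrature in
  the ring-angle parametrisation (the integrand is smooth there even though
  the arcsine density diverges at |x| = R), optimized by L-BFGS-B from four
  starts with box bounds R ∈ [0, 300], σ ∈ [0.5, 60] nm. This deconvolves
  the blur; simulated recovery at R = 40, σ = 7 gives RMSE ≈ 1 nm at
  n ≈ 500. Truth-recovery reports (`npcgold recover`, the acceptance
  script) therefore quote the ML radius, while the summary table keeps the
  KDE peak as the value a montage reader would see.

## Axial estimation and symmetry

Particles with |x| ≤ 150 nm (configurable) enter the axial statistic;
particles with |z| ≤ 150 nm enter the radial one — the two windows are
independent, which is why the reported N(Z) and N(R) can differ. Symmetry
is decided first, by an exact two-sided binomial sign test on sign(z)
against p = 1/2 at α = 0.05, zeros excluded (the sign is undefined at the
midplane). If the test rejects, the protein is assigned the majority-sign
face and Z is the signed mean; otherwise Z is the mean of |z|, reported as
±Z. Note the test cannot reject below n = 6 (the minimum two-sided p at
n = 5 is 1/16), so very small samples always classify symmetric; the
default minimum of 10 particles per axis keeps the test meaningful. The
folded mean is upward-biased when the true offset is small relative to the
axial spread (E|Z₀ + ε| > |Z₀| for Z₀ → 0); the per-side mixture mean was
considered and not adopted as the default because Fig-style tables report
a single ± value.

## Bootstrap errors

All reported "± err" values are half-widths of percentile bootstrap
intervals: B resamples with replacement (default 2000, seeded from the
analysis config), statistic recomputed per resample, interval at the
configured level (default 95%). For the mean this achieves 90–99% empirical
coverage at n = 50 (checked by simulation); for the KDE peak the interval
reflects sampling variability of the peak location, not the blur-induced
bias discussed above. Degenerate all-identical samples short-circuit to a
zero-width error.

## Synthetic labeling model

The simulator emulates the physical chain that produces a gold particle:
epitopes on a ring of radius R₀ at axial offset Z₀ (both faces with
independent random face assignment when symmetric, one face otherwise;
ring angles continuous by default, with an optional discrete-spoke mode
for the 8-fold symmetric pore), section-slab truncation (|depth| ≤ t/2,
default t = 80 nm, configurable, may be infinite), Bernoulli thinning by
labeling efficiency, displacement by the antibody+gold linkage (uniform in
a 20 nm ball by default — two ~7 nm IgG reaches plus a 6 nm gold radius;
or isotropic normal), projection to (x, z) by dropping the depth
coordinate, Gaussian alignment jitter (default sd 5 nm), and excision at
300 nm. Defaults of 25 pores × 20 epitopes ≈ 500 particles per protein
match a realistic montage-scale dataset. Ground truth (R₀, Z₀, symmetry)
travels with the dataset, and `write_dataset` can emit the tables in raw
image coordinates (random pore placement, orientation and nucleoplasm
side, inverted through the common-frame map) so simulated data exercises
the full alignment path and is indistinguishable from real input.

What the simulator does **not** model: electron-optical contrast, particle
clustering or double labeling, surface-exposure bias of resin-embedded
epitopes, non-perpendicular sectioning, or annotation error in the pore
center and NE angle beyond the isotropic jitter term. Passing recovery
tests therefore demonstrate correctness of the geometry and statistics
under the stated generative assumptions, not robustness to every real-data
pathology.

## Numerical and design choices

- Half-open binning with edges anchored at 0 (midplane a boundary).
- KDE: hand-written Gaussian kernel sum (vectorized) rather than a library
  KDE, because the bootstrap needs a cheap evaluator, the Silverman
  rule-of-thumb constant differs between libraries, and boundary
  reflection at 0 is required for folded data; an independent library KDE
  cross-checks it in the tests.
- Ring-density quadrature: fixed 96-node Gauss–Legendre in ring angle;
  unit mass holds to 1e-6 against adaptive quadrature.
- Degenerate inputs: all-identical samples give zero-width errors; all-zero
  z classifies symmetric; empty tables read as empty results with a logged
  warning; a protein failing the minimum particle count on either axis is
  skipped with a logged warning rather than emitting a partial row, since
  the summary schema requires both axes.
- Determinism: every stochastic step (simulation, bootstrap) is driven by
  an explicit seed; identical config + seed reproduce byte-identical
  summary tables, and each run writes a manifest (config echo, input
  hashes, library versions) sufficient to reproduce it.
- Problem sizes in the test and acceptance runs (20-seed sweeps at 25
  pores × 20 epitopes; 300×500 bootstrap replicates; 10⁵-particle
  Monte-Carlo identity checks) were chosen to make Monte-Carlo error small
  relative to the tolerances while keeping a full run in the low minutes
  on one CPU.

## Known limitations

- The KDE-peak radial value intentionally reports the blurred montage mode;
  users wanting the epitope ring radius should use the ML fit.
- The sign test treats particles as independent, ignoring within-pore
  correlation; with few pores and many particles per pore the test can be
  anticonservative.
- The folded-Z bias near zero offset (above) makes small symmetric offsets
  read slightly large.
- Real deposited coordinate tables vary in whether they are per-micrograph
  or already montage-frame; the table dialect must declare units and frame,
  and mis-declared input is not detectable from the numbers alone.
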