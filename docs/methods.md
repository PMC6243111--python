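# Methods

`peritract` implements a within-subject, longitudinal analysis of white-matter
(WM) circuitry around traumatic cerebral microbleeds (CMBs). The design goal
is patient-tailored inference: instead of warping all subjects to a template
and running voxel-wise statistics, each subject's own tractography is matched
across imaging sessions, and change statistics are evaluated along matched
streamlines, against an empirical noise floor measured in rescanned controls.

## Diffusion model and tractography

The diffusion tensor `D` (symmetric 3×3, mm²/s) is estimated per voxel from
single-shell diffusion-weighted images under the monoexponential model
`S_k = S0 exp(-b g_kᵀ D g_k)` by unweighted log-linear least squares: with
design rows `b·(g_x², g_y², g_z², 2g_xg_y, 2g_xg_z, 2g_yg_z)`, the six unique
components solve `B d = log(S0) - log(S_k)` through one shared pseudoinverse.
Weighted or robust estimators (WLS, RESTORE) would improve behaviour at low
SNR but introduce estimator-specific tuning; the log-linear fit is the
reproducible baseline and is exact on noiseless data (round-trip residual
< 1e-8 mm²/s in the test suite). Voxels with non-positive signal are flagged
invalid rather than raising.

Scalar maps follow the standard eigenvalue formulas with λ1 ≥ λ2 ≥ λ3:
fractional anisotropy FA = √(3/2)·‖λ − λ̄‖/‖λ‖ (zero tensor ⇒ FA 0 by
convention), mean diffusivity MD = λ̄, and the Westin linear measure
CL = (λ1 − λ2)/(λ1 + λ2 + λ3). CL is used as the seeding criterion because
it is bounded in [0, 1] and selective for single-orientation voxels.

Tractography is deterministic fixed step-length propagation along the
trilinearly interpolated principal eigenvector, run in both directions from
each seed and concatenated. Defaults: seed spacing 0.5 mm, CL start
threshold 0.3, FA stopping threshold 0.17, step 0.5 mm, streamline length
restricted to [20, 110] mm. Bends are limited by a maximum turning angle per
step (default 35°); a per-step angle is used rather than a curvature in
mm⁻¹ because the latter is unit-ambiguous across tools. Eigenvector sign is
chosen to preserve the direction of travel. All propagation is vectorized
across active seeds, so dense seeding stays fast.

## Streamlines as space curves

Streamlines are treated as piecewise-differentiable 3D space curves. After
cubic-spline resampling to a uniform arc-length grid (default 0.5 mm,
matching the tracking step), curvature and torsion are computed from
finite-difference Frenet formulas

    κ = |r′ × r″| / |r′|³,   τ = (r′ × r″)·r‴ / |r′ × r″|²,

with centred differences in the interior and one-sided differences at the
ends. Both are invariant under rigid motion, which is the property the
matcher relies on; the suite verifies closed forms for circles (κ = 1/r,
τ = 0) and helices (κ = a/(a²+b²), τ = b/(a²+b²)) to 1% at 0.2 mm sampling
and rigid-motion invariance to 1e-6. Note that κ and τ are also invariant
under reversal of traversal direction (r′ and r‴ flip sign together);
reversal merely reverses the profile order. Torsion is numerically
meaningless on near-straight stretches, so it is flagged undefined where
κ < 1e-4 mm⁻¹ (configurable; the pipeline raises the floor to 0.02 mm⁻¹ on
noisy tracked data). Optional Gaussian smoothing of coordinates (σ in mm,
off by default) is available for noisy tractography output; the pipeline
uses σ = 2 mm.

## Cross-session matching

Two curves relate by a rigid transform iff their κ/τ profiles agree under a
one-to-one arc-length correspondence. Matching proceeds in four steps:

1. **Curve index correspondence.** Both curves are resampled at a common
   spacing; the target's orientation (which end is "start") and the integer
   offset of the shorter curve along the longer are chosen to minimize the
   mean squared κ/τ difference over the overlap. A `position` metric
   (minimizing mean Euclidean distance of paired points) is available for
   curves already in a common frame: for straight or constant-curvature
   stretches the invariant profile carries no alignment information, and
   spatial alignment is then the only well-posed choice. The pipeline uses
   the position metric; the feature metric is the default for frame-free
   matching.
2. **Feature distance.** Mean over corresponded samples of
   (Δκ)² + w(Δτ)², w = 1 by default; samples with undefined torsion
   contribute the curvature term only.
3. **Assignment.** Greedy one-to-one matching on the feature distance with
   an admissibility ceiling (default 0.01 mm⁻²). Greedy equals the
   brute-force minimum-total-distance assignment in ≥ 95% of random
   noiseless bundle trials (oracle-tested); an optimal Hungarian assignment
   is available behind a flag. An optional small position term in the
   assignment cost (pipeline default 1e-3 per mm) resolves ties among
   geometrically indistinguishable curves such as parallel tracks — without
   it, the within-bundle assignment is an arbitrary permutation.
4. **Transforms.** Each matched pair gets a local rigid transform from
   Schönemann's closed-form SVD solution of the orthogonal Procrustes
   problem (proper rotation enforced); the global transform is a single
   pooled Procrustes over all matched point pairs, which directly minimizes
   the total squared inter-curve distance.

Identifiability caveat: a circular arc maps onto itself under rotation about
its own axis, so no matcher can recover the global transform from
constant-curvature geometry alone. The synthetic generator therefore
includes a varying-curvature ("sine") bundle family for transform-recovery
studies; on tracked sine phantoms at SNR 30 the global rotation is recovered
to < 1e-2 rad while the translation floors at ~0.6 mm — the same
between-session reconstruction variability that the uncertainty radius
(below) quantifies, not an estimator bias.

## Prototyping

A bundle's prototype is its most trajectory-representative streamline:
pairwise symmetrized mean closest-point distances feed a Gaussian affinity
`a(i,j) = exp(-d²/σ_aff²)` (σ_aff default 5 mm, on the order of a bundle's
width), and the streamline with the largest affinity row sum is selected;
ties prefer the longer streamline then the lower index. Selection is
deliberately not by maximum length, which is noise-vulnerable (regression
test: an elongated outlier is never selected). For dispersed bundles an
optional mode partitions the affinity matrix spectrally, with the cluster
count chosen by the eigengap, and returns one prototype per cluster.

## Microbleed detection and etiology

SWI and FLAIR volumes are first normalized by the in-mask median intensity,
making every later threshold scale-free. Detection stages:

- **Voxel stage.** Hypointense voxels fall below median − z·(1.4826·MAD)
  (z = 3). A mask-normalized Gaussian presmoothing (σ = 0.5 voxel) localizes
  candidate regions and suppresses isolated noise voxels; candidates are
  then refined to the raw-threshold voxels so sizes are not inflated and
  adjacent lesions bridged by smoothing are split again. 26-connected
  components outside [4, 120] mm³ are discarded (4 mm³ ≈ the conventional
  2 mm minimum CMB diameter); components 26-adjacent to the brain-mask
  boundary are rejected outright, since CMBs are by definition not connected
  to the meninges.
- **Shape stage.** Sphericity is the isoperimetric ratio
  π^(1/3)(6V)^(2/3)/A of the component's surface — a marching-cubes mesh of
  the Gaussian-smoothed occupancy field for blob-like components (the
  smoothing suppresses the voxelization staircase), or the exact voxel-face
  surface for thin components where a mesh is unreliable. Labels follow the
  Microbleed Anatomic Rating Scale vocabulary: *certain* requires
  sphericity ≥ 0.85 and margin contrast ≥ 0.3; *doubtful* requires
  sphericity ≥ 0.65 or contrast ≥ 0.15; all else is rejected. All cut-offs
  are operating points exposed in `DetectorParams`, not physical constants.
- **Etiology stage.** A CMB is *traumatic* iff its 1-voxel perilesional
  shell is FLAIR-hyperintense over ≥ 50% of its voxels acutely (edema ring)
  and ≤ 10% chronically (the edema resolved). A ring persisting across
  sessions indicates a chronic small-vessel etiology (*non_traumatic*);
  no acute ring, or a missing chronic scan, is *indeterminate*.

On the phantom cohort used in validation (20 volumes, 10 lesions each,
radius 1.2–3 mm, contrast ≥ 0.4), sensitivity is ≥ 0.95 with ≤ 1 false
positive per volume, and the etiology rule is exact on its three-case
fixture.

## Uncertainty ellipsoid and radius

Repeated scans of the same (control) subject measure how much tractography
differs for non-biological reasons. For every matched point pair the
residual displacement (target − transformed source) is deposited at the
source voxel; each voxel's displacement set is summarized by its raw second
moment M = mean(d dᵀ) about the origin — deliberately not mean-centred, so a
purely systematic shift contributes as much as random spread. The
uncertainty radius is 2·√λ_max(M): the full major axis of the ellipsoid,
spanning ±|d| for a constant displacement d (the factor is configurable for
users preferring a semi-axis convention). Voxels with fewer than 5 samples
are masked. The estimator recovers planted magnitudes (constant 2 mm shift ⇒
radius 4.0; isotropic σ = 1 mm noise ⇒ radius 2.0 ± 0.15 at n = 1000). On
tracked phantoms the radius is scale-dependent — sparser seeding means the
nearest matched reconstruction lies farther away — so radii are comparable
only within a fixed tracking configuration.

## Along-tract statistics and inference

FA is sampled by trilinear interpolation along each resampled streamline.
Pointwise mean and sample variance (n−1) over a bundle's streamlines are
evaluated on the *common domain*: the longest arc-length interval covered by
at least 80% of the bundle's streamlines ("preponderance" operationalized as
coverage 0.8, configurable).

The longitudinal statistic is the between-session change in perilesional
mean FA. In the pipeline it is estimated pairwise: each matched streamline is
differenced against its own counterpart over the *perilesional window*
(samples within 1.5 × ROI radius of the lesion centroid, transferred into
the follow-up session through the point correspondence). Pairwise
differencing cancels per-track composition offsets (edge vs. core partial
volume) that dominate a difference of bundle means, and the window keeps two
lesions on one tract statistically separable.

Inference is reference-based: control subjects rescanned over a short
interval are processed by the *identical* estimator at pseudo-lesion sites,
their per-bundle ΔmeanFA values pooled within age group into an empirical
reference (μ_ref, σ_ref). Each patient bundle is tested with
z = (Δ − μ_ref)/σ_ref, two-sided normal p, and Holm step-down FWER
correction across the subject's bundles at α = 0.05 (Holm is uniformly more
powerful than Bonferroni at the same FWER; Bonferroni is available).
Patients are compared against the age-matched (old-control) reference. The
per-subject summary is the fraction of traumatic CMBs with at least one
significantly changed perilesional bundle. At cohort level an ANCOVA of
ΔmeanFA on age group × diagnosis with sex as covariate is fitted
(statsmodels OLS, type-II ANOVA); when a stratification cell is empty by
design — no young patients — the additive model is used. A Welch t utility
(unequal-variance t with Welch–Satterthwaite degrees of freedom) supports
demographic comparisons.

## Synthetic data: what it emulates, and what it does not

The generator produces every input the pipeline consumes, with full seed
determinism and emitted ground truth:

- tensor fields with coherent bundles (straight / arc / helix / sine
  centerlines; bundle eigenvalues (1.7, 0.2, 0.2)×10⁻³ mm²/s, FA ≈ 0.8704;
  isotropic background 0.7×10⁻³, FA = 0), default grid 64³ at 2 mm;
- DWI at b = 0 and 1000 s/mm² over 64 Fibonacci-sphere directions with
  Rician magnitude noise (SNR = S0/σ, default 30);
- SWI with hypointense spherical lesions and acute/chronic FLAIR pairs with
  resolving or persisting hyperintense rings, inside an ellipsoidal brain
  mask (additive Gaussian noise, σ = 0.02 of background);
- longitudinal session pairs related by a bounded rigid motion (default 2°
  + ~1 mm), with the perilesional FA decrease planted *exactly* via
  closed-form eigenvalue shrinkage toward isotropy (MD-preserving), default
  ΔFA = −0.10;
- cohorts with patient / old-control / young-control arms, per-subject
  seeds spawned from one master seed, and a planted fraction of affected
  CMBs.

The phantoms emulate measurement geometry and noise, not anatomy: no
crossing or kissing fibres, no susceptibility or eddy artifacts, no real
head shapes, and bundle FA is homogeneous. Passing tests therefore
demonstrate that the estimators recover what was planted under realistic
noise and motion — not that the pipeline resolves crossing-fibre anatomy.

## Validation problem sizes and numerical choices

Cohort-level validation uses four parallel bundles (radius 6 mm, length
66 mm) in a 96 mm cube at 2 mm voxels, tracking seeded at 3 mm with up to 16
streamlines matched per bundle, four lesions per patient, and cohorts of
4–8 patients with 3–4 old and 0–2 young controls — sizes chosen so the full
suite and the acceptance script each run on a single CPU in minutes while
leaving every stage (detection, tracking, matching, uncertainty, testing)
exercised end-to-end. The pipeline discards tracked streamlines whose mean
sampled FA falls below a quality floor (0.3 generally; 0.8 in the phantom
cohorts, where bundle FA is 0.87 and partial-volume shells fall well below)
— this restricts inference to tracks coursing through coherent WM and is the
synthetic analogue of excluding poorly reconstructed fibres. Ties are broken
deterministically everywhere (feature distance, then lower source index;
prototype ties by length then index), so equal configurations reproduce
byte-identical reports.

## Known limitations

- Rigid matching only; no deformable streamline registration.
- Single-tensor model; no multi-shell or crossing-fibre reconstruction.
- The curvature/torsion feature space is blind to the alignment of
  straight and constant-curvature stretches; the position metric and
  position-weighted assignment mitigate this for co-registered sessions.
- Reference distributions assume control and patient scans share the
  acquisition and processing configuration.
- Detector thresholds are tuned operating points for normalized
  intensities; new contrasts require revisiting `DetectorParams`.
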