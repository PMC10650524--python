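# Methods

## Statistical model

The observation unit is a rectangular microscope window (default
1200 × 900 μm, origin at a corner, x ∈ [0, width], y ∈ [0, height])
containing the planar coordinates of stomatal centers. Three per-window
statistics are computed:

* **Stomatal density** SD = n / A with A the window area in mm²
  (1.08 mm² for the default window).
* **Mean nearest-neighbor distance** MNND: the arithmetic mean over the n
  stomata of each stoma's Euclidean distance to its closest neighbor
  within the same window, in μm. No edge correction is applied on the
  measurement path: points near the border lack neighbors outside the
  window, which biases MNND upward by roughly
  0.05 · P/(n · r̄) relative (P the perimeter), i.e. ~2–3% at
  study-typical counts. A toroidal (periodic) metric is provided purely so
  simulation checks can be run free of that bias; it is never the default
  for real data.
* **Aggregation index** SAI = MNND / r̄_E where r̄_E = 1/(2√ρ) is the
  expected nearest-neighbor distance of a homogeneous Poisson (CSR)
  process at the observed density ρ (in μm⁻²; ρ = SD/10⁶ — the single
  unit-conversion constant in the code base). Equivalently
  SAI = 2·MNND·√ρ; both forms agree to floating-point precision and the
  index is dimensionless. Interpretation: SAI < 1 aggregated, = 1 random,
  > 1 regular; the asymptotic maximum 2·√(2/√3) ≈ 2.1491 is attained by a
  hexagonal lattice. Small, uncorrected windows can exceed that bound
  (four points on the window corners give SAI = 2√3), so it is not
  enforced per window. Per-window SAI is reported descriptively against 1;
  a classical Clark–Evans z-test is available as an optional extra.

## Scaling analysis

With x = ln(MNND μm) and y = ln(SD mm⁻²) pooled per species across
windows, the line y = a + b·x is fitted by reduced major axis:
|b| = s_y/s_x, sign(b) = sign(r), a = ȳ − b·x̄, r² the squared Pearson
correlation. RMA is used because both axes are estimates. Under CSR the
relation is exact with b = −2 and a = ln(10⁶/4) ≈ 12.43; fitted CIs
excluding those anchors indicate non-random dispersion.

Uncertainty comes from a pair bootstrap: (x, y) windows are resampled with
replacement (n per replicate, default 3000 replicates), the RMA refit on
each, and 95% CIs taken as the 2.5th/97.5th empirical quantiles (numpy's
linear interpolation between order statistics; the quantile definition is
deliberately a single documented choice). The resampling unit is the
window, pooled per species; leaves are not treated as clusters — the
within-leaf permutation analysis carries the leaf structure instead.
Degenerate resamples (zero variance on an axis or exactly zero covariance)
are redrawn, at most 100 attempts per replicate, then an error is raised.
A cluster-bootstrap variant (``clusters=`` labels, typically the leaf id)
resamples whole leaves instead of windows for users who prefer to
acknowledge within-leaf correlation in the scaling CIs.

Two groups are compared on the replicate scale: each group gets an
independent bootstrap stream (both spawned from the one user seed), the
replicate-wise differences D_k = θ̂₁,k − θ̂₂,k are formed for intercept and
slope, and the percentile 95% CI of D decides the verdict (CI ∋ 0 → no
significant difference; lower bound > 0 → group 1 larger; upper bound
< 0 → group 2 larger). Whether the two streams should be paired or
independent is underdetermined; independent streams are the default and
the seed scheme records the choice.

### Finite-count attenuation of the RMA slope

Given a window with n points, ln MNND carries sampling noise with standard
deviation ≈ 0.52/√n that is independent of the density signal. RMA's
|b| = s_y/s_x means this noise inflates s_x and shrinks |b|: at
study-typical counts (155–437 per window) the expected fitted slope under
CSR is ≈ −1.96 rather than −2, and the ≈ ±0.05-wide 95% CI then contains
−2 in well under 95% of realizations. The CSR anchors are asymptotic in
the per-window count. Consequently the anchor-recovery acceptance check
simulates CSR windows with counts log-uniform in [2000, 20000] (224
windows, toroidal distances), where the attenuation is negligible and the
bootstrap CIs contain (−2, 12.43) at essentially their nominal rate, while
a separate test pins the study-scale behavior (fitted slope in
(−2.05, −1.88)). Interpreting real fits therefore warrants slight caution:
a slope a few percent shallower than −2 is expected under randomness at
these counts, whereas the strongly steeper slopes produced by repulsive
patterns are far outside that effect.

## Within-leaf comparisons

The sampling design is paired within leaves: every leaf contributes one
window per (layer, position) cell. Cell contrasts (each layer pair within
a position; the two positions within each layer) are tested with a
sign-flip permutation test on the per-leaf paired differences, statistic
T = mean difference, two-sided p-value
(1 + #{|T_perm| ≥ |T_obs|}) / (1 + n_perm) for Monte-Carlo sampling
(default n_perm = 9999) or the exact tail proportion over all 2ⁿ sign
patterns when 2ⁿ ≤ n_perm. This is a deliberate, assumption-light stand-in
for a linear mixed-effects model with leaf as a random effect: it shares
the comparison structure (within-leaf pairing) but not the LMM's test
mechanics, and reports label it as such. α = 0.05, no multiple-testing
correction by default (a Holm option exists behind a flag, via
statsmodels).

Letters are assigned by the transitive-closure convention: cells are
grouped by the connected components of the "not significantly different at
α" graph, so a chain A≈B, B≈C shares one letter even if A vs. C alone is
significant. This is simpler than clique-based compact letter displays and
can merge cells a clique display would separate; it is the documented,
intended behavior. Components are lettered in order of decreasing mean.

Summaries report mean, median and CV% = 100·(sample SD)/mean (two
decimals) per species × layer × position × metric.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not leaf images:

* **CSR**: Poisson(ρA) count, uniform coordinates — the SAI = 1 null.
* **Matérn type-II hard core** (default study process): Poisson proposals
  with i.i.d. uniform marks; a point survives iff no proposal with a
  smaller mark lies within the hard-core radius h. Minimum spacing ≥ h by
  construction. On a torus the retained intensity is
  λ_ret = (1 − e^{−λπh²})/(πh²), which the generator inverts to
  pre-compensate proposal intensities for thinning loss and the tests use
  as a quantitative oracle. Simple sequential inhibition is available as
  an alternative hard-core kind (denser packing, no closed form).
* **Thomas cluster**: Poisson parents (simulated with a 4σ margin so
  boundary clusters contribute), Poisson(μ) offspring per parent scattered
  N(0, σ²I), clipped to the window — the SAI < 1 regime.

The default study design mirrors a two-species leaf survey: species A with
16 leaves × 3 layers × 2 positions (96 windows) and species B with
16 leaves × 4 layers × 2 positions (128 windows), 224 windows total.
Density schedules (mm⁻²) are A: midrib 340/295/250 apex→base, margin
220/212/205; B: midrib 350/312/272/232, margin 215/208/202/196 — midrib
above margin in every layer, declining apex→base at the midrib, nearly
flat at the margin. These values are generator parameters chosen to be
realistic for dense-stomata evergreen leaves; they are not measurements.
The hard-core radius defaults to 25 μm, consistent with the one-cell
spacing rule for stomata of ~20–30 μm length, giving SAI ≈ 1.2–1.4 across
the schedule. Leaf-to-leaf variability is a mean-one lognormal factor
(σ = 0.05, clipped to ±15%) shared by all windows of a leaf. Realized
window counts are confined to [155, 437] by redrawing the whole window
(logged in the manifest); with the default schedule redraws are rare, so
the conditioning distorts cell means by far less than the 10% tracking
tolerance the generator guarantees.

All randomness descends from one master seed through
`numpy.random.SeedSequence` spawning in a fixed order (species block →
leaf-factor stream + one child per window), so a dataset is reproduced
bit-identically from the manifest's seed.

What the generator does *not* emulate: stomatal size and shape, anisotropy
along veins, scale-dependent aggregation (regular at small scales, random
at areole scale), measurement noise in hand-clicked centers, or missing
stomata at window borders. Passing tests therefore demonstrate the
pipeline's correctness on patterns with known structure, not the biology
of any particular species.

## Numerical choices and degenerate inputs

* Nearest neighbors via `scipy.spatial.cKDTree` for n > 64, an O(n²) scan
  below; results are identical (tested against the brute-force oracle).
  The toroidal metric uses the tree's periodic box; coordinates exactly on
  the far edge wrap to 0.
* Patterns with fewer than two points have no MNND: window statistics
  raise an error naming the window. Duplicate coordinates (possible in
  hand-clicked data, impossible for real stomata) are kept but logged as
  warnings; they contribute zero NNDs.
* Matérn-II proposal intensities are refused when the target retained
  intensity exceeds 1/(πh²), and proposal packings when the expected disc
  area λ·π(h/2)² would cover the window.
* Coordinate CSVs serialize floats with 6 significant digits (write →
  read → write is byte-identical); all internal computation is double
  precision.
* RMA requires n ≥ 3, nonzero variance on both axes and nonzero
  correlation (the slope sign is otherwise undefined); these raise
  immediately on the original data rather than inside the bootstrap.

## Problem sizes

Default analyses run in seconds: 224 windows of 155–437 points, 3000
bootstrap replicates (vectorized over replicates), 9999-permutation tests.
The simulation-based validation suites use 50 meta-repetitions of
224-window CSR studies for anchor recovery, 500 windows for the CSR SAI
reference, 200 patterns for the brute-force oracle, and 40 meta-repetitions
for the null behavior of the group comparison — sizes chosen to make
Monte-Carlo standard errors small relative to the tolerances being
asserted.

## Known limitations

* The permutation stand-in matches the comparison structure of a
  mixed-effects analysis, not its statistics; letters from the two
  approaches can differ near the significance boundary.
* No edge-corrected MNND estimator (Donnelly or border-region) is
  implemented; the Euclidean path reproduces the field's common,
  uncorrected measurement convention, and the toroidal path exists for
  simulation validation only.
* The default pair bootstrap ignores leaf-level clustering of windows;
  the cluster-bootstrap flag widens CIs accordingly but is not the
  default reporting path.
* SAI is a single-scale summary at the window size; it cannot detect
  scale-dependent structure within the window.
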