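# Methods

This note documents the statistical procedures, the synthetic data model
used to validate them, and the design decisions taken where the problem
left genuine freedom.

## Buffer geometry

Land cover is a categorical raster on a projected metric grid; classes are
`forest`, `urban`, `agriculture` and the complement `other`, so per-buffer
proportions always partition unity. A cell belongs to a buffer iff its
*center* lies within Euclidean distance r of the site (compared on squared
distances, hence exact in floating point). This rule is deliberately
simple: it is checkable against brute-force enumeration of cell centers,
and its area bias relative to exact polygon clipping vanishes as
`cell_size / r → 0` (at the default 25 m cells and the smallest 150 m
radius, a buffer already holds ~113 cells).

Buffers must lie fully inside the grid; out-of-extent buffers raise an
error rather than being silently truncated, because truncation biases
proportions in a direction that correlates with site position. Producers
of grids are expected to pad the landscape by the largest radius — the
synthetic generator does.

The radius series is half-open `[r_min, r_max)` with a uniform step. This
is a convention choice for the ambiguous endpoint of a "from 150 to 5000 m
by 10 m" design: the half-open form gives 485 radii (150 … 4990), the
count the canonical multi-scale design uses, where an inclusive endpoint
would give 486.

For a whole radius series, squared distances from a site to every cell
center are sorted once; each radius is then a prefix of that ordering, so
profiling 485 radii costs one O(N log N) sort per site instead of 485 disc
scans. Every entry is identical (not merely close) to the per-call
`cover_fraction` computation, and tests assert this.

## Community responses

Counts are pooled across sessions and life stages before computing
responses, giving one value per site. Shannon diversity uses the natural
logarithm; sites with no individuals have no defined proportions and are
dropped with a logged warning. Abundance is total individuals divided by
sampling effort (number of larval habitats plus CO₂-baited traps across
all sessions; a count ≥ 1 per site).

Rare taxa carry too few individuals per site for stable regressions. The
common-taxa filter keeps the shortest prefix of taxa, sorted by decreasing
total count (alphabetical tie-break, so deterministic), whose cumulative
share of all individuals reaches a threshold, default 0.97. Note the
filter is a cumulative-share rule: on a community whose seven dominant
taxa hold exactly 97% in expectation, sampling noise can push the realized
cut to six or eight taxa.

A session-subset operation supports seasonality checks (e.g. dropping
spring sessions); an empty subset is an error, not an all-zero table.

## Scale selection

For one component and one response, the R² of the with-intercept OLS fit
(equivalently, squared Pearson correlation) is computed at every radius;
the selected scale is the argmax. Two conventions:

* **Zero-variance cover** (e.g. no urban cells within small radii of any
  site) gives R² = 0 rather than an error, keeping profiles total over the
  series; occurrences are logged.
* **Ties** resolve to the smallest radius, on parsimony grounds: absent
  evidence for a larger extent, prefer the smaller one.

Plain R² is used rather than adjusted R²; for single-predictor models at
fixed n the two rank radii identically, so the selection is unaffected.

### Bootstrap

The resampling unit is the site — the whole row of response plus covers —
because sites are the independent observational units. Each of B
replicates draws n sites with replacement and recomputes the full profile.
A resample with fewer than three distinct sites or a constant response
cannot support a regression; such draws are *redrawn* rather than dropped,
keeping B fixed (redraw counts are logged and reported). The distribution
is summarized by its mode (tie → smallest radius) and a central percentile
interval. B defaults to 1000.

## Standardized effect models

Each response is regressed on the three components jointly, with response
and predictors all z-scored (sample SD, n−1), so coefficients are fully
standardized and comparable across components. Full standardization (the
response too) is a choice; it makes a planted "standardized effect"
directly the estimand. p-values are two-sided t-tests with n−4 residual
df; no multiple-testing correction is applied, and the significance codes
are p ≤ .10 → `p`, ≤ .05 → `*`, ≤ .01 → `**`, ≤ .001 → `***`.

Pairwise predictor correlation above |r| = 0.95 raises a collinearity
error naming the pair: with three gradients that are causally entangled in
real landscapes, a silent fit of a near-singular design would produce
arbitrary signs. The limit is deliberately permissive (real anthropisation
components are strongly correlated); it only rejects designs where the
individual betas are numerically meaningless.

The a priori comparison refits the same model with every component at one
common radius, default 400 m — the median daily movement distance of
mosquitoes — to quantify what is lost by fixing the scale in advance.

## Synthetic data model

The generator produces data with planted truth so every stage is testable
by parameter recovery.

**Landscape.** One Gaussian-filtered white-noise field per declared class
(filter σ = autocorrelation range / (2 · cell size)); classes claim their
target share of cells in declaration order, each taking the
highest-field-value cells still unassigned. Quantile thresholding makes
realized proportions exact to within one cell. The autocorrelation range
(default 300 m) governs how correlated cover is between nearby radii —
i.e. how sharply the R² profile peaks, the property recovery tests probe.

**Sites.** Rejection-sampled uniform points in the grid shrunk by a margin
equal to the largest radius (so the edge policy never triggers), with a
pairwise minimum separation (default 400 m) emulating a design that limits
buffer overlap. Efforts are uniform integers in 8–20.

**Response.** Linear predictor η_s = Σ_c β_c · z(cover at true_scale_c).
Three noise conventions:

* `noise_sd` — absolute Gaussian noise SD (0 gives exact recovery);
* `snr` — noise SD set to sd(η)/snr per dataset;
* neither — σ² = max(0, 1 − var(η)), giving the response unit sample
  variance so the planted β are themselves the standardized coefficients
  the effect model estimates. This calibration is what lets replicated
  fits recover the planted values without systematic shrinkage from
  standardizing a response whose variance exceeds the signal's.

Count families draw per-site totals with log mean =
log(mean_total) + 0.4·η from a Poisson or negative-binomial (default
dispersion k = 4, so SD ≈ half the mean at μ = 750 — strong
overdispersion typical of larval-plus-trap counts), then split them
multinomially across taxa (7 common taxa with geometric weights holding
97% of individuals, an even rare tail with the remaining 3% over 11 taxa)
and uniformly across 5 sessions.

**Defaults as study conditions.** 16 sites; radius series 150–2000 m in
50 m steps (a coarsened desk-scale analogue of 150–5000 × 10 m, chosen so
replicated experiments run in seconds while keeping ≥ 35 candidate
scales); planted scales 200 / 500 / 2000 m and planted standardized
effects −0.5 / +0.6 / 0.0 for forest / urban / agriculture; 25 m cells on
a 260-cell grid whose 2000 m margin leaves a 2.5 km core for site
placement.

**What the generator does not emulate.** Real geography (elevation,
lakes, rivers), vector polygons (everything is rasterized), spatial
autocorrelation of the *response* beyond what cover induces, detection
error, and between-session population dynamics. Passing recovery tests
therefore demonstrates the statistical machinery is correct and
well-calibrated under the stated generative model — not that a 16-site
field survey has power to resolve any particular real-world scale.

## Recovery experiments

* **Scale recovery** uses a single planted component (default forest at
  1000 m, β = 1): with noise 0 selection is exact by construction (R² = 1
  at the planted radius, strictly less elsewhere); at snr 3 the median
  |selected − true| stays within 2 grid steps over 100 replicates.
* **Bootstrap agreement** checks, on strong-signal datasets (snr 5), that
  the B = 200 bootstrap mode equals the full-data selected scale in ≥ 90%
  of replicates and that the mass concentrates near the mode.
* **Effect recovery** uses the three-component default; means of the
  estimated betas over 200 replicates match the planted values within
  Monte-Carlo error, and sign recovery for the nonzero effects exceeds
  95%.
* **A priori attenuation** plants a 0.6 effect at 2000 m and compares
  |β| fitted at the planted scales against the 400 m a priori fit,
  noise-free. This experiment uses a sparser class mix (25/15/15%) and
  wider site spacing (600 m) than the default: at 2000 m radii,
  compositional closure pushes class covers toward collinearity, and the
  attenuation question requires a fittable three-component design at both
  scales.

Replicates whose design matrix at the planted scales is collinear or
degenerate are redrawn with a fresh seed (the same convention the
bootstrap uses for degenerate resamples); redraws are rare under the
default designs and are counted.

All experiment randomness descends from one `SeedSequence`, so every
result is exactly reproducible from a single integer seed.

## Numerical details and degenerate inputs

* Distances are compared as squared quantities; no square roots, so
  boundary cells are classified identically in the fast profiling path,
  the per-call path and the brute-force oracle.
* R² is clipped to [0, 1] against rounding at perfect fits.
* An all-zero count site: undefined Shannon, excluded with a warning.
* A constant response across sites: hard error at profile time (no scale
  is identifiable).
* Site packing and landscape thresholds are deterministic given a seed;
  infeasible packings fail after bounded restarts.

## Known limitations

* Selection maximizes R² over a discrete radius grid; uncertainty from
  the grid step itself (≤ half a step) is not modeled.
* The bootstrap mode on a discrete grid is a coarse location summary;
  with B = 200 and flat profiles it can sit anywhere in a wide plateau
  (mirrored by the wide central intervals reported alongside).
* No spatial autocorrelation correction in the regressions: sites are
  treated as independent, as in the motivating survey design.
* The collinearity guard rejects rather than regularizes; strongly
  entangled gradients require a different estimand (e.g. joint
  anthropisation axes), which is out of scope.
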