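# Methods

This note documents the statistical models implemented in `arcrange`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make results exact and
reproducible.

## Home-range estimation

The utilization distribution (UD) of an animal-year is a mixture of isotropic
bivariate normal kernels, one per GPS fix, with a single scalar bandwidth
*h* (metres). The LSCV score

LSCV(h) = ∫ f̂² − (2/n) Σᵢ f̂₋ᵢ(xᵢ)

is evaluated in closed form from pairwise squared distances (the convolution
of two normal kernels is a normal kernel at h√2) and minimized over 100
log-spaced candidates spanning [0.05, 2] × the bivariate normal-reference
bandwidth σ·n^(−1/6), refined by golden-section search to 1e−3 relative
tolerance. Duplicate coordinates are deterministically jittered by at most
0.1 cell before scoring. LSCV's well-documented failure mode — no interior
minimum — triggers a fallback to the normal-reference bandwidth with a logged
warning; an all-identical point set is an error. The UD is evaluated on a
regular grid (default: raster-aligned at the cover cell size, configurable)
that must cover the fixes padded by ≥ 3h per side, then renormalized to unit
mass.

The 95% home range is the smallest set of highest-density cells holding 95%
of UD mass. Its polygon is the exact union of those cells' squares — no
marching-squares smoothing — so the reported area (km²) equals cell count ×
cell area and closed-form checks are exact. Against the analytic 95% disk of
a single Gaussian kernel (radius h√(−2 ln 0.05)) the cell-union area agrees
within 0.4% at cell = h/10.

MCPs are convex hulls (shapely); the multi-annual MCP pools all of an
animal's years. Annual ranges are treated as independent across years, which
is appropriate for populations with low inter-annual site fidelity. The
study-area filter keeps animals with ≥ 60% of the range polygon inside the
study area (≥ rule at the boundary) and drops outside fixes from selection
analyses.

## Season definition

Cover use is pooled over animals into bi-weekly periods anchored at the first
observed week. A trailing partial period (monitoring window ends mid-period)
is folded into the last full period, and periods with fewer fixes than 25% of
the median period count are dropped: truncated or under-sampled periods have
use proportions too unstable to cluster and otherwise surface as spurious
one-period "seasons". Per-period cover proportions are z-scored per cover
(zero-variance covers become all-zero columns) and clustered with Ward
linkage on Euclidean distance; merge heights are converted to Wishart
objective-function increments (ΔSSE) computed directly from cluster
memberships.

For the split from k to k+1 clusters, the Duda–Hart index Je(2)/Je(1) and
pseudo-t² = ((Je(1)−Je(2))/Je(2))·(n_m−2) are tabulated for k = 1..6. A low
ratio with a high pseudo-t² supports splitting further; the chosen k is the
smallest k ≥ 2 where the ratio first turns up and the pseudo-t² first turns
down relative to the previous split — the first simultaneous local extremum
of both criteria, with ties toward smaller k. (The k = 1 statistics are
one-sided and dominate whenever any structure exists, so k = 1 is reserved
for the no-structure case, detected as zero clustering variance.) If the
criteria never agree the largest Duda–Hart ratio wins and
`diagnostics["agreement"]` is false.

Ward clustering ignores time, but seasons are contiguous by definition.
Cluster labels are therefore repaired: while more runs than clusters remain,
the shortest run is dissolved into the neighbouring run whose cluster
centroid is closer, and runs are renumbered in temporal order. Season breaks
are reported as the last week of each season, e.g. `{"k": 3, "breaks_week":
[31, 39]}`.

## Resource selection

Selection is a use–availability logistic regression: response 1 for GPS
fixes, 0 for availability points drawn uniformly inside the animal's
multi-annual 100% MCP at 1 point/km² (count = round(area × density), floor
30), cover entered as dummies against the water reference, and a per-animal
random intercept so the bear is the unit of replication. The 80:20
train:test split is per-animal, round-half-up on the training count
(599 fixes → 479/120); animals with < 5 fixes go entirely to training.

No installed package fits a frequentist random-intercept logistic model, so
`arcrange.mixed_logit` implements it directly: the marginal likelihood
integrates the intercept out with adaptive Gauss–Hermite quadrature (15
nodes; each group's integrand is recentred at its mode, found by scalar
Newton iteration, and rescaled by the curvature there), and (β, log σ) is
maximized with L-BFGS-B from a plain-logistic start. Standard errors come
from the numerically differentiated Hessian. In the σ → 0 limit the fit
matches `statsmodels` `Logit` to < 1e−5; with programmed intercept variance
it recovers both slope and σ (checked in tests). Covers exhibiting complete
separation are flagged and dropped from the design; covers absent from the
data are reported as matrix with a flag.

Each cover's record carries β, SE, z = β/SE, CI = β ± 1.96·SE, Wald = z²,
and RSI = exp(|β|) reported to one decimal. The RSI is the odds-ratio
*magnitude*: avoided covers report the strength of avoidance, which is why
classification needs the sign as well — *highly selected* means β > 0 and
RSI ≥ 2.0; water is the reference class; everything else is matrix. The
reclassified three-class map preserves water cells across seasons.

Validation uses the held-out 20%: per animal, u_s is the fraction of test
fixes on highly-selected cells and a_s the fraction of cells with centres
inside the multi-annual MCP that are highly selected (availability units are
raster cells, use units are fixes). w_s = u_s/a_s; animals with a_s = 0 are
excluded with a warning. The Wald test regresses w_s on an intercept and
compares the mean to 1 with F on (1, n−1) df. Under zero programmed
preference the test rejects at 2% over 200 replicates (nominal 5%, the
conservatism reflecting the small per-replicate animal counts); under strong
programmed preference it rejects in 20/20.

## Landscape metrics

Metrics operate on the cells whose centres fall inside a range polygon.
Edges use 4-neighbour (rook) adjacency; a class edge is a cell side facing a
different class, and sides on the clip boundary count toward the total by
default (both conventions are implemented and tested). LSI = 0.25·E/√A is 1
for a single compact square patch and grows with dispersion; it is invariant
to cell-size rescaling. Edge density is class edge length per clip area in
m/ha — edge density is a length-per-area quantity, so the package uses m/ha
even where tables elsewhere print an area unit for it. Shannon–Wiener
diversity is computed on the original cover raster (not the reclassified
map), as is water LSI/edge (identical either way, since water is preserved).

## Home-range-size models

Candidates are linear mixed models of log₁₀ area with a per-animal random
intercept, fit by maximum likelihood (not REML) so AICc is comparable across
fixed-effect structures. When no animal contributes more than one range the
intercept variance is unidentifiable and the model collapses to its σ_b = 0
boundary, fit by OLS; the same fallback applies if the mixed optimizer fails
numerically. AICc = −2logL + 2k + 2k(k+1)/(n−k−1). The parameter count k
follows the published-table convention — intercept 1, +1 per named term
(reproductive status counts once despite entering as two dummies), +1 for a
quadratic, variance components uncounted — because that convention is
required to reproduce the printed k and ΔAICc columns; a standard count is
available via `k_convention="standard"`. R² is the squared correlation
between fixed-effect fitted values and observations (0 for the null model by
definition, matching the published-table convention).

Model ranking: Δᵢ = AICcᵢ − min, wᵢ = exp(−Δᵢ/2)/Σ exp(−Δⱼ/2); confidence
set = models with w ≥ 0.10 × w_best; importance(term) = Σ w over set members
containing the term; plausibility ratio = importance(A)/importance(B);
model averaging is conditional (weights renormalized over members containing
each coefficient) with a sign-consistency report against the best model.
Collinearity screening forbids pairs with |Pearson r| ≥ 0.6 from co-occurring
(keeping the covariate with the smaller univariate P), excludes constant
covariates, and rejects candidates with any VIF > 10. The random-effect
check is a likelihood-ratio test against the 0.5·χ²₀ + 0.5·χ²₁ boundary
mixture, skipped when no animal repeats. Group comparisons use a
subadult-vs-adult t test on solitary females (pooling iff P > 0.05), one-way
ANOVA over the three statuses, and Tukey HSD (Tukey–Kramer on unbalanced
groups).

## Synthetic data

The generator defines the study conditions the tests run under.

*Landscape*: a standard-normal field smoothed by a Gaussian filter
(`aggregation` = smoothing length in cells; 0 = i.i.d. cells) and thresholded
at the cumulative target-proportion quantiles, which hits class proportions
essentially exactly at any clumping. The default is 512×512 cells of 28.5 m
with 10 vegetation covers plus 35% water and aggregation 3 — a
low-heterogeneity Arctic mosaic. LSI of the water class falls from ~99
(aggregation 0) to ~9 (aggregation 5) on a 256² grid, so one parameter spans
i.i.d. noise to large coherent patches.

*Movement*: a biased correlated random walk advancing at the 4-h collar
schedule across the 1 April – 30 November non-denning period. Turning angles
are von Mises(0, κ) (κ = 1 by default; uniform when κ = 0); step lengths are
gamma(shape 2) with status-scaled mean (default 300 m, scaled 1.0 / 0.6 /
1.2 for solitary / cub-of-year / cub ≥ 1 yr, mirroring the observed ordering
of range sizes). Each proposed destination is accepted with probability
exp(w_dest − w_max), the Metropolis-style thinning that makes realized use
proportional to availability × exp(w); after 10 rejections the last proposal
is accepted (bounded per-step cost, at the price of a slight attenuation of
strong programmed preferences — a programmed log-weight of +2 is recovered
by the RSF at ≈ 1.8). Positions reflect at the raster boundary. Because real
collars miss many scheduled acquisitions, each animal emits a random subset
of its scheduled positions — 279–959 fixes by default, the observed range —
so emitted tracks span the whole season range with gaps. Seasonal preference
maps (cover → log-weight) switch at programmed week breaks (default 31 and
39); water is strongly avoided (−2.5) by default. The truth record stores
the programmed weights, breaks, and statuses for recovery tests.

The defaults mirror published field conditions (≈30 females, 279–959 fixes,
three seasons, ~35% water); where the field value is unknowable (step scale,
turn concentration) the values are chosen to give home ranges of tens of km²
on the default landscape, the scale at which all stages are exercised.

What the generator does **not** emulate: home-range attraction or site
fidelity (the walk is diffusive, so range area grows with track length),
inter-annual range drift, GPS positional error, habitat-dependent fix
failure, and temporally autocorrelated preference within a season. Passing
recovery tests therefore show the estimators are correct under the model's
own assumptions — independence of availability sampling, selection acting on
the destination cover only — not that field data meet those assumptions.

`simulate_range_covariates` additionally draws covariate tables directly
(shape indices, proportions, diversity at field-like scales) with a known
generating model for log₁₀ area, for tests of the model-comparison stage in
isolation.

## Numerical conventions and test scales

* Cells are half-open, row 0 at the bottom, origin at the lower-left outer
  corner; a point on a shared edge belongs to the +x/+y cell.
* Isopleth thresholds include ties; "within one cell ring" is the tolerance
  for support-recovery checks.
* Akaike weights are invariant to constant AICc shifts (tested by property).
* All randomness flows through explicit seeds; identical configuration and
  seed reproduce byte-identical artifacts, including the run report.
* Test problem sizes: 96–192² landscapes, 8–20 animals, 150–500 fixes per
  animal, 20-replicate recovery experiments and 200-replicate null
  calibrations; the brute-force oracles run at n = 200 (LSCV), n = 500
  (convex hull), and 100 random 64² rasters (edge counting). These sizes are
  the package's choice of a thorough-but-quick default; all scale up through
  the specs.

## Known limitations

* The LSCV search is one-dimensional (isotropic kernel); anisotropic or
  adaptive kernels are out of scope.
* Isopleth polygons are cell unions: exact, but visually blocky; smooth
  contouring is deliberately not provided.
* The RSF assumes selection on the destination cover of each step;
  step-selection or point-process formulations are out of scope.
* Selection-table rows are from one multi-cover model by default; per-cover
  univariate fits are available behind a flag
  (`fit_rsf` on single-cover subsets) but not the default.
* With ≤ ~10 animals the Wald selection-ratio test is conservative
  (rejection ~2% at nominal 5%).
* The pseudo-t²/Duda–Hart chooser caps k at 6; April–November biology admits
  few seasons.
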