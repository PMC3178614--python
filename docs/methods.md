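# Methods

This note documents the models, defaults, and design choices behind
`sdmbaseline`, and what the synthetic experiments do and do not show.

## Occurrence filtering

Records carry Darwin-Core-style fields: species, decimal WGS84
coordinates, a georeferencing-error radius in meters, a collection year,
and a voucher flag. Three conjunctive quality rules are applied, with
per-rule removal counts reported:

- **uncertainty** — retained iff the radius is known and ≤ 1 km (default).
  The 1 km default matches the analysis resolution of 30 arc-second cells.
  A record with *unknown* radius fails the rule: its precision cannot be
  certified.
- **year** — retained iff the year is known and ≥ 1950 (default), keeping
  records temporally congruent with climate-normal-era environmental
  layers. Unknown years likewise fail.
- **voucher** — optionally (default on) only specimen-vouchered records
  are retained, since unvouchered observations cannot be re-verified.

The rules commute and the filter is idempotent; both properties are
tested. Records snap to grid cells under a half-open convention
`[west, east) × (south, north]`, so a point on an interior boundary
deterministically joins the cell whose west/north edge it touches
(near-integer coordinate fuzz below 1e-9 cell widths is snapped first).
A species is eligible for modelling when its filtered records occupy at
least 10 unique cells — enforced on unique cells, which implies the
≥ 10-record requirement automatically.

## Maximum-entropy model

Presence/background maxent with an L1-regularized convex objective
(negative mean presence log-probability plus log partition plus weighted
L1 penalty). Numerical choices:

- **Features**: per continuous layer — linear, quadratic, forward and
  reverse hinges and step functions at 8 interior quantile knots; pairwise
  products across layers; one 0/1 indicator per declared category of a
  categorical layer. All features min-max scaled to [0, 1] over the
  background. Constant layers contribute nothing (warned).
- **Feature-class tiers** (`classes="auto"`, by training sample size m):
  m < 10 linear only; 10–14 adds quadratic; 15–79 adds hinge; ≥ 80 adds
  product and threshold. These mirror the widely used presence-only
  modelling defaults.
- **Regularization**: β_j = multiplier × base(class, m) × max(sd_j, 0.05)
  / √m, where base interpolates the conventional class-specific tables
  (linear/quadratic/product: 1.0 → 0.05 over m = 0 → 100; category:
  0.65 → 0.25; threshold: 2 → 1; hinge: 0.5) and sd_j is the feature's
  standard deviation over presences. The 0.05 floor keeps a positive
  budget for features constant across presences. Multiplier default 1.0.
- **Optimizer**: proximal gradient (soft-thresholding) with backtracking
  line search; monotone in the objective by construction; tol 1e-5 on
  relative objective change, max 500 iterations, step re-growth ×1.25
  after each accepted step. On problems of ≤ 100 cells and ≤ 3 features
  the solution matches an independent, iteratively refined dense grid
  search of the identical objective to < 1e-3 (tested); the no-feature
  and infinite-regularization limits recover the uniform distribution
  exactly.
- **Background**: all valid cells when ≤ 10,000, else a seeded uniform
  sample of 10,000 with presence cells always included.
- **Outputs**: raw q normalized over the background (conservation to
  1e-9 is asserted in tests); logistic L = c·q/(1 + c·q) with c = e^H,
  the τ = 0.5 prevalence convention. The logistic transform is strictly
  increasing in q, so AUCs are identical on either scale.

## Replication and validation

Each species is fitted `n_rep` times (default 100; tests and the
acceptance script use 3–10 to keep runtimes in seconds — a size choice of
this package, stated here once). Each replicate withholds
round(0.4·n) ≥ 1 presence cells as test records. AUC is the rank-based
Mann–Whitney statistic with ties credited 0.5, background cells serving
as the negative class.

Eleven thresholds drive the binomial omission tests, reconstructing the
conventional threshold rows of maxent-style reports: fixed cumulative
levels 1/5/10, minimum and 10th-percentile training presence, equal and
maximal sensitivity+specificity on each partition (candidate thresholds
are the distinct presence scores of that partition), a balance rule
minimizing 6·omission + 0.04·cumulative + 1.6·area, and the equate-entropy
rule (predicted area a* = e^H / N). For each threshold and partition the
one-sided p-value is P(X ≥ k), X ~ Binomial(n, a), with a the fractional
predicted area — exact tails via scipy. Under a null (random) presence
placement the fixed-cumulative tests are calibrated; presence-derived
thresholds are conservative, which only makes acceptance criterion (ii)
stricter.

The acceptance rule is the conjunction: (i) mean test AUC > 0.9;
(ii) **every** omission test in every replicate has p < 0.05 (the strict
all-tests reading; an aggregate reading would be weaker and is not
implemented); (iii) |mean train AUC − mean test AUC| / mean train AUC
< 0.05. The gap is relative by default because "percent difference"
between two quantities on [0, 1] is ambiguous; `gap_mode="absolute"` is
available.

Expert variable-set selection is represented only by its arithmetic:
independent 1–5 rankings averaged per candidate, top-k candidates chosen
with lexicographic tie-breaking (flagged), then per-species argmax of
mean test AUC with ties to the lower set id.

## Community construction

The per-species watershed statistic is the maximum logistic value over
watershed cells of the **cell-wise mean** of replicate surfaces
(mean-then-max). Averaging before taking the max is more stable than
averaging per-replicate maxima, which ride the upper tail of replicate
noise; the per-replicate variant remains available
(`aggregate="per-replicate"`). Classification at threshold 0.5: any
detection ⇒ *documented*; native, undetected, probability > threshold ⇒
*modeled-but-undocumented*; otherwise *low-suitability*. Non-native
species are never classified modeled-but-undocumented — an undetected,
high-suitability non-native is annotated *potential-invader* instead,
since for non-natives high suitability predicts establishment risk, not
historical membership.

## Assemblage comparison

Bray–Curtis dissimilarity d = Σ|x−y| / Σ(x+y) (a pair of all-zero sites
is defined as d = 0 and flagged). The Mantel statistic is the Pearson
correlation of corresponding off-diagonal entries; the null jointly
permutes rows/columns of the second matrix; p = (1 + #{r_perm ≥ r_obs}) /
(1 + n_perm), one-tailed "greater" by default, 9999 permutations, fully
seeded. Empirical type-I error at α = 0.05 over independent random
matrices is within Monte-Carlo noise of nominal (tested at 1000 trials).

## Synthetic data: what it emulates, and what it does not

Continuous layers are low-order polynomial trends plus Gaussian-smoothed
noise, standardized; categorical layers are contiguous nearest-center
regions. Virtual species have logistic-linear niches
s(x) = σ(α + Σβ·env + category bonus). Occurrence sampling draws cells
∝ s(x)·detectability, jitters points within cells, and attaches reported
error radii (lognormal ≤ 1 km vs uniform 1–3 km mixture, 30% large),
years spanning the 1950 cutoff (25% before), and voucher flags (90%
vouchered) — so every filter rule is exercised on every run.

Default species are drawn with slopes ~ N(0, 3²) and intercepts
~ N(−4, 2²): a mix of restricted-range specialists and broad generalists.
This is deliberate. Regional presence-only modelling of basin faunas
operates in a specialist regime — species occupying a few percent of a
region-wide background — and only in that regime are test AUCs above 0.9
attainable at all; generalists' models fail the acceptance rule, as some
should. The staged recovery scenarios use a fixed specialist
(~4% prevalence) and a "ghost" species whose niche is constructed from
the focal watershed's environmental profile (slopes along the
watershed-vs-landscape mean difference, intercept set so suitability at
the watershed's mean environment is ≈ 0.92). The construction *is* the
scenario the end-to-end check requires: genuinely high true suitability
inside the mask, with sampling there withheld. The synthetic watershed
occupies an environmentally distinctive corner of the grid, as a
spring-fed watershed differs from its surrounding basin.

What passing these tests shows: the estimator recovers known niches,
ranks habitat correctly, conserves probability mass, and the full
pipeline's classification logic behaves as specified under known truth.
What it does not show: performance under real-world complications absent
from the generator — spatial sampling bias toward roads and towns,
positional error *in the coordinates themselves* (only the reported
radius is simulated), niche shapes beyond logistic-linear (quadratic
optima can be expressed via `cat_prefs`-free custom species but are not
defaulted), dispersal limitation, and stream-network connectivity.
Real-data claims require real-data validation.

## Degenerate inputs and tie-breaking

Empty layer stacks, all-nodata masks, zero-presence fits, constant
distance matrices, and non-finite features all raise informative errors
rather than propagating NaNs. Deterministic tie-breaks: boundary cell
membership (west/north edge), expert-rank and best-model ties
(lexicographic / lower id, flagged), stable sorts in the community table.

## Known limitations

- The optimizer is first-order; very ill-conditioned feature sets
  converge slowly (bounded by max_iter, reported via `converged`).
- Omission thresholds derived from few presence scores are coarse; with
  < 10 test records the equal-sensitivity thresholds can coincide with
  the minimum presence.
- The ESRI ASCII raster format carries no CRS; grids are assumed WGS84
  geographic, and no reprojection is performed.
- Collection-event detection counts in the pipeline are sites-with-
  positive-count per survey, a simplification of event-level records.
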