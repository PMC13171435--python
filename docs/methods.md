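# Methods

This note documents the models, the numerical choices and the synthetic
study designs implemented in `hoiforest`, and what the validation studies
do and do not establish.

## Crowding indices

A neighbour of diameter `dbh_j` (cm) at distance `d` (m) from a focal stem
contributes `dbh_j**a / max(d, d_min)**b` crowding units; only stems within
the neighbourhood radius `R` contribute. Defaults: `a = b = 1` (contribution
proportional to size and inverse in distance), `R = 10 m`, `d_min = 0.1 m`.
The exponents are configurable because several kernel dialects
(`dbh²/d²` etc.) are in common use; the distance clamp prevents co-located
stems (multi-stem mapping artefacts) from contributing unbounded crowding.
Summing over conspecific and heterospecific neighbours gives the pairwise
indices `n_i` and `n_h`.

Each higher-order index weights a transmitter j's contribution by j's own
crowding, computed with the same kernel and radius around j. The initiator
identity is classified **relative to the focal species**: `n_ii` and `n_hi`
use j's crowding by stems of the focal species, `n_ih` and `n_hh` by all
other stems. This matches the coefficient notation in which β_ihi denotes an
interspecific pairwise effect modified by a *conspecific* (focal-species)
initiator. By default the focal stem is removed from its transmitters'
crowding so it cannot initiate higher-order effects on itself; the toggle
exists because either convention is defensible.

The batch computation builds sparse within-radius contribution matrices from
a k-d tree and evaluates all six indices as sparse matrix-vector products
per focal species; heterospecific crowding is accumulated directly (not as a
difference of totals) so zero indices are exactly zero. The test suite and
acceptance study verify equality with exhaustive per-focal loops to 1e-10
relative on random plots across kernel settings.

**Edge policy.** A focal stem is `interior` only if it lies at least `2R`
from every plot edge — at `R` its own neighbourhood is complete, and at `2R`
so are its transmitters' neighbourhoods, which the higher-order indices
need. Non-interior stems are excluded as focal observations but always act
as neighbours and initiators. No toroidal wrapping.

## Demographic models

Growth uses the multiplicative model `Growth = G_i · DBH^γ · e^Pair · e^HOI`
fitted by OLS after natural-log transformation; the response is annualized
DBH increment (cm/yr) from decimal census dates. Because the log transform
requires positive growth, survivors with non-positive measured increments
(shrinkage, measurement error) are floored at a configurable
0.01 cm/yr (count logged); a drop policy is available. Survival over the
census interval is a single Bernoulli per stem, fitted by maximum-likelihood
logistic regression on `1/DBH, DBH, DBH²` (fast juvenile mortality decline
plus U-shaped senescence) with the same neighbourhood terms. The linear
predictor enters as `P(survive) = 1/(1+e^{-η})` so that negative interaction
coefficients reduce survival — the orientation under which α < 0 reads as
competition consistently across both responses.

Species enter the growth analysis with more than 100 trees in the plot, and
the survival analysis additionally with at least 20 survivors and 20 deaths.
Model classes are nested: null (size terms), pair-only (+`n_i`, `n_h`),
HOI-inclusive (+ the four higher-order indices). Pairwise coefficients from
the pair-only class are reported as α_modified, from the HOI-inclusive class
as α_true. AIC is `-2·loglik + 2k` with `k` counting all free parameters
including the Gaussian variance for growth; the constant offset relative to
other AIC conventions cancels in every comparison. The ΔAIC ≥ 2 rule picks
the HOI-inclusive class only when it undercuts *both* simpler classes by ≥2,
then pair-only vs null likewise; ties collapse to the simplest class.

Degenerate designs (an index constant across a species' stems) are handled
by dropping the offending column and flagging the fit rather than failing,
so plot-wide batch runs complete; flagged fits are excluded from gradient
regressions and RC. Perfectly separable survival data fall back to a lightly
ridge-penalized logistic fit (α = 1e-4), flagged, with no Wald intervals.
Predicted-vs-observed correlations are in-sample (log scale for growth),
compared across classes by paired two-sided t-tests over species.

## Gradients and cumulative effects

"Exponential regression" of a quantity on latitude is implemented as OLS of
the log magnitude on absolute latitude — this reproduces the t / (n−2)-df
structure of a linear fit and is the standard reading. Coefficients are
split by sign (competitive < 0, facilitative > 0; zeros enter neither
subset) and fitted separately, with a two-sided t-test on the slope;
fits require n ≥ 3. Species are weighted equally (no precision weighting).
Plot richness per hectare is the mean species count over non-overlapping
100 m × 100 m quadrats (a total-richness/area alternative is available);
plot-level coefficient summaries report mean ± s.e.m. per sign subset.

RC statistics use the HOI-inclusive fit for every growth-eligible species
regardless of AIC support class: per tree, `Pair` and `HOI` are the fitted
linear neighbourhood effects, and `RC = mean(e^effect)` over the species'
interior trees, a dimensionless multiplier on growth rate (neutral = 1).
Natural logs throughout; abundance is census-1 main stems per hectare. The
Table-style model is OLS of `log RC` on `log abundance`, `|latitude|` and
their interaction; zone predictions evaluate it at the mid-latitudes of the
tropical (11.75°), subtropical (29.25°) and temperate (45°) zones with
pointwise 95% confidence bands.

## Synthetic forests

The generator emulates a multi-plot census network at desk scale: default
20 plots of 1 ha evenly spaced over 2–52° absolute latitude, 0.15 stems/m²
above the 1 cm DBH census floor, log-series species abundances with
equatorial richness 60 decaying at 3%/degree, truncated-lognormal DBHs
(log-mean ln 3, log-sd 0.8), uniform or Thomas-cluster point patterns, a
5-year census interval and lognormal growth noise (σ = 0.5). Interaction
coefficients are drawn per species with magnitude
`scale · e^{decay·|lat|}` times a lognormal spread, and competitive/
facilitative signs equally frequent by default; default decays are
−0.05/degree for intraspecific pairwise and most higher-order types, and 0
for the interspecific pairwise and het-het higher-order types, emulating the
observed contrast. Coefficient scales (8e-3 pairwise, 1e-4 higher-order)
keep the neighbourhood terms of order 0.1–0.3 on the log-growth scale given
the typical index magnitudes these defaults produce. Growth and survival are
drawn from exactly the models the inference fits, using the same crowding
configuration, so estimation is unbiased by construction and any bias found
in validation indicates an implementation defect. Everything is
deterministic given the seed; true parameters are recorded per plot×species.

What the generator does *not* emulate: habitat heterogeneity and
environmental autocorrelation, recruitment dynamics, per-species-pair
interaction matrices (the inference's mean-field heterospecific pooling is
built into the truth), measurement error in DBH, and nonlinear higher-order
functional forms. Passing validation therefore shows the estimator is
correct and well calibrated *under its own assumptions*, not that those
assumptions hold in real forests.

## Validation study designs

Replicate studies fix one simulated spatial design and redraw the stochastic
demography per replicate; conditional on the design this makes OLS t-interval
coverage exactly nominal and keeps 200-replicate studies inside a minute.
Problem sizes: coefficient-recovery and AIC studies use 2,000 interior focal
stems of one species in a 300 × 300 m map (density 0.12/m², focal share
0.3) with well-identified truth values; the gradient-contrast study uses 50
replicate 20-plot coefficient networks; the RC study 200 replicate
500-species tables. The oracle-equivalence study covers 50 random plots with
varied kernels plus one 1,000-stem instance. The delta-AIC false-support
rate under a zero-β truth is expected near `P(χ²₄ ≥ 10) ≈ 4%`; the studies
bound it at 10%.

## Known limitations

Growth and survival are modelled separately (no joint demographic model and
no recruitment); heterospecific effects are pooled (no per-pair α matrix);
the survival response ignores interval-length heterogeneity across plots
beyond annualization of growth; gradient regressions use species-level
point estimates without propagating their standard errors; and the
pair-only/HOI comparison assumes the linear higher-order form — nonlinear
HOI kernels are out of scope.
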