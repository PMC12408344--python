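# Methods

## Kinetic model

Bean-mass temperature, testa/pulp pH and (after reflection) cotyledon pH
are modelled with the 5-parameter generalized logistic

    y(t) = y0 + (yf − y0) / (1 + exp(−k (t − ti)))^(1/ν)

- `y0`, `yf` — lower/upper asymptotes, native units (°C or pH units);
- `k` — rate, 1/h (k > 0);
- `ti` — inflection-locating time parameter, h (the actual inflection
  sits at `ti − ln(ν)/k`);
- `ν` — asymmetry, dimensionless (> 0; ν = 1 gives the symmetric
  logistic).

The family is sigmoidal, admits asymmetry, and has closed forms for the
rate `dy/dt = (yf−y0)(k/ν) u (1+u)^(−1/ν−1)` with `u = exp(−k(t−ti))`,
the inflection time `ti − ln(ν)/k`, and the inflection value
`y0 + (yf−y0)(1+ν)^(−1/ν)`. For this family the maximum-rate time and
the zero of the second derivative coincide for every ν; both are exposed
(`time_to_max_ke` located numerically, `time_to_inflection`
analytically) and tested for agreement.

**Inverted series.** "Inverse" cotyledon pH means reflection about the
series maximum (`max(y) − y`), not the reciprocal: reflection preserves
the sigmoid shape so the same model applies, and the recorded offset
makes the operation an involution.

**Fitting.** Multi-start trust-region least squares
(`scipy.optimize.least_squares` with bounds `k > 0`, `ν ∈ [1e−3, 1e3]`).
Starts: asymptotes from the data min/max, `ti` from the steepest
empirical slope, `k` from `4·max-slope/span`, ν ∈ {0.3, 1, 3}, plus two
seeded jittered starts per ν (deterministic given the fit seed). The
best-residual solution is returned; non-convergence is reported in the
result, not raised. Fitting requires ≥ 15 observations and a value span
above `min_span` (default 0.5 native units; smaller spans are declared
non-kinetic).

**Parameter identifiability.** `k` and `ν` compensate each other along a
near-flat valley of the least-squares surface (a well-known property of
Richards-type curves): very different (k, ν) pairs produce nearly
identical curves. At measurement noise of ~2% of span with ~20 points,
the Fisher information of the design bounds the achievable relative
error of ν near 25–40% regardless of estimator, while `y0`, `yf` and
`ti` recover to within a few percent. Derived features (rates, phase
durations, inflection point) depend on the curve shape, not the raw
(k, ν) coordinates, and are stable.

## The 13 kinetic features

"Kinetic energy" is taken proportional to `(dy/dt)²`, so its maximum
coincides with the maximum rate; `value_at_max_ke` is `y` at that time.
Phase boundaries use the tangent construction: the tangent at the
inflection point is intersected with the two asymptotes; the exponential
phase runs from the curve start (first observation time) to the lower
intersection, the linear phase between the intersections, and the decay
phase from the upper intersection until the curve reaches
`y0 + 0.95·(yf − y0)` (cutoff configurable). Phases are contiguous;
boundaries that precede the series start are clamped, so durations are
non-negative and per-phase `rate = delta/duration` whenever the duration
is positive.

## Growth features and marker selection

Marker taxa are filtered from a per-taxon coefficient table by inclusive
thresholds (bacteria ≥ 10, fungi ≥ 5, both configurable). Computing the
coefficients themselves (a community-dissimilarity decomposition) is out
of scope; the table is an input.

The seven trajectory features are computed on an optionally smoothed
series (centered moving average, default window 3, shrunk at the edges;
window 1 disables smoothing and is used wherever exact closed-form
checks matter). Conventions, chosen because fermentation trajectories
routinely peak at the sampling boundaries:

- endpoints count as local extrema (one-sided comparison);
- all argmax/argmin ties resolve to the earliest time;
- `midpoint` is where the piecewise-linear interpolant first reaches
  half of the *observed* maximum (not a fitted carrying capacity);
- `inflection_point` is the left endpoint of the steepest
  forward-difference segment of the smoothed series.

## Feature reduction and %IncMSE

Features are min-max rescaled per column (constant columns map to 0;
the operation is idempotent). Pairwise Pearson correlations and
two-sided p-values (`t = r√((n−2)/(1−r²))` against t with n−2 df) are
computed; features are clustered by Ward linkage on Euclidean distances
between their correlation vectors — equivalent to `hclust`'s `ward.D2`
on those coordinates. The tree is cut at a user-specified count or
height; the default cut maximizes the mean silhouette over
k ∈ [2, p−1], a reproducible stand-in for visual dendrogram inspection.
Each cluster is represented by its highest-CV member, with CV computed
on the raw (pre-rescale) values because min-max scaling distorts
sd/mean; ties break to the lexicographically first name, and zero-mean
features (undefined CV) are deprioritized.

Importance is the percentage increase in out-of-bag MSE: per tree, the
OOB error is recomputed after permuting one feature within the OOB set;
the mean increase over trees is normalized by the baseline OOB MSE and
multiplied by 100. The forest is built from scikit-learn regression
trees with an explicit bootstrap (500 trees by default, `mtry =
max(p//3, 1)`, leaf size 5), and every bootstrap draw, OOB index set and
permutation is recorded so reported importances can be replayed exactly
from the frozen forest. A constant response yields all-zero importances
with a warning. One forest is fitted per sensory attribute, seeded
deterministically from the base seed.

## Network expansion and community reduction

Networks are reaction sets over metabolite identifiers — no
stoichiometry, no flux constraints; this plain expansion semantics is
the only one the available network descriptions support. A reaction
fires forward when all substrates are reachable; reversible reactions
may also fire backward. The scope is the least fixpoint (order
independent, monotone in both seeds and reactions, idempotent).
Community expansion runs over the union of member reactions, i.e.
unrestricted metabolite exchange. No currency-metabolite filtering is
applied unless the caller supplies an ignore list.

The default cocoa-pulp seed set names the artificial-pulp components
(sucrose, glucose, fructose, citric acid, pectin, two carboxymethyl
celluloses, amino-acid proxies for yeast extract and peptone, calcium
lactate, Tween 80, magnesium and manganese sulfate).

`minimal_communities` targets, by default, everything the full community
can produce (the union of individual produced sets plus the added value
of cooperation), so "equivalent metabolic capabilities" means covering
the community's entire producible set; passing the added-value set
targets the cooperation gain only. Both modes are exposed
(`--targets full|added_value`). Search is exhaustive by increasing
subset size for pools up to 20 organisms (stopping at the first feasible
size, which guarantees minimality of every reported solution); larger
pools use a seeded greedy cover with deletion pruning and 100 restarts,
flagged non-exhaustive. Key species = union over minimal communities;
essential = intersection; alternative = key − essential. Infeasible
targets produce an explicit error listing the unreachable metabolites.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *structure* of a farm fermentation study —
a 168 h campaign, 15+ sampling points, replicate boxes, temperature at
two depths rising ~25 → 48 °C, testa/pulp pH rising 3.5 → 4.6, cotyledon
pH falling 6.5 → 4.8, bacterial/fungal succession (early enterobacteria
collapse, lactic/acetic blooms, yeast rise), 0–10 panel scores driven
linearly by a few planted features, and a community whose targets
require an exact planted cross-feeding chain. Noise is additive
Gaussian on the measurement scale (defaults: 0.5 °C, 0.05 pH units,
0.02 relative abundance; the source measurements publish no error
magnitudes, so these are free parameters chosen once as plausible
instrument/replicate scatter).

Not emulated: autocorrelated sensor drift, box-turning disturbances,
compositional count noise from sequencing, panelist effects, nonlinear
feature–flavour response, or realistic genome-scale network topology
(background reactions are random). Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise model,
not robustness to every artefact of real field data.

All generators draw from named sub-streams of a single configuration
seed, so equal seeds give byte-identical outputs. The planted network
instance is verified by enumeration before being returned (bounded
retries; construction makes chain intermediates producible only by their
designated organism, so the planted community is the unique minimal
solution).

## Pipeline and problem sizes

The orchestrated runs write plain-text artifacts (long CSV/TSV tables,
JSON networks and reports) whose content hashes are recorded in a
manifest; identical configurations reproduce identical hashes, and every
JSON artifact embeds the configuration hash and package version. Stage
failures are recorded in the report with the stage name before the error
propagates.

Default verification sizes, chosen to exercise each estimator at the
scale where its behaviour is interpretable: 100 curves for parameter
recovery; 1,000 random 10-point trajectories against the index-scan
oracle; 25–50 forest seeds for planted-importance recovery and 50–100
pure-noise datasets for the null; 500 random networks against the naive
fixpoint oracle; exhaustive powerset cross-checks on pools of ≤ 12
organisms; and two identically seeded end-to-end runs for determinism.

## Known limitations

- Raw `k`/`ν` estimates are reported as fitted but should be interpreted
  through derived curve features (see identifiability above).
- The silhouette-based default cluster cut can differ from a cut chosen
  by eye on a dendrogram; pass `k` or a height to override.
- Greedy community search beyond 20 organisms is approximate and flagged
  as such.
- The SBML reader (via cobra, optional) ignores stoichiometric
  coefficients and boundary reactions, matching the expansion semantics.
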