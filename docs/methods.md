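# Methods

This note documents the models, rules and numerical choices behind
`clearwater`, in the order data flows through the pipeline.

## 1. The clear-water-phase rule

A transition between consecutive sampled weeks qualifies iff secchi depth
strictly increases, chlorophyll-a strictly decreases, and total zooplankton
strictly increases. A *maximal* run of at least two qualifying transitions
(three observations) is a candidate episode; it is confirmed as an event
iff turbidity decreases net over the run, i.e. TUR(end) < TUR(onset).

Choices worth making explicit:

- **Strict inequalities.** Ties break a run. This is conservative: flat
  stretches of data can never accumulate into an event.
- **"Two-week period" = two qualifying transitions.** Reported event
  durations ("2-week", "3-week") then map one-to-one onto run lengths 2
  and 3.
- **Turbidity as a net, final confirmation.** The three continuous
  conditions are checked per transition; turbidity only net over the event.
  The stricter per-transition variant is available
  (`detect_events(..., strict_turbidity=True)`) but is not the default,
  as intermittent storm-driven seston can produce single up-ticks inside a
  genuine clearing episode.
- **Gaps.** A step of more than 9 days between samples is a missing week;
  no transition across it can qualify, so events never span gaps.
- Detection uses only signs of differences, hence is invariant to affine
  rescaling of any single variable (unit changes cannot alter events).

## 2. Before/after statistics

For each event, "before" is the onset-week value and "after" the end-week
value, one pair per event; a configurable k-week pre/post window mean is
available as an alternative pairing. The paired t statistic is computed on
differences d = after − before, so a transparency **increase** yields
**positive** t (reports that pair the columns the other way round show the
opposite sign for the same contrast — only the sign convention differs).
With sd(d) = 0 the test is degenerate: t = 0, p = 1 if the mean difference
is also 0 (no change), otherwise flagged with infinite t rather than
silently dividing by zero. Pearson screening uses pairwise deletion;
zero-variance and under-sampled (< 3 complete pairs) combinations are
returned flagged as undefined instead of propagating NaN. Tests are
two-sided at α = 0.05 with no multiple-testing correction — the screening
output reports raw p-values, and readers should treat borderline entries
accordingly.

## 3. Hydrology

HRT = storage / outflow, converted to days. Storage-based retention time is
the standard reservoir definition; an inflow-based variant only differs
when the water balance is far from closed, which the level-control contract
rules out here. Non-positive outflow yields a flagged undefined value
(never infinity) and is excluded from period means. Seasons are the
meteorological month blocks (spring Mar–May, …); winter spans the year
boundary and is attributed to the year containing its January. Seasonal
totals over complete years partition the annual total exactly.

## 4. Discretization

Each modeled variable is min–max normalized (constant variables are
rejected by name) and cut into 3 ordered states by divisive
variance-minimizing clustering. The cut points are found *exactly* by
dynamic programming over the sorted values (O(k·m²)); for three bins this
is identical to exhaustive enumeration of all two-cut partitions. A greedy
top-down splitter was rejected because it is provably suboptimal on the
plainest possible input — a uniform grid, where greedy yields 75/75/150
occupancy versus the optimal near-equal thirds — and because exactness
makes the mapping deterministic and order-free. Equal-frequency binning is
retained as a fallback dialect (`method="equal_frequency"`).

## 5. Bayesian networks

- **Score.** BDeu log marginal likelihood with uniform structure prior.
  The equivalent sample size (prior strength) defaults to 50. Note a large
  ESS densifies learned graphs; this is inherent to BDeu, not a bug.
- **Search.** Greedy hill-climbing over add/delete/reverse moves, steepest
  ascent with seeded random tie-shuffling, 20 random restarts by default
  (restart 0 from the empty graph, later restarts from random legal DAGs).
  Move legality: acyclicity, tier(u) ≤ tier(v) for every edge u → v, and at
  most 8 parents per node. Within-tier edges are allowed in both
  directions; only retrogressive cross-tier edges are forbidden.
- **Parameters.** Dirichlet posterior means,
  θ̂ = (N_jk + ESS/(r·q)) / (N_j + ESS/q); columns always sum to 1 and no
  parameter is ever exactly 0 or 1, which keeps the sensitivity derivatives
  defined everywhere.
- **Inference.** Exact variable elimination with a greedy
  smallest-intermediate-factor ordering. At ≤ 25 ternary nodes this is
  fast and exact; evidence with probability exactly zero raises a dedicated
  error rather than returning garbage.
- **Sensitivity.** For a target T and node X, the joint is multilinear in
  each CPT column under proportional co-variation, so the derivative of
  P(T = s) w.r.t. a parameter θ_{k₀|j} has the closed form
  P(T=s, X=k₀, Pa=j)/θ_{k₀} − Σ_{k≠k₀} P(T=s, X=k, Pa=j)/(1−θ_{k₀}),
  computed from one exact joint marginal per node and verified against
  central finite differences. A node d-separated from the target scores 0.
- **Strength of influence.** For an edge u → v, the mean Euclidean distance
  between v's conditional distributions over all unordered pairs of u's
  states, averaged over co-parent configurations weighted by their
  empirical frequency (uniform without data). Values lie in [0, √2] and
  are 0 exactly when the child's CPT ignores the parent. Hellinger distance
  is available by flag; Euclidean is the default of the tool family this
  diagnostic comes from.
- **Validation.** Stratified k-fold (default k = 10, config-exposed):
  structure and parameters are re-learned per fold, the target's most
  probable state is predicted from all other variables, and per-fold
  accuracies are reported. Complete-case analysis throughout the network
  stage (weeks missing any modeled variable are dropped).

## 6. The synthetic generator

The generator exists so that every downstream stage has a known answer key;
it is a minimal difference-equation system, not a calibrated ecosystem
model.

**Forcing (daily).** Water temperature is a sinusoid over `temp_range`
(min mid-January, max mid-July). Rainfall is zero-inflated gamma
(wet-day probability 0.30, 0.45 in June–August; shape 0.7) whose summer
scale multiplier is solved so the *expected* June–August share equals
`summer_precip_fraction` (default 0.63); the base scale targets ≈ 950 mm
a year. Inflow is baseflow plus an exponentially recessed (3-day) runoff
response; outflow relaxes storage toward the level-control target over
2 days, emulating sluice-gate operation — annual mean inflow and outflow
agree within 5%, water level stays in a narrow band, and HRT ≈
volume/outflow lands at 10–20 d with the default 2.44 × 10⁸ m³ volume and
150 m³ s⁻¹ baseflow.

**Weekly dynamics.** Sampling takes the value on the sampling day (weekly
grab sampling), every 7 days. Dissolved nutrient pools follow antecedent
7-day rainfall; bulk TN/TP are fixed ratios of the dissolved pools.
Phytoplankton relaxes geometrically (memory 0.25) toward a
temperature-driven equilibrium with Monod limitation on a *deterministic
seasonal TP climatology*; zooplankton taxa are smooth increasing functions
of temperature, with Cladocera emerging logistically above ≈ 12 °C scaled
by each site's favorability. This is the key design choice: because the
baseline detection variables (chl-a, zooplankton, secchi) are all monotone
in temperature between pulses, noise-free runs contain *no* spurious
qualifying runs, and the planted grazing pulses are the only CWP episodes —
which is what makes "precision = recall = 1.0 on noise-free data" a
meaningful, achievable contract. The realized stochastic TP still
correlates positively with turbidity and phytoplankton through the shared
monsoon seasonality.

**Pulses.** Grazing pulses arrive at a seasonally weighted rate (default
4.5 yr⁻¹, weighted toward the 10–24 °C window; an exact per-site count can
be forced). During a pulse, Cladocera gets additive boosts
(40/90/150 Ind L⁻¹ × favorability per pulse week), phytoplankton is grazed
to 40% per week, and suspended solids are cleared to 55% per week (filter
feeders remove seston, not only algae). The storm response of SS is capped
at 150 mm of weekly rain so that even a monsoon storm on an event's end
week cannot reverse the net turbidity decrease — without both the
clarification and the cap, planted events could be vetoed by weather and
the noise-free recovery contract would not hold. Secchi depth is a strictly
decreasing function of turbidity and chl-a, soft-capped below the site mean
depth by a tanh, so the depth bound never creates ties.

**What it does not emulate.** No hydrodynamics, stratification,
biogeochemical mass balance, taxonomy below coarse groups, or calibration
to any real reservoir. Passing tests on synthetic data demonstrate the
*pipeline's* correctness (the detector finds exactly what was planted, the
network recovers the wired structure), not ecological validity of any
specific field inference.

**Ground truth.** Planted events (site, onset, end) and the generator's
causal wiring (`TRUE_DAG`, acyclic and tier-consistent) are emitted for
scoring detection and structure recovery.

## 7. Problem sizes and determinism

Default synthetic runs are 4 sites × 2 years (104 weekly records per site,
the size of the monitoring design the generator emulates). The benchmark
suite uses 3–6-node networks for enumeration oracles, an 8-node tiered
network at n = 2,000 for structure recovery, and 10,000 replicates for the
type-I calibration of the paired test. All stochastic stages take explicit
seeds; identical parameters give bit-identical outputs, and the pipeline's
report bundle is byte-reproducible from its config (the manifest records
the config hash and seed).

## 8. Known limitations

- The CWP rule is the package's single event definition; alternative
  definitions from the literature (e.g. secchi depth above a seasonal mean)
  are out of scope.
- The before/after pairing (onset vs end week) is one defensible reading of
  a before/after design; the windowed alternative is provided because the
  choice is not uniquely determined.
- BDeu with ESS = 50 on ~100-row site series learns dense graphs; edges
  should be read together with the strength-of-influence ranking rather
  than as individually significant.
- The generator's pulse process is exogenous: it plants grazing episodes
  rather than emerging them from predator–prey dynamics, by design, so that
  ground truth is exact.
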