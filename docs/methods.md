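# Methods

This note records the modelling choices behind the package, the parameters
that matter, what the synthetic generator does and does not emulate, and
the numerical conventions a user should know before trusting a result.

## Pipeline model

The method treats a child's commute as a path on an undirected, classed
road network in a single planar metric coordinate system (all distances in
meters; 25/40/50/100 m buffers would be meaningless in degrees).  Four road
classes are used throughout: main, residential, footpath, minor.

**GPS workflow.** The five inclusion criteria are applied in a fixed order
(timestamp validity, weekday, commute window, school footprint, 40 m home
radius, building footprints) and every rejected fix is logged with the
first criterion it failed.  Conventions:

* Commute windows 07:30–09:30 and 14:30–16:30 are treated as *closed*
  intervals at minute resolution; a fix at exactly 09:30 is inside.
* "Weekday" is Monday–Friday of the timestamp's local calendar; no holiday
  calendar is applied.
* The 40 m home exclusion is measured to the home *point*, not a footprint.
* Trips are consecutive fixes of one participant on one day inside one
  window, ordered by timestamp.  Where a window contains several fix runs
  (separated by gaps longer than `max_gap_s`, default 600 s), only one run
  is kept: the run whose final fix lies nearest the direction's destination
  anchor (school in the morning, home in the afternoon).  This replaces a
  manual cleaning step with a deterministic rule; `keep_all_runs` disables
  it.
* Mean trip speed is total consecutive-fix path length divided by elapsed
  time (not the mean of instantaneous speeds); walking means strictly
  < 10 m/s.
* Outlier removal (fixes > 100 m from every other fix of the trip) iterates
  to a fixed point, since one removal can expose another.
* Route polylines get the home and school anchor points appended in travel
  order; anchor stubs count toward route length.

**Routing.** Dijkstra on arc weight = length (distance mode, producing the
SNR) or length × cost_per_m (cost mode, producing the WNR).  Among
equal-weight paths the lexicographically smallest node-id sequence wins, so
routing is deterministic.  Snapping takes the nearest network node, ties to
the smallest node id, and errors beyond `snap_max_distance` (default
500 m).  Costs live on arcs (edges), not nodes: the flagging rule
("within 25 m of the network arc") is an arc property.

**Cost tables.** Each direction has six slots: one cost per road class plus
a traffic-light cost and an outlet cost.  Assignment order matters and is
*reassignment*, not multiplication: class costs first, then traffic-light
flagged arcs are set to the traffic-light cost, then outlet-flagged arcs to
the outlet cost.  An arc carrying both flags therefore ends with the outlet
cost by default (`flag_precedence` flips this; the narration order is the
only guidance available).  The shipped default tables are the published
calibrated values (to school: 0.8/0.5/0.8/1.5 for main/residential/
footpath/minor, 0.5 traffic lights, 0.8 outlets; home: 0.8/0.4/0.8/1.2,
0.7, 0.5).

**Calibration.** Odds ratios seed costs as cost = 1/OR clipped to
[0.1, 10]; grid search over finite per-slot candidate grids maximises the
mean 50 m intersection of candidate WNRs against the GPS routes, breaking
ties toward the table closest to all-ones (the least informative table).
Above `max_tables` (2048) combinations a seeded random subsample is
evaluated.  Grid search was chosen because it is deterministic and fully
auditable; nothing in the method requires gradients.

**Validation.** The intersection metric divides by the *modelled* route's
length.  A participant with several GPS routes in one direction is scored
against each and contributes the mean.  The exposure agreement model is a
school-level random-intercept linear regression fitted by REML
(statsmodels MixedLM); with a single school it falls back to OLS with a
warning.  p-values use the normal approximation to t.

## The conditional logistic model and separation

Each stratum pairs a participant's GPS route with their SNR.  The
conditional likelihood reduces to intercept-free logistic regression on
within-pair covariate differences with the outcome fixed at 1; it is
maximised by Newton–Raphson (step-halving, convergence at score norm
< 1e-8), with standard errors from the inverse observed information,
OR = exp(b) and 95% CI = exp(b ± 1.96·SE).  The printed population
equation carries an intercept b₀; the conditional likelihood has none, so
none is estimated.

Matched route data are prone to non-identifiability, and the model handles
three distinct failure modes explicitly:

* **All-zero differences** carry no information and are dropped with a
  warning.
* **One-signed differences** (a covariate always larger on one side) have
  no finite MLE; they are screened out with a warning and their sign is
  recorded on the model (`one_signed`), since an infinite MLE is still
  maximal evidence for a direction.
* **Joint quasi-separation.** When walkers are near-optimisers, the cost
  vector that generated their choices is itself a separating direction —
  every chosen route beats its SNR under the chooser's own costs — so the
  plain MLE diverges along it.  The Newton fit detects both the divergence
  and the zero-gradient plateau (all fitted probabilities → 1) and raises;
  `fit(method="firth")`, Firth's bias-reduced penalized likelihood, always
  has a finite interior maximum and is the pipeline default.

Two covariate-set facts follow from using fully on-network synthetic
routes.  First, the four road-class percentages each sum to ~100 per
route, so their within-pair differences are linearly dependent: one class
(minor) is dropped as the reference in the synthetic-study covariate set.
Second, a completely recorded trace is always longer than its SNR (noise
inflation plus detour surplus), making the length difference one-signed;
real traces are partially recorded, which is how a length covariate with
OR ≈ 1 was estimable in the original application.  The synthetic-study
default (`STUDY_COVARIATES`) is therefore the compact, stable set:
traffic-light count, outlet count, % residential, % main.  The richer
`DEFAULT_COVARIATES` (length, bluespace, woodland, accidents, all classes)
remains the entry point for real data.

Backward stepwise selection removes the covariate with the largest Wald p
above alpha (default 0.05) and refits; an AIC criterion is available.
Route length, when present, is never removed.

## Synthetic generator

The generator emulates the study conditions end-to-end:

* **Town**: an R×C grid of nodes at `block_length` spacing with node
  jitter ≤ 0.2·block_length (arcs stay non-crossing), each arc assigned
  one road class by sampling the requested class mix; traffic lights at
  nodes; outlets and crossings within 10 m of arcs; bluespace/woodland
  polygons beside arcs; buildings in block interiors (clear of roads, so
  noiseless commute fixes never fall inside one); homes and schools on
  distinct nodes, homes preferentially ≥ 2.5 blocks from any school, every
  school serving at least two homes.
* **Walkers** follow the minimum-cost path under their *perceived* costs:
  the ground-truth cost table multiplied by walker-level slot preferences
  exp(N(0, `preference_sd`)) (default 0.25) and arc-level random-utility
  noise exp(N(0, `route_noise_sd`)) (default 0.3).  Both are essential:
  with deterministic optimisers the route-choice estimand is degenerate
  (see separation above), and the defaults put the cohort in the
  probabilistic-choice regime a logistic model assumes.
* **Fixes** are emitted every `fix_interval` s (default 10) at
  `walk_speed` (default 1.4 m/s) along the path, displaced by AR(1)
  Gaussian noise with stationary sd `gps_noise_sd` (default 5 m) and lag-1
  correlation `gps_noise_rho` (default 0.9): GPS error drifts slowly, and
  white noise at 14 m fix spacing would inflate trace length by ~20%,
  which real loggers do not show.  Fixes within 45 m of home or inside the
  school footprint are not emitted (they would be filtered anyway).  With
  probability `p_partial` (default 0.5) a trip records only the chainage
  window [U(0, 0.2), U(0.85, 1)] of the path (cold start / early cut-off).
* **Timestamps** fall on weekdays inside the correct commute window, with
  the whole trip fitted inside the window.
* **Decoys** (default 10% of commute fixes) cycle through midday fixes on
  the path, fixes inside buildings, fixes within 40 m of home, and weekend
  fixes, exercising every inclusion criterion.

What the generator does **not** emulate: real urban morphology (it is a
perturbed grid), elevation, multi-modal travel, day-to-day route
variation, GPS multipath/urban-canyon error structure, and school-level
behavioural clustering beyond school assignment.  Passing recovery tests
therefore shows the *inference machinery* is correct under the stated
model, not that the published effect sizes generalise.

## Experiment sizes and numerical conventions

The recovery experiments use 12×12 towns with 200 m blocks, 25 traffic
lights, 30 outlets and 100 walkers per cohort, 20 seeded cohorts.  Block
length must exceed the 100 m outlet-exposure buffer: on finer grids a
walker can avoid an outlet's arc while staying within 100 m of the outlet,
so avoidance would be invisible in the exposure count.  Sign-recovery
experiments use measurement-error-free traces (`p_partial = 0`): partial
recording replaces walked stretches with straight anchor chords, which
deletes passed traffic lights from the GPS counts and would bias the very
covariates under test.  Coverage simulations use 200 replicates of 500
strata; exposure-model simulations use 15 schools × 30 routes × 200
replicates.  Road-class percentages are computed by 5 m chainage sampling
against the nearest arc within 25 m (off-network length beyond tolerance
stays unclassified).  Route geometries are compared exactly; floating
tie-breaks in routing are resolved lexicographically.

## Known limitations

* Per-route WNE monotonicity in the outlet cost is false in general
  (rerouting away from a flagged arc can pass within 100 m of different
  outlets); only the cohort mean decreases reliably, and that is what the
  tests assert.
* The calibration objective (mean intersection) is a step function of the
  cost table, so grid resolution bounds the achievable optimum; no
  continuous optimisation is attempted.
* The conditional logit assumes the SNR is the relevant counterfactual
  choice; it is a two-alternative approximation to a path-set choice
  model.
* Firth estimates under heavy quasi-separation are finite but can be
  large; they are evidence about direction, not precise effect sizes.
* One synthetic cohort in twenty may still fail sign recovery or
  separation screening; the acceptance properties are stated as ≥ 90%
  rates, not certainties.
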