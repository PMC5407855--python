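# Methods

## The problem and the model

An observer experiences a stream of objects whose transitions are drawn from
a hidden relational graph. The package's premise is that a scalar response
measured for each ordered object pair (an fMRI adaptation estimate for the
object given its predecessor, or a log response time in an incidental task)
scales linearly with some notion of proximity between the pair on the graph:

    response(s, i→j) = β · m(i, j) + u_s(j) + ε,

where `m` is a proximity metric, `u_s(j)` is a subject-specific offset for
object `j`, and `ε` is measurement noise. Everything downstream —
competitive regressions, distance contrasts, map recovery — estimates or
tests aspects of this model. The candidate metrics differ in what they claim
the brain stores: link distance and Euclidean distance describe a veridical
map; communicability (`−e^A`) and the negative successor representation
(`−(I − γA)⁻¹`) describe *predictive* representations that discount walks by
length and so distort the map toward frequently travelled routes. Because
the candidates are strongly correlated on any small graph, the package
always fits them competitively (jointly, per subject, with an intercept) and
pushes inference to the group level with one-sample t-tests on per-subject
coefficients.

## Graphs

The analyses are topology-parametric; graphs are inputs. The shipped
defaults are constraint-satisfying reconstructions, not canonical objects:

- the **reduced graph** (test day): 7 nodes, 7 edges — a 5-cycle 1–4–6–3–5
  with pendant nodes 2 (on 1) and 7 (on 5). It is connected, has diameter
  exactly 3, contains edges {1,2}, {4,6}, {5,7}, {3,5}, {1,5}, omits
  {2,4}, {4,7}, {1,7}, and ships with an exact unit-edge planar layout
  (regular pentagon of side 1 plus radial pendants), so Euclidean distances
  with "linked pairs at distance 1" are available without approximation;
- the **training graph**: 12 nodes, 17 edges — the reduced graph as induced
  subgraph plus an outer ring (8–9–10–11–12) with one spoke to each of
  nodes 2, 4, 6, 3, 7. Minimum degree 2 ensures the window-constrained
  random walk rarely dead-ends (bounded backtracking handles the rest).

## Successor-representation discount

The SR series `Σ γⁿAⁿ` converges only for `γ·λmax < 1`. The package
therefore parameterises the discount as a *fraction* of the critical value:
`γ = gamma_fraction / λmax`, default `gamma_fraction = 0.85`. A fraction
≥ 1 raises a divergence error.

## Sequence designs

- **Training walk**: uniform random choice among the current node's
  neighbours excluding any node seen in the last `exclusion_window` (= 3)
  positions; dead ends trigger backtracking (up to 50 undos) and then a
  restart with a derived seed. Deterministic given the seed.
- **Balanced test sequences**: a randomised Hierholzer Eulerian circuit on
  the complete directed multigraph with arc multiplicity `reps`. This
  guarantees, by construction rather than by rejection sampling, that every
  ordered pair of distinct objects occurs exactly `reps` times as a
  consecutive pair, that no object repeats immediately, and that the
  sequence length is exactly n(n−1)·reps + 1.
- **Cover task**: patches are Bernoulli(0.5) per trial; exactly one probe
  per ordered transition type (42 probes = 10% of the 420 transition trials
  in a scanner run); each probe trial and the two following trials are
  flagged for exclusion.
- Inter-trial intervals for event exports are Poisson with mean 2 s,
  resampled into [1, 5] s (the truncation bounds are a package choice; the
  design only states the mean).

## Experience-derived distances

Directed transition counts from training feed two constructs: the asymmetry
index `a = |c_xy − c_yx|/(c_xy + c_yx)` (0 = symmetric experience, 1 =
one-directional), and per-direction edge lengths `d = 1 − c/(1 + cmax)`
(`cmax` = the most-travelled directed edge), which make often-travelled
edges short. Pairwise distances are then single-source shortest paths over
these weights, either directional or symmetrised by averaging the two
directions — the regressor pair used to test whether responses track
directional experience or its non-directional (map-like) summary.

## Map recovery

1. **Group matrix**: cell-wise mean of per-subject response matrices,
   diagonal fixed at 0 (objects never repeat, so the diagonal is unmeasured).
2. **Dissimilarity**: average the two triangles, shift the off-diagonal so
   its minimum is exactly 1, re-zero the diagonal. (Symmetrising before the
   shift keeps the off-diagonal minimum exactly at 1; shifting first would
   let the averaging push it above 1.)
3. **MDS**: nonmetric (Kruskal stress-1) by default, 20 seeded random
   restarts, best solution kept; metric MDS by option. Implemented on
   scikit-learn's SMACOF with tight convergence (eps 1e−9) so that exactly
   embeddable configurations are reproduced to ~1e−3.
4. **Test**: the observed statistic is the Pearson correlation between
   embedded distances and true link distances over the 21 unordered pairs.
   The null is *exhaustive*: all connected simple graphs with the same node
   and edge counts (68,295 for 7 nodes / 7 edges, filtered from 116,280
   candidate edge sets by union-find), each scored by the correlation of its
   own link distances with the same embedding. The permutation p is the
   fraction of null members at or above the observed statistic (no +1
   smoothing; ties count against the hypothesis). A second statistic counts
   proper line crossings of each topology's edges at the fixed embedding;
   a genuinely two-dimensional map should draw the true graph with zero
   crossings, while only a small fraction of random topologies are
   crossing-free.
   Crossing semantics: segments sharing an endpoint never cross; an endpoint
   touching another segment's interior does not count; collinear overlap in
   more than a point does.

## Response-time pipeline

Log-transform, subtract each object's mean log-RT within subject, average
the demeaned values per transition within each block, then across blocks —
one value per ordered pair per subject. Incorrect trials are excluded by
default (switchable). Because this removes object-specific means from the
responses, the default RT regression also demeans each regressor within
object (equivalent to object fixed effects); without this the removed
column means re-enter the design as systematic structure and can load
spuriously on collinear competitors at high signal-to-noise. Binned
visualisation sorts pairs by communicability into 6 equal-count bins
(a count of 6 matches the figure this summary mirrors; 7 is available by
argument).

## Synthetic cohorts

The generator emulates exactly the structure the analyses presuppose —
linear metric scaling, Gaussian per-object offsets, Gaussian trial noise,
balanced designs — and none of the things real data add: no haemodynamics,
no autocorrelated noise, no learning dynamics across blocks, no
subject-level variation in β. Passing tests therefore validate the
*analysis machinery* (estimators, nulls, error control), not the empirical
claim that brains behave this way.

Defaults (chosen once, as plausible orders of magnitude where the designs
do not fix them): 23 subjects for adaptation cohorts and 26 for behavioural
cohorts; training 12 blocks × 133 items; scanner 3 runs × 421 items;
behaviour 10 blocks × 127 items; adaptation scale β = 1, object SD 0.5,
noise SD 1.0 (arbitrary units); response times β = 0.05 on the log scale
(≈ 60 ms over the communicability range at a 700 ms baseline), object SD
0.1, trial noise SD 0.3 (a ~30% coefficient of variation, typical of simple
RT tasks).

## Numerical and design notes

- Communicability uses `scipy.linalg.expm`; the SR uses a direct solve of
  `(I − γA)`. Both are cross-checked against truncated walk series in the
  tests.
- Ensemble statistics are vectorised: batched boolean matrix powers give
  all 68,295 link-distance matrices at once; crossing counts reduce to a
  precomputed 21×21 edge-pair crossing table contracted with each member's
  edge mask.
- The repeated-measures ANOVA is the classic two-way decomposition
  (condition, subject, residual); it is verified against an independent
  implementation in the test suite.
- Group t-tests with zero coefficient variance: exactly-zero coefficients
  give t = 0, p = 1; non-zero constant coefficients give NaN plus an
  explicit flag rather than an exception.
- Per-stage seeds are derived as `sha256(f"{run_seed}:{stage}")`, so any
  stage can be re-run in isolation, bit-reproducibly.
- Regressors are mean-centred (not z-scored) by default; z-scoring is a
  switch. The correlation statistic in map recovery is Pearson on the
  upper triangle.

## Limitations

- The shipped graphs are reconstructions satisfying the documented textual
  constraints; analyses on other topologies should pass graphs explicitly.
- The exhaustive null is practical for small graphs only (C(21,7) ≈ 1.2e5
  candidates at 7 nodes); larger graphs would need sampled nulls.
- The RT generator draws error trials independently of difficulty, so
  accuracy-based exclusions are exchangeable noise here, unlike real data.
- Nonmetric MDS has restart-dependent local minima; results are seeded and
  use 20 restarts, but embeddings are identified only up to rotation,
  reflection and (for nonmetric) monotone rescaling.
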