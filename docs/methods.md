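# Methods

`seasonet` analyses seasonal structure in bipartite plant–pollinator
networks built from dated visitation records. This note documents the
models and procedures, the parameters that matter, what the synthetic
community generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Networks from visit records

The atomic datum is a dated observation of one bee species visiting one
plant species (an optional count defaults to 1). For a period (calendar
month, season, or the full year), the network's nodes are exactly the
species involved in at least one interaction in that period; links are the
distinct (plant, pollinator) pairs, weighted by summed visits. Duplicate
(date, plant, pollinator) rows are summed rather than rejected, since
field sheets legitimately contain repeats. Identifiers are opaque,
case-sensitive strings from disjoint namespaces; no taxonomic
normalization is attempted.

Seasons are assigned by month alone through a configurable calendar. The
default encodes the central-Brazilian Cerrado regime: rainy from October
through March, dry from April through September, with the transitional
months April and October assigned to the dry and rainy seasons
respectively.

**Interaction frequency.** For link (i, j), F_ij = (visits by bee j to
plant i) / (number of distinct days plant i was visited by *any* bee
within the period). The denominator proxies the plant's flowering
activity, so plants flowering for only part of the period are not
penalized. The denominator counts distinct dates with at least one visit,
not visitation events — the reading of "days the plant was observed
interacting" adopted here. It is recomputed within each period, so
seasonal networks use seasonal denominators. Weighted degree of a species
is the sum of F over its links.

## Structural metrics

- **Connectance.** Reported as BC = 2L/(N_po·N_pl), the doubled variant
  used by the field study this package models; the conventional
  L/(N_po·N_pl) is available behind a flag (`doubled=False`). The doubled
  form is the default so reported values are comparable with the study's
  tables.
- **NODF nestedness** (0–100). For each pair of rows (and of columns),
  the pair contributes the percentage of the poorer node's links
  contained in the richer node's links when fills *strictly* decrease,
  else 0 (the original definition's decreasing-fill condition); the score
  averages contributions over all row pairs plus column pairs. The
  implementation is fill-sorted-equivalent (position-independent) and
  agrees with `vegan::nestednodf(..., order = TRUE)`.
- **Nestedness significance.** Empirical p = (1 + #{null NODF ≥
  observed}) / (1 + n_rand) against constrained randomizations. The
  default null (`fixedL`) preserves N_pl, N_po and L, wiring L distinct
  links uniformly over the cells; rows or columns may go empty in a null
  draw — forcing coverage would bias the null upward in fill structure. A
  `marginal` option additionally weights cell inclusion by the product of
  observed marginals.
- **Degree-distribution model selection.** Exponential (rate κ),
  power law (exponent γ) and truncated power law (γ plus cutoff κ) are
  fitted by *discrete maximum likelihood* with the pmf normalized
  numerically over the observed support k = 1…k_max, and ranked by AIC
  (ties broken toward fewer parameters). MLE was chosen over least squares
  on cumulative curves for statistical defensibility; results can differ
  from curve-fitting implementations. The truncated-power-law likelihood
  is maximized by bounded quasi-Newton search from three starts, with
  γ ≥ 0 enforced (the exponential limit lies on the γ = 0 boundary).
- **Seasonal differences.** A one-tailed permutation test: visit records
  are reassigned to the two seasons preserving each season's record
  count, networks rebuilt, and the metric difference recomputed; the tail
  follows the sign of the observed difference, and permutations on which
  the metric is undefined are redrawn (capped at 1000). This permutation
  scheme is a reconstruction — the study does not spell out its testing
  machinery — and is labelled as such in reports.

## Turnover partitioning

For consecutive monthly networks, Whittaker's presence-based index is
applied to element sets: β = (a+b+c)/((2a+b+c)/2) − 1, algebraically
(b+c)/(2a+b+c), with a shared and b, c unique elements. Elements are
links (β_int), links restricted to species present in both months
(β_rw, rewiring), all species (β_S), plants (β_pl) and pollinators
(β_po). β_st — dissimilarity due to species turnover — is obtained
strictly by subtraction, β_st = β_int − β_rw, not by a direct formula;
the two constructions differ in general and the subtraction definition is
the one implemented. Because the shared-link count is identical in the
full and restricted computations and the Whittaker form is monotone in
b+c, 0 ≤ β_rw ≤ β_int ≤ 1 always holds.

Degenerate cases: when the two restricted link sets are non-empty and
disjoint, β_rw = 1; when *no* links among shared species exist in either
month, β_rw is defined as 0 (no rewiring is possible) so the partition
still closes. Months with zero interactions propagate a flagged undefined
record (NaN) rather than an arbitrary 0 or 1.

**Correlations and the constrained null.** Because adjacent month pairs
share a month, turnover series are serially dependent and parametric
p-values for Spearman's r_s are biased. Significance therefore comes from
a Monte-Carlo null: each simulation replaces every monthly network with a
random one of identical dimensions — species drawn uniformly without
replacement from the year's pools, L distinct links wired uniformly among
the drawn species — and the correlation is recomputed. Keeping (N_pl,
N_po, L) fixed keeps connectance fixed automatically. Two open readings
were settled as follows: species are redrawn independently per month (the
simplest reading), and the species sets of a null month are the *drawn*
sets even if a drawn species receives no link, which preserves the
month's dimensions exactly. Default n_sim is 10^5; tests run at 10^2–10^3.
The two-tailed p compares |r|; a one-tailed p in the observed direction
is reported alongside. All empirical p-values use (1+hits)/(1+n), so
p = 0 never occurs.

## Robustness simulations

Species of one guild are removed one at a time; the x-axis is the
fraction of that guild removed (including x = 0), so AUC on the unit
square is comparable across networks. Removal keys are the *initial*
(weighted) degrees — species are ranked once by niche breadth; an
optional flag re-ranks after each removal for sensitivity analysis. Ties
are broken by permuting the removal sequence within tie blocks each
iteration, so targeted removals also yield a curve ensemble (100
iterations by default).

- *Unweighted (species) mode:* after each removal, any opposite-guild
  species left without surviving partners is secondarily extinct; y is
  the fraction of the opposite guild surviving.
- *Weighted (flow) mode:* each link weight is first converted to its
  fractional contribution to total visitation; y is the fraction of flow
  on links with both endpoints alive. Secondarily extinct species carry
  no surviving links, so flow accounting is unaffected by their formal
  removal.

Point-wise and AUC confidence intervals are 95% percentile (2.5/97.5)
over iterations — the CI method is otherwise unspecified in the source
methodology. Loss after removal of 50% of the target guild is read at
x = floor(S/2)/S and reported as a remaining fraction and a species
count. Two experiments are flagged significantly different when their
AUC percentile CIs do not overlap. The x-axis counts primary removals
only (the standard attack-tolerance convention); secondary losses appear
in y.

## Link-based rarefaction

The sampling unit is the unique link — the first record of each (plant,
pollinator) pair; repeat visits do not advance the curve. This avoids
confounding by uneven daily sampling effort (e.g. rain-shortened field
days). The unique-link sequence is shuffled (100 randomizations by
default) and features — plant/pollinator richness, mean partners per
guild, connectance, optionally NODF — are evaluated on the growing
network, giving a mean curve and a 95% percentile envelope that closes to
zero width at x = L.

**Asymptote heuristic.** Saturation is asserted visually in the field
literature; here it is an explicit criterion: the mean absolute change
per step over the final `window` fraction of the curve (default 10%),
relative to the curve's local magnitude, must fall below `tol` (default
0.005 per step). Both thresholds are exposed because any such criterion
is scale-dependent: long, slowly-climbing richness curves can satisfy a
per-step relative threshold, so conclusions should quote the measured
relative slope, which the diagnostics include.

## The synthetic community generator

No field dataset is distributed with this package, so analyses and tests
run on a generator that emulates the *summary structure* of a weekly-
sampled bi-seasonal community rather than any real interaction matrix:

- **Scale** (defaults): 93 plants, 111 pollinators, a target of 968
  visits over 47 sampling days spread evenly across a 12-month study year
  (Oct 1 – Sep 30).
- **Phenology:** each seasonal species receives a contiguous activity
  window of 4–16 weeks placed uniformly inside its season's block;
  aseasonal species (default 30% of pollinators — the social-bee
  analogue — and 5% of plants) are active year-round. Seasonal species
  are split 60/40 between rainy and dry, mirroring the larger rainy
  community; the split is a package choice, as no figure is published.
- **Propensities:** pair propensity = plant abundance × pollinator
  abundance × compatibility, with lognormal abundances (log-sd 1.0) and a
  Pareto-tailed compatibility factor (tail exponent 1.5, capped at 20).
  The two-layer product yields truncated-power-law-like degree tails; an
  empirical interaction matrix is deliberately *not* imitated because
  none is available.
- **Sampling:** each feasible day draws a Poisson number of visits (rate
  = target/feasible days) and allocates them to co-active pairs
  proportionally to propensity. All draws flow through one seeded
  generator stream, so output is byte-identical given a seed.

`generator_selfcheck` verifies the intended structure on generated data:
aseasonal pollinators over-represented in the top degree decile, pooled
degrees best fit by a truncated power law, and median monthly β_int
above 0.5.

**What the generator does not emulate — and what passing tests therefore
do not show.** Daily visit rates are constant across feasible days, so
seasonal *visit* totals come out roughly equal even though the dry-season
community is smaller in species and links; the real community concentrated
two-thirds of its visits in the rainy season. Aseasonal species differ
from seasonal ones only in activity span, not in intrinsic abundance, so
the pollinator-versus-plant removal asymmetry (the aseasonal-keystone
signature) expresses itself reliably in *weighted* (visitation-flow)
robustness but not systematically in unweighted species-loss robustness.
Within-side, within-season degree fits can prefer any of the three
models on a given realization; only the pooled-degree fit is reliably
truncated-power-law. Monthly β_int is consistently high (median ≈ 0.85)
but its minimum across month pairs can fall to ≈ 0.6, below the 0.747
floor seen in the field year. Tests passing on generated data certify
the estimators and simulations, not fidelity to any particular field
matrix.

## Numerical conventions

- Empirical p-values: (1 + hits)/(1 + n) throughout.
- AIC = 2·(free parameters) − 2·logL; rank ties go to fewer parameters.
- Trapezoidal integration for AUC on the x-grid including x = 0.
- Percentile CIs (2.5/97.5) wherever an ensemble is summarized.
- Edge-list round trips recover per-plant active-day counts from
  visits/frequency, which is exact because all links of a plant share the
  plant's denominator.
- Analysis drivers run at desk scale: 999 nestedness randomizations,
  499 permutations, 2000 null simulations, 100 robustness iterations and
  100 rarefaction randomizations; all are exposed as flags.

## Known limitations

- The rewiring component follows the subtraction definition; comparisons
  with β-partition software using the direct decomposition will differ.
- The `fixedL` nestedness null admits empty rows/columns; nestedness
  p-values are therefore conservative relative to nulls that force
  coverage.
- The constrained correlation null redraws species independently per
  month; temporal autocorrelation of species identity under the null is
  therefore absent by construction.
- The asymptote criterion is a heuristic whose outcome depends on curve
  length; treat the boolean as a flag on the reported relative slope.
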