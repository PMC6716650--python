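# Methods

## Model and inference

`arealscan` works with areal count data: regions i = 1..m with populations
N_i, case counts c_i, centroid coordinates, and optional covariate
percentages. The null model is spatial randomness conditional on the total
count C = Σc_i: cases fall into regions independently with probabilities
N_i/N. The alternative for a zone z (a subset of regions) is a distinct
Poisson rate inside versus outside z.

With c the observed and e = C·n_z/N the expected count in z, the Poisson
scan log-likelihood ratio is

    LLR(z) = c ln(c/e) + (C−c) ln((C−c)/(C−e)),

set to 0 for non-elevated zones (c ≤ e) in a high-prevalence scan, with
0·ln 0 ≡ 0 so the edge cases c = 0 and c = C are finite. A small negative
floating-point residue at c ≈ e is clamped to 0. The implementation is
validated against an independent evaluation via Poisson log-pmfs at the
inside/outside MLE means (the factorial terms cancel) to 10⁻⁹ relative
error.

Two risk-ratio summaries are attached to every zone: the inside/outside
relative risk rr_io = (c/e)/((C−c)/(C−e)) and the observed/expected ratio
oe = c/e. Recomputation from published cluster tables shows circular-scan
software reports rr_io while flexible-scan software reports oe, so the
reporting filter uses rr_io for circular scans and oe for flexible scans by
default; both are always stored and the choice is configurable.

### Zone families

*Circular*: for each centre region, neighbours are added in ascending
centroid distance (ties broken lexicographically by region id, making the
family invariant to input row order) while the cumulative population stays
within `max_pop_fraction` of the study total (default 0.13, chosen so a
study area whose largest unit holds 13% of the population can still flag
that unit). Duplicate member sets from different centres are kept once.
Distances are Euclidean in planar mode or great-circle (haversine,
R = 6371 km) in spherical mode; both are offered because centroid tables
arrive in either form.

*Flexible*: all connected subsets of at most K regions (default 10) that
contain a centre and lie within that centre's (K−1)-nearest-neighbour
ball. Connectivity is judged on an explicit adjacency (rook polygon
adjacency when geometry is available, otherwise a symmetric K-NN graph).
Enumeration grows subsets with an ordered extension/exclusion recursion so
each subset appears once per centre, dedupes globally, and refuses
instances above a zone budget (default 5×10⁶) — exhaustive flexible
scanning is only practical for small-to-moderate window sizes. Correctness
is checked against an exhaustive connected-subset oracle on graphs of up
to 14 nodes.

*Restriction*: the flexible statistic is the restricted LLR — the LLR times
the indicator that every member region is individually elevated, region i
being "hot" when its one-tailed mid-p P(X > c_i) + ½P(X = c_i),
X ~ Poisson(e_i), falls below α₁. Default α₁ = 0.2, the published default
for the restricted flexible scan; mid-p is the default tail convention with
the plain tail available. The restriction is recomputed on every Monte
Carlo replicate, and the same restricted statistic is used for observed and
replicate data.

### Monte Carlo testing

Replicates are multinomial redistributions of C over regions with
probabilities N_i/N (conditional on C — required for exchangeability of the
family maximum), generated from a seeded `numpy` Generator in batches whose
size bounds the regions × replicates working set. Each zone's p-value is
(1 + #{replicate max ≥ observed statistic}) / (R + 1), so the smallest
attainable p with R = 999 is 0.001. Zone statistics for observed and
replicate data flow through one sparse zone-membership matrix product.

### Cluster selection

Scored zones are taken in decreasing statistic order (ties broken by member
tuple); any zone sharing a region with an already-kept zone is discarded
("no geographical overlap"). Kept zones are filtered to p ≤ α (default
0.05) and prevalence ratio strictly above `pr_min` (default 1.2, to avoid
reporting very-low-excess clusters), then ranked 1..n with rank 1 the
primary cluster.

## Covariate adjustment

Step 1 fits cases ~ covariates with log link and offset ln N_i by IRLS
(statsmodels GLM; convergence tolerance 10⁻⁸, max 100 iterations; rank
deficiency and non-convergence are errors). Covariates enter untransformed
on the log-rate scale. Step 2 rescans with the fitted expecteds ê_i
replacing N_i wherever population acts as the at-risk denominator: the
null expecteds become C·ê_z/Σê, the multinomial probabilities become
ê_i/Σê, and the circular population cap applies to ê. Under this
convention an intercept-only model reproduces the unadjusted scan exactly,
which the tests assert. Adjustment is wired for both scan variants; the
flexible path is an extension beyond the usual circular-only practice. No
overdispersion correction is applied (pure Poisson).

A consequence of the error contract: a covariate that is constant across
regions makes the design rank-deficient alongside the intercept and is
rejected rather than silently ignored.

## Method comparison

Given each method's binary region classification ("in any reported
cluster"): Po = (a+d)/n, Pe = ((a+b)(a+c)+(c+d)(b+d))/n², κ = (Po−Pe)/(1−Pe)
with large-sample SE √(Po(1−Po)/(n(1−Pe)²)) for the 95% CI; PABAK = 2Po−1
with CI obtained by transforming the Clopper–Pearson exact interval of Po —
this pairing reproduces published four-decimal intervals for both
statistics. Degenerate marginals (Pe = 1) raise rather than return NaN.
The exact McNemar p is min(1, 2·P(X ≤ min(b,c))), X ~ Binomial(b+c, ½),
defined as 1 with no discordant pairs. The proportion test replicates R's
`prop.test` Yates-corrected pooled chi-square (correction capped at the
observed absolute difference, so equal proportions give statistic 0).

CLIC = −2·ΣLLR + ln(p)·n uses the natural log: recomputing from a published
circular-scan table reproduces the printed magnitude (25,532) under ln and
not under log₁₀. The formula yields negative values for realistic inputs
while published tables print positive ones, so both the signed value and
the magnitude are returned; rankings are conventionally made
lower-is-better on the magnitude, and no further intent is guessed.

## Synthetic data

The generator emulates the structure of county-level prevalence data:
lattices (or random planar layouts) with log-uniform populations between
10⁴ and 2.5×10⁶, baseline prevalence π₀ = 0.037, embedded zones of disk, L,
line or free shape with relative risks spanning 1.2–2.5, and Gaussian
region-level covariates with log-linear effects. Rates are
λ_i = π₀·RR_i·exp(Σβ_k(x_ik − x̄_k)) — covariates are centred so π₀ remains
the marginal prevalence — and counts are Poisson(λ_i N_i), truncated at N_i
with a warning (prevalence counts cannot exceed denominators). Everything
is a pure function of (scenario, seed).

Named scenarios fix the study conditions used by the tests: a null 10×10
lattice (5,000 adults/cell); a 5-cell disk hotspot at RR 2.0; a 7-cell
L-shaped hotspot at RR 2.0; a covariate-driven scenario whose disk's
~1.6-fold excess comes entirely from a +6-point shift of a
hypertension-like covariate (β = ln(1.6)/6); and a "florida-like" layout of
67 irregular regions whose largest holds 13% of the total population.

What the generator does **not** emulate: survey weighting and its design
effects, spatially autocorrelated covariate fields beyond the zone
structure, and irregular county geometry (grid adjacency stands in for
polygon adjacency). Passing simulation tests therefore demonstrate
calibration and power under idealized areal sampling, not performance on
any particular real surveillance system.

## Simulation-based checks and problem sizes

The suite verifies, at sizes chosen to keep a single-CPU run short: type-I
error of both scans within the 99% binomial band around α = 0.05 over 200
null lattices (199 replicates per scan; 10×10 circular, 8×8 with K = 5
flexible; the PR filter is disabled there so every significant maximum
counts); disk-hotspot recovery (Jaccard ≥ 0.6 and p ≤ 0.05) in ≥90% of 100
runs; strictly higher mean Jaccard for the flexible scan on the L-shaped
hotspot, paired over 100 seeds; disappearance of the covariate-driven
cluster after adjustment in ≥80% of 40 runs; and GLM coefficient recovery
within 3 SE on 200 regions. Detection is scored on the union of reported
cluster members, since an irregular hotspot may legitimately be reported as
several non-overlapping pieces when it exceeds a single neighbour ball.

## Known limitations

- Only the discrete Poisson high-prevalence model: no Bernoulli, ordinal,
  space-time or elliptic variants, and no Gumbel-approximated p-values.
- Circle centres are region centroids; grid-point centres are not offered.
- The flexible enumeration is exhaustive, hence exponential in K; the zone
  budget fails fast instead of degrading to a heuristic search.
- Jenks/natural-breaks classification uses exact dynamic programming
  (Fisher's optimal partition), fine for hundreds of values but quadratic
  in the input size.
- GeoJSON is the only geometry format; no shapefile parsing or projection
  transforms.
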