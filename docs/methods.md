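# Methods

This note records the modelling choices behind the package: what is
computed, which knobs matter, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## Data model and scaling

A solvent table is an ordered set of named records over a declared property
schema (22 numeric columns by default, units in
`src/sussol/data/property_schema.yaml`).  Missing values are first-class:
empty CSV cells become NaN, and clustering/MDS refuse to run until the
caller resolves missingness.  The resolution strategy is column dropping,
not imputation: `select_feature_columns(table, query)` removes every
property the query solvent lacks, then every remaining property missing for
any solvent.  Imputation was rejected because the downstream statistics
(co-clustering counts) have no mechanism to propagate imputation
uncertainty.

Feature scaling is weighted min–max to [0, 1] per column (dataset minimum to
0, maximum to 1, constant columns to 0.5), then multiplied by a per-column
weight (default 1).  Min–max matches the normalized candidate visualization
convention in this field; z-scoring is available (`scaling="zscore"`) for
users whose property distributions are heavy-tailed, but is not the default
because outliers in solvent tables are usually real chemistry, not noise.
Weights are a user instrument: up-weighting a property that is critical for
an application (e.g. water solubility) pulls the clustering toward it.

Hansen distance uses the conventional factor-4 dispersion weighting,
`Ra^2 = 4 dD^2 + dP^2 + dH^2`; the ~4 MPa^1/2 miscibility rule of thumb for
nonpolar pairs presumes exactly this convention.  Radius subsetting is
strict (`< radius`) and always retains the reference solvent.  Range filters
are inclusive on both bounds and conjunctive; records missing a filtered
property are excluded rather than passed through (conservative; a filter
states a requirement the record cannot demonstrate it meets).

## CHEM21-style SH&E scoring

Scores are integers 1–10 (10 = worst) with fixed colour bands (green 1–3,
yellow 4–6, red 7–10).  All band tables live in an editable YAML file
(`src/sussol/data/chem21_rules.yaml`):

* **Safety**: base score from flash-point bands (>= 60 °C -> 1 down to
  < −20 °C -> 7, with a combined "cryogenic flash point and boiling below
  45 °C" band at 8), +1 penalty point each for autoignition below 200 °C
  (the "low autoignition" threshold is not standardized; 200 °C is our
  configurable default), high resistivity, and peroxide formation; a high
  energy of decomposition forces 10.  A missing flash point falls into the
  most conservative ordinary band (7) with a logged warning.
* **Health**: worst mapped H3xx statement (codes matched on their 4-character
  stem so H360FD triggers the H360 entry), +1 for boiling points below
  85 °C; unknown toxicology data scores 5.
* **Environment**: boiling-point bands (70–139 °C ideal -> 3; 50–200 °C ->
  5; else 7: low boilers emit, high boilers resist recycling), raised by the
  worst H4xx statement (max, not sum) and by REACH status; H420 (ozone
  hazard) forces 10; unknown data contributes 5.

The overall ranking rule is deliberately configurable because published
score tables are not fully consistent under any single threshold rule.  The
shipped default — Hazardous iff safety >= 8, health >= 9, environment >= 10,
or (health >= 7 and environment >= 7); Recommended iff all three <= 3; else
Problematic — reproduces the published rankings we use as regression
fixtures with one known exception, and a per-solvent manual override
mirrors the "changed by the solvent team" practice of the guides.  The
scores are screening aids, not risk assessments.

## SOM clustering

Rectangular, non-toroidal grid; Euclidean BMU matching with ties broken to
the lowest neuron index; online training.  Choices the literature leaves
open, fixed here as defaults:

* **Neighbourhood**: "bubble" (uniform update inside the radius), matching
  the unweighted update rule `y <- y + gamma (x - y)` applied to all
  neighbours of the BMU; Gaussian weighting is available as an option.
* **Decay**: learning rate linearly from `gamma0` (default 0.5) to a floor
  of 0.01, neighbourhood radius linearly from `max(width, height)/2` to 0,
  both over the presentation budget.  The floor is capped at `gamma0` so the
  degenerate `gamma0 = 0` configuration (useful in tests) leaves the map at
  its initialization.
* **Budget**: `500 * n` presentations by default (n = number of solvents).
* **Initialization**: prototypes drawn uniformly inside the per-column data
  range (seeded), which also guarantees prototypes never leave the data's
  bounding box under bubble updates; explicit `initial_weights` are accepted
  for warm starts and reproducible tests.
* **Grid size** is required user input; there is no robust heuristic
  (published analyses use 15x15 for ~500 solvents but 5x5–7x7 for 40–60
  solvent subsets).

Ensembles train B maps with seeds `base_seed + b`, so a fixed base seed
reproduces the full ensemble exactly.

## Stability statistics

`NEIGH_ij^b(r)` is 1 iff the two solvents' neurons are within Chebyshev
distance r on the grid — the Chebyshev metric is the only one consistent
with a neighbourhood of `nu = (2r+1)^2` neurons.  `STAB_ij = count_ij / B`.
The null model treats a pair's count as Binomial(B, nu/U); `nu` is clamped
to U for radii that cover the whole grid (the null probability for the
truncated neighbourhoods of edge neurons is kept at `nu/U`, as the closed
form states).  The band uses the normal approximation with the exact normal
quantile (1.95996... rather than 1.96; both round to the same published
limits), and significance is tested with strict inequality on the
*unrounded* limits; rounding to one decimal is display-only.  The validity
conditions `B*p > 10` and `B*(1-p) > 10` are reported as a flag and a
warning, never enforced — note that the common configuration B = 10·U sits
exactly on the boundary and is flagged invalid under the strict inequality.
No multiple-testing correction is applied across the n−1 pairwise tests
against one query; the candidate list is a screening device and users should
treat counts near the band edge accordingly.

Candidate lists keep every solvent (other than the query) whose count
exceeds the upper limit, annotated with STAB, Hansen distance and SH&E
scores, sorted by Hansen distance or by (health, environment, safety).
Tag-based exclusion (e.g. `protic`) filters the candidate list only, never
the clustering — a qualitative requirement should not distort the property
geometry.  The per-property relative standard deviation over a candidate
list uses the sample (n−1) standard deviation over the full list by default
(a `top_k` argument restricts it), returns 0 for a single candidate by
convention, and NaN for a zero mean.

## Metric MDS

Distances are Euclidean in the scaled, weighted feature space and can be
logged to CSV for external tools.  The 2D configuration minimizes raw metric
stress `sum_{i<j} (d_ij - dhat_ij)^2` by SMACOF majorization (Guttman
transform) from a classical-scaling (Torgerson) start; majorization makes
the recorded stress sequence monotone non-increasing, which the test suite
asserts on every fit.  Reported stress is normalized by `sum d_ij^2`
(squared Kruskal stress-1), so `sigma_n` lies in [0, 1] and `1 - sigma_n` is
the fitted proportion.  The "variance share" diagnostic is the fraction of
positive classical-scaling eigenvalue mass captured by the first two
components — one defensible reading of "variance accounted for by the two
dimensions", exposed as a diagnostic rather than a claim.  Axis–property
Pearson correlations are pairwise-complete and reported as numbers only;
the axes are dimensionless and the package never hard-codes semantic labels
(volatility, polarity) onto them.

## Synthetic data

`make_blob_table` draws Gaussian clusters around archetype property profiles
(mid-chain alkane, short-chain alcohol, small ketone — the "obviously
distinct chemical families" setting used to sanity-check clusterers), with
per-property standard deviation 2% of the plausibility range, clipped to
plausibility bounds, melting point kept below boiling point, and true labels
returned separately.  `make_homologous_series` produces monotone
boiling-point / water-solubility / molecular-weight trends with an optional
outsized jump between consecutive members.  `inject_missing` masks a seeded
fraction of one column.

What the generator does **not** emulate: correlated property noise within a
family, heavy-tailed property distributions, measurement error structure,
overlapping families, or the joint distribution of any real catalogue.
Passing recovery tests therefore shows the pipeline is *correct* (it finds
structure that is genuinely there and nothing when there is none), not that
real solvent tables are as easy; real families overlap, and STAB values in
practice sit well below 1.

## Problem sizes and numerical choices

Test and reproduction runs use deliberately small configurations — 30
solvents in 3 families, a 3x1 grid, B = 30 = 10·U ensemble runs, default
presentation budget — chosen as the smallest setting where the binomial band
cleanly separates within-family from cross-family pairs.  MDS runs cap at
300 majorization iterations with a relative stress-decrease tolerance of
1e-10.  Degenerate inputs are defined, not rejected: constant feature
columns scale to 0.5, a single-point MDS embeds at the origin with zero
stress, an all-zero distance matrix has `sigma_n = 0`, and a
radius covering the grid gives the degenerate band `lower = upper = B`.

## Known limitations

* SH&E band tables are reconstructions; users with access to the primary
  hazard guides should review and edit the YAML rules.
* The SOM has no convergence diagnostic; the ensemble statistics are the
  intended safeguard against unconverged single runs.
* Candidate significance ignores multiple testing (above) and the stability
  statistic inherits any bias of the chosen grid size.
* Column dropping discards information when a query solvent is sparsely
  characterized; with very few surviving columns the clustering degrades,
  and the code only errors when *zero* columns survive.
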