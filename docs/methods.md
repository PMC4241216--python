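# Methods

## The variability model

The unit of analysis is the *management object*: a (phase of management,
country) pair. Six phases (diagnosis, surgery, chemotherapy, radiotherapy,
follow-up without relapse, follow-up with relapse) crossed with two
countries give the reference m = 12. Each of the 8 resource categories
(biopsies, hospital admissions, imaging, external consultations,
transfusions, radiotherapy sessions, radiotherapy preparation,
chemotherapy drugs) contributes two *areas of variability* — a quantity
area and a unit-cost area — for n = 16 columns, built from 60 *final
factors* (30 distinct resources × {quantity, unit cost}).

Aggregation rules:

- **Quantity areas**: per patient, sum the member factors; per object,
  average over the object's patients (patients with no record in the
  phase do not enter the denominator; an unvisited phase yields 0). The
  chemotherapy-drug area counts distinct drugs given (yes/no per drug).
- **Unit-cost areas**: the country mean of the member factors' tariffs,
  assigned only to objects whose paired quantity area is positive and 0
  otherwise — so a cost cell is zero *iff* its quantity cell is zero.
  Two means are available: the unweighted mean over member factors
  (`cost_mode="simple"`, the default) and a usage-weighted mean over the
  object's factor mix (`"usage_weighted"`). The bundled reference matrix
  shows country cost areas varying across objects (e.g. imaging cost
  76.34 / 75.59 / 98.75 within France), which only the weighted variant
  can produce; both are therefore exposed.
- **Discounting**: amounts incurred t years after diagnosis are
  discounted at rate r (default 4%/year) as PV = amount/(1+r)^t. When
  enabled in the builder, each cost cell is multiplied by the object's
  mean present-value factor derived from the records' year offsets, so
  matrix cells are already-discounted means. Matrix-level analyses take
  the cells as given.

Standardization uses the **population** (1/m) standard deviation — most
library defaults use 1/(m−1); the choice rescales all columns equally and
does not affect distances' ordering, the cophenetic coefficient,
partitions or inertia proportions, but it is applied literally for
reproducibility. A zero-variance column aborts with an error naming the
area: factors that do not vary between locations must be excluded from
the configuration rather than silently dropped.

## Distances and clustering

Three metrics on the rows of X: Euclidean, city-block, and Mahalanobis
with the sample (1/(m−1)) covariance V. With fewer objects than areas V
is singular; the Moore–Penrose pseudo-inverse (relative rank tolerance
1e−10) is substituted and the inversion mode recorded on the result.

Agglomeration supports single, complete and average linkage (implemented
with Lance–Williams updates, which are exactly equivalent to the
min/max/mean set definitions — the test suite proves this against an
exhaustive brute-force oracle on all small instances), plus centroid
linkage d(x̄_r, x̄_s) and Ward linkage (n_r n_s)/(n_r + n_s)·d²(x̄_r, x̄_s)
(the incremental within-group sum of squares; heights are therefore in
squared-distance units). Centroid and Ward are recomputed from cluster
centroids at every step so they remain defined — as heuristics — under
non-Euclidean metrics, which the 15-combination scan requires; a warning
is emitted in that case. Ties in the minimal criterion break toward the
lexicographically smallest (smaller id, larger id) pair, making every
tree deterministic. Centroid inversions (a merge lower than an earlier
one) are permitted and flagged on the tree.

Model selection: for each metric × linkage pair, the cophenetic distance
Z_ij (height of the lowest common node) is correlated with the original
distances Y_ij by the Pearson-type coefficient c; the pair maximizing c
is retained. Degenerate combinations (constant distances, or m = 2 where
only one pairwise distance exists) are recorded as missing rather than
aborting the scan.

`cut(tree, k)` removes the last k−1 merges — identical to removing the
k−1 highest for monotone linkages, and deterministic under centroid
inversions. Display numbering follows the convention leaves 1..m, new
clusters m+1..2m−1 in merge order.

## Choosing k

Over cuts k ∈ [2, m−1]: RSQ = 1 − SSW/SST; SPRSQ = the SSW increase of
the merge that produced the k-cluster solution, as a share of SST (the
SPRSQ of all m−1 merges telescope to 1, so RSQ(k) equals the summed SPRSQ
of the merges not yet performed); RMSSTD of the newly formed cluster uses
the pooled denominator n_vars × (size − 1), the SAS PROC CLUSTER
convention, with 0 for singletons; pseudo-F is the Calinski–Harabasz
ratio (SSB/(k−1))/(SSW/(m−k)), computed on X — the space the clusters
were formed in — and reported alongside a max-normalized copy so all four
curves share one plot.

`suggest_k` returns the **first local maximum** of the pseudo-F curve
(ties toward smaller k), with the global argmax available via
`rule="max"`. The peak rule is the default because pseudo-F curves over
nested hierarchical cuts routinely drift upward again at large k, where
the partition is mostly singletons and no longer interesting; the first
pronounced peak is the conventional reading of the statistic for
hierarchies. On the bundled matrix the first peak is at k = 4 while the
global argmax over [2, 11] sits at k = 6 — the two rules genuinely
disagree, and the package reports the peak.

## PCA

Γ = (1/m) X′X is the correlation matrix of the areas (trace n, so
Kaiser's λ > 1 rule is on the right scale). Eigenvalues are clamped at 0
and sorted descending; each axis's sign is fixed so its largest-magnitude
loading is positive, hence factor maps are reproducible but may be
mirrored relative to other software — comparisons should be
sign-insensitive. ψ_α = X u_α are object coordinates, φ_α(j) = √λ_α
u_α(j) equals the correlation of area j with factor α (verified as an
identity in the tests), CTR are squared-coordinate shares (summing to 1
per axis), cos²_α(j) = φ_α²(j)/Σ_α φ_α²(j) sums to 1 per area over all
axes, and r_j = √(φ₁² + φ₂²) with the conventional 0.8 ring flags areas
trustworthy on the first plane. For tied eigenvalues the eigenvector
basis within the tied block is arbitrary; only invariants (proportions,
subspace projectors) are asserted in that case.

The HCPC view places leaves at their (F1, F2) coordinates and every
internal node at the center of gravity of its member objects, raised to
its merge height. The tree embedded is the one selected by the cophenetic
scan on full X, projected afterwards — not a re-clustering of PC scores —
because the display is meant to show how the *same* partition looks in
the plane that carries most of the inertia. (Re-clustering retained
scores is possible by passing PC coordinates back through the clustering
API, but it is deliberately not the default.)

## The bundled reference matrix

`load_sarcoma_matrix()` ships a 12 × 16 matrix of Franco-Italian sarcoma
management data (2009 €) transcribed from a published costing analysis.
The printed source runs all cells of a row together; the transcription
was validated by enumerating every tokenization of each row into 16
well-formed numbers under the structural constraints (cost zero iff
quantity zero, country-constant tariffs, plausibility bounds). Two cells
deserve note: the France external-consultation tariff reads 90 (the
reading 9 leaves a surplus digit in two rows), and the France
hospital-day tariff 918.3 recurs in every France row.

**Known limitation — printed table vs. analysed data.** The analysis
published alongside this matrix reported a best cophenetic coefficient of
0.83035, a country-wise 4-cluster partition, two/three-axis inertia of
44.76%/59.43% and 6 Kaiser eigenvalues. On the printed matrix, under the
method exactly as described, this package obtains c = 0.78980, a
phase-wise partition, 55.55%/74.38% and 5 eigenvalues — and an exhaustive
search over transcription variants and preprocessing choices (raw vs
standardized data, alternative scalings, all 15 combinations) shows *no*
reading of the printed table that reproduces those published values. The
qualitative conclusions do reproduce: average + Euclidean wins the scan,
and the pseudo-F peak falls at k = 4. The discrepancy is recorded here
rather than patched: the matrix the original analysis actually used
(distributed as supplementary files that are no longer retrievable)
evidently differs from the printed table, and this package reports what
the printed data yield.

## Synthetic cohorts

`generate_patients` draws reproducible patient-level records: every
patient traverses the four treatment phases and exactly one follow-up
phase (Bernoulli relapse split); per-(country, phase, factor) intensities
follow Poisson (counts), lognormal (skewed intensities, fixed shape
σ = 0.75 so the s.d. is of the same order as the mean, matching the
heavy-tailed costs such data show), Bernoulli (drug flags) or fixed
families. Defaults mirror the reference cohort: 58 French / 161 Italian
patients, relapse probabilities 16/58 and 37/161, intensities derived by
splitting each bundled quantity cell evenly over its member factors, and
per-country tariffs set to the median non-zero cost cell per area. What
the generator does **not** emulate: correlation between resources within
a patient, per-patient cost heterogeneity beyond the family variance,
censoring, or within-country center effects — so passing tests show the
pipeline's statistical machinery is correct, not that real cohorts will
produce equally clean structure.

`planted_config` builds cohorts with known 4-group structure for recovery
experiments: radiotherapy resources are used only by phases
G = {chemotherapy, radiotherapy, follow-up with relapse} and their
tariffs diverge 5× between countries, while the remaining phases form two
distinct profiles (hospital-heavy surgery vs. light ambulatory phases)
identical across countries. Every area varies across objects (a
requirement of the standardization step). The planted partition —
G-France, G-Italy, surgery, ambulatory — is recovered with adjusted Rand
index 1.0 across 20 seeds at 150 patients per country in the test suite.

## Numerical choices and sizes

- Pseudo-inverse rank tolerance 1e−10 (relative); tiny negative squared
  Mahalanobis distances from the pseudo-inverse are clipped at 0.
- Eigenvalue clamp at 0; axes with λ below 1e−10 × λ₁ are treated as
  null (contributions undefined, coordinates 0).
- All CSV output uses 12 significant digits; report JSON rounds to 12
  significant digits; presentation layers round to 2–5 decimals.
- Test problem sizes: brute-force agglomeration oracles run on all random
  instances with m ≤ 6, validity-index oracles on m ≤ 8, law-of-large-
  numbers checks at 5 000 patients per country, planted recovery at 150
  per country over 20 seeds — sizes at which the checked properties are
  already exact or statistically unambiguous.
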