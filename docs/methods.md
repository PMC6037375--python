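# Methods

## Data model

The raw unit is one diagnosis event: (patient_id, age in completed years,
sex, ICD-10 code).  Codes are truncated to their 3-character category at
ingest (`J21.0` → `J21`), the granularity at which chapter membership and
all downstream statistics are defined.  Each patient carries exactly one
age and one sex; conflicting rows abort in strict mode and resolve to the
first occurrence in lenient mode.  This single-age simplification is an
assumption: over a study window of a year or two a patient's integer age
is nearly constant, and the per-patient summaries (age histogram, median)
are defined over distinct patients, never visits.

`N`, the denominator of every prevalence and relative-risk computation, is
the number of distinct patients appearing in the records.  All
co-occurrence quantities use set semantics — a patient contributes at most
once to a code's prevalence `P_i` and to a pair's co-occurrence `C_ij` —
so every downstream statistic is invariant to visit multiplicity.

The 22-chapter catalog (I: A00–B99 … XXII: U00–U99) ships embedded with
the standard WHO ranges and can be overridden from a 3-column TSV.
Chapter ranges are compared lexicographically on the 3-character code,
which is order-consistent because codes are letter + two digits.

## Age-density vectors

A code's age density is the length-100 vector `p[i] = (distinct patients
with the code aged i) / (distinct patients with the code)`, ages 0–99 with
older patients clamped into the last bin (the vector length fixes 100
elements; clamping avoids discarding valid elderly records).  Codes with
fewer than `min_patients` carriers (default 100) are excluded from
clustering: a 100-bin estimate from a handful of patients is mostly noise,
and in heavy-tailed code-frequency distributions the rare half of the
codes contributes little record mass.  The default is a package choice,
exposed in the config.

Cumulative vectors are running sums.  Optional KDE smoothing convolves
the discrete density with a Gaussian kernel, reflecting at both boundaries
so mass cannot leak below age 0 or above 99, then renormalizes; the
automatic bandwidth is Silverman's rule applied to the sample the density
implies.  Clustering operates on the raw density vectors; a CDF-based
variant can be produced by the caller (cumulative_density) but is not the
default representation.

## Ward clustering

Clustering is agglomerative with Ward's minimum-variance criterion under
Euclidean distance: at each step, merge the pair of clusters whose union
least increases the total within-cluster sum of squared distances to
centroids.  The implementation maintains pairwise merge costs with the
Lance–Williams recurrence

    D(k, i∪j) = [(n_i+n_k) D(k,i) + (n_j+n_k) D(k,j) − n_k D(i,j)] / (n_i+n_j+n_k)

initialized at `D(i,j) = ‖x_i − x_j‖²/2` for singletons, so heights are
the exact merge cost ΔSSE in squared-distance units (scipy's dendrogram
convention stores `sqrt(2·ΔSSE)`; `LinkageTree.to_scipy` converts).  Ward
with Euclidean distance is reducible, so merge heights are monotone.
Exact cost ties are broken by the smallest (left id, right id) pair,
making results platform-stable; the tie rule is a package convention.
The agglomeration is the naive O(n³) scan, ample for the few hundred
codes that survive the frequency filter.

Cutting the tree at k undoes the last k−1 merges; cluster labels 1..k are
assigned in order of each cluster's smallest leaf index, so labelings are
deterministic and cuts at successive k are nested refinements.

### Elbow selection

`W(k)`, the total within-cluster sum of squared distances for the cut at
k, is computed for k = 1..k_max (default 20).  k* maximizes the discrete
second difference of **log W** over interior k (ties to the smallest k).
The log scale matters: the absolute second difference of W measures
curvature in absolute units, so when between-cluster separations are
unequal — one archetype far from all others, two elderly archetypes close
together — the largest absolute curvature sits at the first big splits
regardless of how much data is available, and the elbow lands below the
true cluster count.  The second difference of log W is scale-invariant
(it compares successive *ratios* of W), recovers the true k on both
balanced and unbalanced geometries, and reduces to the same answer as the
absolute rule when separations are comparable.  The full curve is always
returned and written out so a caller can override k*.

### Dendrogram summary

For reporting, the tree is truncated at a fixed depth (default 6) below
the root; each collapsed branch is labeled by its member code with the
largest distinct-patient count (ties to the lexicographically smallest
code) and that code's prevalence as a percentage of N.  Exports: indented
text and Newick.

## Cluster–chapter association

The association unit is the code, not the patient: each 2×2 table
cross-classifies the chapter-mapped clustered codes by membership in one
cluster and one chapter, and the Fisher exact test gives the tail
probability of the observed overlap under the hypergeometric null with
fixed margins.  The default alternative is one-sided enrichment
("greater"); two-sided (point-probability criterion, with a 1e-12
relative gate so exact ties are included) is available, and the choice is
echoed in the output metadata.  Point probabilities are computed with
log-space factorials (`gammaln`), stable up to margins of a million.
Scores are reported as 1 − p.  No multiple-testing adjustment is applied
by default; a Benjamini–Hochberg post-processor is available but off, so
the reported scores are raw.

Being an exact discrete test, the one-sided p-value is conservative: its
attainable size at nominal 0.05 is below 0.05 by an amount that depends on
the margins.  The test suite therefore calibrates the rejection rate
against the exact attainable size computed per table, not against the
nominal level.

Per-cluster patient profiles (sex proportions, 0–99 age histogram) are
computed over the distinct patients carrying at least one code of the
cluster; a patient with codes in two clusters appears in both profiles.

## Comorbidity network

Nodes are codes with prevalence at least `min_prevalence`; every pair
with `C_ij ≥ 1` is an edge carrying `C_ij` and
`RR_ij = C_ij·N/(P_i·P_j)`.  Prevalences enter as counts, which makes RR
dimensionless; pairs that never co-occur are not edges, so RR = 0 values
appear only if injected externally.  No confidence filtering is applied
to edges — the analysis uses raw RR ranks, and `top_edges` (ties at the
cutoff to larger C, then lexicographic pair) exists for visualization-
style subsetting.  Co-occurrence counting is a sparse
patient-by-code incidence product, exact and fast at hundreds of
thousands of patients.

Edges are partitioned by the cluster labels of their endpoints into
intra- and inter-cluster sets (edges touching unlabeled nodes are dropped
with a logged count).  The two RR samples are compared with the
two-sample KS statistic on raw RR values and with the Jensen–Shannon
divergence (base 2, in bits) between histograms of log₁₀ RR over a fixed
rule: 50 equal-width bins spanning the pooled positive log range plus a
designated underflow bin for non-positive values.  Per-cluster panels
restrict the intra sample to one cluster's edges against the common inter
sample.  By default all edges are compared; a `top_m` switch restricts
the comparison to the highest-RR edges.

## Synthetic cohorts

The generator's job is to produce cohorts in which the structure the
pipeline is supposed to find is planted and known.

**Population ages.**  A two-piece normal peaked at 34 (σ_left 23,
σ_right 19) mixed with a 10% uniform floor, discretized on 0–99: unimodal
with mode 34, median 34, mildly left-skewed, and bounded away from zero
at the oldest ages so elderly-skewed codes have carriers at any cohort
size.

**Archetypes.**  Six fixed shapes, discretized Beta(a, b) densities on
ages 0–99 (evaluated at bin midpoints and normalized):

| archetype | shape | character | designated chapters | sex bias |
|---|---|---|---|---|
| A | Beta(1.2, 10) | infants/children (>70% below 15) | X, VIII | — |
| B | Beta(1.8, 4.5) | teens and early adulthood | I | — |
| C | Beta(30, 70) | narrow 20–40 band (≈98% inside) | XV | 0.95 female |
| D | uniform 0.01 | flat across all ages | VII, XI | — |
| E | Beta(11, 5.5) | seniors, bulk over 60 | XIII | — |
| F | Beta(18, 4) | elderly, bulk over 70 | IX, XIV | — |

Code names are assigned round-robin from each archetype's designated
chapter ranges so chapter–cluster association has planted signal.  The
shape and rate constants were fixed from a design-time power analysis
(per-code sampling noise ‖ε‖ ≈ m^(−1/2) versus the pairwise L2 separation
of the archetype densities, m the expected carriers per code) so that the
closest pair (E, F) remains separable at the default cohort size.

**Carriage.**  A patient of age a carries a code of archetype density f
with probability `base_rate · w(a)/max(w)` where `w = f/pop` — an
importance weight, so the *carriers'* age distribution is exactly f and
every planted code's empirical age density converges to its archetype as
the cohort grows.  (Weighting by f alone would plant `pop·f`, not f.)
With probability `noise` (default 0.05) the uniform density stands in for
f, blurring every code slightly toward flat.  Defaults: 100 000 patients,
6 archetypes × 30 codes, base_rate 0.08, geometric visit counts with
mean 2 (any positive visit distribution is equivalent downstream, by the
set semantics).  Everything derives from one seed; equal seeds give
byte-identical cohorts.

**Sex.**  A patient carrying at least one code of a sex-biased archetype
draws sex from that bias (first such archetype in list order); everyone
else draws a fair coin.  Co-occurrence is induced *only* through shared
age profiles — there is no explicit disease–disease coupling — so
elevated intra-archetype RR in the output is attributable to age
structure alone, which is precisely the effect the pipeline is meant to
expose.

**What the generator does not emulate:** realistic marginal prevalences
of real claims data, within-archetype heterogeneity of shapes,
longitudinal progression, coding noise correlated across visits, or
true biological comorbidity beyond age/sex structure.  Passing the
recovery tests shows the pipeline correctly extracts age-density
structure when present; it does not certify performance on cohorts whose
cluster structure is weaker or confounded in ways the generator omits.

## Pipeline and determinism

Stages (simulate/load → densities → cluster → associate → network →
compare) communicate only through plain-text artifacts (TSV, JSON,
GraphML) in the output directory, so each stage is independently
inspectable and chained stage runs are byte-identical to a full run.  The
manifest records the effective config, the seed and SHA-256 digests of
the eight core artifacts.  All randomness flows from the single config
seed.

## Numerical choices and degenerate inputs

- Density vectors must sum to 1 within 1e-9; TSV round-trips preserve
  them to 1e-12.
- Ward heights are compared to the brute-force recompute-from-scratch
  oracle within 1e-9 in tests; tie-breaks are exact-equality
  lexicographic.
- Fisher: degenerate margins (a zero row or column) give p = 1; the
  two-sided tie gate is 1e-12 relative.
- Elbow: W values below 1e-12 of W(1) are floored before taking logs
  (exact-duplicate inputs can reach W = 0 above the singleton cut).
- KS p-values use the asymptotic two-sample formula (sample sizes here
  are thousands of edges).
- Empty cohorts, codes with zero carriers, cuts with k outside 1..n,
  non-positive bandwidths and empty edge sets raise typed errors rather
  than returning silent defaults.

## Problem sizes

The default study conditions — 100 000 patients, 180 planted codes,
roughly half a million visit records — run the full pipeline in seconds
on one core, and all validation (including exhaustive Fisher enumeration
to table totals of 30 and five-seed recovery runs) completes in well
under a minute each.  These sizes were chosen so the planted structure is
comfortably above the sampling-noise floor derived in the power analysis
above.
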