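# agedense

Age-density clustering of ICD-10 diagnosis codes and relative-risk
comorbidity networks.

Large claims databases record, for every medical visit, the patient's age,
sex and an ICD-10 diagnosis code.  Each code has a characteristic *age
signature*: chickenpox concentrates in children, Cesarean delivery in
women between 20 and 40, glaucoma in the elderly.  `agedense` is a pipeline
for epidemiologists and health-data scientists that turns a raw visit
table into

1. **age-density vectors** — for each code *c*, the length-100 vector
   *p*(age = *i* | patient ∈ *c*), *i* = 0…99, estimated over the distinct
   patients carrying the code;
2. **clusters of codes with similar age signatures** — Ward-linkage
   hierarchical agglomerative clustering of those vectors under Euclidean
   distance, with the cluster count *k* chosen by the elbow of the total
   within-cluster distance curve *W(k)*, plus a depth-limited dendrogram
   summary labeled by each branch's most common code;
3. **cluster–chapter associations** — a Fisher exact test of each cluster
   against each of the 22 WHO ICD-10 chapters (association strength
   reported as 1 − *p*), together with per-cluster sex and age profiles;
4. **a comorbidity network** — codes as nodes with prevalence *P<sub>i</sub>*
   (distinct patients), and for every co-occurring pair the relative risk

   *RR<sub>ij</sub>* = *C<sub>ij</sub>* · *N* / (*P<sub>i</sub>* · *P<sub>j</sub>*),

   where *C<sub>ij</sub>* is the number of distinct patients carrying both
   codes and *N* the number of patients in the data — then partitioned into
   intra-cluster and inter-cluster edges whose RR distributions are
   contrasted with the two-sample Kolmogorov–Smirnov statistic and the
   Jensen–Shannon divergence of log₁₀ RR histograms.

Because real claims data are proprietary, the package ships a synthetic
cohort generator that plants known structure — six archetypal age-density
shapes (infant, youth, a female-dominated reproductive-age band, uniform,
senior, elderly), a population age distribution peaked at 34, and
co-occurrence induced purely through shared age profiles — so every stage
of the pipeline can be validated against ground truth.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from agedense import (GeneratorConfig, generate_cohort, compute_all_densities,
                      ward_linkage, cut_tree, elbow_select, build_network,
                      partition_edges, compare_rr_distributions)

config = GeneratorConfig()  # 100k patients, 6 archetypes x 30 codes
cohort, truth = generate_cohort(config)
print(f"cohort: N={cohort.N} patients, {cohort.n_records} records, "
      f"{len(cohort.codes)} codes")

densities = compute_all_densities(cohort, min_patients=100)
X = np.array([d.p for d in densities])
codes = [d.code for d in densities]

k, curve = elbow_select(X, k_max=20)
assignment = cut_tree(ward_linkage(X), k, codes=codes)
ari = adjusted_rand_score([truth.code_archetype[c] for c in codes],
                          [assignment.labels[c] for c in codes])
print(f"elbow selects k* = {k}; ARI vs planted archetypes = {ari:.2f}")

network = build_network(cohort)
intra, inter = partition_edges(network, assignment)
comparison = compare_rr_distributions(intra["RR"].to_numpy(),
                                      inter["RR"].to_numpy())
print(f"median RR: intra={np.median(intra['RR']):.2f}, "
      f"inter={np.median(inter['RR']):.2f}")
print(f"KS={comparison.ks_statistic:.3f}, "
      f"JS={comparison.js_divergence:.3f} bits")
```

prints

```
cohort: N=88822 patients, 527612 records, 180 codes
elbow selects k* = 6; ARI vs planted archetypes = 1.00
median RR: intra=3.12, inter=0.67
KS=0.626, JS=0.503 bits
```

The elbow recovers the six planted archetypes exactly (adjusted Rand
index 1.0), and comorbidity edges *inside* an age cluster carry markedly
higher relative risk (median 3.12) than edges *between* clusters (median
0.67): shared age profiles alone are enough to elevate comorbidity
coefficients.

## Command line

The same pipeline runs from a shell, end to end or stage by stage, with
plain TSV/JSON/GraphML artifacts and a digest manifest:

```sh
agedense run --config config.yaml --out results/
agedense simulate --out results/      # or stage by stage:
agedense densities --out results/
agedense cluster --out results/
agedense associate --out results/
agedense network --out results/
agedense compare --out results/
```

Chained stages reproduce the full run byte for byte.  A visit table of
your own goes in via the `input:` config key (delimited text with
patient_id, age, sex, code columns); the chapter catalog, symptom-chapter
exclusion (XVIII–XXII), minimum code frequency, fixed *k* override,
Fisher sidedness and top-*m* edge restriction are all configurable.

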