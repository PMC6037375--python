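"""Shared fixtures: tiny hand-built cohorts and independent brute-force oracles."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from agedense import Cohort, GeneratorConfig, generate_cohort


def make_cohort(rows) -> Cohort:
    """Build a cohort from (patient_id, age, sex, code) tuples."""
    df = pd.DataFrame(rows, columns=["patient_id", "age", "sex", "code"])
    df["age"] = df["age"].astype(np.int64)
    return Cohort(df)


@pytest.fixture
def tiny_cohort() -> Cohort:
    return make_cohort(
        [
            ("p1", 30, "female", "J06"),
            ("p1", 30, "female", "M54"),
            ("p2", 10, "male", "J06"),
            ("p2", 10, "male", "J06"),
            ("p3", 70, "female", "M54"),
            ("p4", 34, "male", "Z00"),
        ]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default planted cohort (6 archetypes, 30 codes each, noise 0.05,
    100 000 patients, seed 20130301), shared across recovery tests."""
    return generate_cohort(GeneratorConfig())


# ---------------------------------------------------------------------------
# Independent oracles (never call the code paths they check)


def ward_oracle(X: np.ndarray):
    """Naive Ward agglomeration recomputing within-cluster sums of squares
    from scratch at every step.  Same id scheme and tie-break as the
    implementation contract: leaves 0..n-1, merge t creates id n+t, minimal
    (cost, (left, right)) merges first."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]

    def sse(idx):
        block = X[list(idx)]
        return float(((block - block.mean(axis=0)) ** 2).sum())

    clusters = {i: (i,) for i in range(n)}
    merges = []
    for t in range(n - 1):
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if i >= j:
                    continue
                cost = sse(clusters[i] + clusters[j]) - sse(clusters[i]) - sse(clusters[j])
                key = (cost, (i, j))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (cost, _), i, j = best
        merges.append((i, j, cost, len(clusters[i]) + len(clusters[j])))
        clusters[n + t] = clusters.pop(i) + clusters.pop(j)
    return np.array(merges)


def fisher_oracle(a: int, b: int, c: int, d: int, alternative: str) -> Fraction:
    """Exact rational Fisher p-value by enumerating every table with the
    observed margins."""
    N = a + b + c + d
    K = a + c
    n = a + b
    lo, hi = max(0, n + K - N), min(n, K)
    denom = comb(N, n)
    pmf = {x: Fraction(comb(K, x) * comb(N - K, n - x), denom) for x in range(lo, hi + 1)}
    if alternative == "greater":
        return sum(p for x, p in pmf.items() if x >= a)
    obs = pmf[a]
    return sum(p for p in pmf.values() if p <= obs)


def cooccurrence_oracle(cohort: Cohort):
    """Quadratic per-patient set-intersection co-occurrence counts."""
    patient_codes: dict[str, set[str]] = {}
    for row in cohort.records.itertuples(index=False):
        patient_codes.setdefault(row.patient_id, set()).add(row.code)
    counts: dict[tuple[str, str], int] = {}
    for codes in patient_codes.values():
        ordered = sorted(codes)
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                pair = (ordered[i], ordered[j])
                counts[pair] = counts.get(pair, 0) + 1
    return counts


def random_cohort(rng: np.random.Generator, n_patients: int, codes) -> Cohort:
    """Random cohort for oracle equivalence checks; visit multiplicity included."""
    rows = []
    for p in range(n_patients):
        age = int(rng.integers(0, 100))
        sex = "female" if rng.random() < 0.5 else "male"
        for code in codes:
            if rng.random() < 0.3:
                for _ in range(int(rng.integers(1, 4))):
                    rows.append((f"p{p}", age, sex, code))
    if not rows:
        rows = [("p0", 50, "female", codes[0])]
    return make_cohort(rows)
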