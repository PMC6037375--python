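"""Cluster–chapter association via the Fisher exact test, and per-cluster
patient profiles.

The unit of the test is the diagnosis code (the clustering unit): each 2×2
table cross-classifies the chapter-mapped clustered codes by membership in
one cluster and one chapter.  Association strength is reported as
1 − p-value.  By default the alternative is one-sided enrichment
("greater"), no multiple-testing adjustment is applied, and both choices
are echoed in the output metadata; a Benjamini–Hochberg post-processor is
available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .records import Cohort, DataError, N_AGE_BINS
from .clustering import ClusterAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "build_table",
    "fisher_exact",
    "associate_all",
    "cluster_patient_profile",
    "benjamini_hochberg",
]

#: Relative slack when deciding whether a table's point probability is
#: "at most" the observed one in the two-sided sum.
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class ContingencyTable:
    """Counts [in-cluster ∧ in-chapter, in-cluster ∧ not, not ∧ in, not ∧ not]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssociationResult:
    cluster: int
    chapter: str
    p_value: float
    table: ContingencyTable

    @property
    def score(self) -> float:
        """Association strength, 1 − p."""
        return 1.0 - self.p_value


def build_table(
    assignment: ClusterAssignment,
    chapter_map: dict[str, str | None],
    cluster: int,
    chapter: str,
) -> ContingencyTable:
    """Cross-tabulate chapter-mapped clustered codes for one (cluster, chapter).

    Codes mapping to no chapter are excluded (with a logged count).
    """
    mapped = {c: ch for c, ch in chapter_map.items() if c in assignment.labels and ch}
    dropped = sum(1 for c in assignment.labels if chapter_map.get(c) is None)
    if dropped:
        logger.info("build_table: %d code(s) outside every chapter excluded", dropped)
    if cluster not in set(assignment.labels.values()):
        raise DataError(f"unknown cluster label: {cluster}")
    if chapter not in set(mapped.values()):
        raise DataError(f"no clustered code maps to chapter {chapter!r}")
    a = b = c_ = d = 0
    for code, ch in mapped.items():
        in_cl = assignment.labels[code] == cluster
        in_ch = ch == chapter
        if in_cl and in_ch:
            a += 1
        elif in_cl:
            b += 1
        elif in_ch:
            c_ += 1
        else:
            d += 1
    return ContingencyTable(a, b, c_, d)


def _hypergeom_logpmf(x: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P(X = x) for X ~ Hypergeom(N, K, n), via log factorials."""
    x = np.asarray(x)
    return (
        gammaln(K + 1) - gammaln(x + 1) - gammaln(K - x + 1)
        + gammaln(N - K + 1) - gammaln(n - x + 1) - gammaln(N - K - n + x + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def fisher_exact(table: ContingencyTable, alternative: str = "greater") -> float:
    """Exact hypergeometric tail probability for a 2×2 table, margins fixed.

    ``greater``: P(A >= a).  ``two-sided``: sum of the probabilities of all
    tables with the same margins whose point probability is at most the
    observed one (up to 1e-12 relative slack, so exact ties are included).
    Degenerate margins (a zero row or column) give p = 1.  Computed with
    log-space factorials, stable up to margins of a million.
    """
    if alternative not in ("greater", "two-sided"):
        raise DataError(f"alternative must be 'greater' or 'two-sided': {alternative!r}")
    N = table.total
    K = table.a + table.c  # chapter margin
    n = table.a + table.b  # cluster margin
    lo = max(0, n + K - N)
    hi = min(n, K)
    if lo == hi:  # degenerate: only one table possible
        return 1.0
    support = np.arange(lo, hi + 1)
    logpmf = _hypergeom_logpmf(support, N, K, n)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    obs = table.a - lo
    if alternative == "greater":
        p = pmf[obs:].sum()
    else:
        p = pmf[pmf <= pmf[obs] * (1.0 + _TIE_RTOL)].sum()
    return float(min(p, 1.0))


def associate_all(
    assignment: ClusterAssignment,
    chapter_map: dict[str, str | None],
    alternative: str = "greater",
) -> list[AssociationResult]:
    """Fisher test for every (cluster, chapter) pair, sorted by cluster then
    chapter; no multiple-testing adjustment."""
    clusters = sorted(set(assignment.labels.values()))
    chapters = sorted(
        {ch for c, ch in chapter_map.items() if c in assignment.labels and ch}
    )
    if not clusters or not chapters:
        raise DataError("need at least one cluster and one chapter")
    out = []
    for cl in clusters:
        for ch in chapters:
            t = build_table(assignment, chapter_map, cl, ch)
            out.append(AssociationResult(cl, ch, fisher_exact(t, alternative), t))
    return out


def benjamini_hochberg(results: list[AssociationResult]) -> list[float]:
    """Optional BH-adjusted q-values in the order of ``results``."""
    p = np.asarray([r.p_value for r in results])
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        q[i] = running
    return q.tolist()


def results_to_frames(
    results: list[AssociationResult], alternative: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide score matrix (clusters × chapters, cells 1−p) and a long table
    with raw p-values and cell counts; the alternative is echoed as metadata
    columns."""
    long = pd.DataFrame(
        {
            "cluster": [r.cluster for r in results],
            "chapter": [r.chapter for r in results],
            "p_value": [r.p_value for r in results],
            "score": [r.score for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "alternative": alternative,
        }
    )
    wide = long.pivot(index="cluster", columns="chapter", values="score")
    return wide, long


def cluster_patient_profile(
    cohort: Cohort, assignment: ClusterAssignment, cluster: int
) -> tuple[dict[str, float], np.ndarray]:
    """Sex proportions and 0–99 age histogram of the cluster's patients.

    The patient set is everyone with at least one record of a code in the
    cluster; a patient with codes in two clusters contributes to both
    profiles.
    """
    codes = [c for c, l in assignment.labels.items() if l == cluster]
    if not codes:
        raise DataError(f"unknown or empty cluster: {cluster}")
    rows = cohort.records[cohort.records["code"].isin(codes)]
    patients = rows["patient_id"].unique()
    if patients.size == 0:
        return {"female": 0.0, "male": 0.0}, np.zeros(N_AGE_BINS, dtype=int)
    sexes = cohort.patient_sex.loc[patients]
    ages = cohort.patient_age.loc[patients].to_numpy()
    hist = np.bincount(np.minimum(ages, N_AGE_BINS - 1), minlength=N_AGE_BINS)
    frac_f = float((sexes == "female").mean())
    return {"female": frac_f, "male": 1.0 - frac_f}, hist
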