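"""Relative-risk comorbidity networks and intra/inter-cluster comparison.

Nodes are diagnosis codes with prevalence P_i (distinct patients); an edge
between codes i and j carries the co-occurrence count C_ij (distinct
patients having both) and the relative risk

    RR_ij = C_ij · N / (P_i · P_j),

which exceeds 1 when the pair co-occurs more often than independence
predicts.  Pairs that never co-occur are not edges.  Edges are partitioned
into intra-cluster (endpoints share an age-density cluster) and
inter-cluster sets, whose RR distributions are compared with the
two-sample KS statistic and the Jensen–Shannon divergence of log10(RR)
histograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial.distance import jensenshannon
from scipy.stats import ks_2samp

from .records import Cohort, DataError
from .clustering import ClusterAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "ComorbidityNetwork",
    "RRComparison",
    "cooccurrence_counts",
    "relative_risk",
    "build_network",
    "top_edges",
    "partition_edges",
    "compare_rr_distributions",
    "compare_per_cluster",
]

#: Fixed binning rule for the JS divergence: 50 equal-width bins over the
#: pooled log10(RR) range, plus a designated underflow bin for RR = 0.
_JS_BINS = 50


def cooccurrence_counts(
    cohort: Cohort, eligible: set[str] | None = None
) -> dict[tuple[str, str], int]:
    """C_ij for every unordered pair of eligible codes with C_ij >= 1.

    C_ij is the number of distinct patients having at least one record of
    each code (set semantics; visit counts are irrelevant).
    """
    df = cohort.records[["patient_id", "code"]].drop_duplicates()
    if eligible is not None:
        df = df[df["code"].isin(eligible)]
    if df.empty:
        return {}
    codes = np.sort(df["code"].unique())
    code_ix = {c: i for i, c in enumerate(codes)}
    pat, pat_ix = np.unique(df["patient_id"].to_numpy(), return_inverse=True)
    col = df["code"].map(code_ix).to_numpy()
    M = sparse.csr_matrix(
        (np.ones(len(df), dtype=np.int64), (pat_ix, col)),
        shape=(pat.size, codes.size),
    )
    C = sparse.triu(M.T @ M, k=1).tocoo()
    return {
        (codes[i], codes[j]): int(v) for i, j, v in zip(C.row, C.col, C.data)
    }


def relative_risk(C_ij: int, N: int, P_i: int, P_j: int) -> float:
    """RR_ij = C_ij·N / (P_i·P_j)."""
    if P_i <= 0 or P_j <= 0:
        raise DataError("prevalences must be positive")
    if N < 1:
        raise DataError("N must be at least 1")
    if C_ij > min(P_i, P_j):
        raise DataError("C_ij cannot exceed min(P_i, P_j)")
    return C_ij * N / (P_i * P_j)


@dataclass
class ComorbidityNetwork:
    """Codes as nodes (prevalence P_i), RR-weighted co-occurrence edges."""

    nodes: dict[str, int]  # code -> P_i
    N: int
    edges: pd.DataFrame = field(repr=False)  # columns code_i, code_j, C, RR

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def to_networkx(self, assignment: ClusterAssignment | None = None) -> nx.Graph:
        g = nx.Graph()
        for code, p in self.nodes.items():
            attrs = {"prevalence": int(p)}
            if assignment is not None and code in assignment.labels:
                attrs["cluster"] = int(assignment.labels[code])
            g.add_node(code, **attrs)
        for r in self.edges.itertuples(index=False):
            g.add_edge(r.code_i, r.code_j, C=int(r.C), RR=float(r.RR))
        return g

    def to_edge_frame(self, assignment: ClusterAssignment | None = None) -> pd.DataFrame:
        df = self.edges.copy()
        if assignment is not None:
            li = df["code_i"].map(assignment.labels)
            lj = df["code_j"].map(assignment.labels)
            df["edge_type"] = np.where(
                li.isna() | lj.isna(), "unlabeled",
                np.where(li == lj, "intra", "inter"),
            )
        return df


def build_network(cohort: Cohort, min_prevalence: int = 1) -> ComorbidityNetwork:
    """Comorbidity network over codes with P_i >= min_prevalence."""
    counts = cohort.records.groupby("code")["patient_id"].nunique()
    nodes = {str(c): int(v) for c, v in counts.items() if v >= min_prevalence}
    N = cohort.N
    co = cooccurrence_counts(cohort, eligible=set(nodes))
    if co:
        pairs = sorted(co)
        ci = [p[0] for p in pairs]
        cj = [p[1] for p in pairs]
        C = np.array([co[p] for p in pairs], dtype=np.int64)
        Pi = np.array([nodes[c] for c in ci], dtype=np.int64)
        Pj = np.array([nodes[c] for c in cj], dtype=np.int64)
        edges = pd.DataFrame(
            {"code_i": ci, "code_j": cj, "C": C, "RR": C * N / (Pi * Pj)}
        )
    else:
        edges = pd.DataFrame(columns=["code_i", "code_j", "C", "RR"])
    return ComorbidityNetwork(nodes, N, edges)


def top_edges(network: ComorbidityNetwork, m: int = 2000) -> ComorbidityNetwork:
    """Subnetwork of the m largest-RR edges and their incident nodes.

    Ties at the cutoff go to the larger C, then the lexicographically
    smaller code pair.
    """
    if m < 1:
        raise DataError("m must be >= 1")
    df = network.edges.sort_values(
        ["RR", "C", "code_i", "code_j"], ascending=[False, False, True, True]
    ).head(m)
    df = df.reset_index(drop=True)
    keep = set(df["code_i"]) | set(df["code_j"])
    return ComorbidityNetwork(
        {c: p for c, p in network.nodes.items() if c in keep}, network.N, df
    )


def partition_edges(
    network: ComorbidityNetwork, assignment: ClusterAssignment
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split edges into (intra, inter) by cluster labels of the endpoints.

    Edges touching an unlabeled node are dropped with a logged count.
    """
    df = network.edges
    li = df["code_i"].map(assignment.labels)
    lj = df["code_j"].map(assignment.labels)
    labeled = li.notna() & lj.notna()
    n_drop = int((~labeled).sum())
    if n_drop:
        logger.info("partition_edges: dropping %d edge(s) with unlabeled endpoints", n_drop)
    intra = df[labeled & (li == lj)].reset_index(drop=True)
    inter = df[labeled & (li != lj)].reset_index(drop=True)
    return intra, inter


@dataclass(frozen=True)
class RRComparison:
    """Divergence between the intra- and inter-cluster RR distributions."""

    intra: np.ndarray
    inter: np.ndarray
    ks_statistic: float
    ks_pvalue: float
    js_divergence: float  # bits


def _log_histogram(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Histogram of log10 values over _JS_BINS shared bins + underflow bin."""
    h = np.zeros(_JS_BINS + 1)
    zero = values <= 0
    h[0] = zero.sum()
    logs = np.log10(values[~zero])
    if hi <= lo:
        hi = lo + 1e-12
    idx = np.clip(((logs - lo) / (hi - lo) * _JS_BINS).astype(int), 0, _JS_BINS - 1)
    np.add.at(h, idx + 1, 1)
    return h / h.sum()


def compare_rr_distributions(intra, inter) -> RRComparison:
    """Two-sample KS statistic on raw RR values and base-2 Jensen–Shannon
    divergence between log10(RR) histograms over shared bins.

    The binning rule is fixed: 50 equal-width bins spanning the pooled
    positive log range, with RR = 0 values (never produced by observed
    edges, but accepted) in a designated underflow bin.
    """
    intra = np.asarray(intra, dtype=float)
    inter = np.asarray(inter, dtype=float)
    if intra.size == 0 or inter.size == 0:
        raise DataError("both edge sets must be non-empty")
    ks = ks_2samp(intra, inter, alternative="two-sided", method="asymp")
    pooled = np.concatenate([intra, inter])
    pos = pooled[pooled > 0]
    lo, hi = (np.log10(pos.min()), np.log10(pos.max())) if pos.size else (0.0, 1.0)
    p = _log_histogram(intra, lo, hi)
    q = _log_histogram(inter, lo, hi)
    js = float(jensenshannon(p, q, base=2) ** 2)
    return RRComparison(intra, inter, float(ks.statistic), float(ks.pvalue), js)


def compare_per_cluster(
    network: ComorbidityNetwork, assignment: ClusterAssignment
) -> dict[int, RRComparison]:
    """One comparison per cluster: that cluster's intra edges vs all inter
    edges (the per-panel view of the intra/inter contrast)."""
    intra, inter = partition_edges(network, assignment)
    if inter.empty:
        raise DataError("no inter-cluster edges")
    li = intra["code_i"].map(assignment.labels)
    out: dict[int, RRComparison] = {}
    for cl in sorted(set(assignment.labels.values())):
        vals = intra[li == cl]["RR"].to_numpy()
        if vals.size:
            out[cl] = compare_rr_distributions(vals, inter["RR"].to_numpy())
    return out
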