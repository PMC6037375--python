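"""Per-code age-density vectors: p(age | patient carries code), ages 0–99.

Each retained diagnosis code is represented by a length-100 probability
vector whose i-th entry is the fraction of the code's distinct patients who
are i years old.  A patient with many visits for the same code counts once
(set semantics), so the vectors are invariant to visit multiplicity.  Ages
of 100 and above are clamped into the last bin rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import Cohort, DataError, N_AGE_BINS

__all__ = [
    "CodeAgeDensity",
    "compute_density",
    "compute_all_densities",
    "cumulative_density",
    "kde_smooth",
    "densities_to_frame",
    "frame_to_densities",
]


@dataclass(frozen=True)
class CodeAgeDensity:
    """Age distribution of the distinct patients carrying one code."""

    code: str
    p: np.ndarray
    n_patients: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.shape != (N_AGE_BINS,):
            raise DataError(f"{self.code}: density must have {N_AGE_BINS} entries")
        if (p < 0).any():
            raise DataError(f"{self.code}: negative density entries")
        if self.n_patients >= 1 and abs(p.sum() - 1.0) > 1e-9:
            raise DataError(f"{self.code}: density sums to {p.sum()}, not 1")


def _patient_ages(cohort: Cohort, code: str) -> np.ndarray:
    rows = cohort.records[cohort.records["code"] == code]
    ages = rows.drop_duplicates("patient_id")["age"].to_numpy()
    return np.minimum(ages, N_AGE_BINS - 1)


def compute_density(cohort: Cohort, code: str) -> CodeAgeDensity:
    """Empirical age density of one code over its distinct patients."""
    ages = _patient_ages(cohort, code)
    if ages.size == 0:
        raise DataError(f"no patients carry code {code!r}")
    counts = np.bincount(ages, minlength=N_AGE_BINS).astype(float)
    return CodeAgeDensity(code, counts / ages.size, int(ages.size))


def compute_all_densities(cohort: Cohort, min_patients: int = 100) -> list[CodeAgeDensity]:
    """One density per code carried by at least ``min_patients`` distinct
    patients, in lexicographic code order.

    The threshold exists because rare codes give noisy 100-bin estimates;
    the default of 100 patients keeps per-bin sampling error moderate while
    retaining the bulk of the record mass in a heavy-tailed code-frequency
    distribution.
    """
    if cohort.n_records == 0:
        return []
    dedup = cohort.records.drop_duplicates(["code", "patient_id"])
    out = []
    for code, grp in dedup.groupby("code", sort=True):
        if len(grp) < min_patients:
            continue
        ages = np.minimum(grp["age"].to_numpy(), N_AGE_BINS - 1)
        counts = np.bincount(ages, minlength=N_AGE_BINS).astype(float)
        out.append(CodeAgeDensity(str(code), counts / len(grp), int(len(grp))))
    return out


def cumulative_density(d: CodeAgeDensity) -> np.ndarray:
    """Running sum of the density; non-decreasing, ends at 1."""
    return np.cumsum(d.p)


def _silverman_bandwidth(d: CodeAgeDensity) -> float:
    """Silverman's rule on the sample implied by the discrete density."""
    ages = np.arange(N_AGE_BINS)
    mean = float(ages @ d.p)
    sd = float(np.sqrt(((ages - mean) ** 2) @ d.p))
    cdf = np.cumsum(d.p)
    q25, q75 = (int(np.searchsorted(cdf, q)) for q in (0.25, 0.75))
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = 1.0
    return float(0.9 * spread * max(d.n_patients, 2) ** (-1 / 5))


def kde_smooth(d: CodeAgeDensity, bandwidth: float | str = "auto") -> np.ndarray:
    """Gaussian-kernel smoothing of the density on the 0–99 grid.

    Boundary handling is reflection at both edges (ages are bounded at 0
    and 99, so probability mass must not leak out); the result is
    renormalized to sum to 1.  ``bandwidth='auto'`` applies Silverman's rule
    to the sample the density implies.
    """
    if bandwidth == "auto":
        h = _silverman_bandwidth(d)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise DataError("bandwidth must be positive")
    # reflect the density about both boundaries, convolve, take the middle
    ext = np.concatenate([d.p[::-1], d.p, d.p[::-1]])
    grid = np.arange(-N_AGE_BINS, 2 * N_AGE_BINS)
    target = np.arange(N_AGE_BINS)
    kern = np.exp(-((target[:, None] - grid[None, :]) ** 2) / (2 * h * h))
    sm = kern @ ext
    total = sm.sum()
    if total <= 0:
        return d.p.copy()
    return sm / total


# ---------------------------------------------------------------------------
# Wide-matrix TSV round-trip


def densities_to_frame(densities: list[CodeAgeDensity]) -> pd.DataFrame:
    """Wide matrix: one row per code, columns n_patients and age_0..age_99."""
    df = pd.DataFrame(
        [d.p for d in densities],
        index=pd.Index([d.code for d in densities], name="code"),
        columns=[f"age_{i}" for i in range(N_AGE_BINS)],
    )
    df.insert(0, "n_patients", [d.n_patients for d in densities])
    return df


def frame_to_densities(df: pd.DataFrame) -> list[CodeAgeDensity]:
    cols = [f"age_{i}" for i in range(N_AGE_BINS)]
    return [
        CodeAgeDensity(str(code), row[cols].to_numpy(dtype=float), int(row["n_patients"]))
        for code, row in df.iterrows()
    ]


def write_densities(densities: list[CodeAgeDensity], path) -> None:
    densities_to_frame(densities).to_csv(path, sep="\t", float_format="%.17g")


def read_densities(path) -> list[CodeAgeDensity]:
    return frame_to_densities(pd.read_csv(path, sep="\t", index_col="code"))
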