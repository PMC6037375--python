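"""Patient visit records: data model, delimited-text I/O, ICD-10 chapters, filters.

The unit of raw data is one diagnosis event: a patient identifier, the
patient's age in completed years, sex, and an ICD-10 code.  Codes are
normalized to 3-character granularity at ingest (``J21.0`` -> ``J21``), the
level at which all downstream analyses operate.  A :class:`Cohort` holds the
event table together with the universe size ``N`` of distinct patients, which
is the denominator of every prevalence and relative-risk computation.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VisitRecord",
    "Cohort",
    "ChapterCatalog",
    "DataError",
    "ConfigurationError",
    "default_catalog",
    "read_visits",
    "write_visits",
    "truncate_code",
    "chapter_of",
    "exclude_chapters",
    "code_patient_counts",
    "code_frequency_cdf",
    "chapter_network",
    "population_age_summary",
]

#: Full ICD-10 lexical pattern: letter, two digits, optional ".xx" subdivision.
ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}(?:\.[A-Z0-9]{1,2})?$")
#: 3-character form only.
ICD10_3CHAR = re.compile(r"^[A-Z][0-9]{2}$")

MAX_AGE = 120
N_AGE_BINS = 100

_SEX_ALIASES = {
    "f": "female",
    "female": "female",
    "m": "male",
    "male": "male",
}


class DataError(ValueError):
    """Raised when input rows violate the record invariants in strict mode."""


class ConfigurationError(ValueError):
    """Raised for invalid options: missing columns, unknown chapter labels."""


@dataclass(frozen=True)
class VisitRecord:
    """One diagnosis event."""

    patient_id: str
    age: int
    sex: str
    code: str

    def __post_init__(self) -> None:
        if not isinstance(self.age, (int, np.integer)) or not 0 <= self.age <= MAX_AGE:
            raise DataError(f"age must be an integer in [0, {MAX_AGE}], got {self.age!r}")
        if self.sex not in ("female", "male"):
            raise DataError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not ICD10_PATTERN.match(self.code):
            raise DataError(f"not an ICD-10 code: {self.code!r}")


def truncate_code(code: str) -> str:
    """Normalize an ICD-10 code to its 3-character category (``'j21.0'`` -> ``'J21'``).

    Raises
    ------
    DataError
        If *code* does not match the ICD-10 lexical pattern.
    """
    up = str(code).strip().upper()
    if not ICD10_PATTERN.match(up):
        raise DataError(f"not an ICD-10 code: {code!r}")
    return up[:3]


# ---------------------------------------------------------------------------
# Chapter catalog


#: The 22 WHO top-level chapters as inclusive 3-character code ranges.
WHO_CHAPTER_RANGES: tuple[tuple[str, str, str], ...] = (
    ("I", "A00", "B99"),
    ("II", "C00", "D48"),
    ("III", "D50", "D89"),
    ("IV", "E00", "E90"),
    ("V", "F00", "F99"),
    ("VI", "G00", "G99"),
    ("VII", "H00", "H59"),
    ("VIII", "H60", "H95"),
    ("IX", "I00", "I99"),
    ("X", "J00", "J99"),
    ("XI", "K00", "K93"),
    ("XII", "L00", "L99"),
    ("XIII", "M00", "M99"),
    ("XIV", "N00", "N99"),
    ("XV", "O00", "O99"),
    ("XVI", "P00", "P96"),
    ("XVII", "Q00", "Q99"),
    ("XVIII", "R00", "R99"),
    ("XIX", "S00", "T98"),
    ("XX", "V01", "Y98"),
    ("XXI", "Z00", "Z99"),
    ("XXII", "U00", "U99"),
)


@dataclass(frozen=True)
class ChapterCatalog:
    """Ordered list of (chapter label, range start, range end) triples.

    Ranges are inclusive and compared lexicographically on the 3-character
    code, which is order-consistent because every code is letter + 2 digits.
    """

    entries: tuple[tuple[str, str, str], ...] = WHO_CHAPTER_RANGES

    def __post_init__(self) -> None:
        for label, lo, hi in self.entries:
            if not (ICD10_3CHAR.match(lo) and ICD10_3CHAR.match(hi)) or lo > hi:
                raise ConfigurationError(f"invalid range for chapter {label}: {lo}–{hi}")
        ordered = sorted((lo, hi, label) for label, lo, hi in self.entries)
        for (_, hi_a, lab_a), (lo_b, _, lab_b) in zip(ordered, ordered[1:]):
            if lo_b <= hi_a:
                raise ConfigurationError(f"chapters {lab_a} and {lab_b} overlap")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.entries)

    @classmethod
    def from_file(cls, path) -> "ChapterCatalog":
        """Load a catalog from a 3-column TSV: label, range start, range end."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 3:
            raise ConfigurationError("catalog file needs columns: label, start, end")
        return cls(tuple((r.iloc[0], r.iloc[1], r.iloc[2]) for _, r in df.iterrows()))


def default_catalog() -> ChapterCatalog:
    """The standard 22-chapter WHO catalog."""
    return ChapterCatalog()


def chapter_of(code: str, catalog: ChapterCatalog | None = None) -> str | None:
    """Chapter label containing a 3-character code, or None if outside all ranges."""
    catalog = catalog or default_catalog()
    code = str(code).upper()[:3]
    for label, lo, hi in catalog.entries:
        if lo <= code <= hi:
            return label
    return None


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class Cohort:
    """An event table plus the distinct-patient universe.

    ``records`` has columns patient_id (str), age (int), sex (str), code
    (3-character str).  Each patient carries exactly one age and one sex; the
    constructor enforces this (first occurrence wins in lenient ingest, a
    conflict is a hard error otherwise — see :func:`read_visits`).
    """

    records: pd.DataFrame
    patient_age: pd.Series = field(repr=False, default=None)
    patient_sex: pd.Series = field(repr=False, default=None)

    def __post_init__(self) -> None:
        required = {"patient_id", "age", "sex", "code"}
        missing = required - set(self.records.columns)
        if missing:
            raise ConfigurationError(f"records missing columns: {sorted(missing)}")
        if self.patient_age is None or self.patient_sex is None:
            firsts = self.records.drop_duplicates("patient_id")
            self.patient_age = firsts.set_index("patient_id")["age"]
            self.patient_sex = firsts.set_index("patient_id")["sex"]

    @property
    def N(self) -> int:
        """Number of distinct patients."""
        return int(self.patient_age.shape[0])

    @property
    def n_records(self) -> int:
        return int(self.records.shape[0])

    @property
    def codes(self) -> list[str]:
        return sorted(self.records["code"].unique())

    @classmethod
    def from_records(cls, rows: Iterable[VisitRecord]) -> "Cohort":
        rows = list(rows)
        df = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in rows],
                "age": np.asarray([r.age for r in rows], dtype=np.int64),
                "sex": [r.sex for r in rows],
                "code": [truncate_code(r.code) for r in rows],
            }
        )
        _check_consistency(df, strict=True)
        return cls(df)

    def iter_records(self) -> Iterable[VisitRecord]:
        for row in self.records.itertuples(index=False):
            yield VisitRecord(row.patient_id, int(row.age), row.sex, row.code)


def _check_consistency(df: pd.DataFrame, strict: bool) -> None:
    """Every patient must have a single age and sex across its rows."""
    for col in ("age", "sex"):
        nuniq = df.groupby("patient_id", sort=False)[col].nunique()
        bad = nuniq[nuniq > 1]
        if len(bad):
            if strict:
                raise DataError(
                    f"conflicting {col} for patient(s): {', '.join(map(str, bad.index[:5]))}"
                )
            logger.warning("conflicting %s for %d patient(s); keeping first occurrence",
                           col, len(bad))


def read_visits(
    path,
    *,
    sep: str | None = None,
    columns: Mapping[str, str] | None = None,
    strict: bool = True,
) -> Cohort:
    """Read a delimited visit table into a :class:`Cohort`.

    Parameters
    ----------
    path
        Delimited text file (comma or tab; gzip-transparent), UTF-8, with a
        header row.
    sep
        Field delimiter; autodetected from the header line when None.
    columns
        Optional mapping from the canonical names ``patient_id``, ``age``,
        ``sex``, ``code`` to the column names used in the file.
    strict
        In strict mode any malformed row or per-patient age/sex conflict
        aborts with :class:`DataError`; in lenient mode malformed rows are
        dropped with a logged count and the first age/sex per patient wins.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", dtype=str)
    colmap = {"patient_id": "patient_id", "age": "age", "sex": "sex", "code": "code"}
    if columns:
        colmap.update(columns)
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise ConfigurationError(f"input file missing column(s): {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})[
        ["patient_id", "age", "sex", "code"]
    ]

    if df.empty:
        df = df.assign(age=df["age"].astype(np.int64))
        return Cohort(df)

    age_num = pd.to_numeric(df["age"], errors="coerce")
    ok_age = age_num.notna() & (age_num == age_num.round()) & age_num.between(0, MAX_AGE)
    sex_norm = df["sex"].str.strip().str.lower().map(_SEX_ALIASES)
    ok_sex = sex_norm.notna()
    code_up = df["code"].str.strip().str.upper()
    ok_code = code_up.str.match(ICD10_PATTERN).fillna(False)
    ok = ok_age & ok_sex & ok_code

    n_bad = int((~ok).sum())
    if n_bad:
        if strict:
            first = df.index[~ok][0]
            raise DataError(f"{n_bad} malformed row(s); first at line {first + 2}")
        logger.warning("dropping %d malformed row(s)", n_bad)

    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"][ok],
            "age": age_num[ok].astype(np.int64),
            "sex": sex_norm[ok],
            "code": code_up[ok].str.slice(0, 3),
        }
    ).reset_index(drop=True)
    _check_consistency(out, strict=strict)
    if not strict:
        # first occurrence wins: rewrite each patient's age/sex from its first row
        firsts = out.drop_duplicates("patient_id").set_index("patient_id")
        out["age"] = out["patient_id"].map(firsts["age"]).astype(np.int64)
        out["sex"] = out["patient_id"].map(firsts["sex"])
    return Cohort(out)


def write_visits(cohort: Cohort, path, *, sep: str = "\t") -> None:
    """Write the event table back out (round-trips through :func:`read_visits`)."""
    cohort.records.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Filters and summaries


def exclude_chapters(
    cohort: Cohort,
    chapters: Iterable[str],
    catalog: ChapterCatalog | None = None,
) -> Cohort:
    """Drop all records whose code falls in any of the given chapters.

    N is recomputed over the remaining records.  An unknown chapter label is a
    :class:`ConfigurationError`.
    """
    catalog = catalog or default_catalog()
    chapters = set(chapters)
    unknown = chapters - set(catalog.labels)
    if unknown:
        raise ConfigurationError(f"unknown chapter label(s): {sorted(unknown)}")
    if not chapters:
        return Cohort(cohort.records.copy())
    code_ch = {c: chapter_of(c, catalog) for c in cohort.records["code"].unique()}
    keep = ~cohort.records["code"].map(code_ch).isin(chapters)
    return Cohort(cohort.records[keep].reset_index(drop=True))


def code_patient_counts(cohort: Cohort) -> dict[str, int]:
    """Distinct-patient count per 3-character code (the prevalence P_i)."""
    if cohort.n_records == 0:
        return {}
    counts = cohort.records.groupby("code")["patient_id"].nunique()
    return {str(c): int(v) for c, v in counts.sort_index().items()}


class _StepCDF:
    """Empirical CDF of per-code observation counts: CDF(t) = frac of codes with count <= t."""

    def __init__(self, counts: np.ndarray):
        self.counts = np.sort(np.asarray(counts))

    def __call__(self, t) -> float | np.ndarray:
        r = np.searchsorted(self.counts, t, side="right") / self.counts.size
        return float(r) if np.isscalar(t) else r


def code_frequency_cdf(cohort: Cohort) -> _StepCDF:
    """Empirical CDF of the number of observations (records) per code.

    Evaluated at a threshold t it gives the fraction of codes observed at
    most t times; this is the curve that shows how heavy-tailed code usage
    is (roughly half of all codes are rare while the common half carries
    most records).
    """
    if cohort.n_records == 0:
        raise DataError("code_frequency_cdf needs a non-empty cohort")
    return _StepCDF(cohort.records["code"].value_counts().to_numpy())


def chapter_network(cohort: Cohort, catalog: ChapterCatalog | None = None) -> nx.Graph:
    """Weighted undirected chapter co-occurrence graph.

    Node weight = number of records mapping into the chapter; edge weight
    between two chapters = number of distinct patients with at least one
    record in each.  Records whose code falls outside every chapter range are
    ignored.
    """
    catalog = catalog or default_catalog()
    code_ch = {c: chapter_of(c, catalog) for c in cohort.records["code"].unique()}
    mapped = cohort.records.assign(chapter=cohort.records["code"].map(code_ch)).dropna(
        subset=["chapter"]
    )
    g = nx.Graph()
    for ch, cnt in mapped["chapter"].value_counts().items():
        g.add_node(ch, weight=int(cnt))
    pair_counts: dict[tuple[str, str], int] = {}
    for _, chapters in mapped.groupby("patient_id", sort=False)["chapter"]:
        for a, b in itertools.combinations(sorted(set(chapters)), 2):
            pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    for (a, b), w in pair_counts.items():
        g.add_edge(a, b, weight=int(w))
    return g


def population_age_summary(cohort: Cohort) -> tuple[np.ndarray, float]:
    """Per-patient age histogram over bins 0..99 and the median patient age.

    Each distinct patient contributes once regardless of visit count; ages
    beyond 99 are clamped into bin 99 for the histogram (the median uses the
    raw ages).
    """
    if cohort.N == 0:
        raise DataError("population_age_summary needs a non-empty cohort")
    ages = cohort.patient_age.to_numpy()
    hist = np.bincount(np.minimum(ages, N_AGE_BINS - 1), minlength=N_AGE_BINS)
    return hist, float(np.median(ages))
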