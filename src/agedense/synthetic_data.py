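"""Synthetic patient cohorts with planted age-density cluster structure.

The generator emulates the statistical structure the analysis pipeline
assumes in real claims data, with known ground truth:

* a population age distribution peaked in the mid-thirties;
* diagnosis codes whose patient-age densities follow one of a small set of
  archetype shapes (infant-skewed, youth-skewed, a narrow reproductive-age
  band, uniform, senior, elderly);
* a strongly female-biased reproductive-age archetype;
* co-occurrence induced *only* through shared age profiles — two codes of
  the same archetype concentrate in the same patients because those patients
  are the right age, which is exactly the mechanism that elevates
  intra-cluster relative risk without any explicit disease–disease coupling.

Carriage is importance-weighted: a patient of age ``a`` carries a code of
archetype density ``f`` with probability proportional to ``f(a) / pop(a)``,
so the ages of the carriers are distributed exactly as ``f`` and the
empirical age density of every planted code converges to its archetype.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .records import Cohort, ConfigurationError, chapter_of, default_catalog

__all__ = [
    "ArchetypeSpec",
    "GeneratorConfig",
    "PlantedTruth",
    "default_archetypes",
    "default_population_age_density",
    "generate_cohort",
    "write_truth",
    "read_truth",
]

N_AGES = 100

#: Population age density constants: two-piece normal + uniform floor.
_POP_MODE = 34
_POP_SIGMA_LEFT = 23.0
_POP_SIGMA_RIGHT = 19.0
_POP_UNIFORM_WEIGHT = 0.10


def default_population_age_density() -> np.ndarray:
    """Discrete population age density over ages 0–99, mode 34 and median 34.

    A two-piece normal (peak at 34, wider left shoulder) mixed with a 10%
    uniform floor: unimodal, mildly left-skewed so the median coincides with
    the mode, and bounded away from zero at the oldest ages so every age is
    represented in a large cohort.
    """
    ages = np.arange(N_AGES)
    sigma = np.where(ages < _POP_MODE, _POP_SIGMA_LEFT, _POP_SIGMA_RIGHT)
    w = np.exp(-((ages - _POP_MODE) ** 2) / (2 * sigma**2))
    p = (1 - _POP_UNIFORM_WEIGHT) * w / w.sum() + _POP_UNIFORM_WEIGHT / N_AGES
    return p


@dataclass(frozen=True)
class ArchetypeSpec:
    """A planted age-density shape for a group of synthetic codes.

    Parameters
    ----------
    name
        Label used in :class:`PlantedTruth`.
    density
        Length-100 probability vector over ages 0–99.
    sex_bias
        Probability that a patient carrying this archetype's codes is
        female; 0.5 means no bias.
    chapters
        1–3 chapter labels; the archetype's synthetic codes are named from
        these chapters' code ranges so chapter–cluster association has
        signal.
    """

    name: str
    density: np.ndarray
    sex_bias: float = 0.5
    chapters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "density", d)
        if d.shape != (N_AGES,) or (d < 0).any() or abs(d.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"archetype {self.name!r}: density must be 100 non-negative entries summing to 1"
            )
        if not 0.0 <= self.sex_bias <= 1.0:
            raise ConfigurationError(f"archetype {self.name!r}: sex_bias outside [0,1]")


def _beta_density(a: float, b: float) -> np.ndarray:
    x = (np.arange(N_AGES) + 0.5) / N_AGES
    f = stats.beta.pdf(x, a, b)
    return f / f.sum()


#: Fixed Beta(a, b) shape parameters of the six default archetypes.
DEFAULT_ARCHETYPE_SHAPES: dict[str, tuple[float, float] | None] = {
    "A": (1.2, 10.0),   # infant/child-skewed
    "B": (1.8, 4.5),    # teenage years and early adulthood
    "C": (30.0, 70.0),  # narrow reproductive-age band, female-dominated
    "D": None,          # uniform across all ages
    "E": (11.0, 5.5),   # seniors, 60+
    "F": (18.0, 4.0),   # elderly, 70+
}

_DEFAULT_CHAPTERS = {
    "A": ("X", "VIII"),
    "B": ("I",),
    "C": ("XV",),
    "D": ("VII", "XI"),
    "E": ("XIII",),
    "F": ("IX", "XIV"),
}


def default_archetypes() -> list[ArchetypeSpec]:
    """The six default archetypes: infant, youth, reproductive-age (female-
    biased), uniform, senior, elderly.

    Shapes are discretized Beta densities over ages 0–99 with the fixed
    parameters in :data:`DEFAULT_ARCHETYPE_SHAPES`; archetype D is exactly
    uniform (every entry 0.01); archetype C carries a 0.95 female bias.
    """
    out = []
    for name, shape in DEFAULT_ARCHETYPE_SHAPES.items():
        density = np.full(N_AGES, 1.0 / N_AGES) if shape is None else _beta_density(*shape)
        out.append(
            ArchetypeSpec(
                name=name,
                density=density,
                sex_bias=0.95 if name == "C" else 0.5,
                chapters=_DEFAULT_CHAPTERS[name],
            )
        )
    return out


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the cohort generator; deterministic given ``seed``."""

    n_patients: int = 100_000
    codes_per_archetype: int = 30
    archetypes: Sequence[ArchetypeSpec] = field(default_factory=default_archetypes)
    base_rate: float = 0.08
    noise: float = 0.05
    population_age_density: np.ndarray = field(
        default_factory=default_population_age_density
    )
    mean_visits_per_condition: float = 2.0
    seed: int = 20130301

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.codes_per_archetype < 1:
            raise ConfigurationError("n_patients and codes_per_archetype must be positive")
        if not 0.0 < self.base_rate <= 1.0:
            raise ConfigurationError("base_rate must be in (0, 1]")
        if not 0.0 <= self.noise < 1.0:
            raise ConfigurationError("noise must be in [0, 1)")
        if self.mean_visits_per_condition < 1.0:
            raise ConfigurationError("mean_visits_per_condition must be >= 1")
        pop = np.asarray(self.population_age_density, dtype=float)
        object.__setattr__(self, "population_age_density", pop)
        if pop.shape != (N_AGES,) or (pop <= 0).any() or abs(pop.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "population_age_density must be 100 positive entries summing to 1"
            )

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth map from each generated code to its archetype name."""

    code_archetype: dict[str, str]

    def labels_for(self, codes: Sequence[str]) -> list[str]:
        return [self.code_archetype[c] for c in codes]


def _chapter_range_codes(chapter: str) -> list[str]:
    """All 3-character codes inside a chapter's range, in lexical order."""
    catalog = default_catalog()
    for label, lo, hi in catalog.entries:
        if label == chapter:
            letters = [chr(c) for c in range(ord(lo[0]), ord(hi[0]) + 1)]
            codes = [
                f"{ltr}{n:02d}" for ltr in letters for n in range(100)
            ]
            return [c for c in codes if lo <= c <= hi]
    raise ConfigurationError(f"unknown chapter label: {chapter}")


def _assign_code_names(archetypes: Sequence[ArchetypeSpec], per_arch: int) -> dict[str, list[str]]:
    """Deterministic chapter-consistent code names, round-robin over each
    archetype's designated chapters, skipping codes already taken."""
    used: set[str] = set()
    out: dict[str, list[str]] = {}
    for spec in archetypes:
        chapters = spec.chapters or ("X",)
        pools = [[c for c in _chapter_range_codes(ch)] for ch in chapters]
        cursors = [0] * len(pools)
        names: list[str] = []
        i = 0
        while len(names) < per_arch:
            pool = pools[i % len(pools)]
            cur = cursors[i % len(pools)]
            while cur < len(pool) and pool[cur] in used:
                cur += 1
            if cur < len(pool):
                names.append(pool[cur])
                used.add(pool[cur])
                cursors[i % len(pools)] = cur + 1
            i += 1
            if i > 10 * per_arch * len(pools) and len(names) < per_arch:
                raise ConfigurationError(
                    f"archetype {spec.name!r}: chapter ranges exhausted generating codes"
                )
        out[spec.name] = names
    return out


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, PlantedTruth]:
    """Generate a cohort with planted archetypal age-density structure.

    Mechanism (fixed):

    1. each patient's age is drawn from ``population_age_density``;
    2. synthetic code names are assigned round-robin to archetypes from the
       archetype's designated chapter ranges;
    3. a patient of age ``a`` carries a code of archetype density ``f`` with
       probability ``base_rate * w(a) / max(w)`` where ``w = f / pop``
       (with probability ``noise`` the uniform density stands in for ``f``),
       so carrier ages are distributed exactly as ``f``;
    4. a patient carrying at least one code of a sex-biased archetype draws
       sex from that bias (first such archetype in list order); everyone
       else draws a fair coin;
    5. each carried (patient, code) pair emits a geometric number of visit
       records with the configured mean.
    """
    if not config.archetypes:
        raise ConfigurationError("at least one archetype is required")
    rng = np.random.default_rng(config.seed)
    pop = config.population_age_density
    n = config.n_patients

    ages = rng.choice(N_AGES, size=n, p=pop)

    names = _assign_code_names(config.archetypes, config.codes_per_archetype)
    truth = {
        code: spec.name for spec in config.archetypes for code in names[spec.name]
    }

    uniform = np.full(N_AGES, 1.0 / N_AGES)
    w_unif = uniform / pop
    w_unif = w_unif / w_unif.max()

    carried: dict[str, np.ndarray] = {}
    for spec in config.archetypes:
        w = spec.density / pop
        w = w / w.max()
        p_age = config.base_rate * ((1.0 - config.noise) * w + config.noise * w_unif)
        np.clip(p_age, 0.0, 1.0, out=p_age)
        p_patient = p_age[ages]
        for code in names[spec.name]:
            carried[code] = rng.random(n) < p_patient

    # sex: first sex-biased archetype whose codes a patient carries wins
    sex_p_female = np.full(n, 0.5)
    assigned = np.zeros(n, dtype=bool)
    for spec in config.archetypes:
        if spec.sex_bias == 0.5:
            continue
        has = np.zeros(n, dtype=bool)
        for code in names[spec.name]:
            has |= carried[code]
        take = has & ~assigned
        sex_p_female[take] = spec.sex_bias
        assigned |= has
    sex = np.where(rng.random(n) < sex_p_female, "female", "male")

    pid = np.array([f"P{i:07d}" for i in range(n)])
    frames = []
    p_visit = 1.0 / config.mean_visits_per_condition
    for spec in config.archetypes:
        for code in names[spec.name]:
            idx = np.flatnonzero(carried[code])
            if idx.size == 0:
                continue
            visits = rng.geometric(p_visit, size=idx.size)
            rep = np.repeat(idx, visits)
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[rep],
                        "age": ages[rep].astype(np.int64),
                        "sex": sex[rep],
                        "code": code,
                    }
                )
            )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(
            {"patient_id": pd.Series(dtype=str), "age": pd.Series(dtype=np.int64),
             "sex": pd.Series(dtype=str), "code": pd.Series(dtype=str)}
        )
    return Cohort(df), PlantedTruth(truth)


# ---------------------------------------------------------------------------
# Plain-text I/O for ground truth and configs


def write_truth(truth: PlantedTruth, path) -> None:
    pd.DataFrame(
        sorted(truth.code_archetype.items()), columns=["code", "archetype"]
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> PlantedTruth:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return PlantedTruth(dict(zip(df["code"], df["archetype"])))


def config_to_yaml(config: GeneratorConfig, path) -> None:
    """Serialize a generator config (archetype densities included) to YAML."""
    doc = {
        "n_patients": config.n_patients,
        "codes_per_archetype": config.codes_per_archetype,
        "base_rate": config.base_rate,
        "noise": config.noise,
        "mean_visits_per_condition": config.mean_visits_per_condition,
        "seed": config.seed,
        "population_age_density": [float(x) for x in config.population_age_density],
        "archetypes": [
            {
                "name": a.name,
                "sex_bias": a.sex_bias,
                "chapters": list(a.chapters),
                "density": [float(x) for x in a.density],
            }
            for a in config.archetypes
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def config_from_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    archetypes = [
        ArchetypeSpec(
            name=a["name"],
            density=np.asarray(a["density"]),
            sex_bias=a.get("sex_bias", 0.5),
            chapters=tuple(a.get("chapters", ())),
        )
        for a in doc.pop("archetypes")
    ]
    pop = np.asarray(doc.pop("population_age_density"))
    return GeneratorConfig(archetypes=archetypes, population_age_density=pop, **doc)
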