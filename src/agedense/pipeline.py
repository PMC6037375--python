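"""Stage-wise pipeline: simulate/load -> densities -> cluster -> associate ->
network -> compare, with plain-text artifacts and a digest manifest.

Every stage reads its inputs from files in the output directory (or the
configured input table) and writes plain TSV/JSON/GraphML artifacts, so the
stages can be run one at a time and chained runs reproduce a full run
byte-for-byte.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .records import (
    Cohort,
    ConfigurationError,
    chapter_of,
    default_catalog,
    exclude_chapters,
    code_patient_counts,
    population_age_summary,
    read_visits,
    write_visits,
)
from .synthetic_data import GeneratorConfig, generate_cohort, write_truth
from .age_density import compute_all_densities, write_densities, read_densities
from .clustering import (
    ClusterAssignment,
    LinkageTree,
    cut_tree,
    elbow_select,
    summarize_dendrogram,
    total_within_distance,
    ward_linkage,
)
from .association import associate_all, cluster_patient_profile, results_to_frames
from .comorbidity import (
    ComorbidityNetwork,
    build_network,
    compare_per_cluster,
    compare_rr_distributions,
    partition_edges,
    top_edges,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_full", "STAGES"]

#: The artifact files a full run must produce (recorded in the manifest).
CORE_ARTIFACTS = (
    "densities.tsv",
    "linkage.tsv",
    "assignment.tsv",
    "elbow.tsv",
    "associations.tsv",
    "comorbidity.graphml",
    "edges.tsv",
    "comparison.json",
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class PipelineConfig:
    """Effective configuration of a full analysis run."""

    input: str | None = None            # visit table; None -> simulate
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    excluded_chapters: tuple[str, ...] = ()
    min_patients: int = 100
    k_max: int = 20
    k: int | None = None                # fixed override of the elbow choice
    depth: int = 6
    alternative: str = "greater"
    min_prevalence: int = 1
    top_m: int | None = None            # restrict the RR comparison to top-m edges
    out_dir: str = "agedense_out"
    seed: int = 20130301
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.min_patients < 0 or self.min_prevalence < 1 or self.depth < 1:
            raise ConfigurationError("min_patients, min_prevalence, depth out of range")
        if self.k is not None and not 1 <= self.k <= self.k_max:
            raise ConfigurationError(f"fixed k={self.k} outside 1..k_max={self.k_max}")
        object.__setattr__(self, "generator", replace(self.generator, seed=self.seed))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**doc.pop("generator", {}))
        doc.update({k: v for k, v in overrides.items() if v is not None})
        if "excluded_chapters" in doc and doc["excluded_chapters"] is not None:
            doc["excluded_chapters"] = tuple(doc["excluded_chapters"])
        return cls(generator=gen, **doc)

    def echo(self) -> dict:
        return {
            "input": self.input,
            "excluded_chapters": list(self.excluded_chapters),
            "min_patients": self.min_patients,
            "k_max": self.k_max,
            "k": self.k,
            "depth": self.depth,
            "alternative": self.alternative,
            "min_prevalence": self.min_prevalence,
            "top_m": self.top_m,
            "seed": self.seed,
            "generator": {
                "n_patients": self.generator.n_patients,
                "codes_per_archetype": self.generator.codes_per_archetype,
                "base_rate": self.generator.base_rate,
                "noise": self.generator.noise,
                "mean_visits_per_condition": self.generator.mean_visits_per_condition,
                "seed": self.generator.seed,
                "archetypes": [a.name for a in self.generator.archetypes],
            },
        }


def _need(out: Path, name: str) -> Path:
    p = out / name
    if not p.exists():
        raise StageError(f"missing upstream artifact: {p} (run the producing stage first)")
    return p


def _load_cohort(config: PipelineConfig, out: Path) -> Cohort:
    if config.input is not None:
        return read_visits(config.input)
    return read_visits(_need(out, "cohort.tsv"))


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: PipelineConfig, out: Path) -> None:
    if config.input is not None:
        logger.info("input table configured; simulate stage writes nothing")
        return
    cohort, truth = generate_cohort(config.generator)
    write_visits(cohort, out / "cohort.tsv")
    write_truth(truth, out / "truth.tsv")


def stage_densities(config: PipelineConfig, out: Path) -> None:
    cohort = _load_cohort(config, out)
    if config.excluded_chapters:
        cohort = exclude_chapters(cohort, config.excluded_chapters)
    hist, median = population_age_summary(cohort)
    meta = {
        "N": cohort.N,
        "n_records": cohort.n_records,
        "median_age": median,
        "age_histogram": hist.tolist(),
        "excluded_chapters": list(config.excluded_chapters),
    }
    (out / "cohort_meta.json").write_text(json.dumps(meta, indent=1))
    densities = compute_all_densities(cohort, min_patients=config.min_patients)
    if not densities:
        raise StageError(
            f"no code has at least min_patients={config.min_patients} patients"
        )
    write_densities(densities, out / "densities.tsv")


def stage_cluster(config: PipelineConfig, out: Path) -> None:
    densities = read_densities(_need(out, "densities.tsv"))
    meta = json.loads(_need(out, "cohort_meta.json").read_text())
    codes = [d.code for d in densities]
    X = np.array([d.p for d in densities])
    n = len(codes)
    tree = ward_linkage(X)
    tree.to_frame().to_csv(out / "linkage.tsv", sep="\t", index=False)

    k_max = min(config.k_max, n)
    if n >= 3 and k_max >= 3:
        k_star, curve = elbow_select(X, k_max=k_max)
    else:
        k_star = min(n, k_max)
        curve_pts = {
            k: total_within_distance(X, cut_tree(tree, k)) for k in range(1, n + 1)
        }
        from .clustering import ElbowCurve

        curve = ElbowCurve(curve_pts)
        logger.warning("too few codes for an elbow; k* forced to %d", k_star)
    curve.to_frame().to_csv(out / "elbow.tsv", sep="\t", index=False)

    k = config.k if config.k is not None else k_star
    k = min(k, n)
    assignment = cut_tree(tree, k, codes=codes)
    df = assignment.to_frame()
    df["k_selected"] = k_star
    df["k_used"] = k
    df.to_csv(out / "assignment.tsv", sep="\t", index=False)

    counts = {d.code: d.n_patients for d in densities}
    summary = summarize_dendrogram(tree, codes, counts, meta["N"], depth=config.depth)
    (out / "dendrogram.txt").write_text(summary.to_text() + "\n")
    (out / "dendrogram.nwk").write_text(summary.to_newick() + "\n")


def _read_assignment(out: Path) -> ClusterAssignment:
    df = pd.read_csv(_need(out, "assignment.tsv"), sep="\t", dtype={"code": str})
    return ClusterAssignment.from_frame(df)


def stage_associate(config: PipelineConfig, out: Path) -> None:
    assignment = _read_assignment(out)
    catalog = default_catalog()
    chapter_map = {c: chapter_of(c, catalog) for c in assignment.labels}
    results = associate_all(assignment, chapter_map, alternative=config.alternative)
    wide, long = results_to_frames(results, config.alternative)
    wide.to_csv(out / "associations.tsv", sep="\t", float_format="%.17g")
    long.to_csv(out / "associations_long.tsv", sep="\t", index=False, float_format="%.17g")

    cohort = _load_cohort(config, out)
    if config.excluded_chapters:
        cohort = exclude_chapters(cohort, config.excluded_chapters)
    profiles = {}
    for cl in sorted(set(assignment.labels.values())):
        sex, hist = cluster_patient_profile(cohort, assignment, cl)
        ages = np.repeat(np.arange(hist.size), hist)
        profiles[str(cl)] = {
            "sex": sex,
            "age_histogram": hist.tolist(),
            "median_age": float(np.median(ages)) if ages.size else None,
        }
    (out / "cluster_profiles.json").write_text(json.dumps(profiles, indent=1))


def stage_network(config: PipelineConfig, out: Path) -> None:
    cohort = _load_cohort(config, out)
    if config.excluded_chapters:
        cohort = exclude_chapters(cohort, config.excluded_chapters)
    assignment = _read_assignment(out)
    network = build_network(cohort, min_prevalence=config.min_prevalence)
    nx.write_graphml(network.to_networkx(assignment), out / "comorbidity.graphml")
    network.to_edge_frame(assignment).to_csv(
        out / "edges.tsv", sep="\t", index=False, float_format="%.17g"
    )


def stage_compare(config: PipelineConfig, out: Path) -> None:
    edges = pd.read_csv(_need(out, "edges.tsv"), sep="\t", dtype={"code_i": str, "code_j": str})
    assignment = _read_assignment(out)
    # node prevalences are not needed for edge partitioning/comparison
    nodes = dict.fromkeys(pd.concat([edges["code_i"], edges["code_j"]]).unique(), 0)
    network = ComorbidityNetwork(nodes, N=0, edges=edges)
    if config.top_m is not None:
        network = top_edges(network, m=config.top_m)
    intra, inter = partition_edges(network, assignment)
    if inter.empty:
        raise StageError("no inter-cluster edges")
    if intra.empty:
        raise StageError("no intra-cluster edges")
    overall = compare_rr_distributions(intra["RR"].to_numpy(), inter["RR"].to_numpy())
    per_cluster = compare_per_cluster(network, assignment)
    doc = {
        "n_edges_compared": int(network.n_edges),
        "top_m": config.top_m,
        "n_intra": int(intra.shape[0]),
        "n_inter": int(inter.shape[0]),
        "median_intra_rr": float(np.median(intra["RR"])),
        "median_inter_rr": float(np.median(inter["RR"])),
        "ks_statistic": overall.ks_statistic,
        "ks_pvalue": overall.ks_pvalue,
        "js_divergence_bits": overall.js_divergence,
        "per_cluster": {
            str(cl): {
                "n_intra": int(cmp.intra.size),
                "ks_statistic": cmp.ks_statistic,
                "js_divergence_bits": cmp.js_divergence,
            }
            for cl, cmp in per_cluster.items()
        },
    }
    (out / "comparison.json").write_text(json.dumps(doc, indent=1))


STAGES = {
    "simulate": stage_simulate,
    "densities": stage_densities,
    "cluster": stage_cluster,
    "associate": stage_associate,
    "network": stage_network,
    "compare": stage_compare,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_stage(name: str, config: PipelineConfig, out_dir=None) -> None:
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        STAGES[name](config, out)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_full(config: PipelineConfig, out_dir=None) -> dict:
    """Run every stage and write a manifest with config echo and artifact
    digests.  Identical config + seed gives identical digests."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    failure = None
    for name in STAGES:
        try:
            run_stage(name, config, out)
            completed.append(name)
        except StageError as exc:
            failure = str(exc)
            break
    digests = {
        name: _sha256(out / name) for name in CORE_ARTIFACTS if (out / name).exists()
    }
    manifest = {
        "version": __version__,
        "config": config.echo(),
        "stages_completed": completed,
        "failed": failure,
        "artifacts": digests,
        "complete": failure is None and len(digests) == len(CORE_ARTIFACTS),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if failure is not None:
        raise StageError(failure)
    return manifest
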