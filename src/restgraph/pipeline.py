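"""End-to-end pipeline driver.

Runs simulate -> preprocess -> connect -> graph (measures + null
normalization) -> hubs/modules -> stats on a synthetic (or on-disk)
cohort, writing every stage's outputs and a provenance log into a run
directory.  Deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .atlas import load_node_atlas
from .communities import (
    HubResult,
    Partition,
    comodule_matrix,
    group_consensus_partition,
    group_hubs,
    hub_score,
    newman_partition,
)
from .core import WeightedGraph
from .io import write_censor_mask, write_cohort, write_matrix
from .network import partial_correlation, to_weighted_graph
from .nulls import NullEnsembleConfig, normalize_measures, random_equivalent_graph
from .preprocess import PreprocessParams, preprocess_subject
from .stats import (
    ancova_interaction,
    compare_global_measures,
    comodule_group_tests,
    descriptive_group_compare,
    hub_group_tests,
    spearman_table,
)
from .synthetic import CohortConfig, generate_cohort, gothenburg_config, sendai_config

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

STAGES = ("simulate", "preprocess", "connect", "graph", "hubs", "stats")

# Symptom instruments entering the Spearman table and the distress
# covariates entering the ANCOVA, per cohort.
SYMPTOM_INSTRUMENTS = {
    "sendai": ["ibs_sss_colonic", "vsi"],
    "gothenburg": ["ibs_sss_colonic", "ibs_sss_extracolonic", "vsi"],
}
DISTRESS_INSTRUMENTS = {
    "sendai": ["stai_t", "sds"],
    "gothenburg": ["hads_total"],
}
ANCOVA_MEASURES = (
    "clustering_coefficient",
    "betweenness_centrality",
    "characteristic_path_length",
)


@dataclass
class PipelineConfig:
    cohort: str = "sendai"  # "sendai" | "gothenburg"
    seed: int = 0
    n_null: int = 1000
    clustering_family: str = "onnela"
    use_atlas: bool = True  # label nodes from the packaged 45-node atlas
    cohort_overrides: dict[str, Any] = field(default_factory=dict)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)

    def cohort_config(self) -> CohortConfig:
        factory = {"sendai": sendai_config, "gothenburg": gothenburg_config}[self.cohort]
        return factory(seed=self.seed, **self.cohort_overrides)


@dataclass
class PipelineResult:
    run_dir: Path
    manifest: pd.DataFrame
    included: list[str]
    graphs: dict[str, WeightedGraph]
    normalized: pd.DataFrame  # subject x normalized global measure
    hub_results: dict[str, HubResult]
    partitions: dict[str, Partition]
    tables: dict[str, pd.DataFrame]


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 stop_after: str = "stats") -> PipelineResult:
    """Execute the pipeline up to ``stop_after`` and write all outputs."""
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; choose from {STAGES}")
    last = STAGES.index(stop_after)
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cohort_cfg = config.cohort_config()
    provenance: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "cohort": config.cohort,
        "n_null": config.n_null,
        "clustering_family": config.clustering_family,
        "preprocess": vars(config.preprocess) | {"band": list(config.preprocess.band)},
        "stages": {},
    }

    if config.use_atlas and cohort_cfg.n_nodes == 45:
        node_labels = load_node_atlas().nodes
    else:
        node_labels = [f"node{i:02d}" for i in range(cohort_cfg.n_nodes)]

    # --- simulate ---------------------------------------------------------
    subjects, manifest = generate_cohort(cohort_cfg)
    data_dir = write_cohort(run_dir / "data", subjects, manifest, cohort_cfg, node_labels)
    provenance["stages"]["simulate"] = {
        "n_hc": cohort_cfg.n_hc, "n_ibs": cohort_cfg.n_ibs,
        "n_volumes": cohort_cfg.n_volumes, "tr": cohort_cfg.tr,
        "dir": str(data_dir),
    }
    result = PipelineResult(run_dir, manifest, [], {}, pd.DataFrame(), {}, {}, {})
    if last < STAGES.index("preprocess"):
        _write_provenance(run_dir, provenance)
        return result

    # --- preprocess -------------------------------------------------------
    t_keep = cohort_cfg.analyze_volumes or cohort_cfg.n_volumes
    cleaned = {}
    inclusion_rows = []
    for subject in subjects:
        sid = subject.record.subject_id
        ts = subject.roi_series
        if t_keep < ts.n_volumes:
            from .core import CensorMask, MotionTrace, RoiTimeSeries

            ts = RoiTimeSeries(ts.data[:t_keep], ts.tr)
            motion = MotionTrace(
                subject.motion.translations[:t_keep], subject.motion.rotations[:t_keep]
            )
            nuis = subject.nuisance[:t_keep]
        else:
            motion, nuis = subject.motion, subject.nuisance
        ts.node_labels = node_labels
        try:
            filtered, mask, report = preprocess_subject(ts, motion, nuis, config.preprocess)
        except ValueError as exc:
            raise RuntimeError(f"stage preprocess failed for {sid}: {exc}") from exc
        write_censor_mask(run_dir / "data" / f"{sid}_censor.tsv", mask)
        inclusion_rows.append({
            "subject_id": sid, "included": report.included,
            "n_censored": mask.n_censored, "reason": report.reason,
        })
        if report.included:
            cleaned[sid] = filtered
    inclusion = pd.DataFrame(inclusion_rows).set_index("subject_id")
    inclusion.to_csv(run_dir / "inclusion.tsv", sep="\t")
    if not cleaned:
        raise RuntimeError(
            "stage preprocess: no subject passed the inclusion rule "
            f"(first reason: {inclusion_rows[0]['reason']})"
        )
    result.included = list(cleaned)
    provenance["stages"]["preprocess"] = {
        "n_included": len(cleaned), "n_excluded": len(subjects) - len(cleaned),
    }
    if last < STAGES.index("connect"):
        _write_provenance(run_dir, provenance)
        return result

    # --- connect ----------------------------------------------------------
    estimators = {}
    for sid, ts in cleaned.items():
        try:
            conn = partial_correlation(ts)
        except ValueError as exc:
            raise RuntimeError(f"stage connect failed for {sid}: {exc}") from exc
        estimators[sid] = conn.estimator
        graph = to_weighted_graph(conn)
        result.graphs[sid] = graph
        write_matrix(run_dir / "data" / f"{sid}_weights.tsv", graph.weights, node_labels)
    provenance["stages"]["connect"] = {"estimator_per_subject": estimators}
    if last < STAGES.index("graph"):
        _write_provenance(run_dir, provenance)
        return result

    # --- graph measures + null normalization ------------------------------
    tidy_rows = []
    normalized_rows = {}
    for index, (sid, graph) in enumerate(result.graphs.items()):
        null_seed = np.random.SeedSequence(entropy=config.seed, spawn_key=(1, index))
        mset = normalize_measures(
            graph,
            NullEnsembleConfig(
                n_null=config.n_null,
                seed=int(null_seed.generate_state(1)[0] % (2**31)),
            ),
            config.clustering_family,
        )
        normalized_rows[sid] = dict(mset.normalized)
        for name, value in mset.global_measures.items():
            tidy_rows.append({
                "subject": sid, "measure": name, "scope": "global", "node": "",
                "raw_value": value, "normalized_value": mset.normalized[name],
            })
        for node, row in mset.nodal.iterrows():
            for name, value in row.items():
                tidy_rows.append({
                    "subject": sid, "measure": name, "scope": "nodal", "node": node,
                    "raw_value": value, "normalized_value": np.nan,
                })
    result.normalized = pd.DataFrame(normalized_rows).T
    result.normalized.index.name = "subject_id"
    pd.DataFrame(tidy_rows).to_csv(run_dir / "measures.tsv", sep="\t", index=False)
    result.normalized.to_csv(run_dir / "normalized_measures.tsv", sep="\t")
    provenance["stages"]["graph"] = {"n_null": config.n_null, "aggregate": "mean"}
    if last < STAGES.index("hubs"):
        _write_provenance(run_dir, provenance)
        return result

    # --- hubs and modules -------------------------------------------------
    groups = result.manifest.loc[result.included, "group"]
    null_hub_results = {}
    for index, (sid, graph) in enumerate(result.graphs.items()):
        result.hub_results[sid] = hub_score(graph)
        null_seed = np.random.SeedSequence(entropy=config.seed, spawn_key=(2, index))
        null_graph = random_equivalent_graph(graph, np.random.default_rng(null_seed))
        null_hub_results[sid] = hub_score(null_graph)
        result.partitions[sid] = newman_partition(graph)
    hub_flags = pd.DataFrame(
        {sid: hr.is_hub for sid, hr in result.hub_results.items()},
        index=node_labels,
    ).T
    hub_flags.to_csv(run_dir / "hub_flags.tsv", sep="\t")
    group_hub_table = group_hubs(result.hub_results, null_hub_results, groups.to_dict())
    group_hub_table.to_csv(run_dir / "group_hubs.tsv", sep="\t")
    result.tables["group_hubs"] = group_hub_table
    comembership = comodule_matrix(result.partitions, groups.to_dict())
    for grp, mat in comembership.items():
        write_matrix(run_dir / f"comodule_{grp}.tsv", mat, node_labels)
    consensus = {}
    for grp in sorted(set(groups)):
        members = [result.graphs[sid] for sid in result.included if groups[sid] == grp]
        consensus[grp] = group_consensus_partition(members)
        pd.DataFrame({
            "node": node_labels, "module": consensus[grp].module_of,
        }).to_csv(run_dir / f"consensus_partition_{grp}.tsv", sep="\t", index=False)
    provenance["stages"]["hubs"] = {
        "n_modules": {g: p.n_modules for g, p in consensus.items()},
        "q": {g: p.q for g, p in consensus.items()},
    }
    if last < STAGES.index("stats"):
        _write_provenance(run_dir, provenance)
        return result

    # --- statistics -------------------------------------------------------
    manifest_included = result.manifest.loc[result.included]
    if groups.nunique() < 2:
        raise RuntimeError("stage stats requires both groups after inclusion")
    tables = result.tables
    tables["descriptives"] = descriptive_group_compare(manifest_included)
    tables["global_measures"] = compare_global_measures(result.normalized, groups)
    tables["hub_tests"] = hub_group_tests(hub_flags, groups)
    tables["comodule_tests"] = comodule_group_tests(
        comembership,
        {g: int((groups == g).sum()) for g in ("HC", "IBS")},
        node_labels,
    )
    tables["spearman"] = spearman_table(
        manifest_included, result.normalized, SYMPTOM_INSTRUMENTS[config.cohort]
    )
    ancova_rows = []
    for instrument in DISTRESS_INSTRUMENTS[config.cohort]:
        for measure in ANCOVA_MEASURES:
            res = ancova_interaction(
                result.normalized[measure].to_numpy(),
                groups.to_numpy(),
                manifest_included[instrument].to_numpy(),
            )
            for term, row in res.terms.iterrows():
                ancova_rows.append({
                    "covariate": instrument, "measure": measure, "term": term,
                    "F": row["F"], "df_num": row["df_num"], "df_den": row["df_den"],
                    "p_raw": row["p_raw"],
                    "r_HC": res.slopes.loc["HC", "r"], "r_IBS": res.slopes.loc["IBS", "r"],
                })
    tables["ancova"] = pd.DataFrame(ancova_rows)
    for name, frame in tables.items():
        frame.to_csv(run_dir / f"stats_{name}.tsv", sep="\t")
    provenance["stages"]["stats"] = {"tables": sorted(tables)}
    _write_provenance(run_dir, provenance)
    return result


def _write_provenance(run_dir: Path, provenance: dict[str, Any]) -> None:
    (run_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
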