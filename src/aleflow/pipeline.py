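"""End-to-end pipeline: load → filter/consolidate → map → DAG → enrich →
key mutations → associate, plus per-experiment summary reports.

Every numeric output is fully determined by the run configuration (inputs,
seeds, iterations); a manifest recording these is written beside the
reports so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
import platform
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .annotations import SCALES, AnnotationFramework, load_framework
from .association import (
    associate_all,
    associations_to_frame,
    read_conditions,
)
from .enrichment import (
    EnrichmentResult,
    identify_key_mutations,
    key_mutation_proportions,
    run_enrichment_all_scales,
)
from .errors import ConfigurationError
from .mapping import (
    MutatedFeatureInstance,
    build_convergence_dag,
    export_flow_table,
    instances_to_frame,
    propagate_to_scales,
)
from .mutations import (
    ConsolidatedMutation,
    consolidated_to_frame,
    prepare_mutations,
    read_mutations,
)


@dataclass
class RunConfig:
    """All knobs of one analysis run."""

    annotation_paths: Dict[str, str]
    genome_length: int
    mutation_paths: List[str]
    condition_path: Optional[str] = None
    output_dir: str = "aleflow_out"
    iterations: int = 10_000
    seed: int = 42
    enrichment_alpha: float = 0.05
    association_alpha: float = 0.01
    frequency_threshold: float = 0.5
    scales: Tuple[str, ...] = SCALES

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        for name, value in (
            ("enrichment_alpha", self.enrichment_alpha),
            ("association_alpha", self.association_alpha),
            ("frequency_threshold", self.frequency_threshold),
        ):
            if not (0 < value <= 1):
                raise ConfigurationError(f"{name} must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if "scales" in data:
            data["scales"] = tuple(data["scales"])
        return cls(**data)


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run."""

    consolidated: pd.DataFrame
    instances: pd.DataFrame
    enrichment: pd.DataFrame
    key_mutations: pd.DataFrame
    key_proportions: pd.DataFrame
    associations: pd.DataFrame
    summary: pd.DataFrame
    flows: Dict[str, Tuple[pd.DataFrame, pd.DataFrame]]
    enrichment_results: Dict[str, Dict[str, EnrichmentResult]]


def summarize_experiments(
    mutations: Sequence[ConsolidatedMutation],
    instances: Sequence[MutatedFeatureInstance],
    scales: Sequence[str] = SCALES,
) -> pd.DataFrame:
    """Per-experiment mutation and mutated-feature summary statistics.

    Columns: consolidated mutation count, unique mutation count (distinct
    (position, span, type) across ALEs), mutated feature count per scale,
    and single- vs multi-feature mutation counts at the genomic_feature
    scale. A final ``median`` row gives cross-experiment medians.
    """
    experiments = sorted({m.experiment_id for m in mutations})
    per_mut_features: Dict[Tuple, int] = {}
    for inst in instances:
        if inst.annotation_type == "genomic_feature":
            per_mut_features[inst.mutation_key] = (
                per_mut_features.get(inst.mutation_key, 0) + 1
            )
    rows = []
    for exp in experiments:
        ms = [m for m in mutations if m.experiment_id == exp]
        unique = {(m.position, m.span, m.mutation_type) for m in ms}
        row: Dict[str, float] = {
            "experiment_id": exp,
            "mutations": len(ms),
            "unique_mutations": len(unique),
        }
        for scale in scales:
            feats = {
                i.feature_id
                for i in instances
                if i.annotation_type == scale and i.mutation_key[0] == exp
            }
            row[f"mutated_{scale}"] = len(feats)
        counts = [per_mut_features.get(m.key, 0) for m in ms]
        row["single_feature_mutations"] = sum(1 for c in counts if c == 1)
        row["multi_feature_mutations"] = sum(1 for c in counts if c > 1)
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        med = df.drop(columns="experiment_id").median()
        med["experiment_id"] = "median"
        df = pd.concat([df, med.to_frame().T[df.columns]], ignore_index=True)
    return df


def run_pipeline(config: RunConfig, write: bool = True) -> ReportBundle:
    """Execute every stage and (optionally) write the report bundle."""
    fw = load_framework(config.annotation_paths, config.genome_length)

    records = []
    for path in config.mutation_paths:
        if not os.path.exists(path):
            raise FileNotFoundError(f"mutation file not found: {path}")
        records.extend(read_mutations(path))
    mutations = prepare_mutations(records, config.frequency_threshold)

    instances = propagate_to_scales([], fw, mutations)
    inst_df = instances_to_frame(instances)

    experiments = sorted({m.experiment_id for m in mutations})
    enr_frames = []
    key_frames = []
    flows: Dict[str, Tuple[pd.DataFrame, pd.DataFrame]] = {}
    enrichment_results: Dict[str, Dict[str, EnrichmentResult]] = {}
    prop_frames = []
    for k, exp in enumerate(experiments):
        exp_muts = [m for m in mutations if m.experiment_id == exp]
        exp_inst = [i for i in instances if i.mutation_key[0] == exp]
        results = run_enrichment_all_scales(
            fw,
            exp_inst,
            n_mutations=len(exp_muts),
            scales=config.scales,
            iterations=config.iterations,
            seed=config.seed + 1000 * k,
            alpha=config.enrichment_alpha,
        )
        enrichment_results[exp] = results
        for scale, res in results.items():
            t = res.table.copy()
            t.insert(0, "scale", scale)
            t.insert(0, "experiment_id", exp)
            enr_frames.append(t)
        kms = identify_key_mutations(exp_inst, results, exp)
        key_frames.append(kms.to_frame())
        prop_frames.append(key_mutation_proportions(exp_inst, results))
        dag = build_convergence_dag(exp_muts, fw)
        significant = {s: r.significant_features for s, r in results.items()}
        flows[exp] = export_flow_table(dag, significant=significant)

    enrichment_df = (
        pd.concat(enr_frames, ignore_index=True) if enr_frames else pd.DataFrame()
    )
    key_df = (
        pd.concat(key_frames, ignore_index=True) if key_frames else pd.DataFrame()
    )
    prop_df = (
        pd.concat(prop_frames, ignore_index=True) if prop_frames else pd.DataFrame()
    )

    if config.condition_path:
        conditions = read_conditions(config.condition_path)
        all_ales = sorted({(m.experiment_id, m.ale_id) for m in mutations})
        assoc = associate_all(
            instances, conditions, all_ales, alpha=config.association_alpha
        )
        assoc_df = associations_to_frame(assoc)
    else:
        assoc_df = pd.DataFrame()

    summary = summarize_experiments(mutations, instances, config.scales)
    bundle = ReportBundle(
        consolidated=consolidated_to_frame(mutations),
        instances=inst_df,
        enrichment=enrichment_df,
        key_mutations=key_df,
        key_proportions=prop_df,
        associations=assoc_df,
        summary=summary,
        flows=flows,
        enrichment_results=enrichment_results,
    )
    if write:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: ReportBundle, config: RunConfig) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    bundle.consolidated.to_csv(
        os.path.join(out, "consolidated_mutations.tsv"), sep="\t", index=False
    )
    bundle.instances.to_csv(
        os.path.join(out, "mutated_feature_instances.tsv"), sep="\t", index=False
    )
    bundle.enrichment.to_csv(
        os.path.join(out, "enrichment.tsv"), sep="\t", index=False
    )
    bundle.key_mutations.to_csv(
        os.path.join(out, "key_mutations.tsv"), sep="\t", index=False
    )
    bundle.key_proportions.to_csv(
        os.path.join(out, "key_mutation_proportions.tsv"), sep="\t", index=False
    )
    bundle.associations.to_csv(
        os.path.join(out, "associations.tsv"), sep="\t", index=False
    )
    bundle.summary.to_csv(os.path.join(out, "summary.tsv"), sep="\t", index=False)
    for exp, (flows_df, nodes_df) in bundle.flows.items():
        flows_df.to_csv(os.path.join(out, f"flows_{exp}.tsv"), sep="\t", index=False)
        nodes_df.to_csv(os.path.join(out, f"nodes_{exp}.tsv"), sep="\t", index=False)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "aleflow_version": __version__,
        "python_version": platform.python_version(),
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
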