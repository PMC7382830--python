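"""Shared fixtures: a hand-built toy annotation framework and a cached set
of planted-signal recovery runs reused by several convergence tests."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import pytest
from hypothesis import settings

import aleflow as af

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from aleflow.annotations import (
    AnnotationFramework,
    FunctionalAnnotation,
    GenomicFeature,
    Operon,
    TranscriptionUnit,
    derive_intergenic_regions,
)


def make_toy_framework() -> AnnotationFramework:
    """1 kb genome, 3 genes on 3 TUs/operons, one promoter driving two TUs,
    a TFBS inside gene gA, and regulon/pathway/COG annotations."""
    features = {
        "gA": GenomicFeature("gA", "gene", 100, 300, "+"),
        "gB": GenomicFeature("gB", "gene", 350, 550, "+"),
        "gC": GenomicFeature("gC", "gene", 600, 900, "-"),
        "tf1": GenomicFeature("tf1", "TFBS", 150, 170),
        "pX": GenomicFeature("pX", "promoter", 60, 100),
        "rbsB": GenomicFeature("rbsB", "RBS", 340, 350),
    }
    tus = {
        "tu1": TranscriptionUnit("tu1", 60, 320, ("gA",), ("pX", "tf1")),
        "tu2": TranscriptionUnit("tu2", 330, 560, ("gB",), ("pX", "rbsB")),
        "tu3": TranscriptionUnit("tu3", 580, 920, ("gC",)),
    }
    operons = {
        "o1": Operon("o1", ("tu1",)),
        "o2": Operon("o2", ("tu2",)),
        "o3": Operon("o3", ("tu3",)),
    }
    functional = {
        "R1": FunctionalAnnotation("R1", "regulon", ("gA", "gB")),
        "P1": FunctionalAnnotation("P1", "pathway", ("gB",)),
        "C1": FunctionalAnnotation("C1", "COG", ("gA", "gC")),
    }
    fw = AnnotationFramework(
        genome_length=1000,
        features=features,
        tus=tus,
        operons=operons,
        functional=functional,
    )
    return derive_intergenic_regions(fw)


@pytest.fixture
def toy_framework() -> AnnotationFramework:
    return make_toy_framework()


def make_mutation(
    position: int,
    span: int = 1,
    mutation_type: str = "SNP",
    experiment_id: str = "exp01",
    ale_id: str = "ale01",
) -> af.ConsolidatedMutation:
    return af.ConsolidatedMutation(
        experiment_id=experiment_id,
        ale_id=ale_id,
        position=position,
        span=span,
        mutation_type=mutation_type,
        representative_frequency=1.0,
    )


@dataclass
class RecoveryRun:
    """One planted-signal simulation with its full analysis results."""

    seed: int
    framework: AnnotationFramework
    instances: list
    results: Dict[str, af.EnrichmentResult]
    truth: "object"
    planted_keys: set
    planted_targets: set
    n_mutations: int


def _run_recovery(seed: int) -> RecoveryRun:
    scenario = af.default_recovery_scenario(seed=seed)
    fw, records, _, truth = af.simulate_cohort(scenario)
    muts = af.prepare_mutations(records)
    instances = af.propagate_to_scales([], fw, muts)
    results = af.run_enrichment_all_scales(
        fw, instances, n_mutations=len(muts), seed=seed
    )
    planted = truth.loc[truth["planted"]]
    planted_keys = set(
        map(
            tuple,
            planted[
                ["experiment_id", "ale_id", "position", "span", "mutation_type"]
            ].itertuples(index=False),
        )
    )
    planted_targets = {tuple(t.split(":", 1)) for t in set(planted["target"])}
    return RecoveryRun(
        seed=seed,
        framework=fw,
        instances=instances,
        results=results,
        truth=truth,
        planted_keys=planted_keys,
        planted_targets=planted_targets,
        n_mutations=len(muts),
    )


@pytest.fixture(scope="session")
def recovery_runs() -> List[RecoveryRun]:
    """Twenty planted-signal runs (seeds 0..19), shared across tests."""
    return [_run_recovery(seed) for seed in range(20)]
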