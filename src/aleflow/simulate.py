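"""Synthetic annotation frameworks, ALE mutation sets and condition tables
with known planted structure.

The generator emulates the anatomy of a bacterial ALE mutation study at
desk scale: a single circular-free (linear) chromosome of ~50 kb carrying
non-overlapping genes grouped into transcription units and operons, small
regulatory features (promoters, terminators, TFBS, RBS,
attenuator-terminators) placed in and around TU spans — some deliberately
overlapping coding sequence to exercise overlap semantics — and gene-set
functional annotations (regulons over whole TUs; pathways and COGs over
gene subsets, so the length-exclusion rule is exercised).

Background mutations are placed uniformly per nucleotide, matching the
enrichment null exactly, so calibration tests are self-consistent. Planted
targets add mutations uniformly within a chosen feature's nucleotide
extent across replicate ALEs, creating the convergence signal the
enrichment stage must recover; plants may be linked to a condition label,
in which case they occur only in ALEs of experiments carrying that label.

Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotations import (
    AnnotationFramework,
    FunctionalAnnotation,
    GenomicFeature,
    Operon,
    TranscriptionUnit,
    derive_intergenic_regions,
)
from .errors import ConfigurationError
from .mutations import MutationRecord


@dataclass(frozen=True)
class PlantedTarget:
    """A feature to load with convergent mutations.

    ``feature_id=None`` lets the generator pick a suitable feature of the
    given scale. ``condition`` restricts the plant to ALEs of experiments
    carrying that (condition_type, label).
    """

    scale: str
    feature_id: Optional[str] = None
    feature_type: Optional[str] = None  # hint for auto-pick at genomic_feature scale
    mutations_per_ale: int = 2
    n_ales: Optional[int] = None  # None = every ALE
    condition: Optional[Tuple[str, str]] = None


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic cohort."""

    genome_length: int = 50_000
    n_genes: int = 40
    gene_length_range: Tuple[int, int] = (600, 1400)
    min_gap: int = 50
    genes_per_tu: Tuple[int, int] = (1, 3)
    tus_per_operon: Tuple[int, int] = (1, 2)
    n_regulons: int = 6
    tus_per_regulon: Tuple[int, int] = (2, 3)
    n_pathways: int = 5
    genes_per_pathway: Tuple[int, int] = (2, 4)
    n_cogs: int = 8
    genes_per_cog: Tuple[int, int] = (2, 4)
    promoter_length: int = 40
    terminator_length: int = 30
    rbs_length: int = 12
    rbs_fraction: float = 0.5
    n_tfbs: int = 12
    tfbs_length: int = 20
    n_attenuators: int = 4
    attenuator_length: int = 25
    n_experiments: int = 1
    n_ales: int = 8
    background_mean: float = 2.0
    mutation_type_probs: Dict[str, float] = field(
        default_factory=lambda: {"SNP": 0.80, "DEL": 0.10, "INS": 0.05, "MOB": 0.05}
    )
    indel_span_range: Tuple[int, int] = (1, 10)
    condition_types: Dict[str, List[str]] = field(
        default_factory=lambda: {
            "carbon-source": ["glucose", "glycerol"],
            "strain": ["wild-type", "engineered"],
            "temperature": ["37C", "42C"],
        }
    )
    plants: List[PlantedTarget] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_genes < 0 or self.n_ales < 0:
            raise ConfigurationError("counts and lengths must be non-negative")
        if self.background_mean < 0:
            raise ConfigurationError("background_mean must be >= 0")


def _rng(scenario: SimulationScenario, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(scenario.seed) % (2**31), stream])
    )


def generate_framework(scenario: SimulationScenario) -> AnnotationFramework:
    """Deterministically generate the nested annotation set for a scenario."""
    rng = _rng(scenario, 0)
    n = scenario.n_genes
    lo, hi = scenario.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    slack = scenario.genome_length - int(lengths.sum()) - scenario.min_gap * (n + 1)
    if slack < 0:
        raise ConfigurationError(
            f"cannot pack {n} genes of {lo}-{hi} nt plus {scenario.min_gap} nt "
            f"gaps into a {scenario.genome_length} nt genome"
        )
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1))) if slack else (
        np.zeros(n + 1, dtype=int)
    )
    gaps = scenario.min_gap + extra

    features: Dict[str, GenomicFeature] = {}
    genes: List[GenomicFeature] = []
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        g = GenomicFeature(
            id=f"g{i+1:03d}",
            feature_type="gene",
            start=pos,
            end=pos + int(lengths[i]),
            strand="+" if rng.random() < 0.5 else "-",
        )
        genes.append(g)
        features[g.id] = g
        pos = g.end

    # transcription units over consecutive genes, with short UTR extensions
    tus: Dict[str, TranscriptionUnit] = {}
    tu_list: List[TranscriptionUnit] = []
    i = 0
    while i < n:
        size = int(rng.integers(scenario.genes_per_tu[0], scenario.genes_per_tu[1] + 1))
        members = genes[i : i + size]
        start = max(0, members[0].start - int(rng.integers(20, 61)))
        end = min(scenario.genome_length, members[-1].end + int(rng.integers(20, 61)))
        tu = TranscriptionUnit(
            id=f"tu{len(tu_list)+1:03d}",
            start=start,
            end=end,
            gene_ids=tuple(g.id for g in members),
        )
        tu_list.append(tu)
        i += size

    # regulatory features, attached to their TUs
    reg_ids: Dict[str, List[str]] = {tu.id: [] for tu in tu_list}

    def _add(feature: GenomicFeature, tu_ids: Sequence[str]) -> None:
        features[feature.id] = feature
        for tid in tu_ids:
            reg_ids[tid].append(feature.id)

    for k, tu in enumerate(tu_list):
        pstart = tu.start
        pend = min(pstart + scenario.promoter_length, scenario.genome_length)
        # every fourth promoter also drives the following TU, so one small
        # feature can regulate more than one operon
        targets = [tu.id]
        if k % 4 == 3 and k + 1 < len(tu_list):
            targets.append(tu_list[k + 1].id)
        _add(GenomicFeature(f"p_{tu.id}", "promoter", pstart, pend), targets)
        tstart = max(tu.end - scenario.terminator_length, 0)
        _add(GenomicFeature(f"t_{tu.id}", "terminator", tstart, tu.end), [tu.id])

    gene_tu = {g: tu.id for tu in tu_list for g in tu.gene_ids}
    for j, g in enumerate(genes):
        if rng.random() < scenario.rbs_fraction and g.start >= scenario.rbs_length:
            _add(
                GenomicFeature(
                    f"rbs_{g.id}", "RBS", g.start - scenario.rbs_length, g.start
                ),
                [gene_tu[g.id]],
            )

    for t in range(scenario.n_tfbs):
        if n == 0:
            break
        gi = int(rng.integers(0, n))
        host = genes[gi]
        if t % 2 == 0 and host.length > scenario.tfbs_length:
            # inside a coding sequence (overlapping-feature semantics)
            s = int(rng.integers(host.start, host.end - scenario.tfbs_length))
        else:
            s = max(0, host.start - int(rng.integers(20, 80)))
        e = min(s + scenario.tfbs_length, scenario.genome_length)
        _add(GenomicFeature(f"tfbs{t+1:02d}", "TFBS", s, e), [gene_tu[host.id]])

    for t in range(scenario.n_attenuators):
        if not tu_list:
            break
        tu = tu_list[int(rng.integers(0, len(tu_list)))]
        if tu.length <= scenario.attenuator_length:
            continue
        s = int(rng.integers(tu.start, tu.end - scenario.attenuator_length))
        _add(
            GenomicFeature(
                f"att{t+1:02d}",
                "attenuator_terminator",
                s,
                s + scenario.attenuator_length,
            ),
            [tu.id],
        )

    for tu in tu_list:
        tus[tu.id] = replace(tu, regulatory_ids=tuple(reg_ids[tu.id]))

    # operons over consecutive TUs
    operons: Dict[str, Operon] = {}
    i = 0
    while i < len(tu_list):
        size = int(
            rng.integers(scenario.tus_per_operon[0], scenario.tus_per_operon[1] + 1)
        )
        members = tu_list[i : i + size]
        oid = f"op{len(operons)+1:03d}"
        operons[oid] = Operon(id=oid, tu_ids=tuple(t.id for t in members))
        i += size

    # functional annotations: regulons over whole TUs, pathways/COGs over
    # gene subsets (exercising the non-member exclusion length rule)
    functional: Dict[str, FunctionalAnnotation] = {}
    gene_ids = [g.id for g in genes]
    for r in range(scenario.n_regulons):
        if not tu_list:
            break
        k = min(
            len(tu_list),
            int(rng.integers(scenario.tus_per_regulon[0], scenario.tus_per_regulon[1] + 1)),
        )
        chosen = rng.choice(len(tu_list), size=k, replace=False)
        members = tuple(
            sorted({g for ci in chosen for g in tu_list[int(ci)].gene_ids})
        )
        fid = f"reg{r+1:02d}"
        functional[fid] = FunctionalAnnotation(fid, "regulon", members)
    for prefix, kind, count, span in (
        ("pw", "pathway", scenario.n_pathways, scenario.genes_per_pathway),
        ("cog", "COG", scenario.n_cogs, scenario.genes_per_cog),
    ):
        for r in range(count):
            if not gene_ids:
                break
            k = min(len(gene_ids), int(rng.integers(span[0], span[1] + 1)))
            members = tuple(
                sorted(rng.choice(gene_ids, size=k, replace=False).tolist())
            )
            fid = f"{prefix}{r+1:02d}"
            functional[fid] = FunctionalAnnotation(fid, kind, members)

    fw = AnnotationFramework(
        genome_length=scenario.genome_length,
        features=features,
        tus=tus,
        operons=operons,
        functional=functional,
    )
    return derive_intergenic_regions(fw)


def generate_condition_labels(scenario: SimulationScenario) -> pd.DataFrame:
    """Assign condition labels per experiment (occasionally multi-label)."""
    rng = _rng(scenario, 1)
    rows = []
    for e in range(scenario.n_experiments):
        exp = f"exp{e+1:02d}"
        for ctype, labels in scenario.condition_types.items():
            chosen = {labels[int(rng.integers(0, len(labels)))]}
            if len(labels) > 1 and rng.random() < 0.15:
                chosen.add(labels[int(rng.integers(0, len(labels)))])
            for lab in sorted(chosen):
                rows.append((exp, ctype, lab))
    return pd.DataFrame(rows, columns=["experiment_id", "condition_type", "label"])


def _resolve_plant_feature(
    plant: PlantedTarget, fw: AnnotationFramework, rng: np.random.Generator,
    taken: Set[str],
) -> str:
    if plant.feature_id is not None:
        return plant.feature_id
    if plant.scale in ("genomic_feature", "gene_and_intergenic"):
        ftype = plant.feature_type or "gene"
        pool = sorted(
            f.id
            for f in fw.features.values()
            if f.feature_type == ftype and f.id not in taken
        )
    elif plant.scale == "TU":
        pool = sorted(t for t in fw.tus if t not in taken)
    elif plant.scale == "operon":
        # a plantable operon must host >= 2 genes yet keep a realistic
        # relative footprint: when a single operon covers a large share of a
        # desk-scale genome, its length-proportional null expectation grows
        # so large that no plausible planted signal is distinguishable
        max_len = fw.genome_length // 10
        pool = sorted(
            o
            for o, op in fw.operons.items()
            if o not in taken
            and sum(len(fw.tus[t].gene_ids) for t in op.tu_ids) >= 2
            and fw.feature_length("operon", o) <= max_len
        )
    else:
        pool = sorted(
            f for f, fa in fw.functional.items()
            if fa.kind == plant.scale and f not in taken
        )
    if not pool:
        raise ConfigurationError(
            f"no eligible feature to plant at scale {plant.scale!r}"
        )
    return pool[int(rng.integers(0, len(pool)))]


def _sample_position(
    intervals: Sequence[Tuple[int, int]], rng: np.random.Generator
) -> int:
    lengths = np.array([e - s for s, e in intervals], dtype=float)
    i = int(rng.choice(len(intervals), p=lengths / lengths.sum()))
    s, e = intervals[i]
    return int(rng.integers(s, e))


def generate_mutation_sets(
    scenario: SimulationScenario,
    fw: AnnotationFramework,
    conditions: Optional[pd.DataFrame] = None,
) -> Tuple[List[MutationRecord], pd.DataFrame]:
    """Mutation records plus a ground-truth table flagging planted mutations.

    One clonal endpoint sample per ALE. Background counts are Poisson per
    ALE with uniform positions; planted mutations are SNPs uniform within
    the planted feature's nucleotide extent.
    """
    rng = _rng(scenario, 2)
    if conditions is None:
        conditions = generate_condition_labels(scenario)
    exp_labels: Dict[str, Set[Tuple[str, str]]] = {}
    for row in conditions.itertuples(index=False):
        exp_labels.setdefault(row.experiment_id, set()).add(
            (row.condition_type, row.label)
        )

    type_names = list(scenario.mutation_type_probs)
    type_p = np.array([scenario.mutation_type_probs[t] for t in type_names])
    type_p = type_p / type_p.sum()

    records: List[MutationRecord] = []
    truth_rows = []

    def _emit(exp: str, ale: str, pos: int, span: int, mtype: str,
              planted: bool, target: str) -> None:
        records.append(
            MutationRecord(
                experiment_id=exp,
                ale_id=ale,
                sample_id=f"{ale}-c1",
                sample_kind="clonal",
                position=pos,
                span=span,
                mutation_type=mtype,
                frequency=1.0,
            )
        )
        truth_rows.append((exp, ale, pos, span, mtype, planted, target))

    experiments = [f"exp{e+1:02d}" for e in range(scenario.n_experiments)]
    for exp in experiments:
        for a in range(scenario.n_ales):
            ale = f"ale{a+1:02d}"
            n_bg = int(rng.poisson(scenario.background_mean))
            for _ in range(n_bg):
                mtype = type_names[int(rng.choice(len(type_names), p=type_p))]
                if mtype in ("DEL", "INS"):
                    span = int(
                        rng.integers(
                            scenario.indel_span_range[0],
                            scenario.indel_span_range[1] + 1,
                        )
                    )
                else:
                    span = 1
                pos = int(rng.integers(0, scenario.genome_length - span + 1))
                _emit(exp, ale, pos, span, mtype, False, "")

    taken: Set[str] = set()
    for plant in scenario.plants:
        fid = _resolve_plant_feature(plant, fw, rng, taken)
        taken.add(fid)
        extent = fw.feature_positions(plant.scale, fid)
        target_exps = [
            e
            for e in experiments
            if plant.condition is None or plant.condition in exp_labels.get(e, set())
        ]
        for exp in target_exps:
            n_target = (
                scenario.n_ales if plant.n_ales is None
                else min(plant.n_ales, scenario.n_ales)
            )
            for a in range(n_target):
                ale = f"ale{a+1:02d}"
                for _ in range(plant.mutations_per_ale):
                    pos = _sample_position(extent, rng)
                    _emit(exp, ale, pos, 1, "SNP", True, f"{plant.scale}:{fid}")

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "experiment_id",
            "ale_id",
            "position",
            "span",
            "mutation_type",
            "planted",
            "target",
        ],
    )
    return records, truth


def simulate_cohort(
    scenario: SimulationScenario,
) -> Tuple[AnnotationFramework, List[MutationRecord], pd.DataFrame, pd.DataFrame]:
    """Framework, mutation records, condition table and ground truth."""
    fw = generate_framework(scenario)
    conditions = generate_condition_labels(scenario)
    records, truth = generate_mutation_sets(scenario, fw, conditions)
    return fw, records, conditions, truth


def default_recovery_scenario(
    seed: int = 0, background_mean: float = 1.0
) -> SimulationScenario:
    """The standard planted-signal scenario: 50 kb genome, 8 ALEs, plants at
    gene, promoter and operon scales (the operon plant spreads its mutations
    over the whole operon extent, so convergence is strongest there).

    The background mean of 1.0 mutation/ALE is generous relative to real ALE
    cohorts scaled to a 50 kb genome (~0.1-0.2 mutations/ALE at typical
    per-nucleotide densities); keeping it near the realistic range matters
    because every background mutation landing inside a significantly
    converged broad feature becomes a key mutation by definition.
    """
    return SimulationScenario(
        seed=seed,
        background_mean=background_mean,
        plants=[
            PlantedTarget(scale="genomic_feature", feature_type="gene"),
            PlantedTarget(scale="genomic_feature", feature_type="promoter"),
            PlantedTarget(scale="operon"),
        ],
    )
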