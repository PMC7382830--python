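"""Mutation call tables: reading, filtering and endpoint consolidation.

ALE (adaptive laboratory evolution) resequencing yields per-sample mutation
calls distilled from a variant-calling pipeline. Only endpoint-flask samples
are ingested; all samples sharing an ``ale_id`` are treated as the endpoint
of that independent evolution. Three rules prepare the calls for
convergence analysis:

1. population-sample calls below 50% frequency are dropped (dominant
   selection only); clonal calls are untouched;
2. samples flagged as hypermutators are discarded wholesale;
3. a mutation seen in several samples of one endpoint is represented once,
   by its highest-frequency instance.

Mutation identity for deduplication is ``(position, span, mutation_type)``
within an (experiment, ALE) pair; the same mutation arising in two ALEs
stays separate, since independent occurrences are the convergence signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .errors import SchemaError

SAMPLE_KINDS = ("clonal", "population")
MUTATION_TYPES = ("SNP", "DEL", "INS", "MOB", "AMP", "other")

MUTATION_COLUMNS = [
    "experiment_id",
    "ale_id",
    "sample_id",
    "sample_kind",
    "position",
    "span",
    "mutation_type",
    "frequency",
    "hypermutator",
]


@dataclass(frozen=True)
class MutationRecord:
    """One called mutation in one endpoint sample."""

    experiment_id: str
    ale_id: str
    sample_id: str
    sample_kind: str
    position: int
    span: int
    mutation_type: str
    frequency: float
    hypermutator_flag: bool = False

    def __post_init__(self) -> None:
        if self.sample_kind not in SAMPLE_KINDS:
            raise SchemaError(f"unknown sample_kind {self.sample_kind!r}")
        if self.mutation_type not in MUTATION_TYPES:
            raise SchemaError(f"unknown mutation_type {self.mutation_type!r}")
        if self.span < 1:
            raise SchemaError(f"span must be >= 1, got {self.span}")
        if self.position < 0:
            raise SchemaError(f"position must be >= 0, got {self.position}")
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError(f"frequency outside [0,1]: {self.frequency}")

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.position, self.position + self.span)


@dataclass(frozen=True)
class ConsolidatedMutation:
    """One mutation per endpoint flask, keyed by (experiment, ale, pos, span, type)."""

    experiment_id: str
    ale_id: str
    position: int
    span: int
    mutation_type: str
    representative_frequency: float

    @property
    def key(self) -> Tuple[str, str, int, int, str]:
        return (
            self.experiment_id,
            self.ale_id,
            self.position,
            self.span,
            self.mutation_type,
        )

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.position, self.position + self.span)


def read_mutations(path: str) -> List[MutationRecord]:
    """Read the mutation TSV schema into records.

    Malformed rows raise with their (1-based, header-exclusive) row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                MutationRecord(
                    experiment_id=row.experiment_id,
                    ale_id=row.ale_id,
                    sample_id=row.sample_id,
                    sample_kind=row.sample_kind,
                    position=int(row.position),
                    span=int(row.span),
                    mutation_type=row.mutation_type,
                    frequency=float(row.frequency),
                    hypermutator_flag=str(row.hypermutator) in ("1", "True", "true"),
                )
            )
        except (ValueError, SchemaError) as exc:
            raise type(exc)(f"{path} row {i}: {exc}") from exc
    return records


def write_mutations(records: Iterable[MutationRecord], path: str) -> None:
    pd.DataFrame(
        [
            (
                r.experiment_id,
                r.ale_id,
                r.sample_id,
                r.sample_kind,
                r.position,
                r.span,
                r.mutation_type,
                r.frequency,
                int(r.hypermutator_flag),
            )
            for r in records
        ],
        columns=MUTATION_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def records_from_vcf(
    path: str,
    experiment_id: str,
    ale_id: str,
    sample_id: str,
    sample_kind: str = "clonal",
) -> List[MutationRecord]:
    """Convert a minimal single-sample VCF (SNP/indel rows) to records.

    Frequency is taken from ``INFO/AF`` when present, else 1.0. Positions are
    converted from VCF's 1-based to internal 0-based coordinates; spans are
    REF lengths.
    """
    import pysam

    records = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            ref = rec.ref or ""
            alt = rec.alts[0] if rec.alts else ""
            if len(ref) == len(alt):
                mtype = "SNP" if len(ref) == 1 else "other"
            elif len(ref) > len(alt):
                mtype = "DEL"
            else:
                mtype = "INS"
            af = rec.info.get("AF", 1.0)
            if isinstance(af, tuple):
                af = af[0]
            records.append(
                MutationRecord(
                    experiment_id=experiment_id,
                    ale_id=ale_id,
                    sample_id=sample_id,
                    sample_kind=sample_kind,
                    position=rec.pos - 1,
                    span=max(1, len(ref)),
                    mutation_type=mtype,
                    frequency=float(af),
                )
            )
    return records


def filter_population_frequency(
    records: Iterable[MutationRecord], threshold: float = 0.5
) -> List[MutationRecord]:
    """Drop population-sample calls with frequency strictly below ``threshold``.

    A call at exactly the threshold is retained; clonal calls pass through
    regardless of frequency.
    """
    return [
        r
        for r in records
        if r.sample_kind != "population" or r.frequency >= threshold
    ]


def exclude_hypermutators(records: Iterable[MutationRecord]) -> List[MutationRecord]:
    """Drop every record from a hypermutator-flagged sample."""
    return [r for r in records if not r.hypermutator_flag]


def consolidate_endpoints(
    records: Iterable[MutationRecord],
) -> List[ConsolidatedMutation]:
    """Collapse samples of one endpoint flask to one record per mutation.

    The representative frequency is the maximum over the samples in which
    the mutation was called. Output order is deterministic (sorted by key).
    """
    best: dict = {}
    for r in records:
        key = (r.experiment_id, r.ale_id, r.position, r.span, r.mutation_type)
        if key not in best or r.frequency > best[key]:
            best[key] = r.frequency
    return [
        ConsolidatedMutation(*key, representative_frequency=freq)
        for key, freq in sorted(best.items())
    ]


def prepare_mutations(
    records: Iterable[MutationRecord], frequency_threshold: float = 0.5
) -> List[ConsolidatedMutation]:
    """Full pipeline: frequency filter, hypermutator exclusion, consolidation."""
    filtered = filter_population_frequency(records, frequency_threshold)
    filtered = exclude_hypermutators(filtered)
    return consolidate_endpoints(filtered)


def consolidated_to_frame(mutations: Sequence[ConsolidatedMutation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                m.experiment_id,
                m.ale_id,
                m.position,
                m.span,
                m.mutation_type,
                m.representative_frequency,
            )
            for m in mutations
        ],
        columns=[
            "experiment_id",
            "ale_id",
            "position",
            "span",
            "mutation_type",
            "representative_frequency",
        ],
    )
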