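"""Multiscale genome annotation framework.

The framework nests several scales of annotation around a single bacterial
chromosome: small coordinate-bearing *genomic features* (genes plus the
non-coding regulatory features TFBS, promoter, terminator,
attenuator-terminator and RBS, and derived intergenic regions),
transcription units (TUs) that group genes with their regulatory features,
operons that group TUs, and gene-set functional annotations (regulons,
pathways, COGs).

Internal coordinates are 0-based half-open throughout; GFF3 input
(1-based inclusive) is converted on read. Strand is stored but ignored by
all length and overlap computations.

Length rules for broad annotation types:

* operon — nucleotide union of its TUs' spans;
* regulon — nucleotide union of the spans of its member genes' TUs;
* pathway / COG — the regulon rule, minus the positions of genes inside
  those TUs that do not belong to the pathway/COG (positions shared with a
  member gene are kept).

Overlapping TUs contribute their union, never their sum.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import _intervals as iv
from .errors import (
    CoordinateBoundsError,
    DuplicateIdError,
    FeatureLookupError,
    SchemaError,
    UnresolvedReferenceError,
)

FEATURE_TYPES = (
    "gene",
    "TFBS",
    "promoter",
    "terminator",
    "attenuator_terminator",
    "RBS",
    "intergenic",
)

FUNCTIONAL_KINDS = ("regulon", "pathway", "COG")

#: Ordered annotation scales, small to broad.
SCALES = (
    "genomic_feature",
    "gene_and_intergenic",
    "TU",
    "operon",
    "regulon",
    "pathway",
    "COG",
)

#: Sentinel flank name for intergenic regions touching a chromosome end.
CHROM_END_SENTINEL = "."


@dataclass(frozen=True)
class GenomicFeature:
    """A coordinate-bearing feature, the smallest annotation scale."""

    id: str
    feature_type: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise SchemaError(
                f"feature {self.id!r}: unknown feature_type {self.feature_type!r}"
            )
        if not (0 <= self.start < self.end):
            raise CoordinateBoundsError(
                f"feature {self.id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class TranscriptionUnit:
    """A contiguous transcribed region grouping genes and regulatory features."""

    id: str
    start: int
    end: int
    gene_ids: Tuple[str, ...]
    regulatory_ids: Tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Operon:
    id: str
    tu_ids: Tuple[str, ...]


@dataclass(frozen=True)
class FunctionalAnnotation:
    """A gene-set annotation: regulon, pathway or COG."""

    id: str
    kind: str
    member_gene_ids: Tuple[str, ...]


@dataclass
class AnnotationFramework:
    """The full nested annotation set for one genome.

    Construction validates id uniqueness, coordinate bounds and every
    cross-reference; an invalid framework cannot be instantiated.
    """

    genome_length: int
    features: Dict[str, GenomicFeature] = field(default_factory=dict)
    tus: Dict[str, TranscriptionUnit] = field(default_factory=dict)
    operons: Dict[str, Operon] = field(default_factory=dict)
    functional: Dict[str, FunctionalAnnotation] = field(default_factory=dict)
    annotation_types: Tuple[str, ...] = SCALES

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise CoordinateBoundsError("genome_length must be positive")
        seen: set = set()
        for pool in (self.features, self.tus, self.operons, self.functional):
            for fid in pool:
                if fid in seen:
                    raise DuplicateIdError(f"duplicate annotation id {fid!r}")
                seen.add(fid)
        for f in self.features.values():
            if f.end > self.genome_length:
                raise CoordinateBoundsError(
                    f"feature {f.id!r} end {f.end} exceeds genome "
                    f"length {self.genome_length}"
                )
        for tu in self.tus.values():
            if not tu.gene_ids:
                raise SchemaError(f"TU {tu.id!r} lists no genes")
            if not (0 <= tu.start < tu.end <= self.genome_length):
                raise CoordinateBoundsError(f"TU {tu.id!r} outside genome")
            for gid in tu.gene_ids:
                g = self.features.get(gid)
                if g is None or g.feature_type != "gene":
                    raise UnresolvedReferenceError(
                        f"TU {tu.id!r} references unknown gene {gid!r}"
                    )
                if not (tu.start <= g.start and g.end <= tu.end):
                    raise CoordinateBoundsError(
                        f"gene {gid!r} not contained in TU {tu.id!r}"
                    )
            for rid in tu.regulatory_ids:
                r = self.features.get(rid)
                if r is None or r.feature_type in ("gene", "intergenic"):
                    raise UnresolvedReferenceError(
                        f"TU {tu.id!r} references unknown regulatory "
                        f"feature {rid!r}"
                    )
        for op in self.operons.values():
            if not op.tu_ids:
                raise SchemaError(f"operon {op.id!r} lists no TUs")
            for tid in op.tu_ids:
                if tid not in self.tus:
                    raise UnresolvedReferenceError(
                        f"operon {op.id!r} references unknown TU {tid!r}"
                    )
        for fa in self.functional.values():
            if fa.kind not in FUNCTIONAL_KINDS:
                raise SchemaError(
                    f"functional annotation {fa.id!r}: unknown kind {fa.kind!r}"
                )
            if not fa.member_gene_ids:
                raise SchemaError(f"functional annotation {fa.id!r} has no members")
            for gid in fa.member_gene_ids:
                g = self.features.get(gid)
                if g is None or g.feature_type != "gene":
                    raise UnresolvedReferenceError(
                        f"functional annotation {fa.id!r} references unknown "
                        f"gene {gid!r}"
                    )

    # -- accessors ------------------------------------------------------

    @property
    def genes(self) -> List[GenomicFeature]:
        return [f for f in self.features.values() if f.feature_type == "gene"]

    @property
    def intergenic(self) -> List[GenomicFeature]:
        return [f for f in self.features.values() if f.feature_type == "intergenic"]

    def gene_tus(self, gene_id: str) -> List[TranscriptionUnit]:
        return [tu for tu in self.tus.values() if gene_id in tu.gene_ids]

    def regulatory_tus(self, reg_id: str) -> List[TranscriptionUnit]:
        return [tu for tu in self.tus.values() if reg_id in tu.regulatory_ids]

    def tu_operons(self, tu_id: str) -> List[Operon]:
        return [op for op in self.operons.values() if tu_id in op.tu_ids]

    def gene_functional(self, gene_id: str, kind: str) -> List[FunctionalAnnotation]:
        return [
            fa
            for fa in self.functional.values()
            if fa.kind == kind and gene_id in fa.member_gene_ids
        ]

    def feature_ids_at_scale(self, scale: str) -> List[str]:
        if scale == "genomic_feature":
            return list(self.features)
        if scale == "gene_and_intergenic":
            return [
                f.id
                for f in self.features.values()
                if f.feature_type in ("gene", "intergenic")
            ]
        if scale == "TU":
            return list(self.tus)
        if scale == "operon":
            return list(self.operons)
        if scale in FUNCTIONAL_KINDS:
            return [fid for fid, fa in self.functional.items() if fa.kind == scale]
        raise FeatureLookupError(f"unknown annotation scale {scale!r}")

    # -- length rules ---------------------------------------------------

    def feature_positions(self, scale: str, feature_id: str) -> List[Tuple[int, int]]:
        """Merged interval list of the nucleotide positions a feature covers."""
        if scale in ("genomic_feature", "gene_and_intergenic"):
            f = self.features.get(feature_id)
            if f is None or (
                scale == "gene_and_intergenic"
                and f.feature_type not in ("gene", "intergenic")
            ):
                raise FeatureLookupError(f"{feature_id!r} not at scale {scale!r}")
            return [f.interval]
        if scale == "TU":
            tu = self.tus.get(feature_id)
            if tu is None:
                raise FeatureLookupError(f"unknown TU {feature_id!r}")
            return [tu.interval]
        if scale == "operon":
            op = self.operons.get(feature_id)
            if op is None:
                raise FeatureLookupError(f"unknown operon {feature_id!r}")
            return iv.merge(self.tus[t].interval for t in op.tu_ids)
        if scale in FUNCTIONAL_KINDS:
            fa = self.functional.get(feature_id)
            if fa is None or fa.kind != scale:
                raise FeatureLookupError(f"{feature_id!r} not a {scale}")
            member = set(fa.member_gene_ids)
            tus = {tu.id: tu for g in member for tu in self.gene_tus(g)}
            covered = iv.merge(tu.interval for tu in tus.values())
            if scale == "regulon":
                return covered
            # pathway/COG: drop non-member gene positions inside those TUs,
            # but keep any nucleotide shared with a member gene.
            non_member = [
                self.features[g].interval
                for tu in tus.values()
                for g in tu.gene_ids
                if g not in member
            ]
            member_ivs = [self.features[g].interval for g in member]
            return iv.subtract(covered, iv.subtract(non_member, member_ivs))
        raise FeatureLookupError(f"unknown annotation scale {scale!r}")

    def feature_length(self, scale: str, feature_id: str) -> int:
        """Nucleotide length of a feature under the scale's length rule."""
        return iv.union_length(self.feature_positions(scale, feature_id))

    def scale_coverage(self, scale: str) -> List[Tuple[int, int]]:
        """Union of all nucleotide positions covered at a scale."""
        ivs: List[Tuple[int, int]] = []
        for fid in self.feature_ids_at_scale(scale):
            ivs.extend(self.feature_positions(scale, fid))
        return iv.merge(ivs)


# ---------------------------------------------------------------------------
# intergenic derivation


def derive_intergenic_regions(framework: AnnotationFramework) -> AnnotationFramework:
    """Return a framework with intergenic features filling every gene gap.

    One intergenic feature is added per maximal interval not covered by any
    gene, named ``"leftGene/rightGene"`` after its flanking genes; a
    chromosome end is flanked by the sentinel ``"."``. Genes plus intergenic
    regions then cover the genome exactly once (overlapping genes permitting).
    """
    genes = sorted(framework.genes, key=lambda g: (g.start, g.end))
    gaps = iv.complement([g.interval for g in genes], framework.genome_length)
    features = {
        fid: f
        for fid, f in framework.features.items()
        if f.feature_type != "intergenic"
    }
    for s, e in gaps:
        left = CHROM_END_SENTINEL
        for g in genes:
            if g.end <= s:
                left = g.id
            else:
                break
        right = CHROM_END_SENTINEL
        for g in genes:
            if g.start >= e:
                right = g.id
                break
        fid = f"{left}/{right}"
        if fid in features:  # two gaps between one gene pair cannot occur
            raise DuplicateIdError(f"intergenic name collision for {fid!r}")
        features[fid] = GenomicFeature(fid, "intergenic", s, e)
    return replace(framework, features=features)


# ---------------------------------------------------------------------------
# file loading

_FEATURE_COLUMNS = ["id", "type", "start", "end", "strand"]
_TU_COLUMNS = ["id", "start", "end", "gene_ids", "regulatory_ids"]
_OPERON_COLUMNS = ["id", "tu_ids"]
_FUNCTIONAL_COLUMNS = ["id", "kind", "gene_ids"]


def _read_tsv(path: str, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def _split_ids(cell: str) -> Tuple[str, ...]:
    return tuple(x for x in str(cell).split(";") if x)


def _read_features_gff3(path: str) -> List[GenomicFeature]:
    """Read coordinate-bearing features from GFF3 (1-based inclusive)."""
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        from_string=False,
    )
    out = []
    for rec in db.all_features():
        ftype = rec.featuretype
        if ftype not in FEATURE_TYPES:
            continue
        fid = rec.attributes.get("ID", [rec.id])[0]
        out.append(
            GenomicFeature(
                id=fid,
                feature_type=ftype,
                start=rec.start - 1,  # GFF3 is 1-based inclusive
                end=rec.end,
                strand=rec.strand or ".",
            )
        )
    return out


def _read_features(path: str) -> List[GenomicFeature]:
    if os.path.splitext(path)[1].lower() in (".gff", ".gff3"):
        return _read_features_gff3(path)
    df = _read_tsv(path, _FEATURE_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GenomicFeature(
                id=row.id,
                feature_type=row.type,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand or ".",
            )
        )
    return out


def load_framework(
    annotation_paths: Mapping[str, str],
    genome_length: int,
    derive_intergenic: bool = True,
) -> AnnotationFramework:
    """Load and validate a framework from per-annotation-type files.

    Parameters
    ----------
    annotation_paths
        Keys: ``features`` (TSV or GFF3; required), ``tus``, ``operons``,
        ``functional`` (TSV; optional).
    genome_length
        Chromosome length in nucleotides.
    derive_intergenic
        Add intergenic features for every gene gap after loading.
    """
    if genome_length <= 0:
        raise CoordinateBoundsError("genome_length must be positive")
    if "features" not in annotation_paths:
        raise SchemaError("annotation_paths must include a 'features' entry")

    features: Dict[str, GenomicFeature] = {}
    for f in _read_features(annotation_paths["features"]):
        if f.id in features:
            raise DuplicateIdError(f"duplicate feature id {f.id!r}")
        features[f.id] = f

    tus: Dict[str, TranscriptionUnit] = {}
    if "tus" in annotation_paths:
        for row in _read_tsv(annotation_paths["tus"], _TU_COLUMNS).itertuples(
            index=False
        ):
            if row.id in tus:
                raise DuplicateIdError(f"duplicate TU id {row.id!r}")
            tus[row.id] = TranscriptionUnit(
                id=row.id,
                start=int(row.start),
                end=int(row.end),
                gene_ids=_split_ids(row.gene_ids),
                regulatory_ids=_split_ids(row.regulatory_ids),
            )

    operons: Dict[str, Operon] = {}
    if "operons" in annotation_paths:
        for row in _read_tsv(annotation_paths["operons"], _OPERON_COLUMNS).itertuples(
            index=False
        ):
            if row.id in operons:
                raise DuplicateIdError(f"duplicate operon id {row.id!r}")
            operons[row.id] = Operon(id=row.id, tu_ids=_split_ids(row.tu_ids))

    functional: Dict[str, FunctionalAnnotation] = {}
    if "functional" in annotation_paths:
        for row in _read_tsv(
            annotation_paths["functional"], _FUNCTIONAL_COLUMNS
        ).itertuples(index=False):
            if row.id in functional:
                raise DuplicateIdError(f"duplicate functional id {row.id!r}")
            functional[row.id] = FunctionalAnnotation(
                id=row.id, kind=row.kind, member_gene_ids=_split_ids(row.gene_ids)
            )

    fw = AnnotationFramework(
        genome_length=genome_length,
        features=features,
        tus=tus,
        operons=operons,
        functional=functional,
    )
    if derive_intergenic:
        fw = derive_intergenic_regions(fw)
    return fw


def write_framework(fw: AnnotationFramework, outdir: str) -> Dict[str, str]:
    """Write the four TSV tables; returns the path map load_framework accepts."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    feats = pd.DataFrame(
        [
            (f.id, f.feature_type, f.start, f.end, f.strand)
            for f in fw.features.values()
            if f.feature_type != "intergenic"  # re-derived on load
        ],
        columns=_FEATURE_COLUMNS,
    )
    paths["features"] = os.path.join(outdir, "features.tsv")
    feats.to_csv(paths["features"], sep="\t", index=False)

    tus = pd.DataFrame(
        [
            (t.id, t.start, t.end, ";".join(t.gene_ids), ";".join(t.regulatory_ids))
            for t in fw.tus.values()
        ],
        columns=_TU_COLUMNS,
    )
    paths["tus"] = os.path.join(outdir, "tus.tsv")
    tus.to_csv(paths["tus"], sep="\t", index=False)

    ops = pd.DataFrame(
        [(o.id, ";".join(o.tu_ids)) for o in fw.operons.values()],
        columns=_OPERON_COLUMNS,
    )
    paths["operons"] = os.path.join(outdir, "operons.tsv")
    ops.to_csv(paths["operons"], sep="\t", index=False)

    fun = pd.DataFrame(
        [(f.id, f.kind, ";".join(f.member_gene_ids)) for f in fw.functional.values()],
        columns=_FUNCTIONAL_COLUMNS,
    )
    paths["functional"] = os.path.join(outdir, "functional.tsv")
    fun.to_csv(paths["functional"], sep="\t", index=False)
    return paths
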