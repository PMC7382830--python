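"""Annotation framework: loading, validation, intergenic derivation and the
length rules for broad annotation types."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aleflow import _intervals as iv
from aleflow.annotations import (
    AnnotationFramework,
    FunctionalAnnotation,
    GenomicFeature,
    Operon,
    TranscriptionUnit,
    derive_intergenic_regions,
    load_framework,
    write_framework,
)
from aleflow.errors import (
    CoordinateBoundsError,
    DuplicateIdError,
    UnresolvedReferenceError,
)


def _write_minimal_tables(tmp_path, tu_gene="g1"):
    (tmp_path / "features.tsv").write_text(
        "id\ttype\tstart\tend\tstrand\n"
        "g1\tgene\t0\t100\t+\n"
        "g2\tgene\t200\t300\t-\n"
    )
    (tmp_path / "tus.tsv").write_text(
        f"id\tstart\tend\tgene_ids\tregulatory_ids\ntu1\t0\t120\t{tu_gene}\t\n"
    )
    return {
        "features": str(tmp_path / "features.tsv"),
        "tus": str(tmp_path / "tus.tsv"),
    }


class TestLoading:
    def test_minimal_tables_resolve(self, tmp_path):
        fw = load_framework(_write_minimal_tables(tmp_path), genome_length=300)
        assert len(fw.genes) == 2
        assert len(fw.tus) == 1
        assert fw.tus["tu1"].gene_ids == ("g1",)

    def test_missing_gene_reference_is_named(self, tmp_path):
        paths = _write_minimal_tables(tmp_path, tu_gene="gX")
        with pytest.raises(UnresolvedReferenceError, match="gX"):
            load_framework(paths, genome_length=300)

    def test_gff3_one_based_inclusive_converted(self, tmp_path):
        gff = tmp_path / "features.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr\tsrc\tgene\t11\t20\t.\t+\t.\tID=g1\n"
        )
        fw = load_framework({"features": str(gff)}, genome_length=100)
        g = fw.features["g1"]
        assert (g.start, g.end, g.length) == (10, 20, 10)

    def test_coordinate_outside_genome_rejected(self, tmp_path):
        paths = _write_minimal_tables(tmp_path)
        with pytest.raises(CoordinateBoundsError):
            load_framework(paths, genome_length=250)

    def test_duplicate_id_across_pools_rejected(self):
        with pytest.raises(DuplicateIdError, match="x"):
            AnnotationFramework(
                genome_length=100,
                features={"x": GenomicFeature("x", "gene", 0, 10)},
                tus={"x": TranscriptionUnit("x", 0, 10, ("x",))},
            )

    def test_roundtrip_write_load(self, tmp_path, toy_framework):
        paths = write_framework(toy_framework, str(tmp_path))
        fw2 = load_framework(paths, toy_framework.genome_length)
        assert set(fw2.features) == set(toy_framework.features)
        assert fw2.tus == toy_framework.tus
        assert fw2.operons == toy_framework.operons
        assert fw2.functional == toy_framework.functional


class TestIntergenic:
    def test_single_gap_named_by_flanks(self):
        fw = AnnotationFramework(
            genome_length=300,
            features={
                "g1": GenomicFeature("g1", "gene", 0, 100),
                "g2": GenomicFeature("g2", "gene", 200, 300),
            },
        )
        fw = derive_intergenic_regions(fw)
        inter = fw.intergenic
        assert len(inter) == 1
        assert inter[0].id == "g1/g2"
        assert inter[0].interval == (100, 200)

    def test_tiling_genes_leave_no_gap(self):
        fw = AnnotationFramework(
            genome_length=200,
            features={
                "g1": GenomicFeature("g1", "gene", 0, 100),
                "g2": GenomicFeature("g2", "gene", 100, 200),
            },
        )
        assert derive_intergenic_regions(fw).intergenic == []

    def test_three_gaps_with_chromosome_ends(self):
        fw = AnnotationFramework(
            genome_length=250,
            features={
                "g1": GenomicFeature("g1", "gene", 50, 100),
                "g2": GenomicFeature("g2", "gene", 150, 200),
            },
        )
        fw = derive_intergenic_regions(fw)
        regions = {f.id: f.interval for f in fw.intergenic}
        assert regions == {
            "./g1": (0, 50),
            "g1/g2": (100, 150),
            "g2/.": (200, 250),
        }
        assert sum(e - s for s, e in regions.values()) == 150

    def test_zero_genes_yield_genome_spanning_region(self):
        fw = derive_intergenic_regions(AnnotationFramework(genome_length=500))
        assert [f.interval for f in fw.intergenic] == [(0, 500)]

    @given(
        st.lists(
            st.tuples(st.integers(0, 900), st.integers(1, 100)), max_size=8
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_gene_plus_intergenic_covers_genome(self, raw):
        genome = 1000
        ivs = iv.merge(
            [(s, min(genome, s + l)) for s, l in raw if s < genome]
        )  # non-overlapping genes
        features = {
            f"g{i}": GenomicFeature(f"g{i}", "gene", s, e)
            for i, (s, e) in enumerate(ivs)
        }
        fw = derive_intergenic_regions(
            AnnotationFramework(genome_length=genome, features=features)
        )
        total = sum(f.length for f in fw.features.values())
        assert total == genome


class TestLengthRules:
    def test_regulon_disjoint_tus_sum(self):
        fw = AnnotationFramework(
            genome_length=2000,
            features={
                "a": GenomicFeature("a", "gene", 0, 400),
                "b": GenomicFeature("b", "gene", 1000, 1200),
            },
            tus={
                "t1": TranscriptionUnit("t1", 0, 500, ("a",)),
                "t2": TranscriptionUnit("t2", 1000, 1300, ("b",)),
            },
            functional={"R": FunctionalAnnotation("R", "regulon", ("a", "b"))},
        )
        assert fw.feature_length("regulon", "R") == 800

    def test_regulon_overlapping_tus_use_union(self):
        fw = AnnotationFramework(
            genome_length=2000,
            features={
                "a": GenomicFeature("a", "gene", 0, 400),
                "b": GenomicFeature("b", "gene", 450, 850),
            },
            tus={
                "t1": TranscriptionUnit("t1", 0, 600, ("a",)),
                "t2": TranscriptionUnit("t2", 400, 900, ("b",)),
            },
            functional={"R": FunctionalAnnotation("R", "regulon", ("a", "b"))},
        )
        assert fw.feature_length("regulon", "R") == 900  # union, not 1100

    def test_cog_excludes_non_member_gene_positions(self):
        fw = AnnotationFramework(
            genome_length=2000,
            features={
                "m": GenomicFeature("m", "gene", 100, 400),  # member, 300 nt
                "x": GenomicFeature("x", "gene", 500, 700),  # non-member, 200 nt
            },
            tus={"t1": TranscriptionUnit("t1", 0, 1000, ("m", "x"))},
            functional={"C": FunctionalAnnotation("C", "COG", ("m",))},
        )
        assert fw.feature_length("COG", "C") == 800  # 1000 - 200

    def test_operon_length_is_union_of_tus(self, toy_framework):
        assert toy_framework.feature_length("operon", "o1") == 260

    def test_all_lengths_within_genome(self, toy_framework):
        fw = toy_framework
        for scale in fw.annotation_types:
            for fid in fw.feature_ids_at_scale(scale):
                length = fw.feature_length(scale, fid)
                assert 1 <= length <= fw.genome_length

    def test_broad_lengths_match_per_nucleotide_oracle(self):
        """Union/exclusion arithmetic vs a boolean membership array."""
        import aleflow as af

        scenario = af.SimulationScenario(
            genome_length=8000, n_genes=8, gene_length_range=(200, 600),
            n_tfbs=4, n_attenuators=2, seed=11,
        )
        fw = af.generate_framework(scenario)
        for scale in ("operon", "regulon", "pathway", "COG"):
            for fid in fw.feature_ids_at_scale(scale):
                mask = np.zeros(fw.genome_length, dtype=bool)
                if scale == "operon":
                    for tid in fw.operons[fid].tu_ids:
                        tu = fw.tus[tid]
                        mask[tu.start : tu.end] = True
                else:
                    fa = fw.functional[fid]
                    members = set(fa.member_gene_ids)
                    tus = {
                        tu.id: tu for g in members for tu in fw.gene_tus(g)
                    }
                    for tu in tus.values():
                        mask[tu.start : tu.end] = True
                    if scale in ("pathway", "COG"):
                        drop = np.zeros_like(mask)
                        keep = np.zeros_like(mask)
                        for tu in tus.values():
                            for g in tu.gene_ids:
                                gf = fw.features[g]
                                if g in members:
                                    keep[gf.start : gf.end] = True
                                else:
                                    drop[gf.start : gf.end] = True
                        mask &= ~(drop & ~keep)
                assert fw.feature_length(scale, fid) == int(mask.sum()), (
                    scale,
                    fid,
                )


class TestIntervalHelpers:
    @given(
        st.lists(st.tuples(st.integers(0, 200), st.integers(0, 200)), max_size=10),
        st.lists(st.tuples(st.integers(0, 200), st.integers(0, 200)), max_size=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_set_operations_match_boolean_arrays(self, raw_a, raw_b):
        a = [(min(s, e), max(s, e)) for s, e in raw_a]
        b = [(min(s, e), max(s, e)) for s, e in raw_b]
        mask_a = np.zeros(200, dtype=bool)
        mask_b = np.zeros(200, dtype=bool)
        for s, e in a:
            mask_a[s:e] = True
        for s, e in b:
            mask_b[s:e] = True
        assert iv.union_length(a) == int(mask_a.sum())
        assert iv.union_length(iv.subtract(a, b)) == int((mask_a & ~mask_b).sum())
        assert iv.union_length(iv.intersect(a, b)) == int((mask_a & mask_b).sum())
        assert iv.union_length(iv.complement(a, 200)) == int((~mask_a).sum())
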