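"""Readers/writers: PED, VCF+annotation join, BED tracks, panels."""

import itertools

import pytest

from famprio import cohort_io
from famprio.types import GenePanel, Pedigree, RegulatoryTrack, Sample

FAMILY1_PED = """\
Family_1\tII-1\t0\t0\t1\t1
Family_1\tII-2\t0\t0\t2\t2
Family_1\tIII-1\tII-1\tII-2\t2\t2
"""

FAMILY2_SNIPPET = """\
Family_2\tII-6\t0\t0\t2\t1\tobligate_carrier
Family_2\tIII-3\t0\tII-6\t1\t2
Family_2\tII-1\t0\t0\t2\t1
"""


class TestReadPedigree:
    def test_family1_roles(self, tmp_path):
        p = tmp_path / "fam1.ped"
        p.write_text(FAMILY1_PED)
        peds = cohort_io.read_pedigree(p)
        assert len(peds) == 1
        ped = peds[0]
        assert len(ped.cases) == 2 and len(ped.controls) == 1
        assert {s.sample_id for s in ped.cases} == {"II-2", "III-1"}

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "empty.ped"
        p.write_text("")
        assert cohort_io.read_pedigree(p) == []

    def test_obligate_carrier_not_a_control(self, tmp_path):
        p = tmp_path / "fam2.ped"
        p.write_text(FAMILY2_SNIPPET)
        (ped,) = cohort_io.read_pedigree(p)
        assert [s.sample_id for s in ped.obligate_carriers] == ["II-6"]
        assert "II-6" not in {s.sample_id for s in ped.controls}

    def test_duplicate_sample_rejected(self, tmp_path):
        p = tmp_path / "dup.ped"
        p.write_text("F\tA\t0\t0\t1\t2\nF\tA\t0\t0\t1\t1\n")
        with pytest.raises(ValueError, match="duplicate sample_id"):
            cohort_io.read_pedigree(p)

    def test_unresolvable_parent_names_sample(self, tmp_path):
        p = tmp_path / "bad.ped"
        p.write_text("F\tA\tGHOST\t0\t1\t2\n")
        with pytest.raises(ValueError, match="A.*GHOST|GHOST"):
            cohort_io.read_pedigree(p)

    def test_roundtrip(self, tmp_path, bundle):
        path = tmp_path / "cohort.ped"
        cohort_io.write_pedigree(bundle.pedigrees.values(), path)
        again = {p.family_id: p for p in cohort_io.read_pedigree(path)}
        for fam, ped in bundle.pedigrees.items():
            assert [
                (s.sample_id, s.role, s.sex, s.father_id, s.mother_id)
                for s in again[fam].samples
            ] == [
                (s.sample_id, s.role, s.sex, s.father_id, s.mother_id)
                for s in ped.samples
            ]


MULTIALLELIC_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
1\t100\t.\tA\tC,T\t50\tPASS\t.\tGT\t{gts}
"""


class TestReadVariants:
    def test_multiallelic_split_matches_enumeration(self, tmp_path):
        # every diploid genotype over alleles {ref, C, T} plus missing
        genotypes = [(a, b) for a in range(3) for b in range(a, 3)] + [None]
        names = [f"S{i}" for i in range(len(genotypes))]
        gts = "\t".join(
            "./." if g is None else f"{g[0]}/{g[1]}" for g in genotypes
        )
        p = tmp_path / "multi.vcf"
        p.write_text(
            MULTIALLELIC_VCF.format(samples="\t".join(names), gts=gts)
        )
        variants = cohort_io.read_variants(p)
        assert {v.variant_id for v in variants} == {"1_100_A_C", "1_100_A_T"}
        for v, allele in zip(sorted(variants, key=lambda v: v.alt), (1, 2)):
            for name, g in zip(names, genotypes):
                expected = None if g is None else sum(1 for x in g if x == allele)
                assert v.genotype(name).dosage == expected, (v.alt, name)

    def test_empty_vcf(self, tmp_path):
        p = tmp_path / "empty.vcf"
        p.write_text(MULTIALLELIC_VCF.split("1\t100")[0].format(samples="S0", gts=""))
        assert cohort_io.read_variants(p) == []

    def test_unmatched_annotation_row_warns_and_is_ignored(self, tmp_path, caplog, small_cohort):
        fam = small_cohort.pedigrees[0].family_id
        variants = small_cohort.variants_by_family[fam][:3]
        vcf, tsv = tmp_path / "c.vcf", tmp_path / "c.tsv"
        cohort_io.write_variants(variants, vcf, tsv)
        with open(tsv, "a") as fh:
            row = ["99_1_A_T"] + [""] * (len(cohort_io.ANNOTATION_COLUMNS) - 1)
            fh.write("\t".join(row) + "\n")
        import logging

        with caplog.at_level(logging.WARNING):
            out = cohort_io.read_variants(vcf, tsv)
        assert len(out) == 3
        assert any("99_1_A_T" in r.message for r in caplog.records)

    def test_roundtrip_bit_identical(self, tmp_path, small_cohort):
        fam = small_cohort.pedigrees[0].family_id
        variants = small_cohort.variants_by_family[fam]
        vcf, tsv = tmp_path / "rt.vcf", tmp_path / "rt.tsv"
        cohort_io.write_variants(variants, vcf, tsv)
        again = cohort_io.read_variants(vcf, tsv)
        orig = {v.variant_id: v for v in variants}
        assert len(again) == len(orig)
        for v in again:
            o = orig[v.variant_id]
            for attr in (
                "chrom", "pos", "ref", "alt", "variant_class", "site_quality",
                "site_coverage", "platypus_pass", "gene_symbols",
                "functional_class", "protein_effect", "maf_1000g",
                "maf_exac_nontcga", "cadd_phred", "gerp", "phastcons",
                "phylop", "missense_calls", "nonsense_calls",
                "intolerance_flags", "pli", "missense_z", "mirsvr",
            ):
                assert getattr(v, attr) == getattr(o, attr), (v.variant_id, attr)
            for g in v.genotypes:
                og = o.genotype(g.sample_id)
                assert (g.dosage, g.depth, g.quality, g.forward_alt_reads,
                        g.reverse_alt_reads) == (
                    og.dosage, og.depth, og.quality, og.forward_alt_reads,
                    og.reverse_alt_reads,
                )

    def test_table_style_variant_id(self, bundle):
        dicer = next(
            v for v in bundle.coding_variants if "DICER1" in v.gene_symbols
        )
        assert dicer.variant_id == "14_95560456_A_C"
        assert dicer.cadd_phred == 24


class TestReadTrack:
    def test_three_line_bed(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("1\t10\t20\n1\t30\t40\n2\t5\t9\n")
        track = cohort_io.read_track(p, "promoter")
        assert len(track.intervals) == 3

    def test_label_preserved(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text("1\t100\t107\tmiR-21 seed\n")
        track = cohort_io.read_track(p, "mirna_target")
        assert track.intervals[0][3] == "miR-21 seed"

    def test_unsorted_bed_sorted_on_read(self, tmp_path):
        import random

        rng = random.Random(7)
        rows = [
            (str(rng.choice([1, 2, 10, "X"])), rng.randrange(0, 1000))
            for _ in range(50)
        ]
        p = tmp_path / "u.bed"
        p.write_text("".join(f"{c}\t{s}\t{s + 5}\n" for c, s in rows))
        track = cohort_io.read_track(p, "tfbs")
        from famprio.types import chrom_sort_key

        expected = sorted(
            [(str(c), s, s + 5, None) for c, s in rows],
            key=lambda iv: (chrom_sort_key(iv[0]), iv[1], iv[2]),
        )
        assert track.intervals == expected

    def test_invalid_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("1\t20\t10\n")
        with pytest.raises(ValueError, match="line 1"):
            cohort_io.read_track(p, "enhancer")


class TestReadPanel:
    def test_symbols_uppercased(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("symbol\tcategory\nptch1\tAutosomal Dominant\n")
        panel = cohort_io.read_panel(p)
        assert "PTCH1" in panel.entries

    def test_duplicate_keeps_first(self, tmp_path, caplog):
        p = tmp_path / "p.tsv"
        p.write_text("symbol\tcategory\nTP53\tA\nTP53\tB\n")
        import logging

        with caplog.at_level(logging.WARNING):
            panel = cohort_io.read_panel(p)
        assert panel.entries["TP53"] == "A"
        assert any("TP53" in r.message for r in caplog.records)

    def test_empty_panel_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("symbol\tcategory\n")
        with pytest.raises(ValueError, match="empty"):
            cohort_io.read_panel(p)

    def test_565_entry_panel_roundtrip(self, tmp_path, bundle):
        path = tmp_path / "cpg.tsv"
        cohort_io.write_panel(bundle.cpg_panel, path)
        again = cohort_io.read_panel(path)
        assert len(again) == 565
        assert again.category("DICER1") == "Autosomal Dominant"


class TestPedigreeInvariants:
    def test_self_ancestor_rejected(self):
        with pytest.raises(ValueError, match="ancestor"):
            Pedigree(
                "F",
                [
                    Sample("A", "F", father_id="B", sex="male", role="case"),
                    Sample("B", "F", father_id="A", sex="male", role="control"),
                ],
            )

    def test_family_without_case_rejected(self):
        with pytest.raises(ValueError, match="no case"):
            Pedigree("F", [Sample("A", "F", role="control")])
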