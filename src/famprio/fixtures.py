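"""Worked-example fixtures: the published candidate tables as data.

The underlying patient sequencing data are confidential, so the
pipeline's worked examples are reconstructed from the printed
per-family candidate tables of the source study: 36 missense and 9
truncating coding candidates with their CADD / Int (n/3) / Del (n/10) /
aggregated-verdict values, the 11 cancer-predisposition-panel hits, the
25 familial-HL-panel hits, and the three family pedigrees. Genotypes,
per-tool call patterns consistent with the printed vote counts, panel
filler symbols and the non-coding per-category fixture are synthetic
reconstructions (the printed sources give counts and thresholds, not
raw data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .types import (
    INTOLERANCE_SOURCES,
    MISSENSE_PREDICTORS,
    NONSENSE_PREDICTORS,
    AnnotatedVariant,
    GeneModel,
    GenePanel,
    GenotypeCall,
    Pedigree,
    RegulatoryTrack,
    Sample,
    StructuralVariantRecord,
    parse_variant_id,
)

# ---------------------------------------------------------------------------
# Published coding candidates
# ---------------------------------------------------------------------------

# (family, variant_id, genes, protein effect, CADD PHRED, Int n/3, Del n/10)
# Int "." = no intolerance source reported for the gene.
MISSENSE_TABLE: tuple[tuple, ...] = (
    ("Family_1", "17_48746518_C_T", "ABCC3", "p.P652L", 22.6, 2, 7),
    ("Family_1", "1_49052793_G_A", "AGBL4", "p.R384C", 35, 2, 7),
    ("Family_1", "5_139909090_A_G", "ANKHD1,ANKHD1-EIF4EBP3", "p.N2187D", 25.2, None, 6),
    ("Family_1", "1_160164884_T_C", "CASQ1", "p.I183T", 26.5, 2, 10),
    ("Family_1", "14_95560456_A_C", "DICER1", "p.I1711M", 24, 3, 7),
    ("Family_1", "6_159206584_G_A", "EZR", "p.P75L", 32, 3, 9),
    ("Family_1", "12_8192537_G_A", "FOXJ2", "p.G37R", 29.9, 3, 9),
    ("Family_1", "14_88729713_C_T", "KCNK10", "p.A79T", 27.1, 3, 6),
    ("Family_1", "10_88705360_G_A", "MMRN2", "p.P58L", 29.8, 2, 7),
    ("Family_1", "5_36962227_G_A", "NIPBL", "p.R154Q", 27.5, 3, 8),
    ("Family_1", "2_206614449_A_G", "NRP2", "p.D596G", 23.1, 2, 9),
    ("Family_1", "1_45268632_C_T", "PLK3", "p.T252M", 25.3, 3, 6),
    ("Family_1", "19_45515485_T_C", "RELB", "p.I152T", 26, 3, 6),
    ("Family_1", "6_52372363_G_C", "TRAM2", "p.A205G", 29.8, 3, 10),
    ("Family_1", "22_18613830_C_T", "TUBA8", "p.A450V", 24.7, 3, 10),
    ("Family_1", "X_47272364_G_A", "ZNF157", "p.G298R", 27.6, 2, 6),
    ("Family_2", "9_116151739_G_C", "ALAD", "p.I243M", 22.9, 2, 6),
    ("Family_2", "9_131196759_G_T", "CERCAM", "p.A468S", 24.5, 2, 7),
    ("Family_2", "9_131367689_C_T", "SPTAN1", "p.R1327C", 34, 3, 6),
    ("Family_3", "9_139917418_C_T", "ABCA2", "p.G83S", 26.3, 2, 7),
    ("Family_3", "17_40971572_G_C", "BECN1", "p.P85R", 23.4, 3, 6),
    ("Family_3", "8_67968830_G_T", "COPS5", "p.P131T", 23.9, 3, 9),
    ("Family_3", "3_5246773_C_T", "EDEM1", "p.T160M", 34, 3, 9),
    ("Family_3", "6_131191103_G_A", "EPB41L2", "p.S736F", 22.1, 3, 7),
    ("Family_3", "8_28575243_G_A", "EXTL3", "p.R172H", 23, 3, 6),
    ("Family_3", "3_188123979_A_T", "LPP", "p.E24V", 32, 2, 6),
    ("Family_3", "14_74970734_C_T", "LTBP2", "p.G1493R", 27.7, 3, 10),
    ("Family_3", "3_196730925_C_A", "MFI2", "p.D662Y", 34, 3, 6),
    ("Family_3", "17_27441099_G_A", "MYO18A", "p.A843V", 24.3, 3, 6),
    ("Family_3", "19_14584756_A_G", "PTGER1", "p.L126P", 25.9, 2, 6),
    ("Family_3", "3_49138083_G_A", "QARS", "p.R301C", 34, 2, 9),
    ("Family_3", "17_33428327_G_A", "RAD51D,RAD51L3-RFFL", "p.R266C", 27, 3, 8),
    ("Family_3", "11_9838541_C_T", "SBF2", "p.R1275H", 33, 2, 9),
    ("Family_3", "9_17761502_A_G", "SH3GL2", "p.N14S", 26.1, 3, 9),
    ("Family_3", "20_35467682_G_A", "SOGA1", "p.R46C", 32, 3, 7),
    ("Family_3", "1_43891311_G_A", "SZT2", "p.A96T", 31, 3, 6),
)

# (family, variant_id, gene, functional class, effect, CADD, Int n/3,
#  pathogenic votes among the 8 aggregated predictors, printed verdict)
NONSENSE_TABLE: tuple[tuple, ...] = (
    ("Family_1", "10_88911115_AGT_A", "FAM35A", "frameshift_deletion", "p.2_2del",
     25.8, 2, 0, "PM2"),
    ("Family_1", "3_148802664_C_T", "HLTF", "stopgain_snv", "p.W11X",
     37, 2, 4, "PP3 (4)"),
    ("Family_1", "1_177923437_CTG_C", "SEC16B", "frameshift_deletion", "p.481_481del",
     36, 0, 0, "Uncertain significance"),
    ("Family_1", "15_91546350_TG_T", "VPS33B", "frameshift_deletion", "p.P321fs",
     36, 3, 0, "PVS1"),
    ("Family_3", "7_31683260_AT_A", "CCDC129", "frameshift_deletion", "p.D611fs",
     34, 0, 0, "Uncertain significance"),
    ("Family_3", "1_21267855_C_T", "EIF4G3", "stopgain_snv", "p.W7X",
     14.54, 2, 1, "PVS1, PP3 (1)"),
    ("Family_3", "3_188123978_G_T", "LPP", "stopgain_snv", "p.E24X",
     40, 2, 4, "PM2, PP3 (4)"),
    ("Family_3", "15_24921469_G_A", "NPAP1", "stopgain_snv", "p.W152X",
     24.8, 0, 3, "PM2, PP3 (3)"),
    ("Family_3", "1_241958547_CAG_C", "WDR64", "frameshift_deletion", "p.836_836del",
     37, 0, 0, "Uncertain significance"),
)

# ---------------------------------------------------------------------------
# Published panel-screen tables
# ---------------------------------------------------------------------------

# Cancer-predisposition panel hits:
# (gene, family, variant_id, variant type, classification, CADD, category)
CPG_HIT_TABLE: tuple[tuple, ...] = (
    ("NCOA2", "Family_1", "8_71316112_T_TCCTCCTCCC", "Indel", "Upstream", 15.56,
     "Other CancerGene"),
    ("FUBP1", "Family_1", "1_78414225_A_G", "SNVs", "UTR3", 13.59, "Other CancerGene"),
    ("SEPT6", "Family_1", "X_118751062_CGTGT_C", "Indel", "UTR3", 10.56,
     "Other CancerGene"),
    ("DICER1", "Family_1", "14_95560456_A_C", "SNVs", "Non-synonymous SNV", 24,
     "Autosomal Dominant"),
    ("EZR", "Family_1", "6_159206584_G_A", "SNVs", "Non-synonymous SNV", 32,
     "Other CancerGene"),
    ("BCL6", "Family_3", "3_187463568_C_A", "SNVs", "Upstream; downstream", 13,
     "Other CancerGene"),
    ("LPP", "Family_3", "3_188123978_G_T", "SNVs", "Stopgain SNV", 40,
     "Other CancerGene"),
    ("LPP", "Family_3", "3_188123979_A_T", "SNVs", "Non-synonymous SNV", 32,
     "Other CancerGene"),
    ("LPP", "Family_3", "3_188608373_A_T", "SNVs", "UTR3", 10.5, "Other CancerGene"),
    ("RAD51D", "Family_3", "17_33428327_G_A", "SNVs", "Non-synonymous SNV", 27,
     "Other CancerGene"),
    ("PTCH1", "Family_3", "9_98270531_C_A", "SNVs", "Non-synonymous SNV", 20.4,
     "Autosomal Dominant"),
)

# Familial-HL candidate-panel hits:
# (gene, family, variant_id, CADD, variant type, consequence)
HL_HIT_TABLE: tuple[tuple, ...] = (
    ("ABHD16A", "Family_3", "6_31671105_G_A", 13.23, "SNVs", "UTR5"),
    ("C6orf62", "Family_3", "6_24705773_T_C", 12.31, "SNVs", "UTR3"),
    ("CEP120", "Family_1", "5_122681069_C_T", 12.31, "SNVs", "UTR3"),
    ("EDEM1", "Family_3", "3_5246773_C_T", 34, "SNVs", "Non-synonymous SNV"),
    ("EIF4G3", "Family_3", "1_21267855_C_T", 14.54, "SNVs", "stopgain SNV"),
    ("EPB41L2", "Family_3", "6_131191103_G_A", 22.1, "SNVs", "Non-synonymous SNV"),
    ("EXTL3", "Family_3", "8_28575243_G_A", 23, "SNVs", "Non-synonymous SNV"),
    ("FAM35A", "Family_1", "10_88911115_AGT_A", 25.8, "Indel", "Frameshift deletion"),
    ("FUK", "Family_1", "16_70501193_C_T", 10.08, "SNVs", "UTR3"),
    ("HLTF", "Family_1", "3_148802664_C_T", 37, "SNVs", "stopgain SNV"),
    ("LPP", "Family_3", "3_188608373_A_T", 10.5, "SNVs", "UTR3"),
    ("LPP", "Family_3", "3_188123978_G_T", 40, "SNVs", "stopgain SNV"),
    ("LPP", "Family_3", "3_188123979_A_T", 32, "SNVs", "Non-synonymous SNV"),
    ("LRP6", "Family_3",
     "12_12272924_AATATATATATATATATATATATATATATATATATATAT_A", 12.55, "Indel", "UTR3"),
    ("LTBP2", "Family_3", "14_74970734_C_T", 27.7, "SNVs", "Non-synonymous SNV"),
    ("MAPKAP1", "Family_3", "9_128199770_TAA_T", 14.3, "Indel", "UTR3"),
    ("MARCH10", "Family_3", "17_60885673_G_A", 12.03, "SNVs", "UTR5"),
    ("MYO18A", "Family_3", "17_27441099_G_A", 24.3, "SNVs", "Non-synonymous SNV"),
    ("NCAM1", "Family_1", "11_113134920_C_A", 11.07, "SNVs", "UTR3"),
    ("NIPBL", "Family_1", "5_36962227_G_A", 27.5, "SNVs", "Non-synonymous SNV"),
    ("PHC2", "Family_3", "1_33896663_C_A", 15.12, "SNVs", "upstream"),
    ("RCN1", "Family_3", "11_32112681_C_T", 10.66, "SNVs", "UTR5"),
    ("SBF2", "Family_3", "11_9838541_C_T", 33, "SNVs", "Non-synonymous SNV"),
    ("SLMAP", "Family_1", "3_57742023_C_G", 13.51, "SNVs", "UTR5"),
    ("SZT2", "Family_3", "1_43891311_G_A", 31, "SNVs", "Non-synonymous SNV"),
)

#: Published per-family UTR variant counts after pedigree filtering.
UTR_COUNTS = {
    "utr5": {"Family_1": 130, "Family_2": 5, "Family_3": 314},
    "utr3": {"Family_1": 347, "Family_2": 10, "Family_3": 497},
}

#: Published per-category non-coding retention counts (cohort-wide):
#: 4 TFBS + 15 promoter + 4 super-enhancer on the 5' side, 56 miRNA-seed
#: on the 3' side = 79 non-coding candidates.
NONCODING_CATEGORY_COUNTS = {
    "tfbs": 4,
    "promoter": 15,
    "super_enhancer": 4,
    "mirna_target": 56,
}

# Categories of the 565-gene cancer-predisposition panel with the
# published per-category gene counts.
CPG_PANEL_COMPOSITION = (
    ("Autosomal Dominant", 60),
    ("Autosomal Recessive", 29),
    ("Tumor-Suppressor", 58),
    ("Tyrosine Kinase", 23),
    ("Other CancerGene", 395),
)

CPG_PANEL_SIZE = 565
HL_PANEL_SIZE = 2383


# ---------------------------------------------------------------------------
# Pedigrees of the three families
# ---------------------------------------------------------------------------

def family_pedigrees() -> dict[str, Pedigree]:
    """The three family structures.

    Family 1: affected mother and daughter, unaffected father.
    Family 2: three affected siblings, their unaffected parent as
    obligate carrier, and five unaffected relatives as controls (one
    with a non-HL malignancy, sequenced as a control).
    Family 3: two affected siblings; one parent expected to carry and
    treated as obligate carrier, the other as control.
    """
    fam1 = Pedigree(
        "Family_1",
        [
            Sample("II-1", "Family_1", sex="male", role="control"),
            Sample("II-2", "Family_1", sex="female", role="case"),
            Sample("III-1", "Family_1", father_id="II-1", mother_id="II-2",
                   sex="female", role="case"),
        ],
    )
    fam2 = Pedigree(
        "Family_2",
        [
            Sample("II-1", "Family_2", sex="female", role="control"),
            Sample("II-6", "Family_2", sex="female", role="obligate_carrier"),
            Sample("III-1", "Family_2", mother_id="II-1", sex="female", role="control"),
            Sample("III-2", "Family_2", mother_id="II-1", sex="male", role="control"),
            Sample("III-3", "Family_2", mother_id="II-6", sex="male", role="case"),
            Sample("III-4", "Family_2", mother_id="II-6", sex="female", role="case"),
            Sample("III-5", "Family_2", mother_id="II-6", sex="male", role="case"),
            Sample("III-6", "Family_2", sex="female", role="control"),
            Sample("III-8", "Family_2", sex="male", role="control"),
        ],
    )
    fam3 = Pedigree(
        "Family_3",
        [
            Sample("I-1", "Family_3", sex="male", role="obligate_carrier"),
            Sample("I-2", "Family_3", sex="female", role="control"),
            Sample("II-1", "Family_3", father_id="I-1", mother_id="I-2",
                   sex="male", role="case"),
            Sample("II-2", "Family_3", father_id="I-1", mother_id="I-2",
                   sex="female", role="case"),
        ],
    )
    return {p.family_id: p for p in (fam1, fam2, fam3)}


def _segregating_genotypes(ped: Pedigree) -> list[GenotypeCall]:
    """Synthetic genotypes matching perfect dominant segregation:
    cases and obligate carriers heterozygous, controls homozygous ref."""
    calls = []
    for s in ped.samples:
        carrier = s.role in ("case", "obligate_carrier")
        calls.append(
            GenotypeCall(
                sample_id=s.sample_id,
                dosage=1 if carrier else 0,
                depth=30,
                quality=99.0,
                forward_alt_reads=7 if carrier else 0,
                reverse_alt_reads=8 if carrier else 0,
            )
        )
    return calls


def _calls(names, n_positive, positive, negative):
    return {
        name: (positive if i < n_positive else negative)
        for i, name in enumerate(names)
    }


def _int_flags(n: Optional[int]) -> dict[str, Optional[str]]:
    if n is None:
        return {s: None for s in INTOLERANCE_SOURCES}
    return _calls(INTOLERANCE_SOURCES, n, "intolerant", "tolerant")


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrioritizedRecord:
    """Lightweight screened record: what panel screening needs to see."""

    variant_id: str
    gene_symbols: tuple[str, ...]
    family_id: str = ""
    variant_type: str = ""
    variant_classification: str = ""
    cadd_phred: Optional[float] = None


@dataclass
class FixtureBundle:
    """Everything the worked examples need, reconstructed from print."""

    pedigrees: dict[str, Pedigree]
    coding_variants: list[AnnotatedVariant]
    coding_families: dict[str, str]  # variant_id -> family_id
    cpg_panel: GenePanel
    hl_panel: GenePanel
    cpg_records: list[PrioritizedRecord]
    hl_records: list[PrioritizedRecord]
    noncoding_variants: list[AnnotatedVariant]
    noncoding_tracks: list[RegulatoryTrack]
    noncoding_gene_model: dict[str, GeneModel]
    sv_records: list[StructuralVariantRecord]
    sv_gene_model: dict[str, GeneModel]
    utr_counts: dict[str, dict[str, int]] = field(default_factory=lambda: dict(UTR_COUNTS))

    def coding_by_family(self, family_id: str) -> list[AnnotatedVariant]:
        return [
            v for v in self.coding_variants
            if self.coding_families[v.variant_id] == family_id
        ]


def _coding_variants(pedigrees: dict[str, Pedigree]) -> tuple[list[AnnotatedVariant], dict[str, str]]:
    variants: list[AnnotatedVariant] = []
    families: dict[str, str] = {}
    for fam, vid, genes, effect, cadd, int_n, del_n in MISSENSE_TABLE:
        chrom, pos, ref, alt = parse_variant_id(vid)
        v = AnnotatedVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            variant_class="snv",
            site_quality=100.0, site_coverage=30,
            genotypes=_segregating_genotypes(pedigrees[fam]),
            gene_symbols=tuple(genes.split(",")),
            functional_class="nonsynonymous_snv",
            protein_effect=effect,
            cadd_phred=float(cadd),
            missense_calls=_calls(MISSENSE_PREDICTORS, del_n, "deleterious", "tolerated"),
            intolerance_flags=_int_flags(int_n),
        )
        variants.append(v)
        families[vid] = fam
    for fam, vid, gene, fclass, effect, cadd, int_n, votes, _printed in NONSENSE_TABLE:
        chrom, pos, ref, alt = parse_variant_id(vid)
        v = AnnotatedVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            variant_class="snv" if len(ref) == 1 and len(alt) == 1 else "indel",
            site_quality=100.0, site_coverage=30, platypus_pass=True,
            genotypes=_segregating_genotypes(pedigrees[fam]),
            gene_symbols=(gene,),
            functional_class=fclass,
            protein_effect=effect,
            cadd_phred=float(cadd),
            nonsense_calls=_calls(NONSENSE_PREDICTORS, votes, "pathogenic", "benign"),
            intolerance_flags=_int_flags(int_n),
        )
        variants.append(v)
        families[vid] = fam
    return variants, families


def _cpg_panel() -> GenePanel:
    """565-entry cancer-predisposition panel: the published hit genes plus
    synthetic filler symbols to the published per-category totals."""
    entries: dict[str, str] = {"CHEK2": "Autosomal Dominant"}
    for gene, *_rest, category in CPG_HIT_TABLE:
        entries.setdefault(gene, category)
    counts = {cat: 0 for cat, _ in CPG_PANEL_COMPOSITION}
    for cat in entries.values():
        counts[cat] += 1
    filler_i = 0
    for cat, total in CPG_PANEL_COMPOSITION:
        while counts[cat] < total:
            filler_i += 1
            entries[f"SYNCPG{filler_i:04d}"] = cat
            counts[cat] += 1
    assert len(entries) == CPG_PANEL_SIZE
    return GenePanel("cpg565", entries)


def _hl_panel() -> GenePanel:
    """2,383-entry familial-HL candidate panel: published matched genes
    plus synthetic filler symbols."""
    entries = {gene: "HL candidate" for gene, *_ in HL_HIT_TABLE}
    filler_i = 0
    while len(entries) < HL_PANEL_SIZE:
        filler_i += 1
        entries[f"SYNHL{filler_i:04d}"] = "HL candidate"
    return GenePanel("hl2383", entries)


def _noncoding_fixture(
    pedigrees: dict[str, Pedigree],
) -> tuple[list[AnnotatedVariant], list[RegulatoryTrack], dict[str, GeneModel]]:
    """Per-category non-coding fixture with the published counts planted.

    Synthetic positions: one 3'-side gene whose UTR holds the 56
    miRNA-seed variants, and one 5'-side gene whose UTR holds the
    promoter / TFBS / super-enhancer variants (15 / 4 / 4, disjoint).
    """
    gene_model = {
        "NCGENE3P": GeneModel("NCGENE3P", "1", "+", 10_000, 20_000),
        "NCGENE5P": GeneModel("NCGENE5P", "2", "+", 50_000, 60_000),
    }
    fams = list(pedigrees)
    variants: list[AnnotatedVariant] = []
    mirna_iv, promoter_iv, tfbs_iv, se_iv = [], [], [], []

    def add_variant(chrom, pos0, gene, fclass, cadd, mirsvr=None):
        v = AnnotatedVariant(
            chrom=chrom, pos=pos0 + 1, ref="A", alt="G",
            site_quality=100.0, site_coverage=30,
            genotypes=_segregating_genotypes(pedigrees[fams[len(variants) % 3]]),
            gene_symbols=(gene,),
            functional_class=fclass,
            cadd_phred=cadd,
            mirsvr=mirsvr,
        )
        variants.append(v)
        return v

    # 3' side: 56 miRNA-seed variants inside the 3' UTR
    for i in range(NONCODING_CATEGORY_COUNTS["mirna_target"]):
        pos0 = 19_000 + 10 * i
        add_variant("1", pos0, "NCGENE3P", "utr3", 13.59, mirsvr=-0.1 - 0.01 * i)
        mirna_iv.append(("1", pos0, pos0 + 7, f"miR-{i:03d} seed"))
    # 5' side: promoter, TFBS and super-enhancer variants in the 5' UTR
    cursor = 50_100
    for i in range(NONCODING_CATEGORY_COUNTS["promoter"]):
        add_variant("2", cursor, "NCGENE5P", "utr5", 15.0)
        promoter_iv.append(("2", cursor - 2, cursor + 3, f"promoter_{i:02d}"))
        cursor += 50
    for i in range(NONCODING_CATEGORY_COUNTS["tfbs"]):
        add_variant("2", cursor, "NCGENE5P", "utr5", 12.0)
        tfbs_iv.append(("2", cursor - 2, cursor + 3, f"tfbs_{i:02d}"))
        cursor += 50
    for i in range(NONCODING_CATEGORY_COUNTS["super_enhancer"]):
        add_variant("2", cursor, "NCGENE5P", "utr5", 18.0)
        se_iv.append(("2", cursor - 2, cursor + 3, f"se_{i:02d}"))
        cursor += 50

    tracks = [
        RegulatoryTrack("mirna_targets_synth", "mirna_target", mirna_iv),
        RegulatoryTrack("promoters_synth", "promoter", promoter_iv),
        RegulatoryTrack("tfbs_synth", "tfbs", tfbs_iv),
        RegulatoryTrack("super_enhancers_synth", "super_enhancer", se_iv),
    ]
    return variants, tracks, gene_model


def _sv_fixture(pedigrees: dict[str, Pedigree]) -> tuple[list[StructuralVariantRecord], dict[str, GeneModel]]:
    """The family-1 CHEK2 exon 9-10 deletion plus a common decoy."""
    gene_model = {
        "CHEK2": GeneModel("CHEK2", "22", "-", 29_083_730, 29_137_822),
    }
    case_ids = tuple(s.sample_id for s in pedigrees["Family_1"].cases)
    svs = [
        StructuralVariantRecord(
            chrom="22", start=29_090_000, end=29_095_400, sv_type="deletion",
            filter_pass=True, carrier_sample_ids=case_ids, gnomad_overlap_af=None,
        ),
        StructuralVariantRecord(
            chrom="22", start=29_200_000, end=29_260_000, sv_type="deletion",
            filter_pass=True, carrier_sample_ids=case_ids, gnomad_overlap_af=0.05,
        ),
    ]
    return svs, gene_model


def build_paper_fixtures() -> FixtureBundle:
    """Assemble the full worked-example bundle from the embedded tables."""
    pedigrees = family_pedigrees()
    coding, coding_families = _coding_variants(pedigrees)
    nc_variants, nc_tracks, nc_model = _noncoding_fixture(pedigrees)
    svs, sv_model = _sv_fixture(pedigrees)
    return FixtureBundle(
        pedigrees=pedigrees,
        coding_variants=coding,
        coding_families=coding_families,
        cpg_panel=_cpg_panel(),
        hl_panel=_hl_panel(),
        cpg_records=[
            PrioritizedRecord(
                variant_id=vid,
                gene_symbols=(gene,),
                family_id=fam,
                variant_type=vtype,
                variant_classification=vclass,
                cadd_phred=float(cadd),
            )
            for gene, fam, vid, vtype, vclass, cadd, _cat in CPG_HIT_TABLE
        ],
        hl_records=[
            PrioritizedRecord(
                variant_id=vid,
                gene_symbols=(gene,),
                family_id=fam,
                variant_type=vtype,
                variant_classification=vclass,
                cadd_phred=float(cadd),
            )
            for gene, fam, vid, cadd, vtype, vclass in HL_HIT_TABLE
        ],
        noncoding_variants=nc_variants,
        noncoding_tracks=nc_tracks,
        noncoding_gene_model=nc_model,
        sv_records=svs,
        sv_gene_model=sv_model,
    )
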