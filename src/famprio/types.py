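"""Core domain types for familial variant prioritization.

A cohort is a set of families sequenced jointly; every variant call is
joined with its functional annotation (population frequencies, CADD,
conservation, per-tool effect predictions, gene intolerance) into one
:class:`AnnotatedVariant` record, and the pedigree supplies the
case/control/obligate-carrier roles that drive segregation filtering.

Coordinate conventions: VCF positions and ``variant_id`` are 1-based;
all interval arithmetic (regulatory tracks, gene models, structural
variants) is 0-based half-open. An SNV at 1-based position p occupies
the interval [p-1, p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

#: The ten missense effect predictors whose deleterious/tolerated calls
#: feed the Del (n/10) consensus vote.
MISSENSE_PREDICTORS: tuple[str, ...] = (
    "SIFT",
    "PolyPhen2_HDIV",
    "PolyPhen2_HVAR",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "MetaSVM",
    "MetaLR",
    "PROVEAN",
)

#: The eight predictors behind the aggregated pathogenicity verdict for
#: truncating (stopgain/frameshift) variants.
NONSENSE_PREDICTORS: tuple[str, ...] = (
    "DANN",
    "MutationTaster",
    "FATHMM-MKL",
    "FATHMM-XF",
    "ALoFT",
    "EIGEN",
    "EIGEN-PC",
    "PrimateAI",
)

#: Gene-intolerance flag sources counted in Int (n/3).
INTOLERANCE_SOURCES: tuple[str, ...] = ("ESP6500", "ExAC", "local")

FUNCTIONAL_CLASSES = frozenset(
    {
        "nonsynonymous_snv",
        "synonymous_snv",
        "stopgain_snv",
        "frameshift_deletion",
        "frameshift_insertion",
        "utr5",
        "utr3",
        "upstream",
        "downstream",
        "intronic",
        "intergenic",
        "other",
    }
)

REGULATORY_CATEGORIES = (
    "mirna_target",
    "promoter",
    "enhancer",
    "super_enhancer",
    "tfbs",
    "cpg_island",
)

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome order: 1..22, X, Y, MT, then others lexically."""
    c = chrom.removeprefix("chr")
    return (_CHROM_ORDER.get(c, 99), c)


def make_variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}_{pos}_{ref}_{alt}"


def parse_variant_id(variant_id: str) -> tuple[str, int, str, str]:
    chrom, pos, ref, alt = variant_id.rsplit("_", 3)
    return chrom, int(pos), ref, alt


@dataclass(frozen=True)
class Sample:
    """One sequenced individual with pedigree links and an analysis role."""

    sample_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"  # male | female | unknown
    role: str = "unknown"  # case | control | obligate_carrier | unknown

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"invalid sex {self.sex!r} for sample {self.sample_id}")
        if self.role not in ("case", "control", "obligate_carrier", "unknown"):
            raise ValueError(f"invalid role {self.role!r} for sample {self.sample_id}")


@dataclass
class Pedigree:
    """A family: ordered samples with case/control/obligate-carrier roles.

    An obligate carrier is an unaffected individual who must carry the
    familial variant by pedigree position (e.g. the parent linking two
    affected branches); it is never counted as a control.
    """

    family_id: str
    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(
                f"duplicate sample_id in family {self.family_id}: {sorted(dupes)}"
            )
        known = set(ids)
        by_id = {s.sample_id: s for s in self.samples}
        for s in self.samples:
            for parent, want_sex in ((s.father_id, "male"), (s.mother_id, "female")):
                if parent is None:
                    continue
                if parent not in known:
                    raise ValueError(
                        f"sample {s.sample_id} in family {self.family_id} refers "
                        f"to unknown parent {parent}"
                    )
                psex = by_id[parent].sex
                if psex not in (want_sex, "unknown"):
                    raise ValueError(
                        f"parent {parent} of {s.sample_id} has incompatible sex {psex}"
                    )
        # no individual may be its own ancestor
        for s in self.samples:
            seen: set[str] = set()
            stack = [p for p in (s.father_id, s.mother_id) if p]
            while stack:
                a = stack.pop()
                if a == s.sample_id:
                    raise ValueError(
                        f"pedigree cycle: {s.sample_id} is its own ancestor"
                    )
                if a in seen or a not in by_id:
                    continue
                seen.add(a)
                anc = by_id[a]
                stack.extend(p for p in (anc.father_id, anc.mother_id) if p)
        if not self.cases:
            raise ValueError(f"family {self.family_id} has no case")

    @property
    def cases(self) -> list[Sample]:
        return [s for s in self.samples if s.role == "case"]

    @property
    def controls(self) -> list[Sample]:
        return [s for s in self.samples if s.role == "control"]

    @property
    def obligate_carriers(self) -> list[Sample]:
        return [s for s in self.samples if s.role == "obligate_carrier"]

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


@dataclass(frozen=True)
class GenotypeCall:
    """Per-sample genotype at one site.

    ``dosage`` counts alternate alleles (0/1/2, or None when the call is
    missing). Strand-resolved alt-read counts feed the strand-bias filter.
    """

    sample_id: str
    dosage: Optional[int]
    depth: Optional[int] = None
    quality: Optional[float] = None
    forward_alt_reads: Optional[int] = None
    reverse_alt_reads: Optional[int] = None

    def __post_init__(self) -> None:
        if self.dosage is not None and self.dosage not in (0, 1, 2):
            raise ValueError(f"dosage must be 0/1/2/None, got {self.dosage}")
        if (
            self.depth is not None
            and self.forward_alt_reads is not None
            and self.reverse_alt_reads is not None
            and self.forward_alt_reads + self.reverse_alt_reads > self.depth
        ):
            raise ValueError("strand alt reads exceed depth")

    @property
    def is_carrier(self) -> bool:
        return self.dosage is not None and self.dosage >= 1


@dataclass
class AnnotatedVariant:
    """One variant call joined with its full annotation.

    Missing annotation values are ``None``, never 0 — every downstream
    threshold states its own missing-value handling.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_class: str = "snv"  # snv | indel
    site_quality: Optional[float] = None
    site_coverage: Optional[int] = None
    platypus_pass: bool = True
    genotypes: list[GenotypeCall] = field(default_factory=list)
    gene_symbols: tuple[str, ...] = ()
    functional_class: str = "other"
    protein_effect: Optional[str] = None
    maf_1000g: Optional[float] = None
    maf_exac_nontcga: Optional[float] = None
    cadd_phred: Optional[float] = None
    gerp: Optional[float] = None
    phastcons: Optional[float] = None
    phylop: Optional[float] = None
    # predictor name -> "deleterious" | "tolerated" | None
    missense_calls: dict[str, Optional[str]] = field(default_factory=dict)
    # predictor name -> "pathogenic" | "benign" | None
    nonsense_calls: dict[str, Optional[str]] = field(default_factory=dict)
    # source -> "intolerant" | "tolerant" | None
    intolerance_flags: dict[str, Optional[str]] = field(default_factory=dict)
    pli: Optional[float] = None
    missense_z: Optional[float] = None
    mirsvr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional_class {self.functional_class!r}")
        if not self.missense_calls:
            self.missense_calls = {p: None for p in MISSENSE_PREDICTORS}
        if not self.nonsense_calls:
            self.nonsense_calls = {p: None for p in NONSENSE_PREDICTORS}
        if not self.intolerance_flags:
            self.intolerance_flags = {s: None for s in INTOLERANCE_SOURCES}
        if set(self.missense_calls) != set(MISSENSE_PREDICTORS):
            raise ValueError("missense_calls must have exactly the 10 known predictors")
        if set(self.nonsense_calls) != set(NONSENSE_PREDICTORS):
            raise ValueError("nonsense_calls must have exactly the 8 known predictors")
        if set(self.intolerance_flags) != set(INTOLERANCE_SOURCES):
            raise ValueError("intolerance_flags must have exactly the 3 known sources")

    @property
    def variant_id(self) -> str:
        return make_variant_id(self.chrom, self.pos, self.ref, self.alt)

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open interval occupied by the REF allele."""
        return self.pos - 1, self.pos - 1 + len(self.ref)

    def genotype(self, sample_id: str) -> Optional[GenotypeCall]:
        for g in self.genotypes:
            if g.sample_id == sample_id:
                return g
        return None

    def carriers(self) -> list[GenotypeCall]:
        return [g for g in self.genotypes if g.is_carrier]

    def int_count(self) -> int:
        """Int (n/3): number of sources flagging the gene intolerant."""
        return sum(1 for v in self.intolerance_flags.values() if v == "intolerant")


@dataclass
class RegulatoryTrack:
    """A named set of genomic intervals of one regulatory category.

    Intervals are 0-based half-open ``(chrom, start, end, label)`` and are
    kept sorted by (chrom, start); overlaps are retained as-is.
    """

    name: str
    category: str
    intervals: list[tuple[str, int, int, Optional[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in REGULATORY_CATEGORIES:
            raise ValueError(f"unknown track category {self.category!r}")
        for chrom, start, end, _ in self.intervals:
            if start >= end:
                raise ValueError(
                    f"interval start >= end in track {self.name}: {chrom}:{start}-{end}"
                )
        self.intervals.sort(key=lambda iv: (chrom_sort_key(iv[0]), iv[1], iv[2]))


@dataclass
class GenePanel:
    """Gene panel for screening: uppercase symbol -> category string."""

    name: str
    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fixed = {}
        for sym, cat in self.entries.items():
            if not sym:
                raise ValueError(f"empty gene symbol in panel {self.name}")
            fixed[sym.upper()] = cat
        self.entries = fixed

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.entries

    def category(self, symbol: str) -> Optional[str]:
        return self.entries.get(symbol.upper())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class StructuralVariantRecord:
    """A copy-number/structural call over a 1-based inclusive span."""

    chrom: str
    start: int
    end: int
    sv_type: str = "other"  # deletion | duplication | other
    filter_pass: bool = False
    carrier_sample_ids: tuple[str, ...] = ()
    gnomad_overlap_af: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"SV start > end: {self.chrom}:{self.start}-{self.end}")
        if self.sv_type not in ("deletion", "duplication", "other"):
            raise ValueError(f"unknown sv_type {self.sv_type!r}")

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open span."""
        return self.start - 1, self.end


@dataclass(frozen=True)
class GeneModel:
    """Transcript bounds for region assignment and SV-overlap tests.

    ``tx_start``/``tx_end`` are 0-based half-open on the genome; strand
    determines which end is the transcription start site.
    """

    gene: str
    chrom: str
    strand: str  # + | -
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise ValueError(f"gene {self.gene}: tx_start >= tx_end")

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        """0-based position of the transcription end site."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start
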