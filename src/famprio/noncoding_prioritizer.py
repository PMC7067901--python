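"""Non-coding variant prioritization.

Variants in untranslated regions and 1 kb gene flanks are assigned to a
5'-side (5' UTR or upstream-of-TSS) or 3'-side (3' UTR or
downstream-of-TES) context, strand-aware, then intersected with
regulatory interval tracks. Retention requires a CADD PHRED score > 10
plus positional evidence appropriate to the side: a predicted miRNA
target site for 3'-side variants; a promoter, enhancer, super-enhancer
or transcription-factor binding site for 5'-side variants. CpG-island
membership is recorded but is not a retention criterion.

3'-side candidates are ranked by mirSVR (a machine-learned
down-regulation score for miRNA target sites; more negative = stronger
predicted effect), 5'-side candidates by the breadth of regulatory
evidence.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .types import AnnotatedVariant, GeneModel, RegulatoryTrack, chrom_sort_key

logger = logging.getLogger(__name__)

#: Maximum distance (bases) from a gene edge for upstream/downstream
#: assignment; the bound is inclusive at exactly 1000.
FLANK_BP = 1000

#: Track categories that count as retention evidence per region side.
EVIDENCE_CATEGORIES = {
    "utr3_or_downstream": ("mirna_target",),
    "utr5_or_upstream": ("promoter", "enhancer", "super_enhancer", "tfbs"),
}


@dataclass
class RegionAssignment:
    variant_id: str
    region: str  # utr5_or_upstream | utr3_or_downstream | other
    distance_to_gene_edge: int = 0
    gene: Optional[str] = None


@dataclass
class NoncodingAssessment:
    variant_id: str
    region: str
    gene_symbols: tuple[str, ...]
    cadd_phred: Optional[float]
    cadd_pass: bool
    hits: dict[str, list[str]] = field(default_factory=dict)
    mirsvr: Optional[float] = None
    cpg_island: bool = False
    retained: bool = False
    rank: Optional[int] = None

    def evidence_categories(self) -> list[str]:
        valid = EVIDENCE_CATEGORIES.get(self.region, ())
        return [c for c in valid if self.hits.get(c)]


def _assign_for_gene(v: AnnotatedVariant, gm: GeneModel) -> Optional[tuple[str, int]]:
    """(region, distance) for one gene context, or None if not assignable."""
    pos0 = v.pos - 1
    if v.chrom != gm.chrom:
        return None
    inside = gm.tx_start <= pos0 < gm.tx_end
    if v.functional_class == "utr5":
        return ("utr5_or_upstream", 0) if inside else None
    if v.functional_class == "utr3":
        return ("utr3_or_downstream", 0) if inside else None
    if v.functional_class == "upstream":
        # upstream of a minus-strand gene lies at higher coordinates
        if gm.strand == "+":
            dist = gm.tx_start - pos0
        else:
            dist = pos0 - (gm.tx_end - 1)
        if 1 <= dist <= FLANK_BP:
            return ("utr5_or_upstream", dist)
        return None
    if v.functional_class == "downstream":
        if gm.strand == "+":
            dist = pos0 - (gm.tx_end - 1)
        else:
            dist = gm.tx_start - pos0
        if 1 <= dist <= FLANK_BP:
            return ("utr3_or_downstream", dist)
        return None
    return None


def assign_region(
    v: AnnotatedVariant, gene_model: Mapping[str, GeneModel]
) -> RegionAssignment:
    """Assign a variant to a UTR/flank window, strand-aware.

    UTR classes are assigned when the variant lies within the gene's
    transcript bounds; upstream/downstream classes require the variant
    within 1 kb (inclusive) of the strand-appropriate transcription
    start/end. Multi-gene annotations are tried in order; the first gene
    context that assigns wins. A gene missing from the model logs a
    warning and yields ``other``.
    """
    any_known = False
    for gene in v.gene_symbols:
        gm = gene_model.get(gene.upper())
        if gm is None:
            continue
        any_known = True
        result = _assign_for_gene(v, gm)
        if result is not None:
            region, dist = result
            return RegionAssignment(v.variant_id, region, dist, gene=gm.gene)
    relevant = v.functional_class in ("utr5", "utr3", "upstream", "downstream")
    if relevant and v.gene_symbols and not any_known:
        logger.warning(
            "variant %s: no gene of %s in gene model; region=other",
            v.variant_id,
            v.gene_symbols,
        )
    return RegionAssignment(v.variant_id, "other", 0)


def _build_trees(
    tracks: Iterable[RegulatoryTrack],
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for track in tracks:
        for chrom, start, end, label in track.intervals:
            trees[(track.category, chrom)].addi(start, end, (start, label or track.name))
    return trees


def intersect_tracks(
    variants: Sequence[AnnotatedVariant],
    assignments: Sequence[RegionAssignment],
    tracks: Sequence[RegulatoryTrack],
    cadd_cutoff: float = 10.0,
) -> list[NoncodingAssessment]:
    """Intersect each assigned variant with every regulatory track.

    Containment is 0-based half-open on the variant's position; hit
    labels per category are reported in deterministic (start, label)
    order. CADD is evaluated here so that selection is a pure predicate
    on the assessment.
    """
    trees = _build_trees(tracks)
    by_id = {v.variant_id: v for v in variants}
    out = []
    for a in assignments:
        v = by_id[a.variant_id]
        pos0 = v.pos - 1
        hits: dict[str, list[str]] = {}
        for (category, chrom), tree in trees.items():
            if chrom != v.chrom:
                continue
            found = sorted(iv.data for iv in tree.at(pos0))
            if found:
                hits[category] = [label for _, label in found]
        out.append(
            NoncodingAssessment(
                variant_id=v.variant_id,
                region=a.region,
                gene_symbols=v.gene_symbols,
                cadd_phred=v.cadd_phred,
                cadd_pass=v.cadd_phred is not None and v.cadd_phred > cadd_cutoff,
                hits=hits,
                mirsvr=v.mirsvr,
                cpg_island=bool(hits.get("cpg_island")),
            )
        )
    return out


def select_noncoding(
    assessments: Sequence[NoncodingAssessment],
) -> tuple[list[NoncodingAssessment], dict[str, int]]:
    """Mark retained assessments and report per-category counts.

    Retained = CADD pass and at least one hit in a category valid for
    the region side. Counts are per evidence category, deduplicated by
    variant_id within a category; the total retained count deduplicates
    across categories.
    """
    retained = []
    counts: dict[str, int] = {c: 0 for cats in EVIDENCE_CATEGORIES.values() for c in cats}
    seen_per_cat: dict[str, set[str]] = defaultdict(set)
    for a in assessments:
        evidence = a.evidence_categories()
        a.retained = a.cadd_pass and bool(evidence)
        if a.retained:
            retained.append(a)
            for c in evidence:
                seen_per_cat[c].add(a.variant_id)
    for c, ids in seen_per_cat.items():
        counts[c] = len(ids)
    return retained, counts


def rank_noncoding(retained: Sequence[NoncodingAssessment]) -> list[NoncodingAssessment]:
    """Rank retained candidates within each region side.

    3'-side: ascending mirSVR (missing sorts last), then descending
    CADD. 5'-side: descending number of evidence categories, then
    descending CADD. Ties broken by genomic position. Rank is assigned
    1..n within each side.
    """

    def pos_key(a: NoncodingAssessment):
        chrom, pos, _, _ = a.variant_id.rsplit("_", 3)
        return (chrom_sort_key(chrom), int(pos))

    out = []
    three_side = [a for a in retained if a.region == "utr3_or_downstream"]
    five_side = [a for a in retained if a.region == "utr5_or_upstream"]
    three_side.sort(
        key=lambda a: (
            a.mirsvr if a.mirsvr is not None else math.inf,
            -(a.cadd_phred if a.cadd_phred is not None else -math.inf),
            pos_key(a),
        )
    )
    five_side.sort(
        key=lambda a: (
            -len(a.evidence_categories()),
            -(a.cadd_phred if a.cadd_phred is not None else -math.inf),
            pos_key(a),
        )
    )
    for group in (three_side, five_side):
        for i, a in enumerate(group, 1):
            a.rank = i
        out.extend(group)
    return out


def prioritize_noncoding(
    variants: Sequence[AnnotatedVariant],
    gene_model: Mapping[str, GeneModel],
    tracks: Sequence[RegulatoryTrack],
    cadd_cutoff: float = 10.0,
) -> tuple[list[NoncodingAssessment], dict[str, int]]:
    """Full non-coding arm: assign regions, intersect tracks, select, rank."""
    assignments = [assign_region(v, gene_model) for v in variants]
    assessments = intersect_tracks(variants, assignments, tracks, cadd_cutoff)
    retained, counts = select_noncoding(assessments)
    rank_noncoding(retained)
    return assessments, counts
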