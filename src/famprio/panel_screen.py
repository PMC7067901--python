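"""Gene-panel screening and the rare structural-variant filter.

Prioritized variants are screened against curated gene panels (for
example a 565-gene cancer-predisposition panel, or a disease-specific
candidate list) by exact uppercased symbol match; multi-gene annotations
produce one hit per matching symbol but count once per variant.

Structural variants are retained when they carry a PASS filter, are
present in every case of the family, are not common in gnomAD
(overlap allele frequency <= 1%, missing treated as novel), and overlap
the transcript bounds of at least one panel gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Protocol, Sequence

from .types import (
    GeneModel,
    GenePanel,
    Pedigree,
    StructuralVariantRecord,
)


class PrioritizedLike(Protocol):
    """Anything carrying a variant_id and gene symbols can be screened."""

    variant_id: str
    gene_symbols: tuple[str, ...]


@dataclass(frozen=True)
class PanelHit:
    variant_id: str
    gene_symbol: str
    panel_name: str
    category: str
    variant_type: str = ""  # SNVs | Indel
    variant_classification: str = ""


@dataclass(frozen=True)
class PanelSummary:
    panel_name: str
    n_variants: int  # distinct variant_ids with >= 1 hit
    n_genes: int  # distinct matched symbols


def screen_panel(
    prioritized: Sequence[PrioritizedLike],
    panel: GenePanel,
    alias_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[PanelHit], PanelSummary]:
    """Match prioritized variants against a panel by gene symbol.

    ``alias_map`` optionally maps alternate symbols to panel symbols
    (e.g. from an HGNC alias file); matching is otherwise exact after
    uppercasing. Returns one hit per (variant, matched symbol) and a
    summary of distinct variants and genes hit.
    """
    hits: list[PanelHit] = []
    seen: set[tuple[str, str]] = set()
    for record in prioritized:
        for symbol in record.gene_symbols:
            sym = symbol.upper()
            if alias_map is not None:
                sym = alias_map.get(sym, sym).upper()
            category = panel.category(sym)
            if category is None:
                continue
            key = (record.variant_id, sym)
            if key in seen:
                continue
            seen.add(key)
            hits.append(
                PanelHit(
                    variant_id=record.variant_id,
                    gene_symbol=sym,
                    panel_name=panel.name,
                    category=category,
                    variant_type=getattr(record, "variant_type", ""),
                    variant_classification=getattr(record, "variant_classification", ""),
                )
            )
    summary = PanelSummary(
        panel_name=panel.name,
        n_variants=len({h.variant_id for h in hits}),
        n_genes=len({h.gene_symbol for h in hits}),
    )
    return hits, summary


def sv_overlaps_gene(sv: StructuralVariantRecord, gm: GeneModel) -> bool:
    """Any overlap of the SV span with transcript bounds (gene-level,
    not exon-resolved)."""
    if sv.chrom != gm.chrom:
        return False
    start0, end0 = sv.interval
    return start0 < gm.tx_end and gm.tx_start < end0


def filter_structural_variants(
    svs: Sequence[StructuralVariantRecord],
    ped: Pedigree,
    panel: GenePanel,
    gene_model: Mapping[str, GeneModel],
    max_gnomad_af: float = 0.01,
) -> list[StructuralVariantRecord]:
    """Rare, case-shared, panel-gene-affecting structural variants.

    Retained iff: caller PASS; every case of the family among the
    carriers; gnomAD overlap AF missing or <= ``max_gnomad_af`` (common
    SVs, AF > 1%, are removed); and the span overlaps >= 1 panel gene's
    transcript bounds.
    """
    case_ids = {s.sample_id for s in ped.cases}
    panel_models = [gm for gene, gm in gene_model.items() if gene in panel]
    retained = []
    for sv in svs:
        if not sv.filter_pass:
            continue
        if not case_ids <= set(sv.carrier_sample_ids):
            continue
        if sv.gnomad_overlap_af is not None and sv.gnomad_overlap_af > max_gnomad_af:
            continue
        if not any(sv_overlaps_gene(sv, gm) for gm in panel_models):
            continue
        retained.append(sv)
    return retained
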