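"""Tiered per-family candidate reports and pathway-input export.

Every retained variant appears exactly once in a family's report:
tier 1 if it hit at least one gene panel, tier 2 if retained by the
coding arm without a panel hit, tier 3 if retained by the non-coding
arm without a panel hit. Panel hits re-tier variants, never duplicate
them, so report totals are conserved:
|tier1| + |tier2| + |tier3| = |retained coding| + |retained noncoding|.

The pathway-analysis export is the distinct, sorted gene-symbol list of
retained segregating variants with CADD PHRED above a cutoff (default
20) that are neither intergenic nor intronic — the documented input set
for downstream pathway/network software, which is itself out of scope.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .basic_filters import FunnelCounts
from .coding_prioritizer import CodingAssessment
from .noncoding_prioritizer import NoncodingAssessment
from .panel_screen import PanelHit
from .types import AnnotatedVariant


@dataclass
class PrioritizedVariant:
    """One report row: a retained variant with its tier and evidence."""

    variant_id: str
    gene_symbols: tuple[str, ...]
    arm: str  # coding | noncoding
    category: str  # missense | nonsense | region side
    tier: int
    rank: Optional[int]
    cadd_phred: Optional[float]
    verdict_label: str = ""
    panel_names: tuple[str, ...] = ()


@dataclass
class CandidateReport:
    family_id: str
    rows: list[PrioritizedVariant] = field(default_factory=list)
    funnel: Optional[FunnelCounts] = None
    category_counts: dict[str, int] = field(default_factory=dict)

    def tier_counts(self) -> dict[int, int]:
        out = {1: 0, 2: 0, 3: 0}
        for r in self.rows:
            out[r.tier] += 1
        return out


def build_report(
    family_id: str,
    coding: Sequence[CodingAssessment],
    noncoding: Sequence[NoncodingAssessment],
    panel_hits: Sequence[PanelHit] = (),
    funnel: Optional[FunnelCounts] = None,
) -> CandidateReport:
    """Assemble one family's tiered candidate report.

    A variant retained by both arms is an annotation inconsistency and
    is rejected.
    """
    coding_ids = {a.variant_id for a in coding if a.retained}
    noncoding_ids = {a.variant_id for a in noncoding if a.retained}
    both = coding_ids & noncoding_ids
    if both:
        raise ValueError(
            f"variants retained by both coding and non-coding arms: {sorted(both)}"
        )
    hits_by_variant: dict[str, list[PanelHit]] = {}
    for h in panel_hits:
        hits_by_variant.setdefault(h.variant_id, []).append(h)

    rows = []
    category_counts: dict[str, int] = {
        c: 0
        for c in (
            "missense",
            "nonsense",
            "mirna_target",
            "promoter",
            "enhancer",
            "super_enhancer",
            "tfbs",
        )
    }
    for a in coding:
        if not a.retained:
            continue
        panels = tuple(sorted({h.panel_name for h in hits_by_variant.get(a.variant_id, [])}))
        rows.append(
            PrioritizedVariant(
                variant_id=a.variant_id,
                gene_symbols=a.gene_symbols,
                arm="coding",
                category=a.path,
                tier=1 if panels else 2,
                rank=a.rank,
                cadd_phred=a.cadd_phred,
                verdict_label=a.verdict_label,
                panel_names=panels,
            )
        )
        category_counts[a.path] += 1
    for a in noncoding:
        if not a.retained:
            continue
        panels = tuple(sorted({h.panel_name for h in hits_by_variant.get(a.variant_id, [])}))
        rows.append(
            PrioritizedVariant(
                variant_id=a.variant_id,
                gene_symbols=a.gene_symbols,
                arm="noncoding",
                category=a.region,
                tier=1 if panels else 3,
                rank=a.rank,
                cadd_phred=a.cadd_phred,
                verdict_label=";".join(a.evidence_categories()),
                panel_names=panels,
            )
        )
        for c in a.evidence_categories():
            category_counts[c] += 1
    rows.sort(key=lambda r: (r.tier, r.arm, r.rank if r.rank is not None else 1 << 30))
    return CandidateReport(
        family_id=family_id,
        rows=rows,
        funnel=funnel,
        category_counts=category_counts,
    )


def export_pathway_input(
    variants: Sequence[AnnotatedVariant],
    retained_ids: Iterable[str],
    cadd_cutoff: float = 20.0,
    path: Optional[str | os.PathLike] = None,
) -> list[str]:
    """Distinct sorted gene symbols for pathway-analysis input.

    Includes every gene of a retained, segregating variant with
    CADD PHRED > ``cadd_cutoff`` that is not intergenic or intronic.
    Optionally written one symbol per line.
    """
    retained = set(retained_ids)
    genes: set[str] = set()
    for v in variants:
        if v.variant_id not in retained:
            continue
        if v.functional_class in ("intergenic", "intronic"):
            continue
        if v.cadd_phred is None or v.cadd_phred <= cadd_cutoff:
            continue
        genes.update(g.upper() for g in v.gene_symbols)
    out = sorted(genes)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            for g in out:
                fh.write(g + "\n")
    return out


def write_report(report: CandidateReport, path: str | os.PathLike) -> None:
    """Deterministic TSV serialization of a candidate report."""
    rows = [
        {
            "family_id": report.family_id,
            "tier": r.tier,
            "arm": r.arm,
            "category": r.category,
            "rank": "." if r.rank is None else r.rank,
            "variant_id": r.variant_id,
            "genes": ",".join(r.gene_symbols),
            "cadd_phred": "." if r.cadd_phred is None else f"{r.cadd_phred:g}",
            "evidence": r.verdict_label,
            "panels": ",".join(r.panel_names),
        }
        for r in report.rows
    ]
    pd.DataFrame(
        rows,
        columns=[
            "family_id", "tier", "arm", "category", "rank", "variant_id",
            "genes", "cadd_phred", "evidence", "panels",
        ],
    ).to_csv(path, sep="\t", index=False)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_run_summary(
    path: str | os.PathLike,
    config: dict,
    reports: Sequence[CandidateReport],
) -> dict:
    """JSON run summary: per-family tier/category/funnel counts plus a
    hash of the configuration that produced them."""
    summary = {
        "config_hash": config_hash(config),
        "families": {},
    }
    for rep in reports:
        entry = {
            "tiers": {str(k): v for k, v in rep.tier_counts().items()},
            "categories": rep.category_counts,
        }
        if rep.funnel is not None:
            entry["funnel"] = [
                {"stage": s, "n_in": i, "n_out": o} for s, i, o in rep.funnel.counts
            ]
        summary["families"][rep.family_id] = entry
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
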