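"""Call-quality, strand-bias, frequency, and segregation filtering.

This is the funnel that takes raw joint-genotyped calls down to rare
variants consistent with dominant inheritance in the family: stages are
applied in the fixed order quality -> strand_bias -> frequency ->
segregation, each stage is a pure predicate on the variant (plus
pedigree for segregation), and per-stage input/survivor counts are
tracked per family.

Thresholds follow the conventional germline funnel: site quality > 20,
coverage > 5x, at least one alternate read on each strand for SNVs
(indels are instead required to pass their caller's internal filters),
and a minor allele frequency < 0.1% against both reference panels, with
an absent frequency meaning the variant is novel (treated as 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .types import AnnotatedVariant, Pedigree

logger = logging.getLogger(__name__)

STAGES = ("quality", "strand_bias", "frequency", "segregation")


@dataclass(frozen=True)
class FilterDecision:
    variant_id: str
    stage: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class SegregationPolicy:
    """Deterministic carrier-pattern policy for dominant segregation.

    ``max_control_carriers`` emulates tolerance for phenocopies or
    reduced penetrance among unaffected carriers; the default 0 is the
    strict dominant model. Under ``permissive`` missing-genotype
    handling a missing call in a case is ignored; under ``strict`` it
    fails the variant.
    """

    inheritance: str = "dominant"
    max_control_carriers: int = 0
    require_all_cases: bool = True
    obligate_carriers_must_carry: bool = True
    missing_genotype_handling: str = "permissive"  # permissive | strict

    def __post_init__(self) -> None:
        if self.inheritance != "dominant":
            raise ValueError("only the dominant model is supported")
        if self.missing_genotype_handling not in ("permissive", "strict"):
            raise ValueError("missing_genotype_handling must be permissive or strict")
        if self.max_control_carriers < 0:
            raise ValueError("max_control_carriers must be >= 0")


@dataclass
class FunnelCounts:
    """Per-stage input/survivor counts for one family."""

    family_id: str
    counts: list[tuple[str, int, int]] = field(default_factory=list)  # (stage, n_in, n_out)

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        self.counts.append((stage, n_in, n_out))

    def to_rows(self) -> list[dict]:
        return [
            {"family_id": self.family_id, "stage": s, "n_in": i, "n_out": o}
            for s, i, o in self.counts
        ]


def quality_filter(
    v: AnnotatedVariant, min_quality: float = 20.0, min_coverage: int = 5
) -> FilterDecision:
    """Pass iff site quality > 20 and coverage > 5x (both strict);
    indels must additionally carry their caller's PASS flag."""
    if v.site_quality is None or v.site_coverage is None:
        return FilterDecision(v.variant_id, "quality", False, "missing_metric")
    ok = v.site_quality > min_quality and v.site_coverage > min_coverage
    if v.variant_class == "indel":
        ok = ok and v.platypus_pass
    return FilterDecision(
        v.variant_id,
        "quality",
        ok,
        f"qual={v.site_quality:g} cov={v.site_coverage}"
        + ("" if v.variant_class == "snv" else f" caller_pass={v.platypus_pass}"),
    )


def strand_bias_filter(
    v: AnnotatedVariant, missing_strand: str = "pass"
) -> FilterDecision:
    """SNVs need >= 1 alternate read on each strand in some carrier;
    indels pass this stage unconditionally.

    ``missing_strand`` controls the case where no carrier has strand
    counts at all: ``"pass"`` (default, with a warning) or ``"fail"``.
    """
    if v.variant_class == "indel":
        return FilterDecision(v.variant_id, "strand_bias", True, "indel_not_applicable")
    carriers = v.carriers()
    informative = [
        g
        for g in carriers
        if g.forward_alt_reads is not None and g.reverse_alt_reads is not None
    ]
    if not informative:
        if missing_strand == "fail":
            return FilterDecision(v.variant_id, "strand_bias", False, "no_strand_info")
        if carriers:  # strand fields genuinely absent, not just no carriers
            logger.warning("variant %s has no strand information; passed", v.variant_id)
        return FilterDecision(v.variant_id, "strand_bias", True, "no_strand_info")
    ok = any(g.forward_alt_reads >= 1 and g.reverse_alt_reads >= 1 for g in informative)
    return FilterDecision(v.variant_id, "strand_bias", ok, f"informative_carriers={len(informative)}")


def frequency_filter(v: AnnotatedVariant, threshold: float = 0.001) -> FilterDecision:
    """Pass iff max(MAF over both panels) < threshold, strict; a missing
    frequency counts as 0 (novel variant)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    maf = max(v.maf_1000g or 0.0, v.maf_exac_nontcga or 0.0)
    return FilterDecision(v.variant_id, "frequency", maf < threshold, f"maf={maf:g}")


def segregation_filter(
    v: AnnotatedVariant, ped: Pedigree, policy: SegregationPolicy = SegregationPolicy()
) -> FilterDecision:
    """Dominant-model segregation against the family's roles.

    Under the default policy: every case with a non-missing genotype
    carries (dosage >= 1, counting hom-alt as a carrier), every obligate
    carrier with a non-missing genotype carries, and at most
    ``max_control_carriers`` controls carry. A male X-chromosome dosage
    of 1 is a carrier like any other.
    """
    known = set(ped.sample_ids())
    for g in v.genotypes:
        if g.sample_id not in known:
            raise ValueError(
                f"genotype sample {g.sample_id!r} not in pedigree {ped.family_id!r}"
            )
    dosages = {g.sample_id: g.dosage for g in v.genotypes}
    if not any(s.sample_id in dosages for s in ped.cases):
        raise ValueError(f"pedigree {ped.family_id!r} has zero genotyped cases")

    strict = policy.missing_genotype_handling == "strict"

    def observed(samples):
        out = []
        for s in samples:
            if s.sample_id in dosages:
                out.append(dosages[s.sample_id])
        return out

    case_dosages = observed(ped.cases)
    if strict and any(d is None for d in case_dosages):
        return FilterDecision(v.variant_id, "segregation", False, "missing_case_genotype")
    case_known = [d for d in case_dosages if d is not None]
    case_carriers = sum(1 for d in case_known if d >= 1)
    if policy.require_all_cases:
        cases_ok = case_carriers == len(case_known) and case_carriers > 0
    else:
        cases_ok = case_carriers > 0

    obligate_dosages = observed(ped.obligate_carriers)
    if strict and any(d is None for d in obligate_dosages):
        return FilterDecision(v.variant_id, "segregation", False, "missing_obligate_genotype")
    obligate_known = [d for d in obligate_dosages if d is not None]
    obligates_ok = (
        all(d >= 1 for d in obligate_known)
        if policy.obligate_carriers_must_carry
        else True
    )

    control_known = [d for d in observed(ped.controls) if d is not None]
    control_carriers = sum(1 for d in control_known if d >= 1)
    controls_ok = control_carriers <= policy.max_control_carriers

    detail = (
        f"cases {case_carriers}/{len(case_known)}; "
        f"controls {control_carriers}/{len(control_known)}"
    )
    if obligate_known:
        detail += f"; obligates {sum(1 for d in obligate_known if d >= 1)}/{len(obligate_known)}"
    return FilterDecision(
        v.variant_id, "segregation", cases_ok and obligates_ok and controls_ok, detail
    )


@dataclass(frozen=True)
class FunnelConfig:
    """Thresholds for the four-stage funnel."""

    min_quality: float = 20.0
    min_coverage: int = 5
    maf_threshold: float = 0.001
    missing_strand: str = "pass"
    policy: SegregationPolicy = SegregationPolicy()


def run_funnel(
    variants: Sequence[AnnotatedVariant],
    ped: Pedigree,
    config: FunnelConfig = FunnelConfig(),
) -> tuple[list[AnnotatedVariant], FunnelCounts]:
    """Apply all four stages in order; return survivors and per-stage counts."""
    counts = FunnelCounts(family_id=ped.family_id)
    current = list(variants)
    for stage in STAGES:
        n_in = len(current)
        survivors = []
        for v in current:
            if stage == "quality":
                d = quality_filter(v, config.min_quality, config.min_coverage)
            elif stage == "strand_bias":
                d = strand_bias_filter(v, config.missing_strand)
            elif stage == "frequency":
                d = frequency_filter(v, config.maf_threshold)
            else:
                d = segregation_filter(v, ped, config.policy)
            if d.passed:
                survivors.append(v)
        counts.add(stage, n_in, len(survivors))
        current = survivors
    return current, counts


def write_funnel_counts(
    counts: Iterable[FunnelCounts], path: str
) -> None:
    import pandas as pd

    rows = [r for c in counts for r in c.to_rows()]
    pd.DataFrame(rows, columns=["family_id", "stage", "n_in", "n_out"]).to_csv(
        path, sep="\t", index=False
    )
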