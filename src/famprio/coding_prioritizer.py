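"""Coding-variant prioritization cascade.

Family-segregating coding variants are split into a missense path
(non-synonymous SNVs) and a nonsense path (stopgain and frameshift).
Both require a scaled CADD PHRED score > 10 (top ~1% most deleterious
substitutions genome-wide) and, where conservation scores are present,
GERP > 2.0, PhastCons > 0.3 and PhyloP >= 3.0. Missense variants
additionally need a 60% consensus among up to ten effect predictors
(Del n/10); truncating variants carry an aggregated vote over eight
predictors as an annotation but are never excluded by it — printed
candidate lists retain rows of uncertain significance.

Gene intolerance (Int n/3, pLI, missense Z) is used only to rank
retained variants, never as a cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .types import AnnotatedVariant, chrom_sort_key

#: Minimum number of non-missing missense predictor calls for the
#: consensus vote to be meaningful.
MIN_CONSENSUS_TOOLS = 5


@dataclass
class CodingAssessment:
    """Per-variant outcome of the coding cascade."""

    variant_id: str
    path: str  # missense | nonsense
    gene_symbols: tuple[str, ...]
    cadd_phred: Optional[float]
    cadd_pass: bool
    conservation_pass: str  # pass | fail | not_applicable
    del_votes: int = 0
    del_available: int = 0
    varsome_votes: int = 0
    varsome_available: int = 0
    int_count: int = 0
    pli: Optional[float] = None
    missense_z: Optional[float] = None
    verdict_label: str = ""
    retained: bool = False
    rank: Optional[int] = None


def classify_path(v: AnnotatedVariant) -> str:
    """Route a variant to the missense or nonsense arm of the cascade."""
    if v.functional_class == "nonsynonymous_snv":
        return "missense"
    if v.functional_class in ("stopgain_snv", "frameshift_deletion", "frameshift_insertion"):
        return "nonsense"
    return "not_coding_candidate"


def cadd_filter(v: AnnotatedVariant, cutoff: float = 10.0) -> bool:
    """True iff CADD PHRED is present and strictly above the cutoff."""
    return v.cadd_phred is not None and v.cadd_phred > cutoff


def conservation_filter(v: AnnotatedVariant) -> str:
    """Conjunction over the conservation scores that are present.

    GERP > 2.0, PhastCons > 0.3, PhyloP >= 3.0 (note the non-strict
    PhyloP bound). When all three are absent the test is
    ``not_applicable`` and treated as a pass downstream, flagged in the
    report — conservation tracks do not cover every site.
    """
    checks = []
    if v.gerp is not None:
        checks.append(v.gerp > 2.0)
    if v.phastcons is not None:
        checks.append(v.phastcons > 0.3)
    if v.phylop is not None:
        checks.append(v.phylop >= 3.0)
    if not checks:
        return "not_applicable"
    return "pass" if all(checks) else "fail"


def consensus_deleteriousness(
    v: AnnotatedVariant, fraction: float = 0.6
) -> tuple[int, int, bool]:
    """Del (n/10) consensus for the missense path.

    Returns (deleterious votes, available calls, pass). Pass requires at
    least :data:`MIN_CONSENSUS_TOOLS` non-missing calls and votes >=
    ceil(fraction * available); with all ten tools reporting this is the
    familiar "at least 6 of 10" rule.
    """
    votes = sum(1 for c in v.missense_calls.values() if c == "deleterious")
    available = sum(1 for c in v.missense_calls.values() if c is not None)
    ok = available >= MIN_CONSENSUS_TOOLS and votes >= math.ceil(fraction * available)
    return votes, available, ok


def nonsense_verdict(v: AnnotatedVariant) -> tuple[int, str, bool]:
    """Aggregate pathogenicity vote for the nonsense path.

    Returns (pathogenic votes, verdict label, pass). The label is a
    declared convention over the vote count — ``no_support`` (0),
    ``supporting(k)`` (1-4), ``majority_pathogenic`` (>= 5) — and the
    votes annotate but never exclude: pass tracks the CADD filter alone.
    """
    votes = sum(1 for c in v.nonsense_calls.values() if c == "pathogenic")
    if votes == 0:
        label = "no_support"
    elif votes < 5:
        label = f"supporting({votes})"
    else:
        label = "majority_pathogenic"
    return votes, label, cadd_filter(v)


def _rank_key(a: CodingAssessment):
    primary_votes = a.del_votes if a.path == "missense" else a.varsome_votes
    chrom, pos, _, _ = a.variant_id.rsplit("_", 3)
    return (
        -a.int_count,
        -(a.cadd_phred if a.cadd_phred is not None else -math.inf),
        -primary_votes,
        chrom_sort_key(chrom),
        int(pos),
    )


def intolerance_rank(assessments: Sequence[CodingAssessment]) -> list[CodingAssessment]:
    """Total order over retained assessments: descending Int (n/3), then
    CADD, then the path's vote count, then genomic position. Returns a
    new list sorted with ``rank`` assigned 1..n."""
    ordered = sorted(assessments, key=_rank_key)
    for i, a in enumerate(ordered, 1):
        a.rank = i
    return ordered


def assess_coding(v: AnnotatedVariant, cadd_cutoff: float = 10.0) -> Optional[CodingAssessment]:
    """Run one variant through the cascade; None if not a coding candidate."""
    path = classify_path(v)
    if path == "not_coding_candidate":
        return None
    a = CodingAssessment(
        variant_id=v.variant_id,
        path=path,
        gene_symbols=v.gene_symbols,
        cadd_phred=v.cadd_phred,
        cadd_pass=cadd_filter(v, cadd_cutoff),
        conservation_pass=conservation_filter(v),
        int_count=v.int_count(),
        pli=v.pli,
        missense_z=v.missense_z,
    )
    if path == "missense":
        a.del_votes, a.del_available, consensus_ok = consensus_deleteriousness(v)
        a.verdict_label = f"del({a.del_votes}/{a.del_available})"
        a.retained = a.cadd_pass and a.conservation_pass != "fail" and consensus_ok
    else:
        a.varsome_votes, a.verdict_label, _ = nonsense_verdict(v)
        a.varsome_available = sum(1 for c in v.nonsense_calls.values() if c is not None)
        a.retained = a.cadd_pass and a.conservation_pass != "fail"
    return a


def prioritize_coding(
    variants: Sequence[AnnotatedVariant], cadd_cutoff: float = 10.0
) -> list[CodingAssessment]:
    """Assess one family's segregating variants and rank the retained set.

    Input variants are expected to have already passed the basic funnel.
    Returns every coding-candidate assessment; the retained subset
    carries ranks 1..n.
    """
    assessments = []
    for v in variants:
        a = assess_coding(v, cadd_cutoff)
        if a is not None:
            assessments.append(a)
    retained = [a for a in assessments if a.retained]
    intolerance_rank(retained)
    return assessments


def retained_assessments(assessments: Sequence[CodingAssessment]) -> list[CodingAssessment]:
    return sorted(
        (a for a in assessments if a.retained),
        key=lambda a: a.rank if a.rank is not None else math.inf,
    )
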