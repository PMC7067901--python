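"""Readers and writers for the cohort file formats.

Formats: joint-genotyped VCF 4.2 (FORMAT ``GT:DP:GQ`` plus optional
``ADF``/``ADR`` for per-strand alt read counts), 6-column PED with an
optional 7th role-override column, tab-separated annotation tables keyed
by ``variant_id``, BED3/BED4 regulatory tracks, two-column gene panels,
and tab-separated structural-variant and gene-model tables.

Multi-allelic VCF sites are split into one record per alternate allele,
with allele-specific dosages recomputed from the diploid genotype.
Variants lacking an annotation row are kept with all annotation fields
missing; annotation rows matching no VCF record are logged and dropped —
a reader never silently discards a record.
"""

from __future__ import annotations

import logging
import math
import os
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

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
    chrom_sort_key,
    make_variant_id,
)

logger = logging.getLogger(__name__)

_SEX_CODES = {"1": "male", "2": "female"}
_PHENO_CODES = {"2": "case", "1": "control", "0": "unknown", "-9": "unknown"}


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_pedigree(path: str | os.PathLike) -> list[Pedigree]:
    """Read a PED file into one :class:`Pedigree` per family.

    Columns: family, sample, father, mother, sex (1=male, 2=female,
    0=unknown), phenotype (2=case, 1=control, 0/-9=unknown). An optional
    7th column overrides the role (e.g. ``obligate_carrier`` for an
    unaffected individual who must carry the familial variant).
    """
    families: dict[str, list[Sample]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >= 6 PED columns")
            fam, sid, father, mother, sex, pheno = fields[:6]
            role = _PHENO_CODES.get(pheno, "unknown")
            if len(fields) >= 7 and fields[6].strip():
                override = fields[6].strip()
                if override == "obligate_carrier" and role == "case":
                    raise ValueError(
                        f"{path}: line {lineno}: obligate_carrier override on an "
                        f"affected individual ({sid})"
                    )
                role = override
            sample = Sample(
                sample_id=sid,
                family_id=fam,
                father_id=None if father in ("0", "") else father,
                mother_id=None if mother in ("0", "") else mother,
                sex=_SEX_CODES.get(sex, "unknown"),
                role=role,
            )
            siblings = families.setdefault(fam, [])
            if any(s.sample_id == sid for s in siblings):
                raise ValueError(
                    f"{path}: duplicate sample_id {sid!r} in family {fam!r}"
                )
            siblings.append(sample)
    return [Pedigree(family_id=fam, samples=samples) for fam, samples in families.items()]


def write_pedigree(pedigrees: Iterable[Pedigree], path: str | os.PathLike) -> None:
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    pheno_out = {"case": "2", "control": "1"}
    with open(path, "w", encoding="utf-8") as fh:
        for ped in pedigrees:
            for s in ped.samples:
                role_col = s.role if s.role == "obligate_carrier" else ""
                pheno = pheno_out.get(s.role, "0")
                if s.role == "obligate_carrier":
                    pheno = "1"  # unaffected; role carried in column 7
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            s.sample_id,
                            s.father_id or "0",
                            s.mother_id or "0",
                            sex_out[s.sex],
                            pheno,
                            role_col,
                        ]
                    ).rstrip()
                    + "\n"
                )


# ---------------------------------------------------------------------------
# VCF + annotation TSV
# ---------------------------------------------------------------------------

#: Annotation-table column prefixes for the per-tool call maps.
_DEL_PREFIX = "del_"
_PATHO_PREFIX = "patho_"
_INTOL_PREFIX = "intol_"

_DEL_CODES = {"D": "deleterious", "T": "tolerated"}
_PATHO_CODES = {"P": "pathogenic", "B": "benign"}
_INTOL_CODES = {"I": "intolerant", "T": "tolerant"}

ANNOTATION_COLUMNS = (
    ["variant_id", "gene_symbols", "functional_class", "protein_effect",
     "maf_1000g", "maf_exac_nontcga", "cadd_phred", "gerp", "phastcons", "phylop"]
    + [_DEL_PREFIX + p for p in MISSENSE_PREDICTORS]
    + [_PATHO_PREFIX + p for p in NONSENSE_PREDICTORS]
    + [_INTOL_PREFIX + s for s in INTOLERANCE_SOURCES]
    + ["pli", "missense_z", "mirsvr"]
)


def _opt_float(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in (".", "", "NA", "nan"):
            return None
        return float(value)
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)


def _split_genotype(gt_alleles: Sequence[int], alt_index: int) -> Optional[int]:
    """Allele-specific dosage for alternate allele ``alt_index`` (1-based
    within the site's ALT list) from a diploid integer genotype."""
    if any(a < 0 for a in gt_alleles):
        return None
    return sum(1 for a in gt_alleles if a == alt_index)


def read_variants(
    vcf_path: str | os.PathLike,
    annotation_path: Optional[str | os.PathLike] = None,
) -> list[AnnotatedVariant]:
    """Read a joint-genotyped VCF and join the per-variant annotation table.

    One record per (chrom, pos, ref, alt); multi-allelic sites are split
    with allele-specific dosages. ``ADF``/``ADR`` FORMAT fields, when
    present, supply strand-resolved alt read support.
    """
    vcf = VCF(str(vcf_path))
    sample_names = list(vcf.samples)
    variants: list[AnnotatedVariant] = []
    def fmt(rec, key):
        try:
            return rec.format(key)
        except KeyError:  # field not declared in this VCF's header
            return None

    for rec in vcf:
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        depths = fmt(rec, "DP")
        quals = fmt(rec, "GQ")
        adf = fmt(rec, "ADF")
        adr = fmt(rec, "ADR")
        site_cov = rec.INFO.get("DP")
        if site_cov is None and depths is not None:
            site_cov = int(np.nansum(np.where(depths < 0, np.nan, depths)))
        for alt_i, alt in enumerate(rec.ALT, start=1):
            calls = []
            for si, name in enumerate(sample_names):
                dosage = _split_genotype(gts[si][:2], alt_i)
                depth = None
                if depths is not None and depths[si][0] >= 0:
                    depth = int(depths[si][0])
                gq = None
                if quals is not None and quals[si][0] >= 0:
                    gq = float(quals[si][0])
                fwd = rev = None
                if adf is not None and adf.shape[1] > alt_i and adf[si][alt_i] >= 0:
                    fwd = int(adf[si][alt_i])
                if adr is not None and adr.shape[1] > alt_i and adr[si][alt_i] >= 0:
                    rev = int(adr[si][alt_i])
                calls.append(
                    GenotypeCall(
                        sample_id=name,
                        dosage=dosage,
                        depth=depth,
                        quality=gq,
                        forward_alt_reads=fwd,
                        reverse_alt_reads=rev,
                    )
                )
            variants.append(
                AnnotatedVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    variant_class="snv" if len(rec.REF) == 1 and len(alt) == 1 else "indel",
                    # cyvcf2 exposes QUAL as float32; round away the
                    # representation noise so round-trips are exact
                    site_quality=None if rec.QUAL is None else round(float(rec.QUAL), 4),
                    site_coverage=int(site_cov) if site_cov is not None else None,
                    platypus_pass=rec.FILTER is None or rec.FILTER == "PASS",
                    genotypes=calls,
                )
            )
    if annotation_path is not None:
        annotate_variants(variants, annotation_path)
    return variants


def annotate_variants(
    variants: list[AnnotatedVariant], annotation_path: str | os.PathLike
) -> None:
    """Join an annotation table onto VCF records in place, by variant_id."""
    table = pd.read_csv(annotation_path, sep="\t", dtype=str, keep_default_na=False)
    by_id = {v.variant_id: v for v in variants}
    for _, row in table.iterrows():
        vid = row["variant_id"]
        v = by_id.get(vid)
        if v is None:
            logger.warning("annotation row %s matches no VCF record; ignored", vid)
            continue
        _apply_annotation_row(v, row)


def _apply_annotation_row(v: AnnotatedVariant, row: pd.Series) -> None:
    genes = row.get("gene_symbols", "")
    v.gene_symbols = tuple(g.strip() for g in genes.split(",") if g.strip())
    fc = row.get("functional_class", "").strip()
    if fc:
        v.functional_class = fc
    pe = row.get("protein_effect", "").strip()
    v.protein_effect = pe if pe and pe != "." else None
    for attr in ("maf_1000g", "maf_exac_nontcga", "cadd_phred", "gerp",
                 "phastcons", "phylop", "pli", "missense_z", "mirsvr"):
        if attr in row:
            setattr(v, attr, _opt_float(row[attr]))
    for p in MISSENSE_PREDICTORS:
        col = _DEL_PREFIX + p
        if col in row:
            v.missense_calls[p] = _DEL_CODES.get(row[col].strip())
    for p in NONSENSE_PREDICTORS:
        col = _PATHO_PREFIX + p
        if col in row:
            v.nonsense_calls[p] = _PATHO_CODES.get(row[col].strip())
    for s in INTOLERANCE_SOURCES:
        col = _INTOL_PREFIX + s
        if col in row:
            v.intolerance_flags[s] = _INTOL_CODES.get(row[col].strip())


def _fmt(value, nd: int = 6) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return repr(round(value, nd)) if value != int(value) else str(int(value))
    return str(value)


def write_variants(
    variants: Sequence[AnnotatedVariant],
    vcf_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
    sample_order: Optional[Sequence[str]] = None,
) -> None:
    """Write variants as a VCF 4.2 / annotation-TSV pair.

    The pair round-trips through :func:`read_variants` bit-identically for
    all non-missing fields.
    """
    if sample_order is None:
        seen: dict[str, None] = {}
        for v in variants:
            for g in v.genotypes:
                seen.setdefault(g.sample_id, None)
        sample_order = list(seen)
    ordered = sorted(variants, key=lambda v: (chrom_sort_key(v.chrom), v.pos, v.ref, v.alt))
    with open(vcf_path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Site coverage">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="Forward reads per allele">\n')
        fh.write('##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="Reverse reads per allele">\n')
        for chrom in dict.fromkeys(v.chrom for v in ordered):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_order)
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
        for v in ordered:
            info = f"DP={v.site_coverage}" if v.site_coverage is not None else "."
            cols = [
                v.chrom,
                str(v.pos),
                v.variant_id,
                v.ref,
                v.alt,
                _fmt(v.site_quality),
                "PASS" if v.platypus_pass else "FAIL",
                info,
                "GT:DP:GQ:ADF:ADR",
            ]
            calls = {g.sample_id: g for g in v.genotypes}
            for name in sample_order:
                g = calls.get(name)
                if g is None:
                    cols.append("./.:.:.:.:.")
                    continue
                adf = "." if g.forward_alt_reads is None else f"0,{g.forward_alt_reads}"
                adr = "." if g.reverse_alt_reads is None else f"0,{g.reverse_alt_reads}"
                cols.append(
                    ":".join(
                        [
                            gt_strings[g.dosage],
                            "." if g.depth is None else str(g.depth),
                            "." if g.quality is None else str(int(g.quality)),
                            adf,
                            adr,
                        ]
                    )
                )
            fh.write("\t".join(cols) + "\n")
    write_annotation(ordered, annotation_path)


def write_annotation(
    variants: Sequence[AnnotatedVariant], path: str | os.PathLike
) -> None:
    rev_del = {v: k for k, v in _DEL_CODES.items()}
    rev_patho = {v: k for k, v in _PATHO_CODES.items()}
    rev_intol = {v: k for k, v in _INTOL_CODES.items()}
    rows = []
    for v in variants:
        row = {
            "variant_id": v.variant_id,
            "gene_symbols": ",".join(v.gene_symbols),
            "functional_class": v.functional_class,
            "protein_effect": v.protein_effect or ".",
            "maf_1000g": _fmt(v.maf_1000g),
            "maf_exac_nontcga": _fmt(v.maf_exac_nontcga),
            "cadd_phred": _fmt(v.cadd_phred),
            "gerp": _fmt(v.gerp),
            "phastcons": _fmt(v.phastcons),
            "phylop": _fmt(v.phylop),
            "pli": _fmt(v.pli),
            "missense_z": _fmt(v.missense_z),
            "mirsvr": _fmt(v.mirsvr),
        }
        for p in MISSENSE_PREDICTORS:
            row[_DEL_PREFIX + p] = rev_del.get(v.missense_calls[p], ".")
        for p in NONSENSE_PREDICTORS:
            row[_PATHO_PREFIX + p] = rev_patho.get(v.nonsense_calls[p], ".")
        for s in INTOLERANCE_SOURCES:
            row[_INTOL_PREFIX + s] = rev_intol.get(v.intolerance_flags[s], ".")
        rows.append(row)
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED tracks
# ---------------------------------------------------------------------------

def read_track(path: str | os.PathLike, category: str, name: Optional[str] = None) -> RegulatoryTrack:
    """Read a BED3/BED4 file (0-based half-open) into a sorted track."""
    intervals: list[tuple[str, int, int, Optional[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            label = fields[3] if len(fields) > 3 and fields[3] else None
            intervals.append((chrom, start, end, label))
    return RegulatoryTrack(
        name=name or os.path.splitext(os.path.basename(path))[0],
        category=category,
        intervals=intervals,
    )


def write_track(track: RegulatoryTrack, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end, label in track.intervals:
            cols = [chrom, str(start), str(end)]
            if label is not None:
                cols.append(label)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Gene panels
# ---------------------------------------------------------------------------

def read_panel(path: str | os.PathLike, name: Optional[str] = None) -> GenePanel:
    """Read a two-column (symbol, category) panel TSV with a header row.

    Symbols are uppercased; a duplicate symbol with a conflicting category
    keeps the first occurrence and logs a warning. An empty panel is an
    error.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if table.empty:
        raise ValueError(f"{path}: empty gene panel")
    entries: dict[str, str] = {}
    for _, row in table.iterrows():
        sym = row.iloc[0].strip().upper()
        cat = row.iloc[1].strip()
        if sym in entries:
            if entries[sym] != cat:
                logger.warning(
                    "panel %s: duplicate symbol %s with conflicting category "
                    "(%r kept, %r ignored)", path, sym, entries[sym], cat,
                )
            continue
        entries[sym] = cat
    return GenePanel(name=name or os.path.splitext(os.path.basename(path))[0], entries=entries)


def write_panel(panel: GenePanel, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("symbol\tcategory\n")
        for sym, cat in panel.entries.items():
            fh.write(f"{sym}\t{cat}\n")


# ---------------------------------------------------------------------------
# Gene model and structural variants
# ---------------------------------------------------------------------------

def read_gene_model(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Read a gene-model TSV: gene, chrom, strand, tx_start, tx_end
    (0-based half-open)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    models = {}
    for _, row in table.iterrows():
        gm = GeneModel(
            gene=row["gene"].upper(),
            chrom=row["chrom"],
            strand=row["strand"],
            tx_start=int(row["tx_start"]),
            tx_end=int(row["tx_end"]),
        )
        models[gm.gene] = gm
    return models


def write_gene_model(models: dict[str, GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tchrom\tstrand\ttx_start\ttx_end\n")
        for gm in models.values():
            fh.write(f"{gm.gene}\t{gm.chrom}\t{gm.strand}\t{gm.tx_start}\t{gm.tx_end}\n")


def read_structural_variants(path: str | os.PathLike) -> list[StructuralVariantRecord]:
    """Read a structural-variant TSV: chrom, start, end (1-based inclusive),
    sv_type, filter, carriers (comma-separated), gnomad_af."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in table.iterrows():
        out.append(
            StructuralVariantRecord(
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                sv_type=row["sv_type"],
                filter_pass=row["filter"].upper() == "PASS",
                carrier_sample_ids=tuple(
                    c.strip() for c in row["carriers"].split(",") if c.strip()
                ),
                gnomad_overlap_af=_opt_float(row["gnomad_af"]),
            )
        )
    return out
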