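"""Synthetic cohort generator: families with a planted dominant variant.

The confidential study data cannot be redistributed, so every stage of
the pipeline is exercised on simulated cohorts with the same structure:
a small number of families (default three, jointly 7 affected and 9
unaffected members, mirroring the study cohort), one planted causal
variant per family segregating under a dominant model, and a background
of annotated variants whose genotypes follow Mendelian transmission
from founder genotypes drawn at a population allele frequency.

Background annotation distributions are explicit package conventions:
MAF ~ mixture of a point mass at 0 (private variants, weight ``w0``)
and a scaled Beta; CADD ~ truncated Gamma; conservation scores share a
latent Gaussian with CADD (correlation ``rho``) so that conserved sites
tend to score high; per-tool deleteriousness calls are Bernoulli with a
logistic-in-CADD success probability. Defaults produce realistic funnel
attrition (a few percent of background survives the coding cascade).

``penetrance`` is the probability an affected individual carries the
planted allele; ``phenocopy_rate`` the probability an unaffected
control carries it. At (1, 0) the planted genotypes satisfy the
dominant segregation pattern exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import cohort_io
from .basic_filters import FunnelConfig, run_funnel
from .coding_prioritizer import prioritize_coding
from .types import (
    INTOLERANCE_SOURCES,
    MISSENSE_PREDICTORS,
    NONSENSE_PREDICTORS,
    AnnotatedVariant,
    GeneModel,
    GenotypeCall,
    Pedigree,
    RegulatoryTrack,
    Sample,
)

#: Background functional-class mix (roughly exome/UTR/flank-weighted).
CLASS_WEIGHTS = {
    "nonsynonymous_snv": 0.25,
    "synonymous_snv": 0.13,
    "stopgain_snv": 0.03,
    "frameshift_deletion": 0.02,
    "utr5": 0.08,
    "utr3": 0.12,
    "upstream": 0.05,
    "downstream": 0.05,
    "intronic": 0.20,
    "intergenic": 0.07,
}

PEDIGREE_TEMPLATES = ("trio", "three_generation", "extended_9", "quad")


@dataclass(frozen=True)
class PlantedSpec:
    """Annotation profile of the planted causal variant."""

    gene: str = "PLANTED1"
    functional_class: str = "nonsynonymous_snv"
    cadd: float = 25.0
    del_votes: int = 9
    maf: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    n_families: int = 3
    #: one template name applied to every family, or one name per family
    pedigree_template: str | tuple[str, ...] = ("trio", "extended_9", "quad")
    n_background_variants: int = 500
    planted: PlantedSpec = PlantedSpec()
    # background MAF ~ w0 * point-mass(0) + (1-w0) * maf_scale * Beta(a, b)
    w0: float = 0.3
    beta_a: float = 0.5
    beta_b: float = 20.0
    maf_scale: float = 0.05
    # background CADD ~ Gamma(shape, scale) truncated at cadd_max
    cadd_shape: float = 2.0
    cadd_scale: float = 4.0
    cadd_max: float = 60.0
    #: latent correlation between CADD and conservation scores
    rho: float = 0.6
    # per-tool deleterious-call probability: logistic((cadd - mid) / width)
    p_del_mid: float = 15.0
    p_del_width: float = 4.0
    mean_depth: float = 30.0
    phenocopy_rate: float = 0.0
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w0", "phenocopy_rate"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.penetrance <= 1:
            raise ValueError("penetrance must be in (0, 1]")
        templates = self.templates()
        for t in templates:
            if t not in PEDIGREE_TEMPLATES:
                raise ValueError(f"unknown pedigree template {t!r}")

    def templates(self) -> tuple[str, ...]:
        if isinstance(self.pedigree_template, str):
            return (self.pedigree_template,) * self.n_families
        if len(self.pedigree_template) != self.n_families:
            raise ValueError("pedigree_template tuple must have n_families entries")
        return tuple(self.pedigree_template)


def _template_samples(template: str, family_id: str) -> list[Sample]:
    F = family_id
    if template == "trio":
        # affected parent-child pair, unaffected second parent
        return [
            Sample("FA", F, sex="male", role="control"),
            Sample("MO", F, sex="female", role="case"),
            Sample("CH", F, father_id="FA", mother_id="MO", sex="female", role="case"),
        ]
    if template == "quad":
        # two affected sibs; one parent an unaffected obligate carrier
        return [
            Sample("FA", F, sex="male", role="obligate_carrier"),
            Sample("MO", F, sex="female", role="control"),
            Sample("S1", F, father_id="FA", mother_id="MO", sex="male", role="case"),
            Sample("S2", F, father_id="FA", mother_id="MO", sex="female", role="case"),
        ]
    if template == "three_generation":
        # dominant transmission across three generations
        return [
            Sample("GF", F, sex="male", role="control"),
            Sample("GM", F, sex="female", role="case"),
            Sample("P1", F, father_id="GF", mother_id="GM", sex="male", role="case"),
            Sample("P2", F, sex="female", role="control"),
            Sample("C1", F, father_id="P1", mother_id="P2", sex="female", role="case"),
        ]
    if template == "extended_9":
        # three affected sibs, parent an obligate carrier, five controls
        return [
            Sample("P1", F, sex="female", role="obligate_carrier"),
            Sample("P2", F, sex="male", role="control"),
            Sample("S1", F, father_id="P2", mother_id="P1", sex="male", role="case"),
            Sample("S2", F, father_id="P2", mother_id="P1", sex="female", role="case"),
            Sample("S3", F, father_id="P2", mother_id="P1", sex="male", role="case"),
            Sample("U1", F, father_id="P2", mother_id="P1", sex="female", role="control"),
            Sample("U2", F, father_id="P2", mother_id="P1", sex="male", role="control"),
            Sample("U3", F, sex="female", role="control"),
            Sample("U4", F, sex="male", role="control"),
        ]
    raise ValueError(f"unknown template {template!r}")


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    pedigrees: list[Pedigree]
    variants_by_family: dict[str, list[AnnotatedVariant]]
    tracks: list[RegulatoryTrack]
    gene_model: dict[str, GeneModel]
    truth: list[tuple[str, str]]  # (variant_id, family_id) of planted variants

    def planted_id(self, family_id: str) -> str:
        for vid, fam in self.truth:
            if fam == family_id:
                return vid
        raise KeyError(family_id)

    def write(self, outdir: str | os.PathLike) -> dict[str, Path]:
        """Write the cohort in the formats the readers consume.

        Deterministic: identical cohorts produce byte-identical files.
        """
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        ped_path = out / "cohort.ped"
        cohort_io.write_pedigree(self.pedigrees, ped_path)
        paths["ped"] = ped_path
        for ped in self.pedigrees:
            fam = ped.family_id
            vcf = out / f"{fam}.vcf"
            tsv = out / f"{fam}.annotation.tsv"
            cohort_io.write_variants(
                self.variants_by_family[fam], vcf, tsv, sample_order=ped.sample_ids()
            )
            paths[f"vcf:{fam}"] = vcf
            paths[f"annotation:{fam}"] = tsv
        tracks_dir = out / "tracks"
        tracks_dir.mkdir(exist_ok=True)
        for track in self.tracks:
            p = tracks_dir / f"{track.category}.bed"
            cohort_io.write_track(track, p)
            paths[f"track:{track.category}"] = p
        gm_path = out / "gene_model.tsv"
        cohort_io.write_gene_model(self.gene_model, gm_path)
        paths["gene_model"] = gm_path
        truth_path = out / "truth.tsv"
        with open(truth_path, "w", encoding="utf-8") as fh:
            fh.write("variant_id\tfamily_id\tplanted\n")
            for vid, fam in self.truth:
                fh.write(f"{vid}\t{fam}\ttrue\n")
        paths["truth"] = truth_path
        return paths


def _truncated_gamma(rng: np.random.Generator, u: float, shape: float,
                     scale: float, upper: float) -> float:
    """Gamma quantile of u, resampled into [0, upper] by CDF inversion."""
    cap = stats.gamma.cdf(upper, shape, scale=scale)
    return float(stats.gamma.ppf(u * cap, shape, scale=scale))


def _transmit(rng: np.random.Generator, dosage: int) -> int:
    """One allele transmitted from a diploid parent with given alt dosage."""
    return int(rng.random() < dosage / 2.0)


def _mendelian_genotypes(
    rng: np.random.Generator, ped: Pedigree, maf: float, private: bool
) -> dict[str, int]:
    """Founder genotypes at the given MAF, children by transmission."""
    dosages: dict[str, int] = {}
    founders = [s for s in ped.samples if s.father_id is None and s.mother_id is None]
    if private:
        carrier = founders[rng.integers(len(founders))]
        for s in founders:
            dosages[s.sample_id] = 1 if s.sample_id == carrier.sample_id else 0
    else:
        for s in founders:
            dosages[s.sample_id] = int(rng.binomial(2, maf))
    # samples are ordered parents-before-children in every template
    for s in ped.samples:
        if s.sample_id in dosages:
            continue
        d = 0
        for parent in (s.father_id, s.mother_id):
            if parent is None:
                d += _transmit(rng, int(rng.binomial(2, maf)))
            else:
                d += _transmit(rng, dosages[parent])
        dosages[s.sample_id] = d
    return dosages


def _genotype_calls(
    rng: np.random.Generator,
    ped: Pedigree,
    dosages: dict[str, int],
    mean_depth: float,
    balanced: bool = False,
) -> list[GenotypeCall]:
    calls = []
    for s in ped.samples:
        d = dosages[s.sample_id]
        depth = max(1, int(rng.poisson(mean_depth)))
        if d == 0:
            fwd = rev = 0
        elif balanced:
            fwd = rev = max(1, depth // 4)
        else:
            alt = int(rng.binomial(depth, 0.5 if d == 1 else 0.95))
            alt = min(alt, depth)
            fwd = int(rng.binomial(alt, 0.5))
            rev = alt - fwd
        calls.append(
            GenotypeCall(
                sample_id=s.sample_id,
                dosage=d,
                depth=depth,
                quality=99.0,
                forward_alt_reads=fwd,
                reverse_alt_reads=rev,
            )
        )
    return calls


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort under the configured study conditions.

    The seed fully determines the output. Each family receives one
    planted variant (carried per ``penetrance``/``phenocopy_rate``) and
    ``n_background_variants`` background variants with Mendelian
    genotypes; regulatory tracks cover a subset of the non-coding
    background so the non-coding arm has true positives to find.
    """
    rng = np.random.default_rng(cfg.seed)
    templates = cfg.templates()
    pedigrees = [
        Pedigree(f"SimFam_{i + 1}", _template_samples(templates[i], f"SimFam_{i + 1}"))
        for i in range(cfg.n_families)
    ]
    gene_model: dict[str, GeneModel] = {}
    track_intervals: dict[str, list] = {
        "mirna_target": [],
        "promoter": [],
        "enhancer": [],
        "super_enhancer": [],
        "tfbs": [],
    }
    five_side_cats = ("promoter", "enhancer", "super_enhancer", "tfbs")
    variants_by_family: dict[str, list[AnnotatedVariant]] = {}
    truth: list[tuple[str, str]] = []
    class_names = list(CLASS_WEIGHTS)
    class_p = np.array(list(CLASS_WEIGHTS.values()))
    class_p = class_p / class_p.sum()

    for fam_i, ped in enumerate(pedigrees):
        fam = ped.family_id
        variants: list[AnnotatedVariant] = []

        # --- planted causal variant ---
        planted_pos = 1_000_000 + 10_000 * fam_i
        planted_dosages = {}
        for s in ped.samples:
            if s.role == "case":
                carrier = rng.random() < cfg.penetrance
            elif s.role == "obligate_carrier":
                carrier = True
            else:
                carrier = rng.random() < cfg.phenocopy_rate
            planted_dosages[s.sample_id] = 1 if carrier else 0
        planted = AnnotatedVariant(
            chrom="1", pos=planted_pos, ref="G", alt="A",
            site_quality=99.0, site_coverage=int(cfg.mean_depth),
            genotypes=_genotype_calls(rng, ped, planted_dosages, cfg.mean_depth,
                                      balanced=True),
            gene_symbols=(cfg.planted.gene,),
            functional_class=cfg.planted.functional_class,
            protein_effect="p.A100T",
            cadd_phred=cfg.planted.cadd,
            gerp=4.0, phastcons=0.9, phylop=3.5,
            maf_1000g=cfg.planted.maf or None,
            maf_exac_nontcga=cfg.planted.maf or None,
            missense_calls={
                p: ("deleterious" if i < cfg.planted.del_votes else "tolerated")
                for i, p in enumerate(MISSENSE_PREDICTORS)
            },
            nonsense_calls={
                p: ("pathogenic" if i < 6 else "benign")
                for i, p in enumerate(NONSENSE_PREDICTORS)
            },
            intolerance_flags={s: "intolerant" for s in INTOLERANCE_SOURCES},
            pli=0.99, missense_z=3.2,
        )
        variants.append(planted)
        truth.append((planted.variant_id, fam))

        # --- background variants ---
        chroms = rng.integers(1, 23, size=cfg.n_background_variants)
        for i in range(cfg.n_background_variants):
            chrom = str(chroms[i])
            pos = int(rng.integers(2_000_000, 50_000_000))
            fclass = class_names[rng.choice(len(class_names), p=class_p)]
            private = rng.random() < cfg.w0
            maf = 0.0 if private else float(
                cfg.maf_scale * rng.beta(cfg.beta_a, cfg.beta_b)
            )
            dosages = _mendelian_genotypes(rng, ped, maf, private)

            u_c = rng.random()
            cadd = _truncated_gamma(rng, u_c, cfg.cadd_shape, cfg.cadd_scale,
                                    cfg.cadd_max)
            z_c = float(stats.norm.ppf(np.clip(u_c, 1e-12, 1 - 1e-12)))
            lat = cfg.rho * z_c + np.sqrt(1 - cfg.rho**2) * rng.standard_normal(3)
            gerp = float(2.0 + 1.5 * lat[0])
            phastcons = float(stats.norm.cdf(lat[1]))
            phylop = float(1.0 + 2.0 * lat[2])
            p_del = _logistic((cadd - cfg.p_del_mid) / cfg.p_del_width)
            is_indel = fclass == "frameshift_deletion"
            gene = f"BG{fam_i + 1}_{i:04d}"

            v = AnnotatedVariant(
                chrom=chrom,
                pos=pos,
                ref="AT" if is_indel else "C",
                alt="A" if is_indel else "T",
                variant_class="indel" if is_indel else "snv",
                site_quality=float(np.round(rng.uniform(10, 100), 1)),
                site_coverage=int(rng.poisson(cfg.mean_depth)),
                platypus_pass=bool(rng.random() < 0.9) if is_indel else True,
                genotypes=_genotype_calls(rng, ped, dosages, cfg.mean_depth),
                gene_symbols=(gene,),
                functional_class=fclass,
                cadd_phred=float(np.round(cadd, 2)),
                gerp=float(np.round(gerp, 2)),
                phastcons=float(np.round(phastcons, 3)),
                phylop=float(np.round(phylop, 2)),
                maf_1000g=None if private else float(np.round(maf, 6)),
                # second panel drawn as a subsample of the first, never
                # larger, so max(MAF) over panels keeps the Beta CDF
                maf_exac_nontcga=None if private else float(
                    np.round(maf * rng.uniform(0.5, 1.0), 6)
                ),
                missense_calls={
                    p: ("deleterious" if rng.random() < p_del else "tolerated")
                    for p in MISSENSE_PREDICTORS
                },
                nonsense_calls={
                    p: ("pathogenic" if rng.random() < p_del else "benign")
                    for p in NONSENSE_PREDICTORS
                },
                intolerance_flags={
                    s: ("intolerant" if rng.random() < 0.3 else "tolerant")
                    for s in INTOLERANCE_SOURCES
                },
                pli=float(np.round(rng.random(), 3)),
                missense_z=float(np.round(rng.normal(0, 2), 2)),
            )
            # UTR/flank variants get a gene-model entry so the non-coding
            # arm can assign them; half of them sit in a regulatory track.
            if fclass in ("utr5", "utr3", "upstream", "downstream"):
                pos0 = pos - 1
                if fclass in ("utr5", "utr3"):
                    tx_start, tx_end = pos0 - 1_500, pos0 + 1_500
                elif fclass == "upstream":
                    tx_start, tx_end = pos0 + int(rng.integers(1, 1001)), pos0 + 4_000
                else:  # downstream
                    tx_end = pos0 - int(rng.integers(0, 1000))
                    tx_start = tx_end - 3_000
                gene_model[gene] = GeneModel(gene, chrom, "+", tx_start, tx_end)
                if rng.random() < 0.5:
                    iv = (chrom, pos0 - 3, pos0 + 4, f"{gene}_site")
                    if fclass in ("utr3", "downstream"):
                        track_intervals["mirna_target"].append(iv)
                        v.mirsvr = float(np.round(-rng.random(), 3))
                    else:
                        cat = five_side_cats[rng.integers(len(five_side_cats))]
                        track_intervals[cat].append(iv)
            variants.append(v)
        variants_by_family[fam] = variants

    tracks = [
        RegulatoryTrack(f"sim_{cat}", cat, ivs)
        for cat, ivs in track_intervals.items()
        if ivs
    ]
    return SimulatedCohort(
        config=cfg,
        pedigrees=pedigrees,
        variants_by_family=variants_by_family,
        tracks=tracks,
        gene_model=gene_model,
        truth=truth,
    )


def mendelian_consistent(v: AnnotatedVariant, ped: Pedigree) -> bool:
    """Check every child's dosage against its genotyped parents.

    A child may inherit an alternate allele from a parent only if that
    parent carries one, and must inherit one from every homozygous-alt
    parent; a missing parent may contribute anything.
    """
    dosages = {g.sample_id: g.dosage for g in v.genotypes}
    for s in ped.samples:
        d = dosages.get(s.sample_id)
        if d is None:
            continue
        lo = hi = 0
        for parent in (s.father_id, s.mother_id):
            if parent is None or dosages.get(parent) is None:
                hi += 1
                continue
            pd = dosages[parent]
            hi += 1 if pd >= 1 else 0
            lo += 1 if pd == 2 else 0
        if not (lo <= d <= hi):
            return False
    return True


@dataclass
class RecoveryResult:
    recovery_rate: float
    mean_rank: Optional[float]
    n_trials: int


def recovery_benchmark(
    cfg: SimulationConfig,
    n_replicates: int = 20,
    funnel_config: FunnelConfig = FunnelConfig(),
    cadd_cutoff: float = 10.0,
) -> RecoveryResult:
    """Planted-variant recovery over replicate simulated cohorts.

    For every replicate and family, the basic funnel and the coding
    cascade are run end to end; a trial succeeds when the planted
    variant is among the retained coding candidates. ``recovery_rate``
    is the success fraction; ``mean_rank`` the planted variant's mean
    within-family rank among retained candidates (None if never
    recovered).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    successes = 0
    trials = 0
    ranks: list[int] = []
    for r in range(n_replicates):
        rep_cfg = replace(cfg, seed=(cfg.seed + 7919 * r) % (2**31 - 1))
        cohort = simulate_cohort(rep_cfg)
        for ped in cohort.pedigrees:
            trials += 1
            planted_id = cohort.planted_id(ped.family_id)
            survivors, _ = run_funnel(
                cohort.variants_by_family[ped.family_id], ped, funnel_config
            )
            assessments = prioritize_coding(survivors, cadd_cutoff)
            for a in assessments:
                if a.variant_id == planted_id and a.retained:
                    successes += 1
                    ranks.append(a.rank)
                    break
    return RecoveryResult(
        recovery_rate=successes / trials,
        mean_rank=float(np.mean(ranks)) if ranks else None,
        n_trials=trials,
    )
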