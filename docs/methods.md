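# Methods

## Model and scope

`famprio` operationalizes family-based prioritization of rare germline
variants under an autosomal-dominant model. The unit of analysis is one
family with jointly genotyped members labelled *case* (affected),
*control* (unaffected) or *obligate carrier* (unaffected but required
to carry the familial allele by pedigree position, e.g. the parent
linking affected branches). The pipeline consumes variant calls that
have already been aligned, called and annotated upstream; it never
recomputes annotation scores (CADD, conservation, per-tool effect
predictions, intolerance) — they are inputs.

Coordinates follow the VCF/BED duality: variant positions and
`variant_id` strings (`chrom_pos_ref_alt`) are 1-based, all interval
arithmetic is 0-based half-open, and an SNV at position *p* occupies
[*p*−1, *p*).

## Filtering funnel

Four stages in fixed order, each a pure predicate:

| stage | rule | missing-value handling |
|---|---|---|
| quality | site quality > 20 **and** coverage > 5×; indels also need the caller's PASS | missing metric ⇒ fail (`missing_metric`) |
| strand bias | some carrier has ≥ 1 alt read on each strand (SNVs only) | no strand info anywhere ⇒ configurable pass-with-warning (default) or fail |
| frequency | max(MAF over both panels) < 0.1% (strict) | missing MAF ⇒ 0, i.e. novel |
| segregation | all genotyped cases carry; all genotyped obligate carriers carry; ≤ `max_control_carriers` controls carry | `permissive` (default): missing genotype ignored; `strict`: missing case/obligate genotype fails |

Because the stages are pure predicates, the surviving *set* is
order-invariant (per-stage counts are not), and relaxing any threshold
can only grow it — both properties are asserted in the test suite.

The source analysis describes weighing "the probability of an
individual being a Mendelian case or true control" without formalizing
it; here that ambiguity is exposed as the deterministic
`SegregationPolicy` — `max_control_carriers` emulates tolerance for
phenocopies and reduced penetrance, `require_all_cases` and
`obligate_carriers_must_carry` make the strict dominant pattern
explicit. Homozygous-alternate genotypes count as carriers; a male
X-chromosome dosage of 1 is a carrier like any other.

## Coding cascade

Variants are routed by functional class: non-synonymous SNV →
*missense* path; stopgain / frameshift → *nonsense* path; everything
else leaves the coding arm.

* **CADD**: retained only if CADD PHRED is present and > 10 (missing
  fails — an unscored variant cannot demonstrate deleteriousness).
* **Conservation**: GERP > 2.0, PhastCons > 0.3, PhyloP ≥ 3.0,
  evaluated as a conjunction over the scores that are *present*. All
  three absent ⇒ `not_applicable`, treated as a pass and flagged:
  conservation tracks do not cover every site, and a hard requirement
  would silently discard sparsely annotated candidates. Note the
  deliberately non-strict PhyloP bound.
* **Missense consensus (Del n/10)**: votes = deleterious calls among
  ten predictors; pass requires ≥ 5 non-missing calls and
  votes ≥ ⌈0.6 × available⌉. With all ten reporting this is the
  familiar ≥ 6/10 rule. The available-calls denominator (rather than a
  fixed 10) avoids failing variants merely because some tools lack
  coverage; the floor of five keeps the vote meaningful.
* **Nonsense verdict**: pathogenic votes among eight predictors are
  aggregated into a label (`no_support`, `supporting(k)` for 1–4,
  `majority_pathogenic` for ≥ 5) but never exclude — published
  candidate lists retain truncating variants of uncertain
  significance. The label vocabulary is a declared package convention;
  the upstream aggregator's exact vote-to-ACMG mapping is proprietary.
* **Ranking**: gene intolerance is used *only* to rank, never to cut:
  descending Int (n/3), then CADD, then the path's vote count, then
  genomic position — a total order, so ranking is permutation-
  invariant.

## Non-coding arm

UTR and flank variants are assigned strand-aware to a 5′ side (5′ UTR,
or ≤ 1 kb upstream of the TSS) or a 3′ side (3′ UTR, or ≤ 1 kb
downstream of the transcription end); the 1 kb windows are inclusive at
exactly 1000 bp. Multi-gene annotations are tried in order and the
first assignable gene context wins; counting deduplicates by
variant id. Interval containment is 0-based half-open and backed by an
interval tree; the test suite holds it to an O(n·m) brute-force oracle.

Retention requires CADD > 10 plus side-appropriate evidence: a miRNA
target site on the 3′ side; promoter, enhancer, super-enhancer or TFBS
on the 5′ side. CpG-island membership and free-text chromatin-state
annotations are carried into reports but are not retention criteria.
3′-side candidates are ranked by ascending mirSVR (more negative =
stronger predicted down-regulation; missing sorts last), 5′-side by
breadth of regulatory evidence, ties by CADD then position.

## Panel screening and structural variants

Panel matching is exact after uppercasing (an optional alias map hook
accepts HGNC alias files); a multi-gene variant yields one hit per
matching symbol but counts once toward the distinct-variant summary.
Structural variants are retained when caller-PASS, carried by every
case, not common in gnomAD (overlap AF ≤ 1%; missing = novel), and
overlapping ≥ 1 panel gene's transcript bounds — gene-level overlap,
not exon-resolved, because the screening criterion is gene-level.

## Reports

Tier 1 = retained variant with ≥ 1 panel hit; tier 2 = retained coding
without; tier 3 = retained non-coding without. Panel hits re-tier,
never duplicate, so tier totals equal the retained totals. The
pathway-analysis export is the sorted distinct gene list of retained
segregating variants with CADD > 20 that are not intronic/intergenic;
the downstream pathway software itself is proprietary and out of
scope. Report serialization is deterministic and byte-stable; the JSON
run summary embeds a hash of the configuration.

## Synthetic cohorts

The generator's defaults mirror the study conditions the pipeline
targets: three families totalling 16 members, 7 affected and 9
unaffected — a trio with an affected parent–child pair, a nine-member
family with three affected siblings and an obligate-carrier parent,
and a four-member family with two affected siblings and one
obligate-carrier parent (`quad`; a genuine three-generation template
is also available). Each family receives one planted causal variant
(default: missense, CADD 25, 9/10 deleterious votes, absent from
population panels, fully conserved) and 500 background variants.

Background conventions, chosen once as field-plausible and documented
here because no published distributions exist for them:

* MAF ~ 0.3·δ₀ + 0.7·(0.05·Beta(0.5, 20)) — the point mass yields
  private variants planted in a single founder; the Beta component
  puts most mass below 1%, so roughly half of the non-private
  background fails the 0.1% cut. The second reference panel is drawn
  as a subsample (uniform 0.5–1.0 ×) of the first, so the maximum over
  panels keeps the closed-form mixture CDF used in the calibration
  test.
* CADD ~ Gamma(k = 2, θ = 4) truncated at 60 (mean ≈ 8, ~14% above
  the 10 cutoff).
* Conservation scores share a latent Gaussian with the CADD quantile
  (ρ = 0.6), so deleterious sites tend to look conserved.
* Per-tool calls ~ Bernoulli(σ((CADD − 15)/4)) — at the planted
  CADD 25 most tools vote deleterious; for typical background few do.
* Depth ~ Poisson(30) with binomially split strand counts; site
  quality ~ U(10, 100) so the quality stage removes ~11%.

Background genotypes are generated by Mendelian transmission from
founder genotypes drawn at the variant's MAF and are checked
exhaustively for parent–child consistency. The planted variant is
carried by every case with probability `penetrance` and by every
control with probability `phenocopy_rate` (obligate carriers always
carry); at the defaults (1, 0) its genotypes satisfy the dominant
pattern exactly, and under perturbation only the planted variant may
violate Mendelian transmission — that is precisely the stress the
recovery benchmark needs.

`recovery_benchmark` replays simulate → funnel → coding cascade over
replicate cohorts (replicate seeds derived from the base seed) and
reports the fraction of family-trials in which the planted variant is
retained, plus its mean rank. Under unperturbed defaults recovery is
complete (20 replicates × 3 families) with mean rank 1.

### What the simulation does and does not show

The generator reproduces the *statistical decision structure* the
pipeline assumes — annotation-threshold margins, Mendelian genotypes,
dominant segregation, regulatory-track containment — not real data:
there is no linkage disequilibrium, no population structure, no
sequence context, background sites are independent, and annotation
scores are drawn from conventions rather than from the genome. Passing
tests therefore demonstrate that the implementation applies the stated
rules exactly and recovers a variant that satisfies them; they do not
quantify sensitivity on real cohorts.

## Worked-example fixtures

The published per-family candidate tables are embedded as data
(`famprio.fixtures`): 36 missense and 9 truncating coding candidates
with printed CADD / Int / Del / vote values, the 11
predisposition-panel hits (9 genes), the 25 HL-panel hits (23 genes),
the per-family UTR counts, and the three pedigrees. Values not printed
are reconstructed minimally and labelled synthetic: genotypes follow
perfect segregation; per-tool call patterns realize the printed vote
counts; conservation scores are absent (the printed tables carry
none), which exercises the `not_applicable` path; panel fillers are
synthetic symbols (`SYNCPG…`, `SYNHL…`) bringing panels to their
published sizes (565 / 2,383) and category composition. One printed
source reports "37 potential missense variants" while its table lists
36 rows and the overall total of 45 implies 36; the fixtures follow
the tables. Likewise a printed 5′ UTR total (523) disagrees with its
own per-family breakdown (130 + 5 + 314 = 449); the per-family figures
are treated as authoritative and the total is not used.

## Numerical and degenerate-input choices

* Thresholds are strict (`>`) except PhyloP (`≥`) and the 1 kb windows
  (inclusive at 1000), as stated with each rule.
* Missing annotation values are `None`, never 0; every threshold
  declares its missing-value behaviour at the point of use.
* Readers never silently drop records: unmatched annotation rows are
  logged and ignored, malformed lines raise with the line number, and
  multi-allelic sites are split into per-allele records with dosages
  recomputed from the diploid genotype (the upstream callers' own
  multi-allelic handling being unspecified, splitting is this
  package's convention).
* Tie-breaking in every ranking ends at (chromosome, position), making
  all orders total and deterministic; chromosome order is natural
  (1–22, X, Y, MT).
* cyvcf2 exposes QUAL as float32; it is rounded to 4 decimals on read
  so write→read round-trips are exact.

## Problem sizes

Default test and benchmark sizes — 500 background variants per family,
20 benchmark replicates, 150-variant shared test cohorts, 1,000-pair
interval fuzzing, exhaustive segregation enumeration over all ≤ 4-member
pedigrees — were chosen to give exact or tightly calibrated checks at
desk scale; all are configuration parameters, not limits of the
implementation.

## Known limitations

* Only the dominant model is implemented; recessive and compound-
  heterozygous analyses, de novo detection and kinship checks are out
  of scope.
* Symbol-based panel matching has no built-in alias resolution (hook
  provided); screening is therefore sensitive to symbol vintage.
* Region assignment uses single transcript bounds per gene, not
  isoform-aware UTR annotation.
* The structural-variant filter consumes caller output; CNV calling,
  b-allele modelling and visual inspection are upstream/manual steps.
* Literature-based final candidate selection is inherently manual; the
  report ends at tiered evidence, not a per-family gene call.
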