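"""The quality/strand/frequency/segregation funnel and its oracles."""

import itertools
import random

import pytest

from famprio.basic_filters import (
    FunnelConfig,
    SegregationPolicy,
    frequency_filter,
    quality_filter,
    run_funnel,
    segregation_filter,
    strand_bias_filter,
)
from famprio.synthetic_cohort import SimulationConfig, simulate_cohort
from famprio.types import AnnotatedVariant, GenotypeCall, Pedigree, Sample


def make_variant(**kwargs):
    defaults = dict(chrom="1", pos=100, ref="A", alt="G")
    defaults.update(kwargs)
    return AnnotatedVariant(**defaults)


class TestQualityFilter:
    @pytest.mark.parametrize(
        "quality,coverage,vclass,caller_pass,expected",
        [
            (30, 12, "snv", True, True),
            (20, 12, "snv", True, False),  # strict >
            (30, 5, "snv", True, False),  # strict >
            (30, 12, "indel", False, False),  # indel needs caller PASS
            (30, 12, "indel", True, True),
        ],
    )
    def test_boundaries(self, quality, coverage, vclass, caller_pass, expected):
        ref, alt = ("AT", "A") if vclass == "indel" else ("A", "G")
        v = make_variant(
            ref=ref, alt=alt, variant_class=vclass, site_quality=quality,
            site_coverage=coverage, platypus_pass=caller_pass,
        )
        assert quality_filter(v).passed is expected

    def test_missing_metric_fails(self):
        v = make_variant(site_quality=None, site_coverage=10)
        d = quality_filter(v)
        assert not d.passed and d.detail == "missing_metric"

    def test_random_records_match_predicate_oracle(self):
        rng = random.Random(11)
        for _ in range(1000):
            q = rng.choice([None, rng.uniform(0, 60)])
            c = rng.choice([None, rng.randrange(0, 40)])
            is_indel = rng.random() < 0.3
            cp = rng.random() < 0.8
            v = make_variant(
                ref="AT" if is_indel else "A",
                alt="A" if is_indel else "G",
                variant_class="indel" if is_indel else "snv",
                site_quality=q, site_coverage=c, platypus_pass=cp,
            )
            oracle = (
                q is not None and c is not None and q > 20 and c > 5
                and (cp or not is_indel)
            )
            assert quality_filter(v).passed is oracle


class TestStrandBiasFilter:
    def _with_carrier(self, fwd, rev):
        return make_variant(
            genotypes=[
                GenotypeCall("A", 1, depth=20, forward_alt_reads=fwd,
                             reverse_alt_reads=rev)
            ]
        )

    def test_both_strands_supported_passes(self):
        assert strand_bias_filter(self._with_carrier(3, 1)).passed

    def test_one_sided_fails(self):
        assert not strand_bias_filter(self._with_carrier(4, 0)).passed

    def test_indel_passes_without_strand_fields(self):
        v = make_variant(ref="AT", alt="A", variant_class="indel",
                         genotypes=[GenotypeCall("A", 1)])
        assert strand_bias_filter(v).passed

    def test_missing_strand_info_configurable(self):
        v = make_variant(genotypes=[GenotypeCall("A", 1)])
        assert strand_bias_filter(v, missing_strand="pass").passed
        assert not strand_bias_filter(v, missing_strand="fail").passed


class TestFrequencyFilter:
    def test_below_threshold_with_one_missing_passes(self):
        v = make_variant(maf_1000g=0.0005, maf_exac_nontcga=None)
        assert frequency_filter(v).passed

    def test_boundary_is_strict(self):
        v = make_variant(maf_exac_nontcga=0.001)
        assert not frequency_filter(v).passed

    def test_random_frequencies_match_max_then_compare_oracle(self):
        rng = random.Random(3)
        for _ in range(1000):
            m1 = rng.choice([None, rng.uniform(0, 0.01)])
            m2 = rng.choice([None, rng.uniform(0, 0.01)])
            t = rng.uniform(1e-5, 0.01)
            v = make_variant(maf_1000g=m1, maf_exac_nontcga=m2)
            oracle = max(m1 or 0.0, m2 or 0.0) < t
            assert frequency_filter(v, t).passed is oracle


def _pedigree(roles):
    samples = [
        Sample(f"S{i}", "F", role=r, sex="unknown") for i, r in enumerate(roles)
    ]
    return Pedigree("F", samples)


def _segregation_oracle(roles, dosages, policy):
    """Plain restatement of the dominant carrier-pattern rule."""
    strict = policy.missing_genotype_handling == "strict"
    cases = [d for r, d in zip(roles, dosages) if r == "case"]
    obligates = [d for r, d in zip(roles, dosages) if r == "obligate_carrier"]
    controls = [d for r, d in zip(roles, dosages) if r == "control"]
    if strict and (any(d is None for d in cases) or any(d is None for d in obligates)):
        return False
    case_known = [d for d in cases if d is not None]
    carriers = [d for d in case_known if d >= 1]
    if policy.require_all_cases:
        cases_ok = len(carriers) == len(case_known) and len(carriers) > 0
    else:
        cases_ok = len(carriers) > 0
    obl_known = [d for d in obligates if d is not None]
    obl_ok = all(d >= 1 for d in obl_known) if policy.obligate_carriers_must_carry else True
    ctrl_carriers = sum(1 for d in controls if d is not None and d >= 1)
    return cases_ok and obl_ok and ctrl_carriers <= policy.max_control_carriers


PEDIGREE_SHAPES = [
    ("case", "control"),
    ("case", "case", "control"),
    ("case", "control", "obligate_carrier"),
    ("case", "case", "control", "obligate_carrier"),
    ("case", "case", "case", "control"),
]


class TestSegregationFilter:
    def test_family1_shaped_candidate_passes(self):
        ped = Pedigree(
            "Family_1",
            [
                Sample("II-1", "Family_1", sex="male", role="control"),
                Sample("II-2", "Family_1", sex="female", role="case"),
                Sample("III-1", "Family_1", father_id="II-1", mother_id="II-2",
                       sex="female", role="case"),
            ],
        )
        v = make_variant(
            genotypes=[
                GenotypeCall("II-1", 0),
                GenotypeCall("II-2", 1),
                GenotypeCall("III-1", 1),
            ]
        )
        d = segregation_filter(v, ped)
        assert d.passed and "cases 2/2" in d.detail

    def test_no_carrier_among_cases_fails(self):
        ped = _pedigree(("case", "case", "control"))
        v = make_variant(genotypes=[GenotypeCall(f"S{i}", 0) for i in range(3)])
        assert not segregation_filter(v, ped).passed

    def test_unknown_sample_rejected(self):
        ped = _pedigree(("case",))
        v = make_variant(genotypes=[GenotypeCall("S0", 1), GenotypeCall("GHOST", 1)])
        with pytest.raises(ValueError, match="GHOST"):
            segregation_filter(v, ped)

    def test_zero_genotyped_cases_rejected(self):
        ped = _pedigree(("case", "control"))
        v = make_variant(genotypes=[GenotypeCall("S1", 1)])
        with pytest.raises(ValueError, match="zero genotyped cases"):
            segregation_filter(v, ped)

    @pytest.mark.parametrize("roles", PEDIGREE_SHAPES, ids="-".join)
    @pytest.mark.parametrize("missing", ["permissive", "strict"])
    @pytest.mark.parametrize("max_ctrl", [0, 1])
    def test_exhaustive_enumeration_matches_oracle(self, roles, missing, max_ctrl):
        """All <=4-member pedigrees x all dosage assignments x policies."""
        policy = SegregationPolicy(
            max_control_carriers=max_ctrl, missing_genotype_handling=missing
        )
        ped = _pedigree(roles)
        for dosages in itertools.product((0, 1, 2, None), repeat=len(roles)):
            v = make_variant(
                genotypes=[
                    GenotypeCall(f"S{i}", d) for i, d in enumerate(dosages)
                ]
            )
            got = segregation_filter(v, ped, policy).passed
            assert got is _segregation_oracle(roles, dosages, policy), (
                roles, dosages, missing, max_ctrl,
            )


class TestRunFunnel:
    def test_planted_variant_survives(self, small_cohort):
        for ped in small_cohort.pedigrees:
            survivors, _ = run_funnel(
                small_cohort.variants_by_family[ped.family_id], ped
            )
            assert small_cohort.planted_id(ped.family_id) in {
                v.variant_id for v in survivors
            }

    def test_empty_input(self, small_cohort):
        ped = small_cohort.pedigrees[0]
        survivors, counts = run_funnel([], ped)
        assert survivors == []
        assert all(i == 0 and o == 0 for _, i, o in counts.counts)

    def test_counts_are_conserved_and_chained(self, small_cohort):
        ped = small_cohort.pedigrees[0]
        variants = small_cohort.variants_by_family[ped.family_id]
        survivors, counts = run_funnel(variants, ped)
        stages = counts.counts
        assert stages[0][1] == len(variants)
        for (_, _, out_prev), (_, in_next, _) in zip(stages, stages[1:]):
            assert out_prev == in_next
        assert stages[-1][2] == len(survivors)

    def test_survivors_equal_conjunction_of_stage_predicates(self, small_cohort):
        """Stage order cannot change the final set: each stage is a pure
        predicate, so the survivors are exactly the variants passing all
        four stages independently."""
        ped = small_cohort.pedigrees[0]
        variants = small_cohort.variants_by_family[ped.family_id]
        survivors, _ = run_funnel(variants, ped)
        expected = {
            v.variant_id
            for v in variants
            if quality_filter(v).passed
            and strand_bias_filter(v).passed
            and frequency_filter(v).passed
            and segregation_filter(v, ped).passed
        }
        assert {v.variant_id for v in survivors} == expected

    @pytest.mark.parametrize(
        "strict_cfg,relaxed_cfg",
        [
            (FunnelConfig(), FunnelConfig(min_quality=0.0)),
            (FunnelConfig(), FunnelConfig(maf_threshold=0.01)),
            (
                FunnelConfig(),
                FunnelConfig(policy=SegregationPolicy(max_control_carriers=2)),
            ),
        ],
        ids=["quality", "maf", "control_carriers"],
    )
    def test_monotonicity_under_threshold_relaxation(
        self, small_cohort, strict_cfg, relaxed_cfg
    ):
        for ped in small_cohort.pedigrees:
            variants = small_cohort.variants_by_family[ped.family_id]
            strict, _ = run_funnel(variants, ped, strict_cfg)
            relaxed, _ = run_funnel(variants, ped, relaxed_cfg)
            assert {v.variant_id for v in strict} <= {
                v.variant_id for v in relaxed
            }
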