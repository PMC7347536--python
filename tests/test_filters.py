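import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmbkit.filters import (
    FilterConfig,
    FilterVerdict,
    apply_cascade,
    class_filter,
    dbsnp_cosmic_filter,
    maf_filter,
    pon_filter,
    splice_filter,
    support_filter,
)
from tmbkit.model import ContractError, PanelOfNormals, ValidationError

from conftest import make_call, make_callset, random_callset
from oracle import oracle_failed_rules

CFG = FilterConfig()
SYN_CFG = FilterConfig(include_synonymous=True)


class TestClassFilter:
    @pytest.mark.parametrize(
        "vclass,cfg,expected",
        [
            ("snv", CFG, True),
            ("indel", CFG, True),
            ("frameshift", CFG, True),
            ("start_stop", CFG, True),
            ("synonymous", CFG, False),
            ("synonymous", SYN_CFG, True),
            ("other", CFG, False),
            ("other", SYN_CFG, False),
        ],
    )
    def test_class_gate(self, vclass, cfg, expected):
        assert class_filter(make_call(variant_class=vclass), cfg) is expected

    def test_splice_delegates_to_window(self):
        assert class_filter(
            make_call(variant_class="splice", splice_offset=2), CFG
        )
        assert not class_filter(
            make_call(variant_class="splice", splice_offset=3), CFG
        )


class TestSpliceFilter:
    @pytest.mark.parametrize(
        "offset,expected",
        [(2, True), (-2, True), (0, True), (1, True), (-3, False), (3, False)],
    )
    def test_two_bp_window(self, offset, expected):
        call = make_call(variant_class="splice", splice_offset=offset)
        assert splice_filter(call, CFG) is expected

    def test_missing_offset_is_an_error(self):
        call = make_call(variant_class="splice")
        with pytest.raises(ValidationError):
            splice_filter(call, CFG)

    def test_non_splice_call_rejected(self):
        with pytest.raises(ContractError):
            splice_filter(make_call(variant_class="snv"), CFG)


class TestMafFilter:
    @pytest.mark.parametrize(
        "maf,expected",
        [
            (5e-5, True),   # 0.005%, below the 0.01% gate
            (2e-4, False),  # 0.02%, above
            (1e-4, False),  # exactly at the gate: strict <
            (None, True),   # unseen in the resource
        ],
    )
    def test_frequency_gate(self, maf, expected):
        assert maf_filter(make_call(population_maf=maf), CFG) is expected


class TestDbsnpCosmicFilter:
    @pytest.mark.parametrize(
        "in_dbsnp,in_cosmic,expected",
        [(True, False, False), (True, True, True), (False, False, True),
         (False, True, True)],
    )
    def test_dbsnp_unless_cosmic(self, in_dbsnp, in_cosmic, expected):
        call = make_call(in_dbsnp=in_dbsnp, in_cosmic=in_cosmic)
        assert dbsnp_cosmic_filter(call) is expected


class TestSupportFilter:
    def test_all_boundaries_inclusive(self):
        call = make_call(total_depth=100, alt_depth=5, mq_pass_fraction=0.90)
        assert call.vaf == 0.05
        assert support_filter(call, CFG)

    @pytest.mark.parametrize(
        "depth,alt,mq,expected",
        [
            (100, 4, 1.0, False),   # below read floor even at 50% VAF
            (125, 5, 0.95, False),  # vaf 0.04 below floor
            (100, 5, 0.89, False),  # MQ fraction below floor
            (10, 5, 0.95, True),
        ],
    )
    def test_around_thresholds(self, depth, alt, mq, expected):
        call = make_call(total_depth=depth, alt_depth=alt, mq_pass_fraction=mq)
        assert support_filter(call, CFG) is expected


class TestPonFilter:
    def test_ratio_above_four_passes(self):
        pon = PanelOfNormals(
            entries={("chr1", 100, "C", "T"): [("n1", 0.05)]}, n_normals=1
        )
        call = make_call(pos=100, total_depth=100, alt_depth=40)  # Af 0.40
        assert pon_filter(call, pon, CFG)  # ratio 8 > 4

    def test_ratio_two_fails(self):
        pon = PanelOfNormals(
            entries={("chr1", 100, "C", "T"): [("n1", 0.05)]}, n_normals=1
        )
        call = make_call(pos=100, total_depth=100, alt_depth=10)  # Af 0.10
        assert not pon_filter(call, pon, CFG)

    def test_ratio_exactly_four_fails(self):
        pon = PanelOfNormals(
            entries={("chr1", 100, "C", "T"): [("n1", 0.1)]}, n_normals=1
        )
        call = make_call(pos=100, total_depth=100, alt_depth=40)  # ratio == 4
        assert not pon_filter(call, pon, CFG)

    def test_absent_from_all_normals_passes(self, empty_pon):
        assert pon_filter(make_call(), empty_pon, CFG)

    def test_must_hold_against_every_detected_normal(self):
        pon = PanelOfNormals(
            entries={("chr1", 100, "C", "T"): [("n1", 0.01), ("n2", 0.3)]},
            n_normals=2,
        )
        call = make_call(pos=100, total_depth=100, alt_depth=40)
        assert not pon_filter(call, pon, CFG)  # fails against n2


class TestCascade:
    def test_independent_rules_all_reported(self, empty_pon):
        call = make_call(population_maf=0.3, in_dbsnp=True)
        verdicts = apply_cascade(make_callset([call]), empty_pon, CFG)
        assert verdicts[call.key] == FilterVerdict(
            passed=False, failed_rules=("maf", "dbsnp")
        )

    def test_three_call_fixture(self):
        germline = make_call(
            pos=10, total_depth=100, alt_depth=50, population_maf=0.3,
            in_dbsnp=True,
        )
        artifact = make_call(pos=20, total_depth=100, alt_depth=3)
        somatic = make_call(pos=30, total_depth=100, alt_depth=40)
        cs = make_callset([germline, artifact, somatic])
        pon = PanelOfNormals(entries={}, n_normals=21)
        verdicts = apply_cascade(cs, pon, CFG)
        # oracle: re-evaluate each rule by hand
        for call in cs:
            expected = oracle_failed_rules(call, {}, CFG)
            assert set(verdicts[call.key].failed_rules) == expected
        assert set(verdicts[germline.key].failed_rules) == {"maf", "dbsnp"}
        assert set(verdicts[artifact.key].failed_rules) == {"support"}
        assert verdicts[somatic.key].passed

    def test_paired_with_empty_normal_equals_tumor_only(self, empty_pon):
        calls = [make_call(pos=p) for p in (1, 2, 3)]
        tumor_only = apply_cascade(make_callset(calls), empty_pon, CFG)
        paired_cs = make_callset(
            calls, mode="paired", matched_normal_id="N1"
        )
        paired = apply_cascade(
            paired_cs, empty_pon, CFG,
            matched_normal=make_callset([], sample_id="N1"),
        )
        assert tumor_only == paired

    def test_paired_mode_requires_normal(self, empty_pon):
        cs = make_callset([make_call()], mode="paired", matched_normal_id="N")
        with pytest.raises(ContractError):
            apply_cascade(cs, empty_pon, CFG)

    def test_oracle_equivalence_on_random_callsets(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            cs, pon = random_callset(rng, int(rng.integers(1, 60)))
            verdicts = apply_cascade(cs, pon, CFG)
            plain = {k: [af for _, af in v] for k, v in pon.entries.items()}
            for call in cs:
                assert set(verdicts[call.key].failed_rules) == oracle_failed_rules(
                    call, plain, CFG
                ), call

    def test_paired_pass_set_subset_of_tumor_only(self):
        rng = np.random.default_rng(11)
        cs, pon = random_callset(rng, 80)
        normal_calls = [
            make_call(pos=c.pos, total_depth=100, alt_depth=50)
            for c in list(cs)[::3]
        ]
        normal = make_callset(normal_calls, sample_id="N1")
        v_to = apply_cascade(cs, pon, CFG)
        paired_cs = make_callset(list(cs), mode="paired", matched_normal_id="N1")
        v_pa = apply_cascade(paired_cs, pon, CFG, matched_normal=normal)
        pass_to = {k for k, v in v_to.items() if v.passed}
        pass_pa = {k for k, v in v_pa.items() if v.passed}
        assert pass_pa <= pass_to

    def test_synonymous_mode_only_adds_synonymous_calls(self):
        rng = np.random.default_rng(13)
        cs, pon = random_callset(rng, 120)
        v_excl = apply_cascade(cs, pon, CFG)
        v_incl = apply_cascade(cs, pon, SYN_CFG)
        pass_excl = {k for k, v in v_excl.items() if v.passed}
        pass_incl = {k for k, v in v_incl.items() if v.passed}
        assert pass_excl <= pass_incl
        gained = pass_incl - pass_excl
        by_key = {c.key: c for c in cs}
        assert all(by_key[k].variant_class == "synonymous" for k in gained)


tighten = st.sampled_from(
    ["min_vaf", "min_alt_reads", "pon_ratio", "maf_threshold", "splice_window_bp",
     "min_mq_pass_fraction"]
)


class TestMonotonicity:
    @given(seed=st.integers(0, 200), which=tighten)
    @settings(max_examples=60)
    def test_tightening_never_grows_pass_set(self, seed, which):
        rng = np.random.default_rng(seed)
        cs, pon = random_callset(rng, 40)
        base = FilterConfig(include_synonymous=True)
        if which in ("min_vaf", "min_mq_pass_fraction"):
            new = getattr(base, which) + 0.05
        elif which in ("min_alt_reads", "pon_ratio"):
            new = getattr(base, which) + 3
        elif which == "maf_threshold":
            new = base.maf_threshold / 10
        else:  # splice_window_bp
            new = 1
        tight = dataclasses.replace(base, **{which: new})
        pass_base = {
            k for k, v in apply_cascade(cs, pon, base).items() if v.passed
        }
        pass_tight = {
            k for k, v in apply_cascade(cs, pon, tight).items() if v.passed
        }
        assert pass_tight <= pass_base


class TestFilterConfig:
    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValidationError):
            FilterConfig(min_vaf=0)
        with pytest.raises(ValidationError):
            FilterConfig(maf_threshold=-1e-4)
        with pytest.raises(ValidationError):
            FilterConfig(min_vaf=1.0)

    def test_verdict_consistency_enforced(self):
        with pytest.raises(ValidationError):
            FilterVerdict(passed=True, failed_rules=("maf",))
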