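import numpy as np
import pytest

from tmbkit.filters import FilterConfig
from tmbkit.model import ValidationError
from tmbkit.pipeline import call_assay
from tmbkit.simulate import (
    SimulationConfig,
    build_population_pool,
    project_to_panel,
    simulate_cohort,
    simulate_pon,
    simulate_sample,
    simulate_territories,
)

SMALL = SimulationConfig(
    seed=17, exome_mb=3.0, panel_specs=(("panel_A", 0.5),),
    germline_het_per_exome=400, tmb_true=20,
)


@pytest.fixture(scope="module")
def small_world():
    exome, panels = simulate_territories(SMALL)
    pool = build_population_pool(SMALL, exome)
    return exome, panels, pool


class TestTerritories:
    def test_exome_hits_target_size(self, small_world):
        exome, _, _ = small_world
        assert exome.coding_mb == pytest.approx(3.0, rel=0.01)

    def test_default_exome_scale(self):
        cfg = SimulationConfig(seed=2)
        exome, panels = simulate_territories(cfg)
        assert 35.5 <= exome.coding_mb <= 36.3
        sizes = {p.name: p.coding_mb for p in panels}
        assert sizes["panel_D"] == pytest.approx(1.1, rel=0.01)
        assert sizes["panel_E"] == pytest.approx(1.3, rel=0.01)

    def test_deterministic_given_seed(self):
        a, pa = simulate_territories(SMALL)
        b, pb = simulate_territories(SMALL)
        assert a.intervals == b.intervals
        assert [p.intervals for p in pa] == [p.intervals for p in pb]

    def test_panel_contained_in_exome(self, small_world):
        exome, panels, _ = small_world
        for chrom, start, end in panels[0].intervals:
            assert exome.contains(chrom, start)
            assert exome.contains(chrom, end - 1)

    def test_oversized_panel_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(exome_mb=1.0, panel_specs=(("big", 2.0),))


class TestSimulateSample:
    def test_deterministic(self, small_world):
        exome, _, pool = small_world
        a = simulate_sample(SMALL, exome, pool, "S1")
        b = simulate_sample(SMALL, exome, pool, "S1")
        assert a.truth.equals(b.truth)
        assert [c.key for c in a.assays["exome"].callset] == [
            c.key for c in b.assays["exome"].callset
        ]
        assert a.assays["exome"].callset.calls == b.assays["exome"].callset.calls

    def test_somatic_count_poisson_scale(self, small_world):
        exome, _, pool = small_world
        s = simulate_sample(SMALL, exome, pool, "S2", with_normal=False)
        n_somatic = (s.truth["label"] == "somatic").sum()
        mean = SMALL.tmb_true * exome.coding_mb
        assert abs(n_somatic - mean) < 4 * np.sqrt(mean)

    def test_full_purity_gives_half_vaf(self, small_world):
        exome, _, pool = small_world
        cfg = SimulationConfig(
            seed=17, exome_mb=3.0, panel_specs=(), purity=1.0,
            germline_het_per_exome=0, tmb_true=50, artifact_rate_per_mb=0.0,
        )
        s = simulate_sample(cfg, exome, pool, "S3", with_normal=False)
        som = s.truth[s.truth["label"] == "somatic"]
        assert som["true_vaf"].mean() == pytest.approx(0.5, abs=0.03)

    def test_zero_artifact_rate_means_no_artifacts(self, small_world):
        exome, _, pool = small_world
        cfg = SimulationConfig(
            seed=17, exome_mb=3.0, panel_specs=(),
            germline_het_per_exome=50, artifact_rate_per_mb=0.0,
        )
        s = simulate_sample(cfg, exome, pool, "S4", with_normal=False)
        assert (s.truth["label"] == "artifact").sum() == 0

    def test_truth_maps_to_calls_uniquely(self, small_world):
        exome, _, pool = small_world
        s = simulate_sample(SMALL, exome, pool, "S5", with_normal=False)
        truth_keys = set(
            zip(s.truth["chrom"], s.truth["pos0"] + 1, s.truth["ref"], s.truth["alt"])
        )
        call_keys = [c.key for c in s.assays["exome"].callset]
        assert len(call_keys) == len(set(call_keys))
        assert set(call_keys) <= truth_keys


class TestProjectToPanel:
    def test_identity_projection_keeps_all_keys(self, small_world):
        exome, _, pool = small_world
        s = simulate_sample(SMALL, exome, pool, "S6", with_normal=False)
        data = project_to_panel(SMALL, s, exome)
        # same truth restriction; calls may differ in depth draw but keys are
        # a subset of truth either way and every truth variant was re-tried
        exome_keys = {c.key for c in s.assays["exome"].callset}
        panel_keys = {c.key for c in data.callset}
        # deep coverage: dropout is the only source of asymmetry
        assert len(exome_keys ^ panel_keys) <= 0.02 * len(exome_keys)

    def test_retained_fraction_tracks_panel_size(self, small_world):
        exome, panels, pool = small_world
        s = simulate_sample(SMALL, exome, pool, "S7", with_normal=False)
        data = project_to_panel(SMALL, s, panels[0])
        som_exome = (s.truth["label"] == "somatic").sum()
        som_panel = sum(
            1 for c in data.callset if c.truth_label == "somatic"
        )
        expected = panels[0].coding_mb / exome.coding_mb
        observed = som_panel / som_exome
        assert observed == pytest.approx(expected, abs=3 * np.sqrt(expected / som_exome))

    def test_empty_panel_empty_callset(self, small_world):
        from tmbkit.model import Territory

        exome, _, pool = small_world
        s = simulate_sample(SMALL, exome, pool, "S8", with_normal=False)
        empty = Territory.from_intervals("empty", [])
        data = project_to_panel(SMALL, s, empty)
        assert len(data.callset) == 0


class TestSimulatePon:
    def test_reports_configured_normal_count(self, small_world):
        exome, _, pool = small_world
        pon = simulate_pon(SMALL, exome, pool)
        assert pon.n_normals == SMALL.n_normals_pon == 21

    def test_shared_germline_site_fails_ratio_rule(self, small_world):
        from tmbkit.filters import pon_filter

        from conftest import make_call

        exome, _, pool = small_world
        pon = simulate_pon(SMALL, exome, pool)
        # find a pool site detected in at least one normal
        key = next(iter(pon.entries))
        chrom, pos, ref, alt = key
        tumor_het = make_call(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            total_depth=100, alt_depth=50,
        )
        assert not pon_filter(tumor_het, pon, FilterConfig())

    def test_site_absent_from_normals_passes(self, small_world):
        from tmbkit.filters import pon_filter

        from conftest import make_call

        exome, _, pool = small_world
        pon = simulate_pon(SMALL, exome, pool)
        call = make_call(chrom="chrZ", pos=1, total_depth=100, alt_depth=40)
        assert pon_filter(call, pon, FilterConfig())


class TestCohort:
    def test_germline_overhead_accounting_small(self, small_world):
        from tmbkit.pipeline import germline_accounting

        cohort = simulate_cohort(SMALL, n_samples=2, with_panels=False)
        for sample in cohort.samples:
            delta, germline_lost = germline_accounting(
                sample, cohort, FilterConfig(include_synonymous=True)
            )
            assert delta == germline_lost
            assert delta >= 0

    def test_paired_estimate_tracks_truth(self, small_world):
        cohort = simulate_cohort(
            SMALL, n_samples=2, tmb_values=[20.0, 20.0], with_panels=False
        )
        for sample in cohort.samples:
            data = sample.assays["exome"]
            _, res = call_assay(
                data.callset, data.coverage, cohort.exome, cohort.pon,
                FilterConfig(include_synonymous=True),
                mode="paired", matched_normal=sample.normal.callset,
            )
            truth = sample.truth_tmb(cohort.exome.coding_mb)
            assert res.tmb == pytest.approx(truth, rel=0.25)
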