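"""Synthetic super-child generation: designs, noise structure, compositing."""

import numpy as np
import pytest

from retikin import (
    ChildRecord,
    StudyDesign,
    composite,
    generate_children,
    presets,
    pv_model,
    simulate_tracer,
)

from conftest import make_study


class TestPlasmaVolume:
    def test_toy_coefficients(self):
        assert pv_model(8.4, (0.0, 0.05)) == pytest.approx(0.42)

    def test_proportional_model_scales_with_weight(self):
        assert pv_model(16.8, (0.0, 0.05)) == pytest.approx(2.0 * pv_model(8.4, (0.0, 0.05)))

    def test_missing_coefficients_rejected(self):
        with pytest.raises(ValueError, match="coefficients"):
            pv_model(8.4, None)

    def test_calibrated_presets_recover_group_pool(self, group):
        c = presets.GROUP_CONSTANTS[group]
        pv = pv_model(c["mean_weight_kg"], presets.PV_COEFFICIENTS[group])
        assert pv * c["retinol_conc"] == pytest.approx(c["m5"], rel=1e-12)


class TestDesigns:
    def test_two_sample_design_counts(self):
        design = presets.group_design("guatemala")
        counts = design.expected_counts()
        assert counts[design.anchor] == design.n_children
        others = [c for t, c in counts.items() if t != design.anchor]
        assert sum(others) == design.n_children
        assert max(others) - min(others) <= 1

    def test_one_sample_design_counts_match_stated_pattern(self):
        design = presets.group_design("bangladesh")
        counts = design.expected_counts()
        assert counts[4.0] == 40
        assert all(5 <= counts[t] <= 6 for t in design.schedule if t != 4.0)
        assert sum(counts.values()) == design.n_children

    def test_future_design_preset(self):
        design = presets.group_design("future-design")
        assert design.n_children == 60
        assert design.anchor == 7.0
        assert len(design.schedule) == 13
        assert design.schedule[0] == pytest.approx(5 / 24)
        assert design.schedule[-1] == 42

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError, match="per_time_counts"):
            StudyDesign(
                n_children=10,
                schedule=(1.0, 4.0),
                anchor=4.0,
                samples_per_child=1,
                per_time_counts={1.0: 3, 4.0: 3},
            )

    def test_generated_counts_realize_design(self, group):
        children, design, _ = make_study(group, seed=5)
        realized: dict[float, int] = {}
        for child in children:
            for t in child.times:
                realized[t] = realized.get(t, 0) + 1
        assert realized == design.expected_counts()


class TestGeneration:
    def test_fixed_seed_reproduces_bitwise(self, group):
        a, _, _ = make_study(group, seed=11)
        b, _, _ = make_study(group, seed=11)
        assert a == b

    def test_different_seed_differs(self, group):
        a, _, _ = make_study(group, seed=11)
        b, _, _ = make_study(group, seed=12)
        assert a != b

    def test_zero_noise_zero_variability_reproduces_group_curve(self, group):
        children, _, _ = make_study(group, seed=3, noise_cv=0.0, variability={})
        truth = presets.group_model(group)
        for child in children[:10]:
            expected = simulate_tracer(truth, np.asarray(child.times)).fdp
            np.testing.assert_allclose(child.fdp, expected, rtol=1e-12)

    def test_fdp_definition_holds(self, group):
        children, _, _ = make_study(group, seed=9)
        child = children[0]
        for f, c in zip(child.fdp, child.c13_retinol_umol_l):
            assert f == pytest.approx(c * child.plasma_volume_l / child.dose_umol, rel=1e-12)

    def test_seed_required(self):
        truth = presets.group_model("guatemala")
        c = presets.GROUP_CONSTANTS["guatemala"]
        with pytest.raises(ValueError, match="seed"):
            generate_children(
                truth, m5=c["m5"], u3=c["u3"], design=presets.group_design("guatemala"),
                pv_coefficients=presets.PV_COEFFICIENTS["guatemala"],
                mean_weight_kg=c["mean_weight_kg"], weight_sd_kg=c["weight_sd_kg"],
                retinol_conc_umol_l=c["retinol_conc"], seed=None,
            )


class TestComposite:
    def _child(self, cid, t, fdp, pv=0.5, dose=1.0, conc_total=1.0):
        return ChildRecord(
            child_id=cid, weight_kg=10.0, dose_umol=dose, plasma_volume_l=pv,
            times=(t,), c13_retinol_umol_l=(fdp * dose / pv,),
            total_retinol_umol_l=(conc_total,),
        )

    def test_geometric_mean_of_two(self):
        children = [self._child(0, 4.0, 0.001), self._child(1, 4.0, 0.004)]
        ds = composite(children, group="toy", u3=1.0)
        assert ds.fdp[0] == pytest.approx(0.002, rel=1e-12)
        assert ds.n[0] == 2
        assert ds.fsd[0] == 0.025  # anchor weight

    def test_noise_free_composite_equals_truth(self, group):
        children, design, c = make_study(group, seed=2, noise_cv=0.0, variability={})
        ds = composite(children, group=group, u3=c["u3"], anchor=design.anchor)
        truth_fdp = simulate_tracer(presets.group_model(group), ds.times).fdp
        np.testing.assert_allclose(ds.fdp, truth_fdp, rtol=1e-10)
        assert ds.u3 == c["u3"]

    def test_composite_pool_near_group_constant(self, group):
        children, design, c = make_study(group, seed=21)
        ds = composite(children, group=group, u3=c["u3"], anchor=design.anchor)
        assert ds.m5 == pytest.approx(c["m5"], rel=0.10)

    def test_lognormal_noise_is_median_unbiased_under_geomean(self):
        """Geometric-mean compositing is exact for log-normal noise: the mean
        log composite equals the log truth within Monte Carlo error."""
        noise_cv = 0.3
        design = StudyDesign(
            n_children=1000, schedule=(1.0, 4.0), anchor=4.0,
            samples_per_child=1, per_time_counts={1.0: 0, 4.0: 1000},
        )
        c = presets.GROUP_CONSTANTS["philippines"]
        truth = presets.group_model("philippines")
        children = generate_children(
            truth, m5=c["m5"], u3=c["u3"], design=design,
            pv_coefficients=presets.PV_COEFFICIENTS["philippines"],
            mean_weight_kg=c["mean_weight_kg"], weight_sd_kg=c["weight_sd_kg"],
            retinol_conc_umol_l=c["retinol_conc"], seed=17,
            noise_cv=noise_cv, variability={},
        )
        ds = composite(children, group="philippines", u3=c["u3"])
        truth_fdp = simulate_tracer(truth, ds.times).fdp[0]
        sigma = np.sqrt(np.log(1.0 + noise_cv**2))
        tol = 3.0 * sigma / np.sqrt(1000)
        assert abs(np.log(ds.fdp[0]) - np.log(truth_fdp)) < tol

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no children"):
            composite([], group="toy", u3=1.0)
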