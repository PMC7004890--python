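"""Weighted least squares with parameter sharing: objective, fit, identifiability."""

import numpy as np
import pytest

from retikin import (
    CompositeDataset,
    SharingMap,
    build_group_model,
    composite,
    fit,
    fsd_report,
    objective,
    presets,
    simulate_tracer,
    solve_steady_state,
)

from conftest import make_study, single_group_sharing

ADJUSTABLE = ("DT(3)", "L(5,4)", "L(7,5)", "L(5,7)", "L(6,5)", "L(5,6)", "L(10,6)")


def noise_free_dataset(group="philippines", self_consistent_intake=True):
    """Composite dataset equal to the group truth curve at the schedule times."""
    truth = presets.group_model(group)
    c = presets.GROUP_CONSTANTS[group]
    times = np.array(presets.STANDARD_SCHEDULE, dtype=float)
    fdp = simulate_tracer(truth, times).fdp
    u3 = c["u3"]
    if self_consistent_intake:
        u3 = solve_steady_state(truth, c["m5"], c["u3"]).predicted_intake
    fsd = np.where(times == 4.0, 0.025, 0.05)
    return CompositeDataset(
        group=group,
        times=times,
        fdp=fdp,
        n=np.ones_like(times, dtype=int),
        fsd=fsd,
        m5=c["m5"],
        u3=u3,
    )


def theta_for(sharing, datasets, values):
    groups = [d.group for d in datasets]
    return np.array([values[name] for name, _ in sharing.entries(groups)])


class TestObjective:
    def test_zero_at_generating_truth(self):
        ds = noise_free_dataset()
        sharing = single_group_sharing("philippines")
        theta = theta_for(sharing, [ds], presets.GROUP_PARAMETERS["philippines"])
        res = objective(theta, [ds], sharing)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_perturbing_slope_parameter_costs(self):
        ds = noise_free_dataset()
        sharing = single_group_sharing("philippines")
        values = dict(presets.GROUP_PARAMETERS["philippines"])
        values["L(10,6)"] *= 1.1
        res = objective(theta_for(sharing, [ds], values), [ds], sharing)
        assert np.sum(res**2) > 0.0

    def test_doubling_fsd_halves_residuals(self):
        """Rescaling all weights rescales the objective; the argmin is unchanged."""
        ds = noise_free_dataset()
        sharing = single_group_sharing("philippines")
        values = dict(presets.GROUP_PARAMETERS["philippines"])
        values["L(6,5)"] *= 1.3
        theta = theta_for(sharing, [ds], values)
        r1 = objective(theta, [ds], sharing)
        ds2 = CompositeDataset(
            group=ds.group, times=ds.times, fdp=ds.fdp, n=ds.n,
            fsd=2.0 * ds.fsd, m5=ds.m5, u3=ds.u3, intake_fsd=2.0 * ds.intake_fsd,
        )
        r2 = objective(theta, [ds2], sharing)
        np.testing.assert_allclose(r2, r1 / 2.0, rtol=1e-12)

    def test_anchor_weight_counts_fourfold(self):
        """FSD 0.025 at the anchor gives that residual 4x the weight in the WSS
        of an equal relative deviation weighted at FSD 0.05."""
        ds = noise_free_dataset()
        sharing = single_group_sharing("philippines")
        values = dict(presets.GROUP_PARAMETERS["philippines"])
        values["L(6,5)"] *= 1.2
        res = objective(theta_for(sharing, [ds], values), [ds], sharing)
        plasma = res[: ds.times.size]
        rel_dev = plasma * ds.fsd  # back out the relative deviations
        anchor = ds.times == 4.0
        w = (plasma**2) / (rel_dev**2)  # per-point weight in the WSS
        assert w[anchor][0] == pytest.approx(4.0 * w[~anchor][0], rel=1e-9)

    def test_wrong_theta_length_rejected(self):
        ds = noise_free_dataset()
        sharing = single_group_sharing("philippines")
        with pytest.raises(ValueError, match="elements"):
            objective(np.ones(3), [ds], sharing)


class TestSharingMap:
    def test_duplicate_declaration_rejected(self):
        sharing = SharingMap(shared=["L(6,5)"], independent=["L(6,5)"])
        with pytest.raises(ValueError, match="more than once"):
            sharing.validate(["a", "b"])

    def test_fixed_and_adjustable_clash_rejected(self):
        sharing = presets.partially_parallel_sharing()
        sharing.fixed["L(6,5)"] = 12.3
        with pytest.raises(ValueError, match="both fixed and adjustable"):
            sharing.validate(list(presets.GROUPS))

    def test_uncovered_parameter_rejected(self):
        sharing = presets.partially_parallel_sharing()
        sharing.shared.remove("L(6,5)")
        with pytest.raises(ValueError, match="neither fixed nor adjustable"):
            sharing.validate(list(presets.GROUPS))

    def test_partially_parallel_layout(self):
        sharing = presets.partially_parallel_sharing()
        entries = sharing.entries(list(presets.GROUPS))
        names = [n for n, _ in entries]
        # 2 shared + 3 independent L(10,6) + 4 x (bangladesh + rest) = 13
        assert len(entries) == 13
        assert names.count("L(10,6)") == 3
        assert ("L(5,4)", ("bangladesh",)) in entries
        assert ("L(5,4)", ("philippines", "guatemala")) in entries


class TestFit:
    def test_noise_free_recovery_from_doubled_start(self):
        ds = noise_free_dataset()
        sharing = single_group_sharing("philippines")
        truth = presets.GROUP_PARAMETERS["philippines"]
        init = {name: 2.0 * value for name, value in truth.items()}
        result = fit([ds], sharing, init)
        assert result.success
        for name in ADJUSTABLE:
            assert result.estimate(name) == pytest.approx(truth[name], rel=1e-4), name

    def test_fully_shared_fit_on_duplicated_data_matches_single(self):
        ds = noise_free_dataset("guatemala")
        ds_copy = CompositeDataset(
            group="guatemala-dup", times=ds.times, fdp=ds.fdp, n=ds.n,
            fsd=ds.fsd, m5=ds.m5, u3=ds.u3,
        )
        fixed = {
            "L(4,3)": 0.8, "L(0,3)": 0.2, "DT(8)": 75.0 / 1440.0, "L(10,8)": 1.0,
            "L(8,5)": presets.GROUP_PARAMETERS["guatemala"]["L(8,5)"],
        }
        shared = SharingMap(shared=list(ADJUSTABLE), fixed=fixed)
        init = {n: 1.5 * v for n, v in presets.GROUP_PARAMETERS["guatemala"].items()}
        single = fit([ds], shared, init)
        double = fit([ds, ds_copy], shared, init)
        assert double.models["guatemala"].parameters() == double.models["guatemala-dup"].parameters()
        for name in ADJUSTABLE:
            assert double.estimate(name) == pytest.approx(single.estimate(name), rel=1e-6)

    def test_synthetic_recovery_with_noise(self):
        """One 3-group partially parallel fit at the study design with 5%
        log-normal measurement noise recovers every adjustable parameter."""
        datasets, init = [], {}
        for i, g in enumerate(presets.GROUPS):
            children, design, c = make_study(g, seed=42 + i, noise_cv=0.05, variability={})
            datasets.append(composite(children, group=g, u3=c["u3"], anchor=design.anchor))
            for name, value in presets.GROUP_PARAMETERS[g].items():
                init[(name, g)] = value
        result = fit(datasets, presets.partially_parallel_sharing(), init, seed=3, perturb=0.3)
        assert result.success
        for (name, groups), est in result.estimates.items():
            truth = presets.GROUP_PARAMETERS[groups[0]][name]
            assert est == pytest.approx(truth, rel=0.25), (name, groups)

    def test_nonconvergence_is_reported(self):
        ds = noise_free_dataset()
        sharing = single_group_sharing("philippines")
        init = {n: 2.0 * v for n, v in presets.GROUP_PARAMETERS["philippines"].items()}
        result = fit([ds], sharing, init, max_nfev=2)
        assert not result.success
        assert result.message


class TestFSDReport:
    def test_noise_free_fit_has_tiny_fsds(self):
        ds = noise_free_dataset()
        sharing = single_group_sharing("philippines")
        init = {n: 1.5 * v for n, v in presets.GROUP_PARAMETERS["philippines"].items()}
        report = fsd_report(fit([ds], sharing, init))
        finite = report["fsd"][np.isfinite(report["fsd"])]
        assert (finite < 0.01).all()

    def test_structural_unidentifiability_flagged(self):
        """Two pools with identical exit rates are interchangeable, so their
        inflow rates are only identified in sum: the fit must flag this."""
        params = {
            "DT(3)": 0.2, "L(5,4)": 1.0, "L(6,5)": 3.0, "L(7,5)": 2.0,
            "L(5,7)": 0.3, "L(5,6)": 0.3, "L(10,6)": 0.0, "L(8,5)": 1.0,
        }
        truth = build_group_model(params)
        times = np.array(presets.STANDARD_SCHEDULE, dtype=float)
        ds = CompositeDataset(
            group="toy", times=times, fdp=simulate_tracer(truth, times).fdp,
            n=np.ones_like(times, dtype=int), fsd=np.full_like(times, 0.05),
            m5=0.5, u3=1.0,
        )
        sharing = SharingMap(
            independent=["L(6,5)", "L(7,5)"],
            fixed={k: v for k, v in params.items() if k not in ("L(6,5)", "L(7,5)")}
            | {"L(4,3)": 0.8, "L(0,3)": 0.2, "DT(8)": 75.0 / 1440.0, "L(10,8)": 1.0},
        )
        result = fit([ds], sharing, {"L(6,5)": 2.5, "L(7,5)": 2.5}, use_intake=False)
        report = fsd_report(result)
        assert result.singular or report["poorly_identified"].any()


class TestDatasetValidation:
    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            CompositeDataset(
                group="x", times=[2.0, 1.0], fdp=[0.01, 0.01], n=[1, 1],
                fsd=[0.05, 0.05], m5=0.4, u3=1.0,
            )

    def test_nonpositive_fdp_rejected(self):
        with pytest.raises(ValueError, match="FDp"):
            CompositeDataset(
                group="x", times=[1.0, 2.0], fdp=[0.01, 0.0], n=[1, 1],
                fsd=[0.05, 0.05], m5=0.4, u3=1.0,
            )
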