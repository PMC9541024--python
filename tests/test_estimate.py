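"""Mixed-effects estimation: recovery limits, criteria, bootstrap, VPC."""

import numpy as np
import pandas as pd
import pytest

from piglet_pkpd.datasets import StudyDataset, StudyDesign, generate_study
from piglet_pkpd.estimate import (
    NonConvergenceError,
    _fast_predict,
    bootstrap,
    fit,
    fit_sequential,
    information_criteria,
    vpc,
)
from piglet_pkpd.population import ErrorSpec, PopulationModel
from piglet_pkpd.simulate import simulate_individual

PLASMA_DESIGN = StudyDesign(
    n_per_group=4,
    dose=3.0,
    schedule={"plasma": [0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0]},
    loq={"plasma": 0.001},
)


def _noiseless_pop(pop, sigma=1e-4):
    return PopulationModel(
        structural=pop.structural,
        omega2={},
        error={k: ErrorSpec(v.kind, sigma) for k, v in pop.error.items()},
    )


@pytest.fixture(scope="module")
def keto_plasma_study():
    from piglet_pkpd.config import design_from_config, load_config, load_population

    pop = load_population("ketoprofen_pge2")
    ds = generate_study(design_from_config(load_config("ketoprofen_pge2")), pop, seed=42)
    return pop, ds


class TestFastPredictEquivalence:
    """The optimiser's dict-based fast path must match the model objects."""

    def test_all_models(self, populations):
        t = {"plasma": np.array([0.25, 1.0, 6.0, 24.0]),
             "pd": np.array([2.0, 8.0, 24.0, 48.0])}
        for name, pop in populations.items():
            model = pop.structural
            params = dict(model.param_dict())
            params["dose"] = model.pk.dose
            kind = "two" if "K12" in params else "one"
            link = "isf" if "Ke0in" in params else "effect" if "Ke0" in params else None
            times = dict(t)
            if link == "isf":
                times["isf"] = np.array([2.0, 12.0, 48.0])
            preds = _fast_predict(kind, link, params, times, grid_step=0.01)
            np.testing.assert_allclose(preds["plasma"], model.plasma_expsum()(t["plasma"]),
                                       rtol=1e-12)
            traj = simulate_individual(model, times=times["pd"], grid_step=0.01)
            np.testing.assert_allclose(preds["pd"], traj.e, rtol=1e-9)
            if link == "isf":
                np.testing.assert_allclose(
                    preds["isf"], model.driver_expsum()(times["isf"]), rtol=1e-12
                )


class TestFit:
    def test_exact_recovery_in_noiseless_limit(self, keto_pge2):
        pop = _noiseless_pop(keto_pge2)
        ds = generate_study(PLASMA_DESIGN, pop, seed=1)
        res = fit(ds, pop, streams=["plasma"], free_theta=["Ka", "Ke", "V"],
                  fixed={"sigma_plasma"}, compute_se=False)
        truth = pop.structural.param_dict()
        for name in ("Ka", "Ke", "V"):
            assert res.theta[name] == pytest.approx(truth[name], rel=1e-3)

    def test_objective_history_monotone(self, keto_plasma_study):
        pop, ds = keto_plasma_study
        res = fit(ds, pop, streams=["plasma"], free_theta=["Ka", "Ke", "V"],
                  compute_se=False, maxfev=300, xtol=1e-3)
        hist = np.array(res.history)
        assert len(hist) >= 2
        assert np.all(np.diff(hist) <= 1e-6 * np.abs(hist[:-1]))

    def test_invariant_under_subject_relabeling(self, keto_plasma_study):
        pop, ds = keto_plasma_study
        relabeled = ds.frame.copy()
        relabeled["ID"] = relabeled["ID"].map(lambda i: 100 - i)
        relabeled = relabeled.sort_values(["ID", "TIME", "EVID"], ascending=[True, True, False])
        ds2 = StudyDataset(frame=relabeled.reset_index(drop=True))
        kwargs = dict(streams=["plasma"], free_theta=["Ka", "Ke", "V"],
                      compute_se=False, maxfev=300, xtol=1e-3)
        a = fit(ds, pop, **kwargs)
        b = fit(ds2, pop, **kwargs)
        for name in a.theta:
            assert a.theta[name] == pytest.approx(b.theta[name], rel=1e-3)

    def test_larger_iiv_in_generator_raises_estimate(self, keto_pge2, designs):
        # doubling the true IIV% of Ke should raise the estimated omega^2
        from piglet_pkpd.population import omega2_from_percent

        design = designs["ketoprofen_pge2"]
        base = keto_pge2
        doubled = PopulationModel(
            structural=base.structural,
            omega2={**base.omega2, "Ke": omega2_from_percent(2 * 23.31)},
            error=base.error,
        )
        kwargs = dict(streams=["plasma"], free_theta=["Ka", "Ke", "V"],
                      compute_se=False, maxfev=400, xtol=1e-3)
        est_base = fit(generate_study(design, base, seed=21), base, **kwargs)
        est_doubled = fit(generate_study(design, doubled, seed=21), doubled, **kwargs)
        assert est_doubled.omega2["Ke"] > est_base.omega2["Ke"]

    def test_empty_dataset_rejected(self, keto_pge2, designs):
        ds = generate_study(designs["ketoprofen_pge2"], keto_pge2, seed=1)
        frame = ds.frame[ds.frame["EVID"] == 1].reset_index(drop=True)
        with pytest.warns(UserWarning):
            empty = StudyDataset(frame=frame)
        with pytest.raises(ValueError):
            fit(empty, keto_pge2, streams=["plasma"])


class TestInformationCriteria:
    def test_zero_parameters_collapse_to_ofv(self, keto_pge2):
        pop = _noiseless_pop(keto_pge2, sigma=0.05)
        ds = generate_study(PLASMA_DESIGN, pop, seed=2)
        res = fit(ds, pop, streams=["plasma"], free_theta=[],
                  fixed={"sigma_plasma"}, compute_se=False)
        assert res.n_params == 0
        assert res.aic == res.bic == res.ofv
        aic, bic = information_criteria(res)
        assert aic == bic == res.ofv

    def test_nested_model_has_lower_or_equal_objective(self, keto_plasma_study):
        pop, ds = keto_plasma_study
        kwargs = dict(streams=["plasma"], compute_se=False, maxfev=400, xtol=1e-3)
        small = fit(ds, pop, free_theta=["Ke", "V"], **kwargs)
        large = fit(ds, pop, free_theta=["Ka", "Ke", "V"], **kwargs)
        assert large.ofv <= small.ofv + 1e-3

    def test_nonconverged_fit_rejected(self, keto_plasma_study):
        pop, ds = keto_plasma_study
        res = fit(ds, pop, streams=["plasma"], free_theta=["Ka", "Ke", "V"],
                  compute_se=False, maxfev=300)
        if res.converged:
            pytest.skip("optimizer converged within the tiny budget")
        with pytest.raises(NonConvergenceError):
            information_criteria(res)


class TestSequential:
    def test_pd_before_pk_rejected(self, keto_pge2, designs):
        design = designs["ketoprofen_pge2"]
        ds = generate_study(design, keto_pge2, seed=3)
        pd_only = StudyDataset(
            frame=ds.frame[(ds.frame["EVID"] == 1) | (ds.frame["DVID"] == 3)].reset_index(drop=True)
        )
        with pytest.raises(ValueError, match="PK must be fitted before PD"):
            fit_sequential(pd_only, ds, keto_pge2)

    def test_disjoint_subjects_rejected(self, keto_pge2, designs):
        design = designs["ketoprofen_pge2"]
        ds = generate_study(design, keto_pge2, seed=3)
        shifted = ds.frame.copy()
        shifted["ID"] += 100
        with pytest.raises(ValueError, match="share no subject"):
            fit_sequential(ds, StudyDataset(frame=shifted), keto_pge2)

    def test_pd_recovery_with_pk_frozen_to_truth(self, flunixin):
        # noiseless biomarker data, PK conditioned on truth -> turnover
        # parameters recovered to optimizer tolerance
        design = StudyDesign(
            n_per_group=4, dose=2.2,
            schedule={"plasma": [0.5, 2.0, 8.0], "pd": [0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0, 36.0, 48.0]},
        )
        pop = _noiseless_pop(flunixin, sigma=1e-3)
        ds = generate_study(design, pop, seed=4)
        truth = pop.structural.param_dict()
        frozen = {s: {k: truth[k] for k in ("Ka", "Ke", "K12", "K21", "V")}
                  for s in ds.subjects}
        res = fit(ds, pop, streams=["pd"], free_theta=["Kin", "Kout", "Imax", "IC50"],
                  subject_frozen=frozen, fixed={"sigma_pd"}, compute_se=False)
        for name in ("Kin", "Kout", "Imax", "IC50"):
            assert res.theta[name] == pytest.approx(truth[name], rel=0.02)


class TestBootstrap:
    def _identical_subject_dataset(self, pop):
        ds = generate_study(PLASMA_DESIGN, _noiseless_pop(pop), seed=5)
        one = ds.frame[ds.frame["ID"] == 1]
        frames = []
        for new_id in (1, 2, 3):
            sub = one.copy()
            sub["ID"] = new_id
            frames.append(sub)
        return StudyDataset(frame=pd.concat(frames, ignore_index=True))

    def test_zero_width_on_identical_subjects(self, keto_pge2):
        pop = _noiseless_pop(keto_pge2, sigma=0.05)
        ds = self._identical_subject_dataset(keto_pge2)
        res = bootstrap(ds, pop, n_rep=10, seed=6, streams=["plasma"],
                        free_theta=["Ka", "Ke", "V"], fixed={"sigma_plasma"},
                        maxfev=300, xtol=1e-3)
        assert res.n_failed == 0
        for name in ("Ka", "Ke", "V"):
            lo, hi = res.ci[name]
            assert hi - lo <= 1e-6 * res.median[name]

    def test_seeded_resamples_identical(self, keto_pge2):
        pop = _noiseless_pop(keto_pge2, sigma=0.05)
        ds = self._identical_subject_dataset(keto_pge2)
        kwargs = dict(streams=["plasma"], free_theta=["Ke", "V"],
                      fixed={"sigma_plasma"}, maxfev=200, xtol=1e-3)
        a = bootstrap(ds, pop, n_rep=4, seed=7, **kwargs)
        b = bootstrap(ds, pop, n_rep=4, seed=7, **kwargs)
        assert a.median == b.median
        assert a.estimates == b.estimates

    def test_single_subject_rejected(self, keto_pge2):
        ds = self._identical_subject_dataset(keto_pge2)
        only_one = StudyDataset(frame=ds.frame[ds.frame["ID"] == 1].reset_index(drop=True))
        with pytest.raises(ValueError):
            bootstrap(only_one, keto_pge2, n_rep=2)


@pytest.fixture(scope="module")
def plasma_fit():
    from piglet_pkpd.config import design_from_config, load_config, load_population

    pop = load_population("ketoprofen_pge2")
    ds = generate_study(design_from_config(load_config("ketoprofen_pge2")), pop, seed=8)
    res = fit(ds, pop, streams=["plasma"], free_theta=["Ka", "Ke", "V"],
              compute_se=False)
    assert res.converged
    return pop, ds, res


class TestVpc:
    def test_bands_reproducible_under_seed(self, plasma_fit):
        _, ds, res = plasma_fit
        a = vpc(res, ds, n_sim=20, seed=9, stream="plasma")
        b = vpc(res, ds, n_sim=20, seed=9, stream="plasma")
        np.testing.assert_array_equal(a.predicted_median, b.predicted_median)

    def test_single_replicate_bands_collapse(self, plasma_fit):
        _, ds, res = plasma_fit
        v = vpc(res, ds, n_sim=1, seed=10, stream="plasma")
        np.testing.assert_array_equal(v.predicted_low, v.predicted_high)
        np.testing.assert_array_equal(v.predicted_low, v.predicted_median)

    def test_observed_median_inside_band_for_self_simulated_data(self, plasma_fit):
        pop, ds, res = plasma_fit
        v = vpc(res, ds, n_sim=100, seed=11, stream="plasma")
        # only bins without BLQ censoring are a like-for-like comparison
        obs = ds.observations("plasma", include_blq=True)
        uncensored = np.array([not obs[obs["TIME"] == t]["BLQ"].any() for t in v.times])
        inside = (v.observed[1] >= v.predicted_low[1]) & (v.observed[1] <= v.predicted_high[1])
        assert inside[uncensored].mean() >= 0.9
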