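import numpy as np
import pandas as pd
import pytest

import tacpk.estimation as est
from oracles import quadrature_ofv
from tacpk.cohort import CohortSpec, simulate_cohort
from tacpk.estimation import (
    CovariateCandidate,
    FitError,
    covariate_step,
    fit,
    foce_objective,
    foce_objective_reference,
)
from tacpk.io import Dataset


def toy_dataset(model, n_subjects=2, days=(2, 4, 6, 9, 12, 15), seed=11):
    ds, _ = simulate_cohort(
        CohortSpec(n_subjects=n_subjects, sampling_days=days,
                   obs_per_subject_mean=len(days), seed=seed),
        model,
    )
    return ds


class TestObjective:
    def test_batched_equals_reference(self, cohort, model):
        dataset, _ = cohort
        for method in ("laplace", "focei"):
            ob, _ = foce_objective(dataset, model, method=method)
            orf, _ = foce_objective_reference(dataset, model, method)
            assert ob == pytest.approx(orf, abs=1e-4)

    def test_omega_zero_limit_is_wls_deviance(self, model):
        m0 = model.with_updates(omega_cl=0.0, omega_v=0.0)
        ds = toy_dataset(model, n_subjects=3, seed=4)
        ofv, etas = foce_objective(ds, m0)
        # independent computation of the fixed-effects deviance
        from tacpk.core_model import typical_values, PKParameters, concentration_profile, DoseEvent

        expected = 0.0
        for sd in ds.subjects():
            cl, v = typical_values(m0, sd.weight, sd.covariates)
            pred = concentration_profile(
                PKParameters(cl, v, m0.ka_fixed),
                [DoseEvent(t, a) for t, a in zip(sd.dose_times, sd.dose_amounts)],
                sd.obs_times,
            )
            var = pred**2 * m0.sigma_prop**2 + m0.sigma_add**2
            expected += float(np.sum((sd.obs_dv - pred) ** 2 / var + np.log(var)))
        assert ofv == pytest.approx(expected, abs=1e-6)
        for e in etas.values():
            assert e.eta_cl == 0.0 and e.eta_v == 0.0

    def test_matches_quadrature_on_toy(self, model):
        m = model.with_updates(omega_cl=0.25, omega_v=0.2, sigma_prop=0.2,
                               sigma_add=1.0)
        ds = toy_dataset(m, n_subjects=2, seed=21)
        ofv, _ = foce_objective(ds, m)
        oracle = quadrature_ofv(ds, m, n_points=201)
        assert ofv == pytest.approx(oracle, abs=0.1)

    def test_subject_order_invariance(self, model):
        ds = toy_dataset(model, n_subjects=4, seed=8)
        ev = ds.events
        order = ["S003", "S001", "S004", "S002"]
        shuffled = Dataset(
            pd.concat([ev[ev["ID"] == sid] for sid in order], ignore_index=True)
        )
        o1, _ = foce_objective(ds, model)
        o2, _ = foce_objective(shuffled, model)
        assert o1 == pytest.approx(o2, abs=1e-8)

    def test_relabeling_invariance(self, model):
        ds = toy_dataset(model, n_subjects=3, seed=8)
        ev = ds.events
        ev["ID"] = ev["ID"].map(lambda s: "X" + s)
        o1, _ = foce_objective(ds, model)
        o2, _ = foce_objective(Dataset(ev), model)
        assert o1 == pytest.approx(o2, abs=1e-8)

    def test_duplicating_subjects_doubles_ofv(self, model):
        ds = toy_dataset(model, n_subjects=3, seed=9)
        ev = ds.events
        dup = ev.copy()
        dup["ID"] = dup["ID"].map(lambda s: s + "_B")
        doubled = Dataset(pd.concat([ev, dup], ignore_index=True))
        o1, _ = foce_objective(ds, model)
        o2, _ = foce_objective(doubled, model)
        assert o2 == pytest.approx(2.0 * o1, rel=1e-9)

    def test_degenerate_residual_rejected(self, model):
        ds = toy_dataset(model, n_subjects=1)
        bad = model.with_updates(sigma_prop=0.0, sigma_add=0.0)
        with pytest.raises(FitError, match="residual variance"):
            foce_objective(ds, bad)


class TestFit:
    def test_noiseless_identifiability(self, model):
        gen = model.with_updates(omega_cl=0.0, omega_v=0.0,
                                 sigma_prop=1e-7, sigma_add=1e-7)
        ds = toy_dataset(gen, n_subjects=6, seed=13)
        start = gen.with_updates(tv_cl=10.0, tv_v=9000.0,
                                 sigma_prop=1e-4, sigma_add=1e-4)
        r = fit(ds, start,
                fixed={"omega_cl", "omega_v", "sigma_prop", "sigma_add"},
                compute_se=False)
        assert r.converged
        assert r.estimates.tv_cl == pytest.approx(13.1, rel=1e-3)
        assert r.estimates.tv_v == pytest.approx(10900.0, rel=1e-3)

    def test_multistart_consistency(self, cohort, model, fitted):
        dataset, _ = cohort
        r2 = fit(dataset, model.with_updates(tv_cl=2 * 13.1, tv_v=10900 / 2),
                 compute_se=False)
        assert abs(r2.ofv - fitted.ofv) < 0.01

    def test_ka_must_be_fixed(self, cohort, model):
        # ka is in the implicit fixed set; the packer never frees it
        dataset, _ = cohort
        r = fit(dataset, model, compute_se=False, maxiter=2)
        assert r.estimates.ka_fixed == model.ka_fixed

    def test_se_reported_for_free_parameters(self, cohort, model):
        dataset, _ = cohort
        r = fit(dataset, model, compute_se=True, maxiter=200)
        assert r.converged
        for p in ("tv_cl", "tv_v", "omega_cl", "omega_v",
                  "sigma_prop", "sigma_add"):
            assert p in r.se_percent
            assert r.se_percent[p] > 0

    def test_summary_rows_layout(self, fitted):
        rows = fitted.summary_rows()
        names = [r["parameter"] for r in rows]
        assert names[:3] == ["CL/F (L/h)", "V/F (L)", "Ka (1/h)"]
        assert rows[2]["se_percent"] is None  # fixed parameter


class TestParameterRecovery:
    def test_moderate_cohort_recovery(self, model):
        # informative design: troughs spanning six weeks of TDM
        spec = CohortSpec(n_subjects=80, sampling_days=(1, 3, 7, 14, 21, 28, 42),
                          extra_day_pool=(35, 49, 56), seed=17)
        ds, _ = simulate_cohort(spec, model)
        start = model.with_updates(tv_cl=9.0, tv_v=8000.0, omega_cl=0.3,
                                   omega_v=0.4, sigma_prop=0.2, sigma_add=1.0)
        r = fit(ds, start, compute_se=False)
        assert r.converged
        assert r.estimates.tv_cl == pytest.approx(13.1, rel=0.25)
        assert r.estimates.tv_v == pytest.approx(10900.0, rel=0.25)


class TestCovariateStepLogic:
    """Threshold decisions, isolated from real fitting via a fit stub."""

    @staticmethod
    def _stub_fit_factory(ofv_map):
        def stub(dataset, start, fixed=None, **kwargs):
            key = tuple(sorted(
                (e.covariate, e.parameter) for e in start.covariate_effects
            ))
            return est.FitResult(
                estimates=start, se_percent={}, ofv=ofv_map[key],
                post_hoc_etas={}, converged=True,
            )
        return stub

    def _run(self, monkeypatch, ofv_map, candidates, base_ofv=100.0):
        ds = object.__new__(Dataset)  # never touched by the stub
        monkeypatch.setattr(est, "fit", self._stub_fit_factory(ofv_map))
        monkeypatch.setattr(
            est, "_candidate_effect",
            lambda cand, dataset: est.CovariateEffect(
                cand.parameter, cand.covariate, "linear", 0.0, None
            ),
        )
        base = est.FitResult(
            estimates=est.PopulationModel(), se_percent={}, ofv=base_ofv,
            post_hoc_etas={}, converged=True,
        )
        return covariate_step(ds, base, candidates)

    def test_drop_above_threshold_included(self, monkeypatch):
        cands = [CovariateCandidate("cl", "ALB", "linear")]
        # inclusion lowers OFV by 4.0 (> 3.84) and its removal would raise
        # it back by 4.0 (< 6.63) -> included forward, removed backward
        ofv_map = {(("ALB", "cl"),): 96.0, (): 100.0}
        selected, trace = self._run(monkeypatch, ofv_map, cands)
        steps = [(t["step"], t["status"]) for t in trace]
        assert ("forward", "included") in steps
        assert ("backward", "removed") in steps
        assert len(selected.covariate_effects) == 0

    def test_drop_below_threshold_not_included(self, monkeypatch):
        cands = [CovariateCandidate("cl", "ALB", "linear")]
        ofv_map = {(("ALB", "cl"),): 97.0, (): 100.0}  # drop 3.0 < 3.84
        selected, trace = self._run(monkeypatch, ofv_map, cands)
        assert len(selected.covariate_effects) == 0
        assert all(t["status"] != "included" for t in trace)

    def test_backward_retains_strong_covariate(self, monkeypatch):
        cands = [CovariateCandidate("cl", "ALB", "linear")]
        ofv_map = {(("ALB", "cl"),): 90.0, (): 100.0}  # removal raises by 10 > 6.63
        selected, trace = self._run(monkeypatch, ofv_map, cands)
        assert len(selected.covariate_effects) == 1
        assert any(t["status"] == "retained" for t in trace)

    def test_largest_drop_wins(self, monkeypatch):
        cands = [CovariateCandidate("cl", "ALB", "linear"),
                 CovariateCandidate("cl", "AGE", "linear")]
        ofv_map = {
            (): 100.0,
            (("ALB", "cl"),): 95.0,
            (("AGE", "cl"),): 90.0,
            (("AGE", "cl"), ("ALB", "cl")): 89.0,
        }
        selected, trace = self._run(monkeypatch, ofv_map, cands)
        included = [t for t in trace if t["status"] == "included"]
        assert included[0]["candidate"].startswith("AGE")
        # ALB only drops 1.0 more on top of AGE -> not included; AGE
        # removal raises OFV by 10 -> retained
        assert [e.covariate for e in selected.covariate_effects] == ["AGE"]

    def test_unconverged_base_rejected(self):
        base = est.FitResult(
            estimates=est.PopulationModel(), se_percent={}, ofv=1.0,
            post_hoc_etas={}, converged=False,
        )
        with pytest.raises(FitError, match="converged"):
            covariate_step(None, base, [])


class TestCovariateStepReal:
    def test_detects_true_strong_covariate(self, model):
        # simulate with a real ALB power effect on CL and recover it
        from tacpk.core_model import CovariateEffect

        gen = model.with_updates(covariate_effects=(
            CovariateEffect("cl", "ALB", "power", 2.5, 32.9),
        ))
        spec = CohortSpec(n_subjects=40, seed=77)
        ds, _ = simulate_cohort(spec, gen)
        base = fit(ds, model, compute_se=False)
        assert base.converged
        selected, trace = covariate_step(
            ds, base, [CovariateCandidate("cl", "ALB", "power")]
        )
        assert [e.covariate for e in selected.covariate_effects] == ["ALB"]
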