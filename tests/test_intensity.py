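import math

import numpy as np
import pandas as pd
import pytest

from iiwbias import (
    OutcomeModelSpec,
    VisitModelSpec,
    build_counting_process,
    compute_weights,
    fit_intensity,
    simulate_cohort,
)
from iiwbias.intensity import AndersenGillIntensity, _PartialLikelihood
from iiwbias.simulate import SubjectPath


def _path(sid, times, outcomes, y0=1.0):
    return SubjectPath(sid, y0, np.asarray(times, float), np.asarray(outcomes, float))


class TestCountingProcess:
    def test_zero_visit_subject_is_single_censored_row(self):
        rows = build_counting_process([_path("a", [], [])], VisitModelSpec(tau=2.0))
        assert len(rows) == 1
        r = rows.iloc[0]
        assert (r["start"], r["stop"], r["event"]) == (0.0, 2.0, 0)
        assert r["z"] == pytest.approx(math.log(2.0))  # baseline outcome 1.0

    def test_intervals_partition_follow_up(self):
        rows = build_counting_process(
            [_path("a", [0.5, 1.5], [2.0, 3.0])], VisitModelSpec(tau=2.0)
        )
        assert rows["start"].tolist() == [0.0, 0.5, 1.5]
        assert rows["stop"].tolist() == [0.5, 1.5, 2.0]
        assert rows["event"].tolist() == [1, 1, 0]
        # covariate on each interval comes from the left-endpoint outcome
        assert rows["z"].tolist() == pytest.approx(
            [math.log(2.0), math.log(3.0), math.log(4.0)]
        )

    def test_event_count_is_conserved(self, small_cohort):
        rows = build_counting_process(small_cohort, VisitModelSpec())
        assert rows["event"].sum() == sum(p.n_visits for p in small_cohort)
        # every subject's intervals abut: start equals the previous stop
        for _, grp in rows.groupby("subject_id"):
            assert grp["start"].iloc[0] == 0.0
            assert np.allclose(grp["start"].to_numpy()[1:], grp["stop"].to_numpy()[:-1])

    def test_duplicate_visit_times_rejected(self):
        p = _path("a", [0.5, 1.0], [1.0, 1.0])
        p.visit_times = np.array([0.5, 0.5])  # bypass constructor validation
        with pytest.raises(ValueError, match="duplicate"):
            build_counting_process([p], VisitModelSpec())


class TestPartialLikelihoodFit:
    def test_worked_example_matches_closed_form(self, cox_fixture_rows):
        # score roots: 2 - 3e^g/(e^g+2) = 0 (everyone) and 2 - 3e^g/(e^g+1) = 0
        fit_ev = fit_intensity(cox_fixture_rows, scheme="EV")
        fit_fu = fit_intensity(cox_fixture_rows, scheme="FU")
        assert fit_ev.converged and fit_fu.converged
        assert fit_ev.gamma_hat[0] == pytest.approx(math.log(4.0), abs=1e-6)
        assert fit_fu.gamma_hat[0] == pytest.approx(math.log(2.0), abs=1e-6)
        assert fit_ev.n_subjects == 3 and fit_fu.n_subjects == 2

    def test_newton_matches_dense_grid_search(self, cox_fixture_rows):
        est = AndersenGillIntensity(scheme="EV").fit(cox_fixture_rows)
        pl = _PartialLikelihood(
            cox_fixture_rows["start"].to_numpy(float),
            cox_fixture_rows["stop"].to_numpy(float),
            cox_fixture_rows["event"].to_numpy(int),
            cox_fixture_rows[["z"]].to_numpy(float),
        )
        grid = np.arange(0.0, 3.0, 1e-4)
        lls = np.array([pl.evaluate(np.array([g]))[0] for g in grid])
        assert abs(grid[np.argmax(lls)] - est.coef_[0]) <= 1e-4

    def test_fu_drops_subjects_not_event_times(self, cox_fixture_rows):
        ev = fit_intensity(cox_fixture_rows, "EV")
        fu = fit_intensity(cox_fixture_rows, "FU")
        assert ev.n_events == fu.n_events == 3
        assert fu.n_subjects == ev.n_subjects - 1

    def test_time_transform_invariance(self, cox_fixture_rows):
        # partial likelihood depends only on event ordering and risk sets
        base = fit_intensity(cox_fixture_rows, "EV").gamma_hat[0]
        warped = cox_fixture_rows.copy()
        for col in ("start", "stop"):
            warped[col] = np.expm1(warped[col])  # strictly increasing map
        assert fit_intensity(warped, "EV").gamma_hat[0] == pytest.approx(base, abs=1e-8)

    def test_fu_equals_ev_when_everyone_has_followup(self, small_cohort):
        with_visits = [p for p in small_cohort if p.n_visits > 0]
        rows = build_counting_process(with_visits, VisitModelSpec())
        ev = fit_intensity(rows, "EV")
        fu = fit_intensity(rows, "FU")
        assert np.array_equal(ev.gamma_hat, fu.gamma_hat)
        assert ev.loglik == fu.loglik

    def test_agrees_with_lifelines_cox_time_varying(self, small_cohort):
        lifelines = pytest.importorskip("lifelines")
        rows = build_counting_process(small_cohort, VisitModelSpec())
        mine = fit_intensity(rows, "EV")
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(
            rows.rename(columns={"subject_id": "id"}),
            id_col="id", start_col="start", stop_col="stop", event_col="event",
        )
        assert mine.gamma_hat[0] == pytest.approx(ctv.params_["z"], abs=1e-5)
        assert np.sqrt(mine.cov[0, 0]) == pytest.approx(
            ctv.standard_errors_["z"], rel=1e-3
        )

    def test_no_events_raises(self):
        rows = build_counting_process([_path("a", [], [])], VisitModelSpec())
        with pytest.raises(ValueError, match="empty event set"):
            fit_intensity(rows, "EV")

    def test_constant_covariate_flagged_singular(self, cox_fixture_rows):
        rows = cox_fixture_rows.assign(z=1.0)
        with pytest.raises(ValueError, match="singular"):
            fit_intensity(rows, "EV")

    def test_ev_estimator_consistent_time_invariant_z(self, bernoulli_oracle):
        # mean(gamma_hat^EV) - gamma0 within 3 MC SEs of zero at n=5000
        assert abs(bernoulli_oracle["bias_ev"]) < 3 * bernoulli_oracle["mcse_ev"]
        assert bernoulli_oracle["n_failed"] == 0


class TestWeights:
    def test_null_model_gives_unit_weights(self, cox_fixture_rows):
        fit = fit_intensity(cox_fixture_rows, "EV")
        fit.gamma_hat = np.array([0.0])
        w = compute_weights(fit, cox_fixture_rows[cox_fixture_rows["event"] == 1])
        assert np.all(w == 1.0)

    def test_weight_closed_form_and_positivity(self, cox_fixture_rows):
        fit = fit_intensity(cox_fixture_rows, "EV")
        fit.gamma_hat = np.array([0.5])
        rows = pd.DataFrame({"z": [math.log(4.0), -3.0, 10.0]})
        w = compute_weights(fit, rows)
        assert w[0] == pytest.approx(0.5)  # exp(-0.5 log 4) = 4^{-1/2}
        assert np.all(w > 0)

    def test_unconverged_fit_refused(self, cox_fixture_rows):
        fit = fit_intensity(cox_fixture_rows, "EV")
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            compute_weights(fit, cox_fixture_rows)
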