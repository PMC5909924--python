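import numpy as np
import pytest
from lifelines.utils import concordance_index as lifelines_ci
from sksurv.metrics import concordance_index_ipcw
from sksurv.util import Surv

from survnn import (
    CensoringDistribution,
    ModelSpec,
    TrainConfig,
    breslow_baseline,
    c_harrell,
    c_ipcw,
    evaluate_model,
    integrated_brier,
    logrank_dichotomized,
    repeated_holdout,
    reports_to_frame,
    train,
    train_test_split,
)
from survnn.coxph import BaselineHazard

from .conftest import random_survival
from .oracles import brier_at, harrell_loop, ipcw_loop, logrank_statistic


class TestHarrellC:
    def test_perfect_anti_ordering(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        theta = np.array([4.0, 3.0, 2.0, 1.0])
        assert c_harrell(theta, time, np.ones(4, dtype=int)) == 1.0

    def test_constant_score_is_half(self):
        time = np.array([1.0, 2.0, 3.0])
        assert c_harrell(np.zeros(3), time, np.ones(3, dtype=int)) == 0.5

    def test_worked_three_patient_example(self):
        # pairs (1,2) and (1,3) concordant, (2,3) discordant -> 2/3
        assert c_harrell(
            np.array([3.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]), np.ones(3, dtype=int)
        ) == pytest.approx(2 / 3)

    def test_matches_pairwise_loop_and_lifelines(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = 40
            time, event = random_survival(rng, n)
            theta = rng.normal(0, 1, n)
            ours = c_harrell(theta, time, event)
            assert ours == pytest.approx(harrell_loop(theta, time, event), abs=1e-12)
            # tie-free times: conventions coincide with lifelines exactly
            assert ours == pytest.approx(lifelines_ci(time, -theta, event), abs=1e-12)

    def test_negation_maps_c_to_one_minus_c(self):
        rng = np.random.default_rng(1)
        time, event = random_survival(rng, 50)
        theta = rng.normal(0, 1, 50)
        assert c_harrell(-theta, time, event) == pytest.approx(
            1.0 - c_harrell(theta, time, event), abs=1e-12
        )

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError):
            c_harrell(np.array([1.0, 2.0]), np.array([3.0, 1.0]), np.array([1, 0]))


class TestIPCWC:
    def test_equals_harrell_when_uncensored(self):
        rng = np.random.default_rng(2)
        time = rng.exponential(5, 60)
        event = np.ones(60, dtype=int)
        theta = rng.normal(0, 1, 60)
        assert c_ipcw(theta, time, event) == c_harrell(theta, time, event)

    def test_constant_score_is_half(self):
        rng = np.random.default_rng(3)
        time, event = random_survival(rng, 30)
        assert c_ipcw(np.zeros(30), time, event) == pytest.approx(0.5)

    def test_four_patient_hand_example(self):
        # censoring at t=2 (patient 1); only the earliest event reweighted
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 0, 1, 1])
        theta = np.array([2.0, 0.0, 1.0, 3.0])
        cd = CensoringDistribution(time, event)
        expected = ipcw_loop(theta, time, event, cd.before(time))
        assert c_ipcw(theta, time, event) == pytest.approx(expected, abs=1e-12)

    def test_matches_weighted_loop_and_sksurv(self):
        rng = np.random.default_rng(4)
        for _ in range(6):
            n = 50
            time, event = random_survival(rng, n)
            event[-1] = 1  # sksurv needs the last time to be an event-compatible case
            theta = rng.normal(0, 1, n)
            cd = CensoringDistribution(time, event)
            ours = c_ipcw(theta, time, event)
            assert ours == pytest.approx(ipcw_loop(theta, time, event, cd.before(time)), abs=1e-12)
            y = Surv.from_arrays(event.astype(bool), time)
            sk = concordance_index_ipcw(y, y, theta)[0]
            assert ours == pytest.approx(sk, abs=1e-12)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(5)
        time, event = random_survival(rng, 40)
        theta = rng.normal(0, 1, 40)
        assert c_ipcw(-theta, time, event) == pytest.approx(
            1.0 - c_ipcw(theta, time, event), abs=1e-12
        )


class TestLogrank:
    def test_identical_groups_give_p_one(self):
        time = np.tile(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), 2)
        event = np.tile(np.array([1, 1, 0, 1, 1]), 2)
        theta = np.repeat([0.0, 1.0], 5)  # arbitrary split of duplicated patients
        res = logrank_dichotomized(theta, time, event)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups_strongly_significant(self):
        n = 40
        time = np.concatenate([np.arange(1.0, 21.0), np.arange(100.0, 120.0)])
        event = np.ones(n, dtype=int)
        theta = np.concatenate([np.ones(20), np.zeros(20)])
        assert logrank_dichotomized(theta, time, event).p_value < 0.01

    def test_statistic_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        time, event = random_survival(rng, 30)
        theta = rng.normal(0, 1, 30)
        res = logrank_dichotomized(theta, time, event)
        high = theta > np.median(theta)
        ref = logrank_statistic(time[high], event[high], time[~high], event[~high])
        assert res.statistic == pytest.approx(ref, rel=1e-8)

    def test_median_ties_go_to_low_risk_group(self):
        theta = np.array([0.0, 0.0, 0.0, 1.0])  # median 0: three low, one high
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, dtype=int)
        res = logrank_dichotomized(theta, time, event)
        assert np.isfinite(res.p_value)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank_dichotomized(np.zeros(4), np.arange(1.0, 5.0), np.ones(4, dtype=int))


class TestIntegratedBrier:
    def test_perfect_survival_prediction_scores_zero(self):
        # no events, predicted S identically 1 (empty baseline hazard)
        baseline = BaselineHazard(times=np.array([]), cumulative_hazard=np.array([]))
        time = np.array([2.0, 4.0, 6.0])
        event = np.array([0, 0, 0])
        assert integrated_brier(np.zeros(3), baseline, time, event) == 0.0

    def test_constant_half_probability_uncensored(self):
        # S(t) = 0.5 for every t >= 0 and patient -> BS(t) = 0.25 throughout
        baseline = BaselineHazard(times=np.array([0.0]), cumulative_hazard=np.array([np.log(2.0)]))
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.ones(5, dtype=int)
        val = integrated_brier(np.zeros(5), baseline, time, event)
        assert val == pytest.approx(0.25, abs=1e-12)

    def test_matches_pointwise_oracle_uncensored(self):
        rng = np.random.default_rng(7)
        time = np.sort(rng.exponential(5, 5)) + 0.5
        event = np.ones(5, dtype=int)
        theta = rng.normal(0, 1, 5)
        baseline = breslow_baseline(theta, time, event)
        cd = CensoringDistribution(time, event)
        grid = np.unique(np.concatenate([[0.0], time[event == 1], [time.max()]]))
        ref_bs = []
        for t in grid:
            S_t = baseline.survival(theta, np.array([t]))[:, 0]
            ref_bs.append(brier_at(t, S_t, time, event, cd.before(time), cd.at(np.array([t]))[0]))
        expected = np.trapezoid(ref_bs, grid) / time.max()
        ours = integrated_brier(theta, baseline, time, event)
        assert ours == pytest.approx(expected, abs=1e-12)

    def test_null_model_upper_bounds_well_fit_model(self, small_sim):
        ds, _ = small_sim
        tr, te = train_test_split(ds, 0.3, seed=1)
        fit = train(tr, ModelSpec(n_hidden_layers=0, ridge_lambda=1.0), TrainConfig(n_iterations=200, seed=2))
        theta_tr = fit.model.predict(tr.X)
        theta_te = fit.model.predict(te.X)
        cd = CensoringDistribution(tr.time, tr.event)
        fitted = integrated_brier(
            theta_te, breslow_baseline(theta_tr, tr.time, tr.event), te.time, te.event, censoring=cd
        )
        null = integrated_brier(
            np.zeros(te.n_patients),
            breslow_baseline(np.zeros(tr.n_patients), tr.time, tr.event),
            te.time,
            te.event,
            censoring=cd,
        )
        assert fitted <= null


class TestRepeatedHoldout:
    def test_single_repeat_report(self, small_sim):
        ds, _ = small_sim
        reports = repeated_holdout(
            ds, ModelSpec(n_hidden_layers=0, ridge_lambda=1.0),
            cfg=TrainConfig(n_iterations=40), n_repeats=1, seed=3,
        )
        assert len(reports) == 1
        rep = reports[0]
        assert 0.0 <= rep.c_harrell <= 1.0
        assert 0.0 <= rep.c_ipcw <= 1.0
        assert 0.0 < rep.logrank_p <= 1.0
        assert rep.integrated_brier >= 0.0
        assert rep.n_test == ds.n_patients - int(np.ceil(ds.n_patients * 0.8))

    def test_master_seed_determinism(self, small_sim):
        ds, _ = small_sim
        kwargs = dict(
            spec=ModelSpec(n_hidden_layers=0, ridge_lambda=1.0),
            cfg=TrainConfig(n_iterations=25), n_repeats=2, seed=17,
        )
        a = reports_to_frame(repeated_holdout(ds, **kwargs))
        b = reports_to_frame(repeated_holdout(ds, **kwargs))
        assert a.equals(b)

    def test_cv_selection_inside_harness(self, small_sim):
        ds, _ = small_sim
        reports = repeated_holdout(
            ds, ModelSpec(n_hidden_layers=1),
            cfg=TrainConfig(n_iterations=20),
            grid=[{"ridge_lambda": 0.1}, {"ridge_lambda": 10.0}],
            n_repeats=1, k=3, seed=4,
        )
        assert len(reports) == 1


def test_evaluate_model_uses_training_reference(small_sim):
    ds, _ = small_sim
    tr, te = train_test_split(ds, 0.3, seed=9)
    fit = train(tr, ModelSpec(n_hidden_layers=0, ridge_lambda=1.0), TrainConfig(n_iterations=50, seed=1))
    rep = evaluate_model(fit.model, tr, te)
    assert np.isfinite([rep.c_harrell, rep.c_ipcw, rep.logrank_p, rep.integrated_brier]).all()
    assert rep.n_events_test == te.n_events
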