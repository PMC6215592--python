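import numpy as np
import pandas as pd
import pytest

from transurv import (
    CoxPH,
    ProgressionConfig,
    SurvivalData,
    TransductionConfig,
    TransductiveModel,
    candidate_grid,
    generate_single_endpoint,
    make_learner,
    report_evaluation,
    select_threshold,
    evaluate,
    transduce_dataset,
    transduce_instance,
)
from transurv.exceptions import TransurvError


def small_cohort(seed=13, n=20, censor_frac=0.3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2))
    t = np.abs(X @ np.array([2.0, -1.0]) + 6 + rng.standard_normal(n)) + 0.5
    e = (rng.uniform(size=n) > censor_frac).astype(int)
    e[np.argmax(t)] = 0  # ensure a censored record sits at t_max
    e[np.argmin(t)] = 1  # and at least one event exists
    return SurvivalData(X, t, e)


def cox_cfg(data, m=3):
    return TransductionConfig(
        learner=make_learner("cox"),
        time_point=float(np.median(data.time)),
        grid_size=m,
    )


def training_criterion(data, scores, tp):
    thr = select_threshold(data, scores, tp)
    return evaluate(data, scores, tp, thr).criterion


class TestCandidateGrid:
    def test_arithmetic_grid(self):
        np.testing.assert_allclose(candidate_grid(2, 12, 10), np.arange(2.0, 13.0))

    def test_degenerate_at_tmax(self):
        np.testing.assert_array_equal(candidate_grid(7, 7, 5), [7.0])

    def test_fractional_grid(self):
        np.testing.assert_allclose(candidate_grid(0, 1, 4), [0, 0.25, 0.5, 0.75, 1.0])

    def test_beyond_tmax_rejected(self):
        with pytest.raises(ValueError):
            candidate_grid(8, 7, 5)


class TestTransduceInstance:
    def test_grid_of_one_keeps_censored_time(self):
        data = small_cohort()
        i = int(np.where(data.event == 0)[0][0])
        cfg = cox_cfg(data, m=1)
        # m=1 offers only {U_i, t_max}; force the degenerate single-candidate
        # case via a record already at t_max
        j = int(np.argmax(data.time))
        assert data.event[j] == 0
        best, crit, trace = transduce_instance(data, j, cfg)
        assert best == data.time[j]
        assert trace["candidates"] == [data.time[j]]

    def test_never_worse_than_unmodified_time(self):
        data = small_cohort()
        cfg = cox_cfg(data, m=4)
        for i in np.where(data.event == 0)[0]:
            best, crit, trace = transduce_instance(data, int(i), cfg)
            assert crit >= trace["criteria"][0] - 1e-12  # candidate 0 is U_i

    def test_event_record_rejected(self):
        data = small_cohort()
        i = int(np.where(data.event == 1)[0][0])
        with pytest.raises(ValueError, match="event"):
            transduce_instance(data, i, cox_cfg(data))

    def test_matches_bruteforce_grid_search(self):
        """Per-instance selection equals an independent exhaustive loop."""
        data = small_cohort(seed=23)
        cfg = cox_cfg(data, m=3)
        for i in np.where(data.event == 0)[0][:2]:
            i = int(i)
            grid = np.linspace(data.time[i], data.t_max, 4)
            crits = []
            for u in grid:
                fitted = CoxPH(data.with_time(i, u)).fit()
                crits.append(training_criterion(data, fitted.predict(data), cfg.time_point))
            expected = grid[int(np.argmax(crits))]
            best, _, _ = transduce_instance(data, i, cfg)
            assert best == pytest.approx(expected)


class TestTransduceDataset:
    def test_no_censoring_is_passthrough(self):
        data = small_cohort()
        all_events = SurvivalData(data.X, data.time, np.ones(data.n, dtype=int))
        transduced, final = transduce_dataset(all_events, cox_cfg(all_events))
        np.testing.assert_array_equal(transduced.transduced_times, all_events.time)
        plain = CoxPH(all_events).fit()
        np.testing.assert_allclose(final.params, plain.params, atol=1e-10)

    def test_constraints_hold_on_every_output(self):
        data = small_cohort(seed=31)
        transduced, _ = transduce_dataset(data, cox_cfg(data, m=5))
        t_hat = transduced.transduced_times
        ev = data.event == 1
        np.testing.assert_array_equal(t_hat[ev], data.time[ev])
        assert np.all(t_hat[~ev] >= data.time[~ev])
        assert np.all(t_hat <= data.t_max + 1e-12)

    def test_tampered_targets_rejected(self):
        from transurv import TransducedDataset

        data = small_cohort()
        bad = data.time.copy()
        bad[np.where(data.event == 1)[0][0]] += 1.0
        with pytest.raises(TransurvError, match="event"):
            TransducedDataset(base=data, transduced_times=bad)
        bad2 = data.time.copy()
        bad2[np.where(data.event == 0)[0][0]] = data.t_max + 5
        with pytest.raises(TransurvError, match="outside"):
            TransducedDataset(base=data, transduced_times=bad2)

    def test_singular_equals_exhaustive_with_one_censored_record(self):
        """With a single censored record the joint search degenerates to the
        per-instance search, so both must choose the same target."""
        data = small_cohort(seed=7)
        e = np.ones(data.n, dtype=int)
        i = 5
        e[i] = 0
        one_cens = SurvivalData(data.X, data.time, e)
        cfg = cox_cfg(one_cens, m=4)
        transduced, _ = transduce_dataset(one_cens, cfg)
        # exhaustive oracle: joint grid over the one censored record
        grid = np.linspace(one_cens.time[i], one_cens.t_max, 5)
        crits = []
        for u in grid:
            fitted = cfg.learner(one_cens.with_time(i, u))
            crits.append(training_criterion(one_cens, fitted.predict(one_cens), cfg.time_point))
        assert transduced.transduced_times[i] == pytest.approx(grid[int(np.argmax(crits))])

    def test_frozen_scorer_never_moves_targets(self):
        """A learner whose scores ignore the targets gives a flat criterion,
        so ties break to the censored time and nothing moves."""
        data = small_cohort(seed=11)

        class FrozenResults:
            def predict(self, d):
                return d.X[:, 0]

            weights = None

            def summary(self):  # pragma: no cover
                return pd.DataFrame()

        cfg = TransductionConfig(
            learner=lambda d: FrozenResults(),
            time_point=float(np.median(data.time)),
            grid_size=5,
        )
        transduced, _ = transduce_dataset(data, cfg)
        np.testing.assert_array_equal(transduced.transduced_times, data.time)

    def test_deterministic_traces(self):
        data = small_cohort(seed=19)
        cfg = cox_cfg(data, m=5)
        t1, _ = transduce_dataset(data, cfg)
        t2, _ = transduce_dataset(data, cfg)
        np.testing.assert_array_equal(t1.transduced_times, t2.transduced_times)
        assert t1.provenance == t2.provenance

    def test_trace_frame_layout(self):
        data = small_cohort(seed=19)
        transduced, _ = transduce_dataset(data, cox_cfg(data, m=3))
        frame = transduced.trace_frame()
        assert list(frame.columns) == ["record", "candidate", "criterion", "chosen"]
        n_cens = int((data.event == 0).sum())
        assert frame["chosen"].sum() == n_cens

    def test_targets_move_toward_truth_on_average(self):
        """Across simulated cohorts, transduced censored targets are closer
        to the latent true event times than the censored times were."""
        deltas = []
        for seed in range(20):
            cfg = ProgressionConfig(
                n=50, d=3, beta=np.array([0.9, -0.6, 0.4]),
                progression_beta=np.zeros(3), weibull_scale=60.0,
                censor_rate_target=0.6, seed=100 + seed,
            )
            data, truth = generate_single_endpoint(cfg)
            tcfg = TransductionConfig(
                learner=make_learner("cox"),
                time_point=float(np.median(data.time)),
                grid_size=5,
            )
            transduced, _ = transduce_dataset(data, tcfg)
            cens = data.event == 0
            err_before = np.abs(data.time[cens] - truth.true_time_early[cens]).mean()
            err_after = np.abs(
                transduced.transduced_times[cens] - truth.true_time_early[cens]
            ).mean()
            deltas.append(err_after - err_before)
        assert np.mean(deltas) <= 0


class TestTransductiveModel:
    def test_results_carry_baseline_comparison(self):
        data = small_cohort(seed=3)
        tm = TransductiveModel(data, cox_cfg(data, m=4)).fit()
        assert np.isfinite(tm.baseline_criterion)
        assert np.isfinite(tm.criterion)
        assert tm.weights.shape[0] == data.n_features

    def test_report_evaluation_blocks(self):
        cfg = ProgressionConfig(
            n=120, d=4, beta=np.array([0.8, -0.5, 0.3, 0.0]),
            progression_beta=np.zeros(4), censor_rate_target=0.8, seed=5,
        )
        train, _ = generate_single_endpoint(cfg)
        valid, _ = generate_single_endpoint(
            ProgressionConfig(
                n=80, d=4, beta=np.array([0.8, -0.5, 0.3, 0.0]),
                progression_beta=np.zeros(4), censor_rate_target=0.8, seed=6,
            )
        )
        fitted = CoxPH(train).fit()
        tp = float(np.median(train.time))
        table = report_evaluation(train, valid, valid, fitted, tp)
        assert list(table.columns) == ["training", "validation_early", "validation_late"]
        assert list(table.index) == ["ci", "sensitivity", "specificity", "criterion"]
        # self-consistency: any cell is reproducible from scores + original times
        thr = select_threshold(train, fitted.predict(train), tp)
        ev = evaluate(valid, fitted.predict(valid), tp, thr)
        assert table.loc["ci", "validation_early"] == pytest.approx(ev.ci)
        assert table.loc["criterion", "validation_early"] == pytest.approx(ev.criterion)

    def test_perfectly_separable_training_block(self):
        t = np.array([1.0, 2, 3, 20, 21, 22])
        X = (-t)[:, None]  # score = time, perfectly concordant
        data = SurvivalData(X, t, np.ones(6, dtype=int))
        fitted = CoxPH(data).fit()
        table = report_evaluation(data, None, None, fitted, time_point=10.0)
        assert table.loc["criterion", "training"] == pytest.approx(2.0)

    def test_schema_mismatch_rejected(self):
        data = small_cohort()
        fitted = CoxPH(data).fit()
        other = SurvivalData(np.zeros((4, 3)), [1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="schema"):
            report_evaluation(data, other, None, fitted, 5.0)
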