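"""Inter-call intervals, BEC estimation and bout segmentation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calltag.bouts import (
    BrokenStickBEC,
    ExponentialMixtureBEC,
    bec_from_params,
    bout_statistics,
    compute_icis,
    fit_broken_stick,
    fit_mixture_mle,
    segment_bouts,
)
from calltag.exceptions import (
    DegenerateIntervalError,
    InsufficientDataError,
    InvalidParameterError,
)
from calltag.scene import simulate_call_schedule

TRUE = dict(p_fast=0.7, lambda_fast=2.0, lambda_slow=0.05)
TRUE_BEC = 2.3262447766672514  # ln(1.4/0.015)/1.95


def draw_mixture(n, seed):
    rng = np.random.default_rng(seed)
    fast = rng.random(n) < TRUE["p_fast"]
    rates = np.where(fast, TRUE["lambda_fast"], TRUE["lambda_slow"])
    return rng.exponential(1.0, n) / rates


def calls_frame(onsets, dur=0.3, caller="w"):
    onsets = np.asarray(onsets, dtype=float)
    return pd.DataFrame(
        {"caller_id": caller, "t_start_s": onsets, "t_end_s": onsets + dur}
    )


class TestIcis:
    def test_onset_to_onset_gaps(self):
        s = compute_icis(calls_frame([0.0, 0.5, 3.0]))
        assert np.allclose(s.intervals_s, [0.5, 2.5])

    def test_single_call_gives_empty_series(self):
        assert compute_icis(calls_frame([4.2])).intervals_s.size == 0

    def test_evenly_spaced_calls(self):
        s = compute_icis(np.arange(100.0))
        assert s.intervals_s.size == 99 and np.allclose(s.intervals_s, 1.0)

    def test_duplicate_onsets_raise(self):
        with pytest.raises(DegenerateIntervalError):
            compute_icis(np.array([1.0, 1.0, 2.0]))


class TestMixtureMle:
    def test_closed_form_bec(self):
        assert bec_from_params(**TRUE) == pytest.approx(TRUE_BEC, abs=1e-9)
        assert bec_from_params(0.5, 1.0, 0.5) == pytest.approx(np.log(2.0) / 0.5)

    def test_parameter_recovery_at_n2000(self):
        fit = fit_mixture_mle(draw_mixture(2000, seed=17))
        assert fit.p_fast == pytest.approx(TRUE["p_fast"], rel=0.10)
        assert fit.lambda_fast == pytest.approx(TRUE["lambda_fast"], rel=0.10)
        assert fit.lambda_slow == pytest.approx(TRUE["lambda_slow"], rel=0.10)
        assert fit.bec_s == pytest.approx(TRUE_BEC, rel=0.10)
        assert not fit.degenerate

    def test_single_exponential_flagged_degenerate(self):
        rng = np.random.default_rng(3)
        fit = fit_mixture_mle(rng.exponential(1.0, 500))
        assert fit.degenerate

    def test_bec_invariant_to_interval_order(self):
        t = draw_mixture(800, seed=8)
        a = fit_mixture_mle(t)
        b = fit_mixture_mle(np.random.default_rng(1).permutation(t))
        # identical up to float summation order inside the optimizer
        assert a.bec_s == pytest.approx(b.bec_s, rel=1e-5)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_mixture_mle(np.array([0.5, 1.0, 20.0]))

    def test_nonpositive_intervals_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_mixture_mle(np.array([0.5] * 20 + [-1.0]))

    def test_schedule_roundtrip_recovers_generator_parameters(self):
        # draws from the scene generator feed straight into the estimator
        _, gaps = simulate_call_schedule(**TRUE, duration_s=13000.0, seed=2)
        est = ExponentialMixtureBEC().fit(gaps)
        assert est.bec_s_ == pytest.approx(TRUE_BEC, rel=0.15)


class TestBrokenStick:
    def test_cross_method_consistency_on_mixture(self):
        t = draw_mixture(2000, seed=17)
        bs = fit_broken_stick(t)
        mle = fit_mixture_mle(t)
        assert bs.bec_s / mle.bec_s < 2.0 and mle.bec_s / bs.bec_s < 2.0

    def test_constructed_two_process_corner_recovered(self):
        # widely separated deterministic-rate processes: corner near the
        # analytic density intersection
        rng = np.random.default_rng(0)
        fast = rng.exponential(1 / 5.0, 3000)
        slow = rng.exponential(1 / 0.02, 1000)
        t = np.concatenate([fast, slow])
        truth = bec_from_params(0.75, 5.0, 0.02)
        fit = fit_broken_stick(t, n_bins=25)
        assert fit.bec_s == pytest.approx(truth, rel=0.5)

    def test_single_tight_cluster_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_broken_stick(np.full(50, 0.5) + np.arange(50) * 1e-12)


class TestSegmentation:
    def test_example_with_published_criterion(self):
        bouts, solitary = segment_bouts(calls_frame([0.0, 0.5, 3.0]), bec_s=2.2)
        assert len(bouts) == 1 and bouts[0].call_indices == [0, 1]
        assert solitary == [2]

    def test_gap_exactly_at_bec_splits(self):
        bouts, solitary = segment_bouts(calls_frame([0.0, 2.2, 4.4]), bec_s=2.2)
        assert len(bouts) == 0 and solitary == [0, 1, 2]

    def test_bout_duration_spans_first_start_to_last_end(self):
        bouts, _ = segment_bouts(calls_frame([0.0, 1.0, 2.0], dur=0.4), bec_s=1.5)
        assert bouts[0].duration_s == pytest.approx(2.4)
        assert bouts[0].n_calls == 3

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_bruteforce_scan_and_conserves_calls(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        onsets = np.sort(rng.uniform(0, 100, n))
        onsets = onsets[np.concatenate([[True], np.diff(onsets) > 0])]
        bec = float(rng.uniform(0.5, 10.0))
        bouts, solitary = segment_bouts(calls_frame(onsets, dur=0.1), bec)
        # brute-force oracle: split wherever the gap is >= bec
        runs, cur = [], [0]
        for i in range(1, len(onsets)):
            if onsets[i] - onsets[i - 1] < bec:
                cur.append(i)
            else:
                runs.append(cur)
                cur = [i]
        runs.append(cur)
        expect_bouts = [r for r in runs if len(r) >= 2]
        assert [b.call_indices for b in bouts] == expect_bouts
        assert sum(b.n_calls for b in bouts) + len(solitary) == len(onsets)


class TestBoutStatistics:
    def test_single_bout_hand_computation(self):
        table = calls_frame([0.0, 0.4, 1.0], dur=0.2)
        table["age_class"] = "adult"
        out = bout_statistics(table, bec_s=2.0)
        row = out.iloc[0]
        assert row["median_ici_s"] == pytest.approx(0.5)
        assert row["iqr_ici_s"] == pytest.approx(0.1)
        assert row["n_bouts"] == 1

    def test_identical_icis_have_zero_cv(self):
        table = calls_frame(np.arange(6) * 1.0)
        table["age_class"] = "adult"
        out = bout_statistics(table, bec_s=2.0)
        assert out.iloc[0]["cv_ici"] == pytest.approx(0.0)

    def test_ten_bout_fixture_matches_hand_summary(self):
        # two callers, deterministic onsets; all quantities recomputed by
        # hand below with plain numpy on independently derived pieces
        onsets_a = []
        t = 0.0
        for k in range(6):  # 6 bouts of 3 calls, gaps 0.4/0.6, separated by 30 s
            onsets_a += [t, t + 0.4, t + 1.0]
            t += 30.0
        onsets_b = []
        t = 7.0
        for k in range(4):  # 4 bouts of 2 calls, gap 0.8
            onsets_b += [t, t + 0.8]
            t += 50.0
        ta = calls_frame(onsets_a, dur=0.2, caller="a")
        tb = calls_frame(onsets_b, dur=0.2, caller="b")
        table = pd.concat([ta, tb], ignore_index=True)
        table["age_class"] = "adult"
        out = bout_statistics(table, bec_s=2.2).iloc[0]
        within = [0.4, 0.6] * 6 + [0.8] * 4
        assert out["n_bouts"] == 10
        assert out["median_ici_s"] == pytest.approx(np.median(within))
        q1, q3 = np.quantile(within, [0.25, 0.75])
        assert out["iqr_ici_s"] == pytest.approx(q3 - q1)
        durations = [1.2] * 6 + [1.0] * 4
        assert out["median_bout_duration_s"] == pytest.approx(np.median(durations))
        assert out["median_calls_per_bout"] == pytest.approx(np.median([3] * 6 + [2] * 4))

    def test_quantile_convention_flag_changes_iqr(self):
        table = calls_frame([0.0, 0.3, 0.7, 1.5, 2.0])
        table["age_class"] = "adult"
        lin = bout_statistics(table, bec_s=3.0, quantile_method="linear")
        low = bout_statistics(table, bec_s=3.0, quantile_method="lower")
        assert lin.iloc[0]["iqr_ici_s"] != low.iloc[0]["iqr_ici_s"]

    def test_group_without_bouts_is_omitted(self):
        sparse = calls_frame([0.0, 100.0, 200.0])
        sparse["age_class"] = "calf"
        dense = calls_frame([0.0, 0.5, 1.0], caller="x")
        dense["age_class"] = "adult"
        out = bout_statistics(pd.concat([sparse, dense], ignore_index=True), bec_s=2.2)
        assert list(out["age_class"]) == ["adult"]
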