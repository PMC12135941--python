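"""Synthetic-data generator: determinism, protocol duty cycles, latent
dynamics, and ground-truth consistency."""

import numpy as np
import pytest
from scipy import stats

from damsleep.multibeam import classify_minutes, COARSE_OF
from damsleep.sleep import quiescence, detect_sleep_bouts, bouts_to_minutes
from damsleep.synthetic import (
    SimConfig,
    led_schedule,
    simulate_fly,
    simulate_deprivation,
    simulate_cohort,
    fly_seed,
)


class TestLedSchedule:
    @pytest.mark.parametrize(
        "protocol,duty",
        [
            ("off", 0.0),
            ("1Hz", 5 / 1000),
            ("regular", 100 / 6000),  # (20 x 5 ms) / (20 x 100 ms + 4 s)
            ("10Hz", 5 / 100),
            ("20Hz", 5 / 50),
            ("50Hz", 5 / 20),  # 5 / (5 + 15)
            ("constant", 1.0),
        ],
    )
    def test_duty_fractions(self, protocol, duty):
        sched = led_schedule(protocol, 10)
        assert sched.shape == (10,)
        assert np.all(sched == pytest.approx(duty))

    def test_unknown_protocol_raises(self):
        with pytest.raises(ValueError, match="unknown protocol"):
            led_schedule("2Hz", 10)


class TestSimulateFly:
    def test_deterministic_under_seed(self):
        a, ta = simulate_fly(SimConfig(seed=7), 2, led_protocol="20Hz", led_days=(1,))
        b, tb = simulate_fly(SimConfig(seed=7), 2, led_protocol="20Hz", led_days=(1,))
        assert a == b
        np.testing.assert_array_equal(ta.state, tb.state)
        np.testing.assert_array_equal(ta.behavior, tb.behavior)

    def test_absorbed_sleep_when_wake_rate_zero(self):
        cfg = SimConfig(seed=3, p_ws=1.0, p_sw=0.0, p_sleep_micro=0.0,
                        circadian_gain=1.0)
        s, t = simulate_fly(cfg, 1)
        # falls asleep on the first minute and never wakes
        assert (t.state == "sleep").all()
        assert s.counts.sum() == 0 and s.moves.sum() == 0

    def test_sleep_micro_emits_single_posture_counts(self):
        cfg = SimConfig(seed=3, p_ws=1.0, p_sw=0.0, p_sleep_micro=0.2,
                        circadian_gain=1.0)
        s, t = simulate_fly(cfg, 1)
        micro = s.counts > 0
        assert micro.any()
        assert np.all(s.counts[micro] == 1)
        assert set(t.behavior[micro]) == {"posture_change"}

    def test_stationary_sleep_fraction(self):
        # sleep fraction of the latent chain -> p_ws / (p_ws + p_sw)
        cfg = SimConfig(p_ws=0.08, p_sw=0.04, circadian_gain=1.0,
                        p_sleep_micro=0.0)
        fracs = []
        for seed in range(8):
            _, t = simulate_fly(SimConfig(**{**cfg.__dict__, "seed": seed}), 5)
            fracs.append((t.state == "sleep").mean())
        expect = 0.08 / 0.12
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - expect) < 3 * se + 0.01

    def test_led_effect_one_is_null(self):
        # with led_effect=1 the LED day is statistically like the off day
        on, off = [], []
        for seed in range(60):
            cfg = SimConfig(seed=seed, led_effect=1.0)
            s, t = simulate_fly(cfg, 2, led_protocol="50Hz", led_days=(1,))
            sl = (t.state == "sleep")
            off.append(sl[:1440].sum())
            on.append(sl[1440:].sum())
        p = stats.mannwhitneyu(on, off).pvalue
        assert p > 0.01

    def test_led_effect_above_one_increases_sleep(self):
        on, off = [], []
        for seed in range(30):
            cfg = SimConfig(seed=seed, led_effect=4.0)
            s, t = simulate_fly(cfg, 2, led_protocol="50Hz", led_days=(1,))
            sl = (t.state == "sleep")
            off.append(sl[:1440].sum())
            on.append(sl[1440:].sum())
        assert np.mean(on) > np.mean(off) + 50


class TestDeprivation:
    def test_forced_wake_scores_zero_sleep(self):
        for seed in range(5):
            s, t = simulate_deprivation(
                SimConfig(seed=seed), sd_window=(2160, 2880), n_days=3
            )
            assert (t.state[2160:2880] == "wake").all()
            asleep = bouts_to_minutes(
                detect_sleep_bouts(quiescence(s, "multibeam")), s.n
            )
            assert asleep[2160:2880].sum() == 0

    def test_rebound_disabled_matches_unperturbed_post_window(self):
        # with rebound_gain = 0 the post-SD day has baseline-like sleep
        post, base = [], []
        for seed in range(40):
            cfg = SimConfig(seed=seed, rebound_gain=0.0)
            s, t = simulate_deprivation(cfg, sd_window=(2160, 2880), n_days=3)
            sl = t.state == "sleep"
            base.append(sl[720:1440].sum())   # baseline day light+dark mix
            post.append(sl[2880 + 720 :].sum())
        p = stats.mannwhitneyu(post, base).pvalue
        assert p > 0.01


class TestCohort:
    def test_same_master_seed_reproduces(self):
        a, ta = simulate_cohort(SimConfig(seed=9), 4, 1)
        b, tb = simulate_cohort(SimConfig(seed=9), 4, 1)
        assert a == b

    def test_cohort_size_and_ids(self):
        series, truths = simulate_cohort(SimConfig(seed=1), 32, 1)
        assert len(series) == 32
        assert len({s.fly_id for s in series}) == 32

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            simulate_cohort(SimConfig(seed=1), ["a", "a"], 1)

    def test_per_fly_seed_stable_under_insertion_order(self):
        s1, _ = simulate_cohort(SimConfig(seed=2), ["a", "b"], 1)
        s2, _ = simulate_cohort(SimConfig(seed=2), ["b", "a"], 1)
        assert s1[0] == s2[1] and s1[1] == s2[0]

    def test_fly_seed_below_2_31(self):
        for fid in ("a", "b", "fly999"):
            assert 0 <= fly_seed(123, fid) < 2**31


class TestGroundTruthConsistency:
    def test_classifier_reproduces_emitted_coarse_classes(self):
        cfg = SimConfig(seed=11, p_sleep_micro=0.0)
        s, t = simulate_fly(cfg, 2)
        pred = classify_minutes(s)
        coarse = np.array([COARSE_OF[b] for b in t.behavior], dtype=object)
        np.testing.assert_array_equal(pred, coarse)

    def test_known_confusion_with_sleep_micromovements(self):
        p = 0.1
        cfg = SimConfig(seed=13, p_sleep_micro=p)
        s, t = simulate_fly(cfg, 5)
        pred = classify_minutes(s)
        sleep = t.state == "sleep"
        n_sleep = sleep.sum()
        # a sleeping minute is predicted micromovement exactly when the
        # posture-change emission fired -> Binomial(n_sleep, p)
        frac = (pred[sleep] == "micromovement").mean()
        se = np.sqrt(p * (1 - p) / n_sleep)
        assert abs(frac - p) < 4 * se
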