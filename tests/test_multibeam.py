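"""Multibeam behavior classification and validation statistics."""

import numpy as np
import pytest

from damsleep.multibeam import (
    MICRO_BEHAVIORS,
    VIDEO_BEHAVIORS,
    classify_minutes,
    video_minute_labels,
    sensitivity,
    accuracy,
    combined_walk_micro_sensitivity,
    sleep_inclusive_rest_accuracy,
    count_false_sleep_episodes,
    validate,
    round_percent,
    COARSE_OF,
)

from conftest import make_series


class TestClassifyMinutes:
    def test_hierarchy(self):
        s = make_series([5, 3, 0], moves=[2, 0, 0])
        assert classify_minutes(s).tolist() == [
            "walking",
            "micromovement",
            "rest",
        ]

    def test_requires_moves_channel(self):
        with pytest.raises(ValueError, match="moves"):
            classify_minutes(make_series([1, 2]))


class TestVideoMinuteLabels:
    def test_any_walking_wins_the_minute(self):
        ann = [(0.0, 3.0, "walking"), (3.0, 60.0, "grooming")]
        assert video_minute_labels(ann, 1).tolist() == ["walking"]

    def test_micromovement_only_minute(self):
        ann = [(0.0, 60.0, "grooming")]
        assert video_minute_labels(ann, 1).tolist() == ["grooming"]

    def test_longest_micromovement_wins(self):
        ann = [(0.0, 40.0, "grooming"), (40.0, 60.0, "feeding")]
        assert video_minute_labels(ann, 1).tolist() == ["grooming"]

    def test_duration_tie_breaks_by_fixed_order(self):
        ann = [(0.0, 30.0, "grooming"), (30.0, 60.0, "feeding")]
        # equal durations: feeding precedes grooming in the fixed order
        assert video_minute_labels(ann, 1).tolist() == ["feeding"]

    def test_uncovered_minute_raises(self):
        with pytest.raises(ValueError, match="no annotation"):
            video_minute_labels([(0.0, 60.0, "rest")], 2)

    def test_random_annotations_match_bruteforce(self, rng):
        n_min = 10
        behaviors = list(VIDEO_BEHAVIORS)
        ann = []
        t = 0.0
        while t < n_min * 60:
            dur = rng.uniform(5, 90)
            ann.append((t, min(t + dur, n_min * 60), behaviors[rng.integers(len(behaviors))]))
            t += dur
        got = video_minute_labels(ann, n_min)
        for m in range(n_min):
            durs = {b: 0.0 for b in behaviors}
            for s, e, b in ann:
                lo, hi = max(s, m * 60), min(e, (m + 1) * 60)
                if hi > lo:
                    durs[b] += hi - lo
            if durs["walking"] > 0:
                want = "walking"
            else:
                micro = [(durs[b], -MICRO_BEHAVIORS.index(b), b) for b in MICRO_BEHAVIORS]
                best = max(micro)
                want = best[2] if best[0] > 0 else "rest"
            assert got[m] == want


class TestSensitivityAccuracy:
    def test_perfect_agreement(self):
        truth = np.array(["rest", "walking", "grooming"], dtype=object)
        pred = np.array(["rest", "walking", "micromovement"], dtype=object)
        for b in ("rest", "walking", "grooming"):
            assert sensitivity(pred, truth, b) == 100.0
        for c in ("rest", "walking", "micromovement"):
            assert accuracy(pred, truth, c) == 100.0

    def test_stated_sensitivity_formula(self):
        truth = np.array(["grooming"] * 10, dtype=object)
        pred = np.array(["micromovement"] * 9 + ["rest"], dtype=object)
        assert sensitivity(pred, truth, "grooming") == pytest.approx(90.0)

    def test_stated_accuracy_formula(self):
        truth = np.array(["rest"] * 5 + ["feeding"] * 5, dtype=object)
        pred = np.array(["rest"] * 10, dtype=object)
        assert accuracy(pred, truth, "rest") == pytest.approx(50.0)

    def test_zero_denominators_flagged_none(self):
        truth = np.array(["rest"], dtype=object)
        pred = np.array(["rest"], dtype=object)
        assert sensitivity(pred, truth, "walking") is None
        assert accuracy(pred, truth, "walking") is None

    def test_random_confusion_matches_bruteforce_tally(self, rng):
        preds = np.array(["walking", "micromovement", "rest"], dtype=object)
        truths = np.array(list(VIDEO_BEHAVIORS), dtype=object)
        pred = preds[rng.integers(0, 3, 400)]
        truth = truths[rng.integers(0, len(truths), 400)]
        for b in VIDEO_BEHAVIORS:
            denom = sum(t == b for t in truth)
            num = sum(
                t == b and p == COARSE_OF[b] for p, t in zip(pred, truth)
            )
            want = 100.0 * num / denom if denom else None
            got = sensitivity(pred, truth, b)
            assert got == pytest.approx(want) if want is not None else got is None
        for c in ("walking", "micromovement", "rest"):
            denom = sum(p == c for p in pred)
            num = sum(p == c and COARSE_OF[t] == c for p, t in zip(pred, truth))
            assert accuracy(pred, truth, c) == pytest.approx(100.0 * num / denom)


class TestCombinedAndSleepInclusive:
    def test_walking_predicted_micromovement_counts_as_activity(self):
        truth = np.array(["walking"] * 4, dtype=object)
        pred = np.array(["micromovement"] * 4, dtype=object)
        assert sensitivity(pred, truth, "walking") == 0.0
        assert combined_walk_micro_sensitivity(pred, truth) == 100.0

    def test_perfect_labels(self):
        truth = np.array(["walking", "feeding", "rest"], dtype=object)
        pred = np.array(["walking", "micromovement", "rest"], dtype=object)
        assert combined_walk_micro_sensitivity(pred, truth) == 100.0

    def test_collapsing_never_decreases_sensitivity(self, rng):
        preds = np.array(["walking", "micromovement", "rest"], dtype=object)
        truths = np.array(list(VIDEO_BEHAVIORS), dtype=object)
        for _ in range(100):
            pred = preds[rng.integers(0, 3, 60)]
            truth = truths[rng.integers(0, len(truths), 60)]
            combined = combined_walk_micro_sensitivity(pred, truth)
            if combined is None:
                continue
            parts = [
                sensitivity(pred, truth, b)
                for b in ("walking",) + MICRO_BEHAVIORS
            ]
            parts = [p for p in parts if p is not None]
            if parts:
                # the collapsed super-class can only gain agreement
                n_act = np.isin(truth, ("walking",) + MICRO_BEHAVIORS).sum()
                weighted = sum(
                    p * (truth == b).sum()
                    for p, b in zip(
                        [sensitivity(pred, truth, b) or 0 for b in ("walking",) + MICRO_BEHAVIORS],
                        ("walking",) + MICRO_BEHAVIORS,
                    )
                ) / n_act
                assert combined >= weighted - 1e-9

    def test_remap_absorbs_subtle_behaviors(self):
        truth = np.array(
            ["rest", "posture_change", "proboscis_extension", "single_leg_movement"],
            dtype=object,
        )
        pred = np.array(["rest"] * 4, dtype=object)
        assert accuracy(pred, truth, "rest") == pytest.approx(25.0)
        assert sleep_inclusive_rest_accuracy(pred, truth) == 100.0

    def test_no_remapped_behaviors_equals_plain_accuracy(self):
        truth = np.array(["rest", "feeding", "rest"], dtype=object)
        pred = np.array(["rest", "rest", "rest"], dtype=object)
        assert sleep_inclusive_rest_accuracy(pred, truth) == accuracy(
            pred, truth, "rest"
        )


class TestFalseSleepEpisodes:
    def test_feeding_inside_long_rest_run(self):
        pred = np.array(["rest"] * 10, dtype=object)
        truth = np.array(["rest"] * 5 + ["feeding"] + ["rest"] * 4, dtype=object)
        assert count_false_sleep_episodes(pred, truth) == 1

    def test_no_five_minute_rest_run(self):
        pred = np.array(["rest"] * 4 + ["walking"] + ["rest"] * 4, dtype=object)
        truth = np.array(["feeding"] * 9, dtype=object)
        assert count_false_sleep_episodes(pred, truth) == 0

    def test_random_matches_bruteforce_scan(self, rng):
        for _ in range(100):
            pred = np.where(rng.random(60) < 0.6, "rest", "walking").astype(object)
            truth = np.array(list(VIDEO_BEHAVIORS), dtype=object)[
                rng.integers(0, len(VIDEO_BEHAVIORS), 60)
            ]
            # brute force: walk every maximal rest run
            count = 0
            i = 0
            while i < 60:
                if pred[i] == "rest":
                    j = i
                    while j < 60 and pred[j] == "rest":
                        j += 1
                    if j - i >= 5 and any(
                        t in ("feeding", "grooming") for t in truth[i:j]
                    ):
                        count += 1
                    i = j
                else:
                    i += 1
            assert count_false_sleep_episodes(pred, truth) == count


class TestReport:
    def test_confusion_sums_to_total_and_rounding(self, rng):
        truth = np.array(list(VIDEO_BEHAVIORS), dtype=object)[
            rng.integers(0, len(VIDEO_BEHAVIORS), 500)
        ]
        pred = np.array(["walking", "micromovement", "rest"], dtype=object)[
            rng.integers(0, 3, 500)
        ]
        rep = validate(pred, truth)
        assert rep.confusion.to_numpy().sum() == 500
        for v in list(rep.sensitivity_pct.values()) + list(rep.accuracy_pct.values()):
            if v is not None:
                assert 0 <= v <= 100
                assert v == round(v, 1)

    def test_half_up_percent_rounding(self):
        assert round_percent(88.85) == 88.9
        assert round_percent(88.84) == 88.8
        assert round_percent(91.25) == 91.3
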