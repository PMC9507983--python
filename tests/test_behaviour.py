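"""Behavioural scoring: rating composite, 2AFC accuracy, target-detection
event matching and RT priming, plus the group-level ANOVAs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slfreqtag.behaviour import (
    afc_group_test,
    detection_rt_anova,
    group_stats,
    match_presses,
    rating_anova,
    score_afc,
    score_detection,
    score_rating,
)
from slfreqtag.simulate import BehaviourSimConfig, simulate_behaviour
from slfreqtag.streams import build_lexicon


def _rating_table(words, partwords, nonwords, pid="P1"):
    rows = []
    for cat, vals in (("word", words), ("partword", partwords), ("nonword", nonwords)):
        for i, v in enumerate(vals):
            rows.append(dict(participant_id=pid, item=f"{cat}{i}", category=cat, rating=v))
    return pd.DataFrame(rows)


class TestRating:
    def test_toy_table_matches_hand_arithmetic(self):
        df = _rating_table([4, 3, 4, 3], [2, 2, 3, 1], [1, 2, 1, 2])
        out = score_rating(df)
        assert out.iloc[0]["rating_score"] == pytest.approx(3.5 - 1.75)
        assert out.iloc[0]["mean_word"] == 3.5

    def test_uniform_ratings_score_zero_and_flagged(self):
        df = _rating_table([2] * 4, [2] * 4, [2] * 4)
        out = score_rating(df)
        assert out.iloc[0]["rating_score"] == 0.0
        assert out.iloc[0]["zero_variance"]

    def test_extreme_separation(self):
        df = _rating_table([4] * 4, [1] * 4, [1] * 4)
        assert score_rating(df).iloc[0]["rating_score"] == 3.0

    def test_score_bounded_by_scale(self):
        rng = np.random.default_rng(0)
        df = _rating_table(*(rng.integers(1, 5, 4) for _ in range(3)))
        s = score_rating(df).iloc[0]["rating_score"]
        assert -3.0 <= s <= 3.0

    def test_partial_set_warns(self):
        df = _rating_table([4, 3], [2], [1])
        with pytest.warns(UserWarning, match="expected 12"):
            score_rating(df)


class TestAFC:
    def _trials(self, correct, pid="P1"):
        return pd.DataFrame(
            dict(participant_id=pid, word="w", foil="f", foil_type="partword",
                 choice="w", correct=correct)
        )

    def test_all_correct(self):
        rep = score_afc(
            pd.concat([self._trials([True] * 16, "P1"), self._trials([True] * 16, "P2"),
                       self._trials([True] * 15 + [False], "P3")])
        )
        assert rep.scores.set_index("participant_id").loc["P1", "afc_accuracy"] == 100.0

    def test_eleven_of_sixteen(self):
        rep = score_afc(self._trials([True] * 11 + [False] * 5))
        assert rep.scores.iloc[0]["afc_accuracy"] == pytest.approx(68.75)

    def test_guessers_average_to_chance(self):
        rng = np.random.default_rng(0)
        frames = [
            self._trials(list(rng.random(16) < 0.5), f"P{i}") for i in range(1000)
        ]
        rep = score_afc(pd.concat(frames))
        se = 100 * np.sqrt(0.25 / 16) / np.sqrt(1000)
        assert abs(rep.mean_accuracy - 50.0) < 2 * se
        assert rep.p > 0.001  # no spurious certainty of learning

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            score_afc(pd.DataFrame())


def _detection_tables(targets, presses, pid="P1", stream=0):
    tg = pd.DataFrame(
        [dict(participant_id=pid, stream=stream, onset=o, position=p) for o, p in targets]
    )
    pr = pd.DataFrame(
        [dict(participant_id=pid, stream=stream, time=t) for t in presses]
    )
    return tg, pr


class TestDetection:
    def test_toy_stream_hit_and_fa_rates(self):
        # 4 targets, 3 in-window presses, 2 stray presses
        tg, pr = _detection_tables(
            targets=[(1.0, 1), (5.0, 2), (9.0, 3), (13.0, 1)],
            presses=[1.3, 5.4, 9.2, 0.5, 20.0],
        )
        out = score_detection(tg, pr, mode="adult")
        assert out.iloc[0]["hit_rate"] == 0.75
        assert out.iloc[0]["normalised_fa"] == 0.5

    def test_rt_priming_formula(self):
        # S1 = 600 ms, S3 = 450 ms -> (600 - 450) / 600 = 0.25
        tg, pr = _detection_tables(
            targets=[(1.0, 1), (5.0, 3)], presses=[1.6, 5.45]
        )
        out = score_detection(tg, pr, mode="adult")
        assert out.iloc[0]["rt_priming"] == pytest.approx(0.25)

    def test_press_at_exact_onset_is_false_alarm(self):
        tg, pr = _detection_tables(targets=[(2.0, 1)], presses=[2.0])
        out = score_detection(tg, pr, mode="adult")
        assert out.iloc[0]["hit_rate"] == 0.0
        assert out.iloc[0]["normalised_fa"] == 1.0

    def test_window_depends_on_mode(self):
        tg, pr = _detection_tables(targets=[(2.0, 1)], presses=[3.3])  # 1300 ms
        assert score_detection(tg, pr, "adult").iloc[0]["hit_rate"] == 0.0
        assert score_detection(tg, pr, "child").iloc[0]["hit_rate"] == 1.0

    def test_each_target_consumes_one_press(self):
        # two presses in the same window: one hit, one false alarm
        tg, pr = _detection_tables(targets=[(1.0, 2)], presses=[1.2, 1.4])
        out = score_detection(tg, pr, "adult")
        assert out.iloc[0]["hit_rate"] == 1.0
        assert out.iloc[0]["normalised_fa"] == 1.0

    def test_nearest_preceding_target_wins(self):
        # overlapping windows: press at 2.1 belongs to the 1.9 target
        tg, pr = _detection_tables(targets=[(1.2, 1), (1.9, 2)], presses=[2.1])
        matched, n_fa = match_presses(
            tg[["onset", "position"]].assign(onset=tg["onset"]), pr, 1200.0
        )
        assert bool(matched.loc[matched["onset"] == 1.9, "hit"].iloc[0])
        assert not matched.loc[matched["onset"] == 1.2, "hit"].iloc[0]

    def test_matches_brute_force_event_matcher(self):
        """Randomised streams agree with an independent exhaustive matcher."""
        rng = np.random.default_rng(7)
        onsets = np.sort(rng.uniform(0, 60, 16))
        targets = [(float(o), int(rng.integers(1, 4))) for o in onsets]
        presses = sorted(
            float(t)
            for t in np.concatenate(
                [onsets + rng.uniform(-0.5, 2.0, 16), rng.uniform(0, 60, 5)]
            )
        )
        tg, pr = _detection_tables(targets, presses)
        out = score_detection(tg, pr, "adult")

        # oracle: replay the same assignment rule with explicit loops
        consumed = [False] * len(targets)
        hits, fas = [], 0
        for t in presses:
            best, best_lag = None, None
            for j, (o, _) in enumerate(targets):
                lag = t - o
                if not consumed[j] and 0 < lag <= 1.2:
                    if best_lag is None or lag < best_lag:
                        best, best_lag = j, lag
            if best is None:
                fas += 1
            else:
                consumed[best] = True
                hits.append((best, best_lag))
        assert out.iloc[0]["hit_rate"] == len(hits) / len(targets)
        assert out.iloc[0]["normalised_fa"] == fas / len(targets)
        # per-position RT means agree too
        rts = {1: [], 2: [], 3: []}
        for j, lag in hits:
            rts[targets[j][1]].append(lag * 1000)
        for pos, col in ((1, "s1_rt"), (2, "s2_rt"), (3, "s3_rt")):
            expected = np.mean(rts[pos]) if rts[pos] else np.nan
            got = out.iloc[0][col]
            assert (np.isnan(got) and np.isnan(expected)) or got == pytest.approx(expected)

    def test_no_hits_in_position_yields_nan(self):
        tg, pr = _detection_tables(targets=[(1.0, 1), (5.0, 2)], presses=[1.4])
        out = score_detection(tg, pr, "adult")
        assert np.isnan(out.iloc[0]["s2_rt"]) and np.isnan(out.iloc[0]["s3_rt"])
        assert np.isnan(out.iloc[0]["rt_priming"])

    @settings(max_examples=10, deadline=None)
    @given(scale=st.floats(0.5, 1.9))
    def test_rt_priming_invariant_to_rt_scaling(self, scale):
        base = {1: 0.5, 3: 0.35}
        tg1, pr1 = _detection_tables(
            [(1.0, 1), (5.0, 3)], [1.0 + base[1], 5.0 + base[3]]
        )
        tg2, pr2 = _detection_tables(
            [(1.0, 1), (5.0, 3)], [1.0 + base[1] * scale, 5.0 + base[3] * scale]
        )
        p1 = score_detection(tg1, pr1, "adult").iloc[0]["rt_priming"]
        p2 = score_detection(tg2, pr2, "adult").iloc[0]["rt_priming"]
        assert p1 == pytest.approx(p2)

    def test_press_classification_is_exhaustive(self):
        rng = np.random.default_rng(3)
        targets = [(float(o), 1) for o in np.sort(rng.uniform(0, 30, 8))]
        presses = list(rng.uniform(0, 30, 12))
        tg, pr = _detection_tables(targets, presses)
        out = score_detection(tg, pr, "adult").iloc[0]
        n_hits = out["hit_rate"] * out["n_targets"]
        n_fa = out["normalised_fa"] * out["n_targets"]
        assert n_hits + n_fa == pytest.approx(len(presses))


class TestGroupStats:
    def test_identical_scores_give_null_effects(self):
        df = _rating_table([3, 3, 3, 3], [3, 3, 3, 3], [3, 3, 3, 3], "P1")
        frames = [df]
        for i in range(2, 9):
            frames.append(
                _rating_table([3, 3, 3, 3], [3, 3, 3, 3], [3, 3, 3, 3], f"P{i}")
            )
        out = rating_anova(pd.concat(frames))
        assert out["linear_contrast"]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_gradient_detected_in_most_simulations(self):
        """word > partword > nonword gradient yields a significant linear
        contrast in >= 90% of simulations at the generator's effect size."""
        lex = build_lexicon("A")
        sig = 0
        for seed in range(20):
            tables = simulate_behaviour(
                BehaviourSimConfig(
                    n_participants=20, learning_strength=0.5,
                    tasks=("rating",), seed=seed,
                ),
                lex,
            )
            out = rating_anova(tables.rating)
            sig += out["linear_contrast"]["p"] < 0.05
        assert sig >= 18

    def test_group_offset_without_slope_difference(self):
        """A pure between-group RT offset: significant group effect, null
        position x group interaction."""
        rng = np.random.default_rng(4)
        rows = []
        for g, offset in (("child", 150.0), ("adult", 0.0)):
            for i in range(16):
                base = 500.0 + offset + rng.normal(0, 20)
                rows.append(
                    dict(participant_id=f"{g}{i}", group=g,
                         s1_rt=base + rng.normal(0, 10),
                         s2_rt=base - 40 + rng.normal(0, 10),
                         s3_rt=base - 80 + rng.normal(0, 10))
                )
        out = detection_rt_anova(pd.DataFrame(rows), between="group")
        aov = out["anova"].set_index("Source")
        assert aov.loc["group", "p_unc"] < 0.05
        assert aov.loc["Interaction", "p_unc"] > 0.05

    def test_afc_group_anova_runs(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            dict(
                participant_id=[f"P{i}" for i in range(40)],
                afc_accuracy=rng.normal(65, 10, 40),
                group=["child"] * 20 + ["adult"] * 20,
            )
        )
        out = afc_group_test(df)
        assert {"F", "p_unc"} <= set(out.columns)

    def test_dispatcher(self):
        with pytest.raises(ValueError, match="unknown task"):
            group_stats("memory")
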