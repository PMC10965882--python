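"""Event I/O and the screening cascade."""

import numpy as np
import pytest

from aerialgaze.events import (
    FormatError,
    ScreeningConfig,
    apply_screening,
    in_image_region,
    load_events,
    screen_fixations,
    screen_saccades,
    screen_trials,
)
from aerialgaze.synthetic import write_events_csv
from conftest import make_fixation, make_saccade, make_trial

CFG = ScreeningConfig(image_size_px=(600, 600))


def centered_fixations(n, start=100.0, dur=200.0, pid="p00", img="img0"):
    out = [make_fixation(300, 300, onset=-100, dur=250, pid=pid, img=img, first=True)]
    t = start + 150
    for k in range(n):
        out.append(make_fixation(250 + 10 * k, 300, onset=t, dur=dur, pid=pid, img=img))
        t += dur + 30
    return out


def centered_trial(n, pid="p00", img="img0", correct=True, trackloss=()):
    return make_trial(
        centered_fixations(n, pid=pid, img=img),
        pid=pid, img=img, correct=correct, trackloss=trackloss,
    )


class TestLoadEvents:
    def test_round_trip_through_csv(self, tmp_path, synth_study):
        path = tmp_path / "events.csv"
        trials = synth_study["trials"]
        write_events_csv(trials, path)
        loaded = load_events(path)
        assert len(loaded) == len(trials)
        by_key = {(t.participant_id, t.image_id): t for t in loaded}
        for t in trials:
            lt = by_key[(t.participant_id, t.image_id)]
            assert len(lt.fixations) == len(t.fixations)
            assert len(lt.saccades) == len(t.saccades)
            assert lt.correct == t.correct
            assert lt.fixations[0].is_first  # earliest fixation flagged
            np.testing.assert_allclose(
                [f.x_px for f in lt.fixations], [f.x_px for f in t.fixations]
            )

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert load_events(path) == []

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("participant,image\np0,i0\n")
        with pytest.raises(FormatError):
            load_events(path)


class TestTrialRules:
    # distinct participants per trial keep the 25%-excluded-trials
    # participant rule out of these single-rule checks

    def test_incorrect_trial_excluded(self):
        good = centered_trial(5, img="a", pid="pA")
        bad = centered_trial(5, img="b", correct=False, pid="pB")
        valid, report = screen_trials([good, bad], CFG)
        assert [t.image_id for t in valid] == ["a"]
        assert report.rules["trials_incorrect"]["excluded"] == 1

    def test_exactly_two_valid_fixations_excluded(self):
        # "larger than two": 2 valid fixations fail, 3 pass
        two = centered_trial(2, img="two", pid="pA")
        three = centered_trial(3, img="three", pid="pB")
        valid, report = screen_trials([two, three], CFG)
        assert [t.image_id for t in valid] == ["three"]
        assert report.rules["trials_too_few_fixations"]["excluded"] == 1

    def test_blink_gap_retained_nonblink_gap_excluded(self):
        blink = centered_trial(5, img="blink", pid="pA",
                               trackloss=[(1000.0, 1150.0, True)])
        lost = centered_trial(5, img="lost", pid="pB",
                              trackloss=[(1000.0, 1150.0, False)])
        short_gap = centered_trial(5, img="short", pid="pC",
                                   trackloss=[(1000.0, 1080.0, False)])
        valid, report = screen_trials([blink, lost, short_gap], CFG)
        assert sorted(t.image_id for t in valid) == ["blink", "short"]
        assert report.rules["trials_trackloss_gap"]["excluded"] == 1

    def test_missing_correct_flag_raises(self):
        t = make_trial(centered_fixations(5), correct=None)
        with pytest.raises(ValueError, match="correctness"):
            screen_trials([t], CFG)

    def test_participant_with_heavy_trackloss_excluded(self):
        trials = []
        for img in "abcd":
            trials.append(
                centered_trial(5, pid="lossy", img=img,
                               trackloss=[(0.0, 900.0, True)])  # 30% lost, blink
            )
            trials.append(centered_trial(5, pid="clean", img=img))
        valid, report = screen_trials(trials, CFG)
        assert {t.participant_id for t in valid} == {"clean"}
        assert report.excluded_participants == ["lossy"]


class TestFixationFilters:
    def test_out_of_region_and_boundary(self):
        t = make_trial(
            centered_fixations(4)
            + [make_fixation(650, 300, onset=2000),
               make_fixation(599.0, 300, onset=2300),
               make_fixation(600.0, 300, onset=2600)]
        )
        fixations, report = screen_fixations([t], CFG)
        xs = {f.x_px for f in fixations}
        assert 650 not in xs and 600.0 not in xs  # outside
        assert 599.0 in xs  # boundary pixel is inside
        assert report.rules["fixations_out_of_region"]["excluded"] == 2

    def test_short_fixation_removed(self):
        t = make_trial(
            centered_fixations(4) + [make_fixation(300, 300, onset=2000, dur=90)]
        )
        fixations, report = screen_fixations([t], CFG)
        assert all(f.duration_ms >= 100 for f in fixations)
        assert report.rules["fixations_too_short"]["excluded"] == 1

    def test_two_sd_cutoff_matches_hand_computation(self):
        # durations engineered so one 580 ms fixation sits above
        # mean + 2 SD while the rest survive
        durs = [150, 200, 250, 296, 300, 342, 250, 200, 580]
        fixes = [make_fixation(300, 300, onset=100 + 400 * k, dur=d)
                 for k, d in enumerate(durs)]
        t = make_trial([make_fixation(300, 300, -100, 250, first=True)] + fixes)
        fixations, report = screen_fixations([t], CFG)
        arr = np.array(durs, float)
        cutoff = arr.mean() + 2 * arr.std(ddof=1)
        expected = [d for d in durs if d <= cutoff]
        assert sorted(f.duration_ms for f in fixations) == sorted(expected)
        assert 580 not in [f.duration_ms for f in fixations]
        assert report.rules["fixations_too_long"]["cutoff_ms"] == pytest.approx(cutoff)

    def test_printed_grand_stats_imply_574ms_cutoff(self):
        # grand mean 296 ms, SD 139 ms => cutoff 574 ms: a 580 ms fixation
        # is removed. Two-point sample realizes the moments exactly.
        assert 296 + 2 * 139 == 574
        n = 4000
        a = 139.0 * np.sqrt((n - 1) / n)
        durs = [296.0 - a, 296.0 + a] * (n // 2)
        fixes = [make_fixation(300, 300, onset=1.0 + 0.6 * k, dur=float(d))
                 for k, d in enumerate(durs)]
        probe = make_fixation(300, 300, onset=2900, dur=580.0)
        t = make_trial([make_fixation(300, 300, -100, 250, first=True)] + fixes + [probe])
        fixations, report = screen_fixations([t], CFG)
        assert report.rules["fixations_too_long"]["cutoff_ms"] == pytest.approx(574, abs=0.5)
        assert 580.0 not in [f.duration_ms for f in fixations]


class TestSaccadeFilters:
    def test_anticipatory_saccade_removed(self):
        t = make_trial(
            centered_fixations(4),
            saccades=[make_saccade(300, 300, 310, 300, onset=50),
                      make_saccade(300, 300, 310, 300, onset=80)],
        )
        saccades, report = screen_saccades([t], CFG)
        assert [s.onset_ms for s in saccades] == [80]
        assert report.rules["saccades_anticipatory"]["excluded"] == 1

    def test_out_of_region_endpoint_removed(self):
        t = make_trial(
            centered_fixations(4),
            saccades=[make_saccade(300, 300, -5, 300, onset=200),
                      make_saccade(300, 300, 310, 300, onset=400)],
        )
        saccades, report = screen_saccades([t], CFG)
        assert len(saccades) == 1
        assert report.rules["saccades_out_of_region"]["excluded"] == 1

    def test_all_valid_trial_unchanged(self):
        sacc = [make_saccade(300, 300, 310, 300, onset=200 + 100 * k)
                for k in range(5)]
        t = make_trial(centered_fixations(6), saccades=sacc)
        saccades, _ = screen_saccades([t], CFG)
        assert len(saccades) == len(sacc)


class TestCascadeProperties:
    def test_counts_conserved_per_rule(self, violation_study, violation_cfg):
        cfg = ScreeningConfig(
            image_size_px=(violation_cfg.image_size_px,) * 2
        )
        screened = apply_screening(violation_study["trials"], cfg)
        for rule, d in screened.report.rules.items():
            assert 0 <= d["excluded"] <= d["total"]
            assert 0.0 <= d["pct"] <= 100.0

    def test_planted_violations_counted_exactly(self, violation_study, violation_cfg):
        """Precision and recall 1.0: per-rule report counts equal the
        generator's planted-violation counts."""
        cfg = ScreeningConfig(image_size_px=(violation_cfg.image_size_px,) * 2)
        trials = violation_study["trials"]
        truth = violation_study["truth"]
        screened = apply_screening(trials, cfg)
        r = screened.report.rules
        assert r["trials_incorrect"]["excluded"] == len(truth.incorrect_trials)
        assert (
            r["trials_too_few_fixations"]["excluded"]
            == len(truth.too_few_fixation_trials)
        )
        assert r["trials_trackloss_gap"]["excluded"] == len(truth.trackloss_trials)
        valid_keys = {(t.participant_id, t.image_id) for t in screened.trials}
        for rule, planted in [
            ("fixations_too_short", truth.short_fixations),
            ("fixations_out_of_region", truth.out_fixations),
            ("saccades_anticipatory", truth.early_saccades),
            ("saccades_out_of_region", truth.out_saccades),
        ]:
            in_valid = [k for k in planted if (k[0], k[1]) in valid_keys]
            assert r[rule]["excluded"] == len(in_valid)

    def test_screening_idempotent(self, violation_study, violation_cfg):
        cfg = ScreeningConfig(image_size_px=(violation_cfg.image_size_px,) * 2)
        first = apply_screening(violation_study["trials"], cfg)
        second = apply_screening(
            first.trials, cfg, duration_cutoff_ms=first.duration_cutoff_ms
        )
        for rule, d in second.report.rules.items():
            assert d["excluded"] == 0, f"rule {rule} removed data on re-screening"
        assert len(second.trials) == len(first.trials)

    def test_zero_invalid_rates_remove_nothing(self):
        from aerialgaze.synthetic import (
            SynthConfig, gen_annotations, gen_images, gen_scanpaths,
        )

        gen_cfg = SynthConfig(
            n_categories=2, images_per_category=4, observers=4,
            image_size_px=200, p_incorrect_trial=0.0, p_blink_trial=0.0,
            seed=3,
        )
        rng = np.random.default_rng(3)
        _, cats, objs = gen_images(gen_cfg, rng)
        trials, _ = gen_scanpaths(gen_cfg, gen_annotations(gen_cfg, objs), cats, rng)
        cfg = ScreeningConfig(image_size_px=(200, 200))
        screened = apply_screening(trials, cfg)
        r = screened.report.rules
        for rule in (
            "trials_incorrect", "trials_too_few_fixations", "trials_trackloss_gap",
            "fixations_out_of_region", "fixations_too_short",
            "saccades_anticipatory", "saccades_out_of_region",
        ):
            assert r[rule]["excluded"] == 0


def test_image_region_half_open():
    assert in_image_region(0, 0, (600, 600))
    assert in_image_region(599.99, 599.99, (600, 600))
    assert not in_image_region(600, 300, (600, 600))
    assert not in_image_region(-0.01, 300, (600, 600))
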