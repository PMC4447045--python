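"""Triggered averages, the shuffle null, sequences, chases and receptivity."""

import numpy as np
import pandas as pd
import pytest

from usvmuse import behavior as bhv
from usvmuse.config_io import TRACK_COLUMNS, TrackTable

FPS = 29.0


def make_tracks(n_frames, positions):
    """positions: mouse_id -> (n_frames, 2) array (constant tuples allowed)."""
    rows = []
    for mid, pos in positions.items():
        pos = np.asarray(pos, dtype=float)
        if pos.ndim == 1:
            pos = np.tile(pos, (n_frames, 1))
        for f in range(n_frames):
            rows.append((f, mid, pos[f, 0], pos[f, 1], 0.0, 0.09, 0.035))
    return TrackTable(pd.DataFrame(rows, columns=TRACK_COLUMNS), FPS)


def events_df(records):
    return pd.DataFrame(records, columns=["time", "mouse_id", "sex"])


class TestTriggeredRate:
    def test_single_trigger_counting(self):
        out = bhv.triggered_rate([100.0], [100.5, 101.5], (0.0, 300.0))
        rate = out.rate_hz
        b0 = np.searchsorted(out.bin_edges, 0.0)  # bin [0, 1)
        assert rate[b0] == 1.0 and rate[b0 + 1] == 1.0
        assert rate.sum() == 2.0

    def test_self_train_gives_zero(self):
        trig = [100.0, 150.0, 200.0]
        out = bhv.triggered_rate(trig, trig, (0.0, 300.0))
        assert np.all(out.rate_hz == 0.0)

    def test_edge_triggers_excluded(self):
        with pytest.raises(ValueError, match="edge"):
            bhv.triggered_rate([10.0], [11.0], (0.0, 300.0))

    def test_shifted_train_concentrates_in_first_bin(self):
        """Responses = triggers + 0.5 s: exactly 1 Hz in [0, 1), 0 elsewhere."""
        trig = np.arange(40.0, 3900.0, 70.0)  # spaced beyond the window
        out = bhv.triggered_rate(trig, trig + 0.5, (0.0, 4000.0))
        b0 = np.searchsorted(out.bin_edges, 0.0)
        assert out.rate_hz[b0] == 1.0
        rest = np.delete(out.rate_hz, b0)
        assert np.all(rest == 0.0)

    def test_poisson_responses_flat_at_rate(self, rng):
        lam = 0.5
        T = 4000.0
        resp = np.sort(rng.uniform(0, T, rng.poisson(lam * T)))
        trig = np.sort(rng.uniform(40, T - 40, 300))
        out = bhv.triggered_rate(trig, resp, (0.0, T))
        se = np.sqrt(lam / (out.n_triggers * 1.0))
        assert np.all(np.abs(out.rate_hz - lam) < 4 * se)


class TestPermutationNull:
    def test_seed_deterministic(self, rng):
        trig = np.sort(rng.uniform(40, 260, 30))
        resp = np.sort(rng.uniform(0, 300, 60))
        a = bhv.permutation_null([trig], [resp], [(0, 300.0)],
                                 n_shuffles=50, seed=5)
        b = bhv.permutation_null([trig], [resp], [(0, 300.0)],
                                 n_shuffles=50, seed=5)
        np.testing.assert_array_equal(a["null_max_stat"], b["null_max_stat"])
        assert a["verdict"] == b["verdict"]

    def test_coupled_trains_detected_with_peak_in_first_bin(self, rng):
        T = 2000.0
        trig = np.sort(rng.uniform(40, T - 40, 200))
        resp = trig + rng.uniform(0.05, 0.95, trig.size)  # always answered
        out = bhv.permutation_null([trig], [resp], [(0.0, T)],
                                   n_shuffles=200, seed=1)
        assert out["verdict"] is True
        b0 = np.searchsorted(out["bin_edges"], 0.0)
        assert int(np.argmax(out["observed"])) == b0

    def test_degenerate_identical_curves_not_significant(self):
        trig = np.arange(40.0, 260.0, 10.0)
        out = bhv.permutation_null([trig], [np.array([])], [(0.0, 300.0)],
                                   n_shuffles=50, seed=0)
        assert out["verdict"] is False  # every curve is identically zero

    def test_zero_shuffles_rejected(self):
        with pytest.raises(ValueError):
            bhv.permutation_null([[100.0]], [[1.0]], [(0, 300.0)], n_shuffles=0)


class TestVocalSequences:
    def test_answer_within_one_second(self):
        ev = events_df([(100.0, 0, "M"), (100.8, 2, "F")])
        seqs = bhv.detect_vocal_sequences(ev, "male", record_span=(0, 300))
        assert len(seqs) == 1
        s = seqs[0]
        assert s.onset == 100.0 and s.male_id == 0 and s.female_id == 2

    def test_answer_after_one_second_ignored(self):
        ev = events_df([(100.0, 0, "M"), (101.2, 2, "F")])
        assert bhv.detect_vocal_sequences(ev, "male", record_span=(0, 300)) == []

    def test_two_females_answering_is_ambiguous(self):
        ev = events_df([(100.0, 0, "M"), (100.4, 2, "F"), (100.6, 3, "F")])
        assert bhv.detect_vocal_sequences(ev, "male", record_span=(0, 300)) == []

    def test_ongoing_exchange_not_double_counted(self):
        ev = events_df([(100.0, 0, "M"), (100.5, 2, "F"), (100.9, 0, "M"),
                        (101.3, 2, "F")])
        seqs = bhv.detect_vocal_sequences(ev, "male", record_span=(0, 300))
        assert [s.onset for s in seqs] == [100.0]

    def test_female_initiated_direction(self):
        ev = events_df([(100.0, 2, "F"), (100.7, 1, "M")])
        seqs = bhv.detect_vocal_sequences(ev, "female", record_span=(0, 300))
        assert len(seqs) == 1 and seqs[0].male_id == 1 and seqs[0].female_id == 2

    def test_edge_sequences_flagged_but_returned(self):
        ev = events_df([(10.0, 0, "M"), (10.5, 2, "F"),
                        (100.0, 0, "M"), (100.5, 2, "F")])
        seqs = bhv.detect_vocal_sequences(ev, "male", record_span=(0, 300))
        assert len(seqs) == 2
        assert [s.edge_ok for s in sorted(seqs, key=lambda s: s.onset)] == [False, True]

    def test_simulated_coupled_counts_match_ground_truth(self):
        from usvmuse import simulator as sim

        cfg = sim.ScenarioConfig(duration_s=600.0, male_rate_hz=0.05,
                                 female_rate_hz=0.0, coupling_prob=1.0,
                                 coupling_latency_s=(0.1, 0.9), seed=21)
        s = sim.synth_session(cfg)
        ev = s.events[["time", "mouse_id", "sex"]]
        males = ev[ev["sex"] == "M"]["time"].to_numpy()
        # ground truth: every male call answered -> one sequence per male call
        # whose response window holds exactly one female
        seqs = bhv.detect_vocal_sequences(ev, "male",
                                          record_span=(0, cfg.duration_s))
        n_expected = 0
        fem = ev[ev["sex"] == "F"]
        for t in males:
            win = fem[(fem["time"] > t) & (fem["time"] <= t + 1.0)]
            prior_same = ev[(ev["time"] < t) & (ev["time"] >= t - 1.0)]
            if win["mouse_id"].nunique() == 1 and \
                    not prior_same["mouse_id"].isin(win["mouse_id"]).any():
                n_expected += 1
        assert len(seqs) == n_expected > 0


class TestPairKinematics:
    def test_stationary_mice(self):
        n = int(70 * FPS)
        tracks = make_tracks(n, {0: (0.1, 0.1), 1: (0.5, 0.5),
                                 2: (0.1, 0.4), 3: (0.6, 0.2)})
        seqs = [bhv.VocalSequence(35.0, 0, 2, (35.4,), 0, 2)]
        out = bhv.pair_kinematics(seqs, tracks)
        assert out["n_used"] == 1
        np.testing.assert_allclose(out["vocal_speed"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["vocal_dist"],
                                   np.hypot(0.3, 0.0), atol=1e-12)

    def test_two_identical_windows_average_equals_either(self):
        n = int(160 * FPS)
        rng = np.random.default_rng(0)
        wander = 0.3 + 0.01 * np.cumsum(rng.normal(0, 0.01, (n, 2)), axis=0)
        period = int(50 * FPS)
        wander = 0.3 + 0.05 * np.sin(np.arange(n) * 2 * np.pi / period)[:, None]
        tracks = make_tracks(n, {0: np.column_stack([wander[:, 0], np.full(n, .2)]),
                                 1: (0.5, 0.5), 2: (0.1, 0.4), 3: (0.6, 0.2)})
        seqs = [bhv.VocalSequence(50.0, 0, 2, (), 0, 2),
                bhv.VocalSequence(100.0, 0, 2, (), 0, 2)]
        out = bhv.pair_kinematics(seqs, tracks)
        one = bhv.pair_kinematics(seqs[:1], tracks)
        np.testing.assert_allclose(out["vocal_dist"], one["vocal_dist"],
                                   atol=1e-9)

    def test_window_outside_coverage_skipped(self):
        tracks = make_tracks(int(40 * FPS), {0: (0.1, 0.1), 1: (0.5, 0.5),
                                             2: (0.1, 0.4), 3: (0.6, 0.2)})
        seqs = [bhv.VocalSequence(35.0, 0, 2, (), 0, 2)]
        out = bhv.pair_kinematics(seqs, tracks)
        assert out["n_skipped"] == 1 and out["n_used"] == 0


class TestRelativePosition:
    def _tracks_with_partner(self, rel_xy_fn, n=int(70 * FPS)):
        """Mouse 2 (female, centered) fixed at origin-ish heading 0; partner
        placed by rel_xy_fn(frame)->(dx, dy) in arena coordinates."""
        rows = []
        for f in range(n):
            rows.append((f, 2, 0.3, 0.3, 0.0, 0.09, 0.035))  # heading +x
            dx, dy = rel_xy_fn(f)
            rows.append((f, 0, 0.3 + dx, 0.3 + dy, 0.0, 0.09, 0.035))
        return TrackTable(pd.DataFrame(rows, columns=TRACK_COLUMNS), FPS)

    def test_partner_directly_behind_gives_zero_anterior(self):
        tracks = self._tracks_with_partner(lambda f: (-0.05, 0.0))
        seqs = [bhv.VocalSequence(35.0, 0, 2, (), 0, 2)]
        out = bhv.relative_position_maps(seqs, tracks, offsets=(0.0,))
        assert out[0.0]["anterior_proportion"] == 0.0

    def test_partner_ahead_gives_full_anterior(self):
        tracks = self._tracks_with_partner(lambda f: (0.05, 0.0))
        seqs = [bhv.VocalSequence(35.0, 0, 2, (), 0, 2)]
        out = bhv.relative_position_maps(seqs, tracks, offsets=(0.0,))
        assert out[0.0]["anterior_proportion"] == 1.0

    def test_isotropic_partners_near_half(self, rng):
        n = int(70 * FPS)
        angles = rng.uniform(0, 2 * np.pi, 400)
        tracks = self._tracks_with_partner(
            lambda f: (0.05 * np.cos(angles[f % 400]),
                       0.05 * np.sin(angles[f % 400])))
        seqs = [bhv.VocalSequence(30.0 + 0.1 * j, 0, 2, (), 0, 2)
                for j in range(400)]
        out = bhv.relative_position_maps(seqs, tracks, offsets=(0.0,))
        assert abs(out[0.0]["anterior_proportion"] - 0.5) < 0.1


def scripted_chase_tracks(n_frames=int(60 * FPS), chase=(20.0, 24.0)):
    """Female 2 runs an arc during the chase; male 0 follows 0.5 s behind;
    male 1 and female 3 sit far away."""
    t = np.arange(n_frames) / FPS
    c, r, w = np.array([0.33, 0.33]), 0.18, 2 * np.pi / 4
    fem = np.tile([0.2, 0.2], (n_frames, 1)).astype(float)
    male = np.tile([0.25, 0.2], (n_frames, 1)).astype(float)
    sel = (t >= chase[0]) & (t <= chase[1])
    fem[sel] = c + r * np.column_stack([np.cos(w * (t[sel] - chase[0])),
                                        np.sin(w * (t[sel] - chase[0]))])
    male[sel] = c + r * np.column_stack([np.cos(w * (t[sel] - chase[0] - 0.5)),
                                         np.sin(w * (t[sel] - chase[0] - 0.5))])
    return make_tracks(n_frames, {0: male, 1: (0.6, 0.6), 2: fem,
                                  3: (0.05, 0.6)})


class TestFilterChases:
    def test_scripted_chaser_identified(self):
        tracks = scripted_chase_tracks()
        out = bhv.filter_chases([(20.0, 24.0, 2)], tracks)
        assert len(out) == 1
        assert out[0].male_id == 0 and out[0].female_id == 2

    def test_start_distance_over_20cm_rejected(self):
        n = int(30 * FPS)
        tracks = make_tracks(n, {0: (0.0, 0.0), 1: (0.6, 0.6),
                                 2: (0.25, 0.0), 3: (0.05, 0.6)})
        assert bhv.filter_chases([(10.0, 12.0, 2)], tracks) == []

    def test_short_bouts_merged_then_retained(self):
        """Two 0.1 s bouts 0.2 s apart merge into one 0.4 s chase that passes
        the duration rule neither bout passes alone."""
        tracks = scripted_chase_tracks(chase=(20.0, 24.0))
        out = bhv.filter_chases([(21.5, 21.6, 2), (21.8, 21.9, 2)], tracks)
        assert len(out) == 1
        assert np.isclose(out[0].start, 21.5) and np.isclose(out[0].stop, 21.9)

    def test_sub_duration_chase_dropped(self):
        tracks = scripted_chase_tracks()
        assert bhv.filter_chases([(21.5, 21.6, 2)], tracks) == []

    def test_idempotent(self):
        tracks = scripted_chase_tracks()
        first = bhv.filter_chases([(20.0, 24.0, 2)], tracks)
        again = bhv.filter_chases([(c.start, c.stop, c.female_id)
                                   for c in first], tracks)
        assert [(c.start, c.stop, c.male_id, c.female_id) for c in first] == \
               [(c.start, c.stop, c.male_id, c.female_id) for c in again]


class TestAssociateInteractions:
    CHASES = [bhv.Chase(100.0, 104.0, 0, 2), bhv.Chase(200.0, 203.0, 0, 2)]

    def _seq(self, t, m=0, f=2):
        return bhv.VocalSequence(t, m, f, (), m, f)

    def test_inside_chase(self):
        out = bhv.associate_interactions(self.CHASES, [self._seq(102.0)])
        a = out["assignments"][0]
        assert a["relation"] == "inside" and a["chase"] == 0

    def test_after_previous_before_next_windows(self):
        out = bhv.associate_interactions(self.CHASES,
                                         [self._seq(120.0), self._seq(175.0),
                                          self._seq(150.0)])
        rel = {a["onset"]: (a["relation"], a["chase"])
               for a in out["assignments"]}
        assert rel[120.0] == ("after", 0)
        assert rel[175.0] == ("before", 1)
        assert rel[150.0] == ("unassigned", None)

    def test_partition_exactly_one_bucket_each(self):
        seqs = [self._seq(t) for t in np.arange(95.0, 240.0, 3.7)]
        out = bhv.associate_interactions(self.CHASES, seqs)
        assert len(out["assignments"]) == len(seqs)
        for a in out["assignments"]:
            assert (a["relation"] == "unassigned") == (a["chase"] is None)

    def test_other_pair_not_assigned(self):
        out = bhv.associate_interactions(self.CHASES, [self._seq(102.0, m=1, f=3)])
        assert out["assignments"][0]["relation"] == "unassigned"

    def test_all_inside_gives_zero_outside_rate(self):
        seqs = [self._seq(t) for t in (101.0, 102.0, 201.0)]
        out = bhv.associate_interactions(self.CHASES, seqs)
        for r in out["rates"]:
            assert r["outside_rate_hz"] == 0.0
        assert out["rates"][0]["inside_rate_hz"] == 2 / 4.0

    def test_pair_totals_for_correlation(self):
        seqs = [self._seq(102.0), self._seq(120.0), self._seq(102.5, m=1, f=3)]
        out = bhv.associate_interactions(self.CHASES, seqs)
        tot = out["pair_totals"]
        assert tot[(0, 2)]["n_sequences"] == 2
        assert tot[(0, 2)]["n_chases"] == 2
        assert np.isclose(tot[(0, 2)]["chase_time_s"], 7.0)
        assert tot[(1, 3)]["n_sequences"] == 1


class TestReceptivitySpeeds:
    def _events(self, records):
        return pd.DataFrame(records, columns=["time", "mouse_id", "sex"])

    def test_single_male_vocalization_skipped(self):
        tracks = scripted_chase_tracks()
        chases = [bhv.Chase(20.0, 24.0, 0, 2)]
        ev = self._events([(21.0, 0, "M")])
        out = bhv.receptivity_speeds(chases, ev, tracks)
        assert out["female_p"] is None and "skipped" in out

    def test_unassigned_vocalization_vetoes_male_only(self):
        tracks = scripted_chase_tracks()
        chases = [bhv.Chase(20.0, 24.0, 0, 2)]
        ev = self._events([(21.0, 0, "M"), (21.5, np.nan, "U"),
                           (23.0, 0, "M")])
        out = bhv.receptivity_speeds(chases, ev, tracks)
        # 21.0 is vetoed (unassigned follower); 23.0 is male-only
        assert len(out["samples"]["male_only"]["female"]) == 1
        assert len(out["samples"]["interaction"]["female"]) == 0

    def test_slow_responding_female_detected(self):
        """Females that answer are scripted slower at call time; the class
        medians must reflect it."""
        n = int(120 * FPS)
        t = np.arange(n) / FPS
        fem = np.column_stack([0.1 + 0.3 * ((t % 40) < 20) * (t % 1),
                               np.full(n, 0.2)])
        # female speed alternates: fast in [20,40), [60,80)... slow otherwise
        speed_slow = np.tile([0.2, 0.2], (n, 1)) + 0.001 * np.arange(n)[:, None]
        fem = np.column_stack([
            0.2 + 0.002 * np.cumsum(((t % 40) >= 20).astype(float)),
            np.full(n, 0.2)])
        male = fem + [[-0.05, 0.0]]
        tracks = make_tracks(n, {0: male, 1: (0.6, 0.6), 2: fem, 3: (0.05, 0.6)})
        chases = [bhv.Chase(0.0, 120.0, 0, 2)]
        recs = []
        for tm in np.arange(5.0, 115.0, 10.0):
            fast = (tm % 40) >= 20
            recs.append((tm, 0, "M"))
            if not fast:
                recs.append((tm + 0.5, 2, "F"))
        out = bhv.receptivity_speeds(chases, self._events(recs), tracks)
        assert out["interaction_female_median"] < out["male_only_female_median"]
        assert out["female_p"] is not None


class TestAnalyticHelpers:
    def test_expected_misassigned_from_error_rate(self):
        assert round(bhv.expected_misassigned_count(3486, 0.07)) == 244

    def test_observed_over_expected_exceeds_seven(self):
        exp = bhv.expected_misassigned_count(3486, 0.07)
        assert bhv.observed_to_expected_ratio(1743, exp) > 7.0

    def test_in_chase_fraction(self):
        assert np.isclose(bhv.in_chase_fraction(823, 1743), 47.2, atol=0.05)
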