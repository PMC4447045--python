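"""Vocal-interaction statistics for assigned vocalizations.

Implements the downstream analyses run on caller-assigned vocal events and
trajectories: opposite-sex triggered vocalization-rate averages with a
shuffle-based null, detection of vocal sequences (a male and a female of one
pair vocalizing within 1 s of each other), kinematics of vocal vs non-vocal
pairs around sequence onset, partner-position maps in a mouse-centered frame,
heuristic identification of the chasing male in courtship chases, association
of vocal sequences with chases, and the receptivity comparison of female
speeds during chases with and without vocal interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .config_io import TrackTable

__all__ = [
    "TriggeredAverage",
    "VocalSequence",
    "Chase",
    "triggered_rate",
    "permutation_null",
    "detect_vocal_sequences",
    "pair_kinematics",
    "relative_position_maps",
    "filter_chases",
    "associate_interactions",
    "receptivity_speeds",
    "expected_misassigned_count",
    "observed_to_expected_ratio",
    "in_chase_fraction",
]

WINDOW_S = 30.0
BIN_S = 1.0
SEQUENCE_WINDOW_S = 1.0
CHASE_GAP_MERGE_S = 0.3
CHASE_MIN_DURATION_S = 0.17
CHASE_START_DIST_M = 0.20
CHASE_OVERLAP_FRAC = 0.20
CHASE_CORRIDOR_M = 0.05


@dataclass
class TriggeredAverage:
    """Response rate in 1 s bins across +/-30 s around each trigger."""

    bin_edges: np.ndarray  # 61 edges spanning [-30, 30)
    rate_hz: np.ndarray  # 60 bins
    n_triggers: int
    null_mean: np.ndarray | None = None
    null_min: np.ndarray | None = None
    null_max: np.ndarray | None = None


@dataclass
class VocalSequence:
    onset: float
    initiator_id: object
    responder_id: object
    responder_times: tuple
    male_id: object
    female_id: object
    edge_ok: bool = True


@dataclass
class Chase:
    start: float
    stop: float
    male_id: object
    female_id: object
    source: str = "heuristic"

    @property
    def duration(self) -> float:
        return self.stop - self.start


def _bin_counts(triggers: np.ndarray, responses: np.ndarray,
                window: float = WINDOW_S, bin_s: float = BIN_S) -> np.ndarray:
    """Summed response counts in bins of ``bin_s`` across +/-window, all triggers.

    Bins are half-open [left, right); vectorized over triggers via
    searchsorted so the shuffle null can batch thousands of redraws.
    """
    edges = np.arange(-window, window + bin_s / 2, bin_s)
    return _bin_count_matrix(np.atleast_2d(np.asarray(triggers, float)),
                             np.sort(np.asarray(responses, float)), edges)[0]


def _bin_count_matrix(trigger_sets: np.ndarray, resp_sorted: np.ndarray,
                      edges: np.ndarray) -> np.ndarray:
    """(S, n_triggers) trigger sets -> (S, n_bins) summed response counts."""
    idx = np.searchsorted(resp_sorted,
                          trigger_sets[:, :, None] + edges[None, None, :])
    return np.diff(idx, axis=2).sum(axis=1)


def triggered_rate(triggers: np.ndarray, responses: np.ndarray,
                   record_span: tuple, window: float = WINDOW_S,
                   bin_s: float = BIN_S,
                   exclude_self: bool = True) -> TriggeredAverage:
    """Trigger-aligned response rate (Hz) in 1 s bins over +/-30 s.

    Triggers within ``window`` of the record edges are excluded.  Response
    events at exactly a trigger time are dropped when ``exclude_self`` (a
    train triggered on itself must not count the trigger event).
    """
    t0, t1 = record_span
    trig = np.asarray(triggers, dtype=float)
    trig = trig[(trig > t0 + window) & (trig < t1 - window)]
    if trig.size == 0:
        raise ValueError("no triggers remain after edge exclusion")
    resp = np.asarray(responses, dtype=float)
    if exclude_self:
        resp = resp[~np.isin(resp, trig)]
    counts = _bin_counts(trig, resp, window, bin_s)
    edges = np.arange(-window, window + bin_s / 2, bin_s)
    return TriggeredAverage(edges, counts / trig.size / bin_s, trig.size)


def permutation_null(triggers_per_session: list, responses_per_session: list,
                     record_spans: list, n_shuffles: int = 1000, seed: int = 0,
                     window: float = WINDOW_S, bin_s: float = BIN_S):
    """Shuffle-based null for the group-averaged triggered rate.

    Each shuffle redraws every session's trigger times uniformly over the
    valid span (trigger count preserved, response trains untouched) and
    recomputes the group-average curve.  The verdict statistic is the curve
    maximum over bins: the observation is significant when at most one of the
    ``n_shuffles`` shuffled maxima reaches the observed maximum, i.e. an
    empirical p of about 2/n_shuffles (the binomial 95% upper bound on 1/1000
    is ~0.006, hence the conventional "alpha < 0.006").

    Returns a dict with the observed group curve, per-bin null min/mean/max,
    per-bin exceedance counts, the shuffled maxima, and the verdict.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    edges = np.arange(-window, window + bin_s / 2, bin_s)
    n_bins = edges.size - 1

    obs_curves = []
    for trig, resp, span in zip(triggers_per_session, responses_per_session,
                                record_spans):
        obs_curves.append(triggered_rate(trig, resp, span, window, bin_s).rate_hz)
    observed = np.mean(obs_curves, axis=0)

    null_curves = np.zeros((n_shuffles, n_bins))
    n_sessions = len(triggers_per_session)
    for trig, resp, span in zip(triggers_per_session, responses_per_session,
                                record_spans):
        t0, t1 = span
        n_tr = np.asarray(trig)[(np.asarray(trig) > t0 + window)
                                & (np.asarray(trig) < t1 - window)].size
        fake = rng.uniform(t0 + window, t1 - window, size=(n_shuffles, n_tr))
        counts = _bin_count_matrix(fake, np.sort(np.asarray(resp, float)), edges)
        null_curves += counts / max(n_tr, 1) / bin_s / n_sessions

    exceed = (null_curves >= observed[None, :]).sum(axis=0)
    null_max_stat = null_curves.max(axis=1)
    verdict = bool((null_max_stat >= observed.max()).sum() <= 1)
    return {
        "bin_edges": edges,
        "observed": observed,
        "null_mean": null_curves.mean(axis=0),
        "null_min": null_curves.min(axis=0),
        "null_max": null_curves.max(axis=0),
        "exceedance": exceed,
        "null_max_stat": null_max_stat,
        "verdict": verdict,
    }


def detect_vocal_sequences(events: pd.DataFrame, direction: str = "male",
                           record_span: tuple | None = None,
                           window: float = SEQUENCE_WINDOW_S,
                           edge_margin: float = WINDOW_S) -> list[VocalSequence]:
    """Find vocal sequences: an initiator followed within 1 s by the other sex.

    ``events`` needs columns time, mouse_id, sex.  ``direction`` selects the
    initiating sex ("male" or "female").  A sequence requires all responding
    events within the window to come from one single opposite-sex animal, and
    the initiating event must not itself be a response within an ongoing
    sequence of the same pair.  Sequences within ``edge_margin`` of the record
    edges are flagged (``edge_ok=False``) but returned, since chase-correlation
    counts use all sequences while kinematic analyses drop edge cases.
    """
    init_sex = "M" if direction == "male" else "F"
    resp_sex = "F" if direction == "male" else "M"
    ev = events.sort_values("time").reset_index(drop=True)
    times = ev["time"].to_numpy(float)
    out: list[VocalSequence] = []
    t0 = record_span[0] if record_span else times.min() if times.size else 0.0
    t1 = record_span[1] if record_span else times.max() if times.size else 0.0
    for i, r in ev.iterrows():
        if r["sex"] != init_sex:
            continue
        t = r["time"]
        sel = (times > t) & (times <= t + window) & (ev["sex"] == resp_sex).to_numpy()
        responders = ev[sel]
        if responders.empty:
            continue
        rids = responders["mouse_id"].unique()
        if rids.size != 1:
            continue  # ambiguous: more than one opposite-sex animal answered
        rid = rids[0]
        # skip if this event continues an exchange of the same pair
        prior = ((times < t) & (times >= t - window)
                 & (ev["mouse_id"] == rid).to_numpy())
        if prior.any():
            continue
        male = r["mouse_id"] if init_sex == "M" else rid
        female = rid if init_sex == "M" else r["mouse_id"]
        edge_ok = (t - t0 >= edge_margin) and (t1 - t >= edge_margin)
        out.append(VocalSequence(float(t), r["mouse_id"], rid,
                                 tuple(responders["time"].tolist()),
                                 male, female, edge_ok))
    return out


def _speed_table(tracks: TrackTable) -> dict:
    """Per mouse: positions (F, 2) and instantaneous speeds (F,) m/s."""
    fps = tracks.frame_rate
    out = {}
    for mid in tracks.mouse_ids:
        sub = tracks.table[tracks.table["mouse_id"] == mid].sort_values("frame")
        pos = sub[["x_m", "y_m"]].to_numpy(float)
        frames = sub["frame"].to_numpy(int)
        sp = np.zeros(pos.shape[0])
        if pos.shape[0] > 1:
            d = np.linalg.norm(np.diff(pos, axis=0), axis=1) * fps
            sp[:-1] = d
            sp[-1] = d[-1]
        out[mid] = {"frames": frames, "pos": pos, "speed": sp,
                    "heading": sub["heading_rad"].to_numpy(float),
                    "major": sub["major_m"].to_numpy(float)}
    return out


def pair_kinematics(sequences: list[VocalSequence], tracks: TrackTable,
                    window: float = WINDOW_S):
    """Distance and speed traces for vocal and non-vocal pairs around onsets.

    Returns a dict of frame-resolution traces (mean across usable sequences)
    on a relative-time axis spanning +/-window, plus the number of sequences
    skipped for incomplete track coverage.
    """
    fps = tracks.frame_rate
    st = _speed_table(tracks)
    half = int(round(window * fps))
    rel = np.arange(-half, half + 1) / fps
    ids = tracks.mouse_ids
    acc = {k: [] for k in ["vocal_dist", "nonvocal_dist", "vocal_speed",
                           "nonvocal_speed"]}
    skipped = 0
    for seq in sequences:
        if not seq.edge_ok:
            continue
        f0 = int(round(seq.onset * fps))
        lo, hi = f0 - half, f0 + half
        if lo < 0 or any(hi >= st[m]["frames"].max() + 1 or
                         st[m]["frames"].min() > lo for m in ids):
            skipped += 1
            continue
        vocal = [seq.male_id, seq.female_id]
        nonvocal = [m for m in ids if m not in vocal]
        idx = np.arange(lo, hi + 1)

        def _win(mid, what):
            tr = st[mid]
            pos0 = np.searchsorted(tr["frames"], idx)
            return tr[what][pos0]

        pv = [_win(m, "pos") for m in vocal]
        acc["vocal_dist"].append(np.linalg.norm(pv[0] - pv[1], axis=1))
        sv = [_win(m, "speed") for m in vocal]
        acc["vocal_speed"].append(np.mean(sv, axis=0))
        if len(nonvocal) >= 2:
            pn = [_win(m, "pos") for m in nonvocal[:2]]
            acc["nonvocal_dist"].append(np.linalg.norm(pn[0] - pn[1], axis=1))
            sn = [_win(m, "speed") for m in nonvocal[:2]]
            acc["nonvocal_speed"].append(np.mean(sn, axis=0))
    out = {"rel_time": rel, "n_skipped": skipped,
           "n_used": len(acc["vocal_dist"])}
    for k, v in acc.items():
        out[k] = np.mean(v, axis=0) if v else None
    return out


def relative_position_maps(sequences: list[VocalSequence], tracks: TrackTable,
                           offsets=(-25.0, 0.0, 25.0), center: str = "female",
                           roi_radius: float = 0.10, bin_m: float = 0.01,
                           extent_m: float = 0.35):
    """Partner positions in the centered mouse's body frame, per time offset.

    The centered mouse's body midpoint goes to the origin facing up (+y).
    Returns per offset a 2D histogram and the anterior proportion (fraction of
    counts with y > 0 inside the ROI circle).
    """
    fps = tracks.frame_rate
    st = _speed_table(tracks)
    edges = np.arange(-extent_m, extent_m + bin_m / 2, bin_m)
    results = {}
    for off in offsets:
        pts = []
        for seq in sequences:
            if not seq.edge_ok:
                continue
            f = int(round((seq.onset + off) * fps))
            me = seq.female_id if center == "female" else seq.male_id
            other = seq.male_id if center == "female" else seq.female_id
            trm, tro = st[me], st[other]
            im = np.searchsorted(trm["frames"], f)
            io = np.searchsorted(tro["frames"], f)
            if im >= trm["frames"].size or trm["frames"][im] != f:
                continue
            if io >= tro["frames"].size or tro["frames"][io] != f:
                continue
            d = tro["pos"][io] - trm["pos"][im]
            a = np.pi / 2 - trm["heading"][im]
            R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            pts.append(R @ d)
        pts = np.asarray(pts).reshape(-1, 2)
        H = np.histogram2d(pts[:, 0], pts[:, 1], bins=(edges, edges))[0]
        if pts.size:
            r = np.linalg.norm(pts, axis=1)
            roi = pts[r <= roi_radius]
            anterior = float((roi[:, 1] > 0).sum() / max(roi.shape[0], 1))
        else:
            anterior = np.nan
        results[off] = {"hist": H, "edges": edges, "anterior_proportion": anterior,
                        "n": pts.shape[0]}
    return results


def _overlap_fraction(male_track, female_track, f0, f1, fps,
                      corridor=CHASE_CORRIDOR_M, lag_s: float = 1.0) -> float:
    """Fraction of chase frames [f0, f1] where the male sits within
    ``corridor`` of the female's path 0-1 s earlier (full-track lookback, so
    short bouts still see the pre-bout path)."""
    lag = max(1, int(round(lag_s * fps)))
    mf, mp = male_track["frames"], male_track["pos"]
    ff, fp = female_track["frames"], female_track["pos"]
    hits = 0
    n = 0
    for f in range(f0, f1 + 1):
        i = np.searchsorted(mf, f)
        if i >= mf.size or mf[i] != f:
            continue
        jlo = np.searchsorted(ff, f - lag)
        jhi = np.searchsorted(ff, f, side="right")
        d = np.linalg.norm(fp[jlo:jhi] - mp[i], axis=1)
        if d.size and d.min() <= corridor:
            hits += 1
        n += 1
    return hits / max(n, 1)


def filter_chases(candidates: list, tracks: TrackTable,
                  overlap_frac: float = CHASE_OVERLAP_FRAC,
                  start_dist: float = CHASE_START_DIST_M,
                  merge_gap: float = CHASE_GAP_MERGE_S,
                  min_duration: float = CHASE_MIN_DURATION_S) -> list[Chase]:
    """Identify the chasing male and apply the chase heuristics.

    ``candidates`` are ``(start, stop, female_id)`` intervals (classifier
    output or simulator truth).  For each interval, each male must (1) overlap
    the female's earlier path on at least ``overlap_frac`` of chase frames and
    (2) start within ``start_dist`` of her; the best-overlapping qualifying
    male wins.  Same-participant chases separated by <= ``merge_gap`` are
    merged, and only merged chases longer than ``min_duration`` survive.
    """
    fps = tracks.frame_rate
    st = _speed_table(tracks)
    sexes = {}  # infer males = ids not appearing as chased female
    females = {c[2] for c in candidates}
    males = [m for m in tracks.mouse_ids if m not in females]
    picked: list[Chase] = []
    for (start, stop, fem) in candidates:
        f0, f1 = int(round(start * fps)), int(round(stop * fps))
        trf = st[fem]
        jf = np.searchsorted(trf["frames"], f0)
        if jf >= trf["frames"].size or trf["frames"][jf] != f0:
            continue
        best, best_ov = None, -1.0
        for m in males:
            trm = st[m]
            jm = np.searchsorted(trm["frames"], f0)
            if jm >= trm["frames"].size or trm["frames"][jm] != f0:
                continue
            if np.linalg.norm(trm["pos"][jm] - trf["pos"][jf]) > start_dist:
                continue
            ov = _overlap_fraction(trm, trf, f0, f1, fps)
            if ov >= overlap_frac and ov > best_ov:
                best, best_ov = m, ov
        if best is not None:
            picked.append(Chase(float(start), float(stop), best, fem))
    # merge same-participant chases separated by <= merge_gap
    picked.sort(key=lambda c: (str(c.male_id), str(c.female_id), c.start))
    merged: list[Chase] = []
    for c in picked:
        if (merged and merged[-1].male_id == c.male_id
                and merged[-1].female_id == c.female_id
                and c.start - merged[-1].stop <= merge_gap):
            merged[-1] = Chase(merged[-1].start, max(merged[-1].stop, c.stop),
                               c.male_id, c.female_id)
        else:
            merged.append(Chase(c.start, c.stop, c.male_id, c.female_id))
    out = [c for c in merged if c.duration > min_duration]
    out.sort(key=lambda c: c.start)
    return out


def associate_interactions(chases: list[Chase], sequences: list[VocalSequence],
                           window: float = WINDOW_S):
    """Assign each vocal sequence to (at most) one chase of the same pair.

    Priority: inside the chase interval; else within ``window`` after the end
    of the previous same-pair chase; else within ``window`` before the onset
    of the next same-pair chase; else unassigned.  Also reports per-chase
    inside/outside rates (outside over a 60 s window around onset minus the
    chase duration) and per-pair totals for the chase/interaction correlation.
    """
    assignments = []
    inside_n = {i: 0 for i in range(len(chases))}
    outside_n = {i: 0 for i in range(len(chases))}
    for seq in sequences:
        pair_chases = [(i, c) for i, c in enumerate(chases)
                       if c.male_id == seq.male_id and c.female_id == seq.female_id]
        rel, which = "unassigned", None
        for i, c in pair_chases:
            if c.start <= seq.onset <= c.stop:
                rel, which = "inside", i
                break
        if which is None:
            prev = [(i, c) for i, c in pair_chases if c.stop < seq.onset]
            if prev and seq.onset - prev[-1][1].stop <= window:
                rel, which = "after", prev[-1][0]
            else:
                nxt = [(i, c) for i, c in pair_chases if c.start > seq.onset]
                if nxt and nxt[0][1].start - seq.onset <= window:
                    rel, which = "before", nxt[0][0]
        if which is not None:
            (inside_n if rel == "inside" else outside_n)[which] += 1
        assignments.append({"onset": seq.onset, "male_id": seq.male_id,
                            "female_id": seq.female_id, "chase": which,
                            "relation": rel})
    rates = []
    for i, c in enumerate(chases):
        dur = c.duration
        rates.append({"chase": i, "inside_rate_hz": inside_n[i] / dur,
                      "outside_rate_hz": outside_n[i] / max(2 * window - dur, 1e-9)})
    totals = {}
    for seq in sequences:
        key = (seq.male_id, seq.female_id)
        totals.setdefault(key, {"n_sequences": 0, "n_chases": 0,
                                "chase_time_s": 0.0})
        totals[key]["n_sequences"] += 1
    for c in chases:
        key = (c.male_id, c.female_id)
        totals.setdefault(key, {"n_sequences": 0, "n_chases": 0,
                                "chase_time_s": 0.0})
        totals[key]["n_chases"] += 1
        totals[key]["chase_time_s"] += c.duration
    return {"assignments": assignments, "rates": rates, "pair_totals": totals}


def receptivity_speeds(chases: list[Chase], events: pd.DataFrame,
                       tracks: TrackTable,
                       window: float = SEQUENCE_WINDOW_S):
    """Female/male speeds at in-chase male calls, split by vocal interaction.

    A male vocalization inside a chase it participates in is a *vocal
    interaction* when an assigned vocalization from the chased female follows
    within 1 s; it is *male-only* when no vocalization of any kind (assigned
    or not) follows within 1 s.  Calls followed only by unassigned or
    other-animal vocalizations belong to neither class.  Returns per-class
    speed samples, medians, IQRs (75th-25th) and the rank-sum p-value for the
    female speed comparison (None when a class is empty).
    """
    fps = tracks.frame_rate
    st = _speed_table(tracks)
    ev = events.sort_values("time").reset_index(drop=True)
    times = ev["time"].to_numpy(float)
    samples = {"interaction": {"male": [], "female": []},
               "male_only": {"male": [], "female": []}}
    for _, r in ev.iterrows():
        if r.get("sex") != "M" or pd.isna(r.get("mouse_id")):
            continue
        t = r["time"]
        chase = next((c for c in chases
                      if c.start <= t <= c.stop and c.male_id == r["mouse_id"]),
                     None)
        if chase is None:
            continue
        later = ev[(times > t) & (times <= t + window)]
        if later.empty:
            cls = "male_only"
        else:
            fem_resp = later[(later["sex"] == "F")
                             & (later["mouse_id"] == chase.female_id)]
            cls = "interaction" if not fem_resp.empty else None
        if cls is None:
            continue
        f = int(round(t * fps))
        for role, mid in (("male", chase.male_id), ("female", chase.female_id)):
            tr = st[mid]
            i = np.searchsorted(tr["frames"], f)
            if i < tr["frames"].size and tr["frames"][i] == f:
                samples[cls][role].append(float(tr["speed"][i]))
    out = {"samples": samples}
    fi = samples["interaction"]["female"]
    fo = samples["male_only"]["female"]
    for cls in samples:
        for role in samples[cls]:
            v = np.asarray(samples[cls][role])
            key = f"{cls}_{role}"
            if v.size:
                out[key + "_median"] = float(np.median(v))
                out[key + "_iqr"] = float(np.percentile(v, 75) - np.percentile(v, 25))
    if fi and fo:
        out["female_p"] = float(mannwhitneyu(fi, fo, alternative="two-sided").pvalue)
    else:
        out["female_p"] = None
        out["skipped"] = "one of the comparison classes is empty"
    return out


# ---------------------------------------------------------------------------
# analytic bookkeeping used in the misassignment control

def expected_misassigned_count(n_vocalizations: int, error_rate: float) -> float:
    """Expected count of misassigned calls given an assignment error rate.

    With 3486 calls inside chase-associated vocal interactions and the 7%
    close-proximity error rate, this evaluates to ~244.
    """
    return n_vocalizations * error_rate


def observed_to_expected_ratio(n_observed: int, expected: float) -> float:
    return n_observed / expected


def in_chase_fraction(n_inside: int, n_total: int) -> float:
    """Fraction (%) of chase-associated vocal interactions inside a chase."""
    return 100.0 * n_inside / n_total
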