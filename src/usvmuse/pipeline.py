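"""End-to-end processing: audio -> segments -> snippets -> estimates -> callers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assignment as asg
from . import localization as loc
from . import segmentation as seg
from . import snippets as snip
from .config_io import ArenaFloor, ArrayGeometry, SyncModel, TrackTable

__all__ = ["process_recording", "assignments_to_frame"]


def process_recording(samples: np.ndarray, geom: ArrayGeometry,
                      arena: ArenaFloor, tracks: TrackTable | None = None,
                      sync: SyncModel | None = None, alpha: float = 0.05,
                      min_pixels: int = 1500, levels=loc.DEFAULT_LEVELS,
                      t_offset: float = 0.0, random_state: int = 0,
                      virtual_positions: dict | None = None) -> list[dict]:
    """Run the full chain on one (possibly windowed) multichannel recording.

    ``t_offset`` shifts reported times when ``samples`` is a window cut out of
    a longer record.  Mouse positions for assignment come from ``tracks`` via
    ``sync`` (frame containing the signal midpoint) or, for controlled
    validation runs, from ``virtual_positions`` (mouse_id -> (2,) position).

    Returns one record per extracted vocal signal with its bounding box,
    snippet count, consensus estimate, per-mouse densities/MPIs and the
    assignment decision.
    """
    fs = geom.sample_rate
    segments, image = seg.segment_audio(samples, fs, alpha=alpha,
                                        min_pixels=min_pixels)
    segments = snip.contours_and_merge(segments, image)
    max_lag = loc.max_delay_samples(arena, geom)
    results = []
    for s in segments:
        snips = snip.tile_snippets(s, s.contours, samples, fs, image)
        rec = {"seg_id": s.seg_id, "t_start": s.t_start + t_offset,
               "t_stop": s.t_stop + t_offset, "f_lo": s.f_lo, "f_hi": s.f_hi,
               "n_snippets": len(snips), "localized": False,
               "assigned_mouse": asg.UNASSIGNED, "reason": "too-few-snippets"}
        if snip.snippet_count_gate(snips):
            ests, peaks, _ = loc.localize_snippets(snips, geom, arena,
                                                   levels=levels,
                                                   max_lag=max_lag)
            if ests.shape[0] >= 3:
                rec["localized"] = True
                rec["estimates"] = ests
                t_mid = rec["t_start"] + (rec["t_stop"] - rec["t_start"]) / 2
                positions = virtual_positions
                if positions is None and tracks is not None and sync is not None:
                    frame = sync.frame_of(t_mid)
                    positions = tracks.nose_positions_at(frame)
                if positions:
                    cons, res = asg.assign_signal(ests, positions,
                                                  random_state=random_state)
                    rec.update({
                        "consensus_mean": cons.mean if cons.valid else None,
                        "consensus_cov": cons.covariance if cons.valid else None,
                        "n_inliers": cons.n_inliers,
                        "assigned_mouse": res.assigned_mouse,
                        "reason": res.reason,
                        "mpi": dict(zip(res.mouse_ids, res.mpi)),
                        "densities": dict(zip(res.mouse_ids, res.densities)),
                    })
                else:
                    rec["reason"] = "no-positions"
        results.append(rec)
    return results


def assignments_to_frame(results: list[dict]) -> pd.DataFrame:
    rows = []
    for r in results:
        mean = r.get("consensus_mean")
        cov = r.get("consensus_cov")
        row = {"seg_id": r["seg_id"],
               "t_mid": r["t_start"] + (r["t_stop"] - r["t_start"]) / 2,
               "x_mean": mean[0] if mean is not None else np.nan,
               "y_mean": mean[1] if mean is not None else np.nan,
               "cov_xx": cov[0, 0] if cov is not None else np.nan,
               "cov_xy": cov[0, 1] if cov is not None else np.nan,
               "cov_yy": cov[1, 1] if cov is not None else np.nan,
               "n_inliers": r.get("n_inliers", 0),
               "mouse_id": r["assigned_mouse"], "reason": r["reason"]}
        for mid, v in (r.get("mpi") or {}).items():
            row[f"MPI_{mid}"] = v
        for mid, v in (r.get("densities") or {}).items():
            row[f"D_{mid}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
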