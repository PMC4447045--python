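"""Cutting vocal segments into 5 ms x 2 kHz localization snippets.

A snippet is the atomic unit of localization: a 5 ms slice of all channels,
band-passed to a 2 kHz band centered on the segment's frequency contour in
that time bin.  Only snippets whose time-frequency tile holds at least 11 hot
pixels are localized, and only signals with at least three retained snippets
are localizable at all.

The contour estimator is the per-bin median of hot-pixel frequencies: robust
to spectrogram speckle, and guaranteed to stay inside the support of the hot
pixels.  Harmonic-merged segments carry one contour per harmonic branch and
are tiled branch by branch, so a single time bin can yield several snippets
at different center frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import HotPixelImage, VocalSegment, merge_harmonics

__all__ = [
    "Snippet",
    "frequency_contour",
    "tile_snippets",
    "snippet_count_gate",
    "contours_and_merge",
    "save_snippets",
    "load_snippets",
]

SNIPPET_DURATION_S = 0.005
SNIPPET_BANDWIDTH_HZ = 2000.0
MIN_HOT_PIXELS = 11
MIN_SNIPPETS = 3
ROLLOFF_HZ = 200.0


@dataclass
class Snippet:
    seg_id: int
    snippet_id: int
    t_start: float
    f_center: float
    hot_pixel_count: int
    waveforms: np.ndarray  # (n_samples, K), band-passed, zero-phase
    duration: float = SNIPPET_DURATION_S
    bandwidth: float = SNIPPET_BANDWIDTH_HZ


def frequency_contour(segment: VocalSegment, image: HotPixelImage,
                      bin_s: float = SNIPPET_DURATION_S):
    """Median hot-pixel frequency of the segment in each 5 ms bin.

    Returns ``(bin_starts, freqs)``; bins with no hot pixels are dropped.
    Raises if no bin has any hot pixel.
    """
    ti, fi = segment.pixels[:, 0], segment.pixels[:, 1]
    t = image.time_centers[ti]
    f = image.freqs[fi]
    n_bins = int(np.floor((segment.t_stop - segment.t_start) / bin_s))
    n_bins = max(n_bins, 1)
    starts, vals = [], []
    for b in range(n_bins):
        lo = segment.t_start + b * bin_s
        sel = (t >= lo) & (t < lo + bin_s)
        if not sel.any():
            continue
        starts.append(lo)
        vals.append(float(np.median(f[sel])))
    if not starts:
        raise ValueError(f"segment {segment.seg_id} has no hot pixels in any 5 ms bin")
    return np.asarray(starts), np.asarray(vals)


def _bandpass_zero_phase(x: np.ndarray, fs: float, f_lo: float, f_hi: float,
                         rolloff: float = ROLLOFF_HZ) -> np.ndarray:
    """Frequency-domain band-pass with a smooth cosine roll-off, zero phase.

    A real-valued amplitude mask on the rFFT keeps phase exactly linear
    (zero), which localization requires: inter-channel delays must survive
    filtering untouched.
    """
    n = x.shape[0]
    X = np.fft.rfft(x, axis=0)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = np.zeros_like(f)
    core = (f >= f_lo) & (f <= f_hi)
    mask[core] = 1.0
    if rolloff > 0:
        lo_edge = (f >= f_lo - rolloff) & (f < f_lo)
        mask[lo_edge] = 0.5 * (1 + np.cos(np.pi * (f_lo - f[lo_edge]) / rolloff))
        hi_edge = (f > f_hi) & (f <= f_hi + rolloff)
        mask[hi_edge] = 0.5 * (1 + np.cos(np.pi * (f[hi_edge] - f_hi) / rolloff))
    shape = (f.size,) + (1,) * (x.ndim - 1)
    return np.fft.irfft(X * mask.reshape(shape), n=n, axis=0)


def tile_snippets(segment: VocalSegment, contour, audio: np.ndarray,
                  sample_rate: float, image: HotPixelImage,
                  min_hot_pixels: int = MIN_HOT_PIXELS) -> list[Snippet]:
    """One candidate snippet per 5 ms contour bin; keep those with >= 11 hot pixels.

    ``contour`` is ``(bin_starts, freqs)`` from :func:`frequency_contour`, or a
    list of such tuples for harmonic-merged segments (one per branch).
    Segments shorter than 5 ms yield no snippets.
    """
    if segment.duration < SNIPPET_DURATION_S:
        return []
    audio = np.atleast_2d(np.asarray(audio, dtype=float))
    if audio.ndim == 1:
        audio = audio[:, None]
    n_snip = int(round(SNIPPET_DURATION_S * sample_rate))
    branches = contour if isinstance(contour, list) else [contour]
    ti_all, fi_all = segment.pixels[:, 0], segment.pixels[:, 1]
    pix_t = image.time_centers[ti_all]
    pix_f = image.freqs[fi_all]
    half_bw = SNIPPET_BANDWIDTH_HZ / 2.0
    out: list[Snippet] = []
    sid = 0
    for starts, freqs in branches:
        for t0, fc in zip(starts, freqs):
            i0 = int(round(t0 * sample_rate))
            if i0 < 0 or i0 + n_snip > audio.shape[0]:
                continue
            in_tile = ((pix_t >= t0) & (pix_t < t0 + SNIPPET_DURATION_S)
                       & (pix_f >= fc - half_bw) & (pix_f <= fc + half_bw))
            n_hot = int(in_tile.sum())
            if n_hot < min_hot_pixels:
                continue
            wav = _bandpass_zero_phase(audio[i0:i0 + n_snip], sample_rate,
                                       fc - half_bw, fc + half_bw)
            out.append(Snippet(segment.seg_id, sid, t0, float(fc), n_hot, wav))
            sid += 1
    out.sort(key=lambda s: (s.t_start, s.f_center))
    for i, s in enumerate(out):
        s.snippet_id = i
    return out


def snippet_count_gate(snips: list[Snippet]) -> bool:
    """A signal is localizable iff it retained at least three snippets."""
    return len(snips) >= MIN_SNIPPETS


def contours_and_merge(segments: list[VocalSegment], image: HotPixelImage):
    """Attach frequency contours and merge harmonic stacks.

    Returns the merged segment list; every returned segment has
    ``segment.contours`` set to its list of branch contours.
    """
    contours = {}
    for s in segments:
        try:
            contours[s.seg_id] = frequency_contour(s, image)
        except ValueError:
            continue
    merged = merge_harmonics(segments, contours)
    for s in merged:
        if not s.contours:
            s.contours = [frequency_contour(s, image)]
    return merged


def save_snippets(path: str, snippets_by_seg: dict) -> None:
    """Persist snippets to HDF5 as /seg_<id>/snippet_<j>/{waveforms, meta}."""
    import h5py

    with h5py.File(path, "w") as h5:
        for seg_id, snips in snippets_by_seg.items():
            g = h5.create_group(f"seg_{seg_id}")
            for s in snips:
                gg = g.create_group(f"snippet_{s.snippet_id}")
                gg.create_dataset("waveforms", data=s.waveforms)
                gg.attrs.update({"t_start": s.t_start, "f_center": s.f_center,
                                 "hot_pixel_count": s.hot_pixel_count,
                                 "duration": s.duration, "bandwidth": s.bandwidth})


def load_snippets(path: str) -> dict:
    import h5py

    out: dict[int, list[Snippet]] = {}
    with h5py.File(path, "r") as h5:
        for seg_name in h5:
            seg_id = int(seg_name.split("_")[1])
            snips = []
            for snip_name in h5[seg_name]:
                gg = h5[seg_name][snip_name]
                snips.append(Snippet(seg_id, int(snip_name.split("_")[1]),
                                     float(gg.attrs["t_start"]),
                                     float(gg.attrs["f_center"]),
                                     int(gg.attrs["hot_pixel_count"]),
                                     gg["waveforms"][()],
                                     float(gg.attrs["duration"]),
                                     float(gg.attrs["bandwidth"])))
            snips.sort(key=lambda s: s.snippet_id)
            out[seg_id] = snips
    return out
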