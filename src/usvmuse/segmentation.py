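"""Vocal-signal extraction from multichannel ultrasonic audio.

Each channel is analyzed with multitaper (DPSS) short-time spectra at three
window lengths.  At every time-frequency point, Thomson's harmonic F-test asks
whether a sinusoidal line component stands significantly above the locally
estimated noise; significant points ("hot pixels") from all scales and
channels are combined on a single grid whose time resolution is that of the
shortest window and whose frequency resolution is that of the longest.  The
binary image is gap-filled by dilation with a small box, 8-connected regions
above a minimum hot-pixel count become vocal segments, and time-overlapping
segments whose frequency contours sit at a factor of two or three of each
other are merged as harmonics of one signal.

The F statistic at frequency f with K tapers is

    F(f) = (K - 1) |mu(f)|^2 sum_k U_k(0)^2 / sum_k |Y_k(f) - mu(f) U_k(0)|^2

with Y_k the k-th eigencoefficient, U_k(0) the DC value of taper k, and
mu(f) the regression estimate of the line amplitude; under the noise null
F ~ F(2, 2K-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal.windows import dpss
from scipy.stats import f as f_dist

__all__ = [
    "ScaleParams",
    "HotPixelImage",
    "VocalSegment",
    "DEFAULT_SCALES",
    "multitaper_hot_pixels",
    "combine_scales",
    "extract_segments",
    "merge_harmonics",
    "segment_audio",
]

MIN_FREQ_HZ = 30_000.0  # everything below is treated as non-vocal


@dataclass(frozen=True)
class ScaleParams:
    """One multitaper analysis scale.

    n_tapers=43 with time_bandwidth NW=22 keeps K < 2*NW, the usual bound for
    well-concentrated DPSS tapers.
    """

    nfft: int
    n_tapers: int = 43
    time_bandwidth: float = 22.0
    overlap: float = 0.75

    def __post_init__(self):
        if self.n_tapers >= 2 * self.time_bandwidth:
            raise ValueError("need n_tapers < 2*NW")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.nfft * (1.0 - self.overlap))))


DEFAULT_SCALES = (ScaleParams(128), ScaleParams(256), ScaleParams(512))


@dataclass
class HotPixelImage:
    """Binary significance image on the common time-frequency grid.

    ``mask[t, f]`` is True where any channel/scale was significant;
    ``p_min[t, f]`` keeps the smallest per-pixel p-value seen.
    """

    mask: np.ndarray
    p_min: np.ndarray
    time_centers: np.ndarray  # s, center of each time bin
    freqs: np.ndarray  # Hz, center of each frequency bin
    dt_bin: float  # s, time-bin pitch (hop of the shortest window)
    df_bin: float  # Hz, frequency-bin pitch (of the longest window)
    sample_rate: float

    @property
    def shape(self):
        return self.mask.shape


@dataclass
class VocalSegment:
    """Time-frequency bounding box of one extracted vocal signal."""

    seg_id: int
    t_start: float
    t_stop: float
    f_lo: float
    f_hi: float
    pixels: np.ndarray  # (n, 2) int array of (time_idx, freq_idx) hot pixels
    n_hot_pixels: int
    merged_harmonics: bool = False
    contours: list = field(default_factory=list)  # filled by the snippets stage

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start


def _eigencoefficients_fstat(x: np.ndarray, scale: ScaleParams):
    """Harmonic F statistic per (window, rfft bin) for one waveform."""
    nfft, hop = scale.nfft, scale.hop
    n = x.shape[0]
    if n < nfft:
        raise ValueError(f"record length {n} shorter than nfft {nfft}")
    tapers = dpss(nfft, scale.time_bandwidth, Kmax=scale.n_tapers)  # (K, nfft)
    u0 = tapers.sum(axis=1)  # U_k(0); ~0 for odd (antisymmetric) tapers
    windows = np.lib.stride_tricks.sliding_window_view(x, nfft)[::hop]  # (W, nfft)
    sum_u0sq = float(np.dot(u0, u0))
    # accumulate A = sum_k Y_k * U_k(0) and P = sum_k |Y_k|^2 taper by taper
    # to keep memory at one (W, nfft/2+1) complex array
    A = np.zeros((windows.shape[0], nfft // 2 + 1), dtype=complex)
    P = np.zeros_like(A, dtype=float)
    for k in range(scale.n_tapers):
        Y = np.fft.rfft(windows * tapers[k], n=nfft, axis=1)
        if abs(u0[k]) > 1e-12 * np.abs(u0).max():
            A += Y * u0[k]
        P += np.abs(Y) ** 2
    K = scale.n_tapers
    num = (K - 1) * np.abs(A) ** 2 / sum_u0sq
    resid = P - np.abs(A) ** 2 / sum_u0sq
    resid = np.maximum(resid, np.finfo(float).tiny)
    return num / resid


def multitaper_hot_pixels(waveform: np.ndarray, sample_rate: float,
                          scale: ScaleParams, alpha: float = 0.05):
    """Per-scale significance mask for one channel.

    Returns ``(mask, pvals, time_centers, freqs)`` where ``mask`` is True where
    the harmonic F statistic exceeds the ``F(2, 2K-2)`` quantile at ``1-alpha``
    and the frequency is at or above 30 kHz.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    F = _eigencoefficients_fstat(np.asarray(waveform, dtype=float), scale)
    dof2 = 2 * scale.n_tapers - 2
    thresh = f_dist.ppf(1.0 - alpha, 2, dof2)
    mask = F > thresh
    pvals = f_dist.sf(F, 2, dof2)
    freqs = np.fft.rfftfreq(scale.nfft, d=1.0 / sample_rate)
    low = freqs < MIN_FREQ_HZ
    mask[:, low] = False
    pvals[:, low] = 1.0
    n_win = F.shape[0]
    time_centers = (np.arange(n_win) * scale.hop + scale.nfft / 2) / sample_rate
    return mask, pvals, time_centers, freqs


def combine_scales(per_channel: list, sample_rate: float,
                   n_samples: int, scales=DEFAULT_SCALES) -> HotPixelImage:
    """Combine per-scale, per-channel masks onto the common grid.

    ``per_channel`` is a list over channels, each entry a list of
    ``(mask, pvals, time_centers, freqs)`` tuples (one per scale) as returned
    by :func:`multitaper_hot_pixels`.  Scales are combined by union (a signal
    may only be resolvable at one window length); channels by intersection —
    a vocalization in this small arena is loud on every microphone, while
    noise exceedances are independent across channels, so requiring
    significance on all K channels drives the noise pixel density from alpha
    to ~alpha^K without losing real signal.  The common grid uses the time
    pitch of the shortest window and the frequency pitch of the longest.
    """
    if not per_channel or not per_channel[0]:
        raise ValueError("no masks to combine")
    sc_min = min(scales, key=lambda s: s.nfft)
    nfft_min, hop_min = sc_min.nfft, sc_min.hop
    nfft_max = max(s.nfft for s in scales)
    n_t = (n_samples - nfft_min) // hop_min + 1
    if n_t < 1:
        raise ValueError("record shorter than the shortest analysis window")
    t_centers = (np.arange(n_t) * hop_min + nfft_min / 2) / sample_rate
    freqs = np.fft.rfftfreq(nfft_max, d=1.0 / sample_rate)
    combined = np.ones((n_t, freqs.size), dtype=bool)
    p_min = np.ones_like(combined, dtype=float)
    for chan_scales in per_channel:
        chan = np.zeros_like(combined)
        for mask, pvals, tc, fc in chan_scales:
            if tc[-1] < t_centers[0] - 1e-9 or tc[0] > t_centers[-1] + 1e-9:
                raise ValueError("per-scale mask does not cover the common time span")
            # nearest source window center / frequency bin for each common pixel
            ti = np.clip(np.round(np.interp(t_centers, tc, np.arange(tc.size))), 0,
                         tc.size - 1).astype(int)
            fi = np.clip(np.round(np.interp(freqs, fc, np.arange(fc.size))), 0,
                         fc.size - 1).astype(int)
            chan |= mask[np.ix_(ti, fi)]
            p_min = np.minimum(p_min, pvals[np.ix_(ti, fi)])
        combined &= chan
    combined[:, freqs < MIN_FREQ_HZ] = False
    return HotPixelImage(combined, p_min, t_centers, freqs,
                         dt_bin=hop_min / sample_rate,
                         df_bin=sample_rate / nfft_max,
                         sample_rate=sample_rate)


def extract_segments(image: HotPixelImage, box: tuple[int, int] = (15, 7),
                     min_pixels: int = 1500) -> list[VocalSegment]:
    """Close gaps with a time-x-frequency box, then keep big connected regions.

    The box convolution (thresholded at any positive response, i.e. a binary
    dilation) only repairs connectivity: a surviving component must contain
    strictly more than ``min_pixels`` ORIGINAL hot pixels, and its bounding
    box is that of the original hot pixels.
    """
    mask = image.mask
    if mask.size == 0:
        return []
    closed = ndimage.binary_dilation(mask, structure=np.ones(box, dtype=bool))
    labels, n_lab = ndimage.label(closed, structure=np.ones((3, 3), dtype=int))
    segments: list[VocalSegment] = []
    seg_id = 0
    for lab in range(1, n_lab + 1):
        comp = labels == lab
        hot = comp & mask
        count = int(hot.sum())
        if count <= min_pixels:
            continue
        ti, fi = np.nonzero(hot)
        t0 = image.time_centers[ti.min()] - image.dt_bin / 2
        t1 = image.time_centers[ti.max()] + image.dt_bin / 2
        f0 = image.freqs[fi.min()] - image.df_bin / 2
        f1 = image.freqs[fi.max()] + image.df_bin / 2
        segments.append(VocalSegment(seg_id, t0, t1, max(f0, MIN_FREQ_HZ), f1,
                                     np.column_stack([ti, fi]), count))
        seg_id += 1
    segments.sort(key=lambda s: s.t_start)
    for i, s in enumerate(segments):
        s.seg_id = i
    return segments


def _harmonic_ratio_ok(f1: np.ndarray, f2: np.ndarray, tol: float = 0.10) -> np.ndarray:
    hi = np.maximum(f1, f2)
    lo = np.minimum(f1, f2)
    r = hi / lo
    return (np.abs(r / 2.0 - 1.0) <= tol) | (np.abs(r / 3.0 - 1.0) <= tol)


def merge_harmonics(segments: list[VocalSegment], contours: dict,
                    overlap_frac: float = 0.90, bin_frac: float = 0.90,
                    ratio_tol: float = 0.10) -> list[VocalSegment]:
    """Merge time-overlapping segments that are harmonics of one signal.

    ``contours`` maps seg_id -> (bin_times, freqs) on the 5 ms contour grid.
    Two segments merge when their time overlap exceeds ``overlap_frac`` of the
    shorter one AND at least ``bin_frac`` of the overlapped contour bins have a
    frequency ratio within ``ratio_tol`` of a factor of two or three.  Merging
    is transitive (union-find).
    """
    n = len(segments)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in range(n):
        for b in range(a + 1, n):
            sa, sb = segments[a], segments[b]
            ov = min(sa.t_stop, sb.t_stop) - max(sa.t_start, sb.t_start)
            if ov <= overlap_frac * min(sa.duration, sb.duration):
                continue
            ca = contours.get(sa.seg_id)
            cb = contours.get(sb.seg_id)
            if ca is None or cb is None:
                continue
            ta, fa = ca
            tb, fb = cb
            lo = max(sa.t_start, sb.t_start)
            hi = min(sa.t_stop, sb.t_stop)
            ia = (ta >= lo - 1e-9) & (ta <= hi + 1e-9)
            if not ia.any():
                continue
            # pair each overlapped bin of a with the nearest bin of b
            fb_on_a = np.interp(ta[ia], tb, fb)
            ok = _harmonic_ratio_ok(fa[ia], fb_on_a, ratio_tol)
            if ok.mean() >= bin_frac:
                parent[find(a)] = find(b)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged: list[VocalSegment] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(segments[members[0]])
            continue
        segs = [segments[i] for i in members]
        pixels = np.vstack([s.pixels for s in segs])
        new = VocalSegment(
            seg_id=min(s.seg_id for s in segs),
            t_start=min(s.t_start for s in segs),
            t_stop=max(s.t_stop for s in segs),
            f_lo=min(s.f_lo for s in segs),
            f_hi=max(s.f_hi for s in segs),
            pixels=pixels,
            n_hot_pixels=int(sum(s.n_hot_pixels for s in segs)),
            merged_harmonics=True,
            contours=[contours[s.seg_id] for s in segs if s.seg_id in contours],
        )
        merged.append(new)
    merged.sort(key=lambda s: s.t_start)
    for i, s in enumerate(merged):
        s.seg_id = i
    return merged


def segment_audio(samples: np.ndarray, sample_rate: float, alpha: float = 0.05,
                  scales=DEFAULT_SCALES, box=(15, 7), min_pixels: int = 1500):
    """Full segmentation of an (N, K) multichannel recording.

    Returns ``(segments, image)``.  Harmonic merging needs frequency contours
    and is applied by the snippets stage (see
    :func:`usvmuse.snippets.contours_and_merge`).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    per_channel = []
    for ch in range(samples.shape[1]):
        per_channel.append([multitaper_hot_pixels(samples[:, ch], sample_rate, sc, alpha)
                            for sc in scales])
    image = combine_scales(per_channel, sample_rate, samples.shape[0], scales)
    return extract_segments(image, box=box, min_pixels=min_pixels), image


def segments_to_frame(segments: list[VocalSegment]):
    """Segments as a results table (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [{"seg_id": s.seg_id, "t_start": s.t_start, "t_stop": s.t_stop,
          "f_lo": s.f_lo, "f_hi": s.f_hi, "n_hot_pixels": s.n_hot_pixels,
          "merged_harmonics": s.merged_harmonics} for s in segments]
    )
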