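"""Ground-truth acoustic and behavioral simulator.

Generates everything the pipeline consumes — FM ultrasonic source waveforms,
four-channel array recordings with propagation delays and noise, virtual-mouse
layouts, smooth mouse trajectories with scripted chases, and coupled
male/female vocal event trains — with every event's emitter, time and position
known exactly.  Output is written in the very formats :mod:`usvmuse.config_io`
reads, so simulated sessions are indistinguishable from field data.

Physics: channel k receives the source delayed by tau_k = d_k / c (exact
band-limited fractional-sample delay via an FFT phase ramp) and attenuated by
1/d_k, plus white Gaussian noise whose level sets the stated SNR at the
nearest microphone.  Echoes and directional microphone response are out of
scope (the real arena is anechoic-foam lined).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .config_io import ArenaFloor, ArrayGeometry, TrackTable

__all__ = [
    "UsvModel",
    "ScenarioConfig",
    "default_geometry",
    "default_arena",
    "synth_usv",
    "synth_click",
    "propagate",
    "place_virtual_mice",
    "ou_trajectory",
    "synth_session",
    "SessionData",
]


def default_geometry(sample_rate: float = 450450.0,
                     speed_of_sound: float = 343.0) -> ArrayGeometry:
    """Four microphones above the corners of the 66 cm square arena."""
    z = 0.66
    mics = np.array([[0.0, 0.0, z], [0.66, 0.0, z],
                     [0.66, 0.66, z], [0.0, 0.66, z]])
    return ArrayGeometry(mics, speed_of_sound=speed_of_sound,
                         sample_rate=sample_rate)


def default_arena() -> ArenaFloor:
    return ArenaFloor(np.array([[0.0, 0.0], [0.66, 0.0],
                                [0.66, 0.66], [0.0, 0.66]]))


@dataclass
class UsvModel:
    """A frequency-modulated ultrasonic call.

    ``contour_hz`` holds piecewise-linear breakpoints of instantaneous
    frequency over normalized time; mouse USVs live in the 30-130 kHz band and
    last a few to ~200 ms.  ``fm_depth_hz``/``fm_rate_hz`` superimpose an
    optional sinusoidal modulation.  ``harmonic_weights[h]`` scales the
    (h+1)-th harmonic of the fundamental.
    """

    duration: float = 0.05
    contour_hz: tuple = (70_000.0, 80_000.0)
    harmonic_weights: tuple = (1.0,)
    fm_depth_hz: float = 0.0
    fm_rate_hz: float = 0.0
    envelope_frac: float = 0.25  # Tukey taper fraction

    def __post_init__(self):
        if not 0.003 <= self.duration <= 0.200:
            raise ValueError("USV duration must be within [3, 200] ms")
        c = np.asarray(self.contour_hz, float)
        if np.any(c < 30_000.0) or np.any(c + self.fm_depth_hz > 130_000.0):
            raise ValueError("contour must stay within [30, 130] kHz")


def synth_usv(model: UsvModel, sample_rate: float) -> np.ndarray:
    """Phase-continuous FM synthesis of one call at the source."""
    n = int(round(model.duration * sample_rate))
    if n < 1:
        raise ValueError("zero-duration call")
    t = np.arange(n) / sample_rate
    bp = np.asarray(model.contour_hz, float)
    f_inst = np.interp(t / model.duration, np.linspace(0, 1, bp.size), bp)
    if model.fm_depth_hz > 0:
        f_inst = f_inst + model.fm_depth_hz * np.sin(2 * np.pi * model.fm_rate_hz * t)
    top = max(model.harmonic_weights and len(model.harmonic_weights) or 1, 1)
    if f_inst.max() * top >= sample_rate / 2:
        raise ValueError("contour (with harmonics) exceeds Nyquist")
    phase = 2 * np.pi * np.cumsum(f_inst) / sample_rate
    x = np.zeros(n)
    for h, w in enumerate(model.harmonic_weights, start=1):
        x += w * np.sin(h * phase)
    from scipy.signal.windows import tukey

    return x * tukey(n, model.envelope_frac)


def synth_click(sample_rate: float, duration: float = 0.005,
                band=(30_000.0, 130_000.0), seed: int = 0) -> np.ndarray:
    """Band-limited noise click: a broadband transient for localization tests."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    x = rng.standard_normal(n)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    X[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(X, n=n)
    from scipy.signal.windows import tukey

    return x * tukey(n, 0.1)


def propagate(source: np.ndarray, position, geom: ArrayGeometry,
              snr_db: float | None = None, seed: int | None = 0,
              n_out: int | None = None) -> np.ndarray:
    """Render a source waveform at ``position`` (3D, meters) onto all mics.

    Each channel is the source delayed by tau_k (exact fractional-sample FFT
    delay), scaled by 1/d_k, plus white Gaussian noise at ``snr_db`` relative
    to the RMS at the *nearest* microphone (``snr_db=None`` -> noiseless).
    """
    pos = np.asarray(position, dtype=float)
    d = np.linalg.norm(geom.mic_positions - pos[None, :], axis=1)
    if np.any(d <= 1e-9):
        raise ValueError("source position coincides with a microphone")
    tau = d / geom.speed_of_sound
    src = np.asarray(source, dtype=float)
    pad = int(np.ceil(tau.max() * geom.sample_rate)) + 8
    if n_out is None:
        n_out = src.size + pad
    if n_out < src.size + pad:
        raise ValueError("n_out too short to hold the delayed signal")
    buf = np.zeros(n_out)
    buf[: src.size] = src
    F = np.fft.rfft(buf)
    f = np.fft.rfftfreq(n_out, d=1.0 / geom.sample_rate)
    out = np.empty((n_out, geom.n_mics))
    for k in range(geom.n_mics):
        shifted = np.fft.irfft(F * np.exp(-2j * np.pi * f * tau[k]), n=n_out)
        out[:, k] = shifted / d[k]
    if snr_db is not None:
        if not np.isfinite(snr_db):
            raise ValueError("snr_db must be finite (use None for noiseless)")
        k0 = int(np.argmin(d))
        rms = np.sqrt(np.mean((src / d[k0]) ** 2))
        sigma = rms / 10 ** (snr_db / 20.0)
        rng = np.random.default_rng(seed)
        out += rng.normal(0.0, sigma, size=out.shape)
    return out


def _uniform_in_polygon(arena: ArenaFloor, rng, n: int) -> np.ndarray:
    xmin, ymin, xmax, ymax = arena.bounds()
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform([xmin, ymin], [xmax, ymax], size=(max(4 * (n - got), 16), 2))
        inside = arena.contains(cand)
        take = cand[inside][: n - got]
        pts[got:got + take.shape[0]] = take
        got += take.shape[0]
    return pts


def place_virtual_mice(mode: str, arena: ArenaFloor, seed: int, n: int = 3,
                       true_source=None, radius: float = 0.10,
                       empirical_samples=None, real_position=None,
                       real_heading: float = 0.0) -> np.ndarray:
    """Virtual-mouse layouts for misassignment controls.

    ``uniform``: i.i.d. uniform over the floor polygon.
    ``proximity``: within ``radius`` (default 10 cm) of ``true_source``,
    uniform in direction, distance uniform on (0, radius].
    ``empirical``: bootstrap (distance, orientation) pairs from
    ``empirical_samples`` applied relative to ``real_position``/``real_heading``.
    """
    if arena.area <= 0:
        raise ValueError("empty arena polygon")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        return _uniform_in_polygon(arena, rng, n)
    if mode == "proximity":
        src = np.asarray(true_source, dtype=float)
        out = np.empty((n, 2))
        for j in range(n):
            for _ in range(10_000):
                theta = rng.uniform(0, 2 * np.pi)
                dist = rng.uniform(0, radius)
                p = src + dist * np.array([np.cos(theta), np.sin(theta)])
                if arena.contains(p[None, :])[0]:
                    out[j] = p
                    break
            else:  # fall back: clip to the nearest in-polygon point
                from shapely.ops import nearest_points

                q = nearest_points(arena.as_shapely(), Point(p))[0]
                out[j] = [q.x, q.y]
        return out
    if mode == "empirical":
        samples = np.atleast_2d(np.asarray(empirical_samples, dtype=float))
        idx = rng.integers(0, samples.shape[0], size=n)
        d, theta = samples[idx, 0], samples[idx, 1]
        base = np.asarray(real_position, dtype=float)
        ang = real_heading + theta
        return base[None, :] + np.column_stack([d * np.cos(ang), d * np.sin(ang)])
    raise ValueError(f"unknown placement mode {mode!r}")


def ou_trajectory(n_frames: int, frame_rate: float, arena: ArenaFloor, rng,
                  speed_relax_s: float = 1.0, speed_sigma: float = 0.12,
                  start=None) -> np.ndarray:
    """Ornstein-Uhlenbeck velocity walk with wall reflection; (n_frames, 2) m.

    Defaults give realistic adult-mouse speeds (mostly 0-40 cm/s).
    """
    xmin, ymin, xmax, ymax = arena.bounds()
    margin = 0.02
    dt = 1.0 / frame_rate
    x = np.empty((n_frames, 2))
    x[0] = (_uniform_in_polygon(arena, rng, 1)[0] if start is None
            else np.asarray(start, float))
    v = rng.normal(0, speed_sigma, 2)
    theta = 1.0 / speed_relax_s
    for i in range(1, n_frames):
        v = v - theta * v * dt + speed_sigma * np.sqrt(2 * theta * dt) * rng.standard_normal(2)
        nxt = x[i - 1] + v * dt
        for ax, (lo, hi) in enumerate([(xmin + margin, xmax - margin),
                                       (ymin + margin, ymax - margin)]):
            if nxt[ax] < lo:
                nxt[ax] = 2 * lo - nxt[ax]
                v[ax] = -v[ax]
            elif nxt[ax] > hi:
                nxt[ax] = 2 * hi - nxt[ax]
                v[ax] = -v[ax]
        x[i] = nxt
    return x


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic session.

    Defaults mirror the recorded experiments: a 66 cm square arena, four
    overhead microphones, 450450 Hz audio, 29 Hz video, two males + two
    females, male call rate ~0.25 Hz with females answering within 1 s.
    """

    geometry: ArrayGeometry = field(default_factory=default_geometry)
    arena: ArenaFloor = field(default_factory=default_arena)
    duration_s: float = 60.0
    frame_rate: float = 29.0
    n_mice: int = 4
    sexes: tuple = ("M", "M", "F", "F")
    male_rate_hz: float = 0.25
    female_rate_hz: float = 0.02
    coupling_prob: float = 0.5
    coupling_latency_s: tuple = (0.05, 1.0)
    snr_db: float | None = 15.0
    seed: int = 0
    render_audio: bool = False
    chase_bouts: tuple = ()  # (t_start, t_stop, male_idx, female_idx)
    body_major_m: float = 0.09
    body_minor_m: float = 0.035

    def __post_init__(self):
        if len(self.sexes) != self.n_mice:
            raise ValueError("sexes must have one entry per mouse")
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite or None")


@dataclass
class SessionData:
    tracks: TrackTable
    events: pd.DataFrame  # time, mouse_id, sex, x, y, duration, seg hint
    audio: np.ndarray | None
    config: ScenarioConfig


def _wrap_pi(a):
    return np.mod(a + np.pi, 2 * np.pi) - np.pi


def _random_usv(rng) -> UsvModel:
    """A realistic adult courtship call: 30-80 ms, 55-95 kHz, mild sweep."""
    f0 = rng.uniform(55_000, 90_000)
    sweep = rng.uniform(-15_000, 15_000)
    f1 = np.clip(f0 + sweep, 40_000, 125_000)
    dur = rng.uniform(0.030, 0.080)
    return UsvModel(duration=float(dur), contour_hz=(float(f0), float(f1)))


def synth_session(cfg: ScenarioConfig) -> SessionData:
    """Full synthetic session: trajectories, coupled event trains, audio.

    Scripted chase bouts override the free trajectories: the female runs a
    fast arc and the male tracks her position 0.5 s behind.  Every emitted
    call is logged with its emitter, onset time and source (nose) position.
    """
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration_s * cfg.frame_rate))
    if n_frames < 2:
        raise ValueError("session too short")
    pos = np.stack([ou_trajectory(n_frames, cfg.frame_rate, cfg.arena, rng)
                    for _ in range(cfg.n_mice)])  # (M, F, 2)
    tt = np.arange(n_frames) / cfg.frame_rate
    for (t0, t1, mi, fi) in cfg.chase_bouts:
        sel = (tt >= t0) & (tt <= t1)
        idx = np.nonzero(sel)[0]
        if idx.size < 2:
            continue
        c = np.array([0.33, 0.33])
        r = 0.20
        w = 2 * np.pi / 4.0  # one lap / 4 s
        phase0 = rng.uniform(0, 2 * np.pi)
        lag = 0.5
        pos[fi, idx] = c + r * np.column_stack([
            np.cos(phase0 + w * (tt[idx] - t0)), np.sin(phase0 + w * (tt[idx] - t0))])
        pos[mi, idx] = c + r * np.column_stack([
            np.cos(phase0 + w * (tt[idx] - t0 - lag)),
            np.sin(phase0 + w * (tt[idx] - t0 - lag))])
    # headings from motion
    head = np.zeros((cfg.n_mice, n_frames))
    for m in range(cfg.n_mice):
        d = np.diff(pos[m], axis=0)
        ang = np.arctan2(d[:, 1], d[:, 0])
        head[m, 1:] = ang
        head[m, 0] = ang[0] if ang.size else 0.0
    head = _wrap_pi(head)

    rows = []
    for m in range(cfg.n_mice):
        for fidx in range(n_frames):
            rows.append((fidx, m, pos[m, fidx, 0], pos[m, fidx, 1],
                         head[m, fidx], cfg.body_major_m, cfg.body_minor_m))
    tracks = TrackTable(pd.DataFrame(rows, columns=["frame", "mouse_id", "x_m",
                                                    "y_m", "heading_rad",
                                                    "major_m", "minor_m"]),
                        cfg.frame_rate)

    # event trains: Poisson males, females = baseline + coupled responses
    males = [i for i, s in enumerate(cfg.sexes) if s == "M"]
    females = [i for i, s in enumerate(cfg.sexes) if s == "F"]
    events = []

    def emit(t, mouse):
        model = _random_usv(rng)
        frame = min(int(t * cfg.frame_rate), n_frames - 1)
        nose = pos[mouse, frame] + 0.5 * cfg.body_major_m * np.array(
            [np.cos(head[mouse, frame]), np.sin(head[mouse, frame])])
        events.append({"time": t, "mouse_id": mouse, "sex": cfg.sexes[mouse],
                       "x": nose[0], "y": nose[1],
                       "duration": model.duration, "model": model})

    for m in males:
        n_ev = rng.poisson(cfg.male_rate_hz * cfg.duration_s)
        for t in np.sort(rng.uniform(0, cfg.duration_s, n_ev)):
            emit(float(t), m)
            if females and rng.uniform() < cfg.coupling_prob:
                lat = rng.uniform(*cfg.coupling_latency_s)
                if t + lat < cfg.duration_s:
                    emit(float(t + lat), int(rng.choice(females)))
    for f in females:
        n_ev = rng.poisson(cfg.female_rate_hz * cfg.duration_s)
        for t in np.sort(rng.uniform(0, cfg.duration_s, n_ev)):
            emit(float(t), f)

    ev = pd.DataFrame(events).sort_values("time").reset_index(drop=True) if events \
        else pd.DataFrame(columns=["time", "mouse_id", "sex", "x", "y",
                                   "duration", "model"])

    audio = None
    if cfg.render_audio:
        fs = cfg.geometry.sample_rate
        n_samp = int(round(cfg.duration_s * fs))
        audio = np.zeros((n_samp, cfg.geometry.n_mics))
        for j, r in ev.iterrows():
            src = synth_usv(r["model"], fs)
            pos3 = np.array([r["x"], r["y"], cfg.arena.z_plane])
            rend = propagate(src, pos3, cfg.geometry, snr_db=None)
            i0 = int(round(r["time"] * fs))
            i1 = min(i0 + rend.shape[0], n_samp)
            if i0 < n_samp:
                audio[i0:i1] += rend[: i1 - i0]
        if cfg.snr_db is not None:
            # noise floor scaled to the median per-event nearest-mic RMS
            rmss = []
            for _, r in ev.iterrows():
                d = np.linalg.norm(cfg.geometry.mic_positions
                                   - np.array([r["x"], r["y"], cfg.arena.z_plane]),
                                   axis=1)
                src = synth_usv(r["model"], fs)
                rmss.append(np.sqrt(np.mean(src**2)) / d.min())
            ref = np.median(rmss) if rmss else 1.0
            sigma = ref / 10 ** (cfg.snr_db / 20.0)
            audio += rng.normal(0.0, sigma, size=audio.shape)
    return SessionData(tracks, ev, audio, cfg)
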