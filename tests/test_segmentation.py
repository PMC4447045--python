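"""Multitaper F-test masks, scale combination, region extraction, harmonics."""

import numpy as np
import pytest

from usvmuse import segmentation as seg

FS = 450450.0


def tone(freq, dur, snr_db, seed=0, fs=FS):
    rng = np.random.default_rng(seed)
    n = int(dur * fs)
    t = np.arange(n) / fs
    amp = np.sqrt(2.0) * 10 ** (snr_db / 20.0)
    return amp * np.sin(2 * np.pi * freq * t) + rng.standard_normal(n)


class TestFTestMasks:
    @pytest.mark.parametrize("scale", seg.DEFAULT_SCALES, ids=lambda s: f"nfft{s.nfft}")
    def test_tone_hot_in_every_column(self, scale):
        """A 70 kHz tone at 20 dB SNR is significant near 70 kHz in every
        time column, at every analysis scale."""
        m, p, tc, fc = seg.multitaper_hot_pixels(tone(70e3, 0.1, 20.0), FS, scale)
        b = int(np.argmin(np.abs(fc - 70e3)))
        assert m[:, max(b - 1, 0):b + 2].any(axis=1).all()

    def test_noise_false_positive_rate_near_alpha(self):
        """Under white noise the per-pixel exceedance rate of the F(2, 2K-2)
        test matches its nominal level."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal(int(0.2 * FS))
        for scale in seg.DEFAULT_SCALES:
            m, _, _, fc = seg.multitaper_hot_pixels(x, FS, scale, alpha=0.05)
            rate = m[:, fc >= seg.MIN_FREQ_HZ].mean()
            assert abs(rate - 0.05) < 0.01

    def test_below_30_khz_forced_false(self):
        x = tone(20e3, 0.02, 30.0)
        m, _, _, fc = seg.multitaper_hot_pixels(x, FS, seg.DEFAULT_SCALES[0])
        assert not m[:, fc < seg.MIN_FREQ_HZ].any()

    def test_record_shorter_than_window_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            seg.multitaper_hot_pixels(np.zeros(100), FS, seg.ScaleParams(512))

    def test_taper_count_bound_enforced(self):
        with pytest.raises(ValueError, match="n_tapers"):
            seg.ScaleParams(128, n_tapers=50, time_bandwidth=22.0)


class TestCombineScales:
    def _fake(self, mask, fs, nfft, hop):
        n_win = mask.shape[0]
        tc = (np.arange(n_win) * hop + nfft / 2) / fs
        fc = np.fft.rfftfreq(nfft, 1 / fs)
        return mask, np.where(mask, 0.01, 1.0), tc, fc

    def test_single_scale_single_channel_is_resampled_input(self):
        rng = np.random.default_rng(0)
        n = 8 * 512
        mask = rng.uniform(size=((n - 512) // 256 + 1, 257)) < 0.3
        fc = np.fft.rfftfreq(512, 1 / FS)
        mask[:, fc < seg.MIN_FREQ_HZ] = False
        img = seg.combine_scales([[self._fake(mask, FS, 512, 256)]], FS, n,
                                 scales=(seg.ScaleParams(512),))
        # common grid pitch equals this scale's: content must match per column
        ti = np.clip(np.round(np.interp(img.time_centers,
                                        (np.arange(mask.shape[0]) * 256 + 256) / FS,
                                        np.arange(mask.shape[0]))), 0,
                     mask.shape[0] - 1).astype(int)
        np.testing.assert_array_equal(img.mask, mask[ti])

    def test_union_identity_across_scales(self):
        n = 4 * 512
        sc = (seg.ScaleParams(128), seg.ScaleParams(512))
        n128 = (n - 128) // 64 + 1
        n512 = (n - 512) // 256 + 1
        all_false = np.zeros((n128, 65), dtype=bool)
        all_true = np.ones((n512, 257), dtype=bool)
        img = seg.combine_scales(
            [[self._fake(all_false, FS, 128, 64), self._fake(all_true, FS, 512, 256)]],
            FS, n, scales=sc)
        assert img.mask[:, img.freqs >= seg.MIN_FREQ_HZ].all()

    def test_channels_combine_by_intersection(self):
        n = 4 * 512
        sc = (seg.ScaleParams(512),)
        n512 = (n - 512) // 256 + 1
        all_true = np.ones((n512, 257), dtype=bool)
        half = np.zeros_like(all_true)
        half[:, 150:] = True
        img = seg.combine_scales([[self._fake(all_true, FS, 512, 256)],
                                  [self._fake(half, FS, 512, 256)]], FS, n,
                                 scales=sc)
        fc = np.fft.rfftfreq(512, 1 / FS)
        lo_common = (img.freqs >= seg.MIN_FREQ_HZ) & (img.freqs < fc[150])
        assert not img.mask[:, lo_common].any()
        assert img.mask[:, img.freqs >= fc[150]].all()

    def test_tone_visible_only_at_one_scale_survives(self):
        """A weak tone resolvable only with the longest window still reaches
        the combined image."""
        x = tone(70e3, 0.05, -3.0, seed=1)
        per = [[seg.multitaper_hot_pixels(x, FS, sc) for sc in seg.DEFAULT_SCALES]]
        img = seg.combine_scales(per, FS, x.size)
        m512 = per[0][2][0]
        fc512 = per[0][2][3]
        b = int(np.argmin(np.abs(fc512 - 70e3)))
        if m512[:, b].any():  # resolvable at nfft=512 for this draw
            bb = int(np.argmin(np.abs(img.freqs - 70e3)))
            assert img.mask[:, bb - 1:bb + 2].any()


def make_image(mask):
    n_t, n_f = mask.shape
    return seg.HotPixelImage(mask, np.where(mask, 0.01, 1.0),
                             np.arange(n_t) * (64 / FS) + 64 / FS,
                             seg.MIN_FREQ_HZ + np.arange(n_f) * (FS / 512),
                             64 / FS, FS / 512, FS)


class TestExtractSegments:
    def test_empty_image_gives_empty_list(self):
        assert seg.extract_segments(make_image(np.zeros((50, 40), bool))) == []

    def test_solid_block_exact_bounding_box(self):
        mask = np.zeros((300, 60), bool)
        mask[100:200, 20:40] = True  # 100 x 20 = 2000 px
        img = make_image(mask)
        out = seg.extract_segments(img, min_pixels=1500)
        assert len(out) == 1
        s = out[0]
        assert s.n_hot_pixels == 2000
        assert np.isclose(s.t_start, img.time_centers[100] - img.dt_bin / 2)
        assert np.isclose(s.t_stop, img.time_centers[199] + img.dt_bin / 2)
        assert np.isclose(s.f_lo, img.freqs[20] - img.df_bin / 2)
        assert np.isclose(s.f_hi, img.freqs[39] + img.df_bin / 2)

    def test_small_time_gap_closed_by_box(self):
        mask = np.zeros((400, 60), bool)
        mask[100:200, 20:40] = True
        mask[203:303, 20:40] = True  # 3-pixel gap < box length 15
        out = seg.extract_segments(make_image(mask), min_pixels=1500)
        assert len(out) == 1
        assert out[0].n_hot_pixels == 4000

    def test_min_pixels_is_strict(self):
        mask = np.zeros((300, 60), bool)
        mask[0:75, 20:40] = True  # exactly 1500
        assert seg.extract_segments(make_image(mask), min_pixels=1500) == []
        mask[75, 20] = True  # 1501
        assert len(seg.extract_segments(make_image(mask), min_pixels=1500)) == 1

    def test_disjoint_frequency_signals_stay_separate(self):
        mask = np.zeros((300, 120), bool)
        mask[50:150, 10:30] = True
        mask[50:150, 60:80] = True  # same times, far-apart bands
        out = seg.extract_segments(make_image(mask), min_pixels=1500)
        assert len(out) == 2


class TestMergeHarmonics:
    def _seg(self, sid, t0, t1, f0, f1):
        return seg.VocalSegment(sid, t0, t1, f0, f1,
                                np.zeros((1, 2), int), 2000)

    def _contour(self, t0, t1, f):
        ts = np.arange(t0, t1 - 1e-9, 0.005)
        return ts, np.full(ts.size, f)

    def test_exact_factor_two_full_overlap_merges(self):
        a = self._seg(0, 0.0, 0.05, 60e3, 65e3)
        b = self._seg(1, 0.0, 0.05, 120e3, 130e3)
        cont = {0: self._contour(0, 0.05, 62e3), 1: self._contour(0, 0.05, 124e3)}
        out = seg.merge_harmonics([a, b], cont)
        assert len(out) == 1 and out[0].merged_harmonics
        assert out[0].f_lo == 60e3 and out[0].f_hi == 130e3
        assert len(out[0].contours) == 2

    def test_ratio_2p25_does_not_merge(self):
        a = self._seg(0, 0.0, 0.05, 60e3, 65e3)
        b = self._seg(1, 0.0, 0.05, 130e3, 145e3)
        cont = {0: self._contour(0, 0.05, 62e3), 1: self._contour(0, 0.05, 139.5e3)}
        assert len(seg.merge_harmonics([a, b], cont)) == 2

    def test_factor_three_merges(self):
        a = self._seg(0, 0.0, 0.05, 40e3, 45e3)
        b = self._seg(1, 0.0, 0.05, 120e3, 130e3)
        cont = {0: self._contour(0, 0.05, 42e3), 1: self._contour(0, 0.05, 126e3)}
        assert len(seg.merge_harmonics([a, b], cont)) == 1

    def test_half_overlap_at_factor_two_does_not_merge(self):
        a = self._seg(0, 0.0, 0.05, 60e3, 65e3)
        b = self._seg(1, 0.025, 0.075, 120e3, 130e3)  # 50% of the shorter
        cont = {0: self._contour(0, 0.05, 62e3),
                1: self._contour(0.025, 0.075, 124e3)}
        assert len(seg.merge_harmonics([a, b], cont)) == 2


class TestEndToEnd:
    def test_gain_invariance_of_boxes(self, geom, rng):
        from usvmuse import simulator as sim

        src = sim.synth_usv(sim.UsvModel(duration=0.04,
                                         contour_hz=(65e3, 78e3)), FS)
        rec = sim.propagate(src, [0.3, 0.3, 0.0], geom, snr_db=18.0, seed=4)
        s1, _ = seg.segment_audio(rec, FS)
        s2, _ = seg.segment_audio(rec * 10.0, FS)
        assert len(s1) == len(s2) == 1
        assert np.isclose(s1[0].t_start, s2[0].t_start)
        assert np.isclose(s1[0].f_hi, s2[0].f_hi)
        assert s1[0].n_hot_pixels == s2[0].n_hot_pixels

    def test_segments_respect_invariants(self, geom):
        from usvmuse import simulator as sim

        src = sim.synth_usv(sim.UsvModel(duration=0.04,
                                         contour_hz=(65e3, 78e3)), FS)
        rec = sim.propagate(src, [0.3, 0.3, 0.0], geom, snr_db=15.0, seed=5)
        segments, _ = seg.segment_audio(rec, FS)
        for s in segments:
            assert s.n_hot_pixels > 1500
            assert s.f_lo >= seg.MIN_FREQ_HZ
            assert s.t_stop > s.t_start
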