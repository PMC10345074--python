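"""Segment metrics, spectral band powers and circadian profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noctidip import (
    CircadianHRSpec,
    build_profile,
    generate_rr_series,
    segment_hr,
    segment_series,
    segment_spectral,
    segment_time_domain,
)
from noctidip.hrv import (
    compute_segment_metrics,
    cohort_profile_summary,
    hour_value_matrix,
)
from tests.conftest import make_profile, make_series_1hz


def beats(rr_list, t0=0.0):
    """Beat group from an RR list, times = cumulative sum (seconds)."""
    rr = np.asarray(rr_list, dtype=float)
    return t0 + np.cumsum(rr) / 1000.0, rr


class TestSegmentation:
    def test_48h_gapfree_yields_24_segments_per_hour_slot(self):
        s = make_series_1hz(hours=48.0)
        seg = compute_segment_metrics(s, metrics=("hr",))
        hours = pd.DatetimeIndex(seg["segment_start"]).hour
        counts = hours.value_counts()
        assert len(seg) == 48 * 12
        assert set(counts.index) == set(range(24)) and (counts == 24).all()
        # 12 segments per clock hour per day
        days = pd.DatetimeIndex(seg["segment_start"]).day
        per_day = seg.groupby([days, hours]).size()
        assert (per_day == 12).all()

    def test_single_beat_binning_convention(self):
        s = make_series_1hz(start="2021-03-01 10:02", hours=1 / 3600)
        groups = segment_series(s)
        assert len(groups) == 1
        assert groups[0][0] == pd.Timestamp("2021-03-01 10:00")

    def test_each_beat_in_exactly_one_segment(self, quiet_series_48h):
        groups = segment_series(quiet_series_48h)
        total = sum(len(rr) for _, _, rr in groups)
        assert total == len(quiet_series_48h)


class TestSegmentHR:
    def test_constant_1000ms_is_60bpm(self):
        assert segment_hr(np.full(30, 1000.0)) == 60.0

    def test_alternating_midpoint_median(self):
        rr = np.tile([500.0, 1500.0], 15)
        assert segment_hr(rr) == pytest.approx((120 + 40) / 2)

    def test_800ms_is_75bpm(self):
        assert segment_hr(np.full(10, 800.0)) == pytest.approx(75.0)


def _oracle_time_domain(rr):
    """Brute-force SDNN/RMSSD (no gap handling; for contiguous beats)."""
    rr = np.asarray(rr, dtype=float)
    sdnn = math.sqrt(np.mean((rr - rr.mean()) ** 2))
    diffs = np.diff(rr)
    rmssd = math.sqrt(np.mean(diffs**2))
    return sdnn, rmssd


class TestTimeDomain:
    def test_constant_rr_zero(self):
        t, rr = beats([1000.0] * 40)
        assert segment_time_domain(t, rr) == (0.0, 0.0)

    def test_alternating_closed_form(self):
        t, rr = beats([950.0, 1050.0, 950.0, 1050.0])
        sdnn, rmssd = segment_time_domain(t, rr)
        assert sdnn == pytest.approx(50.0)
        assert rmssd == pytest.approx(100.0)

    def test_oracle_equivalence_1000_random_segments(self):
        # RR range chosen so no pair trips the gap rule: the oracle and the
        # implementation then compute the same plain formulas
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            n = int(rng.integers(4, 120))
            rr = rng.uniform(650, 1250, n)
            t, rr = beats(rr)
            sdnn, rmssd = segment_time_domain(t, rr)
            o_sdnn, o_rmssd = _oracle_time_domain(rr)
            assert sdnn == pytest.approx(o_sdnn, rel=1e-9)
            assert rmssd == pytest.approx(o_rmssd, rel=1e-9)

    def test_pairs_straddling_gap_are_skipped(self):
        # two contiguous runs separated by a 60 s hole
        rr1 = [1000.0, 1000.0, 1000.0, 1000.0]
        rr2 = [1200.0, 1200.0, 1200.0]
        t1, _ = beats(rr1)
        t2, _ = beats(rr2, t0=t1[-1] + 60.0)
        t = np.concatenate([t1, t2])
        rr = np.asarray(rr1 + rr2)
        _, rmssd = segment_time_domain(t, rr)
        # within-run diffs are all zero; the 1000->1200 jump pair is excluded
        assert rmssd == 0.0

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(min_value=800, max_value=1200), min_size=4, max_size=40),
        st.floats(min_value=0.5, max_value=3.0),
        st.floats(min_value=-100, max_value=100),
    )
    def test_scale_equivariance_and_shift_invariance(self, rr_list, c, shift):
        # RR/shift ranges keep every successive pair inside the gap rule, so
        # the transforms act on the plain formulas
        t, rr = beats(rr_list)
        sdnn, rmssd = segment_time_domain(t, rr)
        t_c, rr_c = beats(rr * c)
        sdnn_c, rmssd_c = segment_time_domain(t_c, rr_c)
        assert sdnn_c == pytest.approx(c * sdnn, rel=1e-9, abs=1e-9)
        assert rmssd_c == pytest.approx(c * rmssd, rel=1e-9, abs=1e-9)
        t_s, rr_s = beats(rr + shift)
        sdnn_s, rmssd_s = segment_time_domain(t_s, rr_s)
        assert sdnn_s == pytest.approx(sdnn, rel=1e-9, abs=1e-9)
        assert rmssd_s == pytest.approx(rmssd, rel=1e-9, abs=1e-9)

    def test_hr_scales_inversely(self):
        t, rr = beats([800.0] * 35)
        assert segment_hr(rr * 2) == pytest.approx(segment_hr(rr) / 2)


def tone_segment(freq_hz, amp_ms=25.0, duration_s=300.0, base_ms=1000.0):
    spec = CircadianHRSpec(
        baseline_day_hr=60000.0 / base_ms,
        dip_fraction=0.0,
        lf_amplitude_ms=amp_ms if freq_hz < 0.15 else 0.0,
        lf_freq_hz=freq_hz if freq_hz < 0.15 else 0.1,
        hf_amplitude_ms=amp_ms if freq_hz >= 0.15 else 0.0,
        hf_freq_hz=freq_hz if freq_hz >= 0.15 else 0.25,
        noise_sd_ms=0.0,
    )
    s = generate_rr_series(spec, "2021-03-01 06:00", duration_s / 3600.0, seed=0)
    groups = segment_series(s)
    return max(groups, key=lambda g: len(g[2]))


class TestSpectral:
    def test_hf_tone_localizes_in_hf_band(self):
        _, t, rr = tone_segment(0.25)
        lf, hf = segment_spectral(t - t[0], rr)
        assert hf >= 10 * lf

    def test_lf_tone_localizes_in_lf_band(self):
        _, t, rr = tone_segment(0.10)
        lf, hf = segment_spectral(t - t[0], rr)
        assert lf >= 10 * hf

    def test_constant_rr_zero_power(self):
        t, rr = beats([1000.0] * 300)
        lf, hf = segment_spectral(t, rr)
        assert lf == pytest.approx(0.0, abs=1e-9)
        assert hf == pytest.approx(0.0, abs=1e-9)

    def test_single_tone_captures_90pct_of_power(self):
        from scipy.interpolate import UnivariateSpline
        from scipy.signal import periodogram

        _, t, rr = tone_segment(0.25)
        t = t - t[0]
        spline = UnivariateSpline(t, rr, k=3, s=0.0)
        grid = np.arange(t[0], t[-1], 0.25)
        x = spline(grid) - spline(grid).mean()
        freqs, psd = periodogram(x, fs=4.0)
        df = freqs[1] - freqs[0]
        total = psd[freqs > 0].sum() * df
        _, hf = segment_spectral(t, rr)
        assert hf >= 0.9 * total

    def test_short_or_sparse_segment_missing(self):
        t, rr = beats([1000.0] * 10)
        assert all(math.isnan(v) for v in segment_spectral(t, rr))
        t, rr = beats([400.0] * 100)  # 40 s span only
        assert all(math.isnan(v) for v in segment_spectral(t, rr))


class TestProfiles:
    def segs(self, hour_counts, value=70.0):
        """Synthetic segment table: {hour: n_segments} with constant value."""
        rows = []
        for h, k in hour_counts.items():
            for i in range(k):
                rows.append(
                    {
                        "patient_id": "p1",
                        "segment_start": pd.Timestamp(f"2021-03-01 {h:02d}:{5*i:02d}"),
                        "n_beats": 100,
                        "hr_bpm": value,
                    }
                )
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("k,available", [(0, False), (2, False), (3, True), (5, True)])
    def test_hourly_quorum_sweep(self, k, available):
        prof = build_profile(self.segs({3: k}), "hr")
        assert prof.hour_segment_counts[3] == k
        assert (not math.isnan(prof.hour_values[3])) == available

    def test_three_identical_values_pass_through(self):
        prof = build_profile(self.segs({3: 3}, value=66.0), "hr")
        assert prof.hour_values[3] == 66.0

    def test_counts_conserve_segments(self, quiet_series_48h):
        seg = compute_segment_metrics(quiet_series_48h, metrics=("hr",))
        prof = build_profile(seg, "hr")
        present = seg["hr_bpm"].notna().sum()
        assert prof.hour_segment_counts.sum() == present

    def test_multi_patient_segments_rejected(self):
        df = self.segs({3: 3})
        df.loc[0, "patient_id"] = "p2"
        with pytest.raises(ValueError, match="multiple patients"):
            build_profile(df, "hr")

    def test_synthetic_dipper_night_below_day(self, quiet_series_48h):
        seg = compute_segment_metrics(quiet_series_48h, metrics=("hr",))
        prof = build_profile(seg, "hr")
        night = np.nanmean(prof.hour_values[[0, 1, 2, 3]])
        day = np.nanmean(prof.hour_values[[11, 12, 13, 14]])
        assert night < day

    def test_cohort_summary_mean_and_sd(self):
        mat = hour_value_matrix(
            [make_profile([70.0] * 24, patient_id="a"), make_profile([74.0] * 24, patient_id="b")]
        )
        groups = pd.Series({"a": "g1", "b": "g1"})
        summary = cohort_profile_summary(mat, groups)
        assert (summary["mean"] == 72.0).all()
        assert summary["sd"].iloc[0] == pytest.approx(np.std([70, 74], ddof=1))
        identical = hour_value_matrix(
            [make_profile([70.0] * 24, patient_id="a"), make_profile([70.0] * 24, patient_id="b")]
        )
        assert (cohort_profile_summary(identical, groups)["sd"] == 0).all()
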