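"""Bound-segment classification, survival curves and exponential fitting."""

import numpy as np
import pytest
from scipy import stats

from chromodyn import AcquisitionParams, KineticTruth, simulate_tracks
from chromodyn.core import Track, TrackSet
from chromodyn.dwell import (
    BoundClassifierParams,
    BoundSegment,
    SurvivalCurve,
    _double_model,
    bound_fraction,
    classify_bound,
    classify_bound_trackset,
    estimate_bleach_rate,
    fit_survival,
    survival_curve,
)

ACQ = AcquisitionParams(frame_interval_s=0.2, n_frames=200)
PARAMS = BoundClassifierParams()


def _track(xs_um, ys_um, frames=None):
    xs = np.asarray(xs_um) / ACQ.pixel_size_um
    ys = np.asarray(ys_um) / ACQ.pixel_size_um
    frames = np.arange(len(xs)) if frames is None else np.asarray(frames)
    return Track(0, frames, xs, ys)


class TestClassifyBound:
    def test_stationary_track_is_one_full_segment(self):
        t = _track(np.zeros(20), np.zeros(20))
        segs = classify_bound(t, PARAMS, ACQ)
        assert len(segs) == 1
        assert segs[0].duration_s == pytest.approx(19 * 0.2)

    def test_fast_track_yields_no_segments(self):
        t = _track(np.arange(20) * 2.0, np.zeros(20))  # 2 um per step
        assert classify_bound(t, PARAMS, ACQ) == []

    def test_short_track_yields_empty_result(self):
        t = _track(np.zeros(5), np.zeros(5))
        assert classify_bound(t, PARAMS, ACQ) == []

    def test_two_frame_rule_cuts_slow_drift(self):
        # steps of 0.35 um pass r_min but two-frame drift 0.70 um > r_max
        t = _track(np.arange(20) * 0.35, np.zeros(20))
        assert classify_bound(t, PARAMS, ACQ) == []

    def test_matches_bruteforce_window_oracle_on_simulated_tracks(self):
        """Maximal-run classification agrees with an exhaustive window scan
        for every simulated track over a range of mobilities."""

        def brute_segments(track):
            p = np.column_stack([track.x_px, track.y_px]) * ACQ.pixel_size_nm
            n = len(p)
            d1 = np.linalg.norm(np.diff(p, axis=0), axis=1)
            d2 = np.linalg.norm(p[2:] - p[:-2], axis=1)
            good = [
                (a, b)
                for a in range(n)
                for b in range(a + PARAMS.n_min - 1, n)
                if np.all(d1[a:b] <= PARAMS.r_min_nm) and np.all(d2[a : max(b - 1, a)] <= PARAMS.r_max_nm)
            ]
            maximal = [
                (a, b)
                for a, b in good
                if not any((c <= a and b <= d and (c, d) != (a, b)) for c, d in good)
            ]
            return sorted(maximal)

        for D, seed in [(0.05, 1), (0.2, 2), (0.5, 3)]:
            truth = KineticTruth(frac_bound=0.0, D_free=D, D_bound=0.0, k_ns=1, k_s=1, bleach_lifetime_s=1e9)
            acq = AcquisitionParams(frame_interval_s=0.2, n_frames=40, axial_range_nm=0.0)
            ts = simulate_tracks(truth, acq, 60, seed=seed)
            for t in ts:
                got = [(s.start_frame, s.end_frame) for s in classify_bound(t, PARAMS, acq)]
                assert got == brute_segments(t)

    def test_free_molecules_rarely_classified_bound_in_study_geometry(self):
        """Freely diffusing molecules at the lower edge of the free-diffusion
        search range contribute bound segments to fewer than 1% of
        trajectories once the axial detection slab limits how long they
        stay in focus."""
        truth = KineticTruth(frac_bound=0.0, D_free=0.5, D_bound=0.0, k_ns=1, k_s=1)
        acq = AcquisitionParams(frame_interval_s=0.2, n_frames=200, localization_error_um=0.035)
        n_mol = 5000
        ts = simulate_tracks(truth, acq, n_mol, seed=1)
        n_with = sum(1 for t in ts if classify_bound(t, PARAMS, acq))
        assert n_with / n_mol < 0.01


class TestBoundFraction:
    def test_counts_tracks_with_any_segment(self):
        bound = [_track(np.zeros(20), np.zeros(20)) for _ in range(3)]
        free = [_track(np.arange(20) * 2.0, np.zeros(20)) for _ in range(7)]
        for i, t in enumerate(bound + free):
            t.track_id = i
        ts = TrackSet(bound + free, ACQ)
        assert bound_fraction(ts, PARAMS) == pytest.approx(0.3)

    def test_all_stationary_gives_one(self):
        ts = TrackSet([_track(np.zeros(20), np.zeros(20))] * 5, ACQ)
        assert bound_fraction(ts, PARAMS) == 1.0

    def test_empty_trackset_rejected(self):
        with pytest.raises(ValueError):
            bound_fraction(TrackSet([], ACQ), PARAMS)

    def test_recovers_simulated_bound_fraction_with_long_dwells(self):
        truth = KineticTruth(
            frac_bound=0.15, frac_ns_of_bound=0.0, k_ns=0.01, k_s=0.01, D_bound=0.005,
            D_free=2.0, bleach_lifetime_s=1e6, interconvert=True,
        )
        acq = AcquisitionParams(frame_interval_s=0.2, n_frames=100, axial_range_nm=0.0)
        ts = simulate_tracks(truth, acq, 2000, seed=12)
        assert bound_fraction(ts, PARAMS) == pytest.approx(0.15, abs=0.03)


class TestBleachRate:
    @pytest.mark.parametrize("lifetime", [20.0, 5.0])
    def test_recovers_bleach_rate(self, lifetime):
        truth = KineticTruth(frac_bound=1.0, D_bound=0.005, D_free=2.0, bleach_lifetime_s=lifetime)
        acq = AcquisitionParams(frame_interval_s=0.2, n_frames=200, axial_range_nm=0.0)
        ts = simulate_tracks(truth, acq, 2000, seed=13)
        assert estimate_bleach_rate(ts) == pytest.approx(1.0 / lifetime, rel=0.15)

    def test_no_bleaching_gives_near_zero_rate(self):
        truth = KineticTruth(frac_bound=1.0, D_bound=0.005, D_free=2.0, bleach_lifetime_s=1e9)
        acq = AcquisitionParams(frame_interval_s=0.2, n_frames=100, axial_range_nm=0.0)
        ts = simulate_tracks(truth, acq, 500, seed=14)
        assert estimate_bleach_rate(ts) < 0.005


class TestSurvivalCurve:
    def test_identical_durations_make_a_step(self):
        segs = [BoundSegment(i, 0, 10, 2.0) for i in range(30)]
        c = survival_curve(segs, 0.0, 1.0)
        assert list(c.times) == [2.0]
        assert list(c.survival) == [1.0]

    def test_zero_bleach_rate_is_identity(self):
        rng = np.random.default_rng(0)
        segs = [BoundSegment(i, 0, 1, d) for i, d in enumerate(rng.exponential(2.0, 200))]
        c = survival_curve(segs, 0.0, 1.0)
        durations = np.array([s.duration_s for s in segs])
        raw = np.array([(durations >= t).mean() for t in c.times])
        assert np.allclose(c.survival, raw)

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError):
            survival_curve([BoundSegment(0, 0, 1, 1.0)] * 5, 0.0, 1.0)

    def test_corrected_curve_close_to_true_mixture(self):
        """Dwell mixture (k_s = 0.227, k_ns = 2, F_ns = 0.6) censored by
        20 s bleaching: the corrected curve tracks the true mixture
        survival within KS distance 0.05 at n = 2000."""
        rng = np.random.default_rng(21)
        n = 2000
        is_ns = rng.random(n) < 0.6
        dwell = rng.exponential(np.where(is_ns, 1 / 2.0, 1 / 0.227))
        bleach = rng.exponential(20.0, n)
        obs = np.minimum(dwell, bleach)
        segs = [BoundSegment(i, 0, 1, d) for i, d in enumerate(obs)]
        c = survival_curve(segs, bleach_rate=1 / 20.0, bound_fraction=1.0)
        s_true = 0.6 * np.exp(-2.0 * c.times) + 0.4 * np.exp(-0.227 * c.times)
        s_true = s_true / s_true[0]
        assert np.max(np.abs(c.survival - s_true)) < 0.05


class TestFitSurvival:
    @staticmethod
    def _curve(times, survival, B, n_segments=2000):
        return SurvivalCurve(
            times=np.asarray(times, float),
            survival=np.asarray(survival, float),
            bound_fraction=B,
            bleach_corrected=False,
            bleach_rate=0.0,
            n_segments=n_segments,
        )

    def test_exact_single_exponential_selects_single_model(self):
        t = np.linspace(0, 20, 60)
        c = self._curve(t, 0.3 * np.exp(-0.5 * t), 0.3)
        fit = fit_survival(c)
        assert fit.selected_model == "single"
        assert fit.single_k == pytest.approx(0.5, abs=1e-6)

    def test_exact_double_exponential_recovers_both_rates(self):
        t = np.linspace(0, 20, 100)
        y = 0.3 * (0.6 * np.exp(-2.0 * t) + 0.4 * np.exp(-0.2 * t))
        fit = fit_survival(self._curve(t, y, 0.3))
        assert fit.selected_model == "double"
        assert fit.T_s == pytest.approx(5.0, rel=0.01)
        assert fit.T_ns == pytest.approx(0.5, rel=0.01)
        assert fit.F_ns == pytest.approx(0.6, abs=0.01)

    def test_degenerate_weights_reduce_to_single_exponential(self):
        t = np.linspace(0, 10, 50)
        for f_ns in (0.0, 1.0):
            y = _double_model(t, 1.0, f_ns, 2.0, 0.2)
            k = 2.0 if f_ns == 1.0 else 0.2
            assert np.allclose(y, np.exp(-k * t))

    def test_rate_recovery_invariant_to_time_units(self):
        t = np.linspace(0, 20, 100)
        y = 0.3 * (0.6 * np.exp(-2.0 * t) + 0.4 * np.exp(-0.2 * t))
        fit_s = fit_survival(self._curve(t, y, 0.3))
        fit_ms = fit_survival(self._curve(t * 1000.0, y, 0.3))
        assert fit_ms.T_s == pytest.approx(fit_s.T_s * 1000.0, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_survival(self._curve([1, 2, 3], [0.3, 0.2, 0.1], 0.3))

    @pytest.mark.parametrize("T_s", [2.0, 5.0, 40.0])
    def test_end_to_end_residence_time_recovery(self, T_s):
        """Specific residence times spanning 2-40 s recovered within 20%
        through simulate -> classify -> bleach-correct -> fit. The check
        averages three replicates of 2,000 tracks: a single replicate's
        estimate at T_s = 40 s has ~16% sampling scatter (the residence
        time approaches both the bleach lifetime and the movie length), so
        the 20% accuracy statement is about the estimator, not one draw."""
        truth = KineticTruth(
            frac_bound=0.5, frac_ns_of_bound=0.6, k_ns=2.0, k_s=1.0 / T_s,
            D_bound=0.005, D_free=2.0, bleach_lifetime_s=20.0, interconvert=True,
        )
        acq = AcquisitionParams(frame_interval_s=0.2, n_frames=200, axial_range_nm=0.0, localization_error_um=0.035)
        estimates = []
        for seed in (40, 41, 42):
            ts = simulate_tracks(truth, acq, 2000, seed=seed)
            segs = classify_bound_trackset(ts)
            fit = fit_survival(
                survival_curve(segs, estimate_bleach_rate(ts), bound_fraction(ts))
            )
            estimates.append(fit.residence_time)
        assert np.mean(estimates) == pytest.approx(T_s, rel=0.20)
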