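"""Stage detection, alignment/averaging, scission inference and kinetics."""

import numpy as np
import pytest
from scipy import stats

from patchkit import (
    AlignedEnsemble,
    DegenerateInputError,
    EventParams,
    InsufficientDataError,
    PairingError,
    Track,
    align_tracks,
    align_two_channel,
    detect_scission,
    filter_crowded,
    generate_track_set,
    half_max_time,
    inflection_point,
    invagination_speed,
    patch_lifetime,
    signal_onset,
)
from patchkit.dynamics import compute_references


def step_track(n_flat=50, n_move=30, step=30.0, dt=1.0, noise=0.0, seed=0,
               track_id="s"):
    """Stationary for n_flat frames, then directed at `step` nm/frame."""
    rng = np.random.default_rng(seed)
    n = n_flat + n_move + 1
    t = np.arange(n) * dt
    x = np.where(t <= n_flat * dt, 0.0, (t - n_flat * dt) / dt * step)
    y = np.zeros(n)
    if noise:
        x = x + rng.normal(0, noise, n)
        y = y + rng.normal(0, noise, n)
    intensity = np.concatenate(
        [np.linspace(0, 1, n_flat + 1), np.linspace(1, 0.2, n_move)]
    )
    return Track(track_id, t, x, y, intensity, frame_interval=dt)


class TestFilterCrowded:
    def test_single_track_unchanged(self, random_track):
        tracks = [random_track(0)]
        assert filter_crowded(tracks) == tracks

    def test_coincident_pair_both_removed(self, make_track):
        a = make_track([0, 0, 0], track_id="a")
        b = make_track([0, 0, 0], track_id="b")
        assert filter_crowded([a, b], min_separation=325.0) == []

    def test_distant_pair_kept(self, make_track):
        a = make_track([0, 0, 0], track_id="a")
        b = make_track([1000.0, 1000.0, 1000.0], track_id="b")
        assert len(filter_crowded([a, b], min_separation=325.0)) == 2

    def test_matches_all_pairs_distance_oracle(self, random_track):
        tracks = [random_track(seed=s, n=20, scale=400.0, track_id=f"r{s}") for s in range(8)]
        kept = {tr.track_id for tr in filter_crowded(tracks, min_separation=300.0)}
        # brute-force oracle: all concurrent pairs, all frames
        expected_removed = set()
        for i in range(len(tracks)):
            for j in range(i + 1, len(tracks)):
                a, b = tracks[i], tracks[j]
                n = min(len(a), len(b))
                d = np.hypot(a.x[:n] - b.x[:n], a.y[:n] - b.y[:n])
                if (d < 300.0).any():
                    expected_removed |= {a.track_id, b.track_id}
        assert kept == {tr.track_id for tr in tracks} - expected_removed


class TestInflectionPoint:
    def test_noiseless_step_track_found_exactly(self):
        track = step_track()
        ref = inflection_point(track)
        assert ref.mode == "inflection"
        assert abs(ref.t_ref - 50.0) <= 1.0

    def test_purely_static_track_is_degenerate(self, make_track):
        with pytest.raises(DegenerateInputError):
            inflection_point(make_track([0.0] * 20))

    def test_short_track_is_insufficient(self, make_track):
        with pytest.raises(InsufficientDataError):
            inflection_point(make_track(np.arange(5.0)))

    def test_residual_method_matches_exhaustive_argmin_oracle(self):
        track = step_track(noise=5.0, seed=3)
        ref = inflection_point(track, method="residual", smooth_window=1)
        # independently coded oracle for the regression-residual rule
        d = np.hypot(track.x - track.x[0], track.y - track.y[0])
        slope, intercept, *_ = stats.linregress(track.times, d)
        resid = d - (intercept + slope * track.times)
        best = min(range(len(d)), key=lambda i: (resid[i], i))
        assert ref.t_ref == pytest.approx(track.times[best])

    def test_recovers_simulated_ground_truth(self):
        tracks, truth = generate_track_set(
            25, EventParams(stationary_duration=40.0), seed=3
        )
        hits = 0
        for track, (_, row) in zip(tracks, truth.iterrows()):
            ref = inflection_point(track)
            if abs(ref.t_ref - row.t_inflection) <= 2 * track.frame_interval + 1e-9:
                hits += 1
        assert hits >= 20  # >= 80% on this small batch


class TestHalfMaxTime:
    def test_linear_ramp_crosses_at_midpoint(self, make_track):
        track = make_track([0.0] * 11, intensity=np.linspace(0, 100, 11))
        assert half_max_time(track).t_ref == pytest.approx(5.0)

    def test_interpolates_between_frames(self, make_track):
        track = make_track([0.0] * 4, intensity=[0.0, 30.0, 90.0, 60.0])
        # half-max 45 crossed between frames 1 and 2
        assert half_max_time(track).t_ref == pytest.approx(1.25)

    def test_constant_intensity_flagged_at_first_point(self, make_track):
        ref = half_max_time(make_track([0.0] * 5, intensity=[2.0] * 5))
        assert ref.flagged
        assert ref.t_ref == 0.0

    def test_noisy_logistic_matches_scan_oracle_within_one_frame(self, make_track):
        rng = np.random.default_rng(8)
        t = np.arange(60) * 1.0
        clean = 1.0 / (1.0 + np.exp(-(t - 30) / 3.0))
        intensity = clean * (1 + 0.05 * rng.standard_normal(60))
        track = make_track(np.zeros(60), intensity=intensity)
        oracle_idx = int(np.argmax(intensity >= 0.5 * intensity.max()))
        assert abs(half_max_time(track).t_ref - t[oracle_idx]) <= 1.0


class TestAlignTracks:
    def _shifted_copies(self, offsets):
        """Time-shifted copies of one template: pad the flat phase in front."""
        base = step_track(n_flat=40, track_id="base")
        tracks = []
        for i, off in enumerate(offsets):
            tracks.append(
                Track(
                    f"c{i}",
                    np.arange(len(base) + off) * base.frame_interval,
                    np.concatenate([np.full(off, base.x[0]), base.x]),
                    np.concatenate([np.full(off, base.y[0]), base.y]),
                    np.concatenate([np.full(off, base.intensity[0]), base.intensity]),
                    base.frame_interval,
                )
            )
        return tracks

    def test_identical_tracks_with_offsets_average_to_template(self):
        tracks = self._shifted_copies([0, 3, 7, 12])
        ens = align_tracks(tracks, mode="inflection")
        core = np.isfinite(ens.sd_intensity) & (np.abs(ens.rel_times) < 20)
        assert np.all(ens.sd_intensity[core] < 1e-6)
        assert np.all(ens.sd_displacement[core] < 1e-6)

    def test_normalized_intensity_peaks_at_one(self):
        tracks, _ = generate_track_set(10, EventParams(stationary_duration=20.0), seed=1)
        ens = align_tracks(tracks)
        assert np.nanmax(ens.mean_intensity) <= 1.0 + 1e-6
        # multiplicative intensity noise makes each track's own maximum a
        # noise spike, so the aligned ensemble peaks somewhat below 1
        assert np.nanmax(ens.mean_intensity) > 0.75

    def test_displacement_zero_at_reference(self):
        tracks, _ = generate_track_set(8, EventParams(stationary_duration=15.0), seed=2)
        ens = align_tracks(tracks)
        at_zero = np.argmin(np.abs(ens.rel_times))
        assert ens.mean_displacement[at_zero] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_tracks_raises(self):
        tracks = self._shifted_copies([0, 1])
        with pytest.raises(InsufficientDataError):
            align_tracks(tracks)

    def test_clock_shift_equivariance(self):
        tracks, _ = generate_track_set(6, EventParams(stationary_duration=15.0), seed=5)
        shifted = [
            Track(tr.track_id, tr.times + 11.0, tr.x, tr.y, tr.intensity,
                  tr.frame_interval, tr.protein, tr.fluorophore)
            for tr in tracks
        ]
        a = align_tracks(tracks)
        b = align_tracks(shifted)
        assert np.allclose(a.rel_times, b.rel_times)
        assert np.allclose(a.mean_displacement, b.mean_displacement, equal_nan=True)


def make_ensemble(rel, sd_disp, mean_disp=None):
    n = len(rel)
    return AlignedEnsemble(
        rel_times=np.asarray(rel, dtype=float),
        mean_intensity=np.linspace(0, 1, n),
        sd_intensity=np.zeros(n),
        mean_displacement=(
            np.linspace(0, 100, n) if mean_disp is None else np.asarray(mean_disp, float)
        ),
        sd_displacement=np.asarray(sd_disp, dtype=float),
        n_per_bin=np.full(n, 5),
    )


class TestDetectScission:
    def test_constant_sd_never_triggers(self):
        rel = np.arange(-10, 80) * 0.1
        assert detect_scission(make_ensemble(rel, np.full(len(rel), 10.0))) is None

    def test_step_in_sd_detected_at_step(self):
        rel = np.arange(-10, 80) * 0.1
        sd = np.where(rel >= 4.5, 30.0, 10.0)
        t = detect_scission(make_ensemble(rel, sd))
        assert t == pytest.approx(4.5, abs=0.1 + 1e-9)

    def test_brief_blip_shorter_than_m_ignored(self):
        rel = np.arange(-10, 80) * 0.1
        sd = np.full(len(rel), 10.0)
        blip = np.flatnonzero(rel >= 4.5)[:2]
        sd[blip] = 50.0
        assert detect_scission(make_ensemble(rel, sd), m=3) is None

    def test_monotone_in_k(self):
        rng = np.random.default_rng(4)
        rel = np.arange(-10, 100) * 0.1
        sd = 10.0 + rng.uniform(0, 1, len(rel)) + np.where(rel > 5.0, 25.0, 0.0)
        ens = make_ensemble(rel, sd)
        times = []
        for k in (1.5, 2.0, 2.5, 3.0, 3.6):
            t = detect_scission(ens, k=k)
            times.append(np.inf if t is None else t)
        assert all(a <= b for a, b in zip(times, times[1:]))

    def test_empty_baseline_raises(self):
        rel = np.arange(30) * 0.1 + 5.0  # all bins after the baseline window
        with pytest.raises(InsufficientDataError):
            detect_scission(make_ensemble(rel, np.full(30, 5.0)))


class TestInvaginationSpeed:
    def test_exact_linear_ramp_gives_exact_slope(self):
        rel = np.linspace(0.0, 4.0, 37)
        ens = make_ensemble(rel, np.zeros(37), mean_disp=50.0 * rel)
        speed, stderr = invagination_speed(ens, t_scission=4.0)
        assert speed == pytest.approx(50.0, abs=1e-9)
        assert stderr == pytest.approx(0.0, abs=1e-6)

    def test_constant_displacement_gives_zero_slope(self):
        rel = np.linspace(0.0, 4.0, 20)
        ens = make_ensemble(rel, np.zeros(20), mean_disp=np.full(20, 80.0))
        speed, _ = invagination_speed(ens, t_scission=4.0, debias=False)
        assert speed == pytest.approx(0.0, abs=1e-12)

    def test_noise_floor_debias_recovers_true_slope(self):
        # mean |displacement| of a drift + isotropic noise ~ sqrt((vt)^2 + c^2)
        v, c = 23.8, 30.0
        rel = np.arange(-20, 41) * 0.111
        disp = np.sqrt((v * np.clip(rel, 0, None)) ** 2 + c**2)
        ens = make_ensemble(rel, np.zeros(len(rel)), mean_disp=disp)
        speed_raw, _ = invagination_speed(ens, 4.4, debias=False)
        speed_corr, _ = invagination_speed(ens, 4.4, debias=True)
        assert abs(speed_corr - v) / v < 0.02
        assert abs(speed_corr - v) < abs(speed_raw - v)

    def test_too_few_bins_raises(self):
        rel = np.linspace(0.0, 4.0, 20)
        ens = make_ensemble(rel, np.zeros(20))
        with pytest.raises(InsufficientDataError):
            invagination_speed(ens, t_scission=0.3)


class TestPatchLifetime:
    def test_triangular_profile_similar_triangles(self, make_track):
        up = np.linspace(0, 100, 11)
        down = np.linspace(100, 0, 11)[1:]
        track = make_track(np.zeros(21), intensity=np.concatenate([up, down]))
        assert patch_lifetime(track, frac=0.1) == pytest.approx(18.0)

    def test_frac_zero_gives_full_duration(self, make_track):
        track = make_track(np.zeros(15), intensity=np.linspace(1, 2, 15))
        assert patch_lifetime(track, frac=0.0) == track.duration

    def test_plateau_scales_lifetime(self):
        """A profile with a 3x longer plateau lives ~3x as long."""
        def plateau_track(hold):
            i = np.concatenate(
                [np.linspace(0, 1, 10), np.full(hold, 1.0), np.linspace(1, 0, 10)]
            )
            return Track("p", np.arange(len(i)) * 1.0, np.zeros(len(i)),
                         np.zeros(len(i)), i, frame_interval=1.0)
        short = patch_lifetime(plateau_track(10), frac=0.5)
        long = patch_lifetime(plateau_track(50), frac=0.5)
        assert long / short == pytest.approx(3.0, rel=0.15)

    def test_negative_frac_rejected(self, make_track):
        with pytest.raises(ValueError):
            patch_lifetime(make_track(np.zeros(5), intensity=np.ones(5)), frac=-0.1)


class TestTwoChannel:
    @staticmethod
    def _channel_pair(delay, n_events=4):
        pairs = []
        for i in range(n_events):
            a = step_track(n_flat=40 + 3 * i, track_id=f"a{i}")
            shift = int(delay)
            ib = np.roll(a.intensity, shift)
            ib[:shift] = a.intensity[0]
            b = Track(f"b{i}", a.times, a.x, a.y, ib, a.frame_interval)
            pairs.append((a, b))
        return pairs

    def test_identical_channels_give_identical_ensembles(self):
        pairs = [(a, a) for a, _ in self._channel_pair(0)]
        ens_a, ens_b = align_two_channel(pairs, mode="inflection")
        assert np.allclose(ens_a.mean_intensity, ens_b.mean_intensity, equal_nan=True)
        assert np.array_equal(ens_a.rel_times, ens_b.rel_times)

    def test_delayed_channel_lags_by_delay(self):
        delay = 6.0  # frames == seconds here
        ens_a, ens_b = align_two_channel(self._channel_pair(delay), mode="inflection")

        def crossing(ens):
            ok = np.isfinite(ens.mean_intensity)
            above = ok & (ens.mean_intensity >= 0.5)
            return ens.rel_times[np.flatnonzero(above)[0]]

        lag = crossing(ens_b) - crossing(ens_a)
        assert lag == pytest.approx(delay, abs=1.0)

    def test_non_overlapping_pair_raises(self, make_track):
        a = make_track(np.zeros(5), intensity=np.ones(5))
        late = Track("late", np.arange(5) + 100.0, np.zeros(5), np.zeros(5),
                     np.ones(5), frame_interval=1.0)
        with pytest.raises(PairingError, match="late"):
            align_two_channel([(a, late)])

    def test_signal_onset_from_baseline(self):
        rel = np.arange(-30, 30) * 0.5
        mean_i = np.where(rel < 0, 0.02, 0.02)
        mean_i = mean_i + np.where(rel >= 5.0, 0.5, 0.0)
        ens = AlignedEnsemble(
            rel_times=rel, mean_intensity=mean_i, sd_intensity=np.zeros(len(rel)),
            mean_displacement=np.zeros(len(rel)), sd_displacement=np.zeros(len(rel)),
            n_per_bin=np.full(len(rel), 4),
        )
        assert signal_onset(ens, baseline_end=0.0) == pytest.approx(5.0)


class TestReferenceBatch:
    def test_compute_references_logs_failures_as_none(self, make_track):
        good = step_track(track_id="ok")
        static = make_track([0.0] * 30, track_id="static")
        refs = compute_references([good, static], "inflection")
        assert refs[0] is not None
        assert refs[1] is None
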