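"""Spot detection, linking, off-rate and diffusion estimation."""

import numpy as np
import pytest

from endotrace import tracking
from endotrace.sim import generate_movie
from endotrace.sim import presets as preset_lib
from endotrace.sim.movies import _add_psf


def render_spot(x_px, y_px, amp=263.5, shape=(40, 40), baseline=30.0, sigma=1.2, noise_sd=0.0, rng=None):
    frame = np.full(shape, baseline)
    _add_psf(frame, x_px, y_px, amp, sigma)
    if noise_sd and rng is not None:
        frame = frame + rng.normal(0, noise_sd, shape)
    return frame


class TestDetectParticles:
    def test_well_separated_spots_both_found(self):
        frame = render_spot(12.0, 12.0)
        _add_psf(frame, 22.0, 12.0, 263.5, 1.2)
        dets = tracking.detect_particles(frame, pixel_size=0.1)
        assert len(dets) == 2

    def test_localisation_error_below_a_third_of_a_pixel(self, rng):
        errs = []
        for _ in range(60):
            x = 15.0 + rng.uniform(-0.5, 0.5)
            y = 17.0 + rng.uniform(-0.5, 0.5)
            # SNR ~10: peak ~27 AU over sd ~2.7
            frame = render_spot(x, y, noise_sd=2.7, rng=rng)
            dets = tracking.detect_particles(frame, pixel_size=0.1, threshold_mads=5.0)
            assert dets, "spot not detected"
            best = min(dets, key=lambda d: np.hypot(d.x_um / 0.1 - 0.5 - x, d.y_um / 0.1 - 0.5 - y))
            errs.append(np.hypot(best.x_um / 0.1 - 0.5 - x, best.y_um / 0.1 - 0.5 - y))
        assert np.sqrt(np.mean(np.square(errs))) <= 0.3

    def test_blank_frames_rarely_fire(self, rng):
        hits = 0
        for _ in range(30):
            frame = rng.normal(30.0, 6.0, (63, 63))  # ~40 um^2 field
            hits += len(tracking.detect_particles(frame, pixel_size=0.1))
        # < 0.02 false spots per um^2 per frame
        assert hits / (30 * 39.7) < 0.02

    def test_integrated_intensity_near_analytic_capture(self):
        frame = render_spot(20.0, 20.0)
        det = tracking.detect_particles(frame, pixel_size=0.1)[0]
        from test_sim_movies import capture_fraction_5x5

        assert det.intensity == pytest.approx(263.5 * capture_fraction_5x5(1.2), rel=0.02)


class TestLinking:
    def test_immobile_spot_one_track(self):
        dets = [[tracking.Detection(5.0, 5.0, 100.0)] for _ in range(50)]
        trs = tracking.link_trajectories(dets, frame_interval=0.016)
        assert len(trs) == 1 and trs[0].n_frames == 50

    def test_crossing_tracks_terminate_without_swapping(self):
        # two spots approach within max_displacement: ambiguity, both end
        dets = []
        for t in range(10):
            xa, xb = 2.0 + 0.12 * t, 4.0 - 0.12 * t
            dets.append([tracking.Detection(xa, 3.0, 1.0), tracking.Detection(xb, 3.0, 1.0)])
        trs = tracking.link_trajectories(dets, max_displacement=0.3, frame_interval=0.016)
        assert len(trs) >= 4  # both originals ended at the crossing, new ones started
        assert max(t.n_frames for t in trs) < 10

    def test_single_gap_bridged(self):
        dets = [[tracking.Detection(5.0, 5.0, 1.0)] for _ in range(10)]
        dets[4] = []  # one missed frame
        trs = tracking.link_trajectories(dets, max_gap=1, frame_interval=0.016)
        assert len(trs) == 1 and trs[0].n_frames == 9

    def test_long_absence_closes_track(self):
        dets = [[tracking.Detection(5.0, 5.0, 1.0)] for _ in range(10)]
        dets[4] = []
        dets[5] = []
        trs = tracking.link_trajectories(dets, max_gap=1, frame_interval=0.016)
        assert sorted(t.n_frames for t in trs) == [4, 4]


class TestOffRate:
    def test_closed_form_on_degenerate_sample(self):
        k0, min_dur = 5.0, 0.1
        durations = np.full(30, min_dur + 1.0 / k0)
        est = tracking.estimate_off_rate(durations, frame_interval=0.0, min_duration=min_dur)
        assert est.rate == pytest.approx(k0)

    def test_short_durations_excluded_from_n(self, rng):
        good = rng.exponential(0.2, 100) + 0.1
        bad = np.full(50, 0.01)
        est = tracking.estimate_off_rate(np.concatenate([good, bad]), 0.0, min_duration=0.1)
        assert est.n == 100

    def test_too_few_dwells_rejected(self):
        with pytest.raises(ValueError):
            tracking.estimate_off_rate([1.0] * 10, 0.0, min_duration=0.0)

    @pytest.mark.parametrize("k", [2.0, 7.8, 15.0])
    def test_frame_quantised_estimator_unbiased(self, k, rng):
        dt = 1.0 / 63
        estimates = []
        for _ in range(30):
            T = rng.exponential(1.0 / k, 400)
            phase = rng.uniform(0, 1, 400)
            n = np.floor(phase + T / dt).astype(int)
            d = n[n >= 2] * dt
            estimates.append(tracking.estimate_off_rate(d, dt, 2 * dt, n_boot=0).rate)
        assert np.mean(estimates) == pytest.approx(k, rel=0.05)


class TestDiffusion:
    def brownian_tracks(self, rng, d_coef, n_tracks=120, n_frames=20, dt=1 / 63, loc_sd=0.0):
        out = []
        for _ in range(n_tracks):
            steps = rng.normal(0, np.sqrt(2 * d_coef * dt), (n_frames - 1, 2))
            pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)]) + rng.uniform(2, 18, 2)
            if loc_sd:
                pos = pos + rng.normal(0, loc_sd, pos.shape)
            out.append(
                tracking.Trajectory(
                    frames=np.arange(n_frames), x_um=pos[:, 0], y_um=pos[:, 1],
                    intensities=np.full(n_frames, 1.0), frame_interval=dt,
                )
            )
        return out

    def test_immobile_noiseless_gives_zero(self, rng):
        est = tracking.estimate_diffusion(self.brownian_tracks(rng, 0.0), n_boot=0)
        assert est.D == pytest.approx(0.0, abs=1e-12)

    def test_brownian_slope_is_4d(self, rng):
        est = tracking.estimate_diffusion(self.brownian_tracks(rng, 0.03, n_tracks=150), n_boot=0)
        assert est.D == pytest.approx(0.03, rel=0.1)
        assert est.r_squared > 0.99

    def test_localisation_noise_goes_to_intercept(self, rng):
        loc_sd = 0.03
        est = tracking.estimate_diffusion(self.brownian_tracks(rng, 0.0, loc_sd=loc_sd), n_boot=0)
        assert est.D == pytest.approx(0.0, abs=0.002)
        assert est.intercept == pytest.approx(4 * loc_sd**2, rel=0.3)

    def test_no_qualifying_tracks_rejected(self):
        short = tracking.Trajectory(np.arange(3), np.zeros(3), np.zeros(3), np.ones(3), 0.016)
        with pytest.raises(ValueError):
            tracking.estimate_diffusion([short])


class TestEndToEnd:
    def test_dwell_distribution_matches_ground_truth(self):
        from scipy import stats

        kin, cam = preset_lib.single_molecule_preset()
        movie, truth = generate_movie([], kin, cam, (15.0, 15.0), 8.0, seed=21)
        trs = tracking.track_movie(movie)
        interior = tracking.filter_interior_tracks(trs, (15.0, 15.0), 1.0)
        measured = [t.n_frames for t in interior if t.n_frames >= 2]
        margin = 1.0
        true_frames = [
            t.n_frames
            for t in truth.tracks
            if t.n_frames >= 2
            and t.x_um.min() >= margin and t.x_um.max() <= 14.0
            and t.y_um.min() >= margin and t.y_um.max() <= 14.0
        ]
        assert len(measured) >= 0.9 * len(true_frames)
        ks = stats.ks_2samp(measured, true_frames)
        assert ks.pvalue > 0.01
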