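"""Quantification macro: seed, annulus background, threshold, ROI, mass.

Every arithmetic operation is checked against the exhaustive per-pixel loop
oracles in conftest, plus the scaling/translation symmetries the integrated
intensity must obey.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_annulus_stats, oracle_flood_fill, oracle_mass
from pcmquant.ingest import Projection
from pcmquant.quantify import (
    BackgroundEstimate,
    QuantConfig,
    compute_threshold,
    detect_seed,
    estimate_background,
    integrated_mass,
    quantify_movie,
    segment_roi,
)

CFG = QuantConfig()


def random_frame(seed, ny=None, nx=None):
    rng = np.random.default_rng(seed)
    ny = ny or int(rng.integers(24, 64))
    nx = nx or int(rng.integers(24, 64))
    return rng.normal(500, 30, size=(ny, nx))


class TestDetectSeed:
    def test_single_bright_pixel_found(self):
        frame = np.zeros((50, 60))
        frame[20, 30] = 1000.0
        assert detect_seed(frame, CFG).yx == (20, 30)

    def test_tie_breaks_to_smallest_y_then_x(self):
        frame = np.zeros((40, 40))
        frame[5, 5] = frame[9, 9] = 100.0
        assert detect_seed(frame, QuantConfig(blur_sigma=0)).yx == (5, 5)

    def test_prior_restricts_search_window(self):
        frame = np.zeros((60, 60))
        frame[10, 10] = 500.0   # global max, far away
        frame[40, 42] = 100.0   # local max near prior
        seed = detect_seed(frame, CFG, prior=(40, 40))
        assert seed.yx == (40, 42)

    def test_tracking_off_ignores_prior(self):
        cfg = QuantConfig(track_seed_per_frame=False)
        frame = np.zeros((60, 60))
        frame[10, 10] = 500.0
        assert detect_seed(frame, cfg, prior=(40, 40)).yx == (10, 10)

    def test_constant_frame_flagged_low_confidence(self):
        seed = detect_seed(np.full((30, 30), 7.0), CFG)
        assert seed.low_confidence

    def test_rendered_spot_center_recovered(self, spot_frame):
        frame = spot_frame(center=(40.0, 25.0), shape=(64, 64))
        seed = detect_seed(frame, CFG)
        assert abs(seed.y - 40) <= 1 and abs(seed.x - 25) <= 1

    def test_too_small_frame_rejected(self):
        with pytest.raises(ValueError, match="outer_radius"):
            detect_seed(np.zeros((10, 10)), CFG)


class TestEstimateBackground:
    def test_constant_frame(self):
        bg = estimate_background(np.full((40, 40), 7.0), (20, 20), CFG)
        assert bg.mean_bg == 7.0
        assert bg.stdev_bg == 0.0
        assert not bg.edge_clipped

    def test_spot_inside_inner_radius_excluded(self, spot_frame):
        # sigma=1 spot decays to ~0 well inside r=7
        frame = spot_frame(mass=10_000, center=(20.0, 20.0), background=50.0,
                           shape=(41, 41), sigma=1.0)
        bg = estimate_background(frame, (20, 20), CFG)
        assert bg.mean_bg == pytest.approx(50.0, abs=1e-6)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_pixel_loop_oracle(self, seed):
        frame = random_frame(seed)
        rng = np.random.default_rng(seed + 1)
        cy = int(rng.integers(0, frame.shape[0]))
        cx = int(rng.integers(0, frame.shape[1]))
        bg = estimate_background(frame, (cy, cx), CFG)
        mean, sd, n = oracle_annulus_stats(frame, (cy, cx), 7.0, 10.0)
        assert bg.mean_bg == pytest.approx(mean, rel=1e-12)
        assert bg.stdev_bg == pytest.approx(sd, rel=1e-9)
        assert bg.n_pixels == n

    def test_edge_clipped_flagged(self):
        bg = estimate_background(np.zeros((40, 40)), (0, 0), CFG)
        assert bg.edge_clipped
        assert bg.n_pixels < estimate_background(np.zeros((40, 40)), (20, 20), CFG).n_pixels

    def test_sample_stdev_option(self):
        frame = random_frame(3)
        pop = estimate_background(frame, (15, 15), QuantConfig(stdev_ddof=0))
        samp = estimate_background(frame, (15, 15), QuantConfig(stdev_ddof=1))
        assert samp.stdev_bg > pop.stdev_bg

    def test_center_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(np.zeros((30, 30)), (35, 10), CFG)


class TestComputeThreshold:
    @pytest.mark.parametrize(
        "mean,sd,k,expected",
        [(100.0, 10.0, 3.0, 130.0), (100.0, 0.0, 3.0, 100.0), (100.0, 10.0, 0.0, 100.0)],
    )
    def test_formula(self, mean, sd, k, expected):
        bg = BackgroundEstimate(center=(0, 0), mean_bg=mean, stdev_bg=sd, n_pixels=5)
        assert compute_threshold(bg, QuantConfig(k_sigma=k)) == expected


class TestSegmentRoi:
    def test_block_above_threshold(self):
        frame = np.full((30, 30), 100.0)
        frame[10:15, 10:15] = 200.0
        roi = segment_roi(frame, 130.0, (12, 12), CFG)
        assert roi.sum() == 25

    def test_subthreshold_seed_gives_empty_roi(self):
        frame = np.full((30, 30), 100.0)
        roi = segment_roi(frame, 130.0, (12, 12), CFG)
        assert not roi.any()
        assert integrated_mass(frame, roi, 130.0) == 0.0

    def test_seed_selects_its_own_blob(self):
        frame = np.full((40, 40), 0.0)
        frame[5:15, 5:15] = 10.0   # big blob
        frame[25:28, 25:28] = 10.0  # small blob containing the seed
        roi = segment_roi(frame, 5.0, (26, 26), CFG)
        assert roi.sum() == 9
        assert not roi[10, 10]

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        frame = rng.normal(0, 1, size=(28, 28))
        sy, sx = int(rng.integers(0, 28)), int(rng.integers(0, 28))
        thr = float(rng.normal(0, 0.5))
        roi = segment_roi(frame, thr, (sy, sx), CFG)
        expected = oracle_flood_fill(frame, thr, (sy, sx))
        assert {(y, x) for y, x in zip(*np.nonzero(roi))} == expected

    def test_non_finite_threshold_rejected(self):
        with pytest.raises(ValueError):
            segment_roi(np.zeros((20, 20)), np.nan, (5, 5), CFG)


class TestIntegratedMass:
    def test_uniform_roi(self):
        frame = np.full((20, 20), 100.0)
        frame[5:10, 5:15] = 200.0  # 50 px
        roi = segment_roi(frame, 130.0, (7, 7), CFG)
        assert integrated_mass(frame, roi, 130.0) == pytest.approx(3500.0)

    def test_sum_of_excess(self):
        frame = np.full((20, 20), 0.0)
        frame[3, 3:6] = [131.0, 132.0, 133.0]
        roi = segment_roi(frame, 130.0, (3, 4), CFG)
        assert integrated_mass(frame, roi, 130.0) == pytest.approx(6.0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        frame = rng.normal(100, 20, size=(32, 32))
        sy, sx = int(rng.integers(0, 32)), int(rng.integers(0, 32))
        thr = 100.0
        roi = segment_roi(frame, thr, (sy, sx), CFG)
        pixels = {(y, x) for y, x in zip(*np.nonzero(roi))}
        assert integrated_mass(frame, roi, thr) == pytest.approx(
            oracle_mass(frame, pixels, thr), rel=1e-12, abs=1e-9
        )

    def test_adding_nonnegative_signal_never_decreases_mass(self, rng):
        frame = rng.normal(100, 10, size=(30, 30))
        seed = (15, 15)
        frame[seed] = 200.0
        thr = 120.0
        roi = segment_roi(frame, thr, seed, CFG)
        base = integrated_mass(frame, roi, thr)
        bumped = frame.copy()
        bumped[roi] += rng.uniform(0, 5, size=int(roi.sum()))
        assert integrated_mass(bumped, roi, thr) >= base


class TestSymmetries:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 5000), c=st.floats(0.1, 50.0))
    def test_affine_scaling_covariance(self, seed, c):
        """c*F scales mean, stdev, threshold and mass by exactly c and
        preserves ROI membership (strict > survives positive scaling)."""
        frame = random_frame(seed, 40, 40)
        frame = frame - frame.min() + 1.0  # positive
        center = (20, 20)
        bg1 = estimate_background(frame, center, CFG)
        thr1 = compute_threshold(bg1, CFG)
        roi1 = segment_roi(frame, thr1, center, CFG)
        m1 = integrated_mass(frame, roi1, thr1)

        bg2 = estimate_background(c * frame, center, CFG)
        thr2 = compute_threshold(bg2, CFG)
        roi2 = segment_roi(c * frame, thr2, center, CFG)
        m2 = integrated_mass(c * frame, roi2, thr2)

        assert bg2.mean_bg == pytest.approx(c * bg1.mean_bg, rel=1e-9)
        assert bg2.stdev_bg == pytest.approx(c * bg1.stdev_bg, rel=1e-9)
        assert thr2 == pytest.approx(c * thr1, rel=1e-9)
        np.testing.assert_array_equal(roi1, roi2)
        assert m2 == pytest.approx(c * m1, rel=1e-9, abs=1e-9)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 5000), dy=st.integers(-5, 5), dx=st.integers(-5, 5))
    def test_integer_translation_leaves_scalars_unchanged(self, seed, dy, dx):
        frame = random_frame(seed, 48, 48)
        shifted = np.roll(np.roll(frame, dy, axis=0), dx, axis=1)
        c0 = (24, 24)
        c1 = (24 + dy, 24 + dx)
        bg0 = estimate_background(frame, c0, CFG)
        bg1 = estimate_background(shifted, c1, CFG)
        # np.roll wraps, so stay away from borders: annulus r=10 < 24-5-10
        assert bg1.mean_bg == pytest.approx(bg0.mean_bg, rel=1e-12)
        assert bg1.stdev_bg == pytest.approx(bg0.stdev_bg, rel=1e-12)
        thr = compute_threshold(bg0, CFG)
        m0 = integrated_mass(frame, segment_roi(frame, thr, c0, CFG), thr)
        m1 = integrated_mass(shifted, segment_roi(shifted, thr, c1, CFG), thr)
        assert m1 == pytest.approx(m0, rel=1e-12, abs=1e-9)

    def test_pure_background_yields_zero_mass_almost_always(self):
        """With a +3 sigma threshold, an i.i.d. background frame measured at
        a given centre produces zero mass in at least 95% of trials."""
        rng = np.random.default_rng(7)
        zero = 0
        n_trials = 200
        for _ in range(n_trials):
            frame = rng.normal(500, 20, size=(40, 40))
            center = (20, 20)
            bg = estimate_background(frame, center, CFG)
            thr = compute_threshold(bg, CFG)
            roi = segment_roi(frame, thr, center, CFG)
            if integrated_mass(frame, roi, thr) == 0.0:
                zero += 1
        assert zero / n_trials >= 0.95


def make_projection(frames, dt=10.0):
    return Projection(
        data=np.asarray(frames, dtype=float),
        frame_interval_s=dt, pixel_size_um=0.11, nebd_frame=0,
    )


class TestQuantifyMovie:
    def test_threshold_fixed_from_first_frame(self, spot_frame):
        f0 = spot_frame(mass=30_000)
        f1 = spot_frame(mass=30_000, background=800.0)  # background jumps later
        quants = quantify_movie(make_projection([f0, f1, f1]))
        assert len({q.threshold for q in quants}) == 1
        bg0 = estimate_background(f0, quants[0].seed, CFG)
        assert quants[0].threshold == pytest.approx(compute_threshold(bg0, CFG))

    def test_static_noiseless_spot_mass_tracks_truth(self, spot_frame):
        masses = [20_000, 40_000, 80_000, 40_000]
        frames = [spot_frame(mass=m) for m in masses]
        quants = quantify_movie(make_projection(frames))
        for q, m in zip(quants, masses):
            assert q.integrated_mass == pytest.approx(m, rel=0.05)

    def test_vanished_spot_reports_zero_with_flag(self, spot_frame):
        frames = [spot_frame(mass=30_000)] * 3 + [spot_frame(mass=0.0)] * 2
        quants = quantify_movie(make_projection(frames))
        for q in quants[3:]:
            assert q.integrated_mass == 0.0
            assert "empty_roi" in q.flags

    def test_tracking_follows_moving_spot(self, spot_frame):
        frames = [spot_frame(mass=50_000, center=(24.0, 20.0 + 3 * i), shape=(48, 72))
                  for i in range(8)]
        quants = quantify_movie(make_projection(frames))
        assert abs(quants[-1].seed[1] - 41) <= 1
        for q in quants:
            assert q.integrated_mass == pytest.approx(50_000, rel=0.05)

    def test_merged_mode_halves_mass(self, spot_frame):
        frame = spot_frame(mass=30_000, center=(24.0, 20.0), shape=(48, 48))
        frame += spot_frame(mass=30_000, center=(24.0, 28.0), shape=(48, 48),
                            background=0.0)
        plain = quantify_movie(make_projection([frame]),
                               QuantConfig(merged_inner_radius=14,
                                           merged_outer_radius=20))
        merged = quantify_movie(make_projection([frame]),
                                QuantConfig(merged_mode=True))
        assert "merged_halved" in merged[0].flags
        # merged result is a per-centrosome average of the unresolvable pair
        assert merged[0].integrated_mass == pytest.approx(30_000, rel=0.15)
        # the narrow annulus lands on the companion spot, inflating the
        # threshold and collapsing the naive measurement
        assert plain[0].integrated_mass < 0.2 * merged[0].integrated_mass

    def test_mean_area_threshold_identity(self, spot_frame):
        quants = quantify_movie(make_projection([spot_frame(mass=40_000)]))
        q = quants[0]
        assert q.integrated_mass == pytest.approx(
            (q.mean_roi - q.threshold) * q.area_roi, rel=1e-9
        )


class TestConfig:
    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            QuantConfig(inner_radius=10, outer_radius=7)

    def test_yaml_overrides(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("inner_radius: 5\nouter_radius: 8\nk_sigma: 2\n")
        cfg = QuantConfig.from_yaml(path)
        assert cfg.radii == (5, 8)
        assert cfg.k_sigma == 2
        assert cfg.blur_sigma == 1.0
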