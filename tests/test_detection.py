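import numpy as np
import pandas as pd
import pytest

import roakit as rk
from roakit.detection import ConsistencyError
from roakit.synthetic import SynthParams, simulate_movie, simulate_noise_only


def make_maps(mu, sigma, shape=(8, 8)):
    mu_map = np.full(shape, mu)
    sigma_map = np.full(shape, sigma)
    snr = mu / sigma if sigma > 0 else float("nan")
    return rk.PixelStatMaps(mu_map=mu_map, sigma_map=sigma_map, mu_global=mu,
                            sigma_global=sigma, snr=snr, n_dead=0)


class TestThresholdMap:
    def test_printed_formula(self):
        maps = make_maps(3.0, 0.5)
        np.testing.assert_allclose(rk.threshold_map(maps, kappa=4.0), 5.0)

    def test_kappa_zero_gives_mu(self):
        maps = make_maps(3.0, 0.5)
        with pytest.raises(ValueError):
            rk.DetectionConfig(kappa=0)  # config forbids it...
        # ...but the map operation itself follows the formula
        np.testing.assert_allclose(rk.threshold_map(maps, kappa=1e-12),
                                   maps.mu_map, atol=1e-9)

    def test_dead_pixels_never_active(self):
        mu = np.full((4, 4), 3.0)
        sigma = np.full((4, 4), 0.5)
        sigma[1, 2] = 0.0
        maps = rk.PixelStatMaps(mu_map=mu, sigma_map=sigma, mu_global=3.0,
                                sigma_global=0.5, snr=6.0, n_dead=1)
        tau = rk.threshold_map(maps, kappa=4.0)
        assert np.isinf(tau[1, 2])
        assert np.isfinite(tau).sum() == 15

    def test_ignore_mask_infinite(self):
        maps = make_maps(3.0, 0.5, (4, 4))
        ignore = np.zeros((4, 4), bool)
        ignore[0] = True
        tau = rk.threshold_map(maps, 4.0, ignore=ignore)
        assert np.isinf(tau[0]).all() and np.isfinite(tau[1:]).all()


class TestBinarize:
    def test_constant_movie_all_false(self, tmp_path):
        movie = np.full((120, 8, 8), 100, dtype=np.uint16)
        src = rk.write_movie(tmp_path / "c.h5", movie, rk.MovieMeta(120, 8, 8))
        smoothing = rk.SmoothingConfig()
        from roakit.detection import _estimation_stack
        maps = rk.compute_stat_maps(_estimation_stack(src, smoothing, 64))
        mask = rk.binarize_movie(src, smoothing, maps,
                                 rk.DetectionConfig(edge_ignore=0))
        assert not mask.any()

    def test_planted_strong_transient_mostly_active(self, tmp_path, rng):
        """An 8x8x20 block at +8 sigma above baseline is >= 95% detected."""
        T, H, W = 400, 24, 24
        base = 100.0
        noise_sd = 3.0
        movie = rng.normal(base, noise_sd, size=(T, H, W))
        # +8 sigma in sqrt units: sqrt(base)+8*s_x, s_x = noise_sd/(2 sqrt(base))
        s_x = noise_sd / (2 * np.sqrt(base))
        bump = (np.sqrt(base) + 8 * s_x) ** 2 - base
        movie[100:120, 8:16, 8:16] += bump
        src = rk.write_movie(tmp_path / "p.h5", np.clip(movie, 0, None),
                             rk.MovieMeta(T, H, W))
        smoothing = rk.SmoothingConfig()
        from roakit.detection import _estimation_stack
        maps = rk.compute_stat_maps(_estimation_stack(src, smoothing, 128))
        mask = rk.binarize_movie(src, smoothing, maps,
                                 rk.DetectionConfig(edge_ignore=0))
        inside = mask[100:120, 8:16, 8:16]
        assert inside.mean() >= 0.95

    def test_noise_false_positive_rate(self, rng, tmp_path):
        """kappa=4 on iid noise: active fraction near 1 - Phi(4)."""
        from scipy.stats import norm
        T, H, W = 4000, 32, 32  # 4.1e6 voxels: smoke version of the full check
        movie = rng.normal(900.0, 30.0, size=(T, H, W)).astype(np.float32)
        src = rk.write_movie(tmp_path / "n.h5", movie, rk.MovieMeta(T, H, W))
        smoothing = rk.SmoothingConfig()
        from roakit.detection import _estimation_stack
        maps = rk.compute_stat_maps(_estimation_stack(src, smoothing, 1024))
        mask = rk.binarize_movie(src, smoothing, maps,
                                 rk.DetectionConfig(edge_ignore=0),
                                 chunk_frames=1024)
        frac = mask.mean()
        expected = 1 - norm.cdf(4)
        assert expected / 4 < frac < expected * 4

    def test_shape_mismatch_rejected(self, tmp_path, rng):
        movie = rng.integers(0, 100, (120, 8, 8)).astype(np.uint16)
        src = rk.write_movie(tmp_path / "m.h5", movie, rk.MovieMeta(120, 8, 8))
        maps = make_maps(3.0, 0.5, shape=(6, 6))
        with pytest.raises(ConsistencyError):
            rk.binarize_movie(src, rk.SmoothingConfig(), maps,
                              rk.DetectionConfig())


class TestLabelEvents:
    def test_empty_mask(self):
        labels, n = rk.label_events(np.zeros((5, 4, 4), bool))
        assert n == 0 and not labels.any()

    def test_two_separated_blobs(self):
        mask = np.zeros((10, 8, 8), bool)
        mask[1:3, 1:3, 1:3] = True
        mask[6:8, 5:7, 5:7] = True
        _, n = rk.label_events(mask)
        assert n == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, flood_fill_oracle):
        rng = np.random.default_rng(connectivity)
        for _ in range(40):
            mask = rng.random((12, 10, 10)) < 0.08
            labels, n = rk.label_events(mask, connectivity)
            oracle = flood_fill_oracle(mask, connectivity)
            assert n == oracle.max()
            # identical partition up to relabeling
            pair = labels.astype(np.int64) * (oracle.max() + 1) + oracle
            assert len(np.unique(pair[mask])) == n
            np.testing.assert_array_equal(labels > 0, oracle > 0)


class TestFilterEvents:
    def test_short_single_voxel_dropped(self):
        labels = np.zeros((5, 6, 6), np.int32)
        labels[2, 3, 3] = 1
        out, report = rk.filter_events(
            labels, rk.DetectionConfig(min_size=1, min_duration=2,
                                       edge_ignore=0))
        assert not out.any() and report["n_dropped"] == 1

    def test_no_filters_is_identity(self):
        rng = np.random.default_rng(3)
        mask = rng.random((8, 10, 10)) < 0.1
        labels, _ = rk.label_events(mask)
        out, report = rk.filter_events(
            labels, rk.DetectionConfig(min_size=1, min_duration=1,
                                       edge_ignore=0))
        np.testing.assert_array_equal(out, labels)
        assert report["n_dropped"] == 0

    def test_ignore_band_trimmed(self):
        """Events straddling an ignored 5-px edge band leave no active voxel
        inside the band."""
        T, H, W = 12, 20, 20
        mask = np.zeros((T, H, W), bool)
        mask[3:9, 2:10, 2:10] = True   # straddles the 5-px band
        labels, _ = rk.label_events(mask)
        cfg = rk.DetectionConfig(min_size=1, min_duration=1, edge_ignore=5)
        out, _ = rk.filter_events(labels, cfg)
        band = cfg.resolve_ignore(H, W)
        assert not out[:, band].any()
        assert out.any()  # interior part survives


class TestSummarize:
    def test_single_voxel_event(self):
        labels = np.zeros((10, 6, 6), np.int32)
        labels[5, 2, 3] = 1
        meta = rk.MovieMeta(10, 6, 6, frame_rate=30.0, pixel_size=1.0)
        tab = rk.summarize_events(labels, meta)
        row = tab.iloc[0]
        assert (row.x, row.y, row.t) == (3, 2, 5)
        assert row.duration_frames == 1
        assert row.duration_s == pytest.approx(1 / 30)
        assert row.area_um2 == pytest.approx(1.0)
        assert row.n_voxels == 1

    def test_box_event(self):
        labels = np.zeros((20, 8, 8), np.int32)
        labels[5:15, 2:4, 3:5] = 1
        meta = rk.MovieMeta(20, 8, 8, frame_rate=10.0, pixel_size=2.0)
        tab = rk.summarize_events(labels, meta)
        row = tab.iloc[0]
        assert row.duration_frames == 10
        assert row.area_um2 == pytest.approx(4 * 2.0 ** 2)
        assert row.n_voxels == 40
        assert row.start_frame == 5 and row.end_frame == 14

    def test_random_blobs_match_recomputation(self):
        rng = np.random.default_rng(11)
        mask = rng.random((15, 12, 12)) < 0.07
        labels, n = rk.label_events(mask)
        meta = rk.MovieMeta(15, 12, 12, frame_rate=20.0, pixel_size=0.8)
        tab = rk.summarize_events(labels, meta).set_index("event_id")
        for ev in range(1, n + 1):
            t, y, x = np.nonzero(labels == ev)
            row = tab.loc[ev]
            assert row.start_frame == t.min()
            assert row.end_frame == t.max()
            assert row.duration_frames == t.max() - t.min() + 1
            assert row.n_voxels == t.size
            assert row.footprint_px == len(set(zip(y, x)))
            assert row.area_um2 == pytest.approx(
                len(set(zip(y, x))) * 0.8 ** 2)
            assert row.x == pytest.approx(x.mean())
            assert row.y == pytest.approx(y.mean())
            assert row.t == pytest.approx(t.mean())


class TestTraces:
    def test_all_false_mask(self):
        meta = rk.MovieMeta(10, 4, 4, frame_rate=10.0)
        traces = rk.compute_traces(np.zeros((10, 4, 4), bool),
                                   rk.summarize_events(
                                       np.zeros((10, 4, 4), np.int32), meta),
                                   meta)
        assert (traces.density == 0).all() and (traces.frequency == 0).all()

    def test_full_frame_density_100(self):
        meta = rk.MovieMeta(10, 4, 4, frame_rate=10.0)
        mask = np.zeros((10, 4, 4), bool)
        mask[3] = True
        labels, _ = rk.label_events(mask)
        traces = rk.compute_traces(mask, rk.summarize_events(labels, meta),
                                   meta)
        assert traces.density[3] == pytest.approx(100.0)
        assert traces.density[4] == 0

    def test_frequency_sums_to_event_count(self):
        rng = np.random.default_rng(4)
        mask = rng.random((30, 16, 16)) < 0.03
        labels, n = rk.label_events(mask)
        meta = rk.MovieMeta(30, 16, 16, frame_rate=30.0)
        table = rk.summarize_events(labels, meta)
        traces = rk.compute_traces(mask, table, meta)
        assert traces.frequency.sum() == n == len(table)


@pytest.fixture(scope="module")
def planted_src(tmp_path_factory):
    d = tmp_path_factory.mktemp("roa")
    params = SynthParams(shape=(300, 64, 64), baseline=60.0, gain_a=2.0,
                         offset_b=5.0, event_rate_per_min=60.0,
                         amplitude_sd=8.0, duration_bounds=(6, 30),
                         radius_bounds=(2.5, 5.0), seed=21)
    src, truth = simulate_movie(params, out_path=d / "m.h5")
    return src, truth


class TestRunRoa:
    def test_outputs_persisted(self, planted_src, tmp_path):
        src, _ = planted_src
        store = rk.SidecarStore(src.uri)
        result = rk.run_roa(src, smoothing=rk.SmoothingConfig(), store=store)
        assert store.has("roa_table") and store.has("roa_traces")
        assert store.has("roa_mask_ch0")
        assert len(result.table) > 0

    def test_chunk_sizes_bit_identical(self, planted_src):
        src, _ = planted_src
        smoothing = rk.SmoothingConfig(sigma_px=1.0, n_frames=5)
        results = [rk.run_roa(src, smoothing=smoothing, chunk_frames=c)
                   for c in (50, 300)]
        np.testing.assert_array_equal(results[0].mask, results[1].mask)
        pd.testing.assert_frame_equal(results[0].table, results[1].table)
        np.testing.assert_array_equal(results[0].traces.density,
                                      results[1].traces.density)

    def test_noise_only_movie_yields_no_events(self, tmp_path):
        params = SynthParams(shape=(600, 48, 48), baseline=400.0, gain_a=1.0,
                             offset_b=0.0, event_rate_per_min=0.0, seed=5)
        src = simulate_noise_only(params, out_path=tmp_path / "n.h5")
        result = rk.run_roa(src, smoothing=rk.SmoothingConfig())
        assert len(result.table) == 0

    def test_kappa_monotonicity(self, planted_src):
        src, _ = planted_src
        smoothing = rk.SmoothingConfig()
        counts = []
        voxels = []
        for kappa in (3.0, 4.0, 5.0, 6.0):
            res = rk.run_roa(src, smoothing=smoothing,
                             config=rk.DetectionConfig(kappa=kappa))
            counts.append(len(res.table))
            voxels.append(int(res.mask.sum()))
        assert counts == sorted(counts, reverse=True) or \
            all(a >= b for a, b in zip(counts, counts[1:]))
        assert all(a >= b for a, b in zip(voxels, voxels[1:]))

    def test_detection_recovery_on_ground_truth(self, planted_src):
        """Planted events >= 6 sigma, >= 3x3 px, >= 5 frames at SNR >= 9 are
        recovered with precision and recall >= 0.9."""
        src, truth = planted_src
        result = rk.run_roa(src)  # auto-configured
        assert result.smoothing.achieved_snr >= 9.0
        m = rk.match_events(result.labels, truth, iou_min=0.3)
        assert m.precision >= 0.9
        assert m.recall >= 0.9
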