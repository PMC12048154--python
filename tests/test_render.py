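import numpy as np
import pytest

from grinsim import activity as act
from grinsim import optics as opt
from grinsim import render as rnd
from grinsim import tissue as tis
from _oracles import brute_force_noiseless_render, brute_force_pixel_sampling


def tilted_optics():
    """Shell focal surface (tilted normals) over a 50 µm FOV."""
    return opt.OpticsModel(
        probe_type="uncorrected-6.4",
        focal_surface=opt.FocalSurfaceModel(
            "spherical_shells", shell_radii=(80.0, 300.0), center_depth=30.0, sign=1.0
        ),
        psf=opt.PSFSizeModel(axial=(0.0, 1e-3, 8.0), lateral=(0.0, 1e-4, 3.0)),
        magnification=opt.MagnificationModel(dist=(0.0, 1e-5, 1.0, 0.0)),
        intensity=opt.RadialIntensityProfile(a2=-1e-4),
        fov_um=50.0,
        edge_radius_um=30.0,
        shell_weights=(0.5, 0.5),
    )


class TestMixingMatrix:
    def test_empty_tissue_all_zero(self, flat_optics):
        tv = tis.TissueVolume(
            np.array([50.0, 50.0, 50.0]),
            np.array([1.0, 1.0, 1.0]),
            [],
            0.0,
            0.0,
        )
        labels = tis.rasterize(tv)
        mix, _ = rnd.build_mixing_matrix(
            tv, labels, flat_optics, 8, rnd.NoiseModel(), rng=np.random.default_rng(0)
        )
        assert mix.weights.nnz == 0
        assert np.all(mix.occupancy == 0)

    @pytest.mark.parametrize("optics_fn", ["flat", "tilted"])
    def test_weights_equal_exhaustive_voxel_count(
        self, optics_fn, flat_optics, single_neuron_tissue
    ):
        optics = flat_optics if optics_fn == "flat" else tilted_optics()
        tv = single_neuron_tissue
        labels = tis.rasterize(tv)
        noise = rnd.NoiseModel()
        rng = np.random.default_rng(1)
        bg = rnd.sample_background_field(labels.shape, noise, rng)
        mix, _ = rnd.build_mixing_matrix(tv, labels, optics, 12, noise, bg_mean_field=bg)
        grid, samples = brute_force_pixel_sampling(tv, labels, optics, 12, bg, noise)
        for sh, ref in zip(mix.shells, samples):
            assert np.array_equal(sh.n_in, ref["n_in"])
            assert np.array_equal(sh.n_nucleus, ref["n_nuc"])
            assert np.array_equal(np.asarray(sh.counts.todense()), ref["counts"])
            assert np.allclose(sh.bg_mean_sum, ref["bg_sum"], rtol=1e-12)
            assert np.allclose(sh.bg_sd2_sum, ref["bg_sd2"], rtol=1e-12)

    def test_neuron_beyond_focal_reach_has_zero_weight(self, flat_optics):
        # focal plane at 25 µm, axial semi-extent 5 µm, soma radius 6 µm:
        # a neuron centred at 45 µm depth can never intersect the ellipsoid
        n = tis.NeuronGeom(0, np.array([25.0, 25.0, 45.0]), 6.0, 2.0)
        tv = tis.TissueVolume(
            np.array([50.0, 50.0, 60.0]),
            np.array([0.8, 0.8, 1.0]),
            [n],
            0.0,
            0.0,
        )
        labels = tis.rasterize(tv)
        mix, _ = rnd.build_mixing_matrix(
            tv, labels, flat_optics, 10, rnd.NoiseModel(), rng=np.random.default_rng(0)
        )
        assert mix.weights.nnz == 0


class TestNoiseMaps:
    def test_edge_mixture_mean_matches_arithmetic(self):
        # population mean of the two-component mixture:
        # 0.35 * 137.48 + 0.65 * 126.83 = 130.5575
        noise = rnd.NoiseModel()
        optics = opt.default_optics("corrected-6.4")
        grid = rnd.make_pixel_grid(optics, 400, (400.0, 400.0, 170.0))
        maps = rnd.sample_static_noise_maps(noise, grid, np.random.default_rng(3))
        n = maps["edge_mean"].size
        assert n > 1e4
        mix_mean = noise.edge_mixture_mean()
        mix_var = sum(
            w * (sd**2 + (m - mix_mean) ** 2) for w, m, sd in noise.edge_gmm
        )
        se = np.sqrt(mix_var / n)
        assert abs(maps["edge_mean"].mean() - 130.5575) < 3 * se

    def test_edge_sd_linear_law_with_clamp(self):
        noise = rnd.NoiseModel()
        grid = rnd.make_pixel_grid(opt.default_optics("corrected-6.4"), 64, (400.0, 400.0, 170.0))
        maps = rnd.sample_static_noise_maps(noise, grid, np.random.default_rng(4))
        expect = np.clip(-175.39 + 1.57 * maps["edge_mean"], 0.0, None)
        assert np.allclose(maps["edge_sd"], expect)
        # the printed mixture-2 mean lands close to the clamp point
        assert np.clip(-175.39 + 1.57 * 126.83, 0, None) == pytest.approx(23.7331)

    def test_background_sd_sqrt_law(self, flat_optics):
        noise = rnd.NoiseModel()
        grid = rnd.make_pixel_grid(flat_optics, 64, (50.0, 50.0, 50.0))
        maps = rnd.sample_static_noise_maps(noise, grid, np.random.default_rng(5))
        assert np.allclose(maps["bg_sd"], 29.91 + 7.75 * np.sqrt(maps["bg_mean"]))
        # at mean 0 the law gives the intercept
        assert 29.91 + 7.75 * np.sqrt(0.0) == 29.91

    def test_lognormal_space_switch(self):
        log = rnd.NoiseModel()
        lin = rnd.NoiseModel(lognormal_log_space=False)
        assert log.lognormal_params() == (6.54, 0.78)
        mu, sigma = lin.lognormal_params()
        # linear-space interpretation: matching mean and SD
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(6.54)


class TestRender:
    def _small_setup(self, duration=2.0, seed=6):
        tv = tis.place_neurons(
            (50, 50, 50),
            density_target=8e4,
            seed=2,
            max_consecutive_rejections=200,
        )
        labels = tis.rasterize(tv)
        activity = act.simulate_activity(tv.n_neurons, duration=duration, seed=seed)
        return tv, labels, activity

    def test_noiseless_render_matches_brute_force(self, flat_optics):
        tv, labels, activity = self._small_setup()
        noise = rnd.NoiseModel()
        rng = np.random.default_rng(8)
        bg = rnd.sample_background_field(labels.shape, noise, rng)
        mix, _ = rnd.build_mixing_matrix(
            tv, labels, flat_optics, 16, noise, bg_mean_field=bg
        )
        movie = rnd.render(
            tv, activity, flat_optics, noise, mixing=mix, n_px=16, noise_on=False,
            seed=9,
        )
        traces = activity.frame_traces(movie.frame_rate)
        grid, ref, occupied = brute_force_noiseless_render(
            tv, labels, flat_optics, 16, bg, noise, traces
        )
        flat = movie.frames.reshape(movie.n_frames, -1)[:, grid.central_idx].T
        assert np.allclose(flat[occupied], ref[occupied], rtol=1e-6)

    def test_zero_noise_movie_constant_without_activity(self, flat_optics):
        tv, labels, _ = self._small_setup()
        quiet = act.simulate_activity(tv.n_neurons, duration=1.0, total_rate=0.0,
                                      shared_rate=0.0, seed=0)
        movie = rnd.render(tv, quiet, flat_optics, rnd.NoiseModel(), labels=labels,
                           n_px=16, noise_on=False, seed=1)
        assert np.allclose(movie.frames, movie.frames[0])

    def test_frame_count_at_30hz(self, flat_optics, single_neuron_tissue):
        tv = single_neuron_tissue
        labels = tis.rasterize(tv)
        activity = act.simulate_activity(1, duration=300.0, seed=0)
        movie = rnd.render(tv, activity, flat_optics, rnd.NoiseModel(),
                           labels=labels, n_px=8, duration=300.0, seed=0)
        assert movie.n_frames == 9000

    def test_same_seed_bit_identical(self, flat_optics):
        tv, labels, activity = self._small_setup(duration=1.0)
        movies = [
            rnd.render(tv, activity, flat_optics, rnd.NoiseModel(), labels=labels,
                       n_px=16, seed=77)
            for _ in range(2)
        ]
        assert np.array_equal(movies[0].frames, movies[1].frames)

    def test_corrected_brighter_than_uncorrected_off_axis(self):
        # one neuron at 90 µm radial distance, placed on each probe's focal
        # surface: the corrected probe's tighter PSF concentrates its signal
        results = {}
        for pt in ("corrected-6.4", "uncorrected-6.4"):
            optics = opt.default_optics(pt)
            depth = float(np.atleast_1d(
                np.asarray(opt.surface_depth(90.0, optics.focal_surface)).ravel()
            )[0])
            n = tis.NeuronGeom(0, np.array([290.0, 200.0, depth]), 10.0, 5.0)
            tv = tis.TissueVolume(
                np.array([400.0, 400.0, 170.0]), np.array([0.8, 0.8, 1.0]),
                [n], 0.0, 0.0,
            )
            labels = tis.rasterize(tv)
            spikes = [np.array([100])]
            activity = act.ActivitySet(
                1, 2.0, 1e-3, spikes, act.build_groups(1, 0.0, 0),
                act.SensorParams(), 0.3, 0.0,
            )
            movie = rnd.render(tv, activity, optics, rnd.NoiseModel(),
                               labels=labels, n_px=64, noise_on=False, seed=0)
            amp = (movie.frames.max(axis=0) - movie.frames.min(axis=0)).max()
            results[pt] = amp
        assert results["corrected-6.4"] > results["uncorrected-6.4"]

    def test_edge_noise_is_stationary(self, flat_optics):
        tv, labels, activity = self._small_setup(duration=4.0)
        import dataclasses
        optics = dataclasses.replace(flat_optics, edge_radius_um=15.0)
        movie = rnd.render(tv, activity, optics, rnd.NoiseModel(),
                           labels=labels, n_px=16, seed=3)
        edge = movie.mixing.grid.edge_mask.reshape(16, 16)
        series = movie.frames[:, edge].mean(axis=1)
        t = np.arange(series.size)
        slope = np.polyfit(t, series, 1)[0]
        # drift over the whole movie small vs the frame-to-frame SD
        assert abs(slope * series.size) < 3 * series.std()
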