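import numpy as np
import pytest

from crowdbd.analysis import (
    alpha_from_min_correlation,
    com_trajectory,
    displacement_autocorrelation,
    estimate_D_blocks,
    fit_alpha,
    gaussianity_check,
    msd_multi_origin,
    time_dependent_D,
)
from crowdbd.model import Trajectory
from crowdbd.synthetic import fbm_path
from crowdbd.units import A2_PER_NS_TO_UM2_PER_S


def _traj_from_positions(positions, radii, mol_index, dt=1.0):
    f = len(positions)
    return Trajectory(
        times=np.arange(f) * dt,
        positions=np.asarray(positions, float),
        radii=np.asarray(radii, float),
        mol_index=np.asarray(mol_index),
        box_length=1000.0,
        metadata={"molecule_ids": ["a", "b"]},
    )


class TestCOM:
    def test_single_sphere(self):
        pos = np.random.default_rng(0).normal(size=(5, 1, 3))
        traj = _traj_from_positions(pos, [10.0], [0])
        np.testing.assert_allclose(com_trajectory(traj, 0), pos[:, 0, :])

    def test_equal_spheres_midpoint(self):
        pos = np.zeros((4, 2, 3))
        pos[:, 1, 0] = 10.0
        traj = _traj_from_positions(pos, [8.0, 8.0], [0, 0])
        np.testing.assert_allclose(com_trajectory(traj, 0)[:, 0], 5.0)

    def test_volume_weighting(self):
        pos = np.zeros((2, 2, 3))
        pos[:, 1, 0] = 10.0
        traj = _traj_from_positions(pos, [10.0, 5.0], [0, 0])
        w2 = 5.0**3 / (10.0**3 + 5.0**3)
        np.testing.assert_allclose(com_trajectory(traj, 0)[:, 0], 10.0 * w2)
        np.testing.assert_allclose(
            com_trajectory(traj, 0, weights="geometric")[:, 0], 5.0
        )

    def test_rigid_translation(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(1, 3, 3))
        v = np.array([1.0, -2.0, 0.5])
        pos = base + v[None, None, :] * np.arange(6)[:, None, None]
        traj = _traj_from_positions(pos, [5.0, 7.0, 9.0], [0, 0, 0])
        com = com_trajectory(traj, 0)
        np.testing.assert_allclose(np.diff(com, axis=0), np.tile(v, (5, 1)), atol=1e-12)

    def test_unknown_molecule(self):
        traj = _traj_from_positions(np.zeros((3, 1, 3)), [5.0], [0])
        with pytest.raises(KeyError):
            com_trajectory(traj, 4)


class TestMSD:
    def test_linear_motion_quadratic_msd(self):
        t = np.arange(200)
        v = np.array([0.3, -0.1, 0.2])
        series = t[:, None] * v
        msd = msd_multi_origin(series, 1.0)
        np.testing.assert_allclose(
            msd.msd, (v @ v) * msd.lags**2, rtol=1e-9, atol=1e-9
        )

    def test_constant_position_zero(self):
        msd = msd_multi_origin(np.ones((50, 3)), 1.0)
        np.testing.assert_allclose(msd.msd, 0.0, atol=1e-10)

    def test_matches_naive_all_origins(self):
        rng = np.random.default_rng(8)
        series = np.cumsum(rng.normal(size=(64, 3)), axis=0)
        msd = msd_multi_origin(series, 2.0)
        for m in range(1, 64):
            naive = np.mean(
                ((series[m:] - series[:-m]) ** 2).sum(axis=1)
            )
            assert msd.msd[m] == pytest.approx(naive, rel=1e-10)
            assert msd.origin_counts[m] == 64 - m

    def test_max_lag_validation(self):
        with pytest.raises(ValueError):
            msd_multi_origin(np.zeros((10, 3)), 1.0, max_lag=20.0)


class TestFitAlpha:
    def test_exact_normal_diffusion(self):
        lags = np.arange(101) * 1.0
        D = 2.5
        msd = msd_multi_origin(np.zeros((3, 3)), 1.0)  # placeholder shape
        msd.lags = lags
        msd.msd = 6 * D * lags
        alpha, intercept, se = fit_alpha(msd, (1.0, 100.0))
        assert alpha == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(np.log10(6 * D), abs=1e-12)

    def test_ballistic(self):
        lags = np.arange(51) * 1.0
        msd = msd_multi_origin(np.zeros((3, 3)), 1.0)
        msd.lags = lags
        msd.msd = 4.0 * lags**2
        alpha, _, _ = fit_alpha(msd, (1.0, 50.0))
        assert alpha == pytest.approx(2.0, abs=1e-12)

    def test_fbm_hurst_045(self):
        paths = fbm_path(4096, hurst=0.45, dt=1.0, n_paths=12, seed=5)
        msds = [msd_multi_origin(p, 1.0, max_lag=400.0).msd for p in paths]
        pooled = msd_multi_origin(paths[0], 1.0, max_lag=400.0)
        pooled.msd = np.mean(msds, axis=0)
        alpha, _, se = fit_alpha(pooled, (2.0, 200.0))
        assert alpha == pytest.approx(0.90, abs=max(3 * se, 0.02))

    def test_nonpositive_msd_rejected(self):
        msd = msd_multi_origin(np.zeros((3, 3)), 1.0)
        msd.lags = np.arange(10) * 1.0
        msd.msd = np.zeros(10)
        with pytest.raises(ValueError):
            fit_alpha(msd, (1.0, 9.0))


class TestEstimateDBlocks:
    def test_recovers_known_diffusion(self):
        # free BD with D = 0.5 Å²/ns = 5 µm²/s
        rng = np.random.default_rng(11)
        D = 0.5
        dt = 1.0
        series = np.cumsum(
            rng.normal(0, np.sqrt(2 * D * dt), size=(40000, 3)), axis=0
        )
        est = estimate_D_blocks(series, dt, discard=2000.0, n_blocks=2,
                                window=(10.0, 200.0))
        assert not est.flagged
        pooled_se = max(est.sd / np.sqrt(2), 0.05 * 5.0)
        assert est.d_um2_per_s == pytest.approx(5.0, abs=3 * pooled_se)

    def test_duplicated_blocks_zero_sd(self):
        rng = np.random.default_rng(2)
        block = np.cumsum(rng.normal(0, 1.0, size=(2000, 3)), axis=0)
        series = np.vstack([block, block + block[-1] - block[0]])
        # identical increments in both blocks -> identical block MSDs
        est = estimate_D_blocks(series, 1.0, discard=0.0, n_blocks=2,
                                window=(5.0, 100.0))
        assert est.sd == pytest.approx(0.0, abs=1e-12)

    def test_drift_flagged(self):
        t = np.arange(5000)
        series = np.stack([0.5 * t, np.zeros(5000), np.zeros(5000)], axis=1)
        with pytest.warns(UserWarning):
            est = estimate_D_blocks(series, 1.0, discard=0.0, n_blocks=2,
                                    window=(5.0, 100.0))
        assert est.flagged
        assert est.alpha == pytest.approx(2.0, abs=1e-6)


class TestTimeDependentD:
    def test_constant_for_normal_diffusion(self):
        msd = msd_multi_origin(np.zeros((3, 3)), 1.0)
        msd.lags = np.arange(101) * 1.0
        msd.msd = 6 * 1.7 * msd.lags
        lags, d = time_dependent_D(msd)
        np.testing.assert_allclose(d, 1.7)

    def test_decreasing_for_subdiffusion(self):
        msd = msd_multi_origin(np.zeros((3, 3)), 1.0)
        msd.lags = np.arange(101) * 1.0
        msd.msd = 6 * msd.lags**0.9
        _, d = time_dependent_D(msd)
        assert np.all(np.diff(d) < 0)


class TestDisplacementAutocorrelation:
    def test_t0_normalized_to_one(self):
        rng = np.random.default_rng(4)
        series = np.cumsum(rng.normal(size=(2000, 3)), axis=0)
        c = displacement_autocorrelation(series, 1.0, delta=5.0)
        assert c.normalized[0] == 1.0

    def test_free_bd_uncorrelated_increments(self):
        rng = np.random.default_rng(10)
        reps = [
            displacement_autocorrelation(
                np.cumsum(rng.normal(size=(5000, 3)), axis=0), 1.0, delta=5.0,
                max_lag=50.0,
            ).normalized[5:]
            for _ in range(20)
        ]
        reps = np.array(reps)
        mean = reps.mean(axis=0)
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        assert np.all(np.abs(mean) < 4 * se + 1e-3)

    def test_fbm_closed_form_increment_correlation(self):
        # normalized C_delta(delta) = 2^(2H-1) - 1; H = 0.45 -> -0.06697
        paths = fbm_path(8192, hurst=0.45, dt=1.0, n_paths=16, seed=6)
        vals = [
            displacement_autocorrelation(p, 1.0, delta=8.0, max_lag=80.0)
            for p in paths
        ]
        raw = np.array([v.raw for v in vals]).mean(axis=0)
        norm = raw / raw[0]
        expected = 2 ** (2 * 0.45 - 1) - 1
        se = np.array([v.normalized[8] for v in vals]).std(ddof=1) / 4.0
        assert norm[8] == pytest.approx(expected, abs=max(3 * se, 0.01))

    def test_decay_to_zero_at_long_lag(self):
        paths = fbm_path(8192, hurst=0.45, dt=1.0, n_paths=8, seed=13)
        vals = np.array(
            [
                displacement_autocorrelation(p, 1.0, delta=4.0, max_lag=100.0).normalized
                for p in paths
            ]
        )
        tail = vals.mean(axis=0)[80]  # t = 20 * delta
        assert abs(tail) < 0.02

    def test_delta_must_divide_frame_grid(self):
        series = np.zeros((100, 3))
        with pytest.raises(ValueError):
            displacement_autocorrelation(series, 1.0, delta=2.5)


class TestAlphaInversion:
    @pytest.mark.parametrize(
        "cmin, alpha",
        [(0.0, 1.0), (-0.5, 0.0), (2 ** (0.9 - 1) - 1, 0.9)],
    )
    def test_inversion(self, cmin, alpha):
        assert alpha_from_min_correlation(cmin) == pytest.approx(alpha, abs=1e-12)

    def test_forward_backward_roundtrip(self):
        for a in np.linspace(0.05, 1.0, 20):
            cmin = 2 ** (a - 1) - 1
            assert alpha_from_min_correlation(cmin) == pytest.approx(a, abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            alpha_from_min_correlation(0.1)
        with pytest.raises(ValueError):
            alpha_from_min_correlation(-0.6)


class TestGaussianity:
    def test_gaussian_input(self, rng):
        x = rng.normal(2.0, 3.0, size=(5000, 3))
        rep = gaussianity_check(x, lag=10.0)
        for comp in rep["components"]:
            assert not comp["degenerate"]
            assert abs(comp["excess_kurtosis"]) < 0.2
            assert comp["ks_pvalue"] > 1e-3

    def test_laplace_excess_kurtosis_detected(self, rng):
        x = rng.laplace(size=20000)
        rep = gaussianity_check(x)
        assert rep["components"][0]["excess_kurtosis"] == pytest.approx(3.0, abs=0.4)
        assert rep["components"][0]["ks_pvalue"] < 1e-6

    def test_constant_input_flagged(self):
        rep = gaussianity_check(np.full(500, 1.3))
        assert rep["components"][0]["degenerate"]

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            gaussianity_check(np.zeros(50))


class TestUnits:
    def test_a2ns_to_um2s_roundtrip(self):
        # 1 Å²/ns = 1e-20 m² / 1e-9 s = 1e-11 m²/s = 10 µm²/s
        assert A2_PER_NS_TO_UM2_PER_S == pytest.approx(10.0)
        d_um = 87.0
        assert d_um / A2_PER_NS_TO_UM2_PER_S * A2_PER_NS_TO_UM2_PER_S == d_um


class TestPlotsAndIO:
    def test_plot_helpers_render(self, tmp_path, rng):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from crowdbd.analysis import load_com_csv, save_com_csv
        from crowdbd.plots import (
            plot_correlation,
            plot_msd_loglog,
            plot_time_dependent_D,
        )

        series = np.cumsum(rng.normal(size=(500, 3)), axis=0)
        msd = msd_multi_origin(series, 1.0, max_lag=100.0)
        corr = displacement_autocorrelation(series, 1.0, delta=5.0, max_lag=50.0)
        for fn, arg in [
            (plot_msd_loglog, msd),
            (plot_time_dependent_D, msd),
            (plot_correlation, corr),
        ]:
            ax = fn(arg, label="x")
            ax.figure.savefig(tmp_path / f"{fn.__name__}.png", dpi=40)
            plt.close(ax.figure)

        path = tmp_path / "com.csv"
        save_com_csv(series, 1.0, path)
        back, dt = load_com_csv(path)
        assert dt == pytest.approx(1.0)
        np.testing.assert_allclose(back, series, atol=1e-9)
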