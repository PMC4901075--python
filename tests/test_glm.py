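import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from triconj import glm
from triconj.glm import (
    DesignMatrix,
    DesignRankError,
    HRFParams,
    build_design,
    canonical_hrf,
    fit_run,
    group_tmap,
    grouping_for_task,
    subject_contrast,
    task_contrast,
)
from triconj.synthetic_data import default_task_specs, generate_schedule
from triconj.volume_io import Volume


def double_gamma_closed_form(t, p=HRFParams()):
    """Dense evaluation of the difference-of-gammas from its log-density form."""
    a1 = p.peak_delay / p.peak_dispersion
    a2 = p.undershoot_delay / p.undershoot_dispersion
    t = np.asarray(t, float)
    with np.errstate(divide="ignore"):
        g1 = np.where(
            t > 0,
            np.exp((a1 - 1) * np.log(t) - t / p.peak_dispersion - gammaln(a1) - a1 * np.log(p.peak_dispersion)),
            0.0,
        )
        g2 = np.where(
            t > 0,
            np.exp((a2 - 1) * np.log(t) - t / p.undershoot_dispersion - gammaln(a2) - a2 * np.log(p.undershoot_dispersion)),
            0.0,
        )
    return g1 - p.undershoot_ratio * g2


class TestHRF:
    def test_zero_at_origin(self):
        assert canonical_hrf()[0] == 0.0

    def test_peak_normalized(self):
        assert canonical_hrf().max() == pytest.approx(1.0)

    def test_argmax_near_five_seconds(self):
        # independent dense evaluation of the closed form
        p = HRFParams()
        t_dense = np.arange(0, p.duration, 0.001)
        expected_peak = t_dense[np.argmax(double_gamma_closed_form(t_dense, p))]
        kernel = canonical_hrf(p)
        got_peak = np.argmax(kernel) * p.dt
        assert abs(got_peak - expected_peak) <= p.dt
        assert abs(got_peak - 5.0) <= p.dt

    def test_matches_closed_form(self):
        p = HRFParams()
        t = np.arange(0, p.duration, p.dt)
        dense = double_gamma_closed_form(t, p)
        assert np.allclose(canonical_hrf(p), dense / dense.max(), atol=1e-12)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            HRFParams(peak_dispersion=0.0)
        with pytest.raises(ValueError):
            HRFParams(duration=10.0)


class TestBuildDesign:
    @pytest.mark.parametrize(
        "task,n_cols", [("Value", 15), ("Mathematical", 9), ("Emotion", 3)]
    )
    def test_condition_column_counts(self, task, n_cols, small_grid):
        spec = default_task_specs()[task]
        schedule = generate_schedule(spec, seed=1)[0]
        design = build_design(
            schedule,
            small_grid,
            n_scans=spec.volumes_per_run,
            grouping=grouping_for_task(task),
        )
        assert len(design.task_columns) == n_cols

    def test_empty_schedule_warns(self, small_grid):
        empty = pd.DataFrame(columns=["onset_s", "duration_s", "condition", "outcome"])
        with pytest.warns(UserWarning, match="empty schedule"):
            design = build_design(empty, small_grid, n_scans=20)
        assert design.task_columns == []
        assert design.nuisance_columns == ["intercept"]

    def test_motion_columns_included(self, small_grid):
        spec = default_task_specs()["Emotion"]
        (schedule,) = generate_schedule(spec, seed=1)
        motion = pd.DataFrame(
            np.zeros((spec.volumes_per_run, 6)),
            columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
        )
        design = build_design(
            schedule, small_grid, motion=motion, grouping=grouping_for_task("Emotion")
        )
        assert len(design.nuisance_columns) == 7  # 6 motion + intercept

    def test_onset_past_run_errors(self, small_grid):
        schedule = pd.DataFrame(
            {
                "onset_s": [1000.0],
                "duration_s": [4.0],
                "condition": ["choice"],
                "outcome": ["na"],
            }
        )
        with pytest.raises(ValueError, match="past the end"):
            build_design(schedule, small_grid, n_scans=20)

    def test_all_zero_task_column_rejected(self):
        frame = pd.DataFrame({"choice": np.zeros(10), "intercept": np.ones(10)})
        with pytest.raises(ValueError, match="all-zero"):
            DesignMatrix(frame=frame, task_columns=["choice"], nuisance_columns=["intercept"])


def _random_design(rng, n_scans=40, n_task=3):
    data = {f"c{i}": rng.normal(size=n_scans) for i in range(n_task)}
    data["intercept"] = np.ones(n_scans)
    return DesignMatrix(
        frame=pd.DataFrame(data),
        task_columns=[f"c{i}" for i in range(n_task)],
        nuisance_columns=["intercept"],
    )


class TestFitRun:
    def test_exact_beta_recovery(self, tiny_grid, rng):
        design = _random_design(rng)
        X = design.values
        beta_true = rng.normal(size=(X.shape[1],) + tiny_grid.dims)
        run = np.einsum("tp,pxyz->xyzt", X, beta_true)
        fit = fit_run(run, design, grid=tiny_grid)
        for i, label in enumerate(design.frame.columns):
            assert np.allclose(fit.betas[label], beta_true[i], atol=1e-9)

    def test_residual_orthogonality(self, tiny_grid, rng):
        design = _random_design(rng)
        run = rng.normal(size=tiny_grid.dims + (40,))
        fit = fit_run(run, design, grid=tiny_grid)
        X = design.values
        fitted = np.zeros_like(run)
        for i, label in enumerate(design.frame.columns):
            fitted += fit.betas[label][..., None] * X[:, i]
        resid = run - fitted
        inner = np.einsum("xyzt,tp->xyzp", resid, X)
        norms = np.linalg.norm(run, axis=-1)[..., None] * np.linalg.norm(X, axis=0)
        assert np.all(np.abs(inner) < 1e-8 * np.maximum(norms, 1e-12))

    def test_projection_idempotence(self, tiny_grid, rng):
        design = _random_design(rng)
        run = rng.normal(size=tiny_grid.dims + (40,))
        fit = fit_run(run, design, grid=tiny_grid)
        X = design.values
        fitted = np.zeros_like(run)
        for i, label in enumerate(design.frame.columns):
            fitted += fit.betas[label][..., None] * X[:, i]
        refit = fit_run(fitted, design, grid=tiny_grid)
        for label in design.frame.columns:
            assert np.allclose(refit.betas[label], fit.betas[label], atol=1e-9)

    def test_df_error(self, tiny_grid, rng):
        design = _random_design(rng, n_scans=40, n_task=3)
        run = rng.normal(size=tiny_grid.dims + (40,))
        fit = fit_run(run, design, grid=tiny_grid)
        assert fit.df_error == 40 - 4

    def test_rank_deficient_names_columns(self, tiny_grid, rng):
        n = 40
        base = rng.normal(size=n)
        frame = pd.DataFrame(
            {"c0": base, "c1": 2 * base, "intercept": np.ones(n)}
        )
        design = DesignMatrix(
            frame=frame, task_columns=["c0", "c1"], nuisance_columns=["intercept"]
        )
        run = rng.normal(size=tiny_grid.dims + (n,))
        with pytest.raises(DesignRankError, match="c"):
            fit_run(run, design, grid=tiny_grid)

    def test_frame_count_mismatch(self, tiny_grid, rng):
        design = _random_design(rng, n_scans=40)
        run = rng.normal(size=tiny_grid.dims + (39,))
        with pytest.raises(ValueError, match="frame count"):
            fit_run(run, design, grid=tiny_grid)

    def test_white_noise_t_distribution(self, rng):
        # t of a unit contrast on white noise follows Student t with df_error
        from triconj.volume_io import AcquisitionGrid

        grid = AcquisitionGrid.centered((50, 50, 4), (1, 1, 1), 1.0)
        n, p = 30, 4
        design = _random_design(rng, n_scans=n, n_task=p - 1)
        run = rng.normal(size=grid.dims + (n,))
        fit = fit_run(run, design, grid=grid)
        X = design.values
        xtx_inv = np.linalg.inv(X.T @ X)
        c = np.zeros(p)
        c[0] = 1.0
        var_c = c @ xtx_inv @ c
        t_vals = fit.betas["c0"] / np.sqrt(fit.residual_variance * var_c)
        ks = stats.kstest(t_vals.ravel(), "t", args=(fit.df_error,))
        assert ks.pvalue > 0.01


class TestSubjectContrast:
    def test_single_run_identity(self, tiny_grid, rng):
        design = _random_design(rng)
        run = rng.normal(size=tiny_grid.dims + (40,))
        fit = fit_run(run, design, grid=tiny_grid)
        contrast = {"c0": 1.0}
        vol = subject_contrast([fit], contrast)
        assert np.allclose(vol.values, fit.betas["c0"])

    def test_equal_betas_weight_invariance(self, tiny_grid, rng):
        design = _random_design(rng)
        X = design.values
        beta = rng.normal(size=(X.shape[1],) + tiny_grid.dims)
        run = np.einsum("tp,pxyz->xyzt", X, beta)
        fit1 = fit_run(run, design, grid=tiny_grid)
        fit2 = fit_run(run, design, grid=tiny_grid)
        contrast = {"c0": 1.0, "c1": -0.5}
        a = subject_contrast([fit1, fit2], contrast, weights=[0.9, 0.1])
        b = subject_contrast([fit1, fit2], contrast, weights=[0.5, 0.5])
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_two_run_weighted_mean_oracle(self, tiny_grid, rng):
        design = _random_design(rng)
        X = design.values
        runs = []
        vals = []
        for _ in range(2):
            beta = rng.normal(size=(X.shape[1],) + tiny_grid.dims)
            run = np.einsum("tp,pxyz->xyzt", X, beta)
            runs.append(fit_run(run, design, grid=tiny_grid))
            vals.append(beta[0][0, 0, 0])  # c0 at one voxel
        got = subject_contrast(runs, {"c0": 1.0}, weights=[0.3, 0.7]).values[0, 0, 0]
        assert got == pytest.approx(0.3 * vals[0] + 0.7 * vals[1], abs=1e-9)

    def test_weight_length_mismatch(self, tiny_grid, rng):
        design = _random_design(rng)
        run = rng.normal(size=tiny_grid.dims + (40,))
        fit = fit_run(run, design, grid=tiny_grid)
        with pytest.raises(ValueError, match="length"):
            subject_contrast([fit], {"c0": 1.0}, weights=[0.5, 0.5])


class TestGroupTmap:
    def test_zero_variance_flagged(self, tiny_grid):
        vols = [Volume(values=np.ones(tiny_grid.dims), grid=tiny_grid) for _ in range(4)]
        stat = group_tmap(vols)
        assert not np.isfinite(stat.values.values).any()
        assert stat.df == 3

    def test_antisymmetry(self, tiny_grid, rng):
        vols = [
            Volume(values=rng.normal(size=tiny_grid.dims), grid=tiny_grid)
            for _ in range(6)
        ]
        neg = [Volume(values=-v.values, grid=tiny_grid) for v in vols]
        assert np.allclose(
            group_tmap(vols).values.values, -group_tmap(neg).values.values
        )

    def test_scaling_invariance(self, tiny_grid, rng):
        vols = [
            Volume(values=rng.normal(size=tiny_grid.dims), grid=tiny_grid)
            for _ in range(6)
        ]
        scaled = [Volume(values=3.7 * v.values, grid=tiny_grid) for v in vols]
        assert np.allclose(
            group_tmap(vols).values.values, group_tmap(scaled).values.values
        )

    def test_mean_t_of_shifted_normals(self):
        # E[t] = delta*sqrt(n) * sqrt(df/2)*Gamma((df-1)/2)/Gamma(df/2)
        from triconj.volume_io import AcquisitionGrid

        grid = AcquisitionGrid.centered((20, 20, 20), (1, 1, 1), 1.0)
        rng = np.random.default_rng(5)
        n = 20
        vols = [
            Volume(values=rng.normal(0.5, 1.0, size=grid.dims), grid=grid)
            for _ in range(n)
        ]
        stat = group_tmap(vols)
        df = n - 1
        bias = np.sqrt(df / 2) * np.exp(gammaln((df - 1) / 2) - gammaln(df / 2))
        expected = 0.5 * np.sqrt(n) * bias
        assert stat.values.values.mean() == pytest.approx(expected, abs=0.05)

    def test_needs_two_subjects(self, tiny_grid):
        with pytest.raises(ValueError):
            group_tmap([Volume(values=np.zeros(tiny_grid.dims), grid=tiny_grid)])


class TestTaskContrast:
    def test_choice_and_feedback_split(self, small_grid):
        spec = default_task_specs()["Value"]
        schedule = generate_schedule(spec, seed=1)[0]
        design = build_design(
            schedule,
            small_grid,
            n_scans=spec.volumes_per_run,
            grouping=grouping_for_task("Value"),
        )
        choice = task_contrast(design, "choice")
        feedback = task_contrast(design, "feedback")
        assert len(choice) == 5 and all(k.startswith("choice") for k in choice)
        assert len(feedback) == 10 and all(k.startswith("fb_") for k in feedback)
        assert sum(choice.values()) == pytest.approx(1.0)
        assert sum(feedback.values()) == pytest.approx(1.0)
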