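import json

import numpy as np
import pandas as pd
import pytest

from _oracles import sphere_voxel_count
from triconj import glm
from triconj.conjunction import CATEGORIES
from triconj.synthetic_data import (
    AtlasRegion,
    NoiseModel,
    TaskSpec,
    TruthAtlas,
    default_task_specs,
    demo_atlas,
    demo_task_specs,
    draw_itis,
    generate_cohort,
    generate_schedule,
    gm_probability,
    iti_scale,
    plant_truth,
    simulate_run,
)
from triconj.volume_io import AcquisitionGrid, read_run


def n_trials(tables):
    return sum(t["condition"].str.startswith("choice").sum() for t in tables)


class TestTaskSpec:
    def test_outcome_sum_must_match(self):
        with pytest.raises(ValueError, match="outcome schedule"):
            TaskSpec(
                name="Emotion",
                n_runs=1,
                volumes_per_run=108,
                difficulty_levels=1,
                trials_per_level=20,
                outcome_schedule={"higher": 5},
            )

    def test_iti_mean_in_range(self):
        with pytest.raises(ValueError, match="iti_mean"):
            TaskSpec(
                name="Emotion",
                n_runs=1,
                volumes_per_run=108,
                difficulty_levels=1,
                trials_per_level=20,
                outcome_schedule={"higher": 20},
                iti_mean=0.5,
            )

    def test_default_design_totals(self):
        specs = default_task_specs()
        assert specs["Value"].n_trials == 80
        assert sum(specs["Value"].outcome_schedule.values()) == 80
        assert specs["Value"].outcome_schedule == {
            "higher": 50,
            "lower": 8,
            "either": 12,
            "neither": 10,
        }
        assert specs["Mathematical"].n_trials == 45
        assert specs["Emotion"].n_trials == 20
        assert specs["Emotion"].outcome_schedule == {
            "higher": 10,
            "lower": 2,
            "either": 5,
            "neither": 3,
        }

    def test_default_run_lengths(self):
        specs = default_task_specs()
        assert (specs["Value"].n_runs, specs["Value"].volumes_per_run) == (2, 200)
        assert specs["Mathematical"].volumes_per_run == 224
        assert specs["Emotion"].volumes_per_run == 108


class TestSchedule:
    @pytest.mark.parametrize("task,expected", [("Value", 80), ("Mathematical", 45), ("Emotion", 20)])
    def test_trial_counts(self, task, expected):
        tables = generate_schedule(default_task_specs()[task], seed=7)
        assert n_trials(tables) == expected

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_counts_invariant_over_seeds(self, seed):
        spec = default_task_specs()["Value"]
        tables = generate_schedule(spec, seed=seed)
        assert n_trials(tables) == 80
        # per-level counts: 16 trials per level, split over two runs
        per_level = {}
        for t in tables:
            choice = t[t["condition"].str.startswith("choice")]
            for cond in choice["condition"]:
                per_level[cond] = per_level.get(cond, 0) + 1
        assert per_level == {f"choice_l{i}": 16 for i in range(1, 6)}

    def test_determinism(self):
        spec = default_task_specs()["Emotion"]
        a = generate_schedule(spec, seed=11)
        b = generate_schedule(spec, seed=11)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta, tb)

    def test_onsets_after_lead_in(self):
        spec = default_task_specs()["Value"]
        for table in generate_schedule(spec, seed=2):
            assert table["onset_s"].min() >= spec.lead_fixation

    def test_onsets_fit_run(self):
        spec = default_task_specs()["Mathematical"]
        (table,) = generate_schedule(spec, seed=5)
        end = table["onset_s"].max() + 2.0 + spec.lead_fixation
        assert end <= spec.volumes_per_run * 2.0

    def test_unfittable_schedule_errors(self):
        spec = TaskSpec(
            name="Emotion",
            n_runs=1,
            volumes_per_run=20,  # 40 s cannot hold 20 trials + fixations
            difficulty_levels=1,
            trials_per_level=20,
            outcome_schedule={"higher": 10, "lower": 2, "either": 5, "neither": 3},
        )
        with pytest.raises(ValueError, match="needs"):
            generate_schedule(spec, seed=0)

    def test_feedback_outcome_mix(self):
        spec = default_task_specs()["Value"]
        for table in generate_schedule(spec, seed=21):
            fb = table[table["condition"].str.startswith("feedback")]
            assert set(fb["outcome"]) == {"gain", "nogain"}
        (math_table,) = generate_schedule(default_task_specs()["Mathematical"], seed=21)
        fb = math_table[math_table["condition"].str.startswith("feedback")]
        assert set(fb["outcome"]) == {"correct", "incorrect"}


class TestITI:
    def test_scale_reproduces_mean(self):
        s = iti_scale(1.0, 5.0, 1.5)
        # closed-form truncated-exponential mean at the solved scale
        span = 4.0
        mean = 1.0 + s - span / np.expm1(span / s)
        assert abs(mean - 1.5) < 1e-9

    def test_draws_within_range_and_mean(self, rng):
        itis = draw_itis(rng, 20_000)
        assert itis.min() >= 1.0
        assert itis.max() <= 5.0
        assert abs(itis.mean() - 1.5) < 0.1


class TestPlantTruth:
    def _single_region_atlas(self, grid):
        center = tuple(grid.voxel_to_world(tuple(d // 2 for d in grid.dims)))
        return TruthAtlas(
            regions=(
                AtlasRegion(
                    name="vm",
                    center_mm=center,
                    radius_mm=6.0,
                    category=frozenset({"Value", "Mathematical"}),
                    effect=1.5,
                ),
            )
        )

    def test_category_semantics(self, small_grid):
        atlas = self._single_region_atlas(small_grid)
        truth = plant_truth(atlas, small_grid)
        assert (truth["Value"].values > 0).any()
        assert np.array_equal(truth["Value"].values, truth["Mathematical"].values)
        assert np.all(truth["Emotion"].values == 0)

    def test_empty_atlas(self, small_grid):
        truth = plant_truth(TruthAtlas(regions=()), small_grid)
        for vol in truth.values():
            assert np.all(vol.values == 0)

    def test_sphere_count_vs_enumeration_oracle(self, small_grid):
        atlas = self._single_region_atlas(small_grid)
        truth = plant_truth(atlas, small_grid)
        region = atlas.regions[0]
        expected = sphere_voxel_count(small_grid, region.center_mm, region.radius_mm)
        assert (truth["Value"].values != 0).sum() == expected

    def test_center_outside_grid_errors(self, small_grid):
        atlas = TruthAtlas(
            regions=(
                AtlasRegion(
                    name="out",
                    center_mm=(500.0, 0.0, 0.0),
                    radius_mm=6.0,
                    category=frozenset({"Value"}),
                    effect=1.0,
                ),
            )
        )
        with pytest.raises(ValueError, match="outside"):
            plant_truth(atlas, small_grid)

    def test_demo_atlas_covers_all_categories(self, small_grid):
        atlas = demo_atlas(small_grid)
        assert {r.category for r in atlas.regions} == set(CATEGORIES)
        plant_truth(atlas, small_grid)  # all centers must be inside


class TestSimulateRun:
    def test_noiseless_recovery(self, small_grid):
        spec = demo_task_specs()["Emotion"]
        (schedule,) = generate_schedule(spec, seed=3)
        atlas = demo_atlas(small_grid)
        truth = plant_truth(atlas, small_grid)
        noise = NoiseModel(sigma=0.0, fwhm=0.0, ar1=0.0)
        data, motion = simulate_run(
            schedule, truth["Emotion"], noise, small_grid, seed=4,
            n_scans=spec.volumes_per_run,
        )
        design = glm.build_design(
            schedule, small_grid, motion=motion, grouping=glm.grouping_for_task("Emotion")
        )
        fit = glm.fit_run(data, design, grid=small_grid)
        contrast = glm.subject_contrast([fit], glm.task_contrast(design, "choice"))
        assert np.abs(contrast.values - truth["Emotion"].values).max() < 1e-6

    def test_zero_effect_mean_near_zero(self, tiny_grid):
        spec = demo_task_specs()["Emotion"]
        (schedule,) = generate_schedule(spec, seed=3)
        zero = plant_truth(TruthAtlas(regions=()), tiny_grid)["Emotion"]
        noise = NoiseModel(sigma=1.0, fwhm=0.0, ar1=0.2)
        total = 0.0
        count = 0
        for seed in range(40):
            data, _ = simulate_run(
                schedule, zero, noise, tiny_grid, seed=seed, n_scans=30
            )
            total += data.sum()
            count += data.size
        assert abs(total / count) < 0.02

    def test_sigma_scaling_doubles_residual_sd(self, tiny_grid):
        spec = demo_task_specs()["Emotion"]
        (schedule,) = generate_schedule(spec, seed=3)
        zero = plant_truth(TruthAtlas(regions=()), tiny_grid)["Emotion"]
        grouping = glm.grouping_for_task("Emotion")
        sds = []
        for sigma in (1.0, 2.0):
            noise = NoiseModel(sigma=sigma, fwhm=0.0, ar1=0.0)
            data, motion = simulate_run(
                schedule, zero, noise, tiny_grid, seed=77, n_scans=spec.volumes_per_run
            )
            design = glm.build_design(
                schedule, tiny_grid, motion=motion, grouping=grouping
            )
            fit = glm.fit_run(data, design, grid=tiny_grid)
            sds.append(np.sqrt(fit.residual_variance.mean()))
        # identical seed: noise field is scaled exactly, so the ratio is exact
        assert abs(sds[1] / sds[0] - 2.0) < 1e-9

    def test_determinism(self, tiny_grid):
        spec = demo_task_specs()["Emotion"]
        (schedule,) = generate_schedule(spec, seed=3)
        zero = plant_truth(TruthAtlas(regions=()), tiny_grid)["Emotion"]
        noise = NoiseModel(sigma=1.0, fwhm=4.0, ar1=0.3)
        a, ma = simulate_run(schedule, zero, noise, tiny_grid, seed=5, n_scans=30)
        b, mb = simulate_run(schedule, zero, noise, tiny_grid, seed=5, n_scans=30)
        assert np.array_equal(a, b)
        pd.testing.assert_frame_equal(ma, mb)


class TestGMProbability:
    def test_range_and_coverage(self, small_grid):
        prob = gm_probability(small_grid)
        assert prob.values.min() >= 0 and prob.values.max() <= 1
        center = tuple(d // 2 for d in small_grid.dims)
        assert prob.values[center] == 1.0


class TestCohort:
    def test_structure_and_determinism(self, tmp_path):
        grid = AcquisitionGrid.centered((16, 16, 10), (3.4375, 3.4375, 4.0), 2.0)
        specs = demo_task_specs()
        atlas = demo_atlas(grid)
        noise = NoiseModel(sigma=0.5, fwhm=4.0, ar1=0.2)
        m1 = generate_cohort(2, specs, atlas, noise, seed=42, out_dir=tmp_path / "a", grid=grid)
        m2 = generate_cohort(2, specs, atlas, noise, seed=42, out_dir=tmp_path / "b", grid=grid)
        assert len(m1["subjects"]) == 2
        assert len(m1["subjects"][0]["runs"]) == 4  # 2 Value + 1 Math + 1 Emotion
        # same seed -> byte-identical manifests (paths are relative)
        assert (tmp_path / "a" / "manifest.json").read_text() == (
            tmp_path / "b" / "manifest.json"
        ).read_text()
        # dataset loadable
        run = m1["subjects"][0]["runs"][0]
        data, rg = read_run(tmp_path / "a" / run["bold"])
        assert data.shape == grid.dims + (run["n_scans"],)
        data_b, _ = read_run(tmp_path / "b" / run["bold"])
        assert np.array_equal(data, data_b)
        manifest_on_disk = json.loads((tmp_path / "a" / "manifest.json").read_text())
        assert manifest_on_disk["seed"] == 42
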