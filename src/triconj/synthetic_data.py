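"""Synthetic cohort generation with planted, recoverable activation truth.

Produces trial schedules matching the three-task event-related design,
per-task effect volumes from a truth atlas of spherical regions (each tagged
with one of the seven conjunction categories), and noisy 4-D BOLD runs whose
signal is the HRF-convolved event regressor scaled by the planted effect.
All randomness flows from a single seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from . import volume_io
from .conjunction import CATEGORIES, TASKS, category_from_label, category_label
from .glm import HRFParams, convolve_events
from .volume_io import AcquisitionGrid, Mask, Volume

__all__ = [
    "TaskSpec",
    "AtlasRegion",
    "TruthAtlas",
    "NoiseModel",
    "default_task_specs",
    "demo_task_specs",
    "default_atlas",
    "demo_atlas",
    "iti_scale",
    "draw_itis",
    "generate_schedule",
    "plant_truth",
    "gm_probability",
    "simulate_run",
    "simulate_behavior",
    "generate_cohort",
]

OUTCOME_CATEGORIES = ("higher", "lower", "either", "neither")

# Reference mean/SD accuracy [%] and response time [ms] per task, used as
# defaults for simulated choices and behavioural tables.
BEHAVIOR_DEFAULTS = {
    "Value": {"acc_mean": 63.4, "acc_sd": 5.4, "rt_mean": 1982.0, "rt_sd": 436.0},
    "Mathematical": {"acc_mean": 78.1, "acc_sd": 7.0, "rt_mean": 2447.0, "rt_sd": 280.0},
    "Emotion": {"acc_mean": 56.8, "acc_sd": 14.3, "rt_mean": 1759.0, "rt_sd": 375.0},
}


@dataclasses.dataclass(frozen=True)
class TaskSpec:
    """Structural description of one task's runs and trial schedule."""

    name: str
    n_runs: int
    volumes_per_run: int
    difficulty_levels: int
    trials_per_level: int
    outcome_schedule: Mapping[str, int]
    choice_duration: float = 4.0
    feedback_duration: float = 2.0
    iti_range: tuple[float, float] = (1.0, 5.0)
    iti_mean: float = 1.5
    lead_fixation: float = 20.0

    def __post_init__(self) -> None:
        if self.name not in TASKS:
            raise ValueError(f"task name must be one of {TASKS}")
        total = self.difficulty_levels * self.trials_per_level
        sched = dict(self.outcome_schedule)
        if sum(sched.values()) != total:
            raise ValueError(
                f"outcome schedule sums to {sum(sched.values())}, expected {total}"
            )
        if not self.iti_range[0] <= self.iti_mean <= self.iti_range[1]:
            raise ValueError("iti_mean must lie within iti_range")
        object.__setattr__(self, "outcome_schedule", sched)

    @property
    def n_trials(self) -> int:
        return self.difficulty_levels * self.trials_per_level


def default_task_specs() -> dict[str, TaskSpec]:
    """The acquisition-scale design: 2x200 + 1x224 + 1x108 volumes at TR 2 s."""
    return {
        "Value": TaskSpec(
            name="Value",
            n_runs=2,
            volumes_per_run=200,
            difficulty_levels=5,
            trials_per_level=16,
            outcome_schedule={"higher": 50, "lower": 8, "either": 12, "neither": 10},
        ),
        "Mathematical": TaskSpec(
            name="Mathematical",
            n_runs=1,
            volumes_per_run=224,
            difficulty_levels=3,
            trials_per_level=15,
            # outcomes follow the participant's arithmetic, not a preset list
            outcome_schedule={"actual": 45},
        ),
        "Emotion": TaskSpec(
            name="Emotion",
            n_runs=1,
            volumes_per_run=108,
            difficulty_levels=1,
            trials_per_level=20,
            outcome_schedule={"higher": 10, "lower": 2, "either": 5, "neither": 3},
        ),
    }


def demo_task_specs() -> dict[str, TaskSpec]:
    """Reduced-size design for fast end-to-end runs and tests."""
    return {
        "Value": TaskSpec(
            name="Value",
            n_runs=2,
            volumes_per_run=80,
            difficulty_levels=5,
            trials_per_level=4,
            outcome_schedule={"higher": 0, "lower": 0, "either": 10, "neither": 10},
        ),
        "Mathematical": TaskSpec(
            name="Mathematical",
            n_runs=1,
            volumes_per_run=100,
            difficulty_levels=3,
            trials_per_level=5,
            outcome_schedule={"actual": 15},
        ),
        "Emotion": TaskSpec(
            name="Emotion",
            n_runs=1,
            volumes_per_run=60,
            difficulty_levels=1,
            trials_per_level=8,
            outcome_schedule={"higher": 4, "lower": 1, "either": 2, "neither": 1},
        ),
    }


# ---------------------------------------------------------------------------
# inter-trial intervals


def iti_scale(lo: float, hi: float, mean: float) -> float:
    """Scale of the truncated exponential on [lo, hi] with the given mean."""
    if not lo < mean < hi:
        raise ValueError("mean must lie strictly inside (lo, hi)")
    span = hi - lo
    target = mean - lo

    def trunc_mean(s: float) -> float:
        ratio = span / s
        if ratio > 700:  # truncation negligible; avoid expm1 overflow
            return s
        return s - span / np.expm1(ratio)

    return float(optimize.brentq(lambda s: trunc_mean(s) - target, 1e-6, 1e3))


def draw_itis(
    rng: np.random.Generator,
    n: int,
    lo: float = 1.0,
    hi: float = 5.0,
    mean: float = 1.5,
) -> np.ndarray:
    """Shifted truncated-exponential ITIs on [lo, hi] with the given mean."""
    s = iti_scale(lo, hi, mean)
    u = rng.random(n)
    x = -s * np.log1p(-u * (-np.expm1(-(hi - lo) / s)))
    return lo + x


# ---------------------------------------------------------------------------
# trial schedules


def _split_counts(count: int, n_runs: int) -> list[int]:
    base, extra = divmod(count, n_runs)
    return [base + (1 if r < extra else 0) for r in range(n_runs)]


def _allocate_outcomes(task: TaskSpec) -> list[list[tuple[int, str]]]:
    """Per-run lists of (difficulty level, outcome category) trial slots.

    Outcome categories are spread as evenly as possible over levels and runs
    so that, whenever a category has enough trials, every run x level cell
    sees both a guaranteed win ('either') and a guaranteed loss ('neither').
    """
    levels = list(range(1, task.difficulty_levels + 1))
    per_level: dict[int, list[str]] = {lv: [] for lv in levels}
    # spread every category but the largest as evenly as possible, then let
    # the largest absorb the per-level remainder so each level totals exactly
    # trials_per_level
    cats = sorted(task.outcome_schedule, key=lambda c: task.outcome_schedule[c])
    for cat in cats[:-1]:
        shares = _split_counts(task.outcome_schedule[cat], task.difficulty_levels)
        for lv, share in zip(levels, shares):
            per_level[lv].extend([cat] * share)
    largest = cats[-1]
    for lv in levels:
        rest = task.trials_per_level - len(per_level[lv])
        if rest < 0:
            raise ValueError(
                "outcome schedule cannot be balanced over difficulty levels"
            )
        per_level[lv].extend([largest] * rest)
    runs: list[list[tuple[int, str]]] = [[] for _ in range(task.n_runs)]
    for lv in levels:
        cats = per_level[lv]
        by_cat: dict[str, int] = {}
        for c in cats:
            by_cat[c] = by_cat.get(c, 0) + 1
        for cat in sorted(by_cat):
            for r, share in enumerate(_split_counts(by_cat[cat], task.n_runs)):
                runs[r].extend([(lv, cat)] * share)
    return runs


def generate_schedule(
    task: TaskSpec, seed: int, accuracy: float | None = None
) -> list[pd.DataFrame]:
    """Per-run event tables for one subject's runs of a task.

    Each trial contributes a choice event and an immediately following
    feedback event; trials are separated by truncated-exponential ITIs and a
    lead-in fixation precedes the first trial.  The same seed reproduces the
    identical tables.
    """
    rng = np.random.default_rng(seed)
    if accuracy is None:
        accuracy = BEHAVIOR_DEFAULTS[task.name]["acc_mean"] / 100.0
    tr = 2.0  # schedule feasibility is checked against volumes_per_run * TR
    run_slots = _allocate_outcomes(task)
    tables: list[pd.DataFrame] = []
    for run_idx, slots in enumerate(run_slots):
        order = rng.permutation(len(slots))
        slots = [slots[i] for i in order]
        itis = draw_itis(
            rng, len(slots), task.iti_range[0], task.iti_range[1], task.iti_mean
        )
        correct = rng.random(len(slots)) < accuracy
        if task.name == "Mathematical":
            correct = _ensure_mixed_outcomes(correct, [lv for lv, _ in slots])
        rows = []
        t = task.lead_fixation
        for i, (level, cat) in enumerate(slots):
            cond_suffix = f"_l{level}" if task.difficulty_levels > 1 else ""
            rows.append((t, task.choice_duration, f"choice{cond_suffix}", "na"))
            fb_onset = t + task.choice_duration
            if task.name == "Mathematical":
                outcome = "correct" if correct[i] else "incorrect"
            else:
                outcome = _predetermined_outcome(cat, bool(correct[i]))
            rows.append(
                (fb_onset, task.feedback_duration, f"feedback{cond_suffix}", outcome)
            )
            t = fb_onset + task.feedback_duration + itis[i]
        run_length = task.volumes_per_run * tr
        end_time = t - itis[-1] + task.lead_fixation if slots else task.lead_fixation
        if end_time > run_length:
            raise ValueError(
                f"schedule for {task.name} run {run_idx + 1} needs {end_time:.1f} s "
                f"but the run is only {run_length:.1f} s"
            )
        tables.append(pd.DataFrame(rows, columns=list(volume_io.EVENT_COLUMNS)))
    return tables


def _predetermined_outcome(category: str, correct: bool) -> str:
    if category == "either":
        return "gain"
    if category == "neither":
        return "nogain"
    if category == "higher":
        return "gain" if correct else "nogain"
    if category == "lower":
        return "nogain" if correct else "gain"
    raise ValueError(f"unknown outcome category {category!r}")


def _ensure_mixed_outcomes(correct: np.ndarray, levels: list[int]) -> np.ndarray:
    """Flip simulated choices so every level has >=1 correct and >=1 incorrect.

    Keeps all feedback regressor columns nonzero in per-level designs.
    """
    correct = correct.copy()
    for lv in set(levels):
        idx = [i for i, l in enumerate(levels) if l == lv]
        if len(idx) < 2:
            continue
        vals = correct[idx]
        if vals.all():
            correct[idx[0]] = False
        elif not vals.any():
            correct[idx[0]] = True
    return correct


# ---------------------------------------------------------------------------
# truth atlas and effect volumes


@dataclasses.dataclass(frozen=True)
class AtlasRegion:
    """Spherical planted effect tagged with a conjunction category."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    category: frozenset
    effect: float
    exclude_from_roi: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", frozenset(self.category))
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")

    def effect_for(self, task: str) -> float:
        return self.effect if task in self.category else 0.0


@dataclasses.dataclass(frozen=True)
class TruthAtlas:
    """Collection of planted regions."""

    regions: tuple[AtlasRegion, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))

    def to_json(self) -> list[dict]:
        return [
            {
                "name": r.name,
                "center_mm": list(r.center_mm),
                "radius_mm": r.radius_mm,
                "category": category_label(r.category),
                "effect": r.effect,
                "exclude_from_roi": r.exclude_from_roi,
            }
            for r in self.regions
        ]

    @classmethod
    def from_json(cls, payload: Sequence[dict]) -> "TruthAtlas":
        return cls(
            regions=tuple(
                AtlasRegion(
                    name=r["name"],
                    center_mm=tuple(r["center_mm"]),
                    radius_mm=r["radius_mm"],
                    category=category_from_label(r["category"]),
                    effect=r["effect"],
                    exclude_from_roi=r.get("exclude_from_roi", False),
                )
                for r in payload
            )
        )


def default_atlas(radius_mm: float = 8.0, effect: float = 1.0) -> TruthAtlas:
    """One planted region per conjunction category at reported peak sites.

    The shared Value/Mathematical region carries a stronger effect so that
    whole-brain similarity favours the Value-Mathematical pairing.
    """
    entries = [
        ("L_SMA", (-8.0, 6.0, 54.0), CATEGORIES[0], effect),
        ("L_putamen", (-18.0, 12.0, 2.0), CATEGORIES[1], 1.6 * effect),
        ("R_IPL", (32.0, -54.0, 48.0), CATEGORIES[2], effect),
        ("L_precentral", (-39.0, -3.0, 30.0), CATEGORIES[3], effect),
        ("L_lingual", (-5.0, -71.0, 6.0), CATEGORIES[4], effect),
        ("R_putamen", (20.0, 9.0, 6.0), CATEGORIES[5], effect),
        ("R_IFG", (50.0, 15.0, 32.0), CATEGORIES[6], effect),
    ]
    return TruthAtlas(
        regions=tuple(
            AtlasRegion(
                name=name,
                center_mm=center,
                radius_mm=radius_mm,
                category=cat,
                effect=eff,
            )
            for name, center, cat, eff in entries
        )
    )


def demo_atlas(
    grid: AcquisitionGrid, radius_mm: float = 6.0, effect: float = 1.0
) -> TruthAtlas:
    """Seven regions placed at fixed fractions of the grid field of view."""
    fov = np.array(grid.dims) * np.array(grid.voxel_size)
    lo = grid.voxel_to_world((0, 0, 0))
    hi = grid.voxel_to_world(tuple(d - 1 for d in grid.dims))
    center = (np.asarray(lo) + np.asarray(hi)) / 2.0
    f = 0.24
    offsets = [
        (-f, -f, -f),
        (f, -f, -f),
        (-f, f, -f),
        (f, f, -f),
        (-f, -f, f),
        (f, -f, f),
        (0.0, f, f),
    ]
    regions = []
    for i, (cat, off) in enumerate(zip(CATEGORIES, offsets)):
        pos = center + np.array(off) * fov
        eff = 1.6 * effect if cat == CATEGORIES[1] else effect
        regions.append(
            AtlasRegion(
                name=f"region_{category_label(cat)}",
                center_mm=tuple(pos),
                radius_mm=radius_mm,
                category=cat,
                effect=eff,
            )
        )
    return TruthAtlas(regions=tuple(regions))


def _sphere_membership(
    grid: AcquisitionGrid, center_mm: Sequence[float], radius_mm: float
) -> np.ndarray:
    coords = grid.world_coordinates()
    d2 = ((coords - np.asarray(center_mm, float)) ** 2).sum(axis=-1)
    return d2 <= radius_mm**2


def plant_truth(
    atlas: TruthAtlas,
    grid: AcquisitionGrid,
    region_scale: Mapping[str, float] | None = None,
) -> dict[str, Volume]:
    """Superpose spherical effects into one effect volume per task.

    ``region_scale`` optionally multiplies each region's amplitude (used for
    per-subject variability).  Category-implied zeros are exact.
    """
    volumes = {task: np.zeros(grid.dims) for task in TASKS}
    for region in atlas.regions:
        vox = grid.world_to_voxel(region.center_mm)
        if np.any(vox < -0.5) or np.any(vox > np.array(grid.dims) - 0.5):
            raise ValueError(f"region {region.name} centre lies outside the grid")
        member = _sphere_membership(grid, region.center_mm, region.radius_mm)
        if not member.any():
            raise ValueError(f"region {region.name} covers no voxel")
        scale = 1.0 if region_scale is None else region_scale.get(region.name, 1.0)
        for task in TASKS:
            amp = region.effect_for(task) * scale
            if amp != 0.0:
                volumes[task][member] += amp
    return {task: Volume(values=v, grid=grid) for task, v in volumes.items()}


def truth_masks(atlas: TruthAtlas, grid: AcquisitionGrid) -> dict[str, Mask]:
    """Per-region membership masks (ground truth for recovery scoring)."""
    return {
        r.name: Mask(membership=_sphere_membership(grid, r.center_mm, r.radius_mm), grid=grid)
        for r in atlas.regions
    }


def gm_probability(grid: AcquisitionGrid) -> Volume:
    """Synthetic gray-matter probability: a soft ellipsoid filling the grid."""
    lo = np.asarray(grid.voxel_to_world((0, 0, 0)), float)
    hi = np.asarray(grid.voxel_to_world(tuple(d - 1 for d in grid.dims)), float)
    center = (lo + hi) / 2.0
    radii = np.array(grid.dims) * np.array(grid.voxel_size) / 2.0
    coords = grid.world_coordinates()
    q = (((coords - center) / radii) ** 2).sum(axis=-1)
    prob = np.clip(20.0 * (1.0 - q), 0.0, 1.0)
    return Volume(values=prob, grid=grid)


# ---------------------------------------------------------------------------
# BOLD simulation


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Gaussian noise with spatial smoothness and AR(1) temporal correlation."""

    sigma: float = 1.0
    fwhm: float = 8.0
    ar1: float = 0.2

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.fwhm < 0:
            raise ValueError("fwhm must be >= 0")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must lie in [0, 1)")


def _smoothed_unit_noise(
    rng: np.random.Generator, grid: AcquisitionGrid, fwhm: float
) -> np.ndarray:
    w = rng.standard_normal(grid.dims)
    if fwhm > 0:
        sigma_vox = [
            fwhm / np.sqrt(8 * np.log(2)) / vs for vs in grid.voxel_size
        ]
        w = ndimage.gaussian_filter(w, sigma=sigma_vox)
        w /= w.std()
    return w


def simulate_run(
    schedule: pd.DataFrame,
    effect: Volume,
    noise: NoiseModel,
    grid: AcquisitionGrid,
    seed: int,
    n_scans: int,
    hrf: HRFParams = HRFParams(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate one 4-D run plus its motion table.

    Signal is ``effect x HRF-convolved event regressor`` (choice and feedback
    events share the planted amplitude); noise is spatially smoothed,
    AR(1)-correlated Gaussian; motion is small-amplitude smooth drift used as
    a covariate only (it does not enter the data).
    """
    if n_scans < 1:
        raise ValueError("run length must be positive")
    rng = np.random.default_rng(seed)
    is_choice = schedule["condition"].astype(str).str.startswith("choice")
    regressor = np.zeros(n_scans)
    for sel in (is_choice, ~is_choice):
        sub = schedule[sel]
        if len(sub):
            regressor += convolve_events(
                sub["onset_s"].to_numpy(),
                sub["duration_s"].to_numpy(),
                n_scans,
                grid.tr,
                hrf,
            )
    data = effect.values[..., None] * regressor[None, None, None, :]

    if noise.sigma > 0:
        eps_prev = _smoothed_unit_noise(rng, grid, noise.fwhm)
        data[..., 0] += noise.sigma * eps_prev
        innov = np.sqrt(1.0 - noise.ar1**2)
        for t in range(1, n_scans):
            w = _smoothed_unit_noise(rng, grid, noise.fwhm)
            eps_prev = noise.ar1 * eps_prev + innov * w
            data[..., t] += noise.sigma * eps_prev

    drift = rng.standard_normal((n_scans, 6)) * 0.02
    drift = np.cumsum(drift, axis=0)
    drift = ndimage.gaussian_filter1d(drift, sigma=3.0, axis=0)
    motion = pd.DataFrame(drift, columns=list(volume_io.MOTION_COLUMNS))
    return data, motion


def simulate_behavior(
    n_subjects: int, seed: int, params: Mapping[str, Mapping[str, float]] | None = None
) -> pd.DataFrame:
    """Per-subject accuracy (%) and mean RT (ms) per task."""
    rng = np.random.default_rng(seed)
    params = params or BEHAVIOR_DEFAULTS
    rows = []
    for s in range(1, n_subjects + 1):
        for task in TASKS:
            p = params[task]
            acc = float(np.clip(rng.normal(p["acc_mean"], p["acc_sd"]), 0.0, 100.0))
            rt = float(max(rng.normal(p["rt_mean"], p["rt_sd"]), 200.0))
            rows.append((f"sub-{s:02d}", task, acc, rt))
    return pd.DataFrame(rows, columns=["subject", "task", "accuracy", "mean_rt"])


# ---------------------------------------------------------------------------
# cohort


def iter_cohort(
    n_subjects: int,
    specs: Mapping[str, TaskSpec],
    atlas: TruthAtlas,
    noise: NoiseModel,
    seed: int,
    grid: AcquisitionGrid,
    subject_amp_sd: float = 0.3,
):
    """Yield per-subject simulated runs without touching disk.

    Each item is ``{"id", "amplitude_scale", "runs"}`` where runs is a list of
    ``(task, run_index, schedule, data4d, motion)``.  The random stream is the
    one :func:`generate_cohort` persists.
    """
    for s in range(1, n_subjects + 1):
        sub_rng = np.random.default_rng([seed, s])
        scale = {
            r.name: float(max(1.0 + subject_amp_sd * sub_rng.standard_normal(), 0.1))
            for r in atlas.regions
        }
        sub_truth = plant_truth(atlas, grid, region_scale=scale)
        runs = []
        for task in TASKS:
            spec = specs[task]
            schedules = generate_schedule(spec, seed=int(sub_rng.integers(2**31)))
            for run_idx, schedule in enumerate(schedules, start=1):
                data, motion = simulate_run(
                    schedule,
                    sub_truth[task],
                    noise,
                    grid,
                    seed=int(sub_rng.integers(2**31)),
                    n_scans=spec.volumes_per_run,
                )
                runs.append((task, run_idx, schedule, data, motion))
        yield {"id": f"sub-{s:02d}", "amplitude_scale": scale, "runs": runs}


def generate_cohort(
    n_subjects: int,
    specs: Mapping[str, TaskSpec],
    atlas: TruthAtlas,
    noise: NoiseModel,
    seed: int,
    out_dir: str | Path,
    grid: AcquisitionGrid,
    subject_amp_sd: float = 0.3,
) -> dict:
    """Write a full synthetic dataset and return its manifest.

    Per-subject region amplitudes are Gaussian around the atlas effect size
    with SD ``subject_amp_sd`` (as a fraction of the effect), floored at 10%
    so planted effects keep their sign.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(seed)

    truth = plant_truth(atlas, grid)
    for task, vol in truth.items():
        volume_io.write_volume(out_dir / f"truth_{task}.nii", vol)
    volume_io.write_volume(out_dir / "gm_prob.nii", gm_probability(grid))
    excluded_path = None
    excluded = [r for r in atlas.regions if r.exclude_from_roi]
    if excluded:
        member = np.zeros(grid.dims, bool)
        for r in excluded:
            member |= _sphere_membership(grid, r.center_mm, r.radius_mm)
        volume_io.write_volume(
            out_dir / "excluded.nii", Volume(values=member.astype(float), grid=grid)
        )
        excluded_path = "excluded.nii"
    (out_dir / "atlas.json").write_text(json.dumps(atlas.to_json(), indent=2))

    behavior = simulate_behavior(n_subjects, int(root_rng.integers(2**31)))
    behavior.to_csv(out_dir / "behavior.tsv", sep="\t", index=False)

    subjects = []
    for sub in iter_cohort(
        n_subjects, specs, atlas, noise, seed, grid, subject_amp_sd
    ):
        sub_id = sub["id"]
        sub_dir = out_dir / sub_id
        sub_dir.mkdir(exist_ok=True)
        runs = []
        for task, run_idx, schedule, data, motion in sub["runs"]:
            stem = f"{task}_run-{run_idx}"
            volume_io.write_run(sub_dir / f"{stem}_bold.nii", data, grid)
            volume_io.write_events(sub_dir / f"{stem}_events.tsv", schedule)
            volume_io.write_motion(sub_dir / f"{stem}_motion.tsv", motion)
            runs.append(
                {
                    "task": task,
                    "run": run_idx,
                    "bold": f"{sub_id}/{stem}_bold.nii",
                    "events": f"{sub_id}/{stem}_events.tsv",
                    "motion": f"{sub_id}/{stem}_motion.tsv",
                    "n_scans": data.shape[3],
                }
            )
        subjects.append(
            {"id": sub_id, "runs": runs, "amplitude_scale": sub["amplitude_scale"]}
        )

    manifest = {
        "seed": seed,
        "n_subjects": n_subjects,
        "subject_amp_sd": subject_amp_sd,
        "grid": {
            "dims": list(grid.dims),
            "voxel_size": list(grid.voxel_size),
            "tr": grid.tr,
            "affine": np.asarray(grid.affine).tolist(),
        },
        "noise": dataclasses.asdict(noise),
        "tasks": {
            name: {
                k: (dict(v) if isinstance(v, Mapping) else v)
                for k, v in dataclasses.asdict(spec).items()
            }
            for name, spec in specs.items()
        },
        "truth": {task: f"truth_{task}.nii" for task in TASKS},
        "gm_prob": "gm_prob.nii",
        "excluded": excluded_path,
        "atlas": "atlas.json",
        "behavior": "behavior.tsv",
        "subjects": subjects,
    }
    payload = json.dumps(manifest, indent=2, sort_keys=True)
    manifest["manifest_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
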