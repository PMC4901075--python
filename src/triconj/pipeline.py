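"""Pipeline configuration and stage orchestration.

Stages read and write a fixed layout under one working directory so that
each CLI subcommand can rerun a single stage:

    dataset/      synthetic cohort (runs, events, motion, truth, manifest)
    glm/          subject contrast volumes + group t-maps + df sidecar
    mc/           Monte-Carlo extent-threshold result
    conjunction/  per-category membership/min-t volumes + cluster table
    roi/          ROI masks, response tables, paired comparisons
    similarity/   per-subject r/z table + paired tests
    behavior/     ANOVA + Tukey summaries
    report.json   final bundle

Every JSON/TSV output embeds the config hash and seed; NIfTI outputs carry
them in the header description field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import behavior as behavior_mod
from . import volume_io
from .cluster import mc_extent_threshold
from .conjunction import (
    CATEGORIES,
    TASKS,
    category_label,
    partition,
    t_threshold,
)
from .glm import (
    HRFParams,
    StatMap,
    build_design,
    fit_run,
    group_tmap,
    grouping_for_task,
    run_contrast,
    subject_contrast,
    task_contrast,
)
from .roi import (
    a_priori_catalog,
    extract_responses,
    roi_compare,
    rois_from_conjunctions,
    sphere_roi,
)
from .spatial_similarity import compare_pairs, similarity_mask, subject_similarity
from .synthetic_data import (
    NoiseModel,
    TruthAtlas,
    default_atlas,
    default_task_specs,
    demo_atlas,
    demo_task_specs,
    generate_cohort,
    iter_cohort,
)
from .volume_io import AcquisitionGrid, Mask, Volume

PHASES = ("choice", "feedback")
SIGNS = ("positive", "negative")


@dataclasses.dataclass
class PipelineConfig:
    """All pipeline parameters; defaults run the reduced demo design."""

    seed: int = 0
    n_subjects: int = 12
    dims: tuple[int, int, int] = (32, 32, 20)
    voxel_size: tuple[float, float, float] = (3.4375, 3.4375, 4.0)
    tr: float = 2.0
    task_scale: str = "demo"  # "demo" | "full"
    atlas_kind: str = "demo"  # "demo" | "default"
    atlas_radius_mm: float = 8.0
    atlas_effect: float = 1.0
    noise_sigma: float = 1.0
    noise_fwhm: float = 8.0
    noise_ar1: float = 0.2
    subject_amp_sd: float = 0.3
    voxel_p: float = 0.001
    extent_k: int | None = None  # None -> calibrate from the MC null
    target_alpha: float = 0.001
    mc_iterations: int = 2000
    connectivity: int = 26
    gm_threshold: float = 0.8
    sphere_radius_mm: float = 5.0
    dilation_mm: float | None = None  # None -> one voxel step
    similarity_combine: str = "union"

    def grid(self) -> AcquisitionGrid:
        return AcquisitionGrid.centered(self.dims, self.voxel_size, self.tr)

    def specs(self):
        return default_task_specs() if self.task_scale == "full" else demo_task_specs()

    def atlas(self) -> TruthAtlas:
        if self.atlas_kind == "default":
            return default_atlas(self.atlas_radius_mm, self.atlas_effect)
        return demo_atlas(self.grid(), self.atlas_radius_mm, self.atlas_effect)

    def noise(self) -> NoiseModel:
        return NoiseModel(
            sigma=self.noise_sigma, fwhm=self.noise_fwhm, ar1=self.noise_ar1
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dims"] = list(self.dims)
        d["voxel_size"] = list(self.voxel_size)
        return d

    def sha256(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs = dict(d)
        if "dims" in kwargs:
            kwargs["dims"] = tuple(kwargs["dims"])
        if "voxel_size" in kwargs:
            kwargs["voxel_size"] = tuple(kwargs["voxel_size"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _stamp(config: PipelineConfig) -> dict:
    return {"config_sha256": config.sha256(), "seed": config.seed}


def _write_json(path: Path, payload: dict, config: PipelineConfig) -> dict:
    payload = {**_stamp(config), **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload


def _write_table(path: Path, table: pd.DataFrame, config: PipelineConfig) -> None:
    stamp = _stamp(config)
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={stamp['config_sha256']} seed={stamp['seed']}\n")
        table.to_csv(fh, sep="\t", index=False)


def _write_stamped_volume(
    path: Path, vol: Volume, config: PipelineConfig
) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), np.asarray(vol.grid.affine))
    img.header.set_zooms(vol.grid.voxel_size)
    img.header["descrip"] = f"cfg={config.sha256()[:16]} seed={config.seed}".encode()
    img.to_filename(str(path))


# ---------------------------------------------------------------------------
# subject-level fitting


def fit_subject_contrasts(
    runs_by_task: Mapping[str, list[tuple[pd.DataFrame, np.ndarray, pd.DataFrame]]],
    grid: AcquisitionGrid,
    hrf: HRFParams = HRFParams(),
) -> dict[str, dict[str, Volume]]:
    """GLM per run and run-weighted contrasts per task and phase.

    ``runs_by_task[task]`` is a list of (schedule, data4d, motion) per run.
    """
    out: dict[str, dict[str, Volume]] = {}
    for task, runs in runs_by_task.items():
        grouping = grouping_for_task(task)
        fits = []
        contrast_by_phase: dict[str, dict[str, float]] = {}
        for schedule, data, motion in runs:
            design = build_design(
                schedule, grid, hrf=hrf, motion=motion, grouping=grouping
            )
            fits.append(fit_run(data, design, grid=grid))
            for phase in PHASES:
                contrast_by_phase.setdefault(phase, task_contrast(design, phase))
        out[task] = {
            phase: subject_contrast(fits, contrast_by_phase[phase])
            for phase in PHASES
        }
    return out


def simulate_subject_contrasts(
    config: PipelineConfig,
) -> dict[str, dict[str, dict[str, Volume]]]:
    """In-memory cohort simulation + GLM; contrasts[subject][task][phase]."""
    grid = config.grid()
    contrasts: dict[str, dict[str, dict[str, Volume]]] = {}
    for sub in iter_cohort(
        config.n_subjects,
        config.specs(),
        config.atlas(),
        config.noise(),
        config.seed,
        grid,
        config.subject_amp_sd,
    ):
        runs_by_task: dict[str, list] = {}
        for task, _run_idx, schedule, data, motion in sub["runs"]:
            runs_by_task.setdefault(task, []).append((schedule, data, motion))
        contrasts[sub["id"]] = fit_subject_contrasts(runs_by_task, grid)
    return contrasts


def group_maps(
    contrasts: Mapping[str, Mapping[str, Mapping[str, Volume]]],
) -> dict[str, dict[str, StatMap]]:
    """Group one-sample t-maps per task and phase."""
    subjects = sorted(contrasts)
    out: dict[str, dict[str, StatMap]] = {}
    for task in TASKS:
        out[task] = {}
        for phase in PHASES:
            vols = [contrasts[s][task][phase] for s in subjects]
            out[task][phase] = group_tmap(vols, task=task, phase=phase)
    return out


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, work: Path) -> dict:
    grid = config.grid()
    manifest = generate_cohort(
        config.n_subjects,
        config.specs(),
        config.atlas(),
        config.noise(),
        config.seed,
        work / "dataset",
        grid,
        config.subject_amp_sd,
    )
    return manifest


def _load_manifest(work: Path) -> dict:
    path = work / "dataset" / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"run the simulate stage first ({path} missing)")
    return json.loads(path.read_text())


def stage_glm(config: PipelineConfig, work: Path) -> dict[str, dict[str, StatMap]]:
    manifest = _load_manifest(work)
    dataset = work / "dataset"
    grid = config.grid()
    glm_dir = work / "glm"
    glm_dir.mkdir(parents=True, exist_ok=True)
    contrasts: dict[str, dict[str, dict[str, Volume]]] = {}
    for sub in manifest["subjects"]:
        runs_by_task: dict[str, list] = {}
        for run in sub["runs"]:
            schedule = volume_io.read_events(dataset / run["events"])
            motion = volume_io.read_motion(dataset / run["motion"])
            data, _ = volume_io.read_run(dataset / run["bold"])
            runs_by_task.setdefault(run["task"], []).append((schedule, data, motion))
        contrasts[sub["id"]] = fit_subject_contrasts(runs_by_task, grid)
        for task, by_phase in contrasts[sub["id"]].items():
            for phase, vol in by_phase.items():
                _write_stamped_volume(
                    glm_dir / f"{sub['id']}_{task}_{phase}_contrast.nii", vol, config
                )
    maps = group_maps(contrasts)
    sidecar = {}
    for task in TASKS:
        for phase in PHASES:
            stat = maps[task][phase]
            _write_stamped_volume(
                glm_dir / f"group_{task}_{phase}_t.nii", stat.values, config
            )
            sidecar[f"{task}_{phase}"] = {"df": stat.df}
    _write_json(glm_dir / "group_maps.json", {"maps": sidecar}, config)
    return maps


def _load_group_maps(config: PipelineConfig, work: Path) -> dict[str, dict[str, StatMap]]:
    glm_dir = work / "glm"
    sidecar_path = glm_dir / "group_maps.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"run the glm stage first ({sidecar_path} missing)")
    sidecar = json.loads(sidecar_path.read_text())["maps"]
    maps: dict[str, dict[str, StatMap]] = {}
    for task in TASKS:
        maps[task] = {}
        for phase in PHASES:
            vol = volume_io.read_volume(glm_dir / f"group_{task}_{phase}_t.nii")
            maps[task][phase] = StatMap(
                values=vol, df=sidecar[f"{task}_{phase}"]["df"], task=task, phase=phase
            )
    return maps


def _load_subject_contrasts(
    work: Path,
) -> dict[str, dict[str, dict[str, Volume]]]:
    manifest = _load_manifest(work)
    glm_dir = work / "glm"
    out: dict[str, dict[str, dict[str, Volume]]] = {}
    for sub in manifest["subjects"]:
        out[sub["id"]] = {
            task: {
                phase: volume_io.read_volume(
                    glm_dir / f"{sub['id']}_{task}_{phase}_contrast.nii"
                )
                for phase in PHASES
            }
            for task in TASKS
        }
    return out


def _gray_mask(config: PipelineConfig, work: Path) -> Mask:
    prob = volume_io.read_volume(work / "dataset" / "gm_prob.nii")
    return volume_io.gray_matter_mask(prob, config.gm_threshold)


def stage_mc(config: PipelineConfig, work: Path):
    gray = _gray_mask(config, work)
    result = mc_extent_threshold(
        config.grid(),
        mask=gray,
        fwhm=config.noise_fwhm,
        voxel_p=config.voxel_p,
        n_iter=config.mc_iterations,
        seed=config.seed,
        connectivity=config.connectivity,
    )
    mc_dir = work / "mc"
    mc_dir.mkdir(parents=True, exist_ok=True)
    chosen_k = (
        config.extent_k
        if config.extent_k is not None
        else result.k_for_alpha(config.target_alpha)
    )
    hist = np.bincount(result.null_max_sizes)
    _write_json(
        mc_dir / "mc_result.json",
        {
            "n_iter": result.n_iter,
            "voxel_p": result.voxel_p,
            "fwhm": result.fwhm,
            "connectivity": result.connectivity,
            "target_alpha": config.target_alpha,
            "chosen_k": int(chosen_k),
            "null_max_size_histogram": {
                str(size): int(count) for size, count in enumerate(hist) if count
            },
            "alpha_table": {
                str(k): v for k, v in result.alpha_table(int(hist.size) + 1).items()
            },
        },
        config,
    )
    return result, int(chosen_k)


def _chosen_extent(config: PipelineConfig, work: Path) -> int:
    if config.extent_k is not None:
        return config.extent_k
    path = work / "mc" / "mc_result.json"
    if not path.exists():
        raise FileNotFoundError(f"run the mc-threshold stage first ({path} missing)")
    return int(json.loads(path.read_text())["chosen_k"])


def stage_conjoin(config: PipelineConfig, work: Path) -> pd.DataFrame:
    from .cluster import label_clusters

    maps = _load_group_maps(config, work)
    extent_k = _chosen_extent(config, work)
    conj_dir = work / "conjunction"
    conj_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for phase in PHASES:
        task_maps = {task: maps[task][phase] for task in TASKS}
        for sign in SIGNS:
            parts = partition(
                task_maps,
                sign=sign,
                voxel_p=config.voxel_p,
                extent_k=extent_k,
                connectivity=config.connectivity,
            )
            for include, cmap in parts.items():
                label = category_label(include)
                safe = label.replace("&", "_").replace("~", "n")
                _write_stamped_volume(
                    conj_dir / f"{phase}_{sign}_{safe}_mask.nii",
                    Volume(
                        values=cmap.membership.membership.astype(float),
                        grid=cmap.membership.grid,
                    ),
                    config,
                )
                clusters = label_clusters(
                    cmap.membership,
                    connectivity=config.connectivity,
                    stat=cmap.min_t,
                )
                for k in range(1, clusters.n_clusters + 1):
                    peak = clusters.peaks[k - 1]
                    idx = tuple(
                        np.round(cmap.membership.grid.world_to_voxel(peak)).astype(int)
                    )
                    rows.append(
                        (
                            phase,
                            sign,
                            label,
                            k,
                            int(clusters.sizes[k - 1]),
                            float(peak[0]),
                            float(peak[1]),
                            float(peak[2]),
                            float(cmap.min_t.values[idx]),
                        )
                    )
    table = pd.DataFrame(
        rows,
        columns=["phase", "sign", "conjunction", "cluster", "size", "x", "y", "z", "t"],
    )
    _write_table(conj_dir / "clusters.tsv", table, config)
    return table


def _partitions_for_phase(
    config: PipelineConfig, work: Path, phase: str, sign: str
):
    maps = _load_group_maps(config, work)
    task_maps = {task: maps[task][phase] for task in TASKS}
    return partition(
        task_maps,
        sign=sign,
        voxel_p=config.voxel_p,
        extent_k=_chosen_extent(config, work),
        connectivity=config.connectivity,
    )


def stage_roi_build(config: PipelineConfig, work: Path) -> list:
    """Construct conjunction + a-priori ROIs and write their masks."""
    manifest = _load_manifest(work)
    grid = config.grid()
    roi_dir = work / "roi"
    roi_dir.mkdir(parents=True, exist_ok=True)
    excluded = None
    if manifest.get("excluded"):
        vol = volume_io.read_volume(work / "dataset" / manifest["excluded"])
        excluded = Mask(membership=vol.values > 0.5, grid=vol.grid)

    rois = []
    for sign in SIGNS:
        parts = _partitions_for_phase(config, work, "choice", sign)
        for r in rois_from_conjunctions(
            parts,
            excluded_structures=excluded,
            dilation_mm=config.dilation_mm,
            connectivity=config.connectivity,
        ):
            r.name = f"{sign}_{r.name}"
            rois.append(r)
    # catalog coordinates are MNI; on reduced synthetic grids some spheres
    # fall outside the field of view and are skipped (recorded in the index)
    skipped = []
    for entry in a_priori_catalog():
        vox = grid.world_to_voxel(entry["center_mm"])
        if np.any(vox < -0.5) or np.any(vox > np.array(grid.dims) - 0.5):
            skipped.append(entry["name"])
            continue
        rois.append(
            sphere_roi(
                entry["center_mm"],
                config.sphere_radius_mm,
                grid,
                name=entry["name"],
                category=entry["domain"],
            )
        )

    index = []
    for r in rois:
        safe = r.name.replace("&", "_").replace("~", "n")
        _write_stamped_volume(
            roi_dir / f"roi_{safe}.nii",
            Volume(values=r.membership.membership.astype(float), grid=grid),
            config,
        )
        index.append(
            {
                "name": r.name,
                "source": r.source,
                "category": r.category,
                "n_voxels": r.membership.n_voxels,
            }
        )
    _write_json(
        roi_dir / "roi_index.json",
        {"rois": index, "skipped_a_priori": skipped},
        config,
    )
    return rois


def stage_roi_extract(config: PipelineConfig, work: Path) -> pd.DataFrame:
    rois = stage_roi_build(config, work)
    contrasts = _load_subject_contrasts(work)
    responses = extract_responses(contrasts, rois)
    _write_table(work / "roi" / "responses.tsv", responses, config)
    return responses


def stage_roi_compare(config: PipelineConfig, work: Path) -> pd.DataFrame:
    roi_dir = work / "roi"
    responses_path = roi_dir / "responses.tsv"
    if not responses_path.exists():
        raise FileNotFoundError(f"run roi-extract first ({responses_path} missing)")
    responses = pd.read_csv(responses_path, sep="\t", comment="#")
    index = json.loads((roi_dir / "roi_index.json").read_text())["rois"]
    source_by_name = {r["name"]: r["source"] for r in index}
    tests = []
    pairs = [("Value", "Mathematical"), ("Value", "Emotion"), ("Mathematical", "Emotion")]
    for name in sorted(responses["roi"].unique()):
        for phase in PHASES:
            for task_a, task_b in pairs:
                res = roi_compare(responses, name, phase, task_a, task_b)
                tests.append(
                    (
                        name,
                        source_by_name.get(name, "unknown"),
                        phase,
                        task_a,
                        task_b,
                        res.t,
                        res.df,
                        res.p,
                        res.ci_low,
                        res.ci_high,
                    )
                )
    test_table = pd.DataFrame(
        tests,
        columns=[
            "roi",
            "source",
            "phase",
            "task_a",
            "task_b",
            "t",
            "df",
            "p",
            "ci_low",
            "ci_high",
        ],
    )
    _write_table(roi_dir / "roi_tests.tsv", test_table, config)
    return test_table


def stage_roi(config: PipelineConfig, work: Path) -> pd.DataFrame:
    responses = stage_roi_extract(config, work)
    stage_roi_compare(config, work)
    return responses


def stage_similarity(config: PipelineConfig, work: Path) -> dict:
    maps = _load_group_maps(config, work)
    contrasts = _load_subject_contrasts(work)
    gray = _gray_mask(config, work)
    sim_dir = work / "similarity"
    sim_dir.mkdir(parents=True, exist_ok=True)

    tables = []
    tests = {}
    for phase in PHASES:
        sig = {}
        for task in TASKS:
            stat = maps[task][phase]
            crit = t_threshold(stat.df, config.voxel_p, "positive")
            t = stat.values.values
            sig[task] = Mask(
                membership=np.isfinite(t) & (t >= crit), grid=stat.values.grid
            )
        mask_for_pair = {
            ("Value", "Mathematical"): similarity_mask(
                sig["Value"], sig["Mathematical"], gray, config.similarity_combine
            ),
            ("Value", "Emotion"): similarity_mask(
                sig["Value"], sig["Emotion"], gray, config.similarity_combine
            ),
        }
        table = subject_similarity(contrasts, mask_for_pair, phase)
        tables.append(table)
        res = compare_pairs(table, "Value-Mathematical", "Value-Emotion", phase)
        tests[phase] = {
            "t": res.t,
            "df": res.df,
            "p": res.p,
            "mean_diff": res.mean_diff,
            "mean_z": {
                pair: float(table[table["pair"] == pair]["z"].mean())
                for pair in ("Value-Mathematical", "Value-Emotion")
            },
        }
    full = pd.concat(tables, ignore_index=True)
    _write_table(sim_dir / "similarity.tsv", full, config)
    _write_json(sim_dir / "similarity_tests.json", {"tests": tests}, config)
    return tests


def stage_behavior(config: PipelineConfig, work: Path) -> dict:
    table = pd.read_csv(work / "dataset" / "behavior.tsv", sep="\t")
    beh_dir = work / "behavior"
    beh_dir.mkdir(parents=True, exist_ok=True)
    out = {}
    for measure in ("accuracy", "mean_rt"):
        anova = behavior_mod.anova_tasks(table, measure)
        tukey = behavior_mod.tukey_posthoc(table, measure)
        out[measure] = {
            "anova": dataclasses.asdict(anova),
            "tukey": tukey.to_dict(orient="records"),
        }
    _write_json(beh_dir / "behavior_tests.json", out, config)
    return out


def stage_report(config: PipelineConfig, work: Path) -> dict:
    report = {
        "stages": {},
        "cluster_table": None,
    }
    clusters_path = work / "conjunction" / "clusters.tsv"
    if clusters_path.exists():
        table = pd.read_csv(clusters_path, sep="\t", comment="#")
        report["cluster_table"] = table.to_dict(orient="records")
    for name, path in [
        ("mc", work / "mc" / "mc_result.json"),
        ("similarity", work / "similarity" / "similarity_tests.json"),
        ("behavior", work / "behavior" / "behavior_tests.json"),
    ]:
        if path.exists():
            report["stages"][name] = json.loads(path.read_text())
    return _write_json(work / "report.json", report, config)


def run_pipeline(config: PipelineConfig, work: str | Path) -> dict:
    """Execute every stage in dependency order and write report.json."""
    work = Path(work)
    work.mkdir(parents=True, exist_ok=True)
    stages = [
        ("simulate", stage_simulate),
        ("glm", stage_glm),
        ("mc-threshold", stage_mc),
        ("conjoin", stage_conjoin),
        ("roi", stage_roi),
        ("similarity", stage_similarity),
        ("behavior", stage_behavior),
    ]
    for name, fn in stages:
        try:
            fn(config, work)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return stage_report(config, work)
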