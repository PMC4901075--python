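"""Design matrices and voxel-wise least-squares modelling.

The subject-level model convolves per-condition boxcars with a canonical
double-gamma haemodynamic response, adds six motion covariates and an
intercept, and fits ordinary least squares at every masked voxel.  Subject
contrasts are run-weighted means of per-run contrast values; the group map
is a one-sample t versus zero across subjects.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .volume_io import AcquisitionGrid, Mask, Volume

__all__ = [
    "HRFParams",
    "DesignMatrix",
    "BetaMaps",
    "StatMap",
    "DesignRankError",
    "canonical_hrf",
    "convolve_events",
    "build_design",
    "grouping_for_task",
    "task_contrast",
    "fit_run",
    "subject_contrast",
    "group_tmap",
]

PHASES = ("choice", "feedback")


@dataclasses.dataclass(frozen=True)
class HRFParams:
    """Double-gamma haemodynamic response parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "undershoot_ratio",
            "duration",
            "dt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.duration < self.undershoot_delay:
            raise ValueError("duration must cover the undershoot delay")


def canonical_hrf(params: HRFParams = HRFParams()) -> np.ndarray:
    """Sampled double-gamma kernel, peak-normalized to 1.

    The kernel is the difference of two gamma densities (response minus a
    scaled undershoot) evaluated on ``arange(0, duration, dt)``.
    """
    t = np.arange(0.0, params.duration, params.dt)
    peak = stats.gamma.pdf(
        t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    kernel = peak - params.undershoot_ratio * under
    return kernel / kernel.max()


def convolve_events(
    onsets: Sequence[float],
    durations: Sequence[float],
    n_scans: int,
    tr: float,
    hrf: HRFParams = HRFParams(),
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at scan acquisition times.

    Events are rendered as boxcars on a microtime lattice of step ``hrf.dt``,
    convolved with the canonical kernel, and sampled at t = k * TR.
    """
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if onsets.size == 0:
        return np.zeros(n_scans)
    dt = hrf.dt
    n_fine = int(np.ceil(n_scans * tr / dt)) + 1
    boxcar = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        boxcar[max(i0, 0) : min(max(i1, i0 + 1), n_fine)] = 1.0
    fine = np.convolve(boxcar, canonical_hrf(hrf))[:n_fine] * dt
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)
    return fine[np.minimum(scan_idx, n_fine - 1)]


# ---------------------------------------------------------------------------
# condition grouping


def _value_like_grouping(row: pd.Series) -> str:
    cond = str(row["condition"])
    if cond.startswith("choice"):
        return cond
    level = cond.split("_", 1)[1] if "_" in cond else ""
    suffix = f"_{level}" if level else ""
    return f"fb_{row['outcome']}{suffix}"


def _emotion_grouping(row: pd.Series) -> str:
    cond = str(row["condition"])
    if cond.startswith("choice"):
        return "choice"
    return f"fb_{row['outcome']}"


def grouping_for_task(task: str) -> Callable[[pd.Series], str]:
    """Condition-grouping rule producing the per-task regressor labels.

    Value: difficulty-specific choice plus difficulty-specific gain and
    no-gain feedback (15 columns for 5 levels).  Mathematical: the same rule
    over correct/incorrect feedback (9 columns for 3 levels).  Emotion: one
    choice column plus gain/no-gain feedback (3 columns).
    """
    if task in ("Value", "Mathematical"):
        return _value_like_grouping
    if task == "Emotion":
        return _emotion_grouping
    raise ValueError(f"unknown task {task!r}")


@dataclasses.dataclass
class DesignMatrix:
    """Labeled regressors for one run."""

    frame: pd.DataFrame
    task_columns: list[str]
    nuisance_columns: list[str]

    def __post_init__(self) -> None:
        labels = list(self.frame.columns)
        if len(set(labels)) != len(labels):
            raise ValueError("design column labels must be unique")
        for col in self.task_columns:
            if not np.any(self.frame[col].to_numpy() != 0):
                raise ValueError(f"all-zero task column {col!r}")

    @property
    def n_scans(self) -> int:
        return len(self.frame)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


def build_design(
    schedule: pd.DataFrame,
    grid: AcquisitionGrid,
    hrf: HRFParams = HRFParams(),
    motion: pd.DataFrame | None = None,
    grouping: Callable[[pd.Series], str] | None = None,
    n_scans: int | None = None,
) -> DesignMatrix:
    """Build the run design: grouped condition regressors + motion + intercept."""
    if grouping is None:
        grouping = _value_like_grouping
    if n_scans is None:
        if motion is None:
            raise ValueError("supply n_scans or a motion table")
        n_scans = len(motion)
    run_length = n_scans * grid.tr
    if len(schedule) and schedule["onset_s"].max() >= run_length:
        raise ValueError("schedule onsets extend past the end of the run")

    columns: dict[str, list[tuple[float, float]]] = {}
    for _, row in schedule.iterrows():
        label = grouping(row)
        columns.setdefault(label, []).append(
            (float(row["onset_s"]), float(row["duration_s"]))
        )
    if not columns:
        warnings.warn("empty schedule: design has only nuisance columns")

    data: dict[str, np.ndarray] = {}
    task_columns = sorted(columns)
    for label in task_columns:
        onsets, durations = zip(*columns[label])
        data[label] = convolve_events(onsets, durations, n_scans, grid.tr, hrf)

    nuisance_columns: list[str] = []
    if motion is not None:
        if len(motion) != n_scans:
            raise ValueError("motion rows must equal scan count")
        for col in motion.columns:
            data[f"motion_{col}"] = motion[col].to_numpy(dtype=float)
            nuisance_columns.append(f"motion_{col}")
    data["intercept"] = np.ones(n_scans)
    nuisance_columns.append("intercept")

    frame = pd.DataFrame(data, columns=task_columns + nuisance_columns)
    return DesignMatrix(
        frame=frame, task_columns=task_columns, nuisance_columns=nuisance_columns
    )


def task_contrast(design: DesignMatrix, phase: str) -> dict[str, float]:
    """Equal-weight average over the choice or feedback condition columns."""
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    if phase == "choice":
        cols = [c for c in design.task_columns if c.startswith("choice")]
    else:
        cols = [c for c in design.task_columns if c.startswith("fb_")]
    if not cols:
        raise ValueError(f"no {phase} columns in design")
    return {c: 1.0 / len(cols) for c in cols}


# ---------------------------------------------------------------------------
# fitting


class DesignRankError(ValueError):
    """Raised when the design matrix is rank deficient."""


@dataclasses.dataclass
class BetaMaps:
    """Per-column coefficient volumes plus residual variance for one run."""

    betas: dict[str, np.ndarray]
    residual_variance: np.ndarray
    df_error: int
    grid: AcquisitionGrid
    task_columns: list[str]


def _check_rank(X: np.ndarray, labels: Sequence[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [labels[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise DesignRankError(f"rank-deficient design; collinear columns: {bad}")


def fit_run(
    run: np.ndarray,
    design: DesignMatrix,
    mask: Mask | None = None,
    grid: AcquisitionGrid | None = None,
) -> BetaMaps:
    """Ordinary least squares at every masked voxel of a (x, y, z, t) run."""
    run = np.asarray(run, dtype=float)
    if run.ndim != 4:
        raise ValueError("run must be 4-D (x, y, z, t)")
    if grid is None:
        if mask is None:
            raise ValueError("supply a grid or a mask carrying one")
        grid = mask.grid
    if run.shape[:3] != grid.dims:
        raise ValueError("run spatial shape does not match grid")
    X = design.values
    if run.shape[3] != X.shape[0]:
        raise ValueError(
            f"frame count {run.shape[3]} != design rows {X.shape[0]}"
        )
    labels = list(design.frame.columns)
    _check_rank(X, labels)

    member = mask.membership if mask is not None else np.ones(grid.dims, bool)
    Y = run[member].T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df_error = X.shape[0] - X.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = (resid**2).sum(axis=0) / df_error if df_error > 0 else np.full(
            Y.shape[1], np.nan
        )

    betas: dict[str, np.ndarray] = {}
    for i, label in enumerate(labels):
        vol = np.zeros(grid.dims)
        vol[member] = beta[i]
        betas[label] = vol
    rv = np.zeros(grid.dims)
    rv[member] = sigma2
    return BetaMaps(
        betas=betas,
        residual_variance=rv,
        df_error=df_error,
        grid=grid,
        task_columns=list(design.task_columns),
    )


def run_contrast(run_fit: BetaMaps, contrast: Mapping[str, float]) -> np.ndarray:
    """c' beta for one run; contrast keys must name fitted columns."""
    missing = set(contrast) - set(run_fit.betas)
    if missing:
        raise ValueError(f"contrast references unknown columns {sorted(missing)}")
    out = np.zeros(run_fit.grid.dims)
    for label, weight in contrast.items():
        out += weight * run_fit.betas[label]
    return out


def subject_contrast(
    runs: Sequence[BetaMaps],
    contrast: Mapping[str, float],
    weights: Sequence[float] | None = None,
) -> Volume:
    """Run-weighted mean of per-run contrast values.

    Weights default to 1/n_runs (each run of a task contributes equally) and
    are normalized to sum to one.
    """
    if not runs:
        raise ValueError("need at least one run")
    if weights is None:
        weights = [1.0 / len(runs)] * len(runs)
    if len(weights) != len(runs):
        raise ValueError("weight vector length mismatch")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    out = np.zeros(runs[0].grid.dims)
    for weight, fit in zip(w, runs):
        out += weight * run_contrast(fit, contrast)
    return Volume(values=out, grid=runs[0].grid)


@dataclasses.dataclass
class StatMap:
    """Voxel-wise t statistics with their degrees of freedom."""

    values: Volume
    df: int
    task: str | None = None
    phase: str | None = None
    sign_convention: str = "positive=above baseline"


def group_tmap(
    contrasts: Sequence[Volume],
    task: str | None = None,
    phase: str | None = None,
) -> StatMap:
    """One-sample t versus zero across subjects at each voxel.

    Implements the task-vs-baseline cell contrast of a between-cell factorial
    over tasks.  Zero-variance voxels yield non-finite t values.
    """
    if len(contrasts) < 2:
        raise ValueError("need >= 2 subjects")
    grid = contrasts[0].grid
    for c in contrasts[1:]:
        if not c.grid.same_geometry(grid):
            raise ValueError("subject contrasts must share one grid")
    data = np.stack([c.values for c in contrasts], axis=-1)
    n = data.shape[-1]
    mean = data.mean(axis=-1)
    sd = data.std(axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    return StatMap(values=Volume(values=t, grid=grid), df=n - 1, task=task, phase=phase)
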