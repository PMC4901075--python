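"""Connected components and Monte-Carlo cluster-extent calibration.

The extent threshold is calibrated by repeatedly thresholding smoothed,
restandardized Gaussian noise and recording the maximal suprathreshold
cluster size, following the simulation approach used with fixed-smoothness
cluster correction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, stats

from .volume_io import AcquisitionGrid, Mask, Volume

__all__ = [
    "ClusterSet",
    "MCResult",
    "fwhm_to_sigma_mm",
    "connectivity_structure",
    "label_clusters",
    "extent_filter",
    "smooth_gaussian",
    "mc_extent_threshold",
]


def fwhm_to_sigma_mm(fwhm: float) -> float:
    """Gaussian sigma (mm) for a given full width at half maximum."""
    return fwhm / np.sqrt(8.0 * np.log(2.0))


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3-D neighbourhood footprint for 6-, 18- or 26-connectivity."""
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order[connectivity])


@dataclasses.dataclass
class ClusterSet:
    """Labelled connected components of a mask.

    ``labels`` holds integers 0 (background) .. K; ``sizes[k-1]`` is the voxel
    count of label k; ``peaks[k-1]`` is the world-mm coordinate of the
    maximal statistic (or first voxel, if no statistic was supplied).
    """

    labels: np.ndarray
    sizes: np.ndarray
    peaks: list[np.ndarray]
    grid: AcquisitionGrid

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def label_clusters(
    mask: Mask,
    connectivity: int = 26,
    stat: Volume | None = None,
) -> ClusterSet:
    """Label connected components under the chosen neighbourhood."""
    struct = connectivity_structure(connectivity)
    labels, n = ndimage.label(mask.membership, structure=struct)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    peaks: list[np.ndarray] = []
    for k in range(1, n + 1):
        idx = np.argwhere(labels == k)
        if stat is not None:
            vals = stat.values[tuple(idx.T)]
            peak_idx = idx[int(np.argmax(vals))]
        else:
            peak_idx = idx[0]
        peaks.append(mask.grid.voxel_to_world(peak_idx))
    return ClusterSet(labels=labels, sizes=sizes, peaks=peaks, grid=mask.grid)


def extent_filter(clusters: ClusterSet, k: int) -> Mask:
    """Union of clusters with at least ``k`` voxels."""
    if k < 1:
        raise ValueError("extent threshold must be >= 1")
    keep = np.flatnonzero(clusters.sizes >= k) + 1
    membership = np.isin(clusters.labels, keep)
    return Mask(membership=membership, grid=clusters.grid)


def smooth_gaussian(volume: Volume, fwhm: float) -> Volume:
    """Separable Gaussian smoothing with per-axis sigma = FWHM-sigma / voxel size."""
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return Volume(values=volume.values.copy(), grid=volume.grid)
    sigma_vox = [fwhm_to_sigma_mm(fwhm) / vs for vs in volume.grid.voxel_size]
    smoothed = ndimage.gaussian_filter(volume.values, sigma=sigma_vox)
    return Volume(values=smoothed, grid=volume.grid)


@dataclasses.dataclass
class MCResult:
    """Null distribution of maximal cluster extents."""

    null_max_sizes: np.ndarray
    n_iter: int
    seed: int
    voxel_p: float
    fwhm: float
    connectivity: int

    def alpha_for_k(self, k: int) -> float:
        """Estimated family-wise probability of any cluster >= k voxels."""
        return float(np.mean(self.null_max_sizes >= k))

    def k_for_alpha(self, alpha: float) -> int:
        """Smallest extent threshold achieving the target family-wise alpha."""
        k = 1
        upper = int(self.null_max_sizes.max()) + 1
        while k <= upper and self.alpha_for_k(k) > alpha:
            k += 1
        return k

    def alpha_table(self, k_max: int | None = None) -> dict[int, float]:
        if k_max is None:
            k_max = int(self.null_max_sizes.max()) + 1
        return {k: self.alpha_for_k(k) for k in range(1, k_max + 1)}


def mc_extent_threshold(
    grid: AcquisitionGrid,
    mask: Mask | None = None,
    fwhm: float = 8.0,
    voxel_p: float = 0.001,
    n_iter: int = 10_000,
    seed: int = 0,
    connectivity: int = 26,
) -> MCResult:
    """Monte-Carlo null distribution of the maximal cluster extent.

    Each iteration fills the grid with unit Gaussian noise, smooths to the
    stated FWHM, restandardizes within the mask to unit variance, thresholds
    at the one-sided voxel_p z-cutoff and records the maximal suprathreshold
    cluster size.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < voxel_p <= 1:
        raise ValueError("voxel_p must lie in (0, 1]")
    member = mask.membership if mask is not None else np.ones(grid.dims, bool)
    if not member.any():
        raise ValueError("empty simulation mask")
    struct = connectivity_structure(connectivity)
    sigma_vox = [fwhm_to_sigma_mm(fwhm) / vs for vs in grid.voxel_size]
    z_cut = stats.norm.isf(voxel_p)
    rng = np.random.default_rng(seed)

    max_sizes = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        noise = rng.standard_normal(grid.dims)
        if fwhm > 0:
            noise = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        vals = noise[member]
        noise_z = (noise - vals.mean()) / vals.std()
        supra = member & (noise_z >= z_cut)
        if not supra.any():
            continue
        labels, n = ndimage.label(supra, structure=struct)
        if n:
            max_sizes[it] = int(np.bincount(labels.ravel())[1:].max())
    return MCResult(
        null_max_sizes=max_sizes,
        n_iter=n_iter,
        seed=seed,
        voxel_p=voxel_p,
        fwhm=fwhm,
        connectivity=connectivity,
    )
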