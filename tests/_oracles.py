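"""Independent reference implementations used only to check the package.

These deliberately avoid the library calls used by the implementation
(scipy.ndimage.label, vectorized statistics) so that each check is a genuine
dual route.
"""

from __future__ import annotations

import math

import numpy as np

_OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    18: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0) and abs(dx) + abs(dy) + abs(dz) <= 2
    ],
    26: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
}


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Breadth-first flood fill; returns the set of voxel tuples per component."""
    mask = np.asarray(mask, dtype=bool)
    offsets = _OFFSETS[connectivity]
    visited = np.zeros_like(mask)
    shape = mask.shape
    components: list[frozenset] = []
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        queue = [start]
        visited[start] = True
        comp = []
        while queue:
            vox = queue.pop()
            comp.append(vox)
            x, y, z = vox
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (
                    0 <= nx < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nz < shape[2]
                    and mask[nx, ny, nz]
                    and not visited[nx, ny, nz]
                ):
                    visited[nx, ny, nz] = True
                    queue.append((nx, ny, nz))
        components.append(frozenset(comp))
    return components


def label_components(labels: np.ndarray) -> list[frozenset]:
    """Component voxel sets from an integer label volume (0 = background)."""
    out = []
    for k in range(1, int(labels.max()) + 1):
        vox = {tuple(v) for v in np.argwhere(labels == k)}
        if vox:
            out.append(frozenset(vox))
    return out


def pearson_r(a, b) -> float:
    """Textbook covariance / (sd_a sd_b) with explicit loops."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)


def fisher_z(r: float) -> float:
    return 0.5 * math.log((1 + r) / (1 - r))


def paired_t(a, b) -> tuple[float, int, float]:
    """Difference-score t, df and two-sided p via the t survival function."""
    from scipy import stats

    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    se = math.sqrt(var / n)
    t = mean / se
    return t, n - 1, 2 * stats.t.sf(abs(t), n - 1)


def oneway_anova_ss(groups) -> tuple[float, int, int]:
    """Sums-of-squares decomposition F and dfs for independent groups."""
    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(
        sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups
    )
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, df_b, df_w


def sphere_voxel_count(grid, center_mm, radius_mm) -> int:
    """Count lattice sites within radius by explicit enumeration."""
    count = 0
    for i in range(grid.dims[0]):
        for j in range(grid.dims[1]):
            for k in range(grid.dims[2]):
                world = grid.voxel_to_world((i, j, k))
                d2 = sum((w - c) ** 2 for w, c in zip(world, center_mm))
                if d2 <= radius_mm**2:
                    count += 1
    return count
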