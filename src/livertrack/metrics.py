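"""Registration and tumor-localization metrics, and paired statistics.

Mesh metrics operate on node sets in one-to-one correspondence (RMSE) or as
point clouds (HD95); tumor metrics operate on volumetric binary masks
(center-of-mass error, Dice coefficient, surface HD95).  Paired model
comparisons use the Wilcoxon matched-pairs signed-rank test (delegated to
scipy) with the Hodges-Lehmann estimate of the median difference and its
95 % confidence interval implemented from the Walsh-average order
statistics.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .grid import GridSpec
from .mesh import TriMesh

__all__ = [
    "rmse", "hd95", "come", "dsc", "mask_surface_points",
    "hodges_lehmann", "wilcoxon_signed_rank",
]


def _nodes(m):
    return m.nodes if isinstance(m, TriMesh) else np.asarray(m, float)


def rmse(pred_mesh, gt_mesh) -> float:
    """Root mean squared node-wise distance between corresponding meshes."""
    p, g = _nodes(pred_mesh), _nodes(gt_mesh)
    if p.shape != g.shape:
        raise ValueError("rmse requires node correspondence")
    return float(np.sqrt(((p - g) ** 2).sum(axis=1).mean()))


def hd95(points_x, points_y) -> float:
    """95-percentile symmetric Hausdorff distance between two point sets.

    max( P95 of d(x, Y), P95 of d(y, X) ) with d the nearest-point
    distance; inputs may be meshes (their nodes are used) or (N, 3) arrays.
    """
    x, y = _nodes(points_x), _nodes(points_y)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("hd95 requires non-empty point sets")
    dxy, _ = cKDTree(y).query(x)
    dyx, _ = cKDTree(x).query(y)
    return float(max(np.percentile(dxy, 95), np.percentile(dyx, 95)))


def _centroid(mask: np.ndarray, grid: GridSpec) -> np.ndarray:
    idx = np.argwhere(mask)
    if len(idx) == 0:
        raise ValueError("empty mask has no centroid")
    return np.asarray(grid.origin) + idx.mean(axis=0) * np.asarray(grid.spacing)


def come(mask_pred: np.ndarray, mask_gt: np.ndarray, grid: GridSpec) -> float:
    """Center-of-mass error: distance between mask centroids, mm."""
    return float(np.linalg.norm(_centroid(mask_pred, grid) - _centroid(mask_gt, grid)))


def dsc(mask_v1: np.ndarray, mask_v2: np.ndarray) -> float:
    """Dice similarity coefficient 2|V1 n V2| / (|V1| + |V2|)."""
    v1 = np.asarray(mask_v1, bool)
    v2 = np.asarray(mask_v2, bool)
    if v1.shape != v2.shape:
        raise ValueError("masks must share a grid")
    s = int(v1.sum()) + int(v2.sum())
    if s == 0:
        raise ValueError("Dice undefined for two empty masks")
    return 2.0 * int((v1 & v2).sum()) / s


def mask_surface_points(mask: np.ndarray, grid: GridSpec) -> np.ndarray:
    """World coordinates of a mask's surface voxels (for mask HD95)."""
    from scipy import ndimage

    mask = np.asarray(mask, bool)
    surf = mask & ~ndimage.binary_erosion(mask)
    idx = np.argwhere(surf)
    return np.asarray(grid.origin) + idx * np.asarray(grid.spacing)


# ---------------------------------------------------------------------------
# paired statistics
# ---------------------------------------------------------------------------

def _signed_rank_cdf_quantile(n: int, alpha: float) -> int:
    """Largest k with P(W <= k) <= alpha/2 under H0 of the signed-rank
    statistic for sample size n (exact via subset-sum counting)."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    cdf = np.cumsum(counts) / 2.0 ** n
    k = int(np.searchsorted(cdf, alpha / 2.0, side="right") - 1)
    return max(k, -1)


def hodges_lehmann(paired_differences, alpha: float = 0.05):
    """Hodges-Lehmann estimate of a paired median difference with CI.

    The estimate is the median of all Walsh averages (d_i + d_j)/2 over
    i <= j; the (1-alpha) confidence interval takes the Walsh-average order
    statistics at the exact Wilcoxon signed-rank critical values (normal
    approximation beyond n = 300).

    Returns ``(estimate, (ci_low, ci_high))``.
    """
    d = np.sort(np.asarray(paired_differences, float))
    n = len(d)
    if n == 0:
        raise ValueError("hodges_lehmann requires at least one pair")
    i, j = np.triu_indices(n)
    walsh = np.sort((d[i] + d[j]) / 2.0)
    est = float(np.median(walsh))
    m = len(walsh)
    if n == 1:
        return est, (float(walsh[0]), float(walsh[-1]))
    if n <= 300:
        k = _signed_rank_cdf_quantile(n, alpha)
    else:
        from scipy.stats import norm

        mean = n * (n + 1) / 4.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        k = int(np.floor(mean + norm.ppf(alpha / 2.0) * sd))
    # CI = (W_(k+1), W_(M-k)) in 1-based order statistics
    if k < 0:
        return est, (float(walsh[0]), float(walsh[-1]))
    return est, (float(walsh[k]), float(walsh[m - 1 - k]))


def wilcoxon_signed_rank(a, b):
    """Wilcoxon matched-pairs signed-rank p-value (two-sided), via scipy."""
    from scipy.stats import wilcoxon

    return float(wilcoxon(np.asarray(a, float), np.asarray(b, float)).pvalue)
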