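"""Colony packing statistics from nuclear positions.

Tightly packed colonies put every nucleus close to a neighbour, while
flattened, partially detached colonies stretch the right tail of the
nearest-neighbour distance distribution.  Comparing the two distributions
(two-sample Kolmogorov-Smirnov plus medians) quantifies the packing contrast
between conditions.  Distances are in pixels unless a pixel size is supplied,
and no border-edge correction is applied.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp

__all__ = ["nearest_neighbor_distances", "compare_nn_distributions", "points_from_cells"]


def points_from_cells(cells, pixel_size: float | None = None) -> np.ndarray:
    """Extract an (n, 2) coordinate array from a cell table's centroid columns."""
    pts = np.column_stack([cells["centroid_x"], cells["centroid_y"]]).astype(float)
    if pixel_size is not None:
        pts = pts * pixel_size
    return pts


def nearest_neighbor_distances(points: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to its closest *other* point.

    Uses a k-d tree (k = 2 query; the nearest hit is the point itself).
    Coincident points get distance 0.  A single point has no neighbour and is
    an error.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError(f"expected an (n, d) coordinate array, got shape {points.shape}")
    if not np.all(np.isfinite(points)):
        raise ValueError("coordinates must be finite")
    if len(points) < 2:
        raise ValueError("nearest-neighbor distances need at least 2 points")
    dist, _ = cKDTree(points).query(points, k=2)
    return dist[:, 1]


def compare_nn_distributions(a: np.ndarray, b: np.ndarray) -> dict:
    """Compare two nearest-neighbour distance samples.

    Returns the two-sample KS statistic and p-value plus the per-sample
    medians and their difference (median_b - median_a).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both distance samples must be non-empty")
    if np.array_equal(a, b):
        ks, p = 0.0, 1.0
    else:
        res = ks_2samp(a, b)
        ks, p = float(res.statistic), float(res.pvalue)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return {
        "ks_statistic": ks,
        "p_value": p,
        "median_a": med_a,
        "median_b": med_b,
        "median_difference": med_b - med_a,
    }
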