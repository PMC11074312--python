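"""Single-molecule RNA-FISH quantification.

Individual transcripts appear as diffraction-limited spots in a z-stack.  The
pipeline enhances blobs with a Laplacian-of-Gaussian (LoG) filter, collapses
the stack by maximum-intensity projection (filter first, then project),
detects spots as local maxima above a robust threshold, and assigns each spot
to the segmented cell under it, yielding per-cell transcript counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

__all__ = [
    "log_filter",
    "max_intensity_projection",
    "detect_spots",
    "assign_spots_to_cells",
    "count_transcripts",
]


def log_filter(stack: np.ndarray, sigma_px: float) -> np.ndarray:
    """Scale-normalised, negated Laplacian-of-Gaussian blob filter.

    Bright blobs of radius ~ sigma become positive maxima of the response.
    Linear in the input; a constant image maps to ~ 0.
    """
    stack = np.asarray(stack, dtype=float)
    if sigma_px <= 0:
        raise ValueError("sigma must be positive")
    if sigma_px >= min(stack.shape[-2:]) / 4:
        raise ValueError(
            f"sigma {sigma_px} too large for image of shape {stack.shape[-2:]} "
            "(must be < min(height, width) / 4)"
        )
    return -(sigma_px**2) * ndi.gaussian_laplace(stack, sigma=sigma_px)


def max_intensity_projection(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the leading z axis of a 3-D stack.

    A 2-D input is already a projection; it is returned unchanged with a
    warning.  Idempotent by construction.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        warnings.warn("input has no z dimension; returning it unchanged", stacklevel=2)
        return stack.copy()
    if stack.ndim != 3:
        raise ValueError(f"expected a (z, y, x) stack, got shape {stack.shape}")
    return stack.max(axis=0)


def detect_spots(
    filtered: np.ndarray,
    *,
    threshold: str | float = "k_sigma",
    k: float = 10.0,
    min_separation_px: int = 2,
) -> pd.DataFrame:
    """Call spots as local maxima of a (LoG-filtered, projected) image.

    ``threshold='k_sigma'`` uses median + k x MAD of the filtered image, a
    robust default independent of spot density; a number is an absolute
    cutoff.  The default k = 10 clears the extreme-value tail of the
    z-projected filtered noise (a projection keeps the *maximum* noise
    excursion per pixel, so the cutoff must sit well above a per-pixel
    quantile).  Non-maximum suppression keeps one call per ``min_separation_px``
    neighbourhood.  Returns columns (x, y, intensity).
    """
    filtered = np.asarray(filtered, dtype=float)
    if filtered.ndim != 2:
        raise ValueError("detection expects a 2-D (projected) image")
    if threshold == "k_sigma":
        med = np.median(filtered)
        mad = np.median(np.abs(filtered - med))
        cutoff = med + k * mad
    else:
        cutoff = float(threshold)
    peaks = peak_local_max(
        filtered,
        min_distance=min_separation_px,
        threshold_abs=cutoff,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return pd.DataFrame(columns=["x", "y", "intensity"])
    return pd.DataFrame(
        {
            "x": peaks[:, 1].astype(float),
            "y": peaks[:, 0].astype(float),
            "intensity": filtered[peaks[:, 0], peaks[:, 1]],
        }
    )


def assign_spots_to_cells(spots: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Assign each spot the segmentation label under its (x, y) position.

    Returns one row per cell label (plus label 0 for spots on background,
    the unassigned bucket) with its spot count; cells without spots get 0.
    Spot coordinates outside the label image are an error.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    counts = {int(lab): 0 for lab in np.unique(labels)}
    counts.setdefault(0, 0)
    for _, sp in spots.iterrows():
        r, c = int(round(sp["y"])), int(round(sp["x"]))
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"spot at ({sp['x']}, {sp['y']}) lies outside the image")
        counts[int(labels[r, c])] += 1
    table = pd.DataFrame(
        sorted(counts.items()), columns=["cell", "n_spots"]
    )
    return table


def count_transcripts(
    stack: np.ndarray,
    labels: np.ndarray,
    *,
    sigma_px: float = 1.5,
    threshold: str | float = "k_sigma",
    k: float = 10.0,
    min_separation_px: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full smFISH readout: LoG filter, MIP, detect, assign.

    Returns ``(spots, per_cell_counts)``.
    """
    filtered = log_filter(stack, sigma_px)
    mip = max_intensity_projection(filtered) if filtered.ndim == 3 else filtered
    spots = detect_spots(
        mip, threshold=threshold, k=k, min_separation_px=min_separation_px
    )
    return spots, assign_spots_to_cells(spots, labels)
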