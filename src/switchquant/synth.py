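"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of the study system: colony
images of DAPI-stained nuclei whose packing can be tight (dome-like, as in
knockout cells) or spread (flattened with detached single cells, as in
differentiating wild-type cells); per-nucleus marker fluorescence drawn from
ON/OFF log-normal mixtures in which the probability that the response channel
(NANOG) is ON *decreases* with the driver channel's (OCT6-mCherry)
fold-over-background through a repressive Hill link — the bistable,
dose-dependent repression the analyses are designed to measure; 3-D
diffraction-limited spot stacks for single-molecule FISH; and gene universes
with a known peak-bearing fraction for the enrichment bootstrap.

All log-normal channel levels are parameterised in natural-log
*fold-over-background* units, so an OFF log-mean of 0 puts negative cells at
background (fold ~ 1) and the 2x / 4x fold thresholds used downstream are
meaningful by construction.  Every generator is exactly reproducible from its
seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imaging import ImageStack

__all__ = [
    "ChannelModel",
    "ColonyParams",
    "ExpressionParams",
    "SpotParams",
    "hill_repression",
    "generate_cell_table",
    "generate_colony_image",
    "ground_truth_labels",
    "generate_gene_universe",
    "generate_spot_stack",
]


def hill_repression(fold: np.ndarray | float, f_half: float, h: float) -> np.ndarray | float:
    """P(response ON | driver fold) = 1 / (1 + (fold / f_half)^h).

    A decreasing Hill function: at fold << f_half the response is almost
    surely ON, at fold >> f_half almost surely OFF; ``h`` sets the steepness
    of the switch (h -> inf gives a hard step at ``f_half``).
    """
    fold = np.asarray(fold, dtype=float)
    out = 1.0 / (1.0 + (fold / f_half) ** h)
    return float(out) if out.ndim == 0 else out


@dataclass
class ChannelModel:
    """ON/OFF log-normal mixture for one marker channel (log-fold units)."""

    on_log_mean: float
    on_log_sd: float
    off_log_mean: float = 0.0
    off_log_sd: float = 0.1

    def __post_init__(self):
        vals = [self.on_log_mean, self.on_log_sd, self.off_log_mean, self.off_log_sd]
        if not all(np.isfinite(vals)):
            raise ValueError("channel mixture parameters must be finite")
        if self.on_log_mean <= self.off_log_mean:
            raise ValueError("ON log-mean must exceed OFF log-mean")
        if self.on_log_sd <= 0 or self.off_log_sd <= 0:
            raise ValueError("log-sds must be positive")

    def sample_fold(self, rng: np.random.Generator, on: np.ndarray) -> np.ndarray:
        mu = np.where(on, self.on_log_mean, self.off_log_mean)
        sd = np.where(on, self.on_log_sd, self.off_log_sd)
        return np.exp(rng.normal(mu, sd))


@dataclass
class ExpressionParams:
    """Joint expression model of the driver and response channels.

    The driver is positive with probability ``fraction_driver_positive``; the
    response state is drawn from the repressive Hill link evaluated at the
    realised driver fold-over-background.
    """

    driver: ChannelModel = field(
        default_factory=lambda: ChannelModel(on_log_mean=np.log(3.0), on_log_sd=0.9)
    )
    response: ChannelModel = field(
        default_factory=lambda: ChannelModel(on_log_mean=np.log(8.0), on_log_sd=0.4)
    )
    background_level: float = 100.0
    f_half: float = 2.0
    h: float = 6.0
    fraction_driver_positive: float = 0.7
    dapi_log_mean: float = float(np.log(10.0))
    dapi_log_sd: float = 0.1
    driver_name: str = "mCherry"
    response_name: str = "NANOG"
    seed: int = 0

    def __post_init__(self):
        if not np.isfinite(
            [self.background_level, self.f_half, self.h, self.fraction_driver_positive]
        ).all():
            raise ValueError("expression parameters must be finite")
        if not 0.0 <= self.fraction_driver_positive <= 1.0:
            raise ValueError("fraction_driver_positive must be in [0, 1]")
        if self.f_half <= 0 or self.h <= 0:
            raise ValueError("Hill parameters require f_half > 0 and h > 0")
        if self.background_level <= 0:
            raise ValueError("background_level must be positive")


@dataclass
class ColonyParams:
    """Geometry of simulated colonies.

    ``nuclei_per_colony`` is (mean, dispersion) with dispersion = variance /
    mean: 0 gives the exact rounded mean per colony, 1 Poisson counts, > 1
    negative-binomial overdispersion.  ``packing_mode`` 'tight' draws nucleus
    centers within small colony disks at minimum separation ~ 2 radii (the
    compact, dome-like morphology); 'spread' uses larger disks plus a fraction
    of detached singletons scattered over the image (the flattened morphology
    with colony-detached cells).
    """

    n_colonies: int = 5
    nuclei_per_colony: tuple[float, float] = (20.0, 0.0)
    nucleus_radius_px: tuple[float, float] = (9.0, 0.8)
    packing_mode: str = "tight"
    image_shape_px: tuple[int, int] = (512, 512)
    seed: int = 0
    max_overlap_frac: float = 0.0
    detached_fraction: float = 0.2
    spread_scale: float = 1.8
    read_noise_sd: float = 2.0

    def __post_init__(self):
        if self.n_colonies < 0:
            raise ValueError("n_colonies must be >= 0")
        if self.packing_mode not in ("tight", "spread"):
            raise ValueError(f"packing_mode must be 'tight' or 'spread', got {self.packing_mode!r}")
        if self.nucleus_radius_px[0] <= 0:
            raise ValueError("nucleus radius must be positive")
        if not 0.0 <= self.max_overlap_frac < 1.0:
            raise ValueError("max_overlap_frac must be in [0, 1)")


@dataclass
class SpotParams:
    """Diffraction-limited spot model for the smFISH stack generator."""

    n_spots_per_cell: tuple[float, float] = (15.0, 1.0)
    spot_sigma_px: float = 1.5
    amplitude: float = 200.0
    noise_sd: float = 20.0
    z_planes: int = 9
    baseline: float = 100.0
    min_separation_px: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.spot_sigma_px <= 0:
            raise ValueError("spot sigma must be positive")
        if self.noise_sd <= 0 or self.amplitude <= 0:
            raise ValueError("SNR = amplitude / noise_sd must be positive")
        if self.z_planes < 1:
            raise ValueError("need at least one z plane")


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float, n: int) -> np.ndarray:
    """Counts with variance = dispersion * mean (0 => deterministic, 1 => Poisson)."""
    if n == 0:
        return np.zeros(0, dtype=int)
    if dispersion == 0:
        return np.full(n, int(round(mean)), dtype=int)
    if dispersion <= 1:
        return rng.poisson(mean, size=n)
    # negative binomial: var = m + m^2/r = dispersion * m  =>  r = m / (dispersion - 1)
    r = mean / (dispersion - 1.0)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n)


# ---------------------------------------------------------------------------
# cell tables (image-free fixture for the single-cell statistics)


def generate_cell_table(n_cells: int, expr: ExpressionParams) -> pd.DataFrame:
    """Sample a per-cell table from the joint driver/response model.

    Driver folds come from the positive/negative mixture; each cell's response
    state is Bernoulli with P(ON) given by the Hill link at its realised
    driver fold; the response fold is then drawn from that state's log-normal.
    Intensity columns are fold x background, i.e. what an imaging measurement
    of the same cell would report without noise.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([expr.seed, 1]))
    driver_on = rng.random(n_cells) < expr.fraction_driver_positive
    driver_fold = expr.driver.sample_fold(rng, driver_on)
    p_on = hill_repression(driver_fold, expr.f_half, expr.h)
    response_on = rng.random(n_cells) < p_on
    response_fold = expr.response.sample_fold(rng, response_on)
    bg = expr.background_level
    return pd.DataFrame(
        {
            "label": np.arange(1, n_cells + 1),
            f"mean_{expr.driver_name}": driver_fold * bg,
            f"mean_{expr.response_name}": response_fold * bg,
            "true_driver_fold": driver_fold,
            "true_response_fold": response_fold,
            "true_driver_on": driver_on,
            "true_response_on": response_on,
        }
    )


# ---------------------------------------------------------------------------
# colony images


def _place_in_disk(rng, center, radius):
    t = rng.uniform(0, 2 * np.pi)
    r = radius * np.sqrt(rng.uniform())
    return center[0] + r * np.cos(t), center[1] + r * np.sin(t)


def _place_nuclei(colony: ColonyParams, rng: np.random.Generator):
    """Dart-throwing placement honoring the minimum-separation constraint.

    Returns (x, y, radius, colony_id) arrays.  Raises if the image cannot hold
    the requested nuclei at the packing constraint.
    """
    h, w = colony.image_shape_px
    r_mean, r_sd = colony.nucleus_radius_px
    counts = _draw_counts(
        rng, colony.nuclei_per_colony[0], colony.nuclei_per_colony[1], colony.n_colonies
    )
    xs, ys, rs, cids = [], [], [], []

    def separated(x, y, r):
        for xo, yo, ro in zip(xs, ys, rs):
            min_sep = (r + ro) * (1.0 - colony.max_overlap_frac)
            if (x - xo) ** 2 + (y - yo) ** 2 < min_sep**2:
                return False
        return True

    colony_centers = []
    for cid, n in enumerate(counts):
        if n == 0:
            continue
        base_radius = r_mean * np.sqrt(max(n, 1) / 0.32)
        if colony.packing_mode == "spread":
            disk_radius = base_radius * colony.spread_scale
        else:
            disk_radius = base_radius
        margin = min(disk_radius + 3 * r_mean, min(h, w) / 2 - 2 * r_mean)
        if margin <= 2 * r_mean:
            raise ValueError(
                f"image {h}x{w} too small for a colony of {n} nuclei of radius "
                f"{r_mean} at the {colony.packing_mode!r} packing constraint"
            )
        # spread colonies are sparse and may interleave; tight ones must not
        sep_factor = 0.9 if colony.packing_mode == "tight" else 0.5
        center = None
        # relax colony-center separation gradually before giving up: the
        # per-nucleus separation constraint below still holds regardless
        for factor in (sep_factor, 0.85 * sep_factor, 0.7 * sep_factor):
            for _ in range(500):
                cand = (rng.uniform(margin, w - margin), rng.uniform(margin, h - margin))
                if all(
                    (cand[0] - cx) ** 2 + (cand[1] - cy) ** 2
                    >= (factor * (disk_radius + dr)) ** 2
                    for cx, cy, dr in colony_centers
                ):
                    center = cand
                    break
            if center is not None:
                break
        if center is None:
            raise ValueError(
                f"could not place {colony.n_colonies} colonies in a {h}x{w} image "
                "without violating the colony-separation constraint"
            )
        colony_centers.append((center[0], center[1], disk_radius))

        n_detached = (
            int(round(colony.detached_fraction * n)) if colony.packing_mode == "spread" else 0
        )
        for j in range(n):
            r = float(np.clip(rng.normal(r_mean, r_sd), 0.5 * r_mean, 1.5 * r_mean))
            placed = False
            for _ in range(5000):
                if j < n - n_detached:
                    x, y = _place_in_disk(rng, center, max(disk_radius - r, r))
                else:  # detached singleton: anywhere in the image interior
                    x = rng.uniform(2 * r, w - 2 * r)
                    y = rng.uniform(2 * r, h - 2 * r)
                if not (r <= x <= w - 1 - r and r <= y <= h - 1 - r):
                    continue
                if separated(x, y, r):
                    xs.append(x), ys.append(y), rs.append(r), cids.append(cid)
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"image {h}x{w} too small to place nucleus {j + 1}/{n} of colony "
                    f"{cid} at minimum separation 2 x radius x (1 - "
                    f"{colony.max_overlap_frac}); enlarge the image or reduce counts"
                )
    return (np.array(xs), np.array(ys), np.array(rs), np.array(cids, dtype=int))


def generate_colony_image(
    colony: ColonyParams,
    expr: ExpressionParams,
    *,
    noisy: bool = True,
    edge_blur_px: float = 1.0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a multi-channel colony image plus its ground-truth table.

    Channels are DAPI plus the driver and response markers.  Nuclei are hard
    disks with a 1-px Gaussian edge blur; noise is Poisson shot noise on the
    expected signal plus additive Gaussian read noise over a uniform
    background.  With ``noisy=False`` and ``edge_blur_px=0`` the channels are
    exact: every pixel of nucleus *i* equals its true mean intensity, so
    measuring the ground-truth masks recovers the truth table exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([colony.seed, expr.seed, 2]))
    h, w = colony.image_shape_px
    xs, ys, rs, cids = _place_nuclei(colony, rng)
    n = len(xs)

    bg = expr.background_level
    dapi_fold = np.exp(rng.normal(expr.dapi_log_mean, expr.dapi_log_sd, size=n))
    driver_on = rng.random(n) < expr.fraction_driver_positive
    driver_fold = expr.driver.sample_fold(rng, driver_on)
    response_on = rng.random(n) < hill_repression(driver_fold, expr.f_half, expr.h)
    response_fold = expr.response.sample_fold(rng, response_on)

    folds = {
        "DAPI": dapi_fold,
        expr.driver_name: driver_fold,
        expr.response_name: response_fold,
    }
    yy, xx = np.mgrid[0:h, 0:w]
    channels = {}
    # per-nucleus disk masks (bounded boxes keep this fast)
    masks = []
    for x, y, r in zip(xs, ys, rs):
        x0, x1 = int(max(0, x - r - 2)), int(min(w, x + r + 3))
        y0, y1 = int(max(0, y - r - 2)), int(min(h, y + r + 3))
        sub = (xx[y0:y1, x0:x1] - x) ** 2 + (yy[y0:y1, x0:x1] - y) ** 2 <= r**2
        masks.append((y0, y1, x0, x1, sub))
    for name, fold in folds.items():
        signal = np.zeros((h, w))
        for (y0, y1, x0, x1, sub), f in zip(masks, fold):
            signal[y0:y1, x0:x1][sub] = (f - 1.0) * bg
        if edge_blur_px > 0:
            signal = ndi.gaussian_filter(signal, edge_blur_px)
        field = np.clip(bg + signal, 0.0, None)
        if noisy:
            img = rng.poisson(field).astype(float) + rng.normal(
                0.0, colony.read_noise_sd, size=field.shape
            )
            img = np.clip(img, 0.0, None)
        else:
            img = field
        channels[name] = img

    truth = pd.DataFrame(
        {
            "nucleus": np.arange(1, n + 1),
            "colony": cids,
            "x": xs,
            "y": ys,
            "radius": rs,
            **{f"true_mean_{name}": folds[name] * bg for name in folds},
            "true_driver_fold": driver_fold,
            "true_response_fold": response_fold,
            "true_driver_on": driver_on,
            "true_response_on": response_on,
        }
    )
    return ImageStack(channels=channels, meta={"background_level": bg}), truth


def ground_truth_labels(truth: pd.DataFrame, shape: tuple[int, int]) -> np.ndarray:
    """Render the ground-truth table's disks as a label image (row order = label)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros((h, w), dtype=np.int32)
    for _, row in truth.iterrows():
        mask = (xx - row["x"]) ** 2 + (yy - row["y"]) ** 2 <= row["radius"] ** 2
        labels[mask] = int(row["nucleus"])
    return labels


# ---------------------------------------------------------------------------
# gene universes for the enrichment bootstrap


def generate_gene_universe(
    n_genes: int,
    peak_fraction: float,
    genome_length: int,
    seed: int,
    *,
    basal_up_bp: int = 5000,
    basal_down_bp: int = 1000,
    peak_width_bp: int = 100,
    chrom: str = "chr1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TSS universe plus a peak set whose basal-domain assignment is exact.

    TSSs are placed uniformly at random subject to a minimum spacing larger
    than one basal domain, which guarantees that a peak dropped immediately
    downstream of a flagged gene's TSS overlaps that gene's regulatory domain
    and nobody else's.  Exactly ``round(n_genes * peak_fraction)`` genes carry
    a peak.
    """
    if not 0.0 <= peak_fraction <= 1.0:
        raise ValueError("peak_fraction must be in [0, 1]")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    gap = basal_up_bp + basal_down_bp + 2 * peak_width_bp
    if genome_length < n_genes * gap + 2 * gap:
        raise ValueError(
            f"genome of {genome_length} bp too short to place {n_genes} TSSs at "
            f"minimum spacing {gap} bp without collision"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    free = genome_length - (n_genes + 1) * gap
    offsets = np.sort(rng.choice(free, size=n_genes, replace=False))
    tss = offsets + gap * np.arange(1, n_genes + 1)
    strand = rng.choice(["+", "-"], size=n_genes)
    n_flag = int(round(n_genes * peak_fraction))
    flagged = np.zeros(n_genes, dtype=bool)
    flagged[rng.choice(n_genes, size=n_flag, replace=False)] = True
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(1, n_genes + 1)],
            "chrom": chrom,
            "tss": tss.astype(int),
            "strand": strand,
            "has_peak_true": flagged,
        }
    )
    peaks = pd.DataFrame(
        {
            "chrom": chrom,
            "start": genes.loc[flagged, "tss"].to_numpy(),
            "end": genes.loc[flagged, "tss"].to_numpy() + peak_width_bp,
        }
    ).reset_index(drop=True)
    return genes, peaks


# ---------------------------------------------------------------------------
# smFISH spot stacks


def generate_spot_stack(
    masks: np.ndarray,
    spots: SpotParams,
    *,
    counts_per_cell: dict[int, int] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a 3-D stack of Gaussian spots confined to labeled cells.

    Returns ``(stack, truth)`` with the stack shaped (z, y, x) and one truth
    row per spot: (cell label, x, y, z).  Spot counts per cell follow the
    configured count distribution unless ``counts_per_cell`` pins them
    explicitly (e.g. to couple transcript numbers to a simulated expression
    state); each spot sits at a subpixel position inside its cell's (slightly
    eroded) mask.
    """
    masks = np.asarray(masks)
    label_ids = np.unique(masks)
    label_ids = label_ids[label_ids > 0]
    if label_ids.size == 0:
        raise ValueError("label image contains no cells")
    radius_est = np.sqrt(np.median(np.bincount(masks.ravel())[label_ids]) / np.pi)
    if spots.spot_sigma_px >= radius_est:
        warnings.warn(
            f"spot sigma {spots.spot_sigma_px} px >= typical cell radius "
            f"{radius_est:.1f} px: spots from one cell may merge",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence([spots.seed, 4]))
    if counts_per_cell is None:
        counts = _draw_counts(
            rng, spots.n_spots_per_cell[0], spots.n_spots_per_cell[1], len(label_ids)
        )
    else:
        counts = np.array([int(counts_per_cell.get(int(lab), 0)) for lab in label_ids])
    nz, (h, w) = spots.z_planes, masks.shape
    stack = np.full((nz, h, w), float(spots.baseline))
    rows = []
    erosion = ndi.binary_erosion(masks > 0, iterations=2)
    for lab, n_sp in zip(label_ids, counts):
        mask = (masks == lab) & erosion
        if not mask.any():
            mask = masks == lab
        ys_m, xs_m = np.nonzero(mask)
        placed: list[tuple[float, float]] = []
        for _ in range(n_sp):
            # dart throwing keeps spots mutually resolvable in-plane
            for _attempt in range(200):
                k = rng.integers(len(ys_m))
                x = xs_m[k] + rng.uniform(-0.5, 0.5)
                y = ys_m[k] + rng.uniform(-0.5, 0.5)
                if all(
                    (x - xo) ** 2 + (y - yo) ** 2 >= spots.min_separation_px**2
                    for xo, yo in placed
                ):
                    break
            placed.append((x, y))
            z = rng.uniform(0.5, max(nz - 1.5, 0.5)) if nz > 1 else 0.0
            rows.append((int(lab), x, y, z))
    truth = pd.DataFrame(rows, columns=["cell", "x", "y", "z"])

    s = spots.spot_sigma_px
    half = int(np.ceil(4 * s))
    for _, sp in truth.iterrows():
        x0, y0, z0 = sp["x"], sp["y"], sp["z"]
        zs = np.arange(max(0, int(z0) - half), min(nz, int(z0) + half + 1))
        ys = np.arange(max(0, int(y0) - half), min(h, int(y0) + half + 1))
        xs = np.arange(max(0, int(x0) - half), min(w, int(x0) + half + 1))
        zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
        blob = spots.amplitude * np.exp(
            -((zz - z0) ** 2 + (yy - y0) ** 2 + (xx - x0) ** 2) / (2 * s**2)
        )
        stack[np.ix_(zs, ys, xs)] += blob
    stack += rng.normal(0.0, spots.noise_sd, size=stack.shape)
    return stack, truth
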