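"""Spot colocalization statistics for two-channel smFISH-style fields.

A field is one segmented cell with peroxisome spots (organelle channel)
and mRNA spots (FISH channel) in 2D, after maximal projection of the
acquisition Z-stack.  Colocalization is organelle-centric: the fraction of
peroxisomes with at least one mRNA spot within a distance threshold.  A
random-colocalization baseline is estimated by resampling the mRNA spots
uniformly within the cell mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

__all__ = [
    "CellMask",
    "SpotField",
    "ColocResult",
    "max_project",
    "detect_spots",
    "percent_colocalized",
    "random_baseline",
    "compare_conditions",
]


@dataclass(frozen=True)
class CellMask:
    """Cell boundary in nm: a disk (center + radius) or an arbitrary polygon."""

    center_nm: tuple[float, float] | None = None
    radius_nm: float | None = None
    polygon_nm: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        is_disk = self.center_nm is not None and self.radius_nm is not None
        is_poly = self.polygon_nm is not None
        if is_disk == is_poly:
            raise ValueError("cell mask must be either a disk or a polygon")
        if is_disk and self.radius_nm <= 0:
            raise ValueError("cell radius must be > 0")
        if is_poly and len(self.polygon_nm) < 3:
            raise ValueError("polygon needs >= 3 vertices")

    @property
    def is_disk(self) -> bool:
        return self.polygon_nm is None

    def geometry(self) -> Polygon:
        if self.is_disk:
            return Point(*self.center_nm).buffer(self.radius_nm, quad_segs=64)
        return Polygon(self.polygon_nm)

    def contains(self, points_nm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
        if self.is_disk:
            c = np.asarray(self.center_nm)
            return np.linalg.norm(pts - c, axis=1) <= self.radius_nm
        import shapely

        return shapely.contains_xy(self.geometry(), pts[:, 0], pts[:, 1])

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the mask by rejection from the bounding box."""
        if n == 0:
            return np.empty((0, 2))
        if self.is_disk:
            minx, miny = np.asarray(self.center_nm) - self.radius_nm
            maxx, maxy = np.asarray(self.center_nm) + self.radius_nm
        else:
            minx, miny, maxx, maxy = self.geometry().bounds
        out = np.empty((0, 2))
        while len(out) < n:
            cand = rng.uniform((minx, miny), (maxx, maxy), size=(max(2 * n, 64), 2))
            out = np.vstack([out, cand[self.contains(cand)]])
        return out[:n]


@dataclass
class SpotField:
    """Two-channel spot coordinates (nm) within one cell."""

    peroxisome_spots_nm: np.ndarray
    mrna_spots_nm: np.ndarray
    cell_mask: CellMask
    field_id: str = ""
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peroxisome_spots_nm = np.asarray(
            self.peroxisome_spots_nm, dtype=float).reshape(-1, 2)
        self.mrna_spots_nm = np.asarray(
            self.mrna_spots_nm, dtype=float).reshape(-1, 2)
        for name, pts in (("peroxisome", self.peroxisome_spots_nm),
                          ("mrna", self.mrna_spots_nm)):
            if pts.size and not np.all(np.isfinite(pts)):
                raise ValueError(f"{name} spot coordinates must be finite")
            if pts.size and not self.cell_mask.contains(pts).all():
                raise ValueError(f"{name} spots must lie inside the cell mask")


@dataclass
class ColocResult:
    percent_colocalized: float
    n_peroxisomes: int
    baseline_percent: float | None = None
    baseline_ci: tuple[float, float] | None = None
    p_value: float | None = None
    undefined: bool = False


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a Z-stack (planes on axis 0)."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError(f"expected a (planes, y, x) stack, got shape {stack.shape}")
    return stack.max(axis=0)


def detect_spots(image: np.ndarray, min_sigma: float = 1.0, max_sigma: float = 4.0,
                 threshold: float = 0.05) -> np.ndarray:
    """Detect diffraction-limited spots in a 2D image.

    Laplacian-of-Gaussian blob detection followed by intensity-weighted
    sub-pixel centroid refinement in a window around each blob.  Returns
    (n, 2) array of (x, y) pixel coordinates.
    """
    from skimage.feature import blob_log

    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("detect_spots expects a 2D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    blobs = blob_log(image, min_sigma=min_sigma, max_sigma=max_sigma,
                     threshold=threshold)
    spots = []
    for row, col, sigma in blobs:
        half = max(2, int(round(2 * sigma)))
        r0, r1 = max(0, int(row) - half), min(image.shape[0], int(row) + half + 1)
        c0, c1 = max(0, int(col) - half), min(image.shape[1], int(col) + half + 1)
        win = image[r0:r1, c0:c1]
        win = win - win.min()
        if win.sum() <= 0:
            spots.append((col, row))
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        spots.append(((win * cc).sum() / win.sum(), (win * rr).sum() / win.sum()))
    return np.asarray(spots, dtype=float).reshape(-1, 2)


def percent_colocalized(field: SpotField, threshold_nm: float) -> ColocResult:
    """Percentage of peroxisomes with >= 1 mRNA spot within ``threshold_nm``."""
    if threshold_nm <= 0:
        raise ValueError("threshold_nm must be > 0")
    n_perox = len(field.peroxisome_spots_nm)
    if n_perox == 0:
        return ColocResult(percent_colocalized=float("nan"), n_peroxisomes=0,
                           undefined=True)
    pct = 100.0 * _coloc_fraction(field.peroxisome_spots_nm,
                                  field.mrna_spots_nm, threshold_nm)
    return ColocResult(percent_colocalized=pct, n_peroxisomes=n_perox)


def _coloc_fraction(perox: np.ndarray, mrna: np.ndarray, threshold_nm: float) -> float:
    if len(perox) == 0:
        return float("nan")
    if len(mrna) == 0:
        return 0.0
    tree = cKDTree(mrna)
    dist, _ = tree.query(perox, k=1)
    return float(np.mean(dist < threshold_nm))


def random_baseline(field: SpotField, threshold_nm: float, n_perm: int,
                    seed: int | np.random.Generator) -> tuple[float, tuple[float, float]]:
    """Permutation baseline: mRNA spots resampled uniformly in the cell mask.

    Returns the mean percent colocalized over ``n_perm`` resamplings and a
    central 95% percentile interval.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = len(field.mrna_spots_nm)
    if m == 0 or len(field.peroxisome_spots_nm) == 0:
        return 0.0, (0.0, 0.0)
    percents = np.empty(n_perm)
    for i in range(n_perm):
        resampled = field.cell_mask.sample_uniform(m, rng)
        percents[i] = 100.0 * _coloc_fraction(
            field.peroxisome_spots_nm, resampled, threshold_nm)
    lo, hi = np.percentile(percents, [2.5, 97.5])
    return float(percents.mean()), (float(lo), float(hi))


def colocalization_with_baseline(field: SpotField, threshold_nm: float,
                                 n_perm: int, seed: int) -> ColocResult:
    """Estimate + permutation baseline + one-sided permutation p-value."""
    res = percent_colocalized(field, threshold_nm)
    if res.undefined:
        return res
    rng = np.random.default_rng(seed)
    m = len(field.mrna_spots_nm)
    percents = np.empty(n_perm)
    for i in range(n_perm):
        resampled = field.cell_mask.sample_uniform(m, rng)
        percents[i] = 100.0 * _coloc_fraction(
            field.peroxisome_spots_nm, resampled, threshold_nm)
    lo, hi = np.percentile(percents, [2.5, 97.5])
    res.baseline_percent = float(percents.mean())
    res.baseline_ci = (float(lo), float(hi))
    # permutation p-value with the +1 correction to avoid exact zeros
    res.p_value = float(
        (1 + np.sum(percents >= res.percent_colocalized)) / (1 + n_perm))
    return res


def compare_conditions(group_a, group_b, test: str = "t") -> tuple[float, float]:
    """Two-sided unpaired comparison of per-field percentages.

    ``test`` is ``"t"`` (Student's unpaired t test) or ``"mannwhitney"``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if test == "t":
        if a.size < 2 or b.size < 2:
            raise ValueError("t test needs >= 2 values per group")
        stat, p = stats.ttest_ind(a, b, equal_var=True)
    elif test == "mannwhitney":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r} (use 't' or 'mannwhitney')")
    return float(stat), float(p)
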