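"""Spatial primitives shared by the tomography-scene pipeline.

All coordinates are in pixels unless a name says otherwise; the physical
calibration (``pixel_size_nm``) travels with every object so that distances
can always be reported in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SphereMembrane", "RibosomeSet", "CropBox", "Scene"]


@dataclass(frozen=True)
class SphereMembrane:
    """A modeled spherical organelle boundary.

    Parameters
    ----------
    center : (3,) array-like
        Sphere center in pixel coordinates (z, y, x order is not assumed;
        the package uses a consistent (x, y, z) convention throughout).
    radius_px : float
        Sphere radius in pixels, strictly positive.
    pixel_size_nm : float
        Physical edge length of one (isotropic) voxel in nanometres.
    """

    center: tuple[float, float, float]
    radius_px: float
    pixel_size_nm: float

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError(f"radius_px must be > 0, got {self.radius_px}")
        if self.pixel_size_nm <= 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        c = tuple(float(v) for v in self.center)
        if len(c) != 3 or not all(np.isfinite(c)):
            raise ValueError(f"center must be 3 finite coordinates, got {self.center}")
        object.__setattr__(self, "center", c)

    @property
    def radius_nm(self) -> float:
        return self.radius_px * self.pixel_size_nm

    def surface_distance_px(self, points: np.ndarray) -> np.ndarray:
        """Signed distance from point(s) to the sphere surface, in pixels.

        Positive outside the sphere, negative inside.  ``points`` is
        (n, 3) or (3,).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.linalg.norm(pts - np.asarray(self.center), axis=1) - self.radius_px
        return d if np.ndim(points) > 1 else d[0]

    def surface_distance_nm(self, points: np.ndarray) -> np.ndarray:
        return self.surface_distance_px(points) * self.pixel_size_nm


@dataclass
class RibosomeSet:
    """Centroids of segmented ribosomes, one entry per ribosome center."""

    centroids: np.ndarray  # (n, 3) float, pixels
    pixel_size_nm: float
    labels: np.ndarray | None = None  # optional per-centroid ground-truth labels

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float).reshape(-1, 3)
        if c.size and not np.all(np.isfinite(c)):
            raise ValueError("centroids must be finite")
        if self.pixel_size_nm <= 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        self.centroids = c
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if lab.shape[0] != c.shape[0]:
                raise ValueError("labels must match centroids length")
            self.labels = lab

    def __len__(self) -> int:
        return self.centroids.shape[0]


@dataclass(frozen=True)
class CropBox:
    """Axis-aligned analysis volume in pixel coordinates, half-open bounds."""

    xlim: tuple[float, float]
    ylim: tuple[float, float]
    zlim: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("xlim", "ylim", "zlim"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
                raise ValueError(f"{name} must be a finite increasing pair")
            object.__setattr__(self, name, (float(lo), float(hi)))

    @property
    def shape(self) -> tuple[int, int, int]:
        """Voxel-grid shape (nx, ny, nz) with unit voxels anchored at the lower bound."""
        return tuple(
            int(round(hi - lo)) for lo, hi in (self.xlim, self.ylim, self.zlim)
        )

    @property
    def origin(self) -> tuple[float, float, float]:
        return (self.xlim[0], self.ylim[0], self.zlim[0])

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ok = np.ones(pts.shape[0], dtype=bool)
        for axis, (lo, hi) in enumerate((self.xlim, self.ylim, self.zlim)):
            ok &= (pts[:, axis] >= lo) & (pts[:, axis] < hi)
        return ok

    def volume_px3(self) -> float:
        out = 1.0
        for lo, hi in (self.xlim, self.ylim, self.zlim):
            out *= hi - lo
        return out


@dataclass
class Scene:
    """One cropped tomographic scene: membrane model + picked ribosomes + crop bounds."""

    membrane: SphereMembrane
    ribosomes: RibosomeSet
    crop: CropBox
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.membrane.pixel_size_nm != self.ribosomes.pixel_size_nm:
            raise ValueError("membrane and ribosomes must share pixel_size_nm")

    @property
    def pixel_size_nm(self) -> float:
        return self.membrane.pixel_size_nm
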