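"""Voxel-grid helpers shared by the profiler and the scene simulator.

Grid convention: a :class:`~pexsite.geometry.CropBox` with lower corner
``origin`` maps array index ``(i, j, k)`` (axis order x, y, z) to the
continuous point ``origin + (i, j, k)``; i.e. voxels are unit lattice
points anchored at the crop's lower bound.
"""

from __future__ import annotations

import numpy as np

from .geometry import CropBox, SphereMembrane

__all__ = ["paint_spheres", "radial_distance_grid", "sphere_surface_mask"]


def paint_spheres(shape: tuple[int, int, int], centers: np.ndarray,
                  radius_px: float, origin=(0.0, 0.0, 0.0),
                  out: np.ndarray | None = None) -> np.ndarray:
    """Set to True every lattice point within ``radius_px`` of any center.

    Overlapping spheres union.  Spheres extending past the grid are
    clipped at the boundary.
    """
    vol = np.zeros(shape, dtype=bool) if out is None else out
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        return vol
    local = centers - np.asarray(origin, dtype=float)
    r = float(radius_px)
    for cx, cy, cz in local:
        lo = [max(0, int(np.ceil(c - r))) for c in (cx, cy, cz)]
        hi = [min(n - 1, int(np.floor(c + r))) for c, n in zip((cx, cy, cz), shape)]
        if any(l > h for l, h in zip(lo, hi)):
            continue
        xs = np.arange(lo[0], hi[0] + 1, dtype=float) - cx
        ys = np.arange(lo[1], hi[1] + 1, dtype=float) - cy
        zs = np.arange(lo[2], hi[2] + 1, dtype=float) - cz
        d2 = (xs[:, None, None] ** 2 + ys[None, :, None] ** 2
              + zs[None, None, :] ** 2)
        vol[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= d2 <= r * r
    return vol


def radial_distance_grid(crop: CropBox, center) -> np.ndarray:
    """Distance (px, float32) from every lattice point of ``crop`` to ``center``."""
    nx, ny, nz = crop.shape
    ox, oy, oz = crop.origin
    cx, cy, cz = (float(v) for v in center)
    xs = (np.arange(nx, dtype=np.float32) + np.float32(ox - cx)) ** 2
    ys = (np.arange(ny, dtype=np.float32) + np.float32(oy - cy)) ** 2
    zs = (np.arange(nz, dtype=np.float32) + np.float32(oz - cz)) ** 2
    return np.sqrt(xs[:, None, None] + ys[None, :, None] + zs[None, None, :])


def sphere_surface_mask(membrane: SphereMembrane, crop: CropBox,
                        half_thickness_px: float = 0.5) -> np.ndarray:
    """1-voxel-thick spherical membrane mask on the crop grid."""
    r = radial_distance_grid(crop, membrane.center)
    return np.abs(r - membrane.radius_px) <= half_thickness_px
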