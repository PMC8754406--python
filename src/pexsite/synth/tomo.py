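"""Synthetic tomographic scenes: a spherical organelle in a ribosome cloud.

The generator emulates the geometry of a cryo-ET crop around one
peroxisome: a ~200-nm section (172 px at 1.159 nm/px) cropped 100 px
around the modeled membrane, filled with cytosolic ribosomes at a fixed
number density under a hard membrane exclusion zone, plus a small number
of planted membrane-proximal ribosomes that cross the zone.  Ribosome
centroids keep a hard-core minimum spacing of one ribosome diameter
(18 px, ~20 nm), so the cloud is an overlap-free point process whose mean
count equals density x free volume exactly.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from ..geometry import CropBox, RibosomeSet, Scene, SphereMembrane
from ..voxel import paint_spheres, sphere_surface_mask

__all__ = [
    "TomoSceneParams",
    "generate_tomo_scene",
    "voxelize_scene",
    "sample_default_scenes",
    "DEFAULT_CYTOSOL_DENSITY_PER_PX3",
    "RIBOSOME_DIAMETER_PX",
]

# Ribosomes appear as uniformly sized ~20-nm (18-px) electron-dense bodies;
# the hard-core spacing and the default exclusion half-width both equal one
# ribosome diameter.
RIBOSOME_DIAMETER_PX = 18
DEFAULT_PIXEL_SIZE_NM = 1.159
DEFAULT_EXCLUSION_HALFWIDTH_NM = RIBOSOME_DIAMETER_PX * DEFAULT_PIXEL_SIZE_NM  # 20.862

# Calibrated once so that default crops carry a realistic per-crop ribosome
# count (a few hundred within 100 px of the membrane).
DEFAULT_CYTOSOL_DENSITY_PER_PX3 = 2.0e-5


@dataclass(frozen=True)
class TomoSceneParams:
    """Geometry and intensity of one synthetic scene."""

    sphere_radius_px: float = 43.0
    crop_halfwidth_px: int = 100          # extent beyond the membrane surface, X/Y
    section_thickness_px: int = 172       # ~200 nm slab in Z
    cytosol_density_per_px3: float = DEFAULT_CYTOSOL_DENSITY_PER_PX3
    exclusion_halfwidth_nm: float = DEFAULT_EXCLUSION_HALFWIDTH_NM
    planted_proximal_count: int = 2
    planted_max_distance_nm: float = 20.0
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    hard_core_spacing_px: float = float(RIBOSOME_DIAMETER_PX)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sphere_radius_px <= 0:
            raise ValueError("sphere_radius_px must be > 0")
        if self.crop_halfwidth_px <= 0 or self.section_thickness_px <= 0:
            raise ValueError("crop dimensions must be positive")
        if self.cytosol_density_per_px3 < 0 or self.exclusion_halfwidth_nm < 0:
            raise ValueError("density and exclusion half-width must be >= 0")
        if self.planted_proximal_count < 0:
            raise ValueError("planted_proximal_count must be >= 0")
        if self.exclusion_halfwidth_nm / self.pixel_size_nm > self.crop_halfwidth_px:
            raise ValueError("exclusion zone must lie inside the crop")

    @property
    def exclusion_radius_px(self) -> float:
        return self.sphere_radius_px + self.exclusion_halfwidth_nm / self.pixel_size_nm

    def crop(self) -> CropBox:
        h = self.sphere_radius_px + self.crop_halfwidth_px
        zh = self.section_thickness_px / 2
        return CropBox((-h, h), (-h, h), (-zh, zh))

    def free_volume_px3(self) -> float:
        """Crop volume minus the (slab-clipped) exclusion ball."""
        crop = self.crop()
        a = self.exclusion_radius_px
        h = self.section_thickness_px / 2
        if a <= h:
            ball = 4.0 / 3.0 * math.pi * a ** 3
        else:  # exclusion ball truncated by the section faces
            ball = 2.0 * math.pi * (a ** 2 * h - h ** 3 / 3.0)
        return crop.volume_px3() - ball


def generate_tomo_scene(params: TomoSceneParams) -> Scene:
    """Draw one scene; centroid labels mark the planted proximal ribosomes.

    Cytosolic centroids are uniform over crop minus exclusion ball with
    hard-core spacing; their number is Poisson with mean density x free
    volume.  Exactly ``planted_proximal_count`` extra centroids are placed
    at surface distance uniform in (0, ``planted_max_distance_nm``).
    """
    rng = np.random.default_rng(params.seed)
    crop = params.crop()
    center = np.zeros(3)
    membrane = SphereMembrane((0.0, 0.0, 0.0), params.sphere_radius_px,
                              params.pixel_size_nm)

    placed: list[np.ndarray] = []
    spacing2 = params.hard_core_spacing_px ** 2

    def _clashes(p: np.ndarray) -> bool:
        return any(float(np.sum((p - q) ** 2)) < spacing2 for q in placed)

    # planted proximal ribosomes first (they are guaranteed by construction)
    max_d_px = params.planted_max_distance_nm / params.pixel_size_nm
    for _ in range(params.planted_proximal_count):
        for _attempt in range(10_000):
            d = rng.uniform(0.0, max_d_px)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            p = center + (params.sphere_radius_px + d) * u
            if crop.contains(p[None, :])[0] and not _clashes(p):
                placed.append(p)
                break
        else:
            raise RuntimeError("failed to place a planted proximal ribosome")
    n_planted = len(placed)

    n_cyto = int(rng.poisson(params.cytosol_density_per_px3
                             * params.free_volume_px3()))
    lo = np.array([crop.xlim[0], crop.ylim[0], crop.zlim[0]])
    hi = np.array([crop.xlim[1], crop.ylim[1], crop.zlim[1]])
    excl2 = params.exclusion_radius_px ** 2
    tries = 0
    max_tries = 2000 * (n_cyto + 1)
    while len(placed) - n_planted < n_cyto:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"cytosolic density {params.cytosol_density_per_px3} too high: "
                f"placed {len(placed) - n_planted}/{n_cyto} after {tries} darts")
        p = rng.uniform(lo, hi)
        if float(np.sum((p - center) ** 2)) <= excl2 or _clashes(p):
            continue
        placed.append(p)

    centroids = (np.asarray(placed, dtype=float) if placed
                 else np.empty((0, 3)))
    labels = np.zeros(len(placed), dtype=bool)
    labels[:n_planted] = True
    ribosomes = RibosomeSet(centroids, params.pixel_size_nm, labels=labels)
    return Scene(membrane, ribosomes, crop,
                 meta={"params": asdict(params),
                       "free_volume_px3": params.free_volume_px3(),
                       "n_planted": n_planted, "n_cytosolic": n_cyto})


def voxelize_scene(membrane: SphereMembrane, ribosomes: RibosomeSet,
                   crop: CropBox, ribosome_radius_px: float = 9.0) -> np.ndarray:
    """Labeled uint8 volume: 0 background, 1 membrane surface, 2 ribosome.

    Each centroid is projected as a solid sphere of ``ribosome_radius_px``
    (overlaps union); the membrane is a 1-voxel spherical shell.  Ribosome
    labels overwrite membrane labels where spheres touch the shell.
    """
    if len(ribosomes) and not crop.contains(ribosomes.centroids).all():
        outside = np.sum(~crop.contains(ribosomes.centroids))
        raise ValueError(f"{outside} centroid(s) outside the crop extent")
    vol = np.zeros(crop.shape, dtype=np.uint8)
    vol[sphere_surface_mask(membrane, crop)] = 1
    ribo = paint_spheres(crop.shape, ribosomes.centroids, ribosome_radius_px,
                         origin=crop.origin)
    vol[ribo] = 2
    return vol


def sample_default_scenes(n_scenes: int, seed: int,
                          radius_range_nm: tuple[float, float] = (25.0, 100.0),
                          planted_range: tuple[int, int] = (1, 3),
                          **overrides) -> list[Scene]:
    """Default-preset scene ensemble.

    Sphere radii are uniform over 25-100 nm (diameters ~50-200 nm, the
    modeled peroxisome size range) and each organelle carries 1-3 planted
    membrane-proximal ribosomes; everything else follows
    :class:`TomoSceneParams` defaults unless overridden.
    """
    rng = np.random.default_rng(seed)
    scenes = []
    for _ in range(n_scenes):
        radius_nm = rng.uniform(*radius_range_nm)
        pixel = overrides.get("pixel_size_nm", DEFAULT_PIXEL_SIZE_NM)
        params = TomoSceneParams(
            sphere_radius_px=radius_nm / pixel,
            planted_proximal_count=int(rng.integers(planted_range[0],
                                                    planted_range[1] + 1)),
            seed=int(rng.integers(0, 2**31 - 1)),
            **overrides,
        )
        scenes.append(generate_tomo_scene(params))
    return scenes
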