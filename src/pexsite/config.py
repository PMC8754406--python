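"""Pipeline-wide configuration.

The constants gathered here are the calibration and thresholds used across
the three analysis stages: the electron-tomography pixel calibration, the
membrane-proximity cutoff for ribosomes, the P-site offset used to place
footprints on the genome, the input-coverage filter and log2 cutoff for
enrichment calling, and the spot-colocalization distance.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Flat bundle of pipeline parameters with lossless flat-file round-trip.

    Attributes
    ----------
    pixel_size_nm : float
        Calibrated tomogram pixel size (nm / px).
    proximal_threshold_nm : float
        A ribosome closer than this to the membrane surface is "proximal".
    psite_offset_nt : int
        Offset from the footprint 3' end to the P-site nucleotide.
    min_input_footprints : int
        Genes with fewer input CDS-mapping footprints than this are excluded.
    enrichment_cutoff_log2 : float
        log2(pulldown/input) above which a gene is called enriched.
    coloc_threshold_nm : float
        Peroxisome-to-mRNA-spot distance defining colocalization.
    rng_seed : int
        Seed for every stochastic stage.
    """

    pixel_size_nm: float = 1.159
    proximal_threshold_nm: float = 20.0
    psite_offset_nt: int = 15
    min_input_footprints: int = 100
    enrichment_cutoff_log2: float = 0.5
    coloc_threshold_nm: float = 300.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_nm", "proximal_threshold_nm",
                     "min_input_footprints", "coloc_threshold_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.psite_offset_nt < 0:
            raise ValueError("psite_offset_nt must be >= 0")
        self.psite_offset_nt = int(self.psite_offset_nt)
        self.min_input_footprints = int(self.min_input_footprints)
        self.rng_seed = int(self.rng_seed)

    def to_file(self, path: str | Path) -> None:
        """Write as a flat ``key = value`` file (one field per line)."""
        lines = [f"{f.name} = {getattr(self, f.name)!r}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs: dict = {}
        known = {f.name: f.type for f in fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = float(value) if "float" in str(known[key]) else int(value)
        return cls(**kwargs)

    def replace(self, **overrides) -> "PipelineConfig":
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data.update(overrides)
        return PipelineConfig(**data)
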