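"""Readers and writers for on-disk formats.

Formats handled here:

* gene annotations — GFF3 (1-based inclusive, converted at this boundary)
  or BED (already 0-based half-open), plus an optional sidecar flag table
  marking dubious / mitochondrial genes;
* footprint tables — TSV with columns chrom, strand, three_prime_pos, length;
* tomography scenes — JSON (sphere model + centroid list + crop + pixel size)
  or an ``.npz`` labeled voxel grid with an explicit pixel size entry;
* spot fields — TSV of two-channel 2D spot coordinates plus a cell mask.

Every reader/writer pair round-trips losslessly on valid inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coloc import CellMask, SpotField
from .genes import (
    MITO_CHROM_NAMES,
    FootprintTable,
    GeneModel,
    gff3_to_internal,
    internal_to_gff3,
)
from .geometry import CropBox, RibosomeSet, Scene, SphereMembrane

__all__ = [
    "read_gene_annotations",
    "write_gene_annotations",
    "read_footprints",
    "write_footprints",
    "read_scene",
    "write_scene",
    "read_volume",
    "write_volume",
    "read_spot_fields",
    "write_spot_fields",
]

VOLUME_LABEL_BACKGROUND = 0
VOLUME_LABEL_MEMBRANE = 1
VOLUME_LABEL_RIBOSOME = 2


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

def read_gene_annotations(path: str | Path,
                          flags_path: str | Path | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 or BED (by extension).

    GFF3 coordinates are 1-based inclusive and converted to the internal
    0-based half-open convention.  Dubious / mitochondrial flags come from
    GFF3 attributes (``orf_classification=Dubious``), from the chromosome
    name for mitochondria, and/or from a sidecar TSV with columns
    ``gene_id``, ``dubious``, ``mitochondrial``.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        genes = _read_bed(path)
    else:
        genes = _read_gff3(path)
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", dtype={"gene_id": str})
        flags = flags.set_index("gene_id")
        for g in genes:
            if g.gene_id in flags.index:
                row = flags.loc[g.gene_id]
                if "dubious" in flags.columns:
                    g.dubious = bool(row["dubious"])
                if "mitochondrial" in flags.columns:
                    g.mitochondrial = bool(row["mitochondrial"])
    for g in genes:
        if g.chrom.lower() in MITO_CHROM_NAMES:
            g.mitochondrial = True
    return genes


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    n_features = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        n_features += 1
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"{path}:{lineno}: malformed GFF3 line "
                             f"({len(parts)} columns, expected 9)")
        if parts[6] not in {"+", "-", ".", "?"}:
            raise ValueError(f"{path}:{lineno}: unknown strand {parts[6]!r}")
    if n_features == 0:
        return []
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True, force=True,
        )
    except Exception as exc:  # sqlite/gffutils wrap parse failures opaquely
        raise _locate_gff3_error(path, exc)

    by_gene: dict[str, GeneModel] = {}
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        gene_id = (feat.attributes.get("Parent") or feat.attributes.get("ID")
                   or [feat.id])[0]
        # strip transcript suffixes like _mRNA so intervals group per gene
        gene_id = gene_id.removesuffix("_mRNA").removesuffix("_CDS")
        if feat.strand not in {"+", "-"}:
            raise ValueError(
                f"{path}: unknown strand {feat.strand!r} for feature {feat.id}")
        start, end = gff3_to_internal(feat.start, feat.end)
        dubious = "dubious" in [
            v.lower() for v in feat.attributes.get("orf_classification", [])
        ]
        if gene_id in by_gene:
            g = by_gene[gene_id]
            g.cds_intervals = sorted(g.cds_intervals + [(start, end)])
            g.dubious = g.dubious or dubious
        else:
            by_gene[gene_id] = GeneModel(
                gene_id=gene_id, chrom=feat.seqid, strand=feat.strand,
                cds_intervals=[(start, end)], dubious=dubious,
            )
    return list(by_gene.values())


def _locate_gff3_error(path: Path, exc: Exception) -> ValueError:
    """Best-effort: name the first malformed GFF3 line for the error message."""
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            return ValueError(
                f"{path}:{lineno}: malformed GFF3 line "
                f"({len(parts)} columns, expected 9)")
        if parts[6] not in {"+", "-", ".", "?"}:
            return ValueError(f"{path}:{lineno}: unknown strand {parts[6]!r}")
    return ValueError(f"{path}: failed to parse GFF3: {exc}")


def _read_bed(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 6:
            raise ValueError(
                f"{path}:{lineno}: BED line needs >= 6 columns "
                f"(chrom start end name score strand), got {len(parts)}")
        chrom, start, end, name, _score, strand = parts[:6]
        if strand not in {"+", "-"}:
            raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
        try:
            s, e = int(start), int(end)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from None
        genes.append(GeneModel(gene_id=name, chrom=chrom, strand=strand,
                               cds_intervals=[(s, e)]))
    return genes


def write_gene_annotations(genes: list[GeneModel], path: str | Path,
                           flags_path: str | Path | None = None) -> None:
    """Write gene models as GFF3 (one gene + one CDS line per interval)."""
    lines = ["##gff-version 3"]
    for g in genes:
        span_start, span_end = g.span
        gs, ge = internal_to_gff3(span_start, span_end)
        attrs = f"ID={g.gene_id}"
        if g.dubious:
            attrs += ";orf_classification=Dubious"
        lines.append("\t".join([
            g.chrom, "pexsite", "gene", str(gs), str(ge), ".", g.strand, ".", attrs,
        ]))
        for i, (s, e) in enumerate(g.cds_intervals):
            cs, ce = internal_to_gff3(s, e)
            lines.append("\t".join([
                g.chrom, "pexsite", "CDS", str(cs), str(ce), ".", g.strand, "0",
                f"ID={g.gene_id}_CDS.{i};Parent={g.gene_id}",
            ]))
    Path(path).write_text("\n".join(lines) + "\n")
    if flags_path is not None:
        pd.DataFrame({
            "gene_id": [g.gene_id for g in genes],
            "dubious": [int(g.dubious) for g in genes],
            "mitochondrial": [int(g.mitochondrial) for g in genes],
        }).to_csv(flags_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

def read_footprints(path: str | Path) -> FootprintTable:
    """Read a footprint TSV (chrom, strand, three_prime_pos, length)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    except pd.errors.EmptyDataError:
        return FootprintTable()
    return FootprintTable(df)


def write_footprints(table: FootprintTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# scenes and volumes
# ---------------------------------------------------------------------------

def write_scene(scene: Scene, path: str | Path) -> None:
    payload = {
        "pixel_size_nm": scene.pixel_size_nm,
        "sphere": {
            "center_px": list(scene.membrane.center),
            "radius_px": scene.membrane.radius_px,
        },
        "crop": {
            "xlim": list(scene.crop.xlim),
            "ylim": list(scene.crop.ylim),
            "zlim": list(scene.crop.zlim),
        },
        "ribosome_centroids_px": scene.ribosomes.centroids.tolist(),
        "meta": scene.meta,
    }
    if scene.ribosomes.labels is not None:
        payload["ribosome_labels"] = np.asarray(scene.ribosomes.labels).tolist()
    Path(path).write_text(json.dumps(payload, indent=1))


def read_scene(path: str | Path) -> Scene:
    """Read a JSON scene.  A missing pixel size is an error, never assumed."""
    data = json.loads(Path(path).read_text())
    if "pixel_size_nm" not in data:
        raise ValueError(f"{path}: scene file lacks required 'pixel_size_nm'")
    px = float(data["pixel_size_nm"])
    sph = data["sphere"]
    membrane = SphereMembrane(tuple(sph["center_px"]), float(sph["radius_px"]), px)
    labels = data.get("ribosome_labels")
    ribosomes = RibosomeSet(
        np.asarray(data.get("ribosome_centroids_px", []), dtype=float).reshape(-1, 3),
        px,
        labels=None if labels is None else np.asarray(labels),
    )
    crop = CropBox(tuple(data["crop"]["xlim"]), tuple(data["crop"]["ylim"]),
                   tuple(data["crop"]["zlim"]))
    return Scene(membrane, ribosomes, crop, meta=data.get("meta", {}))


def write_volume(volume: np.ndarray, pixel_size_nm: float, path: str | Path) -> None:
    """Write a labeled voxel grid as .npz with its pixel calibration."""
    np.savez_compressed(path, volume=volume,
                        pixel_size_nm=np.float64(pixel_size_nm))


def read_volume(path: str | Path) -> tuple[np.ndarray, float]:
    with np.load(path) as data:
        if "pixel_size_nm" not in data:
            raise ValueError(f"{path}: volume file lacks required 'pixel_size_nm'")
        return data["volume"], float(data["pixel_size_nm"])


# ---------------------------------------------------------------------------
# spot fields
# ---------------------------------------------------------------------------

def write_spot_fields(fields: list[SpotField], spots_path: str | Path,
                      masks_path: str | Path) -> None:
    """Write spot fields as a long TSV of spots plus a JSON cell-mask sidecar."""
    rows = []
    masks: dict[str, dict] = {}
    for f in fields:
        for ch, spots in (("peroxisome", f.peroxisome_spots_nm),
                          ("mrna", f.mrna_spots_nm)):
            for (x, y) in spots:
                rows.append((f.field_id, ch, x, y))
        m = f.cell_mask
        if m.is_disk:
            masks[f.field_id] = {"type": "disk", "center_nm": list(m.center_nm),
                                 "radius_nm": m.radius_nm}
        else:
            masks[f.field_id] = {"type": "polygon",
                                 "vertices_nm": [list(v) for v in m.polygon_nm]}
        if f.truth:
            masks[f.field_id]["truth"] = _jsonable(f.truth)
    pd.DataFrame(rows, columns=["field_id", "channel", "x_nm", "y_nm"]).to_csv(
        spots_path, sep="\t", index=False)
    Path(masks_path).write_text(json.dumps(masks, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def read_spot_fields(spots_path: str | Path, masks_path: str | Path) -> list[SpotField]:
    df = pd.read_csv(spots_path, sep="\t", dtype={"field_id": str})
    masks = json.loads(Path(masks_path).read_text())
    fields = []
    for fid in sorted(masks):
        sub = df[df.field_id == fid]
        spec = masks[fid]
        if spec["type"] == "disk":
            mask = CellMask(center_nm=tuple(spec["center_nm"]),
                            radius_nm=float(spec["radius_nm"]))
        else:
            mask = CellMask(polygon_nm=tuple(tuple(v) for v in spec["vertices_nm"]))
        fields.append(SpotField(
            peroxisome_spots_nm=sub.loc[sub.channel == "peroxisome",
                                        ["x_nm", "y_nm"]].to_numpy(float),
            mrna_spots_nm=sub.loc[sub.channel == "mrna",
                                  ["x_nm", "y_nm"]].to_numpy(float),
            cell_mask=mask, field_id=fid, truth=spec.get("truth", {}),
        ))
    return fields
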