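"""Reading and writing the pipeline's on-disk artifacts.

Volumes go to OME-TIFF with voxel-size metadata (via tifffile), tables
to CSV, meshes to PLY, provenance to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import trimesh

from .core import LabeledVolume

__all__ = [
    "write_ome_tiff",
    "read_ome_tiff",
    "write_mesh",
    "save_ground_truth",
    "write_provenance",
]


def write_ome_tiff(
    path: str | Path, volume: np.ndarray,
    voxel_size_um: tuple[float, float, float],
) -> Path:
    """Write a (z, y, x) volume as OME-TIFF with physical pixel sizes."""
    path = Path(path)
    vz, vy, vx = voxel_size_um
    tifffile.imwrite(
        path,
        np.asarray(volume),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": vz,
            "PhysicalSizeY": vy,
            "PhysicalSizeX": vx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )
    return path


def read_ome_tiff(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a ZYX OME-TIFF, returning the array and voxel size (z, y, x)."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        voxel = (1.0, 1.0, 1.0)
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                voxel = (
                    float(px.get("PhysicalSizeZ", 1.0)),
                    float(px.get("PhysicalSizeY", 1.0)),
                    float(px.get("PhysicalSizeX", 1.0)),
                )
    return arr, voxel


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> Path:
    path = Path(path)
    mesh.export(path)
    return path


def write_provenance(path: str | Path, record: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return path


def save_ground_truth(gt, out_dir: str | Path) -> Path:
    """Write a generated rosette: volumes, truth table, provenance."""
    from dataclasses import asdict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    voxel = gt.cell_labels.voxel_size_um
    write_ome_tiff(out / "cell_labels.ome.tif", gt.cell_labels.labels, voxel)
    write_ome_tiff(out / "nucleus_labels.ome.tif", gt.nucleus_labels.labels, voxel)
    for name, vol in gt.channels.items():
        write_ome_tiff(out / f"channel_{name}.ome.tif", vol, voxel)
    for name, vol in gt.probability_maps.items():
        write_ome_tiff(out / f"probability_{name}.ome.tif", vol, voxel)
    gt.truth_table.to_csv(out / "truth_table.csv", index=False)
    write_provenance(
        out / "provenance.json",
        {"config": asdict(gt.config), "organ_index": gt.organ_index},
    )
    return out
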