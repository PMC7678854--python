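"""TIFF / CSV / YAML I/O shared by the pipeline stages.

Stacks and phase maps travel as multi-page 32-bit float TIFF with the z axis
as the page axis; voxel pitch is recorded in OME-TIFF physical-size metadata
and recovered on read.  Configs and run manifests are YAML/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .image_formation import ImageStack3D, VoxelPitch
from .qpi_analysis import PhaseImage


def write_stack(path, stack: ImageStack3D) -> None:
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": stack.pitch.x,
            "PhysicalSizeY": stack.pitch.y,
            "PhysicalSizeZ": stack.pitch.z,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
        },
    )


def read_stack(path, pitch=None) -> ImageStack3D:
    """Read a multi-page TIFF as a stack; pitch is taken from OME metadata
    unless overridden."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if pitch is None:
            pitch = _pitch_from_ome(tf)
    if data.ndim == 2:
        data = data[None]
    if pitch is None:
        raise ValueError(f"{path}: no pixel-size metadata; pass pitch explicitly")
    return ImageStack3D(np.clip(data.astype(np.float64), 0.0, None), VoxelPitch(*pitch))


def _pitch_from_ome(tf: "tifffile.TiffFile"):
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tf.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        return (
            float(px.attrib["PhysicalSizeX"]),
            float(px.attrib["PhysicalSizeY"]),
            float(px.attrib.get("PhysicalSizeZ", px.attrib["PhysicalSizeX"])),
        )
    except Exception:
        return None


def write_phase(path, img: PhaseImage) -> None:
    tifffile.imwrite(
        path,
        img.phase.astype(np.float32),
        ome=True,
        metadata={
            "axes": "YX",
            "PhysicalSizeX": img.pixel_pitch,
            "PhysicalSizeY": img.pixel_pitch,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
        },
    )


def read_phase(path, pixel_pitch=None) -> PhaseImage:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if pixel_pitch is None:
            meta = _pitch_from_ome(tf)
            pixel_pitch = meta[0] if meta else None
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-page phase map")
    if pixel_pitch is None:
        raise ValueError(f"{path}: no pixel-size metadata; pass pixel_pitch explicitly")
    return PhaseImage(data.astype(np.float64), float(pixel_pitch))


def load_config(path) -> dict:
    """YAML (JSON being a YAML subset is accepted transparently)."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_manifest(path, config: dict, seed=None) -> None:
    """Serialize the effective run configuration next to its outputs so every
    artifact is reproducible from the manifest alone."""
    import airyqpi

    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "airyqpi": airyqpi.__version__,
            "numpy": np.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=float) + "\n")
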