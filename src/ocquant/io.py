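"""File I/O: multi-page TIFF with JSON sidecars, SWC skeletons, Matrix Market.

Every writer drops a ``<file>.json`` sidecar next to its output recording
channel names, physical pixel/voxel size, the RNG seed, a hash of the run
configuration and the package version, so any raster can be re-read without
guessing its scale and any result can be traced to its run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .axon import AxonSkeleton
from .errors import ConfigError, FormatError
from .image import ChannelImage, SomaMask

__all__ = [
    "write_sidecar",
    "read_sidecar",
    "write_image",
    "read_volume",
    "write_labels",
    "read_labels",
    "read_swc",
    "write_swc",
    "read_count_matrix",
    "write_count_matrix",
]


# ---------------------------------------------------------------------------
# sidecars
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_sidecar(path: str | Path, payload: dict, seed: int | None = None,
                  config: dict | None = None) -> Path:
    """Write ``<path>.json`` with payload + provenance fields."""
    side = Path(str(path) + ".json")
    body = dict(payload)
    body["software_version"] = __version__
    if seed is not None:
        body["seed"] = int(seed)
    if config is not None:
        body["config_hash"] = config_hash(config)
    side.write_text(json.dumps(body, indent=2, default=_jsonify))
    return side


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_sidecar(path: str | Path) -> dict | None:
    side = Path(str(path) + ".json")
    if side.exists():
        return json.loads(side.read_text())
    return None


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_image(path: str | Path, image: ChannelImage,
                seed: int | None = None, config: dict | None = None) -> Path:
    """Write a ChannelImage as a multi-page TIFF (one page per channel).

    The physical scale and channel names go to the sidecar; 2D images also
    carry TIFF resolution tags.
    """
    path = Path(path)
    data = image.data
    if data.ndim == 3:  # (C, H, W): one page per channel, with resolution
        res = 1.0 / image.pixel_size[-1]  # pixels per µm
        tifffile.imwrite(
            path, data, resolution=(res, res), resolutionunit="MICROMETER"
        )
    else:  # (C, Z, Y, X)
        tifffile.imwrite(path, data)
    write_sidecar(
        path,
        {"channels": image.channels, "pixel_size_um": list(image.pixel_size)},
        seed=seed, config=config,
    )
    return path


def read_volume(
    path: str | Path,
    voxel_size: tuple[float, ...] | None = None,
    channels: list[str] | None = None,
) -> ChannelImage:
    """Read a multi-page TIFF back into a ChannelImage.

    Physical scale resolution order: explicit ``voxel_size`` override →
    JSON sidecar → TIFF resolution tags (2D only).  Raises if none is
    available.
    """
    path = Path(path)
    data = tifffile.imread(path)
    side = read_sidecar(path)
    if channels is None:
        if side and "channels" in side:
            channels = list(side["channels"])
        else:
            channels = [f"ch{i}" for i in range(data.shape[0])]
    if voxel_size is None:
        if side and "pixel_size_um" in side:
            voxel_size = tuple(side["pixel_size_um"])
        else:
            voxel_size = _tiff_resolution(path, data.ndim)
    if voxel_size is None:
        raise ConfigError(
            f"{path}: no resolution metadata; pass an explicit voxel_size"
        )
    return ChannelImage(data=data, channels=channels,
                        pixel_size=tuple(voxel_size))


def _tiff_resolution(path: Path, ndim: int) -> tuple[float, ...] | None:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is None or yres is None:
            return None
        def to_um(tag):
            num, den = tag.value
            if num == 0:
                return None
            return den / num  # µm per pixel when unit is micrometer
        px = to_um(xres)
        py = to_um(yres)
        if px is None or py is None:
            return None
        if ndim == 3:
            return (py, px)
    return None


def write_labels(path: str | Path, mask: SomaMask,
                 seed: int | None = None, config: dict | None = None) -> Path:
    """Write an instance label image as 16-bit TIFF (+ sidecar)."""
    path = Path(path)
    labels = mask.labels
    if labels.max() > np.iinfo(np.uint16).max:
        raise ConfigError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(path, labels.astype(np.uint16))
    write_sidecar(path, {"pixel_size_um": mask.pixel_size, "kind": "labels"},
                  seed=seed, config=config)
    return path


def read_labels(path: str | Path) -> SomaMask:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    side = read_sidecar(path) or {}
    return SomaMask(labels=labels, pixel_size=float(side.get("pixel_size_um", 1.0)))


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(path: str | Path) -> AxonSkeleton:
    """Parse a standard 7-column SWC file (coordinates in µm).

    Columns: id, type, x, y, z, radius, parent (−1 for the root).  Errors
    (bad column count, duplicate ids, missing parents, cycles, multiple
    roots) are reported with the offending line number where possible.
    """
    path = Path(path)
    ids, parents, xyz, radii = [], [], [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            ids.append(int(parts[0]))
            xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
            radii.append(float(parts[5]))
            parents.append(int(parts[6]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    if not ids:
        raise FormatError(f"{path}: no SWC records")
    try:
        return AxonSkeleton(np.array(ids), np.array(parents),
                            np.array(xyz), np.array(radii))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_swc(path: str | Path, skeleton: AxonSkeleton,
              node_type: int = 2) -> Path:
    """Write a skeleton as 7-column SWC (type 2 = axon)."""
    path = Path(path)
    idx = {int(n): i for i, n in enumerate(skeleton.nodes)}
    lines = ["# id type x y z radius parent"]
    for n in skeleton.nodes:
        i = idx[int(n)]
        x, y, z = skeleton.xyz[i]
        lines.append(
            f"{int(n)} {node_type} {x:.4f} {y:.4f} {z:.4f} "
            f"{skeleton.radius[i]:.4f} {int(skeleton.parents[i])}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    batch_map: dict[str, str] | str | Path | None = None,
    mito_prefix: str = "mt-",
) -> "CountMatrix":
    """Read Matrix Market + genes.tsv + barcodes.tsv into a CountMatrix.

    ``batch_map`` maps barcode → batch label ("developmental"/"adult"),
    either as a dict or a path to a two-column TSV/CSV; without it every
    cell is labeled "adult".  Genes starting with ``mito_prefix``
    (case-insensitive) are flagged mitochondrial.
    """
    from scipy.io import mmread

    from .qc import CountMatrix

    counts = mmread(str(matrix_path)).tocsr()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if isinstance(batch_map, (str, Path)):
        df = pd.read_csv(batch_map, sep=None, engine="python", header=None)
        batch_map = dict(zip(df[0].astype(str), df[1].astype(str)))
    if batch_map is None:
        batches = np.array(["adult"] * len(barcodes), object)
    else:
        try:
            batches = np.array([batch_map[b] for b in barcodes], object)
        except KeyError as exc:
            raise ConfigError(f"barcode {exc} missing from batch map") from None
    mito = np.array([g.lower().startswith(mito_prefix.lower()) for g in genes])
    return CountMatrix(counts=counts, genes=genes, barcodes=barcodes,
                       mito=mito, batches=batches)


def write_count_matrix(
    out_dir: str | Path,
    matrix: "CountMatrix",
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    """Write matrix.mtx + genes.tsv + barcodes.tsv (+ sidecar) to a directory."""
    from scipy.io import mmwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"), matrix.counts)
    pd.Series(matrix.genes).to_csv(out / "genes.tsv", sep="\t",
                                   header=False, index=False)
    pd.Series(matrix.barcodes).to_csv(out / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    pd.DataFrame({"barcode": matrix.barcodes, "batch": matrix.batches}).to_csv(
        out / "batches.tsv", sep="\t", header=False, index=False
    )
    write_sidecar(out / "matrix.mtx",
                  {"genes": len(matrix.genes), "cells": len(matrix.barcodes)},
                  seed=seed, config=config)
    return out
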