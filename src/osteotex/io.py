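"""Reading and writing image volumes and tabular results.

Volumes are 3D stacks of 8-bit gray-scale slices. The axis convention is
fixed: array index 0 is the long-axis (slice) position, so ``data[i]`` is
one cross-sectional image. Supported on-disk forms are a multi-page TIFF,
a directory of equally sized single-slice TIFF/PNG files (lexicographic
slice order), or a raw uint8 binary with a JSON sidecar giving
``{nx, ny, nz, voxel_size_um}``. Reading never rescales or otherwise
alters intensity values.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelVolume",
    "FormatError",
    "UnsupportedDepthError",
    "read_volume",
    "write_volume",
    "write_table",
]


class FormatError(ValueError):
    """A volume on disk is malformed (missing/ragged slices, bad sidecar)."""


class UnsupportedDepthError(FormatError):
    """Input sample depth is not 8-bit."""


@dataclasses.dataclass(frozen=True)
class VoxelVolume:
    """A 3D grid of 8-bit gray-scale intensities with a physical voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Integer intensities in [0, 255]; axis 0 is the long-axis slice index.
    voxel_size_um : float
        Physical edge length of a (cubic) voxel in micrometres.
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FormatError(f"volume must be 3D, got {arr.ndim}D")
        if any(s < 1 for s in arr.shape):
            raise FormatError(f"all dimensions must be >= 1, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise UnsupportedDepthError(
                f"intensities must be integers, got dtype {arr.dtype}"
            )
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise UnsupportedDepthError(
                    f"intensities outside the 8-bit range for dtype {arr.dtype}: "
                    f"[{arr.min()}, {arr.max()}]"
                )
            arr = arr.astype(np.uint8)
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "voxel_size_um", float(self.voxel_size_um))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # (nz, ny, nx)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


_SLICE_SUFFIXES = {".tif", ".tiff", ".png"}


def _read_slice(path: Path) -> np.ndarray:
    img = np.asarray(iio.imread(path))
    if img.ndim == 3 and img.shape[-1] == 1:
        img = img[..., 0]
    if img.ndim != 2:
        raise FormatError(f"{path} is not a single-channel 2D slice (shape {img.shape})")
    if img.dtype != np.uint8:
        raise UnsupportedDepthError(f"{path} has unsupported sample depth {img.dtype}")
    return img


def read_volume(path: str | Path, metadata: str | Path | None = None) -> VoxelVolume:
    """Read a volume from a multi-page TIFF, a slice directory, or raw+sidecar.

    ``metadata`` names the JSON sidecar; if omitted, ``<path>.json`` or the
    path with a ``.json`` suffix is tried. The sidecar is required for raw
    binary input and is the source of ``voxel_size_um`` everywhere.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _load_sidecar(path, metadata)

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES
        )
        if not files:
            raise FormatError(f"no TIFF/PNG slices found in {path}")
        slices = [_read_slice(p) for p in files]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise FormatError(f"ragged slices in {path}: shapes {sorted(shapes)}")
        data = np.stack(slices)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.dtype != np.uint8:
            raise UnsupportedDepthError(
                f"{path} has unsupported sample depth {data.dtype}"
            )
    else:  # raw binary, sidecar mandatory
        if meta is None:
            raise FormatError(f"raw volume {path} requires a JSON metadata sidecar")
        nx, ny, nz = int(meta["nx"]), int(meta["ny"]), int(meta["nz"])
        raw = np.fromfile(path, dtype=np.uint8)
        if raw.size != nx * ny * nz:
            raise FormatError(
                f"{path}: {raw.size} bytes, expected nx*ny*nz = {nx * ny * nz}"
            )
        data = raw.reshape(nz, ny, nx)

    voxel_size = float(meta["voxel_size_um"]) if meta else 1.0
    return VoxelVolume(data=data, voxel_size_um=voxel_size)


def _load_sidecar(path: Path, metadata: str | Path | None) -> Mapping[str, Any] | None:
    if metadata is not None:
        return json.loads(Path(metadata).read_text())
    for candidate in (path.with_suffix(path.suffix + ".json"), path.with_suffix(".json")):
        if candidate != path and candidate.is_file():
            return json.loads(candidate.read_text())
    return None


def write_volume(vol: VoxelVolume, path: str | Path) -> None:
    """Write a volume as a multi-page 8-bit TIFF plus a JSON voxel-size sidecar.

    ``read_volume`` inverts this exactly (bit-identical data, same voxel size).
    """
    path = Path(path)
    tifffile.imwrite(path, vol.data, photometric="minisblack")
    nz, ny, nx = vol.data.shape
    sidecar = {"nx": nx, "ny": ny, "nz": nz, "voxel_size_um": vol.voxel_size_um}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def write_table(
    rows: Sequence[Any], path: str | Path, columns: Sequence[str] | None = None
) -> None:
    """Write records (dataclasses or mappings) sharing one schema as CSV.

    Column order follows the first record (or ``columns`` for an empty
    sequence, giving a header-only file); floats are rendered with at least
    six significant digits.
    """
    path = Path(path)
    dicts = []
    for r in rows:
        if dataclasses.is_dataclass(r) and not isinstance(r, type):
            dicts.append(dataclasses.asdict(r))
        elif isinstance(r, Mapping):
            dicts.append(dict(r))
        else:
            raise TypeError(f"unsupported record type {type(r).__name__}")
    if dicts:
        schema = list(dicts[0].keys())
        for i, d in enumerate(dicts[1:], start=1):
            if list(d.keys()) != schema:
                raise ValueError(
                    f"record {i} schema {list(d.keys())} != first record schema {schema}"
                )
        if columns is not None and list(columns) != schema:
            raise ValueError(f"explicit columns {list(columns)} != record schema {schema}")
        frame = pd.DataFrame(dicts, columns=schema)
    else:
        frame = pd.DataFrame(columns=list(columns or []))
    frame.to_csv(path, index=False, float_format="%.8g")
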