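"""Volume file I/O, run configuration and provenance.

In-memory volumes are (X, Y, Z) with Z the depth axis (perpendicular to
the imaged surface).  Multi-page TIFF stacks store one Z slice per page
(page layout (Y rows, X cols)), so arrays are transposed on the way in and
out; NIfTI files keep the (X, Y, Z) order.  Binary masks are written
8-bit with {0,1} mapped to {0,255}; intensity volumes 32-bit float.
"""
from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Dict, Tuple

import numpy as np
import tifffile

__all__ = ["read_volume", "write_volume", "write_provenance", "load_config"]


def _to_pages(arr: np.ndarray) -> np.ndarray:
    # (X, Y, Z) -> (Z, Y, X) pages
    return np.ascontiguousarray(arr.transpose(2, 1, 0))


def _from_pages(pages: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(pages.transpose(2, 1, 0))


def read_volume(path: str | Path) -> Tuple[np.ndarray, Dict[str, Any]]:
    """Read a 3-D volume from multi-page TIFF or NIfTI.

    Returns ``(array, metadata)`` with the array in (X, Y, Z) order.
    8-bit data is interpreted as a binary mask ({0,255} or {0,1} -> {0,1});
    other dtypes are returned as float32 intensities.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a single-channel 3-D NIfTI volume, "
                             f"got shape {data.shape}")
        arr = np.asarray(data)
        meta = {"format": "nifti", "zooms": tuple(img.header.get_zooms())}
    elif path.suffix.lower() in (".tif", ".tiff"):
        pages = tifffile.imread(str(path))
        if pages.ndim == 2:
            pages = pages[None]
        if pages.ndim != 3:
            raise ValueError(
                f"expected a single-channel multi-page TIFF, got shape "
                f"{pages.shape} (multi-channel input is not supported)")
        arr = _from_pages(pages)
        meta = {"format": "tiff"}
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if arr.dtype == np.uint8:
        arr = (arr > 0).astype(np.uint8)
        meta["kind"] = "mask"
    else:
        arr = arr.astype(np.float32)
        meta["kind"] = "intensity"
    return arr, meta


def write_volume(arr: np.ndarray, path: str | Path,
                 dtype: str = "float32") -> None:
    """Write an (X, Y, Z) volume.

    ``dtype='uint8'`` treats the volume as a binary mask and stores
    {0,1} as {0,255}; ``'float32'`` stores raw intensities.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} is missing")
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ValueError("volumes must be 3-D")
    if dtype == "uint8":
        data = ((arr > 0) * np.uint8(255))
    elif dtype == "float32":
        data = arr.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}; "
                         f"use 'uint8' or 'float32'")
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), _to_pages(data))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj):
        return asdict(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_provenance(out_dir: str | Path, command: str,
                     config: Dict[str, Any], seed: int) -> Path:
    """Record how an output directory was produced (config hash, seed,
    library versions) so runs can be reproduced bit-for-bit."""
    import vangan

    cfg = {k: _jsonable(v) for k, v in config.items()}
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    record = {
        "command": command,
        "seed": int(seed),
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "versions": {
            "vangan": vangan.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    out = Path(out_dir) / "provenance.json"
    out.write_text(json.dumps(record, indent=2, default=str))
    return out


def load_config(path: str | Path, allowed_keys: set[str]) -> Dict[str, Any]:
    """Load a YAML config, rejecting unknown keys."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(data) - allowed_keys
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return data
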