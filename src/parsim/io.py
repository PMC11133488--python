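"""Shared file I/O: TIFF stacks, JSON reports, config files."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

__all__ = ["read_stack", "write_stack", "write_float_image",
           "write_json", "read_json", "load_config_file"]


def read_stack(path: str | Path) -> np.ndarray:
    """Read a (multi-page) TIFF as a float array of shape (n, h, w)."""
    data = tifffile.imread(path)
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    return data


def write_stack(path: str | Path, images: np.ndarray) -> None:
    """Write images as 16-bit unsigned multi-page TIFF (values clipped)."""
    data = np.clip(np.asarray(images), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")


def write_float_image(path: str | Path, image: np.ndarray) -> None:
    """Write a reconstruction as 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32),
                     photometric="minisblack")


def write_json(path: str | Path, payload: dict[str, Any]) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True,
                                     default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_json(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data
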