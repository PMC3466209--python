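"""Image and sidecar I/O.

Canonical on-disk image format is 16-bit grayscale TIFF; 8/16-bit PNG and
TIFF are accepted on input.  Float images are linearly mapped onto the
16-bit range and the mapping (min/max) is recorded in a sidecar JSON next
to the image so the physical values can be recovered exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import DomainError
from .phantoms import ImageGrid


def read_image(path: str | Path, pixel_size: float | None = None) -> ImageGrid:
    """Read a grayscale TIFF/PNG micrograph.

    ``pixel_size`` (nm/px) overrides any value found in a sidecar JSON; if
    neither is available the image gets pixel_size 1.0 and downstream
    resolutions are in pixel units.
    """
    path = Path(path)
    if not path.exists():
        raise DomainError(f"image file {path} does not exist")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # collapse RGB(A) of grayscale content
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(float)

    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        lo, hi = meta.get("value_min"), meta.get("value_max")
        if lo is not None and hi is not None and arr.max() > 0:
            arr = lo + arr / 65535.0 * (hi - lo)
    if pixel_size is None:
        pixel_size = meta.get("pixel_size_nm", 1.0)
    return ImageGrid(np.maximum(arr, 0.0), pixel_size)


def write_image(path: str | Path, image: ImageGrid, parameters: dict | None = None) -> None:
    """Write a 16-bit TIFF plus a sidecar JSON with the value mapping,
    pixel size and any run parameters."""
    path = Path(path)
    v = image.values
    lo, hi = float(v.min()), float(v.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 0.0
    data = np.round((v - lo) * scale).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {
        "pixel_size_nm": image.pixel_size,
        "value_min": lo,
        "value_max": hi,
        "shape": list(v.shape),
    }
    if parameters:
        sidecar["parameters"] = parameters
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
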