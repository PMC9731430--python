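"""Multi-channel time-lapse image stack container and TIFF I/O.

The raw observable of the pipeline is a ``T x 3 x H x W`` non-negative
intensity array.  Channel order is fixed throughout the package:

* channel 0, *blue*  — nuclear membrane permeability (nucleic-acid stain),
* channel 1, *green* — cytosolic calcium,
* channel 2, *red*   — mitochondrial membrane potential.

Stacks are written as multi-page TIFF with a JSON sidecar that carries the
physical metadata (pixel size, frame interval, seed) that TIFF itself does
not preserve reliably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

CHANNELS = ("blue", "green", "red")
BLUE, GREEN, RED = 0, 1, 2


@dataclass
class ImageStack:
    """A ``T x 3 x H x W`` fluorescence stack with physical metadata.

    Parameters
    ----------
    data
        Non-negative intensities, float array of shape ``(T, 3, H, W)``.
    pixel_size_um
        Physical pixel size in micrometres per pixel.
    frame_interval_s
        Time between consecutive frames in seconds.
    meta
        Free-form provenance (seed, saturation counts, ...).
    """

    data: np.ndarray
    pixel_size_um: float = 1.289  # 660 um field over 512 px
    frame_interval_s: float = 10.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[1] != len(CHANNELS):
            raise ValueError(
                f"expected (T, 3, H, W) array, got shape {self.data.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def frame_shape(self) -> tuple:
        return self.data.shape[2:]

    def frame(self, t: int) -> np.ndarray:
        """Return the ``(3, H, W)`` frame at index ``t`` (bounds-checked)."""
        if not 0 <= t < self.n_frames:
            raise IndexError(f"frame {t} out of range [0, {self.n_frames})")
        return self.data[t]


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write ``stack`` as a multi-page TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.data,
        photometric="minisblack",
        planarconfig="separate",
        metadata={"axes": "TCYX"},
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    payload = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "channels": list(CHANNELS),
        "shape": list(stack.shape),
        "meta": stack.meta,
    }
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return sidecar


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack` (sidecar optional)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:  # single frame (C, H, W)
        data = data[None]
    kwargs: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        kwargs = {
            "pixel_size_um": payload.get("pixel_size_um", 1.289),
            "frame_interval_s": payload.get("frame_interval_s", 10.0),
            "meta": payload.get("meta", {}),
        }
    return ImageStack(np.asarray(data, dtype=np.float32), **kwargs)
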