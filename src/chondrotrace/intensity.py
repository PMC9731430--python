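"""From tracks and images to clean per-cell intensity traces.

Three steps, in a fixed order: grid-wise background subtraction (the
background is non-uniform and drifts as stain leaks into the matrix after
injury), extraction of the mean intensity over a small window around each
cell centroid, and optional moving-average smoothing of the resulting
traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stack import BLUE, CHANNELS, GREEN, RED, ImageStack
from .tracking import CellTracks


@dataclass
class BackgroundParams:
    """Grid background-subtraction settings.

    The image is split into ``grid x grid`` regions and, per region, the
    mean of its ``n_lowest`` smallest pixel values is subtracted — those
    pixels are matrix, never cell interiors, as long as ``n_lowest`` is a
    tiny fraction of the region.
    """

    grid: int = 8
    n_lowest: int = 20
    clip_negative: bool = False

    def __post_init__(self) -> None:
        if self.grid < 1 or self.n_lowest < 1:
            raise ValueError("grid and n_lowest must be >= 1")


@dataclass
class IntensityTrace:
    """Per-cell blue/green/red intensity vectors over frames."""

    cell_id: int
    frames: np.ndarray
    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    smoothed: bool = False
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        for name in CHANNELS:
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != self.frames.shape:
                raise ValueError(f"{name} length differs from frames")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, v)

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def n_frames(self) -> int:
        return self.frames.size

    def as_array(self) -> np.ndarray:
        """Stack channels into a ``(3, T)`` array (blue, green, red)."""
        return np.stack([self.blue, self.green, self.red])


def region_bounds(size: int, grid: int) -> list[tuple[int, int]]:
    """Floor-split ``size`` pixels into ``grid`` intervals; the remainder
    goes to the last interval."""
    base = size // grid
    if base == 0:
        raise ValueError(f"image of size {size} smaller than grid {grid}")
    bounds = [(k * base, (k + 1) * base) for k in range(grid - 1)]
    bounds.append(((grid - 1) * base, size))
    return bounds


def subtract_background(
    image: np.ndarray, params: BackgroundParams | None = None
) -> np.ndarray:
    """Subtract the per-region mean of the lowest pixel values.

    Applied to a single 2-D image (call per channel and per frame).  The
    output is offset-invariant: adding a constant to the input leaves the
    result unchanged.
    """
    params = params or BackgroundParams()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("subtract_background expects a 2-D image")
    out = np.empty_like(image)
    for y0, y1 in region_bounds(image.shape[0], params.grid):
        for x0, x1 in region_bounds(image.shape[1], params.grid):
            region = image[y0:y1, x0:x1]
            if params.n_lowest > region.size:
                raise ValueError(
                    f"n_lowest={params.n_lowest} exceeds region size {region.size}"
                )
            lowest = np.partition(region.ravel(), params.n_lowest - 1)[
                : params.n_lowest
            ]
            out[y0:y1, x0:x1] = region - lowest.mean()
    if params.clip_negative:
        out = np.clip(out, 0.0, None)
    return out


def subtract_background_frame(
    frame: np.ndarray, params: BackgroundParams | None = None
) -> np.ndarray:
    """Background-subtract each channel of a ``(3, H, W)`` frame."""
    return np.stack([subtract_background(ch, params) for ch in frame])


def smooth(trace: np.ndarray, window: int = 20) -> np.ndarray:
    """Centered moving average with shrink-to-valid boundary handling.

    Near the trace ends the average runs over the in-bounds portion of the
    window only, so no intensities are fabricated; output length equals
    input length.  For even windows the kernel leans one frame backward
    (frame ``i`` averages ``[i - w//2, i + w - w//2)``).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if window < 1:
        raise ValueError("window must be >= 1")
    kernel = np.ones(min(window, trace.size) if window > trace.size else window)
    num = np.convolve(trace, kernel, mode="same")
    den = np.convolve(np.ones_like(trace), kernel, mode="same")
    return num / den


def _round_half_away(v: np.ndarray) -> np.ndarray:
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


def extract_traces(
    stack: ImageStack,
    tracks: CellTracks,
    half_width: int = 1,
    background: BackgroundParams | None = None,
    smooth_window: int | None = None,
) -> list[IntensityTrace]:
    """Extract per-cell three-channel traces from the stack.

    For every tracked cell, frame and channel, the mean over the
    ``(2*half_width+1)**2`` pixel window centered on the rounded centroid
    (half rounds away from zero) is recorded; windows are truncated at
    image borders.  When ``background`` is given, each frame is
    background subtracted first — subtraction always precedes extraction.
    ``smooth_window`` optionally applies the moving average to every
    channel of every trace.
    """
    h, w = stack.frame_shape
    df = tracks.df
    if len(df) and df["frame"].max() >= stack.n_frames:
        raise ValueError(
            f"tracks reference frame {int(df['frame'].max())} "
            f"but stack has {stack.n_frames} frames"
        )
    values: dict[int, dict[int, np.ndarray]] = {}
    for frame, group in df.groupby("frame", sort=True):
        img = stack.frame(int(frame)).astype(float)
        if background is not None:
            img = subtract_background_frame(img, background)
        cx = _round_half_away(group["x"].to_numpy()).astype(int)
        cy = _round_half_away(group["y"].to_numpy()).astype(int)
        for cid, x0, y0 in zip(group["cell_id"].to_numpy(), cx, cy):
            y_lo, y_hi = max(y0 - half_width, 0), min(y0 + half_width + 1, h)
            x_lo, x_hi = max(x0 - half_width, 0), min(x0 + half_width + 1, w)
            if y_lo >= y_hi or x_lo >= x_hi:
                raise ValueError(f"cell {cid} centroid outside image at frame {frame}")
            win = img[:, y_lo:y_hi, x_lo:x_hi]
            values.setdefault(int(cid), {})[int(frame)] = win.mean(axis=(1, 2))

    traces = []
    for cid in sorted(values):
        frames = np.array(sorted(values[cid]), dtype=int)
        arr = np.array([values[cid][f] for f in frames])  # (T, 3)
        chans = [arr[:, BLUE], arr[:, GREEN], arr[:, RED]]
        if smooth_window is not None:
            chans = [smooth(c, smooth_window) for c in chans]
        traces.append(
            IntensityTrace(
                cell_id=cid,
                frames=frames,
                blue=chans[0],
                green=chans[1],
                red=chans[2],
                smoothed=smooth_window is not None,
                background_subtracted=background is not None,
            )
        )
    return traces


def smooth_traces(traces: list[IntensityTrace], window: int = 20) -> list[IntensityTrace]:
    """Return copies of ``traces`` with every channel smoothed."""
    out = []
    for tr in traces:
        out.append(
            IntensityTrace(
                cell_id=tr.cell_id,
                frames=tr.frames.copy(),
                blue=smooth(tr.blue, window),
                green=smooth(tr.green, window),
                red=smooth(tr.red, window),
                smoothed=True,
                background_subtracted=tr.background_subtracted,
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV interchange


def traces_to_frame(traces: list[IntensityTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for k, f in enumerate(tr.frames):
            rows.append((tr.cell_id, int(f), tr.blue[k], tr.green[k], tr.red[k]))
    return pd.DataFrame(rows, columns=["cell_id", "frame", "blue", "green", "red"])


def write_traces(
    traces: list[IntensityTrace], path: str | Path
) -> None:
    """Write traces as CSV with a header comment recording processing flags."""
    path = Path(path)
    flags = {
        "background_subtracted": all(t.background_subtracted for t in traces),
        "smoothed": all(t.smoothed for t in traces),
    }
    with open(path, "w") as fh:
        fh.write(f"# background_subtracted={flags['background_subtracted']} "
                 f"smoothed={flags['smoothed']}\n")
        traces_to_frame(traces).to_csv(fh, index=False, float_format="%.10g")


def read_traces(path: str | Path) -> list[IntensityTrace]:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        flags = {"background_subtracted": False, "smoothed": False}
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=")
                    flags[k] = v == "True"
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    traces = []
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("frame")
        traces.append(
            IntensityTrace(
                cell_id=int(cid),
                frames=g["frame"].to_numpy(),
                blue=g["blue"].to_numpy(),
                green=g["green"].to_numpy(),
                red=g["red"].to_numpy(),
                **flags,
            )
        )
    return traces
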