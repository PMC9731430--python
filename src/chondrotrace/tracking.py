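"""Cell localization and trajectory linking on summed-channel images.

The tracker follows the classic centroid-tracking recipe: band-pass filter
the composite (blue+green+red) image, take local maxima as candidates,
refine each to sub-pixel precision by intensity-weighted centroid, then
link detections frame to frame by minimum-total-displacement assignment
with a short memory for missed detections.  Two enhancements target
fluctuating fluorescence: short gaps between detections are filled by
linear interpolation when the bracketing positions are less than about a
cell diameter apart, and once the tissue has relaxed (cells nearly
static), tracks are extended at their last position to the end of the
movie so intensities can still be read out when a cell goes dim.

Coordinates are 0-based pixel indices with ``(x, y) = (column, row)``;
sub-pixel centroids are real numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .stack import ImageStack

DETECTED = "detected"
INTERPOLATED = "interpolated"
EXTENDED = "extended"

_BIG = 1e9


@dataclass
class TrackParams:
    """Localization and linking settings.

    ``locate_diameter`` (odd, px) is the expected cell image size;
    ``min_mass`` drops dim spurious detections; ``max_link_displacement``
    bounds per-frame motion; gaps of up to ``max_gap_frames`` missing
    frames may be bridged when the bracketing detections are within
    ``max_gap_displacement`` (about one cell diameter).  When
    ``static_extension`` is on, tracks ending after ``static_start_frame``
    (auto-detected from track motion when None) are held at their last
    position to the end of the stack.
    """

    locate_diameter: int = 9
    min_mass: float = 40.0
    peak_threshold: float = 0.6
    max_link_displacement: float = 5.0
    max_gap_frames: int = 5
    max_gap_displacement: float = 10.0
    static_extension: bool = True
    static_start_frame: int | None = None

    def __post_init__(self) -> None:
        if self.locate_diameter < 3 or self.locate_diameter % 2 == 0:
            raise ValueError("locate_diameter must be odd and >= 3")
        if (
            self.max_link_displacement <= 0
            or self.max_gap_displacement <= 0
            or self.max_gap_frames < 0
        ):
            raise ValueError("distances must be positive")


class CellTracks:
    """Per-cell trajectories with per-frame provenance flags.

    Backed by a tidy DataFrame with columns
    ``cell_id, frame, x, y, provenance`` sorted by (cell_id, frame).
    """

    COLUMNS = ["cell_id", "frame", "x", "y", "provenance"]

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None or len(df) == 0:
            df = pd.DataFrame(columns=self.COLUMNS)
        df = df[self.COLUMNS].copy()
        df["cell_id"] = df["cell_id"].astype(int)
        df["frame"] = df["frame"].astype(int)
        self.df = df.sort_values(["cell_id", "frame"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.df["cell_id"].unique()

    @property
    def n_tracks(self) -> int:
        return self.df["cell_id"].nunique()

    def for_cell(self, cell_id: int) -> pd.DataFrame:
        return self.df[self.df["cell_id"] == cell_id]

    def positions_at(self, frame: int) -> pd.DataFrame:
        return self.df[self.df["frame"] == frame]

    def validate(self) -> None:
        """Check structural invariants; raises AssertionError on violation."""
        for cid, g in self.df.groupby("cell_id"):
            frames = g["frame"].to_numpy()
            assert np.all(np.diff(frames) > 0), f"cell {cid}: frames not increasing"
            prov = g["provenance"].to_numpy()
            det = np.flatnonzero(prov == DETECTED)
            if det.size:
                interp = np.flatnonzero(prov == INTERPOLATED)
                assert np.all((interp > det.min()) & (interp < det.max())), (
                    f"cell {cid}: interpolated frame outside detected bracket"
                )
                ext = np.flatnonzero(prov == EXTENDED)
                assert np.all(ext > det.max()), (
                    f"cell {cid}: extended frame before last detection"
                )

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CellTracks":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# operations


def composite(stack: ImageStack, frame: int) -> np.ndarray:
    """Pixelwise sum of the three channels at ``frame``."""
    return stack.frame(frame).sum(axis=0)


def _bandpass(image: np.ndarray, diameter: int) -> np.ndarray:
    smoothed = ndimage.gaussian_filter(image.astype(float), 1.0)
    background = ndimage.uniform_filter(image.astype(float), 2 * diameter + 1)
    return np.clip(smoothed - background, 0.0, None)


def locate(image: np.ndarray, params: TrackParams | None = None) -> pd.DataFrame:
    """Find bright isolated spots with sub-pixel centroids.

    Band-pass filters the image, takes local maxima above
    ``peak_threshold`` as candidates, and refines each by an iteratively
    re-centered intensity-weighted centroid over a ``locate_diameter``
    window (local background from the window border removed).  Detections
    with integrated mass below ``min_mass`` are discarded.

    Returns a DataFrame with columns ``x, y, mass, size``.
    """
    params = params or TrackParams()
    image = np.asarray(image, dtype=float)
    if image.min() < -1e-9:
        raise ValueError("image must be non-negative")
    d = params.locate_diameter
    r = d // 2
    bp = _bandpass(image, d)
    # local-maximum footprint of half a diameter: a cell's own peak must
    # survive next to a brighter neighbor one separation away
    foot = max(3, (d // 2) | 1)
    maxima = (bp == ndimage.maximum_filter(bp, size=foot)) & (
        bp > params.peak_threshold
    )
    ys, xs = np.nonzero(maxima)
    h, w = image.shape
    cand = np.column_stack([xs, ys]).astype(float)
    tree = cKDTree(cand) if len(cand) else None

    rows = []
    for y0, x0 in zip(ys, xs):
        cy, cx = int(y0), int(x0)
        # neighbors whose tails could contaminate the refinement window
        near = tree.query_ball_point([x0, y0], 2.5 * r)
        others = cand[[k for k in near if (cand[k][0], cand[k][1]) != (x0, y0)]]
        total = 0.0
        for _ in range(10):
            y_lo, y_hi = max(cy - r, 0), min(cy + r + 1, h)
            x_lo, x_hi = max(cx - r, 0), min(cx + r + 1, w)
            win = image[y_lo:y_hi, x_lo:x_hi]
            yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
            # keep only pixels nearer to this candidate than to any other,
            # so a bright neighbor's tail cannot drag the centroid away
            own = (xx - x0) ** 2 + (yy - y0) ** 2
            mask = np.ones_like(win, dtype=bool)
            for ox, oy in others:
                mask &= own <= (xx - ox) ** 2 + (yy - oy) ** 2
            border = np.concatenate(
                [win[0, :], win[-1, :], win[1:-1, 0], win[1:-1, -1]]
            )
            net = np.clip(win - np.median(border), 0.0, None) * mask
            total = float(net.sum())
            if total <= 0:
                break
            ybar = float((net * yy).sum() / total)
            xbar = float((net * xx).sum() / total)
            ni, nj = int(round(ybar)), int(round(xbar))
            if (ni, nj) == (cy, cx):
                break
            cy, cx = ni, nj
        if total <= 0 or total < params.min_mass:
            continue
        r2 = ((yy - ybar) ** 2 + (xx - xbar) ** 2) * net
        size = float(np.sqrt(r2.sum() / total))
        rows.append((xbar, ybar, float(total), size))

    df = pd.DataFrame(rows, columns=["x", "y", "mass", "size"])
    # merge candidates that converged to (numerically) the same centroid:
    # keep the most massive within half a diameter
    if len(df):
        df = df.sort_values("mass", ascending=False).reset_index(drop=True)
        xy = df[["x", "y"]].to_numpy()
        keep: list[int] = []
        for i in range(len(df)):
            if all(np.hypot(*(xy[i] - xy[k])) >= r for k in keep):
                keep.append(i)
        df = df.iloc[keep].sort_values(["y", "x"]).reset_index(drop=True)
    return df


def link(detections: pd.DataFrame, params: TrackParams | None = None) -> CellTracks:
    """Link per-frame detections into trajectories.

    Frame-by-frame minimum-total-displacement assignment (Hungarian
    algorithm) with displacement capped at ``max_link_displacement`` for
    consecutive frames and at ``max_gap_displacement`` across memory gaps
    of up to ``max_gap_frames`` missing frames.  Unlinked detections start
    new tracks.  ``detections`` needs columns ``frame, x, y``.
    """
    params = params or TrackParams()
    if detections is None or len(detections) == 0:
        return CellTracks()
    det = detections.sort_values("frame", kind="stable")

    next_id = 0
    active: dict[int, dict] = {}  # tid -> {xy, frame}
    rows: list[tuple] = []

    for frame, group in det.groupby("frame", sort=True):
        frame = int(frame)
        pts = group[["x", "y"]].to_numpy(dtype=float)
        # retire tracks whose gap exceeded the memory
        for tid in [t for t, s in active.items()
                    if frame - s["frame"] - 1 > params.max_gap_frames]:
            del active[tid]
        tids = sorted(active)
        assigned = np.full(len(pts), -1, dtype=int)
        if tids:
            last = np.array([active[t]["xy"] for t in tids])
            gaps = np.array([frame - active[t]["frame"] for t in tids])
            dist = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=2)
            limit = np.where(
                gaps == 1, params.max_link_displacement, params.max_gap_displacement
            )
            cost = np.where(dist <= limit[:, None], dist, _BIG)
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if cost[i, j] < _BIG:
                    assigned[j] = tids[i]
        for j, (x, y) in enumerate(pts):
            tid = assigned[j]
            if tid < 0:
                tid = next_id
                next_id += 1
                active[tid] = {}
            active[tid] = {"xy": np.array([x, y]), "frame": frame}
            rows.append((tid, frame, float(x), float(y), DETECTED))

    return CellTracks(pd.DataFrame(rows, columns=CellTracks.COLUMNS))


def interpolate_gaps(
    tracks: CellTracks, params: TrackParams | None = None
) -> CellTracks:
    """Fill internal detection gaps by linear interpolation.

    A missing stretch between two detected frames is filled (flag
    ``interpolated``) only when the bracketing detections are at most
    ``max_gap_displacement`` apart; larger gaps split the track in two
    (the later part receives a fresh cell_id).
    """
    params = params or TrackParams()
    if len(tracks) == 0:
        return CellTracks()
    next_id = int(tracks.df["cell_id"].max()) + 1
    rows: list[tuple] = []
    for cid, g in tracks.df.groupby("cell_id", sort=True):
        frames = g["frame"].to_numpy()
        xs = g["x"].to_numpy()
        ys = g["y"].to_numpy()
        prov = g["provenance"].to_numpy()
        cur = int(cid)
        rows.append((cur, int(frames[0]), xs[0], ys[0], prov[0]))
        for k in range(1, len(frames)):
            span = frames[k] - frames[k - 1]
            if span > 1:
                disp = float(np.hypot(xs[k] - xs[k - 1], ys[k] - ys[k - 1]))
                if disp <= params.max_gap_displacement:
                    for f in range(int(frames[k - 1]) + 1, int(frames[k])):
                        t = (f - frames[k - 1]) / span
                        rows.append((
                            cur, f,
                            float(xs[k - 1] + t * (xs[k] - xs[k - 1])),
                            float(ys[k - 1] + t * (ys[k] - ys[k - 1])),
                            INTERPOLATED,
                        ))
                else:
                    cur = next_id
                    next_id += 1
            rows.append((cur, int(frames[k]), xs[k], ys[k], prov[k]))
    return CellTracks(pd.DataFrame(rows, columns=CellTracks.COLUMNS))


def detect_static_start(
    tracks: CellTracks, threshold: float = 0.2, window: int = 10
) -> int:
    """First frame after which median per-frame track motion stays small.

    Computes the median displacement of all tracks between consecutive
    frames and returns the first frame from which that median remains
    below ``threshold`` px over a ``window``-frame stretch.  Falls back to
    frame 0 when no motion estimate is available (e.g. all static).
    """
    if len(tracks) == 0:
        return 0
    df = tracks.df[tracks.df["provenance"] == DETECTED]
    df = df.sort_values(["cell_id", "frame"])
    d = df.groupby("cell_id")[["frame", "x", "y"]].diff()
    ok = d["frame"] == 1
    disp = np.hypot(d.loc[ok, "x"], d.loc[ok, "y"])
    frames = df.loc[ok, "frame"].astype(int) - 1
    if disp.empty:
        return 0
    med = pd.Series(disp.values).groupby(frames.values).median()
    full = med.reindex(range(int(med.index.min()), int(med.index.max()) + 1))
    full = full.ffill().bfill()
    quiet = (full < threshold).to_numpy()
    run = 0
    for i, q in enumerate(quiet):
        run = run + 1 if q else 0
        if run >= min(window, len(quiet)):
            return int(full.index[i - run + 1])
    return int(full.index[-1] + 1)


def extend_static(
    tracks: CellTracks,
    n_frames: int | ImageStack,
    params: TrackParams | None = None,
) -> CellTracks:
    """Extend late-ending tracks at their last position to the final frame.

    Only tracks whose last frame falls at or after ``static_start_frame``
    are extended (flag ``extended``); during the moving phase a lost cell
    stays lost.  ``n_frames`` may be given directly or as the stack.
    """
    params = params or TrackParams()
    if isinstance(n_frames, ImageStack):
        n_frames = n_frames.n_frames
    if not params.static_extension or len(tracks) == 0:
        return CellTracks(tracks.df)
    start = params.static_start_frame
    if start is None:
        start = detect_static_start(tracks)
    if start >= n_frames:
        raise ValueError(
            f"static_start_frame {start} beyond stack length {n_frames}"
        )
    rows: list[tuple] = []
    for cid, g in tracks.df.groupby("cell_id", sort=True):
        last = g.iloc[-1]
        lf = int(last["frame"])
        if lf >= start and lf < n_frames - 1:
            for f in range(lf + 1, n_frames):
                rows.append((int(cid), f, float(last["x"]), float(last["y"]), EXTENDED))
    if not rows:
        return CellTracks(tracks.df)
    ext = pd.DataFrame(rows, columns=CellTracks.COLUMNS)
    return CellTracks(pd.concat([tracks.df, ext], ignore_index=True))


def locate_all(stack: ImageStack, params: TrackParams | None = None) -> pd.DataFrame:
    """Locate cells on the composite image of every frame."""
    params = params or TrackParams()
    parts = []
    for t in range(stack.n_frames):
        det = locate(composite(stack, t), params)
        det.insert(0, "frame", t)
        parts.append(det)
    if not parts:
        return pd.DataFrame(columns=["frame", "x", "y", "mass", "size"])
    return pd.concat(parts, ignore_index=True)


def track(stack: ImageStack, params: TrackParams | None = None) -> CellTracks:
    """Full tracking pipeline: composite -> locate -> link -> interpolate
    -> static extension."""
    params = params or TrackParams()
    detections = locate_all(stack, params)
    tracks = link(detections, params)
    tracks = interpolate_gaps(tracks, params)
    return extend_static(tracks, stack.n_frames, params)
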