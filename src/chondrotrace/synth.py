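"""Synthetic ground-truth scenes for end-to-end pipeline validation.

No public dataset accompanies the imaging setup this package targets, so
every stage is validated against simulated scenes with known truth:

* :func:`trace_template` emits the noise-free (or noise-corrupted)
  blue/green/red trace archetype of each of the twelve behavior
  categories, on the canonical background-subtracted intensity scale on
  which the decision-tree thresholds are defined;
* :func:`make_scene` lays cells out in a field, draws their categories,
  assigns impact-distance-dependent positions and relaxation-drift
  trajectories;
* :func:`render_stack` renders the scene into a multi-channel image
  stack (Gaussian spots over a structured background), the input the
  tracking stage consumes.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import BehaviorCategory
from .stack import ImageStack

#: order in which categories consume multinomial counts
CATEGORY_ORDER = list(BehaviorCategory)


@dataclass
class MotionModel:
    """Cell motion: ``static`` or impact-relaxation drift.

    Relaxation drift displaces every cell at t=0 along a spatially
    coherent field — radially outward from the impact site (or field
    center), with magnitude ``amplitude_px`` decaying over
    ``length_scale_px`` away from the center plus a small per-cell jitter
    — and relaxes back exponentially with time constant ``decay_frames``.
    Coherence matters: tissue deforms as a continuum, so neighboring
    cells move together and do not swap or collide.
    """

    kind: str = "relaxation_drift"  # or "static"
    amplitude_px: float = 12.0
    decay_frames: float = 40.0
    length_scale_px: float = 200.0
    jitter_px: float = 0.5


@dataclass
class ScenarioParams:
    """Ground-truth scene parameters.

    Defaults emulate the experimental setup the pipeline targets: a
    512 x 512 px field covering 660 x 660 um (1.289 um/px), ~10 s frame
    cadence, several hundred cells, and death-associated behaviors
    concentrated within 400 um of the impact site.  ``category_weights``
    is uniform over the twelve archetypes so every behavior is exercised.
    """

    n_cells: int = 500
    frame_count: int = 300
    frame_interval: float = 10.0
    field_size: int = 512
    pixel_size: float = 660.0 / 512.0
    category_weights: tuple = tuple([1.0 / 12] * 12)
    impact_center: tuple[float, float] | None = None
    impact_radius_um: float = 400.0
    motion: MotionModel = dc_field(default_factory=MotionModel)
    noise_sd: float = 1.0
    spot_sigma: float = 2.0
    min_separation_px: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        w = np.asarray(self.category_weights, dtype=float)
        if w.size != 12 or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("category_weights must be 12 non-negative values")
        self.category_weights = tuple(w / w.sum())
        if isinstance(self.motion, dict):
            self.motion = MotionModel(**self.motion)


@dataclass
class SyntheticCell:
    cell_id: int
    category: BehaviorCategory
    trajectory: np.ndarray  # (T, 2) of (x, y) px
    true_traces: np.ndarray  # (3, T) a.u.
    spot_sigma: float
    amplitude: float = 1.0


@dataclass
class SyntheticScene:
    cells: list[SyntheticCell]
    params: ScenarioParams

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def truth_labels(self) -> dict[int, BehaviorCategory]:
        return {c.cell_id: c.category for c in self.cells}

    def truth_frame(self) -> pd.DataFrame:
        """Ground truth as a tidy table (cell_id, frame, x, y, category,
        blue, green, red)."""
        rows = []
        for c in self.cells:
            for t in range(self.params.frame_count):
                rows.append((
                    c.cell_id, t,
                    c.trajectory[t, 0], c.trajectory[t, 1],
                    c.category.value,
                    c.true_traces[0, t], c.true_traces[1, t], c.true_traces[2, t],
                ))
        return pd.DataFrame(
            rows,
            columns=["cell_id", "frame", "x", "y", "category",
                     "blue", "green", "red"],
        )


@dataclass
class RenderParams:
    """Image formation settings.

    ``background_offsets`` (optional small 2-D array, upsampled to the
    field) emulates regionally elevated background from stain leakage, as
    does the optional ``leak_halo`` centered on the impact site.
    """

    background_level: float = 2.0
    background_offsets: np.ndarray | None = None
    leak_halo: bool = False
    leak_amplitude: float = 0.0
    leak_radius_px: float = 100.0
    camera_noise_sd: float = 0.5
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.background_level < 0 or self.leak_amplitude < 0:
            raise ValueError("render amplitudes must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


# ---------------------------------------------------------------------------
# trace templates


def _step(t: np.ndarray, at: int) -> np.ndarray:
    return (t >= at).astype(float)


def _bump(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _late_step_frame(frame_count: int) -> int:
    # late enough that the smoothed maximum lands after frame 120 and the
    # changepoint after frame 100, with >= 15 plateau frames remaining
    return min(180, frame_count - 25)


def trace_template(
    category: BehaviorCategory | str,
    frame_count: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin: float = 2.0,
) -> np.ndarray:
    """Noise-free archetype traces for one behavior category.

    Returns a ``(3, frame_count)`` array (blue, green, red) on the
    canonical background-subtracted intensity scale.  Event amplitudes
    exceed the decision-tree thresholds they trigger by ``margin``
    (default twice the threshold), so the noise-free template, after
    standard smoothing and feature extraction, classifies into
    ``category``.  Gaussian noise of sd ``noise_sd`` is added per channel
    and the result clipped at zero.
    """
    category = BehaviorCategory(str(category))
    if frame_count < 150:
        raise ValueError(
            "frame_count must be >= 150: archetype events are placed relative "
            "to the frame-100/120 late-phase boundaries of the decision tree"
        )
    t = np.arange(frame_count, dtype=float)
    blue = np.full(frame_count, 1.0)
    green = np.full(frame_count, 1.0)
    red = np.full(frame_count, 10.0)

    step_amp = margin * 10.0          # vs blue_rise_range 10
    level_amp = margin * 6.0          # staircase levels for category L
    green_amp = margin * 7.5          # smoothed prominence ~ margin * 3
    red_high = margin * 15.0          # vs red_mean_low 6, well above
    red_low = min(2.0, 6.0 / max(margin, 1.0))
    late = _late_step_frame(frame_count)

    if category is BehaviorCategory.A:
        blue = margin * 13.0 * np.exp(-t / 40.0) + 1.0
        red = np.full(frame_count, 3.0)
    elif category is BehaviorCategory.B:
        blue = 1.0 + step_amp * _step(t, 60)
        red = 28.0 * np.exp(-t / 60.0) + 2.0
    elif category is BehaviorCategory.C:
        rise = 1.0 + (step_amp + 1.0) * _step(t, 60)
        decay = np.clip(0.12 * (t - 60.0), 0.0, 16.8) * _step(t, 60)
        blue = rise - decay
        red = 28.0 * np.exp(-t / 60.0) + 2.0
    elif category is BehaviorCategory.D:
        blue = 1.0 + step_amp * _step(t, late)
        red = np.full(frame_count, 8.0)
    elif category is BehaviorCategory.E:
        blue = 1.0 + step_amp * _step(t, 60)
        red = np.full(frame_count, margin * 20.0 + 20.0)
    elif category is BehaviorCategory.F:
        green = 20.0 - 18.0 * _step(t, min(140, late - 15))
        blue = 1.0 + step_amp * _step(t, late)
    elif category is BehaviorCategory.G:
        blue = 1.0 + step_amp * _step(t, 60)
        green = 1.0 + green_amp * _bump(t, min(150, frame_count - 25), 5.0)
    elif category is BehaviorCategory.H:
        green = 1.0 + green_amp * _bump(t, 50, 5.0)
        blue = 1.0 + step_amp * _step(t, 100)
    elif category is BehaviorCategory.I:
        blue = np.full(frame_count, 2.0)
        green = 1.0 + green_amp * (
            _bump(t, 80, 5.0) + _bump(t, min(180, frame_count - 25), 5.0)
        )
        red = np.full(frame_count, red_high)
    elif category is BehaviorCategory.J:
        blue = np.full(frame_count, 2.0)
        red = np.full(frame_count, red_high)
    elif category is BehaviorCategory.K:
        blue = np.full(frame_count, 2.0)
        red = np.full(frame_count, red_low)
    elif category is BehaviorCategory.L:
        blue = (
            1.0
            + level_amp * _step(t, 50)
            + level_amp * _step(t, 110)
            - level_amp * _step(t, 170)
            + level_amp * _step(t, 230)
        )
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown category {category}")

    traces = np.stack([blue, green, red])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        traces = traces + rng.normal(0.0, noise_sd, traces.shape)
    return np.clip(traces, 0.0, None)


# ---------------------------------------------------------------------------
# scene construction


def _place_positions(
    rng: np.random.Generator,
    n: int,
    field: int,
    min_sep: float,
    border: float,
) -> np.ndarray:
    """Seeded dart throwing with a uniform grid for neighbor queries."""
    if n == 0:
        return np.zeros((0, 2))
    cell = max(min_sep, 1.0)
    nx = int(np.ceil(field / cell))
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.zeros((n, 2))
    placed = 0
    attempts = 0
    max_attempts = 200 * n + 1000
    lo, hi = border, field - border
    if hi <= lo:
        raise ValueError("field too small for border margin")
    while placed < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} cells with min separation {min_sep} px "
                f"in a {field} px field (placed {placed})"
            )
        p = rng.uniform(lo, hi, 2)
        gi, gj = int(p[0] / cell), int(p[1] / cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((gi + di, gj + dj), ()):
                    if np.hypot(*(pts[k] - p)) < min_sep:
                        ok = False
                        break
        if ok:
            pts[placed] = p
            grid.setdefault((gi, gj), []).append(placed)
            placed += 1
    return pts


def _assign_positions(
    rng: np.random.Generator,
    categories: list[BehaviorCategory],
    pts: np.ndarray,
    params: ScenarioParams,
) -> np.ndarray:
    """Map cells to positions; with an impact site, death-associated
    categories (B, C) prefer the inside and normal cells (J) the outside."""
    n = len(categories)
    order = np.arange(n)
    if params.impact_center is None:
        perm = rng.permutation(n)
        return pts[perm]
    cx, cy = params.impact_center
    radius_px = params.impact_radius_um / params.pixel_size
    dist = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    inside = list(rng.permutation(np.flatnonzero(dist <= radius_px)))
    outside = list(rng.permutation(np.flatnonzero(dist > radius_px)))
    assigned = np.full(n, -1, dtype=int)

    def take(pref: list[int], alt: list[int]) -> int:
        if pref:
            return pref.pop()
        return alt.pop()

    p_prefer = 0.9
    groups = (
        [i for i in order if categories[i] in (BehaviorCategory.B, BehaviorCategory.C)],
        [i for i in order if categories[i] is BehaviorCategory.J],
        [i for i in order
         if categories[i] not in (BehaviorCategory.B, BehaviorCategory.C,
                                  BehaviorCategory.J)],
    )
    for gi, idxs in enumerate(groups):
        for i in idxs:
            u = rng.random()
            if gi == 0:
                assigned[i] = take(inside, outside) if u < p_prefer else take(outside, inside)
            elif gi == 1:
                assigned[i] = take(outside, inside) if u < p_prefer else take(inside, outside)
            else:
                # uniform over what remains
                pool = inside if (inside and (not outside or u < len(inside) /
                                              (len(inside) + len(outside)))) else outside
                assigned[i] = pool.pop()
    return pts[assigned]


def make_scene(params: ScenarioParams) -> SyntheticScene:
    """Build a ground-truth scene from scenario parameters.

    Per-category cell counts are a single multinomial draw from
    ``category_weights`` (the first use of the seeded generator), cells
    are placed by seeded dart throwing honoring the minimum separation,
    trajectories follow the motion model, and each cell receives its
    category's trace template with per-cell noise.  Identical parameters
    (including seed) give bit-identical scenes.
    """
    rng = np.random.default_rng(params.seed)
    counts = rng.multinomial(params.n_cells, params.category_weights)
    categories: list[BehaviorCategory] = []
    for cat, c in zip(CATEGORY_ORDER, counts):
        categories.extend([cat] * int(c))

    border = max(params.min_separation_px, 3 * params.spot_sigma)
    pts = _place_positions(
        rng, params.n_cells, params.field_size, params.min_separation_px, border
    )
    pts = _assign_positions(rng, categories, pts, params)

    T = params.frame_count
    t = np.arange(T, dtype=float)
    motion = params.motion
    if motion.kind == "relaxation_drift":
        center = np.asarray(
            params.impact_center
            if params.impact_center is not None
            else (params.field_size / 2.0, params.field_size / 2.0)
        )
        decay = np.exp(-t / motion.decay_frames)
    elif motion.kind != "static":
        raise ValueError(f"unknown motion model {motion.kind!r}")
    cells: list[SyntheticCell] = []
    for i, cat in enumerate(categories):
        base = pts[i]
        if motion.kind == "static" or params.n_cells == 0:
            traj = np.tile(base, (T, 1))
        else:
            radial = base - center
            r = float(np.hypot(*radial))
            u = radial / r if r > 1e-9 else np.array([1.0, 0.0])
            mag = motion.amplitude_px * np.exp(-r / motion.length_scale_px)
            disp = mag * u + motion.jitter_px * rng.normal(size=2)
            traj = base[None, :] + decay[:, None] * disp[None, :]
            traj = np.clip(traj, 1.0, params.field_size - 2.0)
        cell_seed = int(rng.integers(0, 2**31 - 1))
        traces = trace_template(cat, T, params.noise_sd, cell_seed)
        cells.append(
            SyntheticCell(
                cell_id=i,
                category=cat,
                trajectory=traj,
                true_traces=traces,
                spot_sigma=params.spot_sigma,
            )
        )
    return SyntheticScene(cells=cells, params=params)


def archetype_scene(
    frame_count: int = 300,
    field_size: int = 128,
    noise_sd: float = 0.0,
    seed: int = 0,
    spot_sigma: float = 2.0,
) -> SyntheticScene:
    """A static scene with exactly one cell per behavior category.

    Cells sit on a regular grid well separated from each other and the
    borders; convenient for exercising the full image pipeline against
    every archetype at once.
    """
    params = ScenarioParams(
        n_cells=12,
        frame_count=frame_count,
        field_size=field_size,
        noise_sd=noise_sd,
        motion=MotionModel(kind="static"),
        spot_sigma=spot_sigma,
        seed=seed,
    )
    ncol = 4
    pitch = (field_size - 40) / (ncol - 1)
    cells = []
    rng = np.random.default_rng(seed)
    for i, cat in enumerate(CATEGORY_ORDER):
        gx = 20 + (i % ncol) * pitch
        gy = 20 + (i // ncol) * pitch
        traj = np.tile([gx, gy], (frame_count, 1)).astype(float)
        cell_seed = int(rng.integers(0, 2**31 - 1))
        cells.append(
            SyntheticCell(
                cell_id=i,
                category=cat,
                trajectory=traj,
                true_traces=trace_template(cat, frame_count, noise_sd, cell_seed),
                spot_sigma=spot_sigma,
            )
        )
    return SyntheticScene(cells=cells, params=params)


# ---------------------------------------------------------------------------
# rendering


def _background(params: ScenarioParams, render: RenderParams) -> np.ndarray:
    size = params.field_size
    bg = np.full((size, size), float(render.background_level))
    if render.background_offsets is not None:
        offsets = np.asarray(render.background_offsets, dtype=float)
        reps = (
            int(np.ceil(size / offsets.shape[0])),
            int(np.ceil(size / offsets.shape[1])),
        )
        bg = bg + np.kron(offsets, np.ones(reps))[:size, :size]
    if render.leak_halo and params.impact_center is not None:
        cx, cy = params.impact_center
        yy, xx = np.mgrid[0:size, 0:size]
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        bg = bg + render.leak_amplitude * np.exp(-0.5 * r2 / render.leak_radius_px**2)
    return bg


def render_frame(
    scene: SyntheticScene,
    t: int,
    render: RenderParams | None = None,
    rng: np.random.Generator | None = None,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Render one ``(3, H, W)`` frame of the scene.

    Each cell is an isotropic Gaussian spot whose per-channel amplitude is
    its true trace value at this frame, added onto the background; camera
    noise is drawn from ``rng`` when provided.
    """
    render = render or RenderParams()
    params = scene.params
    size = params.field_size
    if background is None:
        background = _background(params, render)
    frame = np.tile(background, (3, 1, 1))
    for cell in scene.cells:
        x, y = cell.trajectory[t]
        if not (0 <= x < size and 0 <= y < size):
            raise ValueError(f"cell {cell.cell_id} outside field at frame {t}")
        s = cell.spot_sigma
        r = int(np.ceil(4 * s))
        x0, y0 = int(np.floor(x)), int(np.floor(y))
        x_lo, x_hi = max(x0 - r, 0), min(x0 + r + 2, size)
        y_lo, y_hi = max(y0 - r, 0), min(y0 + r + 2, size)
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        spot = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * s * s))
        for ch in range(3):
            amp = cell.amplitude * cell.true_traces[ch, t]
            frame[ch, y_lo:y_hi, x_lo:x_hi] += amp * spot
    if rng is not None and render.camera_noise_sd > 0:
        frame = frame + rng.normal(0.0, render.camera_noise_sd, frame.shape)
    return np.clip(frame, 0.0, None)


def render_stack(
    scene: SyntheticScene, render: RenderParams | None = None
) -> ImageStack:
    """Render the whole scene into an ImageStack.

    Camera noise is seeded from the scene seed, so the same scene and
    render parameters always produce the identical stack.  Values above
    the bit-depth ceiling are clipped and the saturated-pixel count is
    recorded in ``stack.meta`` (and warned about) rather than silently
    wrapped.
    """
    render = render or RenderParams()
    params = scene.params
    T = params.frame_count
    rng = np.random.default_rng([params.seed, 2**16 + 1])
    background = _background(params, render)
    data = np.empty((T, 3, params.field_size, params.field_size), dtype=np.float32)
    for t in range(T):
        data[t] = render_frame(scene, t, render, rng, background)
    ceiling = float(2**render.bit_depth - 1)
    saturated = int(np.count_nonzero(data > ceiling))
    if saturated:
        warnings.warn(
            f"{saturated} pixels exceed the {render.bit_depth}-bit ceiling; clipped",
            RuntimeWarning,
            stacklevel=2,
        )
        data = np.clip(data, 0.0, ceiling)
    return ImageStack(
        data,
        pixel_size_um=params.pixel_size,
        frame_interval_s=params.frame_interval,
        meta={"seed": params.seed, "saturated_pixels": saturated},
    )


def write_scene(
    scene: SyntheticScene,
    render: RenderParams,
    stack_path: str | Path,
    truth_path: str | Path,
) -> ImageStack:
    """Render and write the stack (TIFF + sidecar) and ground-truth CSV."""
    from .stack import write_stack

    stack = render_stack(scene, render)
    write_stack(stack, stack_path)
    scene.truth_frame().to_csv(truth_path, index=False, float_format="%.10g")
    return stack
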