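"""End-to-end validation benchmarks on synthetic ground truth.

Two headline figures characterize the pipeline:

* :func:`tracking_recovery` — the fraction of cells for which the
  enhanced tracker (linking + gap interpolation + static extension)
  recovers a track covering every frame of the movie, on a rendered
  scene with relaxation drift and random per-frame detection dropout;
* :func:`tree_accuracy` — total accuracy of smoothing + fingerprint
  extraction + the decision tree against ground-truth labels on noisy
  synthetic traces.

Both are computed from scratch from a single integer seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import BehaviorCategory, TreeParams, classify_all, score
from .features import PeakParams, StepParams, fingerprint
from .intensity import IntensityTrace, smooth
from .synth import RenderParams, ScenarioParams, _background, make_scene, render_frame
from .tracking import TrackParams, extend_static, interpolate_gaps, link, locate


def tracking_recovery(
    seed: int = 1,
    n_cells: int = 500,
    frame_count: int = 300,
    field_size: int = 512,
    dropout: float = 0.05,
    noise_sd: float = 1.0,
    camera_noise_sd: float = 0.5,
    track_params: TrackParams | None = None,
    match_tolerance_px: float = 2.0,
) -> dict:
    """Measure the full-duration track recovery fraction.

    Renders a seeded relaxation-drift scene frame by frame, locates cells
    on the composite image, deletes a random ``dropout`` fraction of the
    detections in every frame, links/interpolates/extends, and reports the
    percentage of ground-truth cells matched (mean distance below
    ``match_tolerance_px``) by a recovered track that covers every frame.
    """
    params = ScenarioParams(
        n_cells=n_cells,
        frame_count=frame_count,
        field_size=field_size,
        noise_sd=noise_sd,
        seed=seed,
    )
    scene = make_scene(params)
    render = RenderParams(camera_noise_sd=camera_noise_sd)
    track_params = track_params or TrackParams()
    rng = np.random.default_rng([seed, 2**16 + 1])
    drop_rng = np.random.default_rng([seed, 999])
    background = _background(params, render)

    parts = []
    for t in range(frame_count):
        frame = render_frame(scene, t, render, rng, background)
        det = locate(frame.sum(axis=0), track_params)
        det = det[drop_rng.random(len(det)) >= dropout]
        det.insert(0, "frame", t)
        parts.append(det)
    detections = pd.concat(parts, ignore_index=True)

    tracks = extend_static(
        interpolate_gaps(link(detections, track_params), track_params),
        frame_count,
        track_params,
    )
    full = [
        (g["frame"].to_numpy(), g["x"].to_numpy(), g["y"].to_numpy())
        for _, g in tracks.df.groupby("cell_id")
        if len(g) == frame_count
    ]
    recovered = 0
    for cell in scene.cells:
        for frames, xs, ys in full:
            err = np.hypot(
                xs - cell.trajectory[frames, 0], ys - cell.trajectory[frames, 1]
            ).mean()
            if err < match_tolerance_px:
                recovered += 1
                break
    return {
        "percent": 100.0 * recovered / n_cells,
        "recovered": recovered,
        "n": n_cells,
    }


def tree_accuracy(
    seed: int = 1,
    per_category: int = 100,
    frame_count: int = 300,
    noise_sd: float = 1.0,
    smooth_window: int = 20,
    peak_params: PeakParams | None = None,
    step_params: StepParams | None = None,
    tree_params: TreeParams | None = None,
) -> dict:
    """Measure decision-tree total accuracy on noisy synthetic traces.

    Generates ``per_category`` labeled traces for each of the twelve
    behavior archetypes, smooths them, extracts fingerprints, classifies
    with the default tree, and scores against the generating labels.
    """
    from .synth import trace_template

    tree_params = tree_params or TreeParams()
    rng = np.random.default_rng(seed)
    truth: dict[int, BehaviorCategory] = {}
    fingerprints = []
    cid = 0
    frames = np.arange(frame_count)
    for cat in BehaviorCategory:
        for _ in range(per_category):
            traces = trace_template(
                cat, frame_count, noise_sd, int(rng.integers(0, 2**31 - 1))
            )
            b, g, r = (smooth(traces[k], smooth_window) for k in range(3))
            trace = IntensityTrace(
                cid, frames, b, g, r, smoothed=True, background_subtracted=True
            )
            fingerprints.append(
                fingerprint(
                    trace, peak_params, step_params,
                    after_frames=[tree_params.red_mean_frame],
                )
            )
            truth[cid] = cat
            cid += 1
    result = classify_all(fingerprints, tree_params)
    per_cat, total = score(result, truth)
    return {
        "percent": 100.0 * total,
        "per_category": {c.value: a for c, a in per_cat.items()},
        "n": len(truth),
    }
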