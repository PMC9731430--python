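"""Shared fixtures: small synthetic scenes and independent oracles."""

import numpy as np
import pytest

from chondrotrace.classify import BehaviorCategory
from chondrotrace.synth import (
    MotionModel,
    RenderParams,
    ScenarioParams,
    archetype_scene,
    make_scene,
    render_stack,
    trace_template,
)


@pytest.fixture(scope="session")
def templates_300():
    """Noise-free 300-frame trace templates for all twelve categories."""
    return {
        cat: trace_template(cat, 300, 0.0, seed=0) for cat in BehaviorCategory
    }


@pytest.fixture(scope="session")
def noisy_templates_300():
    """Seeded noisy (sd=1) templates, three replicates per category."""
    out = {}
    for cat in BehaviorCategory:
        out[cat] = [trace_template(cat, 300, 1.0, seed=100 + k) for k in range(3)]
    return out


@pytest.fixture(scope="session")
def small_static_scene():
    """50-cell noise-free static scene (256 px, 150 frames)."""
    params = ScenarioParams(
        n_cells=50,
        frame_count=150,
        field_size=256,
        noise_sd=0.0,
        motion=MotionModel(kind="static"),
        seed=3,
    )
    return make_scene(params)


@pytest.fixture(scope="session")
def small_static_stack(small_static_scene):
    return render_stack(small_static_scene, RenderParams(camera_noise_sd=0.0))


@pytest.fixture(scope="session")
def archetypes_rendered():
    """One cell per category, rendered noise-free."""
    scene = archetype_scene(frame_count=300, field_size=128, noise_sd=0.0, seed=5)
    stack = render_stack(scene, RenderParams(camera_noise_sd=0.0))
    return scene, stack


# ---------------------------------------------------------------------------
# independent oracles (brute force, by definition)


def prominence_oracle(x, min_prominence, max_ratio):
    """Peak locations by scanning every local maximum and computing
    topographic prominence and half-prominence width from first principles."""
    x = np.asarray(x, dtype=float)
    n = x.size
    locs = []
    for i in range(1, n - 1):
        if not (x[i] > x[i - 1] and x[i] >= x[i + 1]):
            continue
        loc = i
        if x[i] == x[i + 1]:  # plateau: candidate is its midpoint, if it falls
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 >= n or x[j + 1] > x[i]:
                continue
            loc = (i + j) // 2
        # walk left/right to the nearest strictly higher sample; the base on
        # each side is the minimum over that stretch
        left_base = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            left_base = min(left_base, x[j])
            j -= 1
        left_bound = j + 1
        if j < 0:
            pass  # reached the start: base is the running minimum
        right_base = x[i]
        j = i + 1
        while j < n and x[j] <= x[i]:
            right_base = min(right_base, x[j])
            j += 1
        right_bound = j - 1
        prom = x[i] - max(left_base, right_base)
        if prom < min_prominence:
            continue
        # half-prominence width with linear interpolation, bounded by the
        # same stretches used for the prominence bases
        level = x[i] - 0.5 * prom
        wl = float(left_bound)
        for k in range(i, left_bound - 1, -1):
            if x[k] < level:
                wl = k + (level - x[k]) / (x[k + 1] - x[k])
                break
        wr = float(right_bound)
        for k in range(i, right_bound + 1):
            if x[k] < level:
                wr = k - (level - x[k]) / (x[k - 1] - x[k])
                break
        width = wr - wl
        if width / prom <= max_ratio:
            locs.append(loc)
    return locs


def single_step_oracle(x, min_segment=2):
    """Exhaustive least-squares single-changepoint location: the split that
    minimizes total SSE of one fitted line per side."""
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size, dtype=float)

    def sse(lo, hi):
        if hi - lo < 2:
            return 0.0
        coef = np.polyfit(t[lo:hi], x[lo:hi], 1)
        resid = x[lo:hi] - np.polyval(coef, t[lo:hi])
        return float(resid @ resid)

    best = None
    for cp in range(min_segment, x.size - min_segment + 1):
        total = sse(0, cp) + sse(cp, x.size)
        if best is None or total < best[0]:
            best = (total, cp)
    return best[1]


@pytest.fixture(scope="session")
def peak_oracle():
    return prominence_oracle


@pytest.fixture(scope="session")
def step_oracle():
    return single_step_oracle
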