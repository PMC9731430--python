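"""Rule-based classification of cell behavior fingerprints.

Twelve behavior categories describe how nuclear membrane permeability
(blue), cytosolic calcium (green) and mitochondrial polarity (red) evolve
after a mechanical insult.  A fixed decision tree over the extracted
fingerprint assigns each cell exactly one category; every threshold is in
background-subtracted arbitrary intensity units (or frames) and lives in
:class:`TreeParams`.  All comparisons are strict inequalities.

The tree resolves, in order: an initially-elevated permeability signal;
then, among cells with permeability changepoints, multi-level signals,
polarized-mitochondria deaths, the ordering of calcium transients versus
the permeability step, late steps (with or without a calcium drop), and
rise-and-fall versus rise-and-plateau shapes; among cells without
changepoints, calcium transients, slow permeability rises, and the normal
versus all-low split on the late red mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .features import FeatureFingerprint


class BehaviorCategory(str, Enum):
    """The twelve cell behavior archetypes."""

    A = "A"  # permeability starts elevated and decays
    B = "B"  # permeability increases early and plateaus / keeps rising
    C = "C"  # permeability increases early then decays
    D = "D"  # permeability increases late, no prior trigger
    E = "E"  # mitochondria polarized yet permeability increases
    F = "F"  # calcium drops after sustained elevation, then permeability rises
    G = "G"  # calcium transient after permeability already elevated
    H = "H"  # calcium transient then permeability increase
    I = "I"  # calcium transient(s) only, permeability unchanged
    J = "J"  # normal: no transients, polarized mitochondria
    K = "K"  # all signals low, depolarized mitochondria
    L = "L"  # permeability shows multiple levels

    def __str__(self) -> str:  # noqa: D105
        return self.value


CATEGORY_DESCRIPTIONS: dict[BehaviorCategory, str] = {
    BehaviorCategory.A: "nuclear membrane permeability starts elevated",
    BehaviorCategory.B: "nuclear membrane permeability increases",
    BehaviorCategory.C: "nuclear membrane permeability increases and decreases",
    BehaviorCategory.D: "nuclear membrane permeability increases late",
    BehaviorCategory.E: "mitochondria polarized but permeability increases",
    BehaviorCategory.F: "calcium drops, then permeability increases",
    BehaviorCategory.G: "permeability elevated, calcium transient afterwards",
    BehaviorCategory.H: "calcium transient, then permeability increases",
    BehaviorCategory.I: "calcium transient, no permeability change",
    BehaviorCategory.J: "normal cells, polarized mitochondria",
    BehaviorCategory.K: "all signals low, depolarized mitochondria",
    BehaviorCategory.L: "permeability has multiple levels",
}


@dataclass
class TreeParams:
    """Decision-tree thresholds (arbitrary intensity units / frame indices).

    Frame-indexed thresholds are interpreted at the long-term imaging
    cadence and are configurable because the cadence itself is a free
    parameter of the acquisition.
    """

    elevated_blue_max: float = 7.0
    elevated_blue_argmax_frame: int = 7
    multilevel_changepoint_count: int = 3  # strictly more than
    red_blue_mean_diff: float = 20.0
    late_argmax_frame: int = 120
    late_changepoint_frame: int = 100
    plateau_range_after_max: float = 8.0
    blue_rise_range: float = 10.0
    red_mean_frame: int = 50
    red_mean_low: float = 6.0

    def __post_init__(self) -> None:
        numeric = (
            self.elevated_blue_max,
            self.elevated_blue_argmax_frame,
            self.multilevel_changepoint_count,
            self.red_blue_mean_diff,
            self.late_argmax_frame,
            self.late_changepoint_frame,
            self.plateau_range_after_max,
            self.blue_rise_range,
            self.red_mean_frame,
            self.red_mean_low,
        )
        if any(v <= 0 for v in numeric):
            raise ValueError("all tree thresholds must be positive")


@dataclass
class ClassificationResult:
    """Per-cell labels with replayable decision paths and dataset counts."""

    cell_ids: list[int]
    categories: list[BehaviorCategory]
    paths: list[tuple[str, ...]]

    @property
    def counts(self) -> dict[BehaviorCategory, int]:
        out = {cat: 0 for cat in BehaviorCategory}
        for cat in self.categories:
            out[cat] += 1
        return out

    def as_mapping(self) -> dict[int, BehaviorCategory]:
        return dict(zip(self.cell_ids, self.categories))

    def __len__(self) -> int:
        return len(self.cell_ids)


def classify_cell(
    fp: FeatureFingerprint, params: TreeParams | None = None
) -> tuple[BehaviorCategory, tuple[str, ...]]:
    """Run one fingerprint through the decision tree.

    Returns the category together with the ordered list of branch
    decisions taken, which replays to the same leaf.
    """
    p = params or TreeParams()
    path: list[str] = []
    blue = fp.stats["blue"]
    red = fp.stats["red"]
    try:
        red_mean_after = red.mean_after[p.red_mean_frame]
    except KeyError as exc:
        raise ValueError(
            f"fingerprint lacks red mean-after-frame({p.red_mean_frame}); "
            "recompute the fingerprint with this frame in after_frames"
        ) from exc

    def leaf(cat: BehaviorCategory) -> tuple[BehaviorCategory, tuple[str, ...]]:
        path.append(f"-> {cat.value}")
        return cat, tuple(path)

    # 1: permeability elevated from the start
    if blue.max > p.elevated_blue_max and blue.argmax < p.elevated_blue_argmax_frame:
        path.append(
            f"blue max>{p.elevated_blue_max} and argmax<{p.elevated_blue_argmax_frame}"
        )
        return leaf(BehaviorCategory.A)
    path.append("blue not elevated at start")

    blue_cps = fp.changepoints["blue"]
    green_peaks = fp.peaks["green"]

    if len(blue_cps) > 0:
        path.append("has blue changepoints")
        # 2a: multiple permeability levels
        if len(blue_cps) > p.multilevel_changepoint_count:
            path.append(f">{p.multilevel_changepoint_count} blue changepoints")
            return leaf(BehaviorCategory.L)
        path.append(f"<= {p.multilevel_changepoint_count} blue changepoints")
        # 2b: polarized mitochondria despite permeability increase
        if fp.red_blue_mean_diff > p.red_blue_mean_diff:
            path.append(f"mean(red-blue)>{p.red_blue_mean_diff}")
            return leaf(BehaviorCategory.E)
        path.append(f"mean(red-blue)<={p.red_blue_mean_diff}")
        # 2c: calcium transients relative to the permeability step
        if len(green_peaks) > 0:
            first_peak = green_peaks.first_location
            first_cp = blue_cps.first_index
            if first_peak < first_cp:
                path.append("green peak before first blue changepoint")
                return leaf(BehaviorCategory.H)
            path.append("green peak after first blue changepoint")
            return leaf(BehaviorCategory.G)
        path.append("no green peaks")
        # 2d: late versus immediate permeability increase
        late = (
            blue.argmax > p.late_argmax_frame
            and blue_cps.first_index > p.late_changepoint_frame
        )
        if late:
            path.append(
                f"late: blue argmax>{p.late_argmax_frame} and "
                f"changepoint>{p.late_changepoint_frame}"
            )
            if len(fp.changepoints["green"]) > 0:
                path.append("has green changepoint")
                return leaf(BehaviorCategory.F)
            path.append("no green changepoint")
            return leaf(BehaviorCategory.D)
        path.append("immediate increase")
        if len(fp.peaks["blue"]) > 0:
            path.append("has blue peaks")
            return leaf(BehaviorCategory.C)
        path.append("no blue peaks")
        if blue.range_after_argmax < p.plateau_range_after_max:
            path.append(f"range after blue max<{p.plateau_range_after_max}")
            return leaf(BehaviorCategory.B)
        path.append("remaining in changepoint branch")
        return leaf(BehaviorCategory.A)

    path.append("no blue changepoints")
    # 3: no permeability step
    if len(green_peaks) > 0:
        path.append("has green peaks")
        return leaf(BehaviorCategory.I)
    path.append("no green peaks")
    if blue.range > p.blue_rise_range:
        path.append(f"blue range>{p.blue_rise_range}")
        return leaf(BehaviorCategory.B)
    path.append(f"blue range<={p.blue_rise_range}")
    if red_mean_after < p.red_mean_low:
        path.append(f"red mean after frame {p.red_mean_frame}<{p.red_mean_low}")
        return leaf(BehaviorCategory.K)
    path.append(f"red mean after frame {p.red_mean_frame}>={p.red_mean_low}")
    return leaf(BehaviorCategory.J)


def classify_all(
    fingerprints: Iterable[FeatureFingerprint], params: TreeParams | None = None
) -> ClassificationResult:
    """Classify every fingerprint independently (order has no effect)."""
    ids, cats, paths = [], [], []
    errors = []
    for fp in fingerprints:
        try:
            cat, path = classify_cell(fp, params)
        except ValueError as exc:
            errors.append((fp.cell_id, str(exc)))
            continue
        ids.append(fp.cell_id)
        cats.append(cat)
        paths.append(path)
    if errors:
        detail = "; ".join(f"cell {cid}: {msg}" for cid, msg in errors[:5])
        raise ValueError(f"{len(errors)} cells failed to classify: {detail}")
    return ClassificationResult(ids, cats, paths)


def score(
    predicted: ClassificationResult,
    truth: Mapping[int, BehaviorCategory | str],
) -> tuple[dict[BehaviorCategory, float | None], float]:
    """Score predictions against ground-truth labels.

    Per-category accuracy is true positives divided by the number of cells
    whose *truth* is that category; categories absent from the truth are
    reported as ``None`` (undefined), never zero.  Total accuracy is the
    overall fraction of correctly labeled cells.
    """
    truth = {cid: BehaviorCategory(str(cat)) for cid, cat in truth.items()}
    pred = predicted.as_mapping()
    if set(pred) != set(truth):
        raise ValueError("predicted and truth cell_id sets differ")
    per_cat: dict[BehaviorCategory, float | None] = {}
    correct_total = 0
    for cat in BehaviorCategory:
        members = [cid for cid, t in truth.items() if t == cat]
        if not members:
            per_cat[cat] = None
            continue
        correct = sum(1 for cid in members if pred[cid] == cat)
        correct_total += correct
        per_cat[cat] = correct / len(members)
    total = correct_total / len(truth) if truth else float("nan")
    return per_cat, total


# ---------------------------------------------------------------------------
# optional third-party time-series classifier benchmark harness


class BackendUnavailableError(RuntimeError):
    """Raised when a requested classifier backend cannot be provided."""


@dataclass
class Backend:
    """Uniform train/predict adapter around an external classifier.

    ``factory(random_state)`` must return an object with sklearn-style
    ``fit(X, y)`` / ``predict(X)``; ``featurize`` maps the raw
    ``(n, 3, T)`` trace array to that model's input matrix.  Classifier
    internals are deliberately outside this package.
    """

    name: str
    factory: Callable[[int], object]
    featurize: Callable[[np.ndarray], np.ndarray]


def _stat_features(X: np.ndarray) -> np.ndarray:
    """Per-channel summary statistics plus a coarse 20-point downsample."""
    n, c, t = X.shape
    stats = [
        X.min(axis=2), X.max(axis=2), X.mean(axis=2), X.std(axis=2),
        np.argmax(X, axis=2).astype(float), np.ptp(X, axis=2),
    ]
    idx = np.linspace(0, t - 1, 20).astype(int)
    down = X[:, :, idx].reshape(n, -1)
    return np.hstack([np.hstack([s for s in stats]), down])


def _flat_features(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    flat = X.reshape(n, -1)
    mu = flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, keepdims=True)
    return (flat - mu) / np.where(sd > 0, sd, 1.0)


def default_backends() -> dict[str, Backend]:
    """Registry of built-in backends (scikit-learn based)."""
    from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import RidgeClassifier

    return {
        "stats-forest": Backend(
            "stats-forest",
            lambda rs: RandomForestClassifier(n_estimators=200, random_state=rs),
            _stat_features,
        ),
        "flat-ridge": Backend(
            "flat-ridge",
            lambda rs: RidgeClassifier(alpha=1.0),
            _flat_features,
        ),
        "stats-gbdt": Backend(
            "stats-gbdt",
            lambda rs: HistGradientBoostingClassifier(random_state=rs),
            _stat_features,
        ),
    }


def benchmark_backends(
    traces: np.ndarray,
    labels: Sequence[str | BehaviorCategory],
    backends: Sequence[str] | None = None,
    split_seed: int = 0,
    split_fraction: float = 0.25,
    split_transients: bool = False,
    registry: Mapping[str, Backend] | None = None,
    peak_params=None,
) -> dict[str, float]:
    """Benchmark interchangeable time-series classifier backends.

    Splits the labeled ``(n, 3, T)`` trace array into train/test with a
    seeded shuffle and reports test accuracy per backend.  With
    ``split_transients`` the transient-bearing cells (any green peak) are
    classified as a separate sub-problem and the reported accuracy is the
    cell-weighted combination.
    """
    from sklearn.model_selection import train_test_split

    X = np.asarray(traces, dtype=float)
    y = np.array([str(BehaviorCategory(str(c))) for c in labels])
    if X.ndim != 3 or X.shape[1] != 3:
        raise ValueError("traces must have shape (n_cells, 3, n_frames)")
    registry = registry if registry is not None else default_backends()
    if backends is None:
        backends = list(registry)
    if not backends:
        raise BackendUnavailableError("no classifier backends registered")
    missing = [b for b in backends if b not in registry]
    if missing:
        raise BackendUnavailableError(
            f"backend(s) not available: {missing}; known: {sorted(registry)}"
        )

    def groups() -> list[tuple[np.ndarray, np.ndarray]]:
        if not split_transients:
            return [(X, y)]
        from .features import find_transients

        has_peak = np.array(
            [bool(find_transients(x[1], peak_params)) for x in X]
        )
        out = []
        for mask in (has_peak, ~has_peak):
            if mask.any():
                out.append((X[mask], y[mask]))
        return out

    results: dict[str, float] = {}
    for name in backends:
        backend = registry[name]
        correct = 0
        total = 0
        for Xg, yg in groups():
            # stratify only when feasible (>1 class, >=2 members each)
            classes, counts = np.unique(yg, return_counts=True)
            strat = yg if len(classes) > 1 and counts.min() >= 2 else None
            Xtr, Xte, ytr, yte = train_test_split(
                Xg, yg, test_size=split_fraction, random_state=split_seed,
                stratify=strat,
            )
            model = backend.factory(split_seed)
            model.fit(backend.featurize(Xtr), ytr)
            pred = model.predict(backend.featurize(Xte))
            correct += int(np.sum(pred == yte))
            total += len(yte)
        results[name] = correct / total
    return results
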