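"""End-to-end pipeline orchestration with reproducibility manifests.

Stages: simulate -> track -> extract -> features -> classify -> map.
Each stage writes CSV/TIFF artifacts plus a manifest entry recording the
input file hashes, the parameters used, the seed and the package version,
sufficient to reproduce any stage in isolation.  All outputs are
byte-deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    BehaviorCategory, ClassificationResult, classify_all, score,
)
from .config import PipelineConfig, config_to_dict
from .features import FeatureFingerprint, fingerprint
from .intensity import extract_traces, write_traces
from .spatial import category_map
from .stack import read_stack
from .synth import make_scene, write_scene
from .tracking import CellTracks, detect_static_start, track


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, cell_ids=None):
        self.stage = stage
        self.cell_ids = cell_ids or []
        suffix = f" (cells: {self.cell_ids[:10]})" if self.cell_ids else ""
        super().__init__(f"stage '{stage}' failed: {message}{suffix}")


class Manifest:
    """Accumulates per-stage provenance and serializes to JSON."""

    def __init__(self, cfg: PipelineConfig, outdir: Path):
        self.outdir = outdir
        self.record = {
            "version": __version__,
            "seed": cfg.seed,
            "config": config_to_dict(cfg),
            "stages": [],
        }

    def add(self, stage: str, inputs: list[Path], outputs: list[Path], params: dict):
        self.record["stages"].append({
            "stage": stage,
            "inputs": {str(p.name): _sha256(p) for p in inputs},
            "outputs": [str(p.name) for p in outputs],
            "params": params,
        })
        self.write()

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.record, indent=2, sort_keys=True))
        return path


def fingerprints_to_frame(fps: list[FeatureFingerprint]) -> pd.DataFrame:
    """Flatten fingerprints to one CSV row per cell (feature sets as JSON)."""
    rows = []
    for fp in fps:
        row: dict = {"cell_id": fp.cell_id,
                     "red_blue_mean_diff": fp.red_blue_mean_diff}
        for ch, st in fp.stats.items():
            for k in ("min", "max", "argmax", "mean", "variance", "range",
                      "range_after_argmax"):
                row[f"{ch}_{k}"] = getattr(st, k)
            for f, v in st.mean_after.items():
                row[f"{ch}_mean_after_{f}"] = v
        for ch, ps in fp.peaks.items():
            row[f"{ch}_peaks"] = json.dumps(
                [[p.location, round(p.height, 6), round(p.prominence, 6),
                  round(p.width, 6)] for p in ps]
            )
        for ch, cs in fp.changepoints.items():
            row[f"{ch}_changepoints"] = json.dumps(
                [[c.index, round(c.pre_slope, 6), round(c.post_slope, 6)]
                 for c in cs]
            )
        rows.append(row)
    return pd.DataFrame(rows)


def labels_to_frame(result: ClassificationResult) -> pd.DataFrame:
    return pd.DataFrame({
        "cell_id": result.cell_ids,
        "category": [c.value for c in result.categories],
        "decision_path": [" | ".join(p) for p in result.paths],
    })


def report_to_frame(per_cat, total, counts) -> pd.DataFrame:
    rows = []
    for cat in BehaviorCategory:
        acc = per_cat.get(cat)
        rows.append({
            "category": cat.value,
            "accuracy": "" if acc is None else round(acc, 4),
            "total_cells": counts.get(cat, 0),
        })
    rows.append({"category": "total", "accuracy": round(total, 4),
                 "total_cells": int(sum(counts.values()))})
    return pd.DataFrame(rows)


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path,
    stack_path: str | Path | None = None,
) -> dict:
    """Run every stage and return the artifact paths.

    Without ``stack_path`` a synthetic scene is simulated first and the
    classification is additionally scored against its ground truth.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(cfg, outdir)
    artifacts: dict[str, Path] = {}
    truth = None

    # -- simulate or load ---------------------------------------------------
    if stack_path is None:
        scenario = dataclasses.replace(cfg.scenario, seed=cfg.seed)
        scene = make_scene(scenario)
        stack_file = outdir / "stack.tif"
        truth_file = outdir / "truth.csv"
        stack = write_scene(scene, cfg.render, stack_file, truth_file)
        truth = scene.truth_labels()
        artifacts["stack"] = stack_file
        artifacts["truth"] = truth_file
        manifest.add("simulate", [], [stack_file, truth_file],
                     {"n_cells": scenario.n_cells, "seed": scenario.seed})
    else:
        stack_file = Path(stack_path)
        stack = read_stack(stack_file)
        artifacts["stack"] = stack_file

    # -- track --------------------------------------------------------------
    try:
        tracks = track(stack, cfg.tracking)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("track", str(exc)) from exc
    # spurious detections form short fragments; real cells are detected in
    # most frames of the movie
    min_det = min(cfg.min_detected_frames, max(1, stack.n_frames // 2))
    det_counts = (
        tracks.df[tracks.df["provenance"] == "detected"]
        .groupby("cell_id")["frame"].count()
    )
    keep = set(det_counts[det_counts >= min_det].index)
    tracks = CellTracks(tracks.df[tracks.df["cell_id"].isin(keep)])
    tracks_file = outdir / "tracks.csv"
    tracks.to_csv(tracks_file)
    artifacts["tracks"] = tracks_file
    manifest.add("track", [stack_file], [tracks_file],
                 dataclasses.asdict(cfg.tracking))

    # -- extract ------------------------------------------------------------
    try:
        traces = extract_traces(
            stack, tracks, background=cfg.background,
            smooth_window=cfg.smooth_window,
        )
    except ValueError as exc:
        raise PipelineError("extract", str(exc)) from exc
    traces_file = outdir / "traces.csv"
    write_traces(traces, traces_file)
    artifacts["traces"] = traces_file
    manifest.add("extract", [tracks_file], [traces_file],
                 {**dataclasses.asdict(cfg.background),
                  "smooth_window": cfg.smooth_window})

    # -- features -----------------------------------------------------------
    after = sorted({cfg.tree.red_mean_frame})
    fps, failed = [], []
    for tr in traces:
        try:
            fps.append(fingerprint(tr, cfg.peaks, cfg.steps, after))
        except ValueError:
            failed.append(tr.cell_id)
    if failed:
        raise PipelineError("features", "fingerprint extraction failed", failed)
    fp_file = outdir / "fingerprints.csv"
    fingerprints_to_frame(fps).to_csv(fp_file, index=False, float_format="%.10g")
    artifacts["fingerprints"] = fp_file
    manifest.add("features", [traces_file], [fp_file],
                 {**dataclasses.asdict(cfg.peaks), **dataclasses.asdict(cfg.steps)})

    # -- classify -----------------------------------------------------------
    result = classify_all(fps, cfg.tree)
    labels_file = outdir / "labels.csv"
    labels_to_frame(result).to_csv(labels_file, index=False)
    artifacts["labels"] = labels_file
    outputs = [labels_file]
    if truth is not None:
        tracked = set(result.cell_ids)
        # ground-truth ids equal track ids only when tracking is perfect;
        # score on the tracked subset matched by position at frame 0
        matched = _match_truth(truth, result, outdir)
        if matched is not None:
            per_cat, total = matched
            report_file = outdir / "accuracy_report.csv"
            report_to_frame(per_cat, total, result.counts).to_csv(
                report_file, index=False
            )
            artifacts["accuracy_report"] = report_file
            outputs.append(report_file)
    manifest.add("classify", [fp_file], outputs, dataclasses.asdict(cfg.tree))

    # -- map ----------------------------------------------------------------
    ref = cfg.spatial.reference_frame
    if ref is None:
        ref = min(detect_static_start(tracks), stack.n_frames - 1)
    try:
        smap = category_map(
            result, tracks, cfg.spatial.bin_size,
            stack.frame_shape, ref,
        )
    except ValueError as exc:
        raise PipelineError("map", str(exc)) from exc
    map_dir = outdir / "maps"
    map_paths = smap.write_csv(map_dir)
    artifacts["maps"] = map_dir
    manifest.add("map", [labels_file],
                 map_paths, {"bin_size": cfg.spatial.bin_size,
                             "reference_frame": int(ref)})
    artifacts["manifest"] = manifest.write()
    return artifacts


def _match_truth(truth, result: ClassificationResult, outdir: Path):
    """Score predictions against truth when cell identities line up.

    Recovered track ids are not ground-truth ids; cells are matched by
    position at frame 0 (tracks CSV) against the truth CSV within 3 px.
    Returns None when fewer than half the cells can be matched.
    """
    tracks = pd.read_csv(outdir / "tracks.csv")
    truth_df = pd.read_csv(outdir / "truth.csv")
    t0 = tracks[tracks["frame"] == 0].set_index("cell_id")
    g0 = truth_df[truth_df["frame"] == 0]
    pred = result.as_mapping()
    pairs = []
    for _, row in g0.iterrows():
        if t0.empty:
            break
        d = np.hypot(t0["x"] - row["x"], t0["y"] - row["y"])
        j = d.idxmin()
        if d.loc[j] <= 3.0 and j in pred:
            pairs.append((int(row["cell_id"]), j))
    if len(pairs) < max(1, len(g0) // 2):
        return None
    sub_truth = {}
    sub_pred_ids, sub_pred_cats, sub_pred_paths = [], [], []
    seen = set()
    for gt_id, tr_id in pairs:
        if tr_id in seen:
            continue
        seen.add(tr_id)
        cat = truth_df.loc[
            (truth_df["cell_id"] == gt_id) & (truth_df["frame"] == 0), "category"
        ].iloc[0]
        sub_truth[tr_id] = BehaviorCategory(cat)
        sub_pred_ids.append(tr_id)
        sub_pred_cats.append(pred[tr_id])
        sub_pred_paths.append(())
    sub_result = ClassificationResult(sub_pred_ids, sub_pred_cats, sub_pred_paths)
    return score(sub_result, sub_truth)
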