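"""End-to-end orchestration of the two-stage inventory methods.

Six method combinations are supported, named by their stage-1 / stage-2 data
sources: ``GSV`` and ``ALS`` (stage 1 only), ``GSV+GSV``, ``GSV+ML``,
``ALS+GSV`` and ``ALS+ML``.  Stage 1 detects every possible tree (street-level
geolocation or CHM local maxima); stage 2 debugs false positives (image
consistency or spectral classification); merging of candidates closer than
4 m runs after every stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as uio
from .chm import clip_buildings, rasterize_chm, smooth_chm
from .core import TreeCandidate
from .evaluate import EvalParams, MatchResult, Metrics, compute_metrics, match_candidates
from .itd import ItdParams, detect_treetops
from .merge import MergeParams, merge_candidates
from .scene_sim import SceneConfig, SceneDetector, SyntheticScene, generate_scene, simulate_detections
from .spectral import ClassifierSpec, feature_table, filter_candidates, select_features, train_classifier
from .street_geoloc import VerifyParams, locate_trees, verify_candidates

__all__ = ["PipelineConfig", "PipelineResult", "METHODS", "run_pipeline", "config_from_dict"]

logger = logging.getLogger(__name__)

METHODS = ("GSV", "ALS", "GSV+GSV", "GSV+ML", "ALS+GSV", "ALS+ML")


@dataclass
class PipelineConfig:
    method: str = "ALS+ML"
    scene: SceneConfig = field(default_factory=SceneConfig)
    itd: ItdParams = field(default_factory=ItdParams)
    verify: VerifyParams = field(default_factory=VerifyParams)
    merge: MergeParams = field(default_factory=MergeParams)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    eval: EvalParams = field(default_factory=EvalParams)
    smooth_window: int = 3
    eval_zone: Optional[str] = None  # None = all trees; 'street' / 'park'
    keep_fraction: float = 1.0  # feature-selection fraction for the ML filter
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:10]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


_BLOCKS = {
    "scene": SceneConfig,
    "itd": ItdParams,
    "verify": VerifyParams,
    "merge": MergeParams,
    "classifier": ClassifierSpec,
    "eval": EvalParams,
}


def config_from_dict(d: dict) -> PipelineConfig:
    """Build a PipelineConfig from a (YAML-loaded) nested dict."""
    kwargs = {}
    for key, val in d.items():
        if key in _BLOCKS:
            block = dict(val or {})
            for rng_key in ("height_range", "crown_radius_range"):
                if rng_key in block:
                    block[rng_key] = tuple(block[rng_key])
            if "street_axes" in block:
                block["street_axes"] = [
                    [tuple(v) for v in axis] for axis in block["street_axes"]
                ]
            if "building_rects" in block:
                block["building_rects"] = [tuple(r) for r in block["building_rects"]]
            kwargs[key] = _BLOCKS[key](**block)
        else:
            kwargs[key] = val
    return PipelineConfig(**kwargs)


@dataclass
class PipelineResult:
    method: str
    scene: SyntheticScene
    stage1: list[TreeCandidate]
    stage1_merged: list[TreeCandidate]
    stage2: Optional[list[TreeCandidate]]
    final: list[TreeCandidate]
    match: Optional[MatchResult]
    metrics: Optional[Metrics]
    counts: dict[str, int]
    cv_accuracy: Optional[float] = None


def _stage1(config: PipelineConfig, scene: SyntheticScene):
    source, detections = config.method.split("+")[0], None
    if source == "ALS":
        if scene.point_cloud is None:
            raise ValueError("ALS methods need a rendered point cloud")
        chm = rasterize_chm(scene.point_cloud, config.scene.cell_size, scene.extent)
        chm = smooth_chm(chm, config.smooth_window)
        chm = clip_buildings(chm, scene.buildings)
        cands = detect_treetops(chm, config.itd)
    else:
        if not scene.stations:
            raise ValueError("GSV methods need panorama stations")
        detections = simulate_detections(scene)
        cands = locate_trees(scene.stations, detections, config.scene.pixel_model)
    return cands, detections


def _stage2(config: PipelineConfig, scene: SyntheticScene, candidates, detections):
    technique = config.method.split("+")[1]
    cv_acc = None
    if technique == "GSV":
        detector = SceneDetector(
            scene,
            detections if detections is not None else simulate_detections(scene),
            match_radius=config.verify.consistency_distance,
        )
        kept = verify_candidates(candidates, scene.stations, detector, config.verify)
    else:
        if scene.ortho is None:
            raise ValueError("ML filtering needs a rendered ortho stack")
        pts = [(x, y) for x, y, _ in scene.truth_labels]
        labels = [lab for _, _, lab in scene.truth_labels]
        train = feature_table(pts, scene.ortho, labels=labels)
        feats = None
        if config.keep_fraction < 1.0:
            feats = select_features(train, keep_fraction=config.keep_fraction, seed=config.seed)
        model = train_classifier(train, config.classifier, features=feats)
        cv_acc = model.cv_accuracy
        kept = filter_candidates(candidates, model, scene.ortho)
    return kept, cv_acc


def run_pipeline(config: PipelineConfig, scene: Optional[SyntheticScene] = None) -> PipelineResult:
    """Run one method combination over a (given or freshly generated) scene.

    Stage sequencing: stage 1 -> merge -> optional stage 2 -> merge ->
    evaluation against the scene's ground truth.  All intermediates are
    written to ``out_dir`` (when set) together with a metrics CSV and a
    run report carrying the config hash.
    """
    if scene is None:
        scene = generate_scene(config.scene)
    counts: dict[str, int] = {}

    stage1, detections = _stage1(config, scene)
    counts["stage1"] = len(stage1)
    stage1_merged = merge_candidates(stage1, config.merge)
    counts["stage1_merged"] = len(stage1_merged)

    stage2 = None
    cv_acc = None
    if "+" in config.method:
        stage2, cv_acc = _stage2(config, scene, stage1_merged, detections)
        counts["stage2"] = len(stage2)
        final = merge_candidates(stage2, config.merge)
    else:
        final = stage1_merged
    counts["final"] = len(final)

    truth = scene.truth_positions(config.eval_zone)
    match = metrics = None
    if len(truth):
        match = match_candidates(final, truth, config.eval)
        metrics = compute_metrics(match)
        counts["truth"] = len(truth)

    result = PipelineResult(
        method=config.method,
        scene=scene,
        stage1=stage1,
        stage1_merged=stage1_merged,
        stage2=stage2,
        final=final,
        match=match,
        metrics=metrics,
        counts=counts,
        cv_accuracy=cv_acc,
    )
    logger.info("pipeline %s: %s", config.method, counts)
    if config.out_dir:
        _write_outputs(config, result)
    return result


def _write_outputs(config: PipelineConfig, result: PipelineResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash()
    uio.write_candidates_geojson(out / f"stage1_{tag}.geojson", result.stage1_merged)
    uio.write_candidates_geojson(out / f"inventory_{tag}.geojson", result.final)
    report = {
        "method": result.method,
        "config_hash": tag,
        "seed": config.seed,
        "counts": result.counts,
        "cv_accuracy": result.cv_accuracy,
    }
    if result.metrics is not None:
        report["metrics"] = dataclasses.asdict(result.metrics)
        mr = result.match
        rows = [
            {
                "method": result.method,
                "TP": mr.TP,
                "FP": mr.FP,
                "FN": mr.FN,
                "p": f"{result.metrics.p:.2f}",
                "r": f"{result.metrics.r:.2f}",
                "F1": f"{result.metrics.F1:.2f}",
            }
        ]
        pd.DataFrame(rows).to_csv(out / f"metrics_{tag}.csv", index=False)
        pd.DataFrame(
            [{"candidate": c, "truth": t, "distance": f"{d:.3f}"} for c, t, d in mr.tp_pairs]
        ).to_csv(out / f"matches_{tag}.csv", index=False)
    (out / f"report_{tag}.json").write_text(json.dumps(report, indent=1))
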