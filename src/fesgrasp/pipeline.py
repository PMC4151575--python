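"""End-to-end perception pipeline and the synthetic-scene evaluation loop.

Glue over the module surfaces: estimate the background once per session,
then per scene segment the target object, build its 3D primitive and
classify the grasp.  ``evaluate_test_set`` reproduces the evaluation
protocol of the system — a composition of scenes per grasp class with
randomized object sizes and orientations, scored against the generating
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .camera_geometry import CameraModel, ColorFrame, DepthFrame
from .grasp_classify import ClassifierConfig, GraspDecision, classify
from .hand_track import TableModel, build_table_model
from .object_extract import ColorSegConfig, ObjectPrimitive, extract_primitive, segment_objects, select_object, table_color_template
from .plane_detect import RansacConfig, estimate_background
from .scene_sim import (
    GroundTruth,
    SceneSpec,
    generate_test_set,
    render_background_frames,
    render_scene,
)


@dataclass
class PipelineConfig:
    ransac: RansacConfig = field(default_factory=RansacConfig)
    seg: ColorSegConfig = field(default_factory=ColorSegConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_background_frames: int = 15


def perceive_object(
    depth: DepthFrame,
    rgb: ColorFrame,
    cam: CameraModel,
    table: TableModel,
    hand_side: str = "right",
    cfg: PipelineConfig | None = None,
    hand=None,
) -> tuple[GraspDecision | None, ObjectPrimitive | None]:
    """Segment, select and classify the target object of one RGB-D frame.

    Returns (None, None) when no object is detected — the same failure mode
    the deployed system reports.
    """
    cfg = cfg or PipelineConfig()
    template = table_color_template(rgb)
    masks = segment_objects(rgb, template, cfg.seg)
    if not masks:
        return None, None
    mask = select_object(masks, cfg.seg.selection_policy, hand=hand, depth=depth, cam=cam, table=table)
    primitive = extract_primitive(mask, depth, cam, table, cfg.seg)
    decision = classify(primitive, hand_side, cfg.classifier)
    return decision, primitive


def background_session(
    spec: SceneSpec, cam: CameraModel, cfg: PipelineConfig, seed: int, with_edges: bool = False
) -> TableModel:
    """Record and process one background session for the scene's table.

    ``with_edges`` fits the table-edge line models too (needed for hand
    tracking; the object-only pipeline can skip them)."""
    frames = render_background_frames(spec, cam, n_frames=cfg.n_background_frames, seed=seed)
    r = cfg.ransac
    bg = estimate_background(
        frames,
        cam,
        RansacConfig(r.n_triplets, r.dist_threshold, r.cluster_angle, seed, r.max_score_points),
        n_frames=cfg.n_background_frames,
    )
    return build_table_model(bg, cam, with_edges=with_edges)


@dataclass
class EvaluationResult:
    n_scenes: int
    n_correct: int
    n_missed: int  # scenes where no object was segmented
    confusion: dict  # (truth, predicted) -> count

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_scenes if self.n_scenes else float("nan")


def classify_scene(
    spec: SceneSpec,
    gt: GroundTruth,
    cam: CameraModel,
    table: TableModel,
    cfg: PipelineConfig | None = None,
) -> str:
    """Render one scene and run the object pipeline; returns the predicted
    grasp label or 'none' when no object was extracted."""
    cfg = cfg or PipelineConfig()
    depth, rgb, _ = render_scene(spec, cam)
    decision, _ = perceive_object(depth, rgb, cam, table, spec.hand_side, cfg)
    return decision.grasp_type if decision is not None else "none"


def evaluate_test_set(
    composition: dict[str, int] | None = None,
    seeds: list[int] = (1,),
    cam: CameraModel | None = None,
    cfg: PipelineConfig | None = None,
    depth_sigma: float = 3.0,
) -> EvaluationResult:
    """Grasp-classification accuracy over generated test scenes.

    One background session is estimated per seed (the deployed system
    records the BCG once at start-up and objects are then swapped on the
    same table) and reused for that seed's scenes.
    """
    cam = cam or CameraModel()
    cfg = cfg or PipelineConfig()
    correct = missed = total = 0
    confusion: dict = {}
    for seed in seeds:
        scenes = generate_test_set(composition, seed=seed, depth_sigma=depth_sigma, cam=cam)
        if not scenes:
            continue
        table = background_session(scenes[0][0], cam, cfg, seed=int(seed))
        for spec, gt in scenes:
            pred = classify_scene(spec, gt, cam, table, cfg)
            truth = gt.objects[0].true_grasp
            confusion[(truth, pred)] = confusion.get((truth, pred), 0) + 1
            total += 1
            if pred == truth:
                correct += 1
            elif pred == "none":
                missed += 1
    return EvaluationResult(n_scenes=total, n_correct=correct, n_missed=missed, confusion=confusion)
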