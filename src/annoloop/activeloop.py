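"""The active-learning annotation cycle with a simulated annotator.

A session walks the annotate -> train -> suggest -> accept/correct loop
against a synthetic scene's ground truth:

1. dispersed unannotated patches are selected on the 2-D embedding and
   "manually" annotated by the oracle (cost: seconds per structure);
2. the model is fine-tuned on every confirmed annotation so far;
3. the model suggests masks for the remaining patches; the oracle accepts
   suggestions whose pixel f-score clears ``accept_threshold`` (one
   click-equivalent) or corrects erroneous pixels with probability
   ``correction_fidelity`` (cost proportional to the erroneous structures).

Accepted and corrected masks are confirmed annotations and feed the next
round's training, which is what lets review progressively replace manual
annotation. Training runs synchronously but its time is excluded from
human time: the annotator is dismissed while the model trains. The session
clock charges training at a deterministic per-patch-epoch rate so logs and
reports are bit-reproducible per seed; real training wall time is tracked
separately on the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics
from .embedding import extract_features, project_2d, select_diverse
from .errors import GateError
from .metrics import EfficiencyReport, count_structures, pixel_f_score
from .model import (ModelConfig, TrainingGate, binarize, build_model, finetune,
                    predict_batch, pretrain_autoencoder)
from .patchio import AnnotationMask, Patch
from .synthdata import SyntheticScene, scene_to_tiles


@dataclass
class CostModel:
    """Per-action human-time costs (seconds) and the deterministic
    training-time charge used by the session clock."""

    seconds_per_manual_structure: float = 7.0
    seconds_per_accept: float = 1.0
    seconds_per_corrected_structure: float = 3.0
    train_seconds_per_patch_epoch: float = 0.5

    def __post_init__(self):
        for name in ("seconds_per_manual_structure", "seconds_per_accept",
                     "seconds_per_corrected_structure", "train_seconds_per_patch_epoch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class OracleConfig:
    """Simulated annotator: accept when good enough, else correct."""

    accept_threshold: float = 0.9
    correction_fidelity: float = 1.0
    cost: CostModel = field(default_factory=CostModel)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.correction_fidelity <= 1.0:
            raise ValueError("correction_fidelity must be in [0, 1]")
        if self.accept_threshold < 0.0:
            raise ValueError("accept_threshold must be >= 0")


@dataclass
class Event:
    t_total: float
    t_human: float
    kind: str  # annotate | train_start | train_end | suggest | accept | correct
    patch_id: str
    structures_touched: int = 0


@dataclass
class SessionLog:
    """Ordered, timed record of every session action.

    Invariant: ``human_seconds + training seconds == total_seconds`` exactly,
    and every train_start has a matching train_end.
    """

    events: list[Event] = field(default_factory=list)
    human_seconds: float = 0.0
    total_seconds: float = 0.0
    warnings: list[str] = field(default_factory=list)
    rng_seed: int | None = None

    def _log(self, kind: str, patch_id: str = "", structures: int = 0):
        self.events.append(Event(t_total=self.total_seconds, t_human=self.human_seconds,
                                 kind=kind, patch_id=patch_id, structures_touched=structures))

    def human_action(self, kind: str, patch_id: str, cost_s: float, structures: int = 0):
        self.human_seconds += cost_s
        self.total_seconds += cost_s
        self._log(kind, patch_id, structures)

    def training(self, duration_s: float):
        self._log("train_start")
        self.total_seconds += duration_s
        self._log("train_end")

    @property
    def training_seconds(self) -> float:
        starts = [e.t_total for e in self.events if e.kind == "train_start"]
        ends = [e.t_total for e in self.events if e.kind == "train_end"]
        return sum(b - a for a, b in zip(starts, ends))

    def to_jsonl(self, path) -> None:
        import json
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e.__dict__) + "\n")


@dataclass
class ReviewResult:
    action: str              # "accept" or "correct"
    mask: np.ndarray         # the resulting binary mask
    cost_seconds: float
    structures_touched: int  # structures completed by this review
    f_score: float


def oracle_review(suggestion: np.ndarray, gt: np.ndarray, cfg: OracleConfig,
                  rng: np.random.Generator | None = None) -> ReviewResult:
    """Accept an accurate suggestion unchanged, or correct its errors.

    Acceptance: pixel f-score(suggestion, gt) >= ``accept_threshold``; cost
    is one accept click. Correction: each erroneous pixel is flipped to the
    ground truth independently with probability ``correction_fidelity``;
    cost is seconds-per-corrected-structure times the number of ground-truth
    structures intersecting the error set.
    """
    suggestion = np.asarray(suggestion, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    f = pixel_f_score(suggestion, gt)
    n_structures = count_structures(gt)
    if f >= cfg.accept_threshold:
        return ReviewResult("accept", suggestion.copy(), cfg.cost.seconds_per_accept,
                            n_structures, f)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    errors = suggestion != gt
    flip = errors & (rng.random(suggestion.shape) < cfg.correction_fidelity)
    corrected = np.where(flip, gt, suggestion)
    from scipy import ndimage
    gt_labels, n_gt = ndimage.label(gt, structure=np.ones((3, 3)))
    touched = len(np.unique(gt_labels[errors & (gt_labels > 0)]))
    cost = cfg.cost.seconds_per_corrected_structure * touched
    return ReviewResult("correct", corrected, cost, n_structures, f)


@dataclass
class Schedule:
    """Round structure of a simulated session.

    Each round manually annotates ``patches_per_round`` dispersed patches,
    fine-tunes, then reviews up to ``reviews_per_round`` model suggestions
    (``None`` mirrors the manual batch size). The final round reviews every
    remaining patch so the session always produces full coverage.
    """

    patches_per_round: int = 3
    rounds: int = 3
    epochs_per_round: int = 8
    pretrain_epochs: int = 2
    reviews_per_round: int | None = None


@dataclass
class SessionResult:
    scene_mask: np.ndarray                  # assembled final mask, scene extent
    patch_masks: dict[str, np.ndarray]      # per-patch final binary masks
    log: SessionLog
    report: EfficiencyReport


def simulate_session(scene: SyntheticScene, model_cfg: ModelConfig | None = None,
                     oracle_cfg: OracleConfig | None = None,
                     schedule: Schedule | None = None, seed: int = 0,
                     gate: TrainingGate | None = None,
                     projector: str = "pca",
                     finetune_lr: float = 2e-3) -> SessionResult:
    """Run a full annotate/train/suggest/review session against ground truth.

    All stochastic choices (first embedding pick, correction sampling,
    training shuffles) derive from one generator seeded by ``seed``, which
    is recorded in the log; fixed seed implies a bit-identical log, report
    and final masks.
    """
    model_cfg = model_cfg or ModelConfig()
    oracle_cfg = oracle_cfg or OracleConfig()
    schedule = schedule or Schedule()
    gate = gate or TrainingGate()
    if schedule.rounds < 1:
        raise ValueError("schedule must have at least one round")
    if schedule.patches_per_round < gate.min_annotated_patches:
        raise GateError(
            f"round 1 must annotate at least {gate.min_annotated_patches} patches "
            f"(gate minimum); schedule provides {schedule.patches_per_round}"
        )
    rng = np.random.default_rng(seed)
    log = SessionLog(rng_seed=seed)
    cost = oracle_cfg.cost

    tiles = scene_to_tiles(scene, tile_size=model_cfg.patch_size)
    patches: list[Patch] = []
    gt_masks: dict[str, np.ndarray] = {}
    origins: dict[str, tuple[int, int]] = {}
    for tile, gt_mask in tiles:
        p = Patch(pixels=tile.pixels, tile_id=tile.tile_id, row=0, col=0)
        patches.append(p)
        gt_masks[p.patch_id] = gt_mask.positive()
        origins[p.patch_id] = tile.origin

    model = build_model(model_cfg, seed=int(rng.integers(2 ** 31)))
    if schedule.pretrain_epochs > 0:
        model = pretrain_autoencoder(model, patches, epochs=schedule.pretrain_epochs,
                                     seed=int(rng.integers(2 ** 31)))
        log.training(cost.train_seconds_per_patch_epoch * len(patches) * schedule.pretrain_epochs)

    confirmed: set[str] = set()  # manually annotated or reviewed
    final_masks: dict[str, np.ndarray] = {}
    by_id = {p.patch_id: p for p in patches}

    for rnd in range(schedule.rounds):
        last_round = rnd == schedule.rounds - 1
        pool = [p for p in patches if p.patch_id not in confirmed]
        if not pool:
            log.warnings.append(f"round {rnd}: patch pool exhausted, terminating early")
            break
        k = min(schedule.patches_per_round, len(pool))
        if model.stage == "untrained":
            # no learned feature space yet: take patches in tile order
            selected = [p.patch_id for p in pool[:k]]
        elif len(pool) >= 2:
            feats = extract_features(model, pool)
            points = project_2d(feats, seed=int(rng.integers(2 ** 31)), method=projector)
            selected = select_diverse(points, k, seed=int(rng.integers(2 ** 31)))
        else:
            selected = [pool[0].patch_id]
        for pid in selected:
            gt = gt_masks[pid]
            n_struct = count_structures(gt)
            by_id[pid].mask = AnnotationMask.from_binary(gt)
            final_masks[pid] = gt.copy()
            confirmed.add(pid)
            log.human_action("annotate", pid,
                             cost.seconds_per_manual_structure * n_struct, n_struct)

        train_set = [p for p in patches if p.mask.is_annotated]
        model = finetune(model, train_set, gate=gate, epochs=schedule.epochs_per_round,
                         seed=int(rng.integers(2 ** 31)), lr=finetune_lr)
        log.training(cost.train_seconds_per_patch_epoch * len(train_set)
                     * schedule.epochs_per_round)

        review_pool = [p for p in patches if p.patch_id not in confirmed]
        if not last_round:
            cap = (schedule.reviews_per_round if schedule.reviews_per_round is not None
                   else schedule.patches_per_round)
            review_pool = review_pool[:cap]
        if review_pool:
            preds = predict_batch(model, review_pool)
            for p, pred in zip(review_pool, preds):
                suggestion = binarize(pred, 0.5)
                log._log("suggest", p.patch_id)
                result = oracle_review(suggestion, gt_masks[p.patch_id], oracle_cfg, rng=rng)
                log.human_action(result.action, p.patch_id, result.cost_seconds,
                                 result.structures_touched)
                final_masks[p.patch_id] = result.mask
                p.mask = AnnotationMask.from_binary(result.mask)  # confirmed annotation
                confirmed.add(p.patch_id)

    h, w = scene.shape
    tile_sz = model_cfg.patch_size
    canvas = np.zeros((int(np.ceil(h / tile_sz)) * tile_sz,
                       int(np.ceil(w / tile_sz)) * tile_sz), dtype=bool)
    for pid, mask in final_masks.items():
        r, c = origins[pid]
        canvas[r:r + tile_sz, c:c + tile_sz] = mask
    scene_mask = canvas[:h, :w]

    f = pixel_f_score(scene_mask, scene.gt_binary())
    n_total = count_structures(scene.gt_binary())
    manual_structures = sum(e.structures_touched for e in log.events if e.kind == "annotate")
    manual_minutes = sum(cost.seconds_per_manual_structure * e.structures_touched
                         for e in log.events if e.kind == "annotate") / 60.0
    if manual_structures >= 1 and manual_minutes > 0:
        m_t = metrics.extrapolate_manual_time(manual_minutes, manual_structures, n_total)
    else:  # no manual subset observed: fall back to the cost model's rate
        m_t = n_total * cost.seconds_per_manual_structure / 60.0
    qa_human = log.human_seconds / 60.0
    qa_total = log.total_seconds / 60.0
    theta = metrics.speedup(m_t, qa_human) if qa_human > 0 else 0
    report = EfficiencyReport(M_t=m_t, QA_t_human=qa_human, QA_t_total=qa_total,
                              theta_t=theta, f_score=f, n_structures=n_total,
                              curve=metrics.efficiency_curve(log))
    return SessionResult(scene_mask=scene_mask, patch_masks=final_masks,
                         log=log, report=report)
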