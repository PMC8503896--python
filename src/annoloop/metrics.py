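"""Quantitative definitions: pixel f-score, structure counts, manual-time
extrapolation, the θ_t speed-up multiplier, and efficiency curves.

Time accounting follows the tool-assisted annotation bookkeeping:

* ``M_t`` — extrapolated fully-manual annotation time, obtained by linearly
  scaling the measured structures-per-minute of a manually annotated subset
  to the whole task;
* ``QA_t`` — tool-assisted *human* time, which excludes model training wall
  time (the annotator is free during training);
* ``θ_t = floor(M_t / QA_t)`` — the integer speed-up multiplier. The floor
  convention is the unique simple rounding rule consistent with the three
  reference worked examples (40,165/391 → 102; 923/101 → 9; 4,433/113 → 39).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ShapeError


@dataclass
class EfficiencyReport:
    """Session-level efficiency summary derived from a SessionLog."""

    M_t: float                 # extrapolated manual minutes
    QA_t_human: float          # tool-assisted human minutes
    QA_t_total: float          # human + training minutes
    theta_t: int               # floor(M_t / QA_t_human)
    f_score: float
    n_structures: int
    curve: list = field(default_factory=list)  # (human-minute, structures/min)

    def __post_init__(self):
        if self.QA_t_human > self.QA_t_total + 1e-9:
            raise ValueError("QA_t_human cannot exceed QA_t_total")
        if not 0.0 <= self.f_score <= 1.0:
            raise ValueError("f_score must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def pixel_f_score(mask: np.ndarray, reference: np.ndarray) -> float:
    """Pixel-level F1 = 2TP / (2TP + FP + FN) against a reference mask.

    Both masks empty is perfect agreement on absence and scores 1.0.
    """
    mask = np.asarray(mask, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if mask.shape != reference.shape:
        raise ShapeError(f"mask shapes differ: {mask.shape} vs {reference.shape}")
    tp = int(np.sum(mask & reference))
    fp = int(np.sum(mask & ~reference))
    fn = int(np.sum(~mask & reference))
    if tp + fp + fn == 0:
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def count_structures(mask: np.ndarray, connectivity: int = 8, min_size: int = 10) -> int:
    """Number of connected foreground components with at least ``min_size`` pixels.

    Defaults (8-connectivity, 10 px minimum) are the package's counting
    convention for "histologic structures" in a binary mask.
    """
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = np.ones((3, 3)) if connectivity == 8 else np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=structure)
    if n == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int(np.sum(sizes >= min_size))


def extrapolate_manual_time(subset_minutes: float, subset_structures: int,
                            total_structures: int) -> float:
    """M_t: scale the measured subset annotation rate to the whole task."""
    if subset_structures < 1:
        raise ValueError("subset_structures must be >= 1")
    if subset_minutes <= 0:
        raise ValueError("subset_minutes must be > 0")
    return total_structures * (subset_minutes / subset_structures)


def speedup(M_t: float, QA_t: float) -> int:
    """Integer speed-up multiplier θ_t = floor(M_t / QA_t)."""
    if QA_t <= 0:
        raise ValueError("QA_t must be > 0")
    return int(math.floor(M_t / QA_t))


def efficiency_curve(log, bin_minutes: float = 1.0) -> list[tuple[float, float]]:
    """Structures completed per human-minute, binned over cumulative human time.

    Events of kind annotate/accept/correct complete structures; each bin's
    rate is its completed-structure count divided by the bin width, indexed
    by the bin's end minute. Conservation holds by construction:
    sum(rate * bin_minutes) equals the total structures completed.
    """
    if bin_minutes <= 0:
        raise ValueError("bin_minutes must be > 0")
    events = [e for e in log.events if e.kind in ("annotate", "accept", "correct")]
    if not events:
        return []
    n_bins = int(math.floor(max(e.t_human for e in events) / (bin_minutes * 60.0))) + 1
    counts = np.zeros(n_bins)
    for e in events:
        counts[int(e.t_human // (bin_minutes * 60.0))] += e.structures_touched
    return [((i + 1) * bin_minutes, counts[i] / bin_minutes) for i in range(n_bins)]


def project_stats(masks: dict[str, np.ndarray], gt: dict[str, np.ndarray] | None = None,
                  connectivity: int = 8, min_size: int = 10) -> pd.DataFrame:
    """Per-image and project-level summary of produced masks.

    One row per image (structure count, positive-pixel area, f-score when a
    ground-truth mask is available) plus a final project-total row whose
    counts and areas are the per-image sums.
    """
    if not masks:
        raise ValueError("project_stats requires at least one image")
    rows = []
    for name in sorted(masks):
        m = np.asarray(masks[name], dtype=bool)
        row = {
            "image": name,
            "n_structures": count_structures(m, connectivity, min_size),
            "positive_area_px": int(m.sum()),
        }
        if gt is not None and name in gt:
            row["f_score"] = pixel_f_score(m, gt[name])
        rows.append(row)
    df = pd.DataFrame(rows)
    total = {
        "image": "PROJECT_TOTAL",
        "n_structures": int(df["n_structures"].sum()),
        "positive_area_px": int(df["positive_area_px"].sum()),
    }
    if "f_score" in df.columns and df["f_score"].notna().any():
        total["f_score"] = float(df["f_score"].mean())
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
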