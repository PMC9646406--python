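"""Voxel- and lesion-level evaluation of new-lesion segmentations.

For cases whose ground truth contains new lesions, segmentation quality
is measured with the Dice overlap and the symmetric Hausdorff distance
between mask surfaces (mm); detection quality with lesion-wise
sensitivity (SEN), positive predictive value (PPV) and their harmonic
mean F1, computed on connected components extracted with an
18-connectivity kernel (faces + edges, not corners) after discarding
components smaller than 3 mm^3. For cases without any true new lesions,
the report instead carries the number (NLP) and total volume (VLP, mm^3)
of predicted lesions.

Lesion matching: a true lesion counts as detected (TP) when the union of
predicted lesions covers at least ``overlap_fraction`` (default 10%) of
its volume; a predicted lesion is a false positive when it intersects no
true lesion. This pinned, configurable rule is logged in every report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, generate_binary_structure, label
from scipy.spatial import cKDTree

__all__ = ["LesionSet", "DetectionCounts", "CaseMetrics", "dice_score",
           "hausdorff_distance", "extract_lesions", "match_lesions",
           "detection_metrics", "nlp_vlp", "evaluate_case", "evaluate_cohort"]

_STRUCT_18 = generate_binary_structure(3, 2)   # faces + edges
_STRUCT_6 = generate_binary_structure(3, 1)    # faces only


def _as_mask(m) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim == 4:
        if m.shape[0] != 1:
            raise ValueError("expected a single-channel mask")
        m = m[0]
    if m.ndim != 3:
        raise ValueError(f"expected a 3D mask, got shape {m.shape}")
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("mask must be binary {0, 1}")
    return m.astype(bool)


@dataclass
class LesionSet:
    """Connected components of a binary mask, labelled 1..n."""

    labels: np.ndarray                 # int map, 0 = background
    voxel_counts: list[int]
    volumes_mm3: list[float]
    connectivity: int = 18

    @property
    def n_lesions(self) -> int:
        return len(self.voxel_counts)


@dataclass
class DetectionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("detection counts must be non-negative")


@dataclass
class CaseMetrics:
    case_id: str
    has_new_lesions: bool
    dice: float | None = None
    hd: float | None = None
    sen: float | None = None
    ppv: float | None = None
    f1: float | None = None
    nlp: int | None = None
    vlp: float | None = None


def dice_score(g, y) -> float:
    """Voxel-wise Dice overlap; 1.0 when both masks are empty (convention)."""
    g, y = _as_mask(g), _as_mask(y)
    if g.shape != y.shape:
        raise ValueError(f"shape mismatch {g.shape} vs {y.shape}")
    denom = g.sum() + y.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(g, y).sum() / denom)


def _surface_points(mask: np.ndarray) -> np.ndarray:
    """Voxels with at least one face neighbor outside the mask."""
    interior = binary_erosion(mask, structure=_STRUCT_6, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff_distance(g, y, voxel_size=(1.0, 1.0, 1.0)) -> float:
    """Symmetric Hausdorff distance between mask surfaces, in mm."""
    g, y = _as_mask(g), _as_mask(y)
    if g.shape != y.shape:
        raise ValueError(f"shape mismatch {g.shape} vs {y.shape}")
    if not g.any() or not y.any():
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    sp = np.asarray(voxel_size, dtype=float)
    pg = _surface_points(g) * sp
    py = _surface_points(y) * sp
    d_gy = cKDTree(py).query(pg)[0].max()
    d_yg = cKDTree(pg).query(py)[0].max()
    return float(max(d_gy, d_yg))


def extract_lesions(mask, voxel_size=(1.0, 1.0, 1.0), connectivity: int = 18,
                    min_volume_mm3: float = 3.0) -> LesionSet:
    """Connected components under 18- (or 6/26-) connectivity, size-filtered."""
    mask = _as_mask(mask)
    struct = {6: _STRUCT_6, 18: _STRUCT_18,
              26: generate_binary_structure(3, 3)}[connectivity]
    labelled, n = label(mask, structure=struct)
    voxel_volume = float(np.prod(voxel_size))
    out = np.zeros_like(labelled)
    counts, volumes = [], []
    next_id = 0
    for comp in range(1, n + 1):
        sel = labelled == comp
        n_vox = int(sel.sum())
        vol = n_vox * voxel_volume
        if vol < min_volume_mm3:
            continue
        next_id += 1
        out[sel] = next_id
        counts.append(n_vox)
        volumes.append(vol)
    return LesionSet(out, counts, volumes, connectivity)


def match_lesions(g_set: LesionSet, y_set: LesionSet,
                  overlap_fraction: float = 0.1) -> DetectionCounts:
    """Count TP/FP/FN lesions under the volume-overlap detection rule."""
    if g_set.labels.shape != y_set.labels.shape:
        raise ValueError("lesion sets live on different grids")
    pred_any = y_set.labels > 0
    tp = 0
    for comp in range(1, g_set.n_lesions + 1):
        sel = g_set.labels == comp
        covered = np.logical_and(sel, pred_any).sum() / sel.sum()
        if covered >= overlap_fraction:
            tp += 1
    fn = g_set.n_lesions - tp
    truth_any = g_set.labels > 0
    fp = 0
    for comp in range(1, y_set.n_lesions + 1):
        if not np.logical_and(y_set.labels == comp, truth_any).any():
            fp += 1
    return DetectionCounts(tp=tp, fp=fp, fn=fn)


def detection_metrics(counts: DetectionCounts) -> tuple[float, float, float]:
    """(SEN, PPV, F1); all 1.0 when there is nothing to detect or predict."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp == fp == fn == 0:
        return 1.0, 1.0, 1.0
    sen = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return float(sen), float(ppv), float(f1)


def nlp_vlp(pred_mask, voxel_size=(1.0, 1.0, 1.0),
            min_volume_mm3: float = 0.0) -> tuple[int, float]:
    """Number and total volume (mm^3) of predicted lesions.

    By default no minimum-size filter is applied to the component count.
    """
    mask = _as_mask(pred_mask)
    lesions = extract_lesions(mask, voxel_size, connectivity=18,
                              min_volume_mm3=min_volume_mm3)
    vlp = float(mask.sum() * np.prod(voxel_size))
    return lesions.n_lesions, vlp


def evaluate_case(case_id: str, truth_mask, pred_mask,
                  voxel_size=(1.0, 1.0, 1.0), connectivity: int = 18,
                  min_volume_mm3: float = 3.0,
                  overlap_fraction: float = 0.1) -> CaseMetrics:
    """Per-case metric bundle, stratified by with/without new lesions."""
    g = _as_mask(truth_mask)
    y = _as_mask(pred_mask)
    if not g.any():
        nlp, vlp = nlp_vlp(y, voxel_size)
        return CaseMetrics(case_id, has_new_lesions=False, nlp=nlp, vlp=vlp)
    g_set = extract_lesions(g, voxel_size, connectivity, min_volume_mm3)
    y_set = extract_lesions(y, voxel_size, connectivity, min_volume_mm3)
    sen, ppv, f1 = detection_metrics(
        match_lesions(g_set, y_set, overlap_fraction))
    hd = hausdorff_distance(g, y, voxel_size) if y.any() else None
    return CaseMetrics(case_id, has_new_lesions=True, dice=dice_score(g, y),
                       hd=hd, sen=sen, ppv=ppv, f1=f1)


def evaluate_cohort(case_ids, truth_masks, pred_masks,
                    voxel_sizes=None, connectivity: int = 18,
                    min_volume_mm3: float = 3.0,
                    overlap_fraction: float = 0.1
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate a cohort; returns (per-case table, stratified mean/SD summary).

    Cases with new lesions contribute Dice/HD/SEN/PPV/F1; cases without
    contribute NLP/VLP. Undefined HD values (empty predictions) are
    excluded from aggregation.
    """
    if voxel_sizes is None:
        voxel_sizes = [(1.0, 1.0, 1.0)] * len(case_ids)
    rows = []
    for cid, g, y, vs in zip(case_ids, truth_masks, pred_masks, voxel_sizes):
        m = evaluate_case(cid, g, y, vs, connectivity, min_volume_mm3,
                          overlap_fraction)
        rows.append(vars(m))
    per_case = pd.DataFrame(rows)
    per_case.attrs["detection_rule"] = (
        f"volume-overlap >= {overlap_fraction:.0%}, {connectivity}-connectivity, "
        f"min lesion volume {min_volume_mm3} mm^3")
    summaries = []
    with_l = per_case[per_case.has_new_lesions]
    without = per_case[~per_case.has_new_lesions]
    for name, group, cols in (("with_new_lesions", with_l,
                               ["dice", "hd", "sen", "ppv", "f1"]),
                              ("without_new_lesions", without, ["nlp", "vlp"])):
        row = {"stratum": name, "n_cases": len(group)}
        for col in cols:
            vals = group[col].dropna() if len(group) else pd.Series(dtype=float)
            row[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else (
                0.0 if len(vals) == 1 else np.nan)
        summaries.append(row)
    return per_case, pd.DataFrame(summaries)
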