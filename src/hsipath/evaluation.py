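"""Patch-level classification metrics and whole-slide margin assessment.

Patch predictions are scored with accuracy, support-weighted F1,
sensitivity (recall of the cancer class) and AU-ROC.  For margin
assessment, per-patch predictions are assembled onto the slide's patch
grid, cleaned with a morphological opening, and compared with the
ground-truth margin mask by the Jaccard index (intersection over union)
and the symmetric Hausdorff distance between foreground cell centres,
reported in millimetres.  The default grid pitch of 0.139 mm corresponds
to 250-pixel tiles at 0.556 um/pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff
from skimage.morphology import opening as _sk_opening
from sklearn.metrics import accuracy_score, f1_score, recall_score, roc_auc_score

#: 250 px tile x 0.556 um/px = 139 um grid pitch
DEFAULT_CELL_PITCH_MM = 0.139


@dataclass
class SlideMask:
    """Binary mask on the slide's patch grid, with physical cell pitch."""

    grid: np.ndarray
    cell_pitch_mm: float = DEFAULT_CELL_PITCH_MM

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if not np.isin(self.grid, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.grid = self.grid.astype(np.uint8)
        if self.cell_pitch_mm <= 0:
            raise ValueError("cell_pitch_mm must be positive")


@dataclass
class MarginResult:
    jaccard: float
    hausdorff_mm: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.jaccard <= 1.0:
            raise ValueError("jaccard out of [0, 1]")
        if self.hausdorff_mm < 0:
            raise ValueError("hausdorff_mm must be >= 0")


def classification_metrics(
    labels: np.ndarray, predicted: np.ndarray, scores: np.ndarray | None = None
) -> dict[str, float]:
    """Accuracy, weighted F1, cancer-class sensitivity, AU-ROC.

    ``labels``/``predicted`` are binary with 1 = cancer; ``scores`` are
    cancer-class probabilities or any monotone ranking score.  AU-ROC uses
    the rank (Mann-Whitney) statistic with tie averaging; if the labels
    contain a single class it is undefined and returned as NaN.
    """
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    if labels.shape != predicted.shape:
        raise ValueError("labels and predictions disagree in length")
    out = {
        "accuracy": float(accuracy_score(labels, predicted)),
        "f1_weighted": float(f1_score(labels, predicted, average="weighted")),
        "sensitivity": float(recall_score(labels, predicted, pos_label=1)),
    }
    if scores is not None:
        if np.unique(labels).size < 2:
            out["auroc"] = float("nan")
        else:
            out["auroc"] = float(roc_auc_score(labels, np.asarray(scores)))
    return out


def assemble_slide_mask(
    predictions: list[tuple[int, int, int]],
    grid_shape: tuple[int, int] | None = None,
    cell_pitch_mm: float = DEFAULT_CELL_PITCH_MM,
) -> SlideMask:
    """Place per-patch cancer predictions ``(grid_row, grid_col, is_cancer)``
    on the patch grid; unseen cells default to 0 (normal)."""
    if grid_shape is None:
        if not predictions:
            raise ValueError("need grid_shape when predictions are empty")
        grid_shape = (
            max(r for r, _, _ in predictions) + 1,
            max(c for _, c, _ in predictions) + 1,
        )
    grid = np.zeros(grid_shape, dtype=np.uint8)
    seen: set[tuple[int, int]] = set()
    for r, c, v in predictions:
        if not (0 <= r < grid_shape[0] and 0 <= c < grid_shape[1]):
            raise ValueError(f"grid index ({r}, {c}) outside {grid_shape}")
        if (r, c) in seen:
            raise ValueError(f"duplicate prediction for cell ({r}, {c})")
        seen.add((r, c))
        grid[r, c] = 1 if v else 0
    return SlideMask(grid, cell_pitch_mm)


def clean_mask(mask: SlideMask, radius: int = 1) -> SlideMask:
    """Morphological opening (erosion then dilation) on the patch grid.

    The structuring element is a Chebyshev-metric disk (a (2r+1) square), so
    solid rectangular regions of at least the element size pass unchanged
    while isolated false-positive specks are removed; radius 0 is the
    identity.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return SlideMask(mask.grid.copy(), mask.cell_pitch_mm)
    footprint = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    opened = _sk_opening(mask.grid.astype(bool), footprint)
    return SlideMask(opened.astype(np.uint8), mask.cell_pitch_mm)


def jaccard(A: SlideMask, B: SlideMask) -> float:
    """|A n B| / |A u B|; two empty masks are identical, hence 1.0."""
    if A.grid.shape != B.grid.shape:
        raise ValueError("mask shapes disagree")
    a, b = A.grid.astype(bool), B.grid.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def hausdorff_mm(A: SlideMask, B: SlideMask) -> float:
    """Symmetric Hausdorff distance between foreground cell centres, in mm.

    ``d_H(X, Y) = max(sup_x d(x, Y), sup_y d(X, y))`` with Euclidean point
    distances on grid coordinates, scaled by the cell pitch.
    """
    if A.grid.shape != B.grid.shape:
        raise ValueError("mask shapes disagree")
    if A.cell_pitch_mm != B.cell_pitch_mm:
        raise ValueError("mask pitches disagree")
    pa = np.argwhere(A.grid)
    pb = np.argwhere(B.grid)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("Hausdorff distance undefined for an empty mask")
    d = max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
    return float(d * A.cell_pitch_mm)


def margin_assessment(
    pred: SlideMask, truth: SlideMask, open_radius: int = 1
) -> MarginResult:
    """Clean the predicted mask, then score it against the ground truth."""
    cleaned = clean_mask(pred, open_radius)
    j = jaccard(cleaned, truth)
    h = hausdorff_mm(cleaned, truth)
    return MarginResult(jaccard=j, hausdorff_mm=h)
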