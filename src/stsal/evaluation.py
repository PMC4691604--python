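"""ROC-AUC scoring of saliency maps against eye fixations.

The score is the area under the ROC curve of the classifier that thresholds
saliency values sampled at fixated (positive) versus non-fixated (negative)
locations — equivalently the Mann–Whitney statistic

    AUC = (#{pos > neg} + ½·#{pos = neg}) / (n_pos · n_neg),

so ties count one half and a constant map scores exactly 0.5.

Human fixations are center-biased, which inflates the naive AUC of any
center-weighted map.  The shuffled variant corrects for this by drawing the
negatives from fixations recorded on *other* images, so the negative set
carries the same center bias as the positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .fusion import SaliencyMap
from .image_pipeline import FixationSet

__all__ = ["AUCResult", "sample_saliency", "auc_basic", "shuffled_auc",
           "mean_auc"]


@dataclass(frozen=True)
class AUCResult:
    image_id: str
    auc: float
    n_positives: int
    n_negatives: int
    n_shuffles: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC out of range: {self.auc}")
        if self.n_positives < 1:
            raise ValueError("need at least one positive fixation")


def sample_saliency(sal: SaliencyMap, fix: FixationSet,
                    native_size: tuple[int, int] | None = None) -> np.ndarray:
    """Saliency values at fixation points, nearest-pixel lookup.

    ``native_size = (width, height)`` of the image the fixations were
    recorded on; coordinates are scaled to the map's resolution before
    lookup.  Points outside the native bounds raise a ValueError naming the
    offending point.
    """
    if len(fix) == 0:
        raise ValueError("empty fixation set")
    h, w = sal.shape
    nat_w, nat_h = native_size if native_size is not None else (w, h)
    pts = fix.as_array()
    for x, y in pts:
        if not (0 <= x < nat_w and 0 <= y < nat_h):
            raise ValueError(
                f"fixation ({x}, {y}) outside image bounds {nat_w}×{nat_h}"
                f" (image {fix.image_id!r})")
    cols = np.clip(np.rint(pts[:, 0] * (w / nat_w)), 0, w - 1).astype(int)
    rows = np.clip(np.rint(pts[:, 1] * (h / nat_h)), 0, h - 1).astype(int)
    return sal.values[rows, cols]


def _auc_from_samples(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann–Whitney AUC via midranks; ties count 1/2."""
    pos = np.asarray(pos, dtype=np.float64)
    neg = np.asarray(neg, dtype=np.float64)
    ranks = rankdata(np.concatenate([pos, neg]), method="average")
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_basic(sal: SaliencyMap, fix: FixationSet, neg: FixationSet,
              native_size: tuple[int, int] | None = None) -> float:
    """AUC with an explicit negative fixation set."""
    pos_vals = sample_saliency(sal, fix, native_size)
    neg_vals = sample_saliency(sal, neg, native_size)
    return _auc_from_samples(pos_vals, neg_vals)


def shuffled_auc(sal: SaliencyMap, fix: FixationSet,
                 other_fix: Sequence[FixationSet], n_shuffles: int = 100,
                 seed: int = 0,
                 native_size: tuple[int, int] | None = None) -> AUCResult:
    """Center-bias-corrected AUC with negatives shuffled from other images.

    Each shuffle samples ``len(fix)`` negative locations from the pooled
    fixations of the other images and scores one AUC; the result is the mean
    over ``n_shuffles`` draws.  Deterministic for a fixed seed.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be ≥ 1")
    others = [f for f in other_fix if len(f) > 0]
    if not others:
        raise ValueError("need a non-empty pool of other images' fixations")
    pool = np.concatenate([f.as_array() for f in others], axis=0)
    pos_vals = sample_saliency(sal, fix, native_size)
    rng = np.random.default_rng(seed)
    n_neg = len(fix)
    aucs = np.empty(n_shuffles)
    for k in range(n_shuffles):
        idx = rng.choice(pool.shape[0], size=n_neg,
                         replace=pool.shape[0] < n_neg)
        neg = FixationSet(tuple(map(tuple, pool[idx])), image_id="<shuffle>")
        aucs[k] = _auc_from_samples(pos_vals, sample_saliency(sal, neg, native_size))
    return AUCResult(image_id=fix.image_id, auc=float(aucs.mean()),
                     n_positives=len(fix), n_negatives=n_neg,
                     n_shuffles=n_shuffles, seed=seed)


def mean_auc(results: Sequence[AUCResult]) -> float:
    """Dataset score: unweighted mean of per-image AUCs."""
    if not results:
        raise ValueError("no AUC results to average")
    return float(np.mean([r.auc for r in results]))
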