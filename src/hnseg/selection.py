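"""Uncertainty-guided candidate selection for localized fine-tuning.

The idea: a segmentation network is most unsure exactly where its
probability map hovers near 0.5, which happens along poorly delineated
contour boundaries.  The per-pixel uncertainty

    u(i,j) = p(i,j)        if 0 <= p <= 0.5
           = 1 - p(i,j)    if 0.5 < p < 1
           = 0             if p = 1        (i.e. u = min(p, 1 - p))

is edge-filtered with the discrete 4-neighbour Laplacian

    L f = f(x+1,y) + f(x-1,y) + f(x,y+1) + f(x,y-1) - 4 f(x,y),

and the magnitude |L u| is averaged over all m pixels of the image to
give a per-image score Un.  Confident, accurate segmentations have Un
near zero; blurry or erratic contours raise it.  Ranking an external
candidate pool by Un and repeatedly folding the top fraction (default
30%, two iterations, so about half the pool) into the training set
targets fine-tuning at the samples the current model handles worst.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .model import HNNet, ProbabilityMap
from .training import TrainConfig, fine_tune

logger = logging.getLogger(__name__)

__all__ = [
    "UncertaintyMap",
    "EdgeMap",
    "SampleScore",
    "SelectionRound",
    "pixel_uncertainty",
    "laplacian",
    "edge_uncertainty",
    "image_score",
    "case_score",
    "score_case",
    "select_top_fraction",
    "run_selection_workflow",
]


@dataclass
class UncertaintyMap:
    values: np.ndarray          # in [0, 0.5]
    case_id: str = ""
    slice_index: int = 0


@dataclass
class EdgeMap:
    values: np.ndarray          # >= 0 (Laplacian magnitude)
    case_id: str = ""
    slice_index: int = 0


@dataclass
class SampleScore:
    case_id: str
    un: float                   # case-level average uncertainty score
    per_slice: list[tuple[int, float]]
    m: int                      # pixels per slice used in the average


@dataclass
class SelectionRound:
    iteration: int
    pool_ids: list[str]
    ranked_scores: list[SampleScore]
    selected_ids: list[str]
    fraction: float


def pixel_uncertainty(p: ProbabilityMap | np.ndarray) -> UncertaintyMap:
    """u = min(p, 1-p): zero at confident pixels, 0.5 at p = 0.5."""
    if isinstance(p, ProbabilityMap):
        values, cid, si = p.values, p.case_id, p.slice_index
    else:
        values, cid, si = np.asarray(p, dtype=np.float64), "", 0
    if values.min() < 0 or values.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return UncertaintyMap(values=np.minimum(values, 1.0 - values),
                          case_id=cid, slice_index=si)


def laplacian(image: np.ndarray) -> np.ndarray:
    """Discrete 4-neighbour Laplacian with replicate borders.

    Interior pixels follow the 5-point stencil exactly; edge pixels use
    replicated neighbours, so constant images map to zero everywhere.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    padded = np.pad(image, 1, mode="edge")
    return (padded[2:, 1:-1] + padded[:-2, 1:-1] +
            padded[1:-1, 2:] + padded[1:-1, :-2] - 4.0 * image)


def edge_uncertainty(u: UncertaintyMap | np.ndarray) -> EdgeMap:
    """G = |Laplacian(u)|: localizes the edges of the uncertainty map.

    The magnitude is used because a signed Laplacian averages toward
    zero across a symmetric edge profile, which would erase the
    ranking signal.
    """
    if isinstance(u, UncertaintyMap):
        values, cid, si = u.values, u.case_id, u.slice_index
    else:
        values, cid, si = np.asarray(u, dtype=np.float64), "", 0
    return EdgeMap(values=np.abs(laplacian(values)), case_id=cid,
                   slice_index=si)


def image_score(g: EdgeMap | np.ndarray) -> float:
    """Un: mean of the edge-uncertainty map over all pixels of the image."""
    values = g.values if isinstance(g, EdgeMap) else np.asarray(g)
    if values.size == 0:
        raise ValueError("empty edge map")
    return float(values.mean())


def case_score(slice_scores, aggregate: str = "mean") -> float:
    """Aggregate per-slice Un values to one per-case score (mean or max)."""
    scores = list(slice_scores)
    if not scores:
        raise ValueError("no slice scores to aggregate")
    if aggregate == "mean":
        return float(np.mean(scores))
    if aggregate == "max":
        return float(np.max(scores))
    raise ValueError(f"unknown aggregate '{aggregate}'")


def score_case(prob_slices: np.ndarray, case_id: str = "",
               aggregate: str = "mean") -> SampleScore:
    """Full per-case scoring chain: p -> u -> G -> per-slice Un -> case Un."""
    prob_slices = np.asarray(prob_slices, dtype=np.float64)
    if prob_slices.ndim == 2:
        prob_slices = prob_slices[None]
    per_slice = []
    for i, p in enumerate(prob_slices):
        g = edge_uncertainty(pixel_uncertainty(p))
        per_slice.append((i, image_score(g)))
    un = case_score([s for _, s in per_slice], aggregate=aggregate)
    return SampleScore(case_id=case_id, un=un, per_slice=per_slice,
                       m=int(prob_slices[0].size))


def select_top_fraction(scores: list[SampleScore],
                        fraction: float = 0.30,
                        iteration: int = 1) -> SelectionRound:
    """Pick the floor(fraction * n) highest-Un samples (at least one).

    Ties are broken by case_id ascending so selection is deterministic.
    """
    if not scores:
        raise ValueError("empty candidate pool")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    n_select = max(1, math.floor(fraction * len(scores)))
    ranked = sorted(scores, key=lambda s: (-s.un, s.case_id))
    selected = [s.case_id for s in ranked[:n_select]]
    return SelectionRound(iteration=iteration,
                          pool_ids=[s.case_id for s in scores],
                          ranked_scores=ranked,
                          selected_ids=selected,
                          fraction=fraction)


def run_selection_workflow(model: HNNet, local_train, public_pool: dict,
                           train_config: TrainConfig,
                           iterations: int = 2, fraction: float = 0.30,
                           aggregate: str = "mean"):
    """Iterative fine-tuning loop over a labeled external candidate pool.

    Each iteration: score every remaining pool case with the current
    model, move the top `fraction` into the training set, and fine-tune
    from the current weights.  With the default fraction 0.30 and two
    iterations on a pool of 30, rounds select 9 then 6 cases — half the
    pool in total.

    Parameters
    ----------
    model : trained HNNet (on `local_train`)
    local_train : list of (slice, mask) pairs
    public_pool : dict case_id -> (slices (S, H, W), masks (S, H, W));
        must be disjoint from the local training set
    train_config : fine-tuning hyperparameters (epochs per round)

    Returns (model, list of SelectionRound).
    """
    remaining = dict(public_pool)
    training_set = list(local_train)
    rounds: list[SelectionRound] = []
    for it in range(1, iterations + 1):
        if not remaining:
            logger.warning("candidate pool exhausted before iteration %d", it)
            break
        model.eval()
        scores = []
        for cid in sorted(remaining):
            slices, _ = remaining[cid]
            probs = model.forward_array(np.asarray(slices, dtype=np.float64))
            scores.append(score_case(probs, case_id=cid, aggregate=aggregate))
        rnd = select_top_fraction(scores, fraction=fraction, iteration=it)
        rounds.append(rnd)
        added = []
        for cid in rnd.selected_ids:
            slices, masks = remaining.pop(cid)
            added.extend(zip(slices, masks))
        model, _ = fine_tune(model, training_set, added, train_config)
        training_set.extend(added)
    return model, rounds
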