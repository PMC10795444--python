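"""Self-contained scaled-down studies on synthetic phantoms.

These drivers reproduce the shape of the full clinical workflow at
desk scale: a small local labeled pool trains a compact HN-Net, an
external domain-shifted pool is ranked by uncertainty and folded into
training over two fine-tuning rounds, and segmentation quality is
evaluated on held-out cases.  Problem sizes (64x64 slices, 5 local
cases x 4 slices, a 30-case candidate pool, 10 test cases) are chosen
so a study completes in about a minute on one CPU core while keeping
the pool size at which one selection round takes 30% (9 cases) and two
rounds take half the pool (15 cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .estimator import HNNetSegmenter
from .metrics import overlap_metrics
from .phantom import (
    CorruptionSpec,
    PhantomSpec,
    corrupt_mask_to_probability,
    generate_phantom_pool,
    pool_to_cases,
    pool_to_dataset,
)
from .selection import SelectionRound, run_selection_workflow, score_case
from .training import TrainConfig

__all__ = [
    "StudyConfig",
    "mean_case_dice",
    "train_baseline",
    "same_domain_study",
    "domain_shift_study",
    "uncertainty_ranking_study",
]


@dataclass
class StudyConfig:
    """Conditions of the scaled-down phantom studies."""

    phantom: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(n_slices=4))
    n_local_cases: int = 5        # x 4 slices = 20 training slices
    n_pool_cases: int = 30        # candidate pool (30% -> 9, then 6)
    n_test_cases: int = 10
    base_channels: int = 8
    depth: int = 2
    train_epochs: int = 20
    finetune_epochs: int = 8
    batch_size: int = 8
    fraction: float = 0.30
    iterations: int = 2


def mean_case_dice(model, cases: dict, threshold: float = 0.5) -> float:
    """Mean volumetric Dice over a dict of preprocessed cases."""
    dices = []
    for _, (slices, masks) in sorted(cases.items()):
        pred = model.forward_array(np.asarray(slices, float)) >= threshold
        dices.append(overlap_metrics(pred, masks)[0])
    return float(np.mean(dices))


def train_baseline(seed: int, config: StudyConfig | None = None):
    """Train the compact network on the local phantom pool."""
    config = config or StudyConfig()
    local = generate_phantom_pool(config.phantom, config.n_local_cases,
                                  seed=seed * 7 + 1, id_prefix="loc")
    ds = pool_to_dataset(local)
    X = np.stack([s for s, _ in ds])
    y = np.stack([m for _, m in ds])
    est = HNNetSegmenter(input_size=config.phantom.image_size,
                         depth=config.depth,
                         base_channels=config.base_channels,
                         epochs=config.train_epochs,
                         batch_size=config.batch_size,
                         random_state=seed)
    est.fit(X, y)
    return est, ds


def same_domain_study(seed: int, config: StudyConfig | None = None) -> dict:
    """Baseline training quality on held-out same-domain phantoms."""
    config = config or StudyConfig()
    est, _ = train_baseline(seed, config)
    test = pool_to_cases(generate_phantom_pool(
        config.phantom, config.n_test_cases, seed=seed * 7 + 2,
        id_prefix="tst"))
    return {"mean_dice": mean_case_dice(est.model_, test),
            "final_loss": est.history_.losses[-1],
            "n_train_slices": config.n_local_cases *
            config.phantom.n_slices}


def domain_shift_study(seed: int, config: StudyConfig | None = None) -> dict:
    """Two-round uncertainty-guided fine-tuning against a shifted pool.

    Returns held-out shifted-domain Dice before and after fine-tuning
    plus the per-round selection counts.
    """
    config = config or StudyConfig()
    est, local_ds = train_baseline(seed, config)
    pool = pool_to_cases(generate_phantom_pool(
        config.phantom, config.n_pool_cases, seed=seed * 7 + 3,
        shifted=True, id_prefix="pub"))
    test = pool_to_cases(generate_phantom_pool(
        config.phantom, config.n_test_cases, seed=seed * 7 + 4,
        shifted=True, id_prefix="tst"))
    before = mean_case_dice(est.model_, test)
    tc = TrainConfig(epochs=config.finetune_epochs,
                     batch_size=config.batch_size, seed=seed)
    model, rounds = run_selection_workflow(
        est.model_, local_ds, pool, tc, iterations=config.iterations,
        fraction=config.fraction)
    after = mean_case_dice(model, test)
    return {"dice_before": before, "dice_after": after,
            "selected_per_round": [len(r.selected_ids) for r in rounds],
            "total_selected_fraction":
            sum(len(r.selected_ids) for r in rounds) / config.n_pool_cases,
            "rounds": rounds}


def uncertainty_ranking_study(seed: int, n_maps: int = 36,
                              image_size: int = 32) -> dict:
    """Does the per-image uncertainty score track segmentation error?

    Corrupts perfect phantom masks along a blur/low-confidence gradient
    and correlates the resulting Un with 1 - Dice of the thresholded
    maps (Spearman).
    """
    spec = PhantomSpec(image_size=image_size, n_slices=3,
                       organ_axes_inplane=(5.0, 9.0),
                       organ_axes_slices=(1.5, 2.5))
    pool = generate_phantom_pool(spec, n_maps, seed=seed)
    uns, errors = [], []
    for i, (_, mask) in enumerate(pool):
        t = i / (n_maps - 1)
        corruption = CorruptionSpec(boundary_blur_sd=0.5 + 3.5 * t,
                                    flip_fraction=0.3 * t,
                                    seed=seed * 1000 + i)
        probs = corrupt_mask_to_probability(mask, corruption)
        uns.append(score_case(probs, case_id=mask.case_id).un)
        errors.append(1.0 - overlap_metrics(probs >= 0.5,
                                            mask.voxels)[0])
    rho = float(spearmanr(uns, errors).statistic)
    return {"spearman": rho, "n_maps": n_maps,
            "un": uns, "error": errors}
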