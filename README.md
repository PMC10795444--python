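# hnseg

Localized auto-segmentation of head-and-neck organs-at-risk (OARs) on CT,
with an uncertainty-guided fine-tuning workflow for adapting a model
trained on a small local cohort to data from other institutions.

Radiotherapy planning requires contouring healthy structures (brain stem,
parotid, esophagus, optic nerve, optic chiasm, mandible, pharyngeal
constrictor) on planning CT. Off-the-shelf auto-contouring tools trained
elsewhere often disagree with local delineation practice, and local labeled
data is scarce. `hnseg` addresses both problems:

1. **HN-Net** — a lightweight residual encoder–decoder CNN, one binary model
   per organ, operating on windowed 2-D CT slices. Blocks use depthwise
   separable 3×3 convolutions with batch normalization and residual
   shortcuts; skip connections are gated by CBAM attention (a channel gate
   followed by a spatial gate, both multiplicative sigmoids); a 1×1
   convolution with a sigmoid head emits per-pixel foreground probabilities.
2. **Uncertainty-guided candidate selection** — given a labeled external
   pool, the current model's probability map *p* is converted to a pixel
   uncertainty *u = min(p, 1 − p)*, edge-filtered with the discrete
   4-neighbour Laplacian ∇²u, and averaged over the image:
   *Uₙ = (1/m) Σ |∇²u|*. High-*Uₙ* samples are the ones the model handles
   worst. The workflow ranks the pool, folds the top 30% into the training
   set, fine-tunes from the current weights, and repeats once more — two
   rounds move about half of the pool (9 + 6 of 30) into training.

Evaluation uses the standard five metrics: Dice, Jaccard, Precision,
Recall, and the symmetric Hausdorff distance in mm (boundary-voxel based,
spacing-aware).

Everything runs on synthetic CT-like phantoms (ellipsoidal "organs" with
Gaussian HU noise and an optional domain shift), so the complete workflow
is exercisable and testable on one CPU with no clinical data. The neural
network is implemented on a compact NumPy reverse-mode autodiff library
(`hnseg.nn`) whose gradients are verified against finite differences.

## Worked example

Train on a small "local" phantom pool, then adapt to a domain-shifted
"public" pool with the two-round selection workflow:

```python
import numpy as np
from hnseg import HNNetSegmenter, PhantomSpec, generate_phantom_pool
from hnseg.phantom import pool_to_dataset, pool_to_cases
from hnseg.selection import run_selection_workflow
from hnseg.training import TrainConfig
from hnseg.experiments import mean_case_dice

spec = PhantomSpec(n_slices=4, seed=0)          # 64x64 CT-like phantoms
local = generate_phantom_pool(spec, 5, seed=1)  # local labeled pool
pool  = generate_phantom_pool(spec, 30, seed=2, shifted=True, id_prefix="pub")
test  = generate_phantom_pool(spec, 10, seed=3, shifted=True, id_prefix="tst")

ds = pool_to_dataset(local)                     # windowed slices + masks
X = np.stack([s for s, _ in ds]); y = np.stack([m for _, m in ds])
model = HNNetSegmenter(input_size=64, depth=2, base_channels=8,
                       epochs=20, random_state=0).fit(X, y)

cases = pool_to_cases(test)
print(f"held-out shifted-domain Dice before fine-tuning: "
      f"{mean_case_dice(model.model_, cases):.3f}")

net, rounds = run_selection_workflow(
    model.model_, ds, pool_to_cases(pool),
    TrainConfig(epochs=8, seed=0), iterations=2, fraction=0.30)
for r in rounds:
    print(f"round {r.iteration}: pool {len(r.pool_ids)}, "
          f"selected {len(r.selected_ids)} "
          f"(top Un = {r.ranked_scores[0].un:.4f})")
print(f"held-out shifted-domain Dice after fine-tuning:  "
      f"{mean_case_dice(net, cases):.3f}")
```

Output:

```
held-out shifted-domain Dice before fine-tuning: 0.273
round 1: pool 30, selected 9 (top Un = 0.0301)
round 2: pool 21, selected 6 (top Un = 0.0135)
held-out shifted-domain Dice after fine-tuning:  0.990
```

The baseline model, trained only on the local pool, largely fails on the
intensity/noise/scale-shifted test cases (Dice 0.27). Two selection rounds
pick 9 then 6 of the 30 candidates — exactly 30% per round of the remaining
pool, 50% cumulatively — and fine-tuning on them recovers the shifted
domain (Dice 0.99).

The same steps are available from the shell:

```bash
hnseg simulate --n 5  --seed 1 --out data/local
hnseg simulate --n 30 --seed 2 --shifted --out data/pool
hnseg train --data data/local --organ brain_stem --out ckpt/
hnseg select --checkpoint ckpt/ --pool data/pool --out selection/
hnseg finetune-workflow --checkpoint ckpt/ --local data/local \
      --pool data/pool --out finetuned/
hnseg evaluate --pred pred/ --ref ref/ --out metrics.csv
```

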