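# nccount

Cell counting for lensless (in-line holographic) blood-sample images by
normalized cross-correlation (NCC) template matching, plus the two
optimizations that make the detector cheap enough for battery-powered
point-of-care devices: **influence-based template-library pruning** and
**periodic skip patterns** for sparse NCC evaluation, each with **linear
threshold compensation** for the counting accuracy it costs.

It is written for people building or studying software-based cytometry on
constrained hardware: the full pipeline runs from a library API or a small
CLI, and a seeded synthetic-scene generator with ground truth makes every
stage testable without imaging hardware.

## The method

A sample image `f` (M×N) is scanned with each K×L template `ω` from a cell
library; at offset `(i, j)` the similarity is

```
R(i,j) = Σ (ω−ω̄)(f_win−f̄) / sqrt( Σ(ω−ω̄)² · Σ(f_win−f̄)² )   ∈ [−1, 1]
```

An offset is *marked* when the maximum of `R` over the library exceeds a
threshold `T` (operating value 0.67); a cell spans several adjacent offsets,
so marked points are clustered (8-connectivity) and the count is the number
of clusters. The cost is proportional to (number of offsets) × (library
size), which two optimizations attack:

- **Library pruning.** Templates are scored by *influence* — the share of
  clusters they are first to detect when templates are visited in library
  order. Exact duplicates and near-duplicates have zero influence and are
  removed for free; low-influence templates are removed greedily while the
  recounted loss stays within a budget. Evaluations scale linearly with
  library size (a 150 → 20 shrink cuts them by 87%).
- **Skip patterns.** A periodic mask evaluates only a lattice of offsets
  (e.g. alternate rows → 50% fewer evaluations). For a cluster of `t` points
  of which `s` are skipped, each exceeding `T` independently with probability
  `p_mark`, the chance the sparse detector still finds a cell the dense one
  found is `[1−(1−p_mark)^(t−s)] / [1−(1−p_mark)^t]` — 98.6% for the
  alternate-row pattern at `p_mark = 0.5`, `t = 9`.
- **Threshold compensation.** Both optimizations depress NCC maxima and lose
  counts. Over the calibration band the count is linear in the threshold,
  `C(T) ≈ αT + β`; inverting the fitted line gives the compensated threshold
  `T* = (target − β)/α`, clamped to stay ≥ 0.60 (the weakest threshold still
  indicating strong correlation).

## Worked example

```python
from nccount import (count_cells, derive_library, generate_scene,
                     preset_pattern)
from nccount.config import RunConfig
from nccount.pipeline import run_optimize
from nccount.synthetic import SceneParams

scene = generate_scene(SceneParams(seed=42))          # 300x400, 60 cells
library = derive_library(scene, n_templates=12,        # 4 distinct crops,
                         duplicate_fraction=1/3,       # 4 exact duplicates,
                         jitter_fraction=1/3, seed=42) # 4 jittered copies

original = count_cells(scene.image, list(library.templates), threshold=0.67)
print(original.count, original.n_evaluations)          # -> 60 1308672

config = RunConfig(threshold=0.67, pattern="p1", loss_budget_percent=8.5)
opt = run_optimize(config, [scene.image], library)
optimized = count_cells(scene.image, list(opt.pruned.templates),
                        opt.compensated_threshold, pattern=preset_pattern(1))
print(len(opt.pruned), optimized.count, optimized.n_evaluations)
# -> 2 60 109056
```

The original detector finds all 60 planted cells with 1,308,672 NCC
evaluations. Pruning removes the ten redundant templates at zero realized
loss, and the alternate-row pattern halves the evaluated offsets: the
optimized detector still counts 60 cells using 109,056 evaluations — 8.3%
of the original work (2/12 of the library × 1/2 of the offsets).

The same pipeline is scriptable from a shell:

```
nccount simulate --out scene --seed 42 --n-templates 12 --duplicate-fraction 0.334
nccount count scene/scene.png --library scene/library --threshold 0.67
nccount optimize-library scene/scene.png --library scene/library --budget 8.5
nccount analyze-patterns
```

`analyze-patterns` prints the preset summary (runtime reduction 50/50/75/89%,
best-case skipped points 3/4/5/8 of 9, detection probability
98.6/97.1/93.9/50.1% at `p_mark = 0.5`).

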