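# plantpatch

Patch-based classification of whole-plant images and dynamic organ
phenotyping.

## The problem

High-throughput phenotyping platforms photograph individual plants (here:
side-view RGB images of *Brassica napus* on a near-black background, one
plant per image, daily over weeks). Manually scoring when flowers first
open or how pod load develops across hundreds of such series does not
scale. `plantpatch` turns each image into a grid of 10×10-pixel patches,
assigns every patch one of six labels —

```
0 background   1 branch   2 leaf   3 bud   4 flower   5 pod
```

— and aggregates patch labels over a dated series into organ-abundance
trajectories and first-appearance dates (first flowering, first pod set).

## Method

**Patchification.** An H×W image is tiled from the top-left into
⌊H/10⌋ × ⌊W/10⌋ full patches (a 2056×2454 side view yields 50,225);
remainder strips are excluded. Each patch carries the label of the
predominant organ within it.

**Imbalance-aware training.** Annotated patches are overwhelmingly
background. The table is split 60/20/20 (stratified, largest-remainder
apportionment per class) and training examples are drawn with replacement
with probability proportional to the inverse-frequency class weight

$$w_c = \frac{1}{(0.6\,N_c)/10} = \frac{10}{0.6\,N_c},$$

where $N_c$ is the total annotated count of class $c$, so each class is
seen equally often in expectation.

**Classifier composition.** Three strategies map model outputs to a final
label per patch:

- `multi6` — one 6-class classifier, argmax;
- `chain` — six one-vs-rest binary classifiers; among those voting
  positive, the highest confidence wins;
- `hierarchical` — a plant/background binary classifier first; only
  plant patches reach a 5-class organ classifier.

**Evaluation.** Per-class precision, recall and F1
($F = 2PR/(P+R)$) with micro (pooled counts), macro (unweighted mean)
and support-weighted aggregation; models are ranked by **macro F1** to
emphasize the minority organ classes.

**Phenotyping.** Per image, patch labels are tallied into per-class
abundances; across a series, the first appearance of a class is the
earliest date its count reaches a threshold for a configurable number of
consecutive days.

Everything is testable without any real imagery: `plantpatch.synthetic`
renders side-view-like plants (seeded branching skeleton, leaves, and a
bud → flower → pod organ succession) together with exact pixel-level
ground truth.

## Worked example

```python
from plantpatch.pipeline import run_synthetic_benchmark

r = run_synthetic_benchmark(seed=11)        # 3 plants x 15 days, ~189k patches
agg = r["report"]["percent"]["aggregates"]
print(f"macro F1:    {agg['macro']['f1']:.2f}")
print(f"weighted F1: {agg['weighted']['f1']:.2f}")
print({p: str(d) for p, d in r["first_flowering"].items()})
```

prints

```
macro F1:    87.14
weighted F1: 99.82
{'plant00': '2018-06-14', 'plant01': '2018-06-14', 'plant02': '2018-06-14'}
```

The hierarchical composition (plant/background binarization, then 5-class
organ classification) reaches macro F1 87.14 on 37,800 held-out synthetic
patches — the rare `bud` class is, as on real data, the hardest — and the
first-flowering date of every generated plant is recovered exactly
(flowering is scheduled on day 8 of the series, 2018-06-14). The
majority-class baseline scores macro F1 16.3.

A command-line interface covers the same steps for on-disk data:

```
plantpatch synth --plants 3 --days 15 --seed 7 --out data/
plantpatch weights --annotations data/annotations.csv
plantpatch split --annotations data/annotations.csv --seed 7 --out split.csv
plantpatch train --images data/ --annotations data/annotations.csv \
    --task binary:background --out models/binary_background
plantpatch predict --images data/ --strategy hierarchical --models models/ \
    --out pred.csv --overlay-dir overlays/
plantpatch evaluate --truth data/annotations.csv --pred pred.csv --out report.json
plantpatch timeseries --pred pred.csv --metadata data/metadata.csv --out series.json
```

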