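# reefscan

Simulated underwater hyperspectral reef surveys, end to end: synthetic reef
scenes with exact ground truth, push-broom scan rendering and preprocessing,
ROI annotation, a spectral-spatial residual-network per-pixel classifier,
photoquadrat point-intercept cover estimation, and the community statistics
used to document reef transitions and to validate hyperspectral cover
estimates against photoquadrats.

## The problem

Benthic monitoring of coral reefs traditionally scores photoquadrats: a
0.25 m² photograph at every meter of a 50 m transect, each overlaid with 50
sampled points identified to one of 58 fine categories, aggregated to 10
broad taxonomic/functional groups (with the habitat-defining staghorn coral
*Acropora abrotanoides* kept separate from other Scleractinia).
Diver-operated hyperspectral imagers promise the same community estimates
from automated per-pixel classification of reflectance spectra.  Validating
such a pipeline on real scans is expensive; this package instead provides a
fully seeded simulator of the whole survey, so every stage — from raw
radiance to ANOSIM — can be tested against known truth.

The statistics at the core:

- Shannon diversity `H = −Σ pᵢ ln pᵢ` and equitability `E = H / ln S`
  (S = 10 groups), from mean percent covers.
- One-way ANOVA with Tukey HSD on √-transformed covers per group.
- Bray–Curtis dissimilarity `d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)`; ANOSIM
  `R = (r̄_between − r̄_within) / (n(n−1)/4)` on ranked dissimilarities of
  untransformed covers with permutation p-values; non-metric MDS
  (Kruskal stress-1, SMACOF with isotonic regression) on √-transformed
  covers.
- The classifier: 1×1 band projection → spectral residual units → feature
  adjustment → spatial (3×3) residual units → window average pooling →
  softmax, trained on 90% of ROI-labeled pixels with inverse-frequency
  class weights, validated on the held-out 10%.

## Worked example

```python
import numpy as np
from reefscan import data, ecostats

means = data.reference_mean_covers()      # bundled survey means (10 groups)
for survey in ("2015", "2017", "2019-PQ"):
    div = ecostats.shannon(means[survey].to_numpy(), S=10)
    print(survey, round(div.H, 2), round(div.E, 2))
```

prints

```
2015 1.14 0.5
2017 1.27 0.55
2019-PQ 0.82 0.35
```

— the 2015→2017 rise in diversity and the post-bleaching 2019 collapse
(H from 1.27 to 0.82) as the community shifted toward turf-algae dominance.
Combined hard-coral cover from the same table is 31.8% (2015) and 38.8%
(2017), falling to 7.1% in 2019.

The full simulated pipeline runs from a TOML config:

```sh
reefscan simulate  --config pipeline.toml   # scenes + scans + truth covers
reefscan preprocess --config pipeline.toml  # smooth, trim, normalize, z-score
reefscan annotate  --config pipeline.toml   # ROIs -> labeled library, 90/10
reefscan train     --config pipeline.toml   # fit the classifier
reefscan predict   --config pipeline.toml   # label every pixel
reefscan survey    --config pipeline.toml   # PQ + DR cover tables
reefscan stats     --config pipeline.toml   # H/E, ANOSIM, ANOVA letters
```

Every stage derives its seed from `master_seed` and appends input/output
hashes to a JSON run manifest.

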