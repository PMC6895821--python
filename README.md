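# punctacoloc

Object-based colocalization analysis of punctate fluorescence signals, with
synthetic ground truth for every stage, plus the accompanying
gene-expression correlation screen and semiquantitative grading utilities.

## The problem

In tissue sections labelled with two fluorophores — for example a
fluorescent cAMP analogue reporting cAMP-binding sites in one channel and an
antibody against a PKA subunit in the other — the signal of interest is
*punctate*: discrete bright spots rather than diffuse staining. The question
"do the two markers sit at the same subcellular sites?" is then an
object-based colocalization question: detect the puncta in each channel,
superimpose the channels, and count how many maxima coincide.

`punctacoloc` implements that analysis as a reproducible pipeline:

1. **Detection.** Each channel is scanned for regional intensity maxima
   (strict 8-neighbourhood; equal-intensity plateaus collapse to their
   centroid pixel). A maximum at pixel *p* is kept when

   *I(p) − bg(p) ≥ Δ*,  with Δ = 10 AU by default,

   where *bg(p)* is the *adjacent background*: the median intensity over an
   annulus 3 px < d ≤ 7 px around *p*. Because the criterion is relative to
   the local surround, detection is invariant to adding a constant to the
   whole image and needs no illumination correction.
2. **Matching.** The two maxima sets are superimposed and paired one-to-one:
   candidate pairs with centre distance ≤ *r* (default 2 px) are accepted
   greedily in order of increasing distance, each maximum used at most once.
   The bidirectional percentages are
   `pct_A = 100 · n_coincident / (n_coincident + n_A_only)` and likewise for
   B; empty channels report NA, never 0 or 100.
3. **Grading.** Ordinal labelling-intensity scores (−, −/+, +, ++, +++)
   from independent observers are encoded on the scale {0, 0.5, 1, 2, 3},
   averaged, and mapped back to the nearest symbol (ties round down).
4. **Expression screen.** On a genes × samples log-scale expression matrix
   with per-sample vital status, `pearson_screen` computes pairwise
   Pearson R with two-sided p-values (t transform, n − 2 df, no
   multiple-testing correction; stars \* p<0.05, \*\* p<0.02, \*\*\* p<0.005)
   and `group_compare` runs dead-vs-alive two-sample t tests.
5. **Synthetic data.** `simulate_image_pair` renders Gaussian puncta on a
   linear background with a *planted* coincident fraction and returns the
   truth registry; `simulate_expression` draws a multivariate-normal
   log-scale matrix with a planted correlation structure and group shift.
   Every stage of the pipeline is therefore testable against known ground
   truth without any external data.

## Worked example

```python
from punctacoloc import (ChannelImage, ImageSimConfig, coloc_report,
                         detect_maxima, match_maxima, simulate_image_pair)

cfg = ImageSimConfig(height=320, width=320, n_spots_A=100, n_spots_B=100,
                     true_coincident_fraction=0.8, partner_jitter=0.5,
                     noise_model="none", seed=42)
img_a, img_b, truth = simulate_image_pair(cfg)
set_a = detect_maxima(ChannelImage(img_a, "A"))
set_b = detect_maxima(ChannelImage(img_b, "B"))
res = match_maxima(set_a, set_b)
print(f"A maxima: {len(set_a)}  B maxima: {len(set_b)}")
print(f"coincident: {res.n_coincident}  A-only: {res.n_a_only}  B-only: {res.n_b_only}")
print(f"pct A coincident: {res.pct_a_coincident:.1f}%")
```

prints

```
A maxima: 100  B maxima: 100
coincident: 80  A-only: 20  B-only: 20
pct A coincident: 80.0%
```

All 100 planted puncta per channel are detected, and the 80 planted
coincidental pairs — B partners jittered by 0.5 px around their A spots —
are exactly the pairs recovered by the matcher, so the recovered
colocalization percentage equals the planted 80%. `coloc_report` pools such
results across images (pooled percentages are computed from pooled counts,
not averaged percentages).

A command-line interface wraps the same functions:

```bash
punctacoloc simulate-images --seed 3 --out-dir out/ --format png
punctacoloc coloc --rgb out/pair_rgb.png --delta 10 --radius 2
punctacoloc simulate-expression --seed 4 --out-dir out/
```

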