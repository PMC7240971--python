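# metaboref

Age- and sex-dependent reference percentiles, SDS scoring and association
analyses for pediatric metabolite panels.

## The problem

Whole-blood amino-acid and acylcarnitine concentrations change strongly over
the first 18 years of life, and differently for girls and boys. To decide
whether a child's value is unusual — or to relate metabolite levels to BMI,
puberty or laboratory markers across a growing cohort — one first needs
age- and sex-specific reference distributions, then a way to express every
measurement on a common scale, and finally association tests that respect
the cohort's structure (repeated annual visits, sibling clusters).

`metaboref` implements that full workflow for panels of ~30 metabolites
(23 amino acids, 6 acylcarnitines, free carnitine) measured in dried blood
spots, together with a synthetic-cohort generator that reproduces the
statistical structure of such studies so every stage is testable without
access to individual-level clinical data.

## The model

References use the LMS method: at each age, the distribution of a
metabolite `y > 0` is summarized by three smooth curves — the Box-Cox power
`L(t)` (skewness), the median `M(t)` and the coefficient of variation
`S(t)` — under the Box-Cox Cole-Green (BCCG) distribution, where

```
z = ((y/M)^L − 1) / (L·S)      (L ≠ 0),      z = ln(y/M)/S   (L = 0)
```

is standard normal, and percentile curves follow as
`C_α(t) = M(t)·(1 + L(t)·S(t)·z_α)^{1/L(t)}`. Metabolites with heavy tails
use the Box-Cox t (BCT) family, which refers `z` to a Student t with `τ`
degrees of freedom. Curves are cubic regression splines on a √age axis,
estimated by maximum likelihood with the spline dimension chosen by BIC;
BCT is selected over BCCG only when its BIC is strictly lower. Repeated
visits and siblings are handled by resampling one observation per family
per iteration and taking pointwise medians of the fitted curves.

Scored values `SDS = z` (normal-scale via probability integral transform
for BCT) feed the association layer: Gaussian random-intercept models
(exact REML for the single-random-effect case) for age-interval trends,
BMI-SDS slopes with a sex-interaction gate, Tanner-stage contrasts against
the pre-pubertal reference, and metabolite × laboratory-marker matrices,
all with Benjamini-Yekutieli FDR control at 5%.

## A worked example

```
$ python examples/02_reference_curves.py
fitted BCCG reference on 2019 observations
spline df per parameter: {'L': 1, 'M': 3, 'S': 1, 'tau': 0}  BIC: 15099.6

percentile curves (umol/L):
level  2.5   10.0  50.0  90.0   97.5
age
0.5    47.9  53.5  65.5  79.3   87.4
2.0    44.7  50.0  61.1  74.0   81.6
6.0    44.6  49.8  60.9  73.7   81.3
12.0   49.7  55.5  67.9  82.2   90.7
17.0   56.6  63.2  77.3  93.7  103.3

max relative error of the fitted median vs generating truth: 0.8%
```

The fit recovered an infancy-peak profile (tyrosine-like: elevated in the
first year, minimum in early childhood, rising through adolescence): the
columns are the 2.5th-97.5th percentile curves a clinician would read a
child's value against, and the last line checks the fitted median against
the curve that generated the data. The other scripts in `examples/` cover
cohort simulation, SDS scoring, QC filters, association testing and the
full configuration-driven pipeline (also available as a thin CLI:
`metaboref simulate | fit-references | score | associate | run-all | schema`).

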