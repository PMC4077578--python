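# jcmflow

Joint modeling and registration of cell populations across a batch of
flow-cytometry samples.

## The problem

Model-based gating identifies cell populations in a single sample as the
components of a finite mixture of heavy-tailed, possibly skewed
distributions. The harder problem in cohort studies is *registration*:
deciding which population in sample *k* corresponds to which population in
every other sample of the batch, in the presence of real inter-sample
variation. Post-hoc meta-clustering of independently fitted models is
fragile exactly when that variation is large.

`jcmflow` fits the batch jointly. Every sample *k* is a *g*-component
mixture of multivariate *t* or unrestricted (Sahu-form) skew *t*
distributions, and all samples share one batch **template** through a
random-effects model (REM) on the component means:

```
y_ijk = a_hik mu_hi + b_hik + e_hijk ,
a_hik ~ N(1, sigma_a^2) ,  b_hik ~ N(0, sigma_b^2) ,
```

where `mu_hi` is the template mean of variable *i* in population *h*, and
`a`, `b` are per-sample scaling and translation effects. Scale matrices
`Sigma_h`, skewness `delta_h` and degrees of freedom `nu_h` live at the
template level. Because component *h* means the same population in every
sample, the fitted labels are registered by construction; the REM
variances quantify inter-sample variation instead of "correcting" it. New
samples are classified against class templates by transform-adjusted
log-likelihood (or Kullback–Leibler distance between models).

Fitting is an Expectation–Conditional-Maximization scheme with a
monotone-trace safeguard; the number of populations can be chosen by BIC.
Everything is testable offline: a synthetic-batch generator draws data
with exactly the template-plus-random-effects structure above, with full
ground truth.

## Worked example

```python
import numpy as np
from jcmflow import (BatchSpec, JCMOptions, default_template, fit_jcm,
                     misclassification_rate, simulate_batch)

template = default_template(p=3, g=3, family="t", separation=4.0, seed=99)
batch, truth = simulate_batch(BatchSpec(
    template=template, m=8, n_per_sample=2000, sigma_a=0.05, sigma_b=0.3,
    seed=3000))
fit = fit_jcm(batch, JCMOptions(family="t", g=3, seed=0, n_starts=2))

mcrs = [misclassification_rate(ps.labels, truth.labels[k])
        for k, ps in enumerate(fit.per_sample)]
print(f"mean registered MCR : {np.mean(mcrs):.4f}")
print(f"sigma_b^2 estimate  : {fit.rem.sigma_b2:.4f}")
print(f"trace monotone      : {bool(np.all(np.diff(fit.total_loglik_trace) >= -1e-6))}")
```

prints

```
mean registered MCR : 0.0041
sigma_b^2 estimate  : 0.1844
trace monotone      : True
```

Eight samples were drawn from a known 3-population template with
translation effects of SD 0.3 and small scaling effects (SD 0.05); the
joint fit registers the populations across all samples with a 0.4%
misclassification rate against the generator's ground truth. The
translation variance estimate (0.18) exceeds the generating 0.09 because
for any one (population, marker, sample) cell the scaling and translation
effects act through a single scalar shift: scaling noise on large mean
magnitudes is partly absorbed into `b`, a known identifiability limit of
the mean-transform REM (see `docs/methods.md`).

The same pipeline is available from the shell:

```
jcm simulate --spec spec.yaml --out sim/
jcm fit --input 'sim/sample*.csv' --g 3 --family t --seed 1 --out run/
jcm evaluate --pred 'run/labels/sample*.txt' --truth 'sim/sample*.truth.txt' --out eval.json
jcm classify --templates 'cls/*.json' --input sim/sample01.csv --out pred.json
jcm plotdata --models run/template.json --marker M1 --out curves.csv
```

FCS 3.0/3.1 float list-mode files are read directly (`.fcs` inputs);
samples are assumed compensated and scale-transformed (an optional
`--arcsinh` cofactor is available).

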