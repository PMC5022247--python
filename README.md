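# nblda

Negative binomial linear discriminant analysis for RNA-Seq count data.

RNA-Seq measures gene expression as non-negative read counts, and with
biological replicates those counts are overdispersed: the variance exceeds
the mean. Classifiers built on a Poisson model (PLDA) ignore that extra
variance. `nblda` implements a discriminant classifier under the negative
binomial model

    X_ig | y_i = k  ~  NB(s_i λ_g d_kg, φ_g),     Var = μ + μ²φ_g,

where `s_i` is a per-sample size factor, `λ_g` a gene abundance, `d_kg` a
multiplicative class effect, and `φ_g` the dispersion. A test sample `x*`
with size factor `s*` is assigned to the class maximizing the Bayes
log-posterior (up to a class-independent constant)

    score_k = Σ_g X*_g [log d_kg − log(1 + s*λ_g d_kg φ_g)]
            − Σ_g φ_g⁻¹ log(1 + s*λ_g d_kg φ_g) + log π_k,

which reduces to the Poisson discriminant score as φ → 0; that limit is
included as the `plda` baseline. The package provides the three standard
size-factor estimators (total count, median-of-ratios, upper quartile), a
shrinkage dispersion estimator (method-of-moments initial values shrunk
toward a common target), a negative binomial simulation engine, and a
repeated-simulation evaluation harness. It is aimed at statisticians and
computational biologists classifying samples (e.g. tumor vs normal) from
gene-level count matrices, and at anyone benchmarking count-model
classifiers. See `docs/methods.md` for the full model account.

## Worked example

```python
import numpy as np
from nblda import SimulationConfig, simulate, fit, predict, misclassification_rate

cfg = SimulationConfig(G=100, n=50, K=2, de_prop=0.4, sigma=5.0, phi=20.0, seed=7)
data = simulate(cfg)                       # train + test counts with ground truth

model = fit(data.train, data.train_labels) # size factors, dispersions, effects, priors
print(f"delta = {model.dispersion_fit.delta:.4f}, "
      f"median dispersion = {np.median(model.phi_hat):.2f}")

pred, post = predict(model, data.test)            # NB score
pred_p, _ = predict(model, data.test, score="plda")  # Poisson baseline
print(f"NBLDA error rate: {misclassification_rate(pred, data.test_labels.labels):.3f}")
print(f"PLDA  error rate: {misclassification_rate(pred_p, data.test_labels.labels):.3f}")
```

Output:

```
delta = 0.9899, median dispersion = 22.77
NBLDA error rate: 0.060
PLDA  error rate: 0.100
```

The shrinkage weight `delta` near 1 means the gene-wise dispersion
estimates were pulled almost entirely to their common target, which here
lands near the generative dispersion 20. Modelling the overdispersion
drops the test error from 10% to 6% on this highly dispersed dataset;
`post` holds the per-sample class posterior probabilities, each row
summing to 1.

The same workflow is available from a shell:

```sh
nblda simulate --G 100 --n 50 --phi 20 --seed 7 --out-prefix sim/
nblda fit --counts sim/train_counts.tsv --labels sim/train_labels.tsv --out model.json
nblda predict --model model.json --counts sim/test_counts.tsv --out predictions.tsv
nblda evaluate --config exp.json --reps 100 --seed 1 --out results.tsv
nblda score-curve --mode common --grid-max 20 --points 200 --out curve.tsv
```

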