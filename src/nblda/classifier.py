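"""The negative binomial discriminant classifier and its Poisson limit.

Model: reads for gene g in a sample of class k are negative binomial with
mean s * lambda_g * d_kg and variance mu + mu^2 * phi_g, where s is the
sample's size factor, lambda_g a gene abundance parameter, d_kg a
multiplicative class effect (d_kg = 1 means no differential expression)
and phi_g the dispersion. Genes are treated as independent.

Classification is by Bayes' rule: a test sample x* with size factor s* is
assigned to the class maximizing the log-posterior, which up to a
class-independent constant equals

    score_k = sum_g X*_g [log d_kg - log(1 + s* lambda_g d_kg phi_g)]
            - sum_g phi_g^{-1} log(1 + s* lambda_g d_kg phi_g)
            + log pi_k.

As phi_g -> 0 each gene's contribution tends to the Poisson limit
X*_g log d_kg - s* lambda_g d_kg, giving the Poisson discriminant score
(PLDA); genes with phi_g = 0 use that analytic limit directly.

Plug-in estimates from labeled training data:
    lambda_hat_g = sum_i X_ig          (total reads per gene)
    d_hat_kg = (sum_{i in C_k} X_ig + 1) / (sum_{i in C_k} s_i lambda_hat_g + 1)
    pi_hat_k = n_k / n
with s_i from the normalization module (summing to 1, so
sum_i s_i lambda_hat_g is on the scale of lambda_hat_g) and phi_hat_g from
the dispersion shrinkage module. The +1 smoothing (posterior mean under a
Gamma prior) keeps d_hat_kg strictly positive even for all-zero genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import CountMatrix, LabelVector, TestSample, ValidationError
from .dispersion import (
    DEFAULT_XI_STRATEGY,
    DispersionFit,
    mom_dispersion,
    shrink_dispersion,
)
from .normalization import (
    DEFAULT_METHOD,
    SizeFactors,
    estimate_size_factors,
    size_factor_test,
)


@dataclass
class NBLDAModel:
    """Fitted parameters of the negative binomial discriminant model."""

    lambda_g: np.ndarray  # (G,) total training reads per gene
    d_kg: np.ndarray  # (K, G) class effects, strictly positive
    pi_k: np.ndarray  # (K,) class priors, summing to 1
    phi_hat: np.ndarray  # (G,) shrunk dispersions, >= 0
    sf: SizeFactors
    class_names: list[str]
    gene_ids: list[str]
    dispersion_fit: DispersionFit | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.lambda_g = np.asarray(self.lambda_g, dtype=float)
        self.d_kg = np.atleast_2d(np.asarray(self.d_kg, dtype=float))
        self.pi_k = np.asarray(self.pi_k, dtype=float)
        self.phi_hat = np.asarray(self.phi_hat, dtype=float)
        K, G = self.d_kg.shape
        if self.lambda_g.shape != (G,) or self.phi_hat.shape != (G,):
            raise ValidationError("gene-dimension mismatch among model fields")
        if self.pi_k.shape != (K,) or len(self.class_names) != K:
            raise ValidationError("class-dimension mismatch among model fields")
        if len(self.gene_ids) != G:
            raise ValidationError("gene_ids length does not match gene dimension")
        if np.any(self.lambda_g < 0):
            raise ValidationError("lambda_g must be non-negative")
        if np.any(self.d_kg <= 0):
            raise ValidationError("class effects d_kg must be strictly positive")
        if np.any(self.pi_k <= 0) or abs(self.pi_k.sum() - 1.0) > 1e-9:
            raise ValidationError("priors must be positive and sum to 1")
        if np.any(self.phi_hat < 0):
            raise ValidationError("dispersions must be non-negative")

    @property
    def K(self) -> int:
        return self.d_kg.shape[0]

    @property
    def G(self) -> int:
        return self.d_kg.shape[1]


@dataclass
class ScoreVector:
    """Per-class discriminant scores and the implied prediction.

    Scores are log-posteriors up to a shared additive constant; the
    predicted class maximizes the score, ties broken toward the smallest
    class index.
    """

    scores: np.ndarray
    predicted: int

    @classmethod
    def from_scores(cls, scores: np.ndarray) -> "ScoreVector":
        scores = np.asarray(scores, dtype=float)
        return cls(scores=scores, predicted=int(np.argmax(scores)) + 1)

    def posteriors(self) -> np.ndarray:
        """Class posterior probabilities via a max-stabilized softmax."""
        z = self.scores - self.scores.max()
        w = np.exp(z)
        return w / w.sum()


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit(
    train: CountMatrix,
    labels: LabelVector,
    sf_method: str = DEFAULT_METHOD,
    xi_strategy: str = DEFAULT_XI_STRATEGY,
    mom_within_class: bool = False,
) -> NBLDAModel:
    """Fit the model on labeled training counts via the plug-in estimators."""
    if labels.n != train.n_samples:
        raise ValidationError(
            f"{labels.n} labels for {train.n_samples} samples"
        )
    sf = estimate_size_factors(train, method=sf_method)
    if train.n_genes >= 3:
        disp = shrink_dispersion(
            train, sf, xi_strategy=xi_strategy, labels=labels, within_class=mom_within_class
        )
    else:
        # shrinkage needs >= 3 genes for its (G-1)/(G-2) divisors; with fewer,
        # fall back to the raw clamped MoM estimates (no shrinkage)
        phi_tilde = mom_dispersion(
            train, sf, labels=labels, within_class=mom_within_class
        )
        disp = DispersionFit(
            phi_initial=phi_tilde, xi=float(phi_tilde.mean()), delta=0.0,
            phi_hat=phi_tilde, xi_strategy=xi_strategy,
        )
    X = train.counts.astype(float)
    lam = X.sum(axis=1)
    K = labels.K
    d = np.empty((K, train.n_genes))
    for k in range(1, K + 1):
        cols = labels.labels == k
        d[k - 1] = (X[:, cols].sum(axis=1) + 1.0) / (sf.s[cols].sum() * lam + 1.0)
    pi = labels.class_sizes() / labels.n
    return NBLDAModel(
        lambda_g=lam,
        d_kg=d,
        pi_k=pi,
        phi_hat=disp.phi_hat,
        sf=sf,
        class_names=list(labels.class_names),
        gene_ids=list(train.gene_ids),
        dispersion_fit=disp,
    )


# ---------------------------------------------------------------------------
# Discriminant scores
# ---------------------------------------------------------------------------


def _check_test(model: NBLDAModel, test: TestSample, s_star: float) -> np.ndarray:
    x = np.asarray(test.counts, dtype=float)
    if x.size != model.G:
        raise ValidationError(f"test sample has {x.size} genes, model has {model.G}")
    if test.gene_ids and test.gene_ids != model.gene_ids:
        raise ValidationError("test sample gene identifiers do not match the model")
    if not s_star > 0:
        raise ValidationError(f"test size factor must be positive, got {s_star}")
    return x


def nblda_score(model: NBLDAModel, test: TestSample, s_star: float) -> ScoreVector:
    """Negative binomial discriminant score for each class.

    Genes with phi_hat = 0 contribute their analytic Poisson limit
    (no epsilon regularization).
    """
    x = _check_test(model, test, s_star)
    phi = model.phi_hat
    mu = s_star * model.lambda_g[None, :] * model.d_kg  # (K, G) test-sample means
    scores = np.empty(model.K)
    pos = phi > 0
    log_d = np.log(model.d_kg)
    for k in range(model.K):
        t = np.log1p(mu[k, pos] * phi[pos])
        nb_part = np.sum(x[pos] * (log_d[k, pos] - t)) - np.sum(t / phi[pos])
        poisson_part = np.sum(x[~pos] * log_d[k, ~pos]) - np.sum(mu[k, ~pos])
        scores[k] = nb_part + poisson_part + np.log(model.pi_k[k])
    return ScoreVector.from_scores(scores)


def plda_score(model: NBLDAModel, test: TestSample, s_star: float) -> ScoreVector:
    """Poisson-limit discriminant score (the PLDA baseline, no transformation)."""
    x = _check_test(model, test, s_star)
    mu = s_star * model.lambda_g[None, :] * model.d_kg
    scores = (x[None, :] * np.log(model.d_kg)).sum(axis=1) - mu.sum(axis=1) + np.log(model.pi_k)
    return ScoreVector.from_scores(scores)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict(
    model: NBLDAModel,
    tests: TestSample | list[TestSample] | CountMatrix,
    score: str = "nblda",
) -> tuple[np.ndarray, np.ndarray]:
    """Classify test samples; returns (class indices, posterior matrix).

    Each test sample's size factor is estimated by the model's recorded
    size-factor method against the training denominators. ``score``
    selects the negative binomial score (default) or the Poisson-limit
    baseline (``"plda"``).
    """
    if isinstance(tests, CountMatrix):
        if tests.gene_ids != model.gene_ids:
            raise ValidationError("test matrix gene identifiers do not match the model")
        tests = [tests.sample(i) for i in range(tests.n_samples)]
    elif isinstance(tests, TestSample):
        tests = [tests]
    score_fn = {"nblda": nblda_score, "plda": plda_score}.get(score)
    if score_fn is None:
        raise ValueError(f"unknown score {score!r}; choose 'nblda' or 'plda'")
    preds = np.empty(len(tests), dtype=np.int64)
    post = np.empty((len(tests), model.K))
    for j, t in enumerate(tests):
        s_star = size_factor_test(t, model.sf)
        sv = score_fn(model, t, s_star)
        preds[j] = sv.predicted
        post[j] = sv.posteriors()
    return preds, post
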