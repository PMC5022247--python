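"""Shared fixtures: small count matrices, random models, and the Bayes oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson

from nblda import CountMatrix, NBLDAModel, SizeFactors, TestSample, labels_from_names


@pytest.fixture
def small_counts() -> CountMatrix:
    """3 genes x 4 samples with varied, hand-readable counts."""
    return CountMatrix(
        counts=np.array([[5, 10, 0, 3], [2, 4, 6, 8], [1, 1, 1, 1]]),
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def small_labels():
    return labels_from_names(["tumor", "normal", "tumor", "normal"])


def make_model(
    rng: np.random.Generator,
    G: int = 10,
    K: int = 2,
    phi_scale: float = 0.5,
    lam_scale: float = 20.0,
) -> NBLDAModel:
    """Random but valid model with unit-sum priors and positive effects."""
    pi = rng.dirichlet(np.full(K, 5.0))
    n = 4
    s = rng.uniform(0.5, 1.5, size=n)
    s /= s.sum()
    return NBLDAModel(
        lambda_g=rng.uniform(1.0, lam_scale, size=G),
        d_kg=np.exp(rng.normal(0.0, 0.5, size=(K, G))),
        pi_k=pi,
        phi_hat=rng.uniform(0.0, phi_scale, size=G),
        sf=SizeFactors(s=s, method="total_count", denominator=float(lam_scale * G)),
        class_names=[f"c{k}" for k in range(K)],
        gene_ids=[f"g{g}" for g in range(G)],
    )


def oracle_posteriors(model: NBLDAModel, test: TestSample, s_star: float) -> np.ndarray:
    """Brute-force Bayes posteriors from the full NB pmf, all constants kept.

    Per gene and class the exact log-pmf (log-Gamma form via scipy's nbinom,
    Poisson at phi = 0) is evaluated and summed across genes; adding
    log-priors and normalizing with logsumexp yields posteriors without
    dropping any class-independent term. Independent of the discriminant
    score implementation.
    """
    x = np.asarray(test.counts)
    log_post = np.empty(model.K)
    for k in range(model.K):
        mu = s_star * model.lambda_g * model.d_kg[k]
        total = np.log(model.pi_k[k])
        for g in range(model.G):
            if model.phi_hat[g] > 0:
                r = 1.0 / model.phi_hat[g]
                p = r / (r + mu[g])
                total += nbinom.logpmf(x[g], r, p)
            else:
                total += poisson.logpmf(x[g], mu[g])
        log_post[k] = total
    return np.exp(log_post - logsumexp(log_post))
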