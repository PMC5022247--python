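"""Synthetic labeled count data from the negative binomial generative design.

Counts are drawn as X_ig | y_i = k ~ NB(s_i * lambda_g * d_kg, phi) with a
common dispersion phi across genes:

- size factors s_i ~ Uniform[0.2, 2.2] i.i.d. (drawn afresh for the test set);
- gene abundances lambda_g ~ Exponential(rate 0.04) i.i.d. (mean 25);
- a fixed fraction ``de_prop`` of genes is differentially expressed:
  log d_kg = z_kg with z_kg ~ N(0, sigma^2) i.i.d. per class and gene;
  the remaining genes have d_kg = 1 exactly;
- class labels are balanced: n // K samples per class, remainder assigned
  to the earliest classes;
- phi = 0 draws from Poisson(mu), matching the NB variance mu + mu^2*phi
  at the boundary.

A single seed drives a hierarchy of independent RNG streams (size factors,
abundances, DE selection, effects, train counts, test counts), so e.g.
enlarging G does not perturb the size-factor draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import CountMatrix, LabelVector

DEFAULT_SF_RANGE = (0.2, 2.2)
DEFAULT_LAMBDA_RATE = 0.04


@dataclass
class SimulationConfig:
    """Parameters of the generative design.

    G genes, n samples (train and test sets each get n), K classes,
    ``de_prop`` fraction of DE genes, sigma the standard deviation of log
    class effects, phi the common dispersion (0 = Poisson). ``phi_chisq_df``
    switches to heterogeneous gene-specific dispersions drawn i.i.d. from a
    chi-squared distribution with that many degrees of freedom.
    """

    G: int = 100
    n: int = 8
    K: int = 2
    de_prop: float = 0.4
    sigma: float = 5.0
    phi: float = 20.0
    sf_range: tuple[float, float] = DEFAULT_SF_RANGE
    lambda_rate: float = DEFAULT_LAMBDA_RATE
    seed: int = 0
    phi_chisq_df: float | None = None  # heterogeneous-dispersion extension

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if self.K < 1 or self.n < self.K:
            raise ValueError("need n >= K >= 1")
        if not 0.0 <= self.de_prop <= 1.0:
            raise ValueError("de_prop must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        lo, hi = self.sf_range
        if not (0 < lo <= hi):
            raise ValueError("sf_range must be a positive interval")
        if self.lambda_rate <= 0:
            raise ValueError("lambda_rate must be > 0")
        if self.phi_chisq_df is not None and self.phi_chisq_df <= 0:
            raise ValueError("phi_chisq_df must be > 0")


@dataclass
class SimulationTruth:
    """Generative parameters behind a simulated dataset."""

    s_train: np.ndarray
    s_test: np.ndarray
    lambda_g: np.ndarray
    d_kg: np.ndarray
    phi_g: np.ndarray  # per-gene; constant vector in the common-phi design
    de_mask: np.ndarray


@dataclass
class SimulatedDataset:
    train: CountMatrix
    train_labels: LabelVector
    test: CountMatrix
    test_labels: LabelVector
    truth: SimulationTruth = field(repr=False)
    config: SimulationConfig = field(repr=False)


def nb_draw(
    mean: float | np.ndarray, phi: float | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Negative binomial draws parameterized by (mean, dispersion).

    Uses r = 1/phi successes and p = r / (r + mean), which gives
    E = mean and Var = mean + mean^2 * phi; phi = 0 falls back to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    if np.any(mean <= 0):
        raise ValueError("negative binomial mean must be positive")
    if np.any(phi < 0):
        raise ValueError("dispersion must be non-negative")
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi == 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def balanced_labels(n: int, K: int, class_names: list[str] | None = None) -> LabelVector:
    """n // K samples per class, remainder going to the earliest classes."""
    base, extra = divmod(n, K)
    counts = [base + (1 if k < extra else 0) for k in range(K)]
    labels = np.concatenate([np.full(c, k + 1, dtype=np.int64) for k, c in enumerate(counts)])
    names = class_names or [f"class{k + 1}" for k in range(K)]
    return LabelVector(labels=labels, class_names=names)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a labeled train/test pair plus ground truth, reproducibly."""
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_sf_train, rng_sf_test, rng_genes, rng_effects, rng_train, rng_test = map(
        np.random.default_rng, streams
    )

    lo, hi = config.sf_range
    s_train = rng_sf_train.uniform(lo, hi, size=config.n)
    s_test = rng_sf_test.uniform(lo, hi, size=config.n)
    lam = rng_genes.exponential(scale=1.0 / config.lambda_rate, size=config.G)

    n_de = int(round(config.de_prop * config.G))
    de_idx = rng_genes.choice(config.G, size=n_de, replace=False)
    de_mask = np.zeros(config.G, dtype=bool)
    de_mask[de_idx] = True
    d = np.ones((config.K, config.G))
    d[:, de_mask] = np.exp(rng_effects.normal(0.0, config.sigma, size=(config.K, n_de)))

    if config.phi_chisq_df is not None:
        phi_g = rng_genes.chisquare(config.phi_chisq_df, size=config.G)
    else:
        phi_g = np.full(config.G, config.phi)

    lv = balanced_labels(config.n, config.K)
    gene_ids = [f"g{g + 1}" for g in range(config.G)]

    def draw_counts(s: np.ndarray, rng: np.random.Generator, prefix: str) -> CountMatrix:
        mu = s[None, :] * lam[:, None] * d[lv.labels - 1].T  # (G, n)
        X = nb_draw(mu, phi_g[:, None], rng)
        ids = [f"{prefix}{i + 1}" for i in range(config.n)]
        return CountMatrix(counts=X, gene_ids=gene_ids, sample_ids=ids)

    train = draw_counts(s_train, rng_train, "train")
    test = draw_counts(s_test, rng_test, "test")
    truth = SimulationTruth(
        s_train=s_train, s_test=s_test, lambda_g=lam, d_kg=d, phi_g=phi_g, de_mask=de_mask
    )
    test_lv = LabelVector(labels=lv.labels.copy(), class_names=list(lv.class_names))
    return SimulatedDataset(
        train=train, train_labels=lv, test=test, test_labels=test_lv,
        truth=truth, config=config,
    )
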