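"""Gene-wise dispersion estimation with shrinkage toward a common target.

The negative binomial dispersion phi_g links mean and variance through
Var = mu + mu^2 * phi_g. Gene-wise method-of-moments (MoM) estimates are
noisy at small n, so they are shrunk toward a common target xi by a
convex combination

    phi_hat_g = delta * xi + (1 - delta) * phi_tilde_g,

with weight

    delta = [sum_g (phi_tilde_g - mean(phi_tilde))^2 / (G-1)]
          / [sum_g (phi_tilde_g - xi)^2        / (G-2)],

clamped to [0, 1] so the result is always between the gene estimate and
the target.

The target xi is chosen by one of two strategies. The literal criterion
"minimize the average squared difference between phi_tilde and phi_hat"
is degenerate: the objective equals delta(xi)^2 * mean((xi - phi_tilde)^2),
which decreases without bound as xi -> +/-inf because delta(xi) falls like
1/(xi - mean)^2. The default strategy therefore takes xi = mean(phi_tilde)
(the natural pooled center, toward which shrinkage contracts the
cross-gene variance); a bounded "grid" strategy minimizes the same
objective over [min phi_tilde, max phi_tilde] instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import CountMatrix, LabelVector, ValidationError
from .normalization import SizeFactors

XI_STRATEGIES = ("mean", "grid")
DEFAULT_XI_STRATEGY = "mean"
_GRID_POINTS = 100


@dataclass
class DispersionFit:
    """Initial MoM estimates, shrinkage target/weight, and shrunk estimates."""

    phi_initial: np.ndarray  # phi_tilde_g >= 0
    xi: float
    delta: float
    phi_hat: np.ndarray  # delta*xi + (1-delta)*phi_tilde_g
    xi_strategy: str = DEFAULT_XI_STRATEGY

    def __post_init__(self) -> None:
        self.phi_initial = np.asarray(self.phi_initial, dtype=float)
        self.phi_hat = np.asarray(self.phi_hat, dtype=float)
        if not 0.0 <= self.delta <= 1.0:
            raise ValidationError(f"delta must lie in [0,1], got {self.delta}")
        if np.any(self.phi_initial < 0) or np.any(self.phi_hat < 0) or self.xi < 0:
            raise ValidationError("dispersions must be non-negative")


def mom_dispersion(
    train: CountMatrix,
    sf: SizeFactors,
    labels: LabelVector | None = None,
    within_class: bool = False,
) -> np.ndarray:
    """Method-of-moments dispersion estimates on size-factor-normalized counts.

    Per gene: phi_tilde = max(0, (v - m) / m^2) where m and v are the mean
    and unbiased variance of X_ig / s_i. Negative raw values (under- or
    equi-dispersion) clamp to 0; all-zero genes get 0.

    By default moments are pooled across all training samples, matching how
    a single class-independent phi_g enters the discriminant score. With
    ``within_class=True`` the moments are taken per class and the resulting
    estimates averaged with weights (n_k - 1) / (n - K), for sensitivity
    analysis when class effects inflate the pooled variance.
    """
    if train.n_samples < 2:
        raise ValidationError("at least two samples are needed to estimate dispersion")
    Z = train.counts / sf.s[None, :]
    if within_class:
        if labels is None:
            raise ValidationError("within_class dispersion requires labels")
        num = np.zeros(train.n_genes)
        den = 0.0
        for k in range(1, labels.K + 1):
            cols = labels.labels == k
            nk = int(cols.sum())
            if nk < 2:
                continue
            num += (nk - 1) * _mom_from_normalized(Z[:, cols])
            den += nk - 1
        if den == 0:
            raise ValidationError("no class has >= 2 samples; cannot estimate within-class moments")
        return num / den
    return _mom_from_normalized(Z)


def _mom_from_normalized(Z: np.ndarray) -> np.ndarray:
    m = Z.mean(axis=1)
    v = Z.var(axis=1, ddof=1)
    phi = np.zeros(Z.shape[0])
    pos = m > 0
    phi[pos] = np.maximum(0.0, (v[pos] - m[pos]) / m[pos] ** 2)
    return phi


def select_xi(phi_initial: np.ndarray, strategy: str = DEFAULT_XI_STRATEGY) -> float:
    """Choose the shrinkage target xi from the initial estimates."""
    phi = np.asarray(phi_initial, dtype=float)
    if phi.size < 3:
        raise ValidationError("xi selection requires at least 3 genes")
    if not np.all(np.isfinite(phi)):
        raise ValidationError("non-finite initial dispersion estimates")
    if strategy == "mean":
        return float(phi.mean())
    if strategy == "grid":
        lo, hi = float(phi.min()), float(phi.max())
        if lo == hi:
            return lo
        grid = np.linspace(lo, hi, _GRID_POINTS)
        # objective = mean((phi_hat(xi) - phi_tilde)^2) = delta(xi)^2 * mean((xi-phi_tilde)^2)
        obj = np.array(
            [shrinkage_weight(phi, x) ** 2 * np.mean((x - phi) ** 2) for x in grid]
        )
        return float(grid[int(np.argmin(obj))])  # argmin ties break toward smaller xi
    raise ValueError(f"unknown xi strategy {strategy!r}; choose from {XI_STRATEGIES}")


def shrinkage_weight(phi_initial: np.ndarray, xi: float) -> float:
    """Weight delta on the target, clamped to [0, 1].

    The ratio compares the cross-gene variance of the initial estimates
    (divisor G-1) with their mean squared distance to the target (divisor
    G-2). If every initial estimate already equals xi the ratio is 0/0;
    full shrinkage (delta = 1) is returned, which leaves the estimates
    unchanged since they all equal the target.
    """
    phi = np.asarray(phi_initial, dtype=float)
    G = phi.size
    if G < 3:
        raise ValidationError("shrinkage weight requires at least 3 genes")
    num = float(np.sum((phi - phi.mean()) ** 2)) / (G - 1)
    den = float(np.sum((phi - xi) ** 2)) / (G - 2)
    if den == 0.0:
        return 1.0
    return float(min(1.0, max(0.0, num / den)))


def shrink_dispersion(
    train: CountMatrix,
    sf: SizeFactors,
    xi_strategy: str = DEFAULT_XI_STRATEGY,
    labels: LabelVector | None = None,
    within_class: bool = False,
) -> DispersionFit:
    """Full pipeline: MoM estimates, target, weight, shrunk dispersions."""
    phi_tilde = mom_dispersion(train, sf, labels=labels, within_class=within_class)
    xi = select_xi(phi_tilde, strategy=xi_strategy)
    delta = shrinkage_weight(phi_tilde, xi)
    phi_hat = delta * xi + (1.0 - delta) * phi_tilde
    return DispersionFit(
        phi_initial=phi_tilde, xi=xi, delta=delta, phi_hat=phi_hat, xi_strategy=xi_strategy
    )
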