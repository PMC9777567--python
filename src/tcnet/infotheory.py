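"""Entropy, mutual information and Total Correlation.

Exact formulas on small discrete joints and on Gaussian models serve as
oracles; sample-based estimators (equal-frequency binned plug-in,
Gaussian-copula, matrix-based Renyi alpha-entropy) handle continuous data.

All quantities are in bits (log base 2) by default; every function takes a
``base`` argument for nats (``base=np.e``) or other bases.

Total Correlation (multi-information) of X1..Xn is

    TC(X) = sum_i H(Xi) - H(X1..Xn)
          = KL( p(x1..xn) || prod_i p(xi) )

It is zero iff the variables are jointly independent, and reduces to mutual
information for n = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
from scipy.special import ndtri, rel_entr
from scipy.stats import rankdata

from .data import TimeSeriesMatrix, ValidationError

__all__ = [
    "DiscreteJoint",
    "GaussianModel",
    "entropy_discrete",
    "mutual_information_discrete",
    "total_correlation_discrete",
    "conditional_total_correlation_discrete",
    "tc_decomposition_residual",
    "gaussian_total_correlation",
    "binned_tc_estimate",
    "copula_tc_estimate",
    "renyi_matrix_tc",
    "equal_frequency_bins",
]


# --------------------------------------------------------------------------
# discrete joints
# --------------------------------------------------------------------------
@dataclass
class DiscreteJoint:
    """Explicit joint probability table over a small discrete system.

    ``probabilities`` is an n-dimensional table whose axis order matches
    ``variable_names``; row-major (C) order over outcomes.  This is the
    brute-force oracle substrate: every information quantity on it is exact.
    """

    variable_names: list[str]
    probabilities: np.ndarray
    cardinalities: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if not self.cardinalities:
            self.cardinalities = list(self.probabilities.shape)
        self.probabilities = self.probabilities.reshape(self.cardinalities)
        if len(self.variable_names) != self.probabilities.ndim:
            raise ValidationError("one name per table axis required")
        if len(set(self.variable_names)) != len(self.variable_names):
            raise ValidationError("variable names must be unique")
        if np.any(self.probabilities < -1e-15):
            raise ValidationError("negative probability")
        self.probabilities = np.clip(self.probabilities, 0.0, None)
        tot = self.probabilities.sum()
        if abs(tot - 1.0) > 1e-12:
            raise ValidationError(f"probabilities sum to {tot}, not 1")

    @property
    def n_vars(self) -> int:
        return len(self.variable_names)

    def _axes(self, names: Sequence[str]) -> list[int]:
        try:
            return [self.variable_names.index(n) for n in names]
        except ValueError as e:  # pragma: no cover - message detail
            raise ValidationError(str(e)) from e

    def marginal(self, names: Sequence[str]) -> "DiscreteJoint":
        """Marginal joint over ``names`` (axis order follows ``names``)."""
        if len(names) == 0:
            raise ValidationError("empty variable subset")
        keep = self._axes(names)
        drop = tuple(i for i in range(self.n_vars) if i not in keep)
        tab = self.probabilities.sum(axis=drop) if drop else self.probabilities
        # reorder remaining axes to requested order
        remaining = [i for i in range(self.n_vars) if i not in drop]
        perm = [remaining.index(k) for k in keep]
        tab = np.transpose(tab, perm)
        return DiscreteJoint([str(n) for n in names], tab)

    @classmethod
    def from_samples(
        cls, labels: np.ndarray, names: Sequence[str] | None = None,
        cardinalities: Sequence[int] | None = None,
    ) -> "DiscreteJoint":
        """Empirical joint from an (n_samples, n_vars) integer label matrix."""
        labels = np.asarray(labels, dtype=int)
        n, p = labels.shape
        if cardinalities is None:
            cardinalities = [int(labels[:, j].max()) + 1 for j in range(p)]
        flat = np.ravel_multi_index(tuple(labels.T), tuple(cardinalities))
        counts = np.bincount(flat, minlength=int(np.prod(cardinalities)))
        probs = counts.reshape(tuple(cardinalities)) / n
        if names is None:
            names = [f"V{j}" for j in range(p)]
        return cls(list(names), probs)

    @classmethod
    def random(
        cls, cardinalities: Sequence[int], rng: np.random.Generator,
        names: Sequence[str] | None = None,
    ) -> "DiscreteJoint":
        """Symmetric Dirichlet(1) draw over all outcome cells (test substrate)."""
        k = int(np.prod(cardinalities))
        probs = rng.dirichlet(np.ones(k)).reshape(tuple(cardinalities))
        if names is None:
            names = [f"V{j}" for j in range(len(cardinalities))]
        return cls(list(names), probs)


def _plogp_sum(p: np.ndarray, base: float) -> float:
    # -sum p log p with 0 log 0 := 0
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


def entropy_discrete(
    joint: DiscreteJoint, axes: Sequence[str] | None = None, base: float = 2.0
) -> float:
    """Shannon entropy H of the marginal on ``axes`` (all variables if None)."""
    if axes is None:
        axes = joint.variable_names
    if len(axes) == 0:
        raise ValidationError("axes must be a non-empty variable subset")
    marg = joint.marginal(axes)
    return _plogp_sum(marg.probabilities.ravel(), base)


def mutual_information_discrete(
    joint: DiscreteJoint, group_a: Sequence[str], group_b: Sequence[str],
    base: float = 2.0,
) -> float:
    """I(A;B) = H(A) + H(B) - H(A,B) for disjoint variable groups."""
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    ha = entropy_discrete(joint, group_a, base)
    hb = entropy_discrete(joint, group_b, base)
    hab = entropy_discrete(joint, list(group_a) + list(group_b), base)
    return ha + hb - hab


def total_correlation_discrete(joint: DiscreteJoint, base: float = 2.0) -> float:
    """TC = sum_i H(Xi) - H(X); zero iff the joint factorises."""
    if joint.n_vars < 2:
        raise ValidationError("Total Correlation requires >= 2 variables")
    hs = sum(entropy_discrete(joint, [n], base) for n in joint.variable_names)
    return hs - entropy_discrete(joint, None, base)


def total_correlation_discrete_kl(joint: DiscreteJoint, base: float = 2.0) -> float:
    """TC via KL( joint || product of marginals ) — independent cross-check."""
    if joint.n_vars < 2:
        raise ValidationError("Total Correlation requires >= 2 variables")
    prod = np.ones(1)
    for n in joint.variable_names:
        prod = np.multiply.outer(prod, joint.marginal([n]).probabilities)
    prod = prod.reshape(joint.probabilities.shape)
    kl_nats = rel_entr(joint.probabilities, prod).sum()
    return float(kl_nats / np.log(base))


def conditional_total_correlation_discrete(
    joint: DiscreteJoint, targets: Sequence[str],
    conditioners: Sequence[str] = (), base: float = 2.0,
) -> float:
    """TC(X|Y) = sum_i H(Xi|Y) - H(X|Y); empty Y degenerates to TC(X)."""
    if len(targets) < 2:
        raise ValidationError("need >= 2 target variables")
    if set(targets) & set(conditioners):
        raise ValidationError("targets and conditioners must be disjoint")
    if len(conditioners) == 0:
        return total_correlation_discrete(joint.marginal(targets), base)
    hy = entropy_discrete(joint, conditioners, base)
    total = 0.0
    for t in targets:
        total += entropy_discrete(joint, [t] + list(conditioners), base) - hy
    h_all = entropy_discrete(joint, list(targets) + list(conditioners), base) - hy
    return total - h_all


def tc_decomposition_residual(
    joint: DiscreteJoint, targets: Sequence[str], latent: Sequence[str],
    base: float = 2.0,
) -> float:
    """|[TC(X) - TC(X|Y)] - [sum_i I(Xi;Y) - I(X;Y)]|.

    Both sides of the latent-factor decomposition identity are computed
    independently from the joint; the residual is zero (to rounding) for
    every valid joint, so this doubles as a self-test of the discrete stack.
    """
    lhs = total_correlation_discrete(joint.marginal(targets), base) - \
        conditional_total_correlation_discrete(joint, targets, latent, base)
    rhs = sum(mutual_information_discrete(joint, [t], latent, base) for t in targets)
    rhs -= mutual_information_discrete(joint, targets, latent, base)
    return abs(lhs - rhs)


# --------------------------------------------------------------------------
# Gaussian closed forms
# --------------------------------------------------------------------------
@dataclass
class GaussianModel:
    """Multivariate Gaussian with symmetric positive-definite covariance."""

    covariance: np.ndarray
    mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        d = self.covariance.shape[0]
        if self.covariance.shape != (d, d):
            raise ValidationError("covariance must be square")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValidationError("covariance must be symmetric (atol 1e-10)")
        if self.mean is None:
            self.mean = np.zeros(d)
        self.mean = np.asarray(self.mean, dtype=float)
        if self.mean.shape != (d,):
            raise ValidationError("mean/covariance dimension mismatch")
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValidationError("covariance must be positive definite")


def gaussian_total_correlation(
    model: GaussianModel | np.ndarray, base: float = 2.0
) -> float:
    """Closed-form TC of a Gaussian: 0.5 * log( prod_i sigma_ii / det Sigma ).

    For two variables with correlation rho this is -0.5*log(1 - rho^2).
    Accepts a GaussianModel or a bare covariance/correlation matrix.
    """
    if not isinstance(model, GaussianModel):
        model = GaussianModel(np.asarray(model, dtype=float))
    cov = model.covariance
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValidationError("covariance not positive definite")
    log_num = np.log(np.diag(cov)).sum()
    return float(0.5 * (log_num - logdet) / np.log(base))


# --------------------------------------------------------------------------
# sample-based estimators
# --------------------------------------------------------------------------
def equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Deterministic equal-frequency discretisation into labels 0..n_bins-1.

    Ties are broken by sample order (ordinal ranks), which keeps the bin
    counts exactly balanced and the mapping reproducible.
    """
    x = np.asarray(x, dtype=float)
    if x.max() == x.min():
        raise ValidationError("constant column: quantile bins undefined")
    ranks = rankdata(x, method="ordinal") - 1  # 0..n-1
    return (ranks * n_bins // len(x)).astype(int)


def binned_tc_estimate(
    ts: TimeSeriesMatrix, n_bins: int = 8, base: float = 2.0
) -> float:
    """Plug-in TC from an equal-frequency-binned empirical joint.

    The plug-in estimator carries a positive bias of roughly
    (prod_i k_i - sum_i k_i + d - 1) / (2 N ln 2) bits (k_i bins per column,
    d columns, N samples), so the bin count should be chosen such that the
    number of joint cells stays well below the sample size.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if ts.n_samples < n_bins:
        raise ValidationError("need at least n_bins rows")
    bad = ts.constant_columns()
    if bad:
        raise ValidationError(f"constant column(s): {bad}")
    labels = np.column_stack(
        [equal_frequency_bins(ts.values[:, j], n_bins) for j in range(ts.n_vars)]
    )
    joint = DiscreteJoint.from_samples(labels, ts.names,
                                       cardinalities=[n_bins] * ts.n_vars)
    return total_correlation_discrete(joint, base)


def copula_tc_estimate(ts: TimeSeriesMatrix, base: float = 2.0) -> float:
    """Gaussian-copula TC: rank-Gaussianise margins, then the Gaussian closed
    form on the empirical correlation matrix of the transformed data.

    A single-pass member of the Gaussianisation family: it captures the
    dependence expressible through a Gaussian copula and is invariant to
    monotone transforms of the margins.  Ties get average ranks; ranks are
    mapped through (r - 0.5)/n before the normal quantile function so the
    transform never produces infinities.
    """
    if ts.n_samples <= ts.n_vars:
        raise ValidationError("need more rows than columns")
    n = ts.n_samples
    z = np.empty_like(ts.values)
    for j in range(ts.n_vars):
        r = rankdata(ts.values[:, j], method="average")
        z[:, j] = ndtri((r - 0.5) / n)
    corr = np.corrcoef(z, rowvar=False)
    corr = np.atleast_2d(corr)
    # guard tiny negative eigenvalues from near-ties
    w = np.linalg.eigvalsh(corr)
    if w.min() <= 0:
        corr = corr + (abs(w.min()) + 1e-10) * np.eye(corr.shape[0])
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return gaussian_total_correlation(corr, base)


def _renyi_entropy_from_gram(gram: np.ndarray, alpha: float, base: float) -> float:
    a = gram / np.trace(gram)
    lam = np.linalg.eigvalsh(a)
    if lam.min() < 0:
        if lam.min() < -1e-8:
            warnings.warn("clipping negative Gram eigenvalues at 0")
        lam = np.clip(lam, 0.0, None)
        lam = lam / lam.sum()
    lam = lam[lam > 0]
    return float(np.log((lam ** alpha).sum()) / ((1.0 - alpha) * np.log(base)))


def renyi_matrix_tc(
    ts: TimeSeriesMatrix, alpha: float = 1.01, kernel_width: float | None = None,
    base: float = 2.0, max_samples: int = 2000, seed: int = 0,
) -> float:
    """Matrix-based Renyi alpha-order TC from Gaussian-kernel Gram matrices.

    Per variable, a Gram matrix K_ij = exp(-(x_i-x_j)^2 / (2 w^2)) is
    trace-normalised and its eigenvalue spectrum yields
    S_alpha = log(sum lambda^alpha)/(1-alpha); the joint entropy uses the
    trace-normalised Hadamard product of the per-variable Grams.  TC is
    sum_i S_alpha(Xi) - S_alpha(X).  The kernel width defaults to the
    per-variable median pairwise distance (floored at 1e-6).

    The Gram matrices are n x n, so for very long series the estimator works
    on an evenly strided subsample of at most ``max_samples`` rows.
    """
    if alpha <= 0 or alpha == 1.0:
        raise ValidationError("alpha must be positive and != 1")
    vals = ts.values
    n = vals.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 rows")
    if n > max_samples:
        idx = np.linspace(0, n - 1, max_samples).astype(int)
        vals = vals[idx]
        n = max_samples
    h_sum = 0.0
    joint = np.ones((n, n))
    for j in range(vals.shape[1]):
        x = vals[:, j]
        d = x[:, None] - x[None, :]
        if np.all(d == 0):
            raise ValidationError(f"degenerate column {ts.names[j]}: no spread")
        if kernel_width is None:
            w = np.median(np.abs(d[np.triu_indices(n, 1)]))
            w = max(w, 1e-6)
        else:
            w = max(float(kernel_width), 1e-6)
        gram = np.exp(-(d ** 2) / (2.0 * w * w))
        h_sum += _renyi_entropy_from_gram(gram, alpha, base)
        joint = joint * gram
    h_joint = _renyi_entropy_from_gram(joint, alpha, base)
    return h_sum - h_joint
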