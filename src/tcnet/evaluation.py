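"""Clustering evaluation (purity) and the two synthetic benchmark runners.

Purity matches each found cluster to its most frequent ground-truth class
and reports the fraction of correctly assigned elements:

    Purity(X, Y) = (1/N) * sum_i max_j |Xi ∩ Yj|

where X is the set of clusters and Y the set of classes.  It is 1 for a
perfect clustering; note the documented degeneracy that all-singleton
clusterings are also maximally pure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import TimeSeriesMatrix, ValidationError

__all__ = ["Partition", "purity", "run_experiment1", "run_experiment2"]


@dataclass
class Partition:
    """Disjoint non-empty blocks covering a finite element set."""

    blocks: list[frozenset]

    def __post_init__(self) -> None:
        self.blocks = [frozenset(b) for b in self.blocks]
        if any(len(b) == 0 for b in self.blocks):
            raise ValidationError("empty block")
        seen: set = set()
        for b in self.blocks:
            if seen & b:
                raise ValidationError("blocks must be pairwise disjoint")
            seen |= b
        self._elements = frozenset(seen)

    @classmethod
    def from_blocks(cls, blocks: Iterable[Iterable]) -> "Partition":
        return cls([frozenset(b) for b in blocks])

    @classmethod
    def from_assignment(cls, assignment, unclustered_as_singletons: bool = True) -> "Partition":
        """Partition from a ClusterAssignment; unclustered (-1) variables
        become singleton blocks by default."""
        return cls(assignment.clusters(unclustered_as_singletons))

    @property
    def elements(self) -> frozenset:
        return self._elements

    @property
    def n_elements(self) -> int:
        return len(self._elements)


def purity(clusters: Partition, classes: Partition) -> float:
    """Fraction of elements whose cluster's majority class is their own."""
    if clusters.elements != classes.elements:
        raise ValidationError("clusters and classes must cover the same elements")
    n = clusters.n_elements
    if n < 1:
        raise ValidationError("empty partitions")
    correct = 0
    for c in clusters.blocks:
        correct += max(len(c & k) for k in classes.blocks)
    return correct / n


# --------------------------------------------------------------------------
# benchmark runners
# --------------------------------------------------------------------------
def run_experiment1(
    n_vars: int = 3,
    sample_sizes: Sequence[int] = (100, 500, 1000, 5000, 10000),
    n_seeds: int = 20,
    base_seed: int = 0,
    n_bins: int | None = None,
    renyi_alpha: float = 1.01,
    corex_m: int = 1,
) -> pd.DataFrame:
    """Null-TC estimator comparison on independent Gaussian channels.

    For each sample size and seed, estimates the Total Correlation of
    ``n_vars`` i.i.d. standard-normal columns (ground truth 0 bits) with the
    CorEx bound, the Gaussian-copula estimator, the binned plug-in, and the
    matrix-based Renyi estimator.  Returns a tidy DataFrame with columns
    (n_samples, seed, estimator, tc_bits).

    The binned plug-in bin count defaults to an adaptive rule
    ``max(2, round(n_samples ** (1 / (n_vars + 1))))`` that keeps the joint
    histogram populated; pass ``n_bins`` to fix it.
    """
    from .corex import Corex
    from .infotheory import binned_tc_estimate, copula_tc_estimate, renyi_matrix_tc
    from .synthetic import gen_independent_gaussians

    rows = []
    for n in sample_sizes:
        bins = n_bins if n_bins is not None else max(2, round(n ** (1.0 / (n_vars + 1))))
        for s in range(n_seeds):
            seed = base_seed + s
            ts = gen_independent_gaussians(n_vars, n, seed)
            est = {
                "corex": Corex(ts, layer_sizes=[corex_m], seed=seed).fit().total_bound,
                "copula": copula_tc_estimate(ts),
                "binned": binned_tc_estimate(ts, n_bins=bins),
                "renyi": renyi_matrix_tc(ts, alpha=renyi_alpha),
            }
            for name, val in est.items():
                rows.append(dict(n_samples=n, seed=seed, estimator=name,
                                 tc_bits=float(val)))
    return pd.DataFrame(rows)


def _clusters_for_method(ts: TimeSeriesMatrix, method: str, *,
                         pearson_tau: float, mi_tau: float, mi_bins: int,
                         corex_seed: int, corex_layers: Sequence[int]):
    from . import connectivity as cn
    from .corex import Corex

    if method == "pearson":
        g = cn.threshold_edges(cn.pairwise_correlation(ts), pearson_tau)
        return cn.components_clusters(g)
    if method == "mutual_information":
        g = cn.threshold_edges(cn.pairwise_mi(ts, "binned", mi_bins), mi_tau)
        return cn.components_clusters(g)
    if method == "partial_correlation":
        # "no fixed threshold": keep edges beyond the ~2 standard-error
        # significance level 2/sqrt(n) of a null partial correlation
        tau = 2.0 / np.sqrt(ts.n_samples)
        g = cn.threshold_edges(cn.partial_correlation(ts), tau)
        return cn.components_clusters(g)
    if method == "corex":
        res = Corex(ts, layer_sizes=list(corex_layers), seed=corex_seed).fit()
        return res.clusters(layer=0)
    raise ValidationError(f"unknown method {method!r}")


def run_experiment2(
    n_samples: int = 500,
    coupling_sd: float = 0.5,
    pearson_tau: float = 0.1,
    mi_tau: float = 0.4,
    mi_bins: int = 8,
    corex_layers: Sequence[int] = (2, 1),
    n_seeds: int = 20,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Clustering comparison on the dependent/independent mixture.

    Per seed, generates the six-variable mixture (X1..X3 independent, Y1-Y3
    a Gaussian chain), clusters it with (a) Pearson correlation thresholded
    at ``pearson_tau``, (b) binned pairwise MI thresholded at ``mi_tau``
    bits, (c) partial correlation with the 2/sqrt(n) significance rule, and
    (d) CorEx (argmax alpha*MI over the first layer's factors), then scores
    each against the ground truth {{X1},{X2},{X3},{Y1,Y2,Y3}} with purity.

    Returns a tidy DataFrame (seed, method, threshold, purity, n_clusters).
    Purity over N=6 elements is always a multiple of 1/6.
    """
    from .synthetic import gen_dependent_mixture

    methods = {
        "pearson": pearson_tau,
        "mutual_information": mi_tau,
        "partial_correlation": float("nan"),
        "corex": float("nan"),
    }
    rows = []
    for s in range(n_seeds):
        seed = base_seed + s
        ts, truth = None, None
        for attempt in range(5):
            ts, truth = gen_dependent_mixture(n_samples, coupling_sd, seed + 100000 * attempt)
            if not ts.constant_columns():
                break
        for method, tau in methods.items():
            assignment = _clusters_for_method(
                ts, method, pearson_tau=pearson_tau, mi_tau=mi_tau,
                mi_bins=mi_bins, corex_seed=seed, corex_layers=corex_layers,
            )
            part = Partition.from_assignment(assignment)
            rows.append(dict(
                seed=seed, method=method, threshold=tau,
                purity=purity(part, truth), n_clusters=len(part.blocks),
            ))
    return pd.DataFrame(rows)
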