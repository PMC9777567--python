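"""Pairwise connectivity matrices, thresholded graphs and clustering.

Three pairwise methods (Pearson correlation, mutual information, partial
correlation), edge thresholding to a weighted graph, connected-component
clustering, and construction of the CorEx tree graph with the usual
conventions: edge weight alpha_ij * I(Xi;Yj), node size proportional to the
Total Correlation a factor explains about its children.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx

from .data import TimeSeriesMatrix, ValidationError
from .infotheory import (
    equal_frequency_bins,
    DiscreteJoint,
    mutual_information_discrete,
)
from .corex import CorexHierarchy

__all__ = [
    "ConnectivityMatrix",
    "ConnectivityGraph",
    "ClusterAssignment",
    "pairwise_correlation",
    "pairwise_mi",
    "partial_correlation",
    "threshold_edges",
    "components_clusters",
    "corex_tree_graph",
]

_METHODS = {"pearson", "mutual_information", "partial_correlation"}


@dataclass
class ConnectivityMatrix:
    """Symmetric variable-by-variable dependence matrix.

    Diagonal convention: 1 for correlation methods, 0 for mutual information
    (avoids self-edge artifacts when thresholding).
    """

    values: np.ndarray
    names: list[str]
    method: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValidationError("matrix/names shape mismatch")
        if self.method not in _METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("matrix must be symmetric")

    def write_tsv(self, path) -> None:
        """TSV with a header row and a leading name column."""
        import pandas as pd

        pd.DataFrame(self.values, index=self.names, columns=self.names).to_csv(
            path, sep="\t", float_format="%.17g"
        )


@dataclass
class ClusterAssignment:
    """Mapping variable id -> integer cluster id; -1 marks unclustered."""

    labels: dict[str, int]

    def clusters(self, unclustered_as_singletons: bool = True) -> list[set[str]]:
        """Cluster blocks; unclustered variables become singleton blocks by
        default (they belong to no discovered group)."""
        groups: dict[int, set[str]] = {}
        singles: list[set[str]] = []
        for v, c in self.labels.items():
            if c == -1 and unclustered_as_singletons:
                singles.append({v})
            else:
                groups.setdefault(c, set()).add(v)
        return list(groups.values()) + singles

    def n_clusters(self) -> int:
        return len(self.clusters())


@dataclass
class ConnectivityGraph:
    """Weighted graph over variables (pairwise kind) or variables + latent
    factors (corex_tree kind), backed by a networkx Graph.

    Node attributes: ``label``, ``group`` (anatomical lobe or block tag) and
    ``size`` (Total Correlation explained, 0 for leaf variables).  Edge
    attribute: ``weight``.
    """

    graph: nx.Graph
    kind: str = "pairwise"

    def __post_init__(self) -> None:
        if self.kind not in {"pairwise", "corex_tree"}:
            raise ValidationError(f"unknown graph kind {self.kind!r}")
        if self.kind == "pairwise" and any(u == v for u, v in self.graph.edges):
            raise ValidationError("pairwise graph must have no self-loops")
        if self.kind == "corex_tree" and not nx.is_forest(self.graph):
            raise ValidationError("corex_tree graph must be acyclic")
        for _, _, d in self.graph.edges(data=True):
            if not np.isfinite(d.get("weight", np.nan)):
                raise ValidationError("edge weights must be finite")

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_json(self, path) -> None:
        doc = {
            "kind": self.kind,
            "nodes": [
                {"id": n, "label": d.get("label", str(n)),
                 "group": d.get("group", ""), "size": float(d.get("size", 0.0))}
                for n, d in self.graph.nodes(data=True)
            ],
            "edges": [
                {"source": u, "target": v, "weight": float(d["weight"])}
                for u, v, d in self.graph.edges(data=True)
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)


def _check_input(ts: TimeSeriesMatrix, min_rows: int = 3) -> None:
    if ts.n_samples < min_rows:
        raise ValidationError(f"need at least {min_rows} rows")
    bad = ts.constant_columns()
    if bad:
        raise ValidationError(f"constant column(s): {bad}")


def pairwise_correlation(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Sample Pearson correlation matrix (unit diagonal)."""
    _check_input(ts)
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix((r + r.T) / 2, list(ts.names), "pearson")


def pairwise_mi(
    ts: TimeSeriesMatrix, estimator: str = "binned", n_bins: int = 8
) -> ConnectivityMatrix:
    """Pairwise mutual information in bits (zero diagonal).

    ``estimator='binned'``: plug-in MI on equal-frequency bins.
    ``estimator='copula'``: Gaussian-copula MI, -0.5*log2(1 - rho_z^2) with
    rho_z the correlation of the rank-Gaussianised pair.
    """
    _check_input(ts)
    if estimator not in {"binned", "copula"}:
        raise ValidationError(f"unknown MI estimator {estimator!r}")
    p = ts.n_vars
    out = np.zeros((p, p))
    if estimator == "binned":
        labels = np.column_stack(
            [equal_frequency_bins(ts.values[:, j], n_bins) for j in range(p)]
        )
        for a in range(p):
            for b in range(a + 1, p):
                joint = DiscreteJoint.from_samples(
                    labels[:, [a, b]], ["a", "b"], [n_bins, n_bins]
                )
                out[a, b] = out[b, a] = mutual_information_discrete(joint, ["a"], ["b"])
    else:
        from scipy.special import ndtri
        from scipy.stats import rankdata

        n = ts.n_samples
        z = np.column_stack(
            [ndtri((rankdata(ts.values[:, j], method="average") - 0.5) / n)
             for j in range(p)]
        )
        rho = np.corrcoef(z, rowvar=False)
        rho = np.clip(np.atleast_2d(rho), -0.999999, 0.999999)
        out = -0.5 * np.log2(1.0 - rho ** 2)
        np.fill_diagonal(out, 0.0)
    return ConnectivityMatrix((out + out.T) / 2, list(ts.names), "mutual_information")


def partial_correlation(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Partial correlation from the standardized negated precision matrix:
    rho_ij = -P_ij / sqrt(P_ii P_jj), conditioning each pair on all other
    variables.  Near-singular covariances get a trace-scaled ridge (1e-6)."""
    if ts.n_samples <= ts.n_vars + 1:
        raise ValidationError("need rows > columns + 1")
    _check_input(ts)
    cov = np.cov(ts.values, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        prec = None
    if prec is None or not np.all(np.isfinite(prec)):
        warnings.warn("singular covariance; applying trace-scaled ridge 1e-6")
        ridge = 1e-6 * np.trace(cov) / cov.shape[0]
        prec = np.linalg.inv(cov + ridge * np.eye(cov.shape[0]))
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return ConnectivityMatrix((pc + pc.T) / 2, list(ts.names), "partial_correlation")


def threshold_edges(
    cm: ConnectivityMatrix, tau: float, absolute: bool | None = None
) -> ConnectivityGraph:
    """Keep edges with weight >= tau (|weight| for correlation methods by
    default, raw values for MI); the node set is preserved."""
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    if absolute is None:
        absolute = cm.method != "mutual_information"
    g = nx.Graph()
    for n in cm.names:
        g.add_node(n, label=n, group="", size=0.0)
    p = len(cm.names)
    for a in range(p):
        for b in range(a + 1, p):
            w = cm.values[a, b]
            key = abs(w) if absolute else w
            if key >= tau:
                g.add_edge(cm.names[a], cm.names[b], weight=float(w))
    return ConnectivityGraph(g, "pairwise")


def components_clusters(g: ConnectivityGraph) -> ClusterAssignment:
    """Connected components of a pairwise graph as clusters; isolated nodes
    become singleton clusters."""
    if g.kind != "pairwise":
        raise ValidationError("components clustering expects a pairwise graph")
    labels: dict[str, int] = {}
    for cid, comp in enumerate(sorted(nx.connected_components(g.graph),
                                      key=lambda c: sorted(c)[0])):
        for n in comp:
            labels[n] = cid
    return ClusterAssignment(labels)


def corex_tree_graph(
    h: CorexHierarchy, labels: dict[str, str] | None = None,
    groups: dict[str, str] | None = None, threshold: float = 0.16,
) -> ConnectivityGraph:
    """Tree graph of a fitted hierarchy.

    Leaves are the observed variables (size 0); each layer adds factor nodes
    sized by the Total Correlation they explain (normalised to max 1 per
    graph).  Each child connects only to its strongest parent factor, with
    edge weight alpha_ij * I(Xi;Yj) in bits; edges below ``threshold`` are
    dropped for legibility.
    """
    if not h.layers:
        raise ValidationError("hierarchy has no fitted layers")
    labels = labels or {}
    groups = groups or {}
    g = nx.Graph()
    for name in h.input_names:
        g.add_node(name, label=labels.get(name, name),
                   group=groups.get(name, ""), size=0.0)
    sizes: dict[str, float] = {}
    child_ids = list(h.input_names)
    for k, layer in enumerate(h.layers):
        factor_ids = [f"L{k + 1}F{j}" for j in range(layer.n_factors)]
        for j, fid in enumerate(factor_ids):
            sizes[fid] = max(float(layer.factor_tc[j]), 0.0)
            g.add_node(fid, label=fid, group=f"layer{k + 1}", size=sizes[fid])
        w = layer.alpha * layer.mi_table
        for i, child in enumerate(child_ids):
            j = int(np.argmax(w[i]))
            if w[i, j] >= threshold:
                g.add_edge(child, factor_ids[j], weight=float(w[i, j]))
        child_ids = factor_ids
    if sizes:
        top = max(sizes.values())
        if top > 0:
            for fid, s in sizes.items():
                g.nodes[fid]["size"] = s / top
    return ConnectivityGraph(g, "corex_tree")
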