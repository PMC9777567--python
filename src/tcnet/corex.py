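"""Correlation Explanation (CorEx): latent factors that explain Total Correlation.

The model searches for m discrete latent factors Y = (Y1..Ym) with a
factorised posterior p(y|x) = prod_j p(yj|x) that maximise a tractable lower
bound on the Total Correlation of the observed variables X:

    TC(X) >= sum_j [ sum_i alpha_ij I(Xi;Yj) - I(Yj;X) ]

where alpha_ij in [0,1] are soft variable-to-factor assignment weights.
Stacking layers — each layer fit on the representation of the one below —
tightens the bound additively and yields an interpretable hierarchy: each
factor "explains" the Total Correlation of its children, and argmax_j
alpha_ij * I(Xi;Yj) clusters the variables.

Model of the data given a factor state: each observed variable is Gaussian
per latent state, p(xi | yj = s) = N(mu_ijs, var_ijs) (inputs are z-scored
internally, so the unconditional margins are approximately N(0,1)).  The fit
alternates a factorised E-step, Gaussian M-step, a plug-in MI table, and the
exponential alpha-competition update

    alpha* = exp(gamma * (I(Xi;Yj) - max_j I(Xi;Yj)))
    alpha <- (1 - lam) * alpha + lam * alpha*

All information quantities are in bits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data import TimeSeriesMatrix, ValidationError, zscore_columns

__all__ = [
    "CorexConfig",
    "CorexLayer",
    "CorexHierarchy",
    "Corex",
    "CorexResults",
    "fit_layer",
    "fit_hierarchy",
    "layer_bound",
    "assign_clusters",
    "serialize_model",
    "load_model",
]

_LN2 = np.log(2.0)
_SCHEMA = "tcnet-corex-1"


@dataclass
class CorexConfig:
    """Hyper-parameters of the CorEx optimiser.

    layer_sizes : factors per layer, e.g. [10, 3, 1]
    n_states    : discrete states per latent factor
    lam         : smoothing constant of the alpha update, in (0, 1]
    gamma       : sharpness of the alpha competition, > 0
    max_iter    : iteration cap per layer
    tol         : bound-change convergence tolerance in bits; the fit stops
                  when |delta bound| < tol over a 10-iteration window
    seed        : base RNG seed; restarts use seed + 1000*r
    n_restarts  : random restarts per layer, best final bound kept
    """

    layer_sizes: list[int] = field(default_factory=lambda: [1])
    n_states: int = 2
    lam: float = 0.3
    gamma: float = 10.0
    max_iter: int = 200
    tol: float = 1e-5
    seed: int = 0
    n_restarts: int = 3
    window: int = 10
    var_floor: float = 1e-4

    def __post_init__(self) -> None:
        self.layer_sizes = [int(m) for m in self.layer_sizes]
        if not self.layer_sizes or any(m < 1 for m in self.layer_sizes):
            raise ValidationError("layer_sizes must be positive integers")
        if any(b > a for a, b in zip(self.layer_sizes, self.layer_sizes[1:])):
            warnings.warn("layer_sizes increase between layers; hierarchy may be degenerate")
        if not (0 < self.lam <= 1):
            raise ValidationError("lam must be in (0, 1]")
        if self.gamma <= 0:
            raise ValidationError("gamma must be positive")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.n_states < 2:
            raise ValidationError("n_states must be >= 2")
        if self.max_iter < 1 or self.n_restarts < 1:
            raise ValidationError("max_iter and n_restarts must be >= 1")


@dataclass
class CorexLayer:
    """One fitted layer: m discrete factors over n input variables."""

    input_names: list[str]
    alpha: np.ndarray            # (n, m) weights in [0, 1]
    state_priors: np.ndarray     # (m, s) p(yj = s)
    state_means: np.ndarray      # (n, m, s) mean of p(xi | yj = s)
    state_vars: np.ndarray       # (n, m, s) variance of p(xi | yj = s)
    mi_table: np.ndarray         # (n, m) I(Xi;Yj) in bits
    iyx: np.ndarray              # (m,) I(Yj;X) in bits
    factor_tc: np.ndarray        # (m,) per-factor contribution to the bound
    bound_history: list[float]
    posteriors: np.ndarray | None = None  # (T, m, s); None after load
    seed: int | None = None

    @property
    def n_inputs(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_factors(self) -> int:
        return self.alpha.shape[1]

    @property
    def bound(self) -> float:
        return float(self.factor_tc.sum())

    def representation(self, map_states: bool = False) -> np.ndarray:
        """Per-sample factor representation passed to the next layer.

        Default: posterior mean of the state index (continuous in
        [0, n_states-1]); ``map_states=True`` gives hard MAP labels instead.
        """
        if self.posteriors is None:
            raise ValidationError("layer has no stored posteriors (loaded from file?)")
        if map_states:
            return np.argmax(self.posteriors, axis=2).astype(float)
        states = np.arange(self.posteriors.shape[2], dtype=float)
        return np.einsum("tjs,s->tj", self.posteriors, states)


@dataclass
class CorexHierarchy:
    """Stack of fitted layers; layer k consumes layer k-1's representation."""

    layers: list[CorexLayer]
    input_names: list[str]
    config: CorexConfig

    @property
    def total_bound(self) -> float:
        return float(sum(l.bound for l in self.layers))


def layer_bound(layer: CorexLayer) -> float:
    """Recompute sum_j [ sum_i alpha_ij I(Xi;Yj) - I(Yj;X) ] from the stored
    weights and MI table; equals the last bound_history entry to 1e-8."""
    if layer.alpha is None or layer.mi_table is None:
        raise ValidationError("layer is not fitted")
    return float((layer.alpha * layer.mi_table).sum() - layer.iyx.sum())


# --------------------------------------------------------------------------
# single-layer optimiser
# --------------------------------------------------------------------------
def _column_hashes(x: np.ndarray) -> list[int]:
    """Stable 64-bit hash per column; ties the random initialisation to the
    column *content* so fits are equivariant under column permutations."""
    import hashlib

    out = []
    for j in range(x.shape[1]):
        h = hashlib.blake2b(np.ascontiguousarray(x[:, j]).tobytes(),
                            digest_size=8).digest()
        out.append(int.from_bytes(h, "little"))
    return out


def _fit_single(
    x: np.ndarray, m: int, cfg: CorexConfig, seed: int, col_hashes: list[int]
) -> dict:
    n, p = x.shape
    s = cfg.n_states
    # per-column RNG streams keyed by (restart seed, column content)
    mu0 = np.empty((p, m, s))
    jitter = np.empty((p, m))
    for i in range(p):
        rng_i = np.random.default_rng([seed, col_hashes[i]])
        # symmetry breaking: random per-state means seed the first E-step
        # (a dead uniform posterior is a fixed point of the updates otherwise)
        mu0[i] = rng_i.normal(scale=0.5, size=(m, s))
        jitter[i] = rng_i.random(m)
    alpha = np.full((p, m), 1.0 / m) + 1e-3 * jitter
    x2 = x * x
    log_prior = np.full((m, s), -np.log(s))
    var0 = np.ones((p, m, s))
    diff0 = x[:, :, None, None] - mu0[None]
    log_pdf0 = -0.5 * diff0 * diff0 / var0[None] - 0.5 * np.log(2 * np.pi * var0)[None]
    log_mix0 = logsumexp(log_pdf0 + log_prior[None, None], axis=3)
    log_q = log_prior[None] + np.einsum("ij,tijs->tjs", alpha, log_pdf0 - log_mix0[..., None])
    q = np.exp(log_q - logsumexp(log_q, axis=2, keepdims=True))
    bound_history: list[float] = []
    best: dict | None = None
    converged = False
    for _ in range(cfg.max_iter):
        # ---- M-step: priors and per-state Gaussian marginals from soft counts
        nk = q.sum(axis=0)                                   # (m, s)
        prior = np.clip(nk / n, 1e-10, None)
        prior = prior / prior.sum(axis=1, keepdims=True)
        log_prior = np.log(prior)
        mu = np.einsum("tjs,ti->ijs", q, x) / nk[None, :, :]
        var = np.einsum("tjs,ti->ijs", q, x2) / nk[None, :, :] - mu * mu
        var = np.clip(var, cfg.var_floor, None)
        # ---- per-sample log densities and log-likelihood ratios
        diff = x[:, :, None, None] - mu[None, :, :, :]        # (t, i, j, s)
        log_pdf = -0.5 * diff * diff / var[None] - 0.5 * np.log(2 * np.pi * var)[None]
        log_mix = logsumexp(log_pdf + log_prior[None, None], axis=3)  # (t, i, j)
        llr = log_pdf - log_mix[..., None]
        # ---- E-step: factorised posterior over latent states
        log_q = log_prior[None] + np.einsum("ij,tijs->tjs", alpha, llr)
        log_q = log_q - logsumexp(log_q, axis=2, keepdims=True)
        q = np.exp(log_q)
        # ---- plug-in information quantities (bits)
        mi = np.einsum("tjs,tijs->ij", q, llr) / (n * _LN2)
        mi = np.clip(mi, 0.0, None)
        iyx = np.einsum("tjs,tjs->j", q, log_q - log_prior[None]) / (n * _LN2)
        iyx = np.clip(iyx, 0.0, None)
        # the bound is accounted with row-normalised weights (sum <= 1) so
        # no variable's dependence is credited to more than one factor while
        # factors are still competing for it
        alpha_acc = alpha / np.clip(alpha.sum(axis=1, keepdims=True), 1.0, None)
        bound = float((alpha_acc * mi).sum() - iyx.sum())
        if not np.isfinite(bound):
            raise FloatingPointError("non-finite bound")
        # incumbent tracking: the model returned is the best iterate seen,
        # and the history records the incumbent bound (the convergence curve
        # of a hill-climber), so transient dips while factors compete for
        # the same variables never degrade the final model
        if best is None or bound > best["bound"]:
            best = dict(alpha=alpha_acc, prior=np.exp(log_prior), mu=mu,
                        var=var, mi=mi, iyx=iyx, posteriors=q, bound=bound)
        bound_history.append(best["bound"])
        # ---- alpha competition update
        alpha_star = np.exp(cfg.gamma * (mi - mi.max(axis=1, keepdims=True)))
        alpha = (1.0 - cfg.lam) * alpha + cfg.lam * alpha_star
        if len(bound_history) > cfg.window:
            recent = np.diff(bound_history[-(cfg.window + 1):])
            if np.all(np.abs(recent) < cfg.tol):
                converged = True
                break
    factor_tc = (best["alpha"] * best["mi"]).sum(axis=0) - best["iyx"]
    return dict(
        alpha=best["alpha"], prior=best["prior"], mu=best["mu"], var=best["var"],
        mi=best["mi"], iyx=best["iyx"], factor_tc=factor_tc,
        bound_history=bound_history, posteriors=best["posteriors"],
        converged=converged,
    )


def fit_layer(
    ts: TimeSeriesMatrix, config: CorexConfig | None = None, m: int | None = None,
    _allow_constant: bool = False,
) -> CorexLayer:
    """Fit one CorEx layer with ``m`` factors (best of ``n_restarts``)."""
    cfg = config or CorexConfig()
    if m is None:
        m = cfg.layer_sizes[0]
    if m < 1:
        raise ValidationError("m must be >= 1")
    if m > ts.n_vars:
        raise ValidationError(f"more factors ({m}) than input variables ({ts.n_vars})")
    bad = ts.constant_columns()
    if bad and not _allow_constant:
        raise ValidationError(f"constant input column(s): {bad}")
    if ts.n_samples < 10 * m:
        warnings.warn(f"only {ts.n_samples} samples for {m} factors; fit may be unstable")
    x = zscore_columns(ts.values, allow_constant=_allow_constant)
    col_hashes = _column_hashes(x)
    best: dict | None = None
    best_seed = None
    errors = []
    for r in range(cfg.n_restarts):
        seed_r = cfg.seed + 1000 * r
        try:
            fit = _fit_single(x, m, cfg, seed_r, col_hashes)
        except FloatingPointError as e:
            errors.append(str(e))
            continue
        if best is None or fit["bound_history"][-1] > best["bound_history"][-1]:
            best = fit
            best_seed = seed_r
    if best is None:
        raise ValidationError(f"all restarts diverged: {errors}")
    return CorexLayer(
        input_names=list(ts.names),
        alpha=best["alpha"],
        state_priors=best["prior"],
        state_means=best["mu"],
        state_vars=best["var"],
        mi_table=best["mi"],
        iyx=best["iyx"],
        factor_tc=best["factor_tc"],
        bound_history=best["bound_history"],
        posteriors=best["posteriors"],
        seed=best_seed,
    )


def fit_hierarchy(ts: TimeSeriesMatrix, config: CorexConfig | None = None) -> CorexHierarchy:
    """Fit a stack of layers; layer k is fit on layer k-1's representation."""
    cfg = config or CorexConfig()
    layers: list[CorexLayer] = []
    current = ts
    for k, m in enumerate(cfg.layer_sizes):
        if m > current.n_vars:
            raise ValidationError(
                f"layer {k}: {m} factors for {current.n_vars} inputs"
            )
        layer = fit_layer(current, cfg, m, _allow_constant=(k > 0))
        layers.append(layer)
        if k + 1 < len(cfg.layer_sizes):
            rep = layer.representation()
            names = [f"L{k + 1}F{j}" for j in range(m)]
            current = TimeSeriesMatrix(rep, names)
    return CorexHierarchy(layers=layers, input_names=list(ts.names), config=cfg)


def assign_clusters(layer: CorexLayer, eps: float = 1e-4):
    """Cluster variables by their dominant factor.

    Variable i goes to argmax_j alpha_ij * I(Xi;Yj) (ties: lowest factor
    index); variables whose best weight is below ``eps`` bits are labelled
    unclustered (-1).
    """
    from .connectivity import ClusterAssignment

    w = layer.alpha * layer.mi_table
    labels = np.argmax(w, axis=1)
    best = w[np.arange(w.shape[0]), labels]
    labels = np.where(best < eps, -1, labels)
    return ClusterAssignment(dict(zip(layer.input_names, labels.astype(int).tolist())))


# --------------------------------------------------------------------------
# serialization (versioned JSON text)
# --------------------------------------------------------------------------
def serialize_model(h: CorexHierarchy, path) -> None:
    """Write a hierarchy as versioned JSON text.

    Weights, MI tables, priors, marginal parameters and bound histories
    round-trip bit-exactly; per-sample posteriors are deliberately not stored
    (they scale with the data, and everything downstream of a saved model —
    bounds, clustering, tree graphs — needs only the parameters).
    """
    doc = {
        "schema": _SCHEMA,
        "input_names": h.input_names,
        "config": asdict(h.config),
        "total_bound": h.total_bound,
        "layers": [
            {
                "input_names": l.input_names,
                "alpha": l.alpha.tolist(),
                "state_priors": l.state_priors.tolist(),
                "state_means": l.state_means.tolist(),
                "state_vars": l.state_vars.tolist(),
                "mi_table": l.mi_table.tolist(),
                "iyx": l.iyx.tolist(),
                "factor_tc": l.factor_tc.tolist(),
                "bound_history": l.bound_history,
                "seed": l.seed,
            }
            for l in h.layers
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> CorexHierarchy:
    """Load a hierarchy written by :func:`serialize_model`."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise ValidationError(f"cannot parse model file: {e}") from e
    if not isinstance(doc, dict) or doc.get("schema") != _SCHEMA:
        raise ValidationError(
            f"unsupported model schema {doc.get('schema') if isinstance(doc, dict) else None!r}; "
            f"expected {_SCHEMA!r}"
        )
    layers = [
        CorexLayer(
            input_names=ld["input_names"],
            alpha=np.array(ld["alpha"], dtype=float),
            state_priors=np.array(ld["state_priors"], dtype=float),
            state_means=np.array(ld["state_means"], dtype=float),
            state_vars=np.array(ld["state_vars"], dtype=float),
            mi_table=np.array(ld["mi_table"], dtype=float),
            iyx=np.array(ld["iyx"], dtype=float),
            factor_tc=np.array(ld["factor_tc"], dtype=float),
            bound_history=list(ld["bound_history"]),
            posteriors=None,
            seed=ld.get("seed"),
        )
        for ld in doc["layers"]
    ]
    cfg = CorexConfig(**doc["config"])
    return CorexHierarchy(layers=layers, input_names=doc["input_names"], config=cfg)


# --------------------------------------------------------------------------
# model / results front-end
# --------------------------------------------------------------------------
class Corex:
    """Hierarchical CorEx model over a time-series matrix.

    Examples
    --------
    >>> model = Corex(ts, layer_sizes=[3, 1], seed=0)   # doctest: +SKIP
    >>> res = model.fit()                                # doctest: +SKIP
    >>> print(res.summary())                             # doctest: +SKIP
    """

    def __init__(self, data, layer_sizes=(1,), **config_kwargs):
        if isinstance(data, TimeSeriesMatrix):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = TimeSeriesMatrix.from_dataframe(data)
        else:
            self.data = TimeSeriesMatrix(np.asarray(data, dtype=float))
        self.config = CorexConfig(layer_sizes=list(layer_sizes), **config_kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, layer_sizes=(1,), **kw) -> "Corex":
        return cls(df, layer_sizes=layer_sizes, **kw)

    def fit(self, seed: int | None = None) -> "CorexResults":
        cfg = self.config
        if seed is not None:
            cfg = CorexConfig(**{**asdict(cfg), "seed": int(seed)})
        hierarchy = fit_hierarchy(self.data, cfg)
        return CorexResults(self, hierarchy)


class CorexResults:
    """Fitted CorEx hierarchy with estimates, diagnostics and a summary."""

    def __init__(self, model: Corex, hierarchy: CorexHierarchy):
        self.model = model
        self.hierarchy = hierarchy

    @property
    def layers(self) -> list[CorexLayer]:
        return self.hierarchy.layers

    @property
    def total_bound(self) -> float:
        """Hierarchy-wide Total Correlation lower bound, in bits."""
        return self.hierarchy.total_bound

    @property
    def alpha(self) -> np.ndarray:
        return self.layers[0].alpha

    @property
    def mi_table(self) -> pd.DataFrame:
        l = self.layers[0]
        return pd.DataFrame(
            l.mi_table, index=l.input_names,
            columns=[f"Y{j}" for j in range(l.n_factors)],
        )

    def clusters(self, layer: int = 0, eps: float = 1e-4):
        return assign_clusters(self.layers[layer], eps=eps)

    def convergence(self, layer: int = 0) -> np.ndarray:
        """Bound value per iteration for the given layer (bits)."""
        return np.asarray(self.layers[layer].bound_history)

    def save(self, path) -> None:
        serialize_model(self.hierarchy, path)

    def summary(self) -> str:
        lines = []
        lines.append("CorEx Total Correlation lower bound")
        lines.append("=" * 52)
        lines.append(f"Observed variables: {len(self.hierarchy.input_names)}")
        lines.append(f"Layer sizes:        {self.hierarchy.config.layer_sizes}")
        lines.append(f"Total bound:        {self.total_bound:.4f} bits")
        for k, l in enumerate(self.layers):
            lines.append("-" * 52)
            lines.append(
                f"Layer {k}: m={l.n_factors}, bound={l.bound:.4f} bits, "
                f"{len(l.bound_history)} iterations"
            )
            for j in range(l.n_factors):
                w = l.alpha[:, j] * l.mi_table[:, j]
                order = np.argsort(w)[::-1]
                top = [
                    f"{l.input_names[i]} ({w[i]:.3f})"
                    for i in order[:4] if w[i] >= 1e-4
                ]
                lines.append(
                    f"  factor {j}: TC explained {l.factor_tc[j]:.4f} bits; "
                    f"children: {', '.join(top) if top else '(none)'}"
                )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<CorexResults layers={self.hierarchy.config.layer_sizes} "
            f"bound={self.total_bound:.4f} bits>"
        )
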