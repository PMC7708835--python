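"""Higher-order factorization machines (HOFMs) for sparse regression.

The model scores a feature vector x in R^d as

    yhat(x) = w.x + sum_{t=2..m} sum_{s=1..k} A_t(P^(t)[:, s] * x)

where A_t(z) = sum_{i1<...<it} z_{i1}...z_{it} is the degree-t ANOVA
kernel.  Interaction weights of every order t are thus factorized as
generalized inner products of per-feature latent vectors of a shared
rank k, which lets the model estimate weights for feature tuples never
co-observed in training -- the property that makes dose-response tensor
completion for new drug combinations possible.

A_t and its exact gradient are computed with the standard O(d*t)
forward/backward dynamic program over the multilinear recurrence
a[t][i] = a[t][i-1] + z_i * a[t-1][i-1].  An exhaustive-enumeration
predictor is provided as an independent test oracle.  Training is
mini-batch SGD with Adam per-parameter step adaptation, fully
deterministic under a seed.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "HOFMModel", "TrainingConfig", "generalized_inner_product", "anova_kernel",
    "predict", "predict_brute_force", "objective", "gradient", "fit",
    "predict_symmetric", "save_model", "load_model",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the regularized least-squares fit.

    ``beta`` is the single L2 strength applied uniformly to the linear
    weights and every factor matrix.  Defaults follow the published
    training budget (learning rate 0.001, 200 epochs); small datasets
    typically want a larger learning rate and more epochs.
    """

    beta: float = 100.0
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 1024
    seed: int = 0
    init_scale: float = 0.01

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class HOFMModel:
    """Linear weights plus one d x k factor matrix per order t = 2..m."""

    m: int
    k: int
    w: np.ndarray
    P: dict[int, np.ndarray] = field(default_factory=dict)
    intercept: float = 0.0
    use_intercept: bool = False
    loss_trace_: Optional[list[float]] = None

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("order m must be >= 1")
        if self.m >= 2 and self.k < 1:
            raise ValueError("rank k must be >= 1 when m >= 2")
        self.w = np.asarray(self.w, dtype=float)
        for t, Pt in self.P.items():
            Pt = np.asarray(Pt, dtype=float)
            if Pt.shape != (self.d, self.k):
                raise ValueError(f"P^({t}) must be ({self.d}, {self.k}), got {Pt.shape}")
            self.P[t] = Pt
        if self.m >= 2 and sorted(self.P) != list(range(2, self.m + 1)):
            raise ValueError("P must hold orders 2..m exactly")

    @property
    def d(self) -> int:
        return len(self.w)

    @classmethod
    def initialize(cls, d: int, m: int, k: int, *, seed: int = 0,
                   init_scale: float = 0.01, use_intercept: bool = False) -> "HOFMModel":
        """Zero linear weights; factors ~ Normal(0, init_scale^2)."""
        rng = np.random.default_rng(seed)
        P = {t: rng.normal(0.0, init_scale, size=(d, k)) for t in range(2, m + 1)}
        return cls(m=m, k=k, w=np.zeros(d), P=P, use_intercept=use_intercept)


def generalized_inner_product(vectors: Sequence[np.ndarray]) -> float:
    """<a_1, ..., a_m> = sum_s a_1s * a_2s * ... * a_ms.

    Generalizes the pairwise dot product to m equal-length vectors; this
    is the factorized form of an order-m interaction weight.
    """
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    length = len(arrs[0])
    if any(len(a) != length for a in arrs):
        raise ValueError("all vectors must have the same length")
    out = np.ones(length)
    for a in arrs:
        out = out * a
    return float(out.sum())


def anova_kernel(p: np.ndarray, x: np.ndarray, t: int) -> float:
    """Degree-t ANOVA kernel A_t(p * x) = sum_{i1<...<it} prod p_i x_i.

    Computed in O(d*t) by the prefix recurrence; equals the exhaustive
    sum over all strictly increasing index t-tuples.
    """
    if t <= 0:
        raise ValueError("degree t must be >= 1")
    p = np.asarray(p, dtype=float)
    x = np.asarray(x, dtype=float)
    if p.shape != x.shape:
        raise ValueError("p and x must have the same length")
    d = len(p)
    if t > d:
        raise ValueError(f"degree {t} exceeds dimension {d}")
    z = p * x
    a = np.zeros(t + 1)
    a[0] = 1.0
    for i in range(d):
        # descending degree so a[r-1] is still the prefix-i value
        for r in range(min(t, i + 1), 0, -1):
            a[r] += z[i] * a[r - 1]
    return float(a[t])


def _power_sums(P: np.ndarray, X: np.ndarray, t: int,
                Xpows: Optional[list] = None) -> list:
    """S_r[b, s] = sum_i (x_bi p_is)^r for r = 1..t, as BLAS products."""
    if Xpows is None:
        Xpows = [None] + [X ** r for r in range(1, t + 1)]
    return [None] + [Xpows[r] @ (P ** r) for r in range(1, t + 1)]


def _anova_from_power_sums(S: list, t: int, B: int, k: int) -> list:
    """A_r for r = 0..t via the Newton-Girard recurrence

        A_r = (1/r) * sum_{j=1..r} (-1)^(j+1) A_{r-j} S_j,

    the power-sum form of the elementary symmetric polynomials; exact
    and fully vectorized (each A_r has shape (B, k))."""
    A = [np.ones((B, k))]
    for r in range(1, t + 1):
        acc = np.zeros((B, k))
        for j in range(1, r + 1):
            acc += ((-1) ** (j + 1)) * A[r - j] * S[j]
        A.append(acc / r)
    return A


def _anova_batch(P: np.ndarray, X: np.ndarray, t: int,
                 Xpows: Optional[list] = None) -> np.ndarray:
    """ANOVA kernels of degree t for a batch: returns (B, k)."""
    B = X.shape[0]
    k = P.shape[1]
    S = _power_sums(P, X, t, Xpows)
    return _anova_from_power_sums(S, t, B, k)[t]


def _anova_batch_grad(P: np.ndarray, X: np.ndarray, t: int, coef: np.ndarray,
                      Xpows: Optional[list] = None):
    """Kernel values and the coef-weighted gradient w.r.t. P.

    Differentiates the Newton-Girard recurrence: with C_{t,r} = dA_t/dS_r,

        C_{t,r} = (1/t) [(-1)^(r+1) A_{t-r}
                         + sum_{j=1..t} (-1)^(j+1) S_j C_{t-j,r}],

    and dS_r/dP[i,s] = r x_bi^r p_is^(r-1), so each term is again a
    matrix product.  Returns (kernel (B, k), grad (d, k)) with
    grad[i, s] = sum_b coef[b] * dA_t/dP[i, s].
    """
    B = X.shape[0]
    k = P.shape[1]
    if Xpows is None:
        Xpows = [None] + [X ** r for r in range(1, t + 1)]
    S = _power_sums(P, X, t, Xpows)
    A = _anova_from_power_sums(S, t, B, k)
    # C[q][r] = dA_q/dS_r, built bottom-up
    C = [[None] * (t + 1) for _ in range(t + 1)]
    for q in range(1, t + 1):
        for r in range(1, q + 1):
            acc = ((-1) ** (r + 1)) * A[q - r]
            for j in range(1, q + 1):
                if r <= q - j:
                    acc = acc + ((-1) ** (j + 1)) * S[j] * C[q - j][r]
            C[q][r] = acc / q
    grad = np.zeros_like(P)
    for r in range(1, t + 1):
        weighted = coef[:, None] * C[t][r]           # (B, k)
        grad += r * (Xpows[r].T @ weighted) * (P ** (r - 1))
    return A[t], grad


def predict(model: HOFMModel, X: np.ndarray) -> np.ndarray:
    """yhat for a single vector (d,) or a batch (B, d).

    yhat(x) = w.x + sum_{t=2..m} sum_s A_t(P^(t)[:, s] * x); there is no
    global intercept unless the model's optional flag is on.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.d:
        raise ValueError(f"expected feature dimension {model.d}, got {X.shape[1]}")
    yhat = X @ model.w
    if model.use_intercept:
        yhat = yhat + model.intercept
    Xpows = [None] + [X ** r for r in range(1, model.m + 1)]
    for t in range(2, model.m + 1):
        yhat = yhat + _anova_batch(model.P[t], X, t, Xpows).sum(axis=1)
    return float(yhat[0]) if single else yhat


def predict_brute_force(model: HOFMModel, x: np.ndarray) -> float:
    """Prediction by explicit enumeration of all index tuples.

    Reconstructs every interaction weight as a generalized inner product
    of factor rows and sums over all strictly increasing tuples.  Test
    oracle only; guarded to d <= 20.
    """
    x = np.asarray(x, dtype=float)
    if len(x) != model.d:
        raise ValueError("dimension mismatch")
    if model.d > 20:
        raise ValueError("brute-force oracle limited to d <= 20")
    yhat = float(model.w @ x)
    if model.use_intercept:
        yhat += model.intercept
    for t in range(2, model.m + 1):
        Pt = model.P[t]
        for idx in itertools.combinations(range(model.d), t):
            weight = generalized_inner_product([Pt[i] for i in idx])
            yhat += weight * float(np.prod(x[list(idx)]))
    return yhat


def objective(model: HOFMModel, X: np.ndarray, y: np.ndarray,
              config: TrainingConfig) -> float:
    """Regularized mean squared error.

    (1/n) sum_i (y_i - yhat_i)^2 + (beta/2)||w||^2
    + sum_t (beta/2)||P^(t)||^2, with one beta shared across orders.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise ValueError("empty dataset")
    resid = y - predict(model, X)
    value = float(np.mean(resid ** 2))
    value += 0.5 * config.beta * float(model.w @ model.w)
    for t in range(2, model.m + 1):
        value += 0.5 * config.beta * float(np.sum(model.P[t] ** 2))
    return value


def gradient(model: HOFMModel, X: np.ndarray, y: np.ndarray,
             config: TrainingConfig):
    """Exact gradient of the batch objective.

    Returns ``(grad_w, {t: grad_P_t})`` (plus ``grad_intercept`` on the
    model's shape when the intercept is enabled, appended as a third
    element).  Matches central finite differences of :func:`objective`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    B = len(y)
    if B == 0:
        raise ValueError("empty batch")
    yhat = X @ model.w
    if model.use_intercept:
        yhat = yhat + model.intercept
    Xpows = [None] + [X ** r for r in range(1, model.m + 1)]
    kernels = {}
    for t in range(2, model.m + 1):
        kernels[t] = _anova_batch(model.P[t], X, t, Xpows)
        yhat = yhat + kernels[t].sum(axis=1)
    coef = (-2.0 / B) * (y - yhat)
    grad_w = X.T @ coef + config.beta * model.w
    grad_P = {}
    for t in range(2, model.m + 1):
        _, gP = _anova_batch_grad(model.P[t], X, t, coef, Xpows)
        grad_P[t] = gP + config.beta * model.P[t]
    if model.use_intercept:
        return grad_w, grad_P, float(coef.sum())
    return grad_w, grad_P


def _check_symmetry(X, layout) -> bool:
    """Cheap proxy check that a design matrix is symmetrically duplicated:
    per-category counts in the drug-A one-hot block must equal those in
    the drug-B block."""
    a = layout.block("drug_a_onehot")
    b = layout.block("drug_b_onehot")
    ca = X[:, a.offset:a.offset + a.width].sum(axis=0)
    cb = X[:, b.offset:b.offset + b.width].sum(axis=0)
    return bool(np.allclose(ca, cb))


def fit(X: np.ndarray, y: np.ndarray, m: int, k: int,
        config: Optional[TrainingConfig] = None,
        layout=None, use_intercept: bool = False) -> HOFMModel:
    """Train a HOFM by mini-batch SGD with Adam step adaptation.

    The caller is expected to pass a symmetrically duplicated training
    set (both drug orientations per combination); when ``layout`` is
    given, a detectably asymmetric design matrix triggers a warning.
    Fully reproducible given ``config.seed``; the per-epoch mean batch
    MSE is recorded in ``model.loss_trace_``.  Aborts on non-finite loss.
    """
    config = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if layout is not None and not _check_symmetry(X, layout):
        warnings.warn("training set looks asymmetric in the drug slots; "
                      "did you forget duplicate_symmetric()?", stacklevel=2)
    model = HOFMModel.initialize(d, m, k, seed=config.seed,
                                 init_scale=config.init_scale,
                                 use_intercept=use_intercept)
    rng = np.random.default_rng(config.seed)

    b1, b2, eps = 0.9, 0.999, 1e-8
    params = {"w": model.w}
    for t in range(2, m + 1):
        params[f"P{t}"] = model.P[t]
    adam_m = {name: np.zeros_like(p) for name, p in params.items()}
    adam_v = {name: np.zeros_like(p) for name, p in params.items()}
    if use_intercept:
        adam_m["b"] = np.zeros(())
        adam_v["b"] = np.zeros(())
    step = 0
    trace: list[float] = []
    batch = min(config.batch_size, n)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_mse = 0.0
        n_batches = 0
        for start in range(0, n, batch):
            idx = perm[start:start + batch]
            Xb, yb = X[idx], y[idx]
            grads = gradient(model, Xb, yb, config)
            grad_map = {"w": grads[0]}
            for t in range(2, m + 1):
                grad_map[f"P{t}"] = grads[1][t]
            if use_intercept:
                grad_map["b"] = np.asarray(grads[2])
            step += 1
            for name, g in grad_map.items():
                adam_m[name] = b1 * adam_m[name] + (1 - b1) * g
                adam_v[name] = b2 * adam_v[name] + (1 - b2) * g * g
                mhat = adam_m[name] / (1 - b1 ** step)
                vhat = adam_v[name] / (1 - b2 ** step)
                update = config.learning_rate * mhat / (np.sqrt(vhat) + eps)
                if name == "w":
                    model.w -= update
                elif name == "b":
                    model.intercept -= float(update)
                else:
                    model.P[int(name[1:])] -= update
            resid = yb - predict(model, Xb)
            mse = float(np.mean(resid ** 2))
            if not np.isfinite(mse):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, step {step}; "
                    "reduce the learning rate")
            epoch_mse += mse
            n_batches += 1
        trace.append(epoch_mse / n_batches)
    model.loss_trace_ = trace
    return model


def predict_symmetric(model: HOFMModel, measurement, layout, tables=None) -> float:
    """Orientation-invariant prediction: mean over both drug orderings."""
    from .encoding import encode_measurements

    X = encode_measurements([measurement, measurement.swapped()], layout, tables)
    return float(np.mean(predict(model, X)))


def save_model(model: HOFMModel, path, layout=None, config=None) -> None:
    """Serialize to a single .npz archive with a JSON text manifest."""
    manifest = {
        "m": model.m, "k": model.k, "use_intercept": model.use_intercept,
        "intercept": model.intercept,
        "layout": layout.to_manifest() if layout is not None else None,
        "config": vars(config) if config is not None else None,
        "loss_trace": model.loss_trace_,
    }
    arrays = {"w": model.w}
    for t, Pt in model.P.items():
        arrays[f"P{t}"] = Pt
    np.savez(path, manifest=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
             **arrays)


def load_model(path):
    """Inverse of :func:`save_model`; returns (model, manifest dict)."""
    with np.load(path) as archive:
        manifest = json.loads(bytes(archive["manifest"]).decode())
        w = archive["w"]
        P = {t: archive[f"P{t}"] for t in range(2, manifest["m"] + 1)}
    model = HOFMModel(m=manifest["m"], k=manifest["k"], w=w, P=P,
                      intercept=manifest["intercept"],
                      use_intercept=manifest["use_intercept"],
                      loss_trace_=manifest.get("loss_trace"))
    return model, manifest
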