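"""Uniform fit/predict interface over the benchmark's regression engines.

Engines: the median baseline, similarity-weighted k-nearest-neighbour
regression, partial least squares (in-repo NIPALS implementation), PLS with
Box-Cox power transformation of the response, random forest, Gaussian
process regression (fixed RBF kernel, grid-searched noise), and epsilon-SVR
with an RBF kernel.  Random forest, GPR and SVR delegate to scikit-learn;
the PLS family is implemented here.

Each engine carries a meta-parameter grid.  ``full`` grids follow the
benchmark protocol; ``reduced`` grids subsample them (every 2nd-4th point,
coarser for random forest) to keep a full sweep desk-scale.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.svm import SVR as SkSVR

from .descriptors import tanimoto_raw

log = logging.getLogger(__name__)

ENGINES = ("MEDIAN", "KNN", "PLS", "PLSP", "RFR", "GPR", "SVR")
ENGINE_ALIASES = {"SVM": "SVR", "MED": "MEDIAN"}


def normalize_engine(name: str) -> str:
    name = name.upper()
    name = ENGINE_ALIASES.get(name, name)
    if name not in ENGINES:
        raise ValueError(f"unknown engine {name!r}")
    return name


@dataclass(frozen=True)
class ModelSpec:
    """One engine plus one concrete meta-parameter assignment."""

    engine: str
    params: tuple[tuple[str, Any], ...] = ()

    @classmethod
    def make(cls, engine: str, params: dict[str, Any] | None = None) -> "ModelSpec":
        return cls(normalize_engine(engine), tuple(sorted((params or {}).items())))

    @property
    def param_dict(self) -> dict[str, Any]:
        return dict(self.params)

    def to_json(self) -> str:
        return json.dumps({"engine": self.engine, "params": self.param_dict}, sort_keys=True)


# ---------------------------------------------------------------------------
# Meta-parameter grids


def param_grid(engine: str, descriptor_length: int, mode: str = "reduced") -> list[dict[str, Any]]:
    """Ordered list of grid points for an engine.

    ``descriptor_length`` fixes the RBF gamma (1/length) for GPR and SVR; it
    does not enter the grid itself.
    """
    engine = normalize_engine(engine)
    if mode not in ("reduced", "full"):
        raise ValueError("grid mode must be 'reduced' or 'full'")
    full = mode == "full"
    if engine == "MEDIAN":
        return [{}]
    if engine == "KNN":
        ks = range(1, 10) if full else (1, 3, 5, 7, 9)
        return [{"k": int(k)} for k in ks]
    if engine == "PLS":
        fs = range(1, 32) if full else range(1, 32, 2)
        return [{"factors": int(f)} for f in fs]
    if engine == "PLSP":
        fs = range(1, 32) if full else (1, 5, 9, 13, 17, 21, 25, 29)
        lams = [round(0.05 * i, 2) for i in range(1, 41)] if full else (0.1, 0.5, 1.0, 1.5, 2.0)
        return [{"factors": int(f), "lam": float(l)} for f in fs for l in lams]
    if engine == "GPR":
        exps = [(-3 + 0.5 * i) for i in range(15)] if full else range(-3, 5)
        return [{"lam": float(10.0**e)} for e in exps]
    if engine == "RFR":
        if full:
            trees, leaves = (50, 100, 250, 500, 1000), range(2, 55, 2)
            mtries, nodes = (0.15, 0.333, 0.45), range(2, 55, 2)
        else:
            trees, leaves, mtries, nodes = (100,), (14, 54), (0.333, 0.45), (2,)
        return [
            {"trees": int(t), "max_leaf_nodes": int(l), "mtry": float(m), "node_size": int(s)}
            for t in trees
            for l in leaves
            for m in mtries
            for s in nodes
        ]
    if engine == "SVR":
        cs = range(5, 16) if full else (5, 9, 13)
        eps = range(-10, 7) if full else (-8, -4, 0, 4)
        return [{"C": float(2.0**c), "epsilon": float(2.0**e)} for c in cs for e in eps]
    raise AssertionError(engine)


def complexity_key(engine: str, params: dict[str, Any]) -> tuple:
    """Ordering used to break CV-error ties toward the simpler model."""
    engine = normalize_engine(engine)
    if engine == "KNN":
        return (params["k"],)
    if engine == "PLS":
        return (params["factors"],)
    if engine == "PLSP":
        return (params["factors"], params["lam"])
    if engine == "GPR":
        return (-params["lam"],)  # stronger regularization is simpler
    if engine == "RFR":
        return (params["trees"], params["max_leaf_nodes"], -params["node_size"], params["mtry"])
    if engine == "SVR":
        return (params["C"], -params["epsilon"])
    return ()


# ---------------------------------------------------------------------------
# Box-Cox


def boxcox(y: np.ndarray, lam: float) -> np.ndarray:
    """Power transform (y^lam - 1)/lam, ln y at lam = 0.  Requires y > 0."""
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ValueError("Box-Cox requires strictly positive input; shift y first")
    if lam == 0:
        return np.log(y)
    # expm1 keeps precision as lam -> 0 (limit is ln y)
    return np.expm1(lam * np.log(y)) / lam


def inverse_boxcox(z: np.ndarray, lam: float) -> np.ndarray:
    """Exact inverse of :func:`boxcox` on its image.

    Values outside the image (which extrapolating models can produce for
    lam != 0) are clipped to the boundary before inversion.
    """
    z = np.asarray(z, dtype=float)
    if lam == 0:
        return np.exp(z)
    arg = np.maximum(lam * z, 1e-12 - 1.0)
    return np.exp(np.log1p(arg) / lam)


# ---------------------------------------------------------------------------
# NIPALS partial least squares (PLS1)


class NIPALSPLS:
    """Partial least squares for a single response, NIPALS algorithm.

    X and y are mean-centered; no variance scaling is applied (binary
    fingerprint columns would be inflated by it).  For a univariate response
    NIPALS needs no inner iteration: each factor's weight vector is the
    deflated covariance X'y.  Requested factors beyond the effective rank of
    X are truncated with a log message.
    """

    def __init__(self, n_factors: int):
        if n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        self.n_factors = n_factors
        self.x_mean_: np.ndarray | None = None
        self.y_mean_: float = 0.0
        self.W_: np.ndarray | None = None  # (d, k) weights
        self.P_: np.ndarray | None = None  # (d, k) loadings
        self.q_: np.ndarray | None = None  # (k,) response loadings
        self.coef_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NIPALSPLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, d = X.shape
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        k_max = min(self.n_factors, n - 1 if n > 1 else 1, d)
        W, P, q = [], [], []
        tol = 1e-12 * max(1.0, float(np.abs(Xc).sum()))
        for _ in range(k_max):
            w = Xc.T @ yc
            wn = np.linalg.norm(w)
            if wn < 1e-12:
                break
            w /= wn
            t = Xc @ w
            tt = float(t @ t)
            if tt < max(tol, 1e-12):
                break
            p = Xc.T @ t / tt
            qk = float(yc @ t / tt)
            Xc = Xc - np.outer(t, p)
            yc = yc - qk * t
            W.append(w)
            P.append(p)
            q.append(qk)
        if not W:  # degenerate: no covariance between X and y
            self.W_ = np.zeros((d, 0))
            self.P_ = np.zeros((d, 0))
            self.q_ = np.zeros(0)
            self.coef_ = np.zeros(d)
            return self
        if len(W) < self.n_factors:
            log.debug("PLS factors truncated from %d to %d (rank limit)", self.n_factors, len(W))
        self.W_ = np.column_stack(W)
        self.P_ = np.column_stack(P)
        self.q_ = np.asarray(q)
        self.coef_ = self._coef(len(W))
        return self

    def _coef(self, k: int) -> np.ndarray:
        Wk, Pk, qk = self.W_[:, :k], self.P_[:, :k], self.q_[:k]
        # B = W (P'W)^-1 q ; P'W is upper triangular with unit-ish diagonal
        A = Pk.T @ Wk
        return Wk @ np.linalg.solve(A, qk)

    @property
    def effective_factors(self) -> int:
        return 0 if self.W_ is None else self.W_.shape[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_

    def predict_at(self, X: np.ndarray, k: int) -> np.ndarray:
        """Prediction using only the first min(k, effective) factors.

        Factors are nested, so one fit at the grid maximum serves every
        smaller factor count — used to make CV over the factor grid cheap.
        """
        k = min(k, self.effective_factors)
        if k == 0:
            return np.full(len(X), self.y_mean_)
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self._coef(k) + self.y_mean_


# ---------------------------------------------------------------------------
# Fit / predict facade


@dataclass
class FittedModel:
    spec: ModelSpec
    state: Any
    n_features: int
    train_fingerprint: str
    notes: dict = field(default_factory=dict)


def _fingerprint(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=float).tobytes())
    h.update(spec.to_json().encode())
    return h.hexdigest()


def fit(spec: ModelSpec, X: np.ndarray, y: np.ndarray, rng_seed: int = 0) -> FittedModel:
    """Fit one engine at one grid point.

    A zero-variance response degenerates every engine to a constant
    (median) model, with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per response value")
    if len(y) < 2:
        raise ValueError("need at least 2 training rows")
    params = spec.param_dict
    fp = _fingerprint(X, y, spec)
    notes: dict = {}
    if np.ptp(y) == 0:
        if spec.engine != "MEDIAN":
            log.warning("zero-variance response: %s degenerates to a constant model", spec.engine)
        return FittedModel(spec, ("const", float(y[0])), X.shape[1], fp, {"degenerate": True})
    d = X.shape[1]
    if spec.engine == "MEDIAN":
        state: Any = ("const", float(np.median(y)))
    elif spec.engine == "KNN":
        state = ("knn", X.copy(), y.copy(), int(params["k"]))
    elif spec.engine == "PLS":
        state = ("pls", NIPALSPLS(int(params["factors"])).fit(X, y))
    elif spec.engine == "PLSP":
        lam = float(params["lam"])
        shift = float(y.min())
        yt = boxcox(y - shift + 1.0, lam)
        state = ("plsp", NIPALSPLS(int(params["factors"])).fit(X, yt), lam, shift)
    elif spec.engine == "RFR":
        rf = RandomForestRegressor(
            n_estimators=int(params["trees"]),
            max_leaf_nodes=int(params["max_leaf_nodes"]),
            max_features=float(params["mtry"]),
            min_samples_leaf=int(params["node_size"]),
            random_state=int(rng_seed) % (2**31),
            n_jobs=1,
        )
        rf.fit(X, y)
        state = ("sk", rf)
    elif spec.engine == "GPR":
        length_scale = float(np.sqrt(d / 2.0))  # gamma = 1/d
        kernel = ConstantKernel(1.0, "fixed") * RBF(length_scale, "fixed")
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=float(params["lam"]), optimizer=None, normalize_y=True
        )
        gp.fit(X, y)
        state = ("sk", gp)
    elif spec.engine == "SVR":
        svr = SkSVR(
            kernel="rbf",
            C=float(params["C"]),
            epsilon=float(params["epsilon"]),
            gamma=1.0 / d,
            cache_size=256,
        )
        svr.fit(X, y)
        state = ("sk", svr)
    else:
        raise AssertionError(spec.engine)
    return FittedModel(spec, state, X.shape[1], fp, notes)


def _knn_predict(Xtr: np.ndarray, ytr: np.ndarray, k: int, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X))
    k = min(k, len(ytr))
    for i, q in enumerate(X):
        num = np.minimum(q, Xtr).sum(axis=1)
        den = np.maximum(q, Xtr).sum(axis=1)
        sims = np.where(den > 0, num / np.where(den > 0, den, 1), 1.0)
        nn = np.argsort(-sims, kind="stable")[:k]
        w = sims[nn]
        if w.sum() <= 0:
            log.debug("all neighbour similarities zero; falling back to unweighted mean")
            out[i] = ytr[nn].mean()
        else:
            out[i] = float(w @ ytr[nn] / w.sum())
    return out


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """One finite prediction per row of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"descriptor length {X.shape[-1]} does not match training length {model.n_features}"
        )
    kind = model.state[0]
    if kind == "const":
        return np.full(len(X), model.state[1])
    if kind == "knn":
        _, Xtr, ytr, k = model.state
        return _knn_predict(Xtr, ytr, k, X)
    if kind == "pls":
        return model.state[1].predict(X)
    if kind == "plsp":
        _, pls, lam, shift = model.state
        z = pls.predict(X)
        return inverse_boxcox(z, lam) + shift - 1.0
    if kind == "sk":
        return np.asarray(model.state[1].predict(X), dtype=float)
    raise AssertionError(kind)
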