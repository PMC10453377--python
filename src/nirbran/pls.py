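"""PLS1 regression, cross-validation and the R^2/RMSE metric suite.

Calibration models are single-response partial least squares (PLS1) on
mean-centred spectra, fitted by NIPALS-style sequential deflation (for a
single response each component is given in closed form, so no inner
iteration is needed).  The number of latent variables (LVs) is chosen by
cross-validation — leave-one-out by default — under the cap
``floor(n_calibration / 10)``: at the study's 99 calibration samples at
most nine LVs are allowed, guarding against overfitting.

Metrics follow the usual chemometric definitions:

* ``RMSECV = sqrt(sum((yhat_-i - y_i)^2) / n)`` over held-out predictions;
* ``R^2 = 1 - SS_res / SS_tot`` (cross-validated, validation or external
  prediction flavours: R^2_cv/RMSECV, R^2_v/RMSEV, R^2_p/RMSEP).

Any pretreatment state (MSC reference, centring) is refitted inside every
cross-validation fold so that held-out samples never leak into it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import PretreatmentSpec, apply_chain

__all__ = [
    "PLSModel",
    "CVResult",
    "lv_cap",
    "fit",
    "cross_validate",
    "select_lvs",
    "evaluate",
]


def lv_cap(n_calibration: int) -> int:
    """Maximum admissible LV count: one tenth of the calibration size."""
    return max(1, math.floor(n_calibration / 10))


# ---------------------------------------------------------------------------
# core NIPALS-style PLS1

def _pls1_components(Xc: np.ndarray, yc: np.ndarray, n_lvs: int):
    """Sequential PLS1 extraction on centred data.

    Returns weights W (p, A), loadings P (p, A) and response loadings
    q (A,); stops early if the residual covariance vanishes.
    """
    X = Xc.copy()
    y = yc.copy()
    p = X.shape[1]
    W = np.zeros((p, n_lvs))
    P = np.zeros((p, n_lvs))
    q = np.zeros(n_lvs)
    eps = 1e-12
    for a in range(n_lvs):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < eps:
            return W[:, :a], P[:, :a], q[:a]
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < eps:
            return W[:, :a], P[:, :a], q[:a]
        pa = X.T @ t / tt
        qa = y @ t / tt
        X -= np.outer(t, pa)
        y = y - qa * t
        W[:, a], P[:, a], q[a] = w, pa, qa
    return W, P, q


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def _fit_predict_path(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, n_lvs: int
) -> np.ndarray:
    """Held-out predictions for every LV count 1..n_lvs in one pass.

    Deflates the test spectra alongside the training data, accumulating
    ``yhat_a = yhat_{a-1} + q_a * t_a(test)``; columns beyond an early
    stop repeat the last prediction.
    """
    xm = Xtr.mean(axis=0)
    ym = ytr.mean()
    X = Xtr - xm
    y = ytr - ym
    T = Xte - xm
    preds = np.full((Xte.shape[0], n_lvs), ym)
    acc = np.zeros(Xte.shape[0])
    eps = 1e-12
    for a in range(n_lvs):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < eps:
            preds[:, a:] = (ym + acc)[:, None]
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < eps:
            preds[:, a:] = (ym + acc)[:, None]
            break
        pa = X.T @ t / tt
        qa = y @ t / tt
        X -= np.outer(t, pa)
        y = y - qa * t
        tte = T @ w
        T -= np.outer(tte, pa)
        acc = acc + qa * tte
        preds[:, a] = ym + acc
    return preds


def _loo_predict_path_batched(X: np.ndarray, y: np.ndarray, n_lvs: int) -> np.ndarray:
    """Leave-one-out counterpart of :func:`_fit_predict_path`, vectorised
    across all n folds at once (identical arithmetic, fold axis first).

    Returns an (n, n_lvs) matrix of held-out predictions.  Used when no
    per-fold state (MSC) must be refitted and the (n, n-1, p) workspace
    fits in memory.
    """
    n, p = X.shape
    idx = np.array([[j for j in range(n) if j != i] for i in range(n)])
    Xf = X[idx]            # (n, n-1, p) fold training blocks
    yf = y[idx]            # (n, n-1)
    xm = Xf.mean(axis=1, keepdims=True)
    ym = yf.mean(axis=1)
    Xf = Xf - xm
    yf = yf - ym[:, None]
    T = X - xm[:, 0, :]    # each fold's held-out spectrum, centred
    preds = np.tile(ym[:, None], (1, n_lvs))
    acc = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    eps = 1e-12
    for a in range(n_lvs):
        w = np.matmul(yf[:, None, :], Xf)[:, 0, :]
        nw = np.linalg.norm(w, axis=1)
        alive &= nw > eps
        w = np.where(alive[:, None], w / np.where(nw > eps, nw, 1.0)[:, None], 0.0)
        t = np.matmul(Xf, w[:, :, None])[:, :, 0]
        tt = np.einsum("fi,fi->f", t, t)
        alive &= tt > eps
        tt_safe = np.where(tt > eps, tt, 1.0)
        pa = np.matmul(t[:, None, :], Xf)[:, 0, :] / tt_safe[:, None]
        qa = np.where(alive, np.einsum("fi,fi->f", yf, t) / tt_safe, 0.0)
        Xf -= t[:, :, None] * pa[:, None, :]
        yf -= qa[:, None] * t
        tte = np.einsum("fj,fj->f", T, w)
        T -= tte[:, None] * pa
        acc = acc + qa * tte
        preds[:, a] = ym + acc
    return preds


# ---------------------------------------------------------------------------
# public model object

@dataclass
class PLSModel:
    """A fitted PLS1 calibration model with its provenance."""

    n_lvs: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray   # (p, n_lvs)
    loadings: np.ndarray  # (p, n_lvs)
    y_loadings: np.ndarray  # (n_lvs,)
    coef: np.ndarray      # (p,) regression vector on centred data
    pretreatment: PretreatmentSpec = field(default_factory=PretreatmentSpec)
    pretreatment_state: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def n_variables(self) -> int:
        return self.coef.size

    def predict(self, X: np.ndarray, pretreated: bool = True) -> np.ndarray:
        """Predict cellulose content (%) for pretreated spectra rows.

        With ``pretreated=False`` the model's own pretreatment chain and
        fitted state are applied first.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not pretreated:
            X, _ = apply_chain(X, self.pretreatment, state=self.pretreatment_state)
        if X.shape[1] != self.n_variables:
            raise ValueError(
                f"model expects {self.n_variables} variables, got {X.shape[1]}"
            )
        return self.y_mean + (X - self.x_mean) @ self.coef

    # -- structured-text serialization -------------------------------------
    def to_json(self) -> str:
        doc = {
            "n_lvs": self.n_lvs,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "pretreatment": {
                "chain": list(self.pretreatment.chain),
                "sg_window": self.pretreatment.sg_window,
                "sg_polyorder": self.pretreatment.sg_polyorder,
            },
            "pretreatment_state": [
                None if s is None else np.asarray(s).tolist()
                for s in self.pretreatment_state
            ],
            "provenance": self.provenance,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "PLSModel":
        doc = json.loads(text)
        return cls(
            n_lvs=doc["n_lvs"],
            x_mean=np.array(doc["x_mean"]),
            y_mean=doc["y_mean"],
            weights=np.array(doc["weights"]).reshape(len(doc["x_mean"]), -1),
            loadings=np.array(doc["loadings"]).reshape(len(doc["x_mean"]), -1),
            y_loadings=np.array(doc["y_loadings"]),
            coef=np.array(doc["coef"]),
            pretreatment=PretreatmentSpec(
                chain=tuple(doc["pretreatment"]["chain"]),
                sg_window=doc["pretreatment"]["sg_window"],
                sg_polyorder=doc["pretreatment"]["sg_polyorder"],
            ),
            pretreatment_state=[
                None if s is None else np.array(s) for s in doc["pretreatment_state"]
            ],
            provenance=doc.get("provenance", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PLSModel":
        return cls.from_json(Path(path).read_text())


def fit(
    X: np.ndarray,
    y: np.ndarray,
    n_lvs: int,
    pretreatment: PretreatmentSpec | None = None,
    pretreatment_state: list | None = None,
    provenance: dict | None = None,
    enforce_cap: bool = True,
) -> PLSModel:
    """Fit PLS1 on mean-centred (already pretreated) calibration data.

    ``n_lvs`` must respect the one-tenth rule: at n calibration samples at
    most ``floor(n/10)`` latent variables are admissible.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if n_lvs < 1:
        raise ValueError("n_lvs must be >= 1")
    if enforce_cap and n_lvs > lv_cap(n):
        raise ValueError(
            f"n_lvs={n_lvs} exceeds the cap floor(n/10)={lv_cap(n)} for "
            f"n={n} calibration samples (LVs must not exceed one tenth of "
            "the calibration set size)"
        )
    if n_lvs > min(n - 1, p):
        raise ValueError(f"n_lvs={n_lvs} exceeds the rank bound min(n-1, p)")
    xm = X.mean(axis=0)
    ym = float(y.mean())
    W, P, q = _pls1_components(X - xm, y - ym, n_lvs)
    coef = _regression_vector(W, P, q)
    return PLSModel(
        n_lvs=W.shape[1],
        x_mean=xm,
        y_mean=ym,
        weights=W,
        loadings=P,
        y_loadings=q,
        coef=coef,
        pretreatment=pretreatment or PretreatmentSpec(),
        pretreatment_state=pretreatment_state or [],
        provenance=provenance or {},
    )


# ---------------------------------------------------------------------------
# cross-validation

@dataclass(frozen=True)
class CVResult:
    """Per-LV cross-validation error table."""

    rmsecv: np.ndarray  # (max_lvs,)
    r2_cv: np.ndarray   # (max_lvs,)

    @property
    def best_lvs(self) -> int:
        return select_lvs(self.rmsecv)

    @property
    def best_rmsecv(self) -> float:
        return float(self.rmsecv[self.best_lvs - 1])

    @property
    def best_r2_cv(self) -> float:
        return float(self.r2_cv[self.best_lvs - 1])


def _fold_indices(n: int, cv: int | str) -> list[np.ndarray]:
    if cv == "loo":
        return [np.array([i]) for i in range(n)]
    k = int(cv)
    if not 2 <= k <= n:
        raise ValueError("k-fold requires 2 <= k <= n")
    # venetian-blind assignment: deterministic, order-based
    return [np.arange(n)[np.arange(n) % k == j] for j in range(k)]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_lvs: int | None = None,
    chain: PretreatmentSpec | None = None,
    cv: int | str = "loo",
    enforce_cap: bool = True,
) -> CVResult:
    """Cross-validated RMSECV and R^2_cv for every LV count up to the cap.

    ``X`` holds raw calibration spectra when ``chain`` is given (the chain,
    including any MSC reference, is refitted on each fold's training part),
    or already-pretreated spectra when ``chain`` is None.  ``cv`` is
    ``"loo"`` (default) or an integer k for deterministic venetian-blind
    k-fold.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    cap = lv_cap(n)
    if max_lvs is None:
        max_lvs = cap
    if enforce_cap and max_lvs > cap:
        raise ValueError(
            f"max_lvs={max_lvs} exceeds the cap floor(n/10)={cap} for n={n}"
        )
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("constant response: cross-validated R^2 is undefined")

    # per-spectrum operators commute with fold splitting; apply them once.
    pre_ops: tuple[str, ...] = ()
    refit_msc = False
    if chain is not None and chain.chain:
        if chain.chain[-1] == "msc":
            pre_ops, refit_msc = chain.chain[:-1], True
        else:
            pre_ops = chain.chain
    if pre_ops:
        X, _ = apply_chain(
            X, PretreatmentSpec(pre_ops, chain.sg_window, chain.sg_polyorder)
        )
    from .preprocess import msc as _msc  # local import avoids cycle at top

    max_lvs = min(max_lvs, n - 2, p)
    # fast path: LOO without per-fold state, folds batched in one workspace
    if cv == "loo" and not refit_msc and n * n * p * 8 < 512e6:
        preds = _loo_predict_path_batched(X, y, max_lvs)
        press = ((preds - y[:, None]) ** 2).sum(axis=0)
        return CVResult(rmsecv=np.sqrt(press / n), r2_cv=1.0 - press / ss_tot)
    press = np.zeros(max_lvs)
    for test_idx in _fold_indices(n, cv):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        Xtr, ytr, Xte = X[mask], y[mask], X[test_idx]
        if refit_msc:
            Xtr, ref = _msc(Xtr)
            Xte, _ = _msc(Xte, reference=ref)
        preds = _fit_predict_path(Xtr, ytr, Xte, max_lvs)
        press += ((preds - y[test_idx][:, None]) ** 2).sum(axis=0)
    rmsecv = np.sqrt(press / n)
    r2 = 1.0 - press / ss_tot
    return CVResult(rmsecv=rmsecv, r2_cv=r2)


def select_lvs(rmsecv: np.ndarray) -> int:
    """LV count minimising RMSECV; ties resolve to fewer LVs."""
    rmsecv = np.asarray(rmsecv, dtype=float)
    if rmsecv.size == 0:
        raise ValueError("empty RMSECV table")
    return int(np.argmin(rmsecv)) + 1


def evaluate(model: PLSModel, X_new: np.ndarray, y_new: np.ndarray,
             pretreated: bool = True) -> tuple[float, float]:
    """(R^2, RMSE) of a model on a held-out set (validation or prediction).

    ``R^2 = 1 - SS_res / SS_tot`` with SS_tot about the held-out mean;
    ``RMSE = sqrt(mean squared error)``, in % cellulose.
    """
    y_new = np.asarray(y_new, dtype=float).ravel()
    yhat = model.predict(X_new, pretreated=pretreated)
    res = float(((yhat - y_new) ** 2).sum())
    tot = float(((y_new - y_new.mean()) ** 2).sum())
    if tot == 0.0:
        raise ValueError("constant held-out response: R^2 is undefined")
    return 1.0 - res / tot, math.sqrt(res / y_new.size)
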