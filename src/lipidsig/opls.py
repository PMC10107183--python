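"""OPLS-DA: orthogonal projections to latent structures, discriminant variant.

The model splits X-variation into components predictive of class membership
and components orthogonal to it.  Orthogonal components are found by the
O-PLS filtering recursion (the X-loading of a PLS component minus its
projection onto the predictive weight space, normalized, then deflated from
X); predictive components are then fit by NIPALS PLS on the filtered matrix.

Reported diagnostics follow chemometrics convention: R²X(cum) is the
fraction of X sum-of-squares captured by all components, R²Y(cum) the
fraction of Y sum-of-squares explained, Q²(cum) = 1 - PRESS/SS(Y) from
stratified K-fold cross-validation, and VIP the variable influence on
projection over the predictive components (mean VIP² is exactly 1).
Model validity is assessed by refitting under random permutations of the
class labels and regressing R²Y/Q² on the |correlation| with the true
labels; a negative Q² intercept indicates a model not explainable by chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OplsModel",
    "PermutationValidation",
    "log_pareto",
    "apply_log_pareto",
    "fit_oplsda",
    "vip",
    "permutation_validate",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scaling

def log_pareto(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log10 transform then Pareto scaling: (log10 x - mean) / sqrt(sd).

    Columns are features.  Constant columns are dropped (their scale is
    undefined).  Returns the scaled matrix and the per-feature parameters.
    """
    x = matrix.astype(float)
    if (x.to_numpy() <= 0).any():
        bad = x.columns[(x <= 0).any(axis=0)]
        raise ValueError(f"non-positive intensities in feature(s): {list(bad)[:5]}")
    lx = np.log10(x)
    mean = lx.mean(axis=0)
    sd = lx.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        log.info("dropping %d constant features", int(constant.sum()))
    keep = x.columns[~constant]
    scaled = (lx[keep] - mean[keep]) / np.sqrt(sd[keep])
    params = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]})
    return scaled, params


def apply_log_pareto(matrix: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Apply stored log-Pareto parameters to (new) data."""
    lx = np.log10(matrix[params.index].astype(float))
    return (lx - params["mean"]) / np.sqrt(params["sd"])


# ---------------------------------------------------------------------------
# model containers

@dataclass
class OplsModel:
    classes: list
    y_codes: np.ndarray            # centered class coding actually used (n, q)
    weights: np.ndarray            # predictive weights (p, A), unit norm
    scores: np.ndarray             # predictive scores (n, A)
    loadings: np.ndarray           # predictive X-loadings (p, A)
    y_loadings: np.ndarray         # (q, A)
    ortho_weights: np.ndarray      # (p, n_ortho)
    ortho_scores: np.ndarray       # (n, n_ortho)
    ortho_loadings: np.ndarray     # (p, n_ortho)
    r2x_cum: float
    r2y_cum: float
    q2_cum: float
    vip: np.ndarray = field(default=None)
    feature_names: list = field(default_factory=list)

    @property
    def n_ortho(self) -> int:
        return self.ortho_weights.shape[1]

    def summary(self) -> dict:
        return {
            "class_number": len(self.classes),
            "n_predictive": self.weights.shape[1],
            "n_orthogonal": self.n_ortho,
            "R2X_cum": round(float(self.r2x_cum), 4),
            "R2Y_cum": round(float(self.r2y_cum), 4),
            "Q2_cum": round(float(self.q2_cum), 4),
        }


@dataclass
class PermutationValidation:
    correlations: np.ndarray   # |corr(permuted y, original y)|, original last (=1)
    r2y: np.ndarray
    q2: np.ndarray
    r2y_intercept: float
    q2_intercept: float


# ---------------------------------------------------------------------------
# core algebra

def _encode_y(y_classes) -> tuple[np.ndarray, list]:
    y = np.asarray(y_classes)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    for c in classes:
        if (y == c).sum() < 3:
            raise ValueError(f"class {c!r} has fewer than 3 samples")
    if len(classes) == 2:
        codes = np.where(y == classes[1], 1.0, -1.0)[:, None]
    else:
        codes = np.array([(y == c).astype(float) for c in classes]).T
    return codes - codes.mean(axis=0), classes


def _pls_weight(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Dominant PLS weight: first left singular vector of X'Y."""
    c = X.T @ Y
    if Y.shape[1] == 1:
        w = c[:, 0]
    else:
        u, _, _ = np.linalg.svd(c, full_matrices=False)
        w = u[:, 0]
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("X carries no covariance with Y")
    return w / nrm


def _fit_core(X: np.ndarray, Y: np.ndarray, n_ortho: int, n_pred: int):
    """O-PLS filtering then NIPALS PLS predictive components.

    Returns dict of weights/scores/loadings for both blocks.
    """
    n, p = X.shape
    if n_ortho >= min(np.linalg.matrix_rank(X), p):
        raise ValueError(f"n_ortho={n_ortho} >= rank of X")
    Xf = X.copy()
    # predictive weight space of the unfiltered matrix
    W_space, _ = np.linalg.qr(Xf.T @ Y)
    Wo, To, Po = [], [], []
    for _ in range(n_ortho):
        w = _pls_weight(Xf, Y)
        t = Xf @ w
        p_load = Xf.T @ t / (t @ t)
        w_o = p_load - W_space @ (W_space.T @ p_load)
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            break  # nothing orthogonal left
        w_o /= nrm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf -= np.outer(t_o, p_o)
        Wo.append(w_o); To.append(t_o); Po.append(p_o)

    Wp, Tp, Pp, Cp = [], [], [], []
    Xd, Yd = Xf.copy(), Y.copy()
    for _ in range(n_pred):
        if np.linalg.norm(Xd.T @ Yd) < 1e-12:
            break
        w = _pls_weight(Xd, Yd)
        t = Xd @ w
        c = Yd.T @ t / (t @ t)
        p_load = Xd.T @ t / (t @ t)
        Xd -= np.outer(t, p_load)
        Yd -= np.outer(t, c)
        Wp.append(w); Tp.append(t); Pp.append(p_load); Cp.append(c)

    stack = lambda v, rows: (np.column_stack(v) if v else np.zeros((rows, 0)))
    return {
        "W": stack(Wp, p), "T": stack(Tp, n), "P": stack(Pp, p),
        "C": stack(Cp, Y.shape[1]),
        "Wo": stack(Wo, p), "To": stack(To, n), "Po": stack(Po, p),
        "X_filtered": Xf,
    }


def _predict(core: dict, X: np.ndarray) -> np.ndarray:
    """Apply the fitted filtering + predictive components to new rows."""
    Xn = X.copy()
    for a in range(core["Wo"].shape[1]):
        t_o = Xn @ core["Wo"][:, a]
        Xn -= np.outer(t_o, core["Po"][:, a])
    Yhat = np.zeros((X.shape[0], core["C"].shape[0]))
    for a in range(core["W"].shape[1]):
        t = Xn @ core["W"][:, a]
        Xn -= np.outer(t, core["P"][:, a])
        Yhat += np.outer(t, core["C"][:, a])
    return Yhat


def _stratified_folds(y, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    y = np.asarray(y)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in pd.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(i)
    return [np.array(sorted(f), dtype=int) for f in folds if f]


def fit_oplsda(X, y_classes, n_ortho: int | str = 1, cv_folds: int = 7,
               seed: int = 0, n_pred: int | None = None) -> OplsModel:
    """Fit an OPLS-DA model on a scaled matrix.

    ``X`` is samples x features (already log/Pareto scaled); ``y_classes``
    the class labels.  ``n_ortho="auto"`` keeps adding orthogonal components
    (up to 3) while each addition improves Q²(cum) by more than 0.01.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    Xa = np.asarray(X, dtype=float)
    Y, classes = _encode_y(y_classes)
    if n_pred is None:
        n_pred = 1 if len(classes) == 2 else len(classes) - 1

    if n_ortho == "auto":
        # grow while each added orthogonal component buys > 0.01 Q2, cap 3
        best = fit_oplsda(X, y_classes, n_ortho=0, cv_folds=cv_folds,
                          seed=seed, n_pred=n_pred)
        for k in range(1, 4):
            try:
                m = fit_oplsda(X, y_classes, n_ortho=k, cv_folds=cv_folds,
                               seed=seed, n_pred=n_pred)
            except ValueError:
                break
            if np.isfinite(m.q2_cum) and m.q2_cum > best.q2_cum + 0.01:
                best = m
            else:
                break
        return best

    core = _fit_core(Xa, Y, int(n_ortho), n_pred)

    ssx = float((Xa ** 2).sum())
    captured = 0.0
    for T, P in ((core["T"], core["P"]), (core["To"], core["Po"])):
        for a in range(T.shape[1]):
            captured += float((T[:, a] ** 2).sum() * (P[:, a] ** 2).sum())
    r2x = captured / ssx if ssx else 0.0

    Yhat = core["T"] @ core["C"].T
    ssy = float((Y ** 2).sum())
    r2y = 1.0 - float(((Y - Yhat) ** 2).sum()) / ssy if ssy else 0.0

    # cross-validated Q2
    rng = np.random.default_rng(seed)
    press = 0.0
    for fold in _stratified_folds(y_classes, cv_folds, rng):
        train = np.setdiff1d(np.arange(Xa.shape[0]), fold)
        try:
            core_cv = _fit_core(Xa[train], Y[train], int(n_ortho), n_pred)
        except ValueError:
            press = np.nan
            break
        pred = _predict(core_cv, Xa[fold])
        press += float(((Y[fold] - pred) ** 2).sum())
    q2 = 1.0 - press / ssy if ssy else 0.0

    model = OplsModel(
        classes=classes, y_codes=Y,
        weights=core["W"], scores=core["T"], loadings=core["P"],
        y_loadings=core["C"],
        ortho_weights=core["Wo"], ortho_scores=core["To"], ortho_loadings=core["Po"],
        r2x_cum=min(r2x, 1.0), r2y_cum=min(max(r2y, 0.0), 1.0), q2_cum=q2,
        feature_names=feature_names,
    )
    model.vip = vip(model)
    return model


def vip(model: OplsModel) -> np.ndarray:
    """Variable influence on projection over the predictive components.

    VIP_i = sqrt( p * sum_a SSY_a w_ia^2 / sum_a SSY_a ), where SSY_a is the
    Y sum-of-squares explained by predictive component a.  Because each
    weight vector has unit norm, mean(VIP^2) = 1 exactly.
    """
    W, T, C = model.weights, model.scores, model.y_loadings
    p = W.shape[0]
    ssy = np.array([(T[:, a] @ T[:, a]) * float(C[:, a] @ C[:, a])
                    for a in range(W.shape[1])])
    if ssy.sum() == 0:
        return np.zeros(p)
    return np.sqrt(p * (W ** 2 @ ssy) / ssy.sum())


def permutation_validate(X, y_classes, n_ortho: int = 1, cv_folds: int = 7,
                         n_perm: int = 100, seed: int = 0,
                         n_pred: int | None = None) -> PermutationValidation:
    """Label-permutation validation of a two-class model.

    Refits the model ``n_perm`` times under random permutations of the class
    labels, regresses R²Y(cum) and Q²(cum) on the |correlation| between
    permuted and original coded labels (the unpermuted model enters at
    correlation 1), and reports the two regression intercepts.
    """
    y = np.asarray(y_classes)
    codes, classes = _encode_y(y)
    if len(classes) != 2:
        raise ValueError("permutation validation applies to two-class models")
    rng = np.random.default_rng(seed)
    corrs, r2ys, q2s = [], [], []
    base = codes[:, 0]
    for b in range(n_perm):
        perm = rng.permutation(len(y))
        y_perm = y[perm]
        r = abs(float(np.corrcoef(base, codes[perm, 0])[0, 1]))
        m = fit_oplsda(X, y_perm, n_ortho=n_ortho, cv_folds=cv_folds,
                       seed=seed + 1 + b, n_pred=n_pred)
        corrs.append(r); r2ys.append(m.r2y_cum); q2s.append(m.q2_cum)
    original = fit_oplsda(X, y, n_ortho=n_ortho, cv_folds=cv_folds, seed=seed,
                          n_pred=n_pred)
    corrs.append(1.0); r2ys.append(original.r2y_cum); q2s.append(original.q2_cum)

    corrs = np.asarray(corrs); r2ys = np.asarray(r2ys); q2s = np.asarray(q2s)
    if np.ptp(corrs) == 0:  # flat series: intercept is the common level
        r2y_int, q2_int = float(np.mean(r2ys)), float(np.mean(q2s))
    else:
        r2y_int = float(np.polyfit(corrs, r2ys, 1)[1])
        q2_int = float(np.polyfit(corrs, q2s, 1)[1])
    return PermutationValidation(correlations=corrs, r2y=r2ys, q2=q2s,
                                 r2y_intercept=r2y_int, q2_intercept=q2_int)
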