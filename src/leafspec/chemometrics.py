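"""PCA and PLS regression, written from first principles.

PCA is the singular value decomposition of the column-centered (optionally
autoscaled) data matrix; factor loadings are Pearson correlations between the
original pretreated variables and a component's score vector.

PLS regression uses the SIMPLS algorithm (de Jong 1993) by default, with
NIPALS available for cross-validation of the implementation; for a single
response the two produce identical prediction operators. Model selection uses
leave-one-out cross-validation with R^2 = 1 - PRESS/SST, where pretreatment
column statistics and the PLS model are refit on each fold's training rows —
the leakage-free protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SpectrumSet
from .preprocess import PretreatmentSpec, apply_rows, center_scale

__all__ = [
    "PCAResult",
    "pca",
    "factor_loading",
    "PLSModel",
    "pls_fit",
    "CVEntry",
    "loocv",
    "split_predict",
    "sweep",
]


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # variables x components
    explained_variance_ratio: np.ndarray
    singular_values: np.ndarray
    mean: np.ndarray | None
    sd: np.ndarray | None


def pca(X: np.ndarray, scaling: bool = False, *, pre_centered: bool = False) -> PCAResult:
    """PCA by SVD of the centered (optionally autoscaled) matrix.

    Sign convention: the largest-magnitude loading element of each component
    is made positive, so score plots reproduce across runs and BLAS builds.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with >= 2 rows")
    mean = sd = None
    if not pre_centered:
        mean = X.mean(axis=0)
        X = X - mean
        if scaling:
            sd = X.std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise ValueError("autoscaling undefined for zero-variance columns")
            X = X / sd
    if not np.any(X):
        raise ValueError("matrix has rank 0 after centering")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: flip so the largest |loading| entry is positive
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = s**2
    return PCAResult(
        scores=U * s,
        loadings=Vt.T,
        explained_variance_ratio=var / var.sum(),
        singular_values=s,
        mean=mean,
        sd=sd,
    )


def factor_loading(
    X_pre: np.ndarray, result: PCAResult | np.ndarray, component: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation of each pretreated variable with one component's scores.

    Returns (correlations, undefined_mask); zero-variance variables get NaN
    and are flagged rather than silently dropped.
    """
    X_pre = np.asarray(X_pre, dtype=float)
    t = result[:, component] if isinstance(result, np.ndarray) else result.scores[:, component]
    if len(t) != X_pre.shape[0]:
        raise ValueError("score vector length must match rows")
    Xc = X_pre - X_pre.mean(axis=0)
    tc = t - t.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    st = np.sqrt((tc**2).sum())
    # constant columns (exactly, or to within centering round-off) are undefined
    undefined = (np.ptp(X_pre, axis=0) == 0) | (sx == 0) | (st == 0)
    sx = np.where(undefined, np.nan, sx)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc.T @ tc) / (sx * st)
    corr[undefined] = np.nan
    return corr, undefined


# ---------------------------------------------------------------------------
# PLS

@dataclass
class PLSModel:
    """Univariate-response PLS model with a coefficient path per component."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray  # p x A (projection weights R: T = Xc @ R)
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    scores: np.ndarray  # n x A, mutually orthogonal
    coef_path: np.ndarray  # p x A; column a-1 = coefficients using a components
    algorithm: str = "simpls"

    @property
    def coef(self) -> np.ndarray:
        return self.coef_path[:, self.n_components - 1]

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        a = self.n_components if n_components is None else n_components
        if not 1 <= a <= self.coef_path.shape[1]:
            raise ValueError("n_components out of fitted range")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef_path[:, a - 1] + self.y_mean


def _simpls(Xc: np.ndarray, yc: np.ndarray, A: int):
    n, p = Xc.shape
    R = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    V = np.zeros((p, A))
    s = Xc.T @ yc
    a = 0
    for a in range(A):
        r = s.copy()  # univariate response: the dominant (only) singular vector
        t = Xc @ r
        nt = np.linalg.norm(t)
        if nt < 1e-12:
            break
        t /= nt
        r /= nt
        pl = Xc.T @ t
        ql = float(yc @ t)
        v = pl.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pl)
            v -= V[:, :a] @ (V[:, :a].T @ v)  # reorthogonalise for stability
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            break
        v /= nv
        s = s - v * (v @ s)
        R[:, a], P[:, a], q[a], T[:, a], V[:, a] = r, pl, ql, t, v
        a += 1
    return R[:, :a], P[:, :a], q[:a], T[:, :a]


def _nipals(Xc: np.ndarray, yc: np.ndarray, A: int):
    n, p = Xc.shape
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    X = Xc.copy()
    a = 0
    for a in range(A):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-24:
            break
        pl = X.T @ t / tt
        ql = float(yc @ t) / tt
        X = X - np.outer(t, pl)
        W[:, a], P[:, a], q[a], T[:, a] = w, pl, ql, t
        a += 1
    W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
    # projection weights mapping the *original* centered X to scores
    R = W @ np.linalg.inv(P.T @ W) if a else W
    return R, P, q, T


def pls_fit(
    X: np.ndarray, y: np.ndarray, n_components: int, algorithm: str = "simpls"
) -> PLSModel:
    """Fit univariate PLS, extracting components that maximise cov(t, y)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y length must match rows of X")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError("n_components must be in [1, min(rows-1, columns)]")
    if np.ptp(y) == 0:
        raise ValueError("constant response: PLS undefined")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    if algorithm == "simpls":
        R, P, q, T = _simpls(Xc, yc, n_components)
    elif algorithm == "nipals":
        R, P, q, T = _nipals(Xc, yc, n_components)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if R.shape[1] == 0:
        raise ValueError("no PLS component could be extracted")
    coef_path = np.cumsum(R * q[None, :], axis=1)
    return PLSModel(
        n_components=R.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=R,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef_path=coef_path,
        algorithm=algorithm,
    )


# ---------------------------------------------------------------------------
# leave-one-out cross-validation

@dataclass
class CVEntry:
    """LOOCV result for one (pretreatment, response) pair."""

    pretreatment: str
    response: str
    r2_by_ncomp: np.ndarray  # index a-1 -> R^2 with a components
    best_ncomp: int
    best_r2: float
    invalid_folds: list = field(default_factory=list)

    @property
    def r2(self) -> float:
        return self.best_r2


def _as_matrix(X, spec: PretreatmentSpec | None) -> np.ndarray:
    if isinstance(X, SpectrumSet):
        X = X.values
    X = np.asarray(X, dtype=float)
    # SNV/smoothing/derivatives act on one row at a time, so applying them
    # before the fold split is identical to refitting them per fold
    return apply_rows(X, spec) if spec is not None else X


def loocv(
    X,
    y: np.ndarray,
    spec: PretreatmentSpec | None = None,
    max_components: int = 10,
    response: str = "y",
    algorithm: str = "simpls",
    scaling: bool | None = None,
) -> CVEntry:
    """Leave-one-out CV of the pretreat -> center/scale -> PLS pipeline.

    R^2 = 1 - PRESS/SST with SST about the overall response mean; the best
    component count maximises R^2 (ties resolved toward fewer components).
    ``scaling`` overrides the spec's flag when the row-wise pretreatment has
    already been applied and ``spec`` is None.
    """
    Xr = _as_matrix(X, spec)
    y = np.asarray(y, dtype=float).ravel()
    n = Xr.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs >= 3 samples")
    if len(y) != n:
        raise ValueError("y length must match samples")
    if scaling is None:
        scaling = spec.scaling if spec is not None else False
    A = min(max_components, n - 2, Xr.shape[1])
    press = np.zeros(A)
    fitted_a = A
    invalid = []
    pred = np.full((n, A), np.nan)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            Xt, stats = center_scale(Xr[keep], scaling=scaling)
            model = pls_fit(Xt, y[keep], min(A, Xt.shape[1]), algorithm=algorithm)
            Xi = stats.apply(Xr[i : i + 1])
            for a in range(model.coef_path.shape[1]):
                pred[i, a] = model.predict(Xi, n_components=a + 1)[0]
            fitted_a = min(fitted_a, model.coef_path.shape[1])
        except ValueError as exc:
            invalid.append((i, str(exc)))
    valid = ~np.isnan(pred[:, 0])
    if valid.sum() < 3:
        raise ValueError("too few valid LOOCV folds")
    sst = float(((y[valid] - y[valid].mean()) ** 2).sum())
    r2 = np.empty(fitted_a)
    for a in range(fitted_a):
        press = float(((y[valid] - pred[valid, a]) ** 2).sum())
        r2[a] = 1.0 - press / sst
    best = int(np.argmax(r2))  # first maximum -> fewest components on ties
    return CVEntry(
        pretreatment="(none)" if spec is None else spec.name,
        response=response,
        r2_by_ncomp=r2,
        best_ncomp=best + 1,
        best_r2=float(r2[best]),
        invalid_folds=invalid,
    )


# ---------------------------------------------------------------------------
# train/test split prediction and the pretreatment sweep

def split_predict(
    train_spectra: SpectrumSet,
    train_expr,
    test_spectra: SpectrumSet,
    spec: PretreatmentSpec,
    n_components: int = 5,
    test_expr=None,
) -> pd.DataFrame:
    """Fit per-cluster PLS models on the training split and predict the test split.

    Pretreatment column statistics and models are fit on training rows only.
    Returns a long frame (sample_id, cluster, predicted[, observed]).
    """
    train_ids = set(train_spectra.meta["sample_id"])
    test_ids = set(test_spectra.meta["sample_id"])
    if train_ids & test_ids:
        raise ValueError("train and test sample ids overlap")
    if list(train_spectra.meta["sample_id"]) != list(train_expr.meta["sample_id"]):
        raise ValueError("training spectra and expression are not aligned")

    Xtr_rows = apply_rows(train_spectra.values, spec)
    Xte_rows = apply_rows(test_spectra.values, spec)
    Xtr, stats = center_scale(Xtr_rows, scaling=spec.scaling)
    Xte = stats.apply(Xte_rows)

    frames = []
    for j, cluster in enumerate(train_expr.clusters):
        y = train_expr.values[:, j]
        a = min(n_components, Xtr.shape[0] - 1, Xtr.shape[1])
        model = pls_fit(Xtr, y, a)
        pred = model.predict(Xte)
        frame = pd.DataFrame(
            {
                "sample_id": test_spectra.meta["sample_id"].to_numpy(),
                "cluster": cluster,
                "predicted": pred,
            }
        )
        if test_expr is not None:
            frame["observed"] = test_expr.values[:, j]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def sweep(
    spectra: SpectrumSet,
    expr,
    specs: list[PretreatmentSpec],
    max_components: int = 10,
) -> pd.DataFrame:
    """Full pretreatment x cluster grid of LOOCV R^2 (one row per pair).

    Columns: pretreatment, cluster, best_ncomp, r2. The per-cluster best
    pretreatment is the row with maximal r2 within each cluster group.
    """
    if not specs:
        raise ValueError("empty pretreatment registry")
    if spectra.n_samples != expr.n_samples:
        raise ValueError("spectra and expression sample counts differ")
    rows = []
    for spec in specs:
        # row-wise transforms are per-sample, so they can be shared across
        # clusters and folds; center/scale statistics are refit inside loocv
        Xr = apply_rows(spectra.values, spec)
        for j, cluster in enumerate(expr.clusters):
            entry = loocv(
                Xr,
                expr.values[:, j],
                spec=None,
                max_components=max_components,
                scaling=spec.scaling,
            )
            rows.append(
                dict(
                    pretreatment=spec.name,
                    cluster=cluster,
                    best_ncomp=entry.best_ncomp,
                    r2=entry.best_r2,
                )
            )
    return pd.DataFrame(rows)
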