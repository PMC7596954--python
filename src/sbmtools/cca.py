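"""Canonical correlation between ICA loadings and symptom batteries.

Plain (unregularized) CCA solved through QR + SVD of the whitened
cross-covariance.  Significance of the main (first) mode is assessed by
permuting the rows of the behavior block and recomputing the first
canonical correlation, with a Bonferroni threshold of
``0.05 / n_modes``.  Raw canonical coefficients are accompanied by
"corrected" coefficients in structure-coefficient form — the correlation
of each original variable with its own set's canonical variate — which
is the interpretable per-variable contribution used for reporting.
Reliability is probed by leave-one-out refitting and by a subsampling
curve of sign-aligned weight correlations versus sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats


class DegenerateColumnError(ValueError):
    """A zero-variance column makes CCA undefined."""


@dataclass
class CCAResult:
    """Canonical correlations, weights, variates and mode inference."""

    correlations: np.ndarray  # (m,) non-increasing, in [0, 1]
    x_weights: np.ndarray  # (px, m) raw canonical coefficients (z-scored X)
    y_weights: np.ndarray  # (py, m)
    x_corrected: np.ndarray  # (px, m) structure coefficients
    y_corrected: np.ndarray  # (py, m)
    x_variates: np.ndarray  # (n, m), unit variance
    y_variates: np.ndarray  # (n, m)
    n_modes: int
    n_samples: int
    perm_p: np.ndarray | None = None  # filled by permutation_test
    n_perm: int = 0
    x_columns: list = field(default_factory=list)
    y_columns: list = field(default_factory=list)

    @property
    def bonferroni_alpha(self) -> float:
        return 0.05 / self.n_modes


@dataclass
class StabilityReport:
    """Leave-one-out weight stability of the main CCA mode."""

    loo_weight_corr_x: np.ndarray  # per-fold sign-aligned correlations
    loo_weight_corr_y: np.ndarray
    mean_x: float
    mean_y: float
    failed_folds: list


def _prepare(x, y) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Complete cases, z-scored columns; names from DataFrames if given."""
    x_cols = list(x.columns) if isinstance(x, pd.DataFrame) else None
    y_cols = list(y.columns) if isinstance(y, pd.DataFrame) else None
    X = np.asarray(x, dtype=np.float64)
    Y = np.asarray(y, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("x and y must have the same number of rows")
    keep = ~(np.isnan(X).any(axis=1) | np.isnan(Y).any(axis=1))
    X, Y = X[keep], Y[keep]
    x_cols = x_cols or [f"x{j + 1}" for j in range(X.shape[1])]
    y_cols = y_cols or [f"y{j + 1}" for j in range(Y.shape[1])]
    for name, M, cols in (("x", X, x_cols), ("y", Y, y_cols)):
        sd = M.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise DegenerateColumnError(
                f"zero-variance column(s) in {name}: {[cols[j] for j in dead]}"
            )
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    Yz = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    return Xz, Yz, x_cols, y_cols


def _cca_core(Xz: np.ndarray, Yz: np.ndarray):
    """Correlations and weights via QR of each block and SVD of Qx^T Qy."""
    n = Xz.shape[0]
    Qx, Rx = np.linalg.qr(Xz)
    Qy, Ry = np.linalg.qr(Yz)
    U, s, Vt = np.linalg.svd(Qx.T @ Qy)
    m = min(Xz.shape[1], Yz.shape[1])
    corr = np.clip(s[:m], 0.0, 1.0)

    def _back_solve(R: np.ndarray, B: np.ndarray) -> np.ndarray:
        if R.shape[0] == R.shape[1] and np.abs(np.diag(R)).min() > 1e-10 * np.abs(np.diag(R)).max():
            return linalg.solve_triangular(R, B)
        return np.linalg.pinv(R) @ B  # ill-posed/rank-deficient block

    wx = _back_solve(Rx, U[:, :m]) * np.sqrt(n - 1)
    wy = _back_solve(Ry, Vt.T[:, :m]) * np.sqrt(n - 1)
    return corr, wx, wy


def first_canonical_correlation(x, y) -> float:
    """First canonical correlation of two blocks (complete cases)."""
    Xz, Yz, _, _ = _prepare(x, y)
    corr, _, _ = _cca_core(Xz, Yz)
    return float(corr[0])


def fit_cca(x, y) -> CCAResult:
    """Fit plain CCA between two blocks; rows with missing y/x dropped.

    Columns are z-scored first (symptom scales have heterogeneous
    units).  Variates are the products of the centered data with the
    canonical coefficients, scaled to unit variance.  A warning is
    emitted when ``n <= px`` (perfect in-sample correlations are then
    guaranteed and the fit is overfit by construction).
    """
    Xz, Yz, x_cols, y_cols = _prepare(x, y)
    n = Xz.shape[0]
    if n <= max(Xz.shape[1], Yz.shape[1]):
        warnings.warn(
            f"n = {n} does not exceed the larger block size "
            f"({max(Xz.shape[1], Yz.shape[1])}); CCA is overfit by construction",
            stacklevel=2,
        )
    corr, wx, wy = _cca_core(Xz, Yz)
    xv = Xz @ wx
    yv = Yz @ wy
    # enforce unit variance exactly (QR scaling is exact up to rounding)
    xv /= xv.std(axis=0, ddof=1)
    yv /= yv.std(axis=0, ddof=1)
    m = corr.shape[0]
    res = CCAResult(
        correlations=corr,
        x_weights=wx,
        y_weights=wy,
        x_corrected=np.empty((Xz.shape[1], m)),
        y_corrected=np.empty((Yz.shape[1], m)),
        x_variates=xv,
        y_variates=yv,
        n_modes=m,
        n_samples=n,
        x_columns=x_cols,
        y_columns=y_cols,
    )
    res.x_corrected, res.y_corrected = correct_coefficients(res, Xz, Yz)
    return res


def correct_coefficients(result: CCAResult, x, y) -> tuple[np.ndarray, np.ndarray]:
    """Structure-coefficient correction of raw canonical weights.

    The corrected coefficient of variable ``j`` for a mode is the
    Pearson correlation between that variable and the mode's canonical
    variate from its own set.  Unlike raw weights, corrected values are
    stable under collinearity and drive the per-variable contribution
    ranking used for reporting.
    """
    X = np.asarray(x, dtype=np.float64)
    Y = np.asarray(y, dtype=np.float64)
    xc = X - X.mean(axis=0)
    yc = Y - Y.mean(axis=0)

    def _corr_block(block: np.ndarray, variates: np.ndarray) -> np.ndarray:
        bs = block.std(axis=0, ddof=1)
        vs = variates.std(axis=0, ddof=1)
        cov = block.T @ (variates - variates.mean(axis=0)) / (block.shape[0] - 1)
        return cov / np.outer(bs, vs)

    return _corr_block(xc, result.x_variates), _corr_block(yc, result.y_variates)


def permutation_test(
    x, y, n_perm: int = 10000, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Permutation p of the main CCA mode: shuffle y rows, refit r1.

    Returns ``(p, null_distribution)`` with the conservative estimate
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)``, honoring the lower
    bound ``1/(n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Xz, Yz, _, _ = _prepare(x, y)
    n = Xz.shape[0]
    Qx, _ = np.linalg.qr(Xz)
    Qy, _ = np.linalg.qr(Yz)
    r_obs = float(np.linalg.svd(Qx.T @ Qy, compute_uv=False)[0])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        # rows of an orthonormal-column matrix can be permuted directly:
        # the permuted columns still span the permuted y block
        null[b] = np.linalg.svd(Qx.T @ Qy[perm], compute_uv=False)[0]
    p = (1.0 + np.sum(null >= r_obs)) / (n_perm + 1.0)
    return float(p), null


def _aligned_corr(w: np.ndarray, w_ref: np.ndarray) -> float:
    """Pearson correlation of weight vectors after sign alignment."""
    sign = 1.0 if float(w @ w_ref) >= 0 else -1.0
    if w.std() == 0 or w_ref.std() == 0:
        return np.nan
    return float(np.corrcoef(sign * w, w_ref)[0, 1])


def loo_stability(x, y) -> StabilityReport:
    """Leave-one-out reliability of the main mode's canonical weights.

    Each fold refits CCA on n-1 subjects, sign-aligns the first-mode
    weights to the full-sample solution, and records their correlation
    (brain and behavior sides separately).
    """
    Xz, Yz, _, _ = _prepare(x, y)
    n = Xz.shape[0]
    if n < 10:
        raise ValueError("leave-one-out requires at least 10 subjects")
    _, wx_full, wy_full = _cca_core(Xz, Yz)
    cx, cy, failed = [], [], []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            _, wx_i, wy_i = _cca_core(Xz[keep], Yz[keep])
            cx.append(_aligned_corr(wx_i[:, 0], wx_full[:, 0]))
            cy.append(_aligned_corr(wy_i[:, 0], wy_full[:, 0]))
        except (np.linalg.LinAlgError, ValueError):
            failed.append(i)
            warnings.warn(f"leave-one-out fold {i} failed; excluded", stacklevel=2)
    cx, cy = np.asarray(cx), np.asarray(cy)
    return StabilityReport(
        loo_weight_corr_x=cx,
        loo_weight_corr_y=cy,
        mean_x=float(np.nanmean(cx)),
        mean_y=float(np.nanmean(cy)),
        failed_folds=failed,
    )


def subsample_reproducibility(
    x, y, sizes, n_draws: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Sign-aligned weight correlation with the full-sample mode vs n.

    For each requested size, ``n_draws`` random subsets are refit and
    the first-mode x-weight correlation with the full-sample weights is
    recorded.  Sizes not exceeding ``max(px, py)`` are ill-posed (CCA is
    overfit by construction); they are flagged but still attempted.
    Returns a DataFrame with size, mean_corr, sd_corr, se_corr, ill_posed.
    """
    Xz, Yz, _, _ = _prepare(x, y)
    n, px = Xz.shape
    py = Yz.shape[1]
    _, wx_full, _ = _cca_core(Xz, Yz)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > n:
            raise ValueError(f"subsample size {size} exceeds n = {n}")
        ill_posed = size <= max(px, py)
        vals = []
        for _ in range(n_draws):
            idx = rng.choice(n, size=size, replace=False)
            if size == n:
                vals.append(1.0)
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, wx_s, _ = _cca_core(Xz[idx], Yz[idx])
                vals.append(_aligned_corr(wx_s[:, 0], wx_full[:, 0]))
            except (np.linalg.LinAlgError, ValueError):
                vals.append(np.nan)
        vals = np.asarray(vals)
        rows.append(
            {
                "size": int(size),
                "mean_corr": float(np.nanmean(vals)),
                "sd_corr": float(np.nanstd(vals, ddof=1)),
                "se_corr": float(np.nanstd(vals, ddof=1) / np.sqrt(np.sum(~np.isnan(vals)))),
                "ill_posed": bool(ill_posed),
            }
        )
    return pd.DataFrame(rows)
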