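"""Spatial ICA decomposition of subject-by-voxel GM density matrices.

Follows the source-based morphometry convention: the stacked maps are
PCA-whitened to the requested model order and a fixed-point ICA rotation
(log-cosh contrast, symmetric decorrelation) is sought that makes the
*spatial* maps maximally non-Gaussian.  Each component is then a
z-scored spatial source with a per-participant loading column (the
mixing matrix).  Two ambiguities inherent to ICA are resolved by
convention: component order follows loading variance (descending), and
each component's sign is flipped so its spatial skewness is positive.

Model order can be fixed, or estimated from the eigenspectrum either by
a cumulative-variance threshold or by a Laplace approximation to the
PCA model evidence (Minka), treating voxels as samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .dataset import GMDataset


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed in every restart."""

    def __init__(self, message: str, records: list):
        super().__init__(message)
        self.records = records


@dataclass
class ICADecomposition:
    """Spatial sources (z-scored), participant loadings and bookkeeping.

    ``loadings @ sources + mean_map`` reconstructs the rank-``order``
    PCA projection of the input matrix exactly (ICA is a rotation of the
    whitened subspace).
    """

    sources: np.ndarray  # (d, V), each row mean 0 / sd 1
    loadings: np.ndarray  # (N, d) mixing matrix
    mean_map: np.ndarray  # (V,) voxel means removed before whitening
    subject_offset: np.ndarray  # (N,) residual offset from source z-scoring
    order: int
    explained_variance: float  # variance fraction kept by whitening
    convergence: list = field(default_factory=list)  # one record per restart
    seed: int = 0

    @property
    def standardized_loadings(self) -> np.ndarray:
        """Loadings scaled to unit variance per column (for GLM use)."""
        sd = self.loadings.std(axis=0, ddof=1)
        return self.loadings / np.where(sd > 0, sd, 1.0)

    def reconstruct(self) -> np.ndarray:
        return (
            self.loadings @ self.sources
            + self.mean_map
            + self.subject_offset[:, None]
        )


@dataclass
class ComponentMatch:
    """One-to-one component correspondence between two decompositions."""

    pairs: list  # (index in a, index in b, |spatial r|)
    unmatched_a: list
    unmatched_b: list


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, GMDataset):
        return data.data
    return np.asarray(data, dtype=np.float64)


# --------------------------------------------------------------- model order


def _laplace_evidence(spectrum: np.ndarray, rank: int, n_samples: int) -> float:
    """Log-evidence of a rank-``rank`` PCA model (Laplace/Minka approximation).

    ``spectrum`` holds covariance eigenvalues (descending) of
    ``n_features`` variables estimated from ``n_samples`` observations.
    """
    n_features = spectrum.shape[0]
    if rank >= n_features:
        raise ValueError("rank must be < number of eigenvalues")
    v = spectrum[rank:].mean()  # residual variance
    if v <= 0:
        return -np.inf
    # dimension of the Stiefel manifold of rank-d bases
    m = n_features * rank - rank * (rank + 1) / 2.0
    i = np.arange(1, rank + 1)
    pu = -rank * np.log(2.0) + np.sum(
        gammaln((n_features - i + 1) / 2.0)
        - np.log(np.pi) * (n_features - i + 1) / 2.0
    )
    pl = -np.sum(np.log(spectrum[:rank])) * n_samples / 2.0
    pv = -np.log(v) * n_samples * (n_features - rank) / 2.0
    pp = np.log(2.0 * np.pi) * (m + rank) / 2.0
    spectrum_ = spectrum.copy()
    spectrum_[rank:] = v
    diff = spectrum[:rank, None] - spectrum[None, :]
    inv_diff = 1.0 / spectrum_[None, :] - 1.0 / spectrum_[:rank, None]
    upper = np.arange(n_features)[None, :] > np.arange(rank)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.log(diff * inv_diff * n_samples)
    pa = float(terms[upper].sum())
    if not np.isfinite(pa):
        return -np.inf
    return pu + pl + pv + pp - pa / 2.0 - rank * np.log(n_samples) / 2.0


def estimate_order(
    data,
    method: str = "laplace",
    variance_fraction: float = 0.9,
    max_order: int | None = None,
) -> int:
    """Estimate the ICA model order from the PCA eigenspectrum.

    ``laplace`` maximizes the Laplace-approximated model evidence over
    candidate ranks; ``variance_threshold`` returns the smallest rank
    whose cumulative eigenvalue fraction reaches ``variance_fraction``.
    Rank-deficient data are truncated to numerical rank first.
    """
    X = _as_matrix(data)
    n, v = X.shape
    if n < 10:
        raise ValueError("order estimation requires at least 10 subjects")
    Xc = X - X.mean(axis=0)
    s = linalg.svdvals(Xc)
    tol = s[0] * max(n, v) * np.finfo(float).eps
    num_rank = int((s > tol).sum())
    eig = (s[:num_rank] ** 2) / v  # covariance eigenvalues, voxels as samples
    upper = min(num_rank, n - 1)
    if max_order is not None:
        upper = min(upper, max_order)
    if method == "variance_threshold":
        frac = np.cumsum(eig) / eig.sum()
        d = int(np.searchsorted(frac, variance_fraction) + 1)
        return min(max(d, 1), upper)
    if method != "laplace":
        raise ValueError(f"unknown method {method!r}")
    if upper < 2:
        return max(upper, 1)
    ll = np.array(
        [_laplace_evidence(eig[:upper + 1], d, v) for d in range(1, upper)]
    )
    return int(np.argmax(ll) + 1)


# ---------------------------------------------------------------- decompose


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    s, u = linalg.eigh(W @ W.T)
    s = np.clip(s, np.finfo(float).tiny, None)
    return (u * (1.0 / np.sqrt(s))) @ u.T @ W


def _fastica_rotation(
    Y: np.ndarray, rng: np.random.Generator, tol: float, max_iter: int
) -> tuple[np.ndarray, dict]:
    """Fixed-point ICA on whitened spatial data Y (d x V), log-cosh contrast."""
    d, v = Y.shape
    W = _sym_decorrelate(rng.standard_normal((d, d)))
    lim = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        WY = W @ Y
        g = np.tanh(WY)
        g_prime = (1.0 - g**2).mean(axis=1)
        W1 = _sym_decorrelate(g @ Y.T / v - g_prime[:, None] * W)
        lim = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W1, W)) - 1.0)))
        W = W1
        if lim < tol:
            break
    # negentropy-style contrast: deviation of E[log cosh] from Gaussian
    e_logcosh = np.log(np.cosh(W @ Y)).mean(axis=1)
    gauss_ref = 0.3745672075250936  # E[log cosh(z)], z standard normal
    contrast = float(np.sum((e_logcosh - gauss_ref) ** 2))
    record = {"iterations": it, "final_tol": lim, "converged": lim < tol,
              "contrast": contrast}
    return W, record


def decompose(
    data,
    order: int,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    variance_normalize: bool = False,
) -> ICADecomposition:
    """PCA-whiten to ``order`` dimensions and run spatial fixed-point ICA.

    The input is column-wise (voxel-wise) demeaned internally; with
    ``variance_normalize`` voxels are additionally scaled to unit
    variance before whitening.  The best of ``n_restarts`` random
    rotations by final contrast value is kept.  Deterministic given
    ``seed``.
    """
    X = _as_matrix(data)
    n, v = X.shape
    if not 1 <= order <= min(n, v):
        raise ValueError(f"order must lie in [1, {min(n, v)}]")
    col_mean = X.mean(axis=0)
    Xc = X - col_mean
    col_scale = np.ones(v)
    if variance_normalize:
        sd = Xc.std(axis=0)
        col_scale = np.where(sd > 0, sd, 1.0)
        Xc = Xc / col_scale

    U, s, Vt = linalg.svd(Xc, full_matrices=False)
    explained = float(np.sum(s[:order] ** 2) / np.sum(s**2))
    Y = Vt[:order] * np.sqrt(v)  # whitened spatial data: Y Y^T / v = I

    master = np.random.default_rng(seed)
    restart_seeds = master.integers(0, 2**31 - 1, size=n_restarts)
    best: tuple[np.ndarray, dict] | None = None
    records = []
    if order == 1:
        W = np.ones((1, 1))
        rec = {"iterations": 0, "final_tol": 0.0, "converged": True,
               "contrast": float(np.sum((np.log(np.cosh(Y)).mean() - 0.37456720752) ** 2))}
        best, records = (W, rec), [rec]
    else:
        for rs in restart_seeds:
            W, rec = _fastica_rotation(
                Y, np.random.default_rng(int(rs)), tol, max_iter
            )
            records.append(rec)
            if rec["converged"] and (best is None or rec["contrast"] > best[1]["contrast"]):
                best = (W, rec)
        if best is None:
            raise ConvergenceError(
                f"fixed-point ICA did not converge in any of {n_restarts} "
                f"restarts (max_iter={max_iter}, tol={tol})",
                records,
            )
    W = best[0]

    sources_raw = W @ Y  # (d, V), rows approx zero mean / unit variance
    loadings_raw = (U[:, :order] * s[:order]) @ W.T / np.sqrt(v)
    # exact z-scoring of sources, with loadings/mean absorbing the shift
    mu = sources_raw.mean(axis=1)
    sd = sources_raw.std(axis=1)
    sd = np.where(sd > 0, sd, 1.0)
    sources = (sources_raw - mu[:, None]) / sd[:, None]
    loadings = loadings_raw * sd
    # reconstruction (on the normalized scale if variance_normalize):
    # loadings @ sources + mean_map + subject_offset[:, None]
    mean_map = col_mean / col_scale if variance_normalize else col_mean
    subject_offset = loadings_raw @ mu

    # sign convention: positive spatial skewness
    skew = stats.skew(sources, axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    sources *= flip[:, None]
    loadings *= flip

    # order by loading variance (explained variance), descending
    idx = np.argsort(-loadings.var(axis=0))
    sources = sources[idx]
    loadings = loadings[:, idx]

    return ICADecomposition(
        sources=sources,
        loadings=loadings,
        mean_map=mean_map,
        subject_offset=subject_offset,
        order=order,
        explained_variance=explained,
        convergence=records,
        seed=seed,
    )


# ------------------------------------------------------------------ matching


def spatial_correlation_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation between rows of two source matrices."""
    if a.shape[1] != b.shape[1]:
        raise ValueError("source matrices have different voxel counts")
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return np.abs(az @ bz.T)


def match_components(
    a: ICADecomposition | np.ndarray,
    b: ICADecomposition | np.ndarray,
    min_abs_r: float = 0.5,
) -> ComponentMatch:
    """Optimal one-to-one matching of components by |spatial correlation|.

    Uses the Hungarian assignment maximizing total |r|; pairs whose |r|
    falls below ``min_abs_r`` are reported as unmatched.  Sign and
    permutation ambiguity of ICA are thereby handled.
    """
    sa = a.sources if isinstance(a, ICADecomposition) else np.asarray(a, float)
    sb = b.sources if isinstance(b, ICADecomposition) else np.asarray(b, float)
    C = spatial_correlation_matrix(sa, sb)
    rows, cols = linear_sum_assignment(-C)
    pairs, una, unb = [], set(range(sa.shape[0])), set(range(sb.shape[0]))
    for i, j in zip(rows, cols):
        r = float(C[i, j])
        if r >= min_abs_r:
            pairs.append((int(i), int(j), r))
            una.discard(int(i))
            unb.discard(int(j))
    return ComponentMatch(
        pairs=pairs, unmatched_a=sorted(una), unmatched_b=sorted(unb)
    )
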