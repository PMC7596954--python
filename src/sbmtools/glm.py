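"""Per-component GLM of participant loadings on diagnosis, with FDR.

Each ICA loading column is regressed on diagnostic group plus nuisance
covariates (age, sex, FSIQ, site; optionally ADHD comorbidity, age^2 and
group-interaction terms).  The group coefficient's t statistic, two-sided
p value and Cohen's d (computed from t, so it is covariate-adjusted) are
reported per component, with Benjamini-Hochberg FDR control across
components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Term sets matching the main analysis and its sensitivity variants.
DEFAULT_TERMS = ("group", "age", "sex", "fsiq", "site")
ADHD_TERMS = DEFAULT_TERMS + ("adhd",)

_TERM_COLUMNS = {
    "group": ["diagnosis"],
    "age": ["age"],
    "sex": ["sex"],
    "fsiq": ["fsiq"],
    "site": ["site"],
    "adhd": ["adhd"],
    "age2": ["age"],
    "age_by_group": ["age", "diagnosis"],
    "age2_by_group": ["age", "diagnosis"],
    "sex_by_group": ["sex", "diagnosis"],
}


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient after dummy coding."""


@dataclass
class DesignMatrix:
    """Named design matrix plus the retained (complete-case) row index."""

    matrix: np.ndarray  # (n_used, p)
    columns: list  # regressor names, 'group' is the effect of interest
    row_index: np.ndarray  # positional indices into the original table
    group_sizes: tuple  # (n TD, n autism) among retained rows

    @property
    def group_col(self) -> int:
        return self.columns.index("group")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GLMFit:
    """Group-effect statistics per component, with BH-FDR decisions."""

    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    d: np.ndarray  # Cohen's d = t * sqrt(1/n1 + 1/n2)
    fdr_significant: np.ndarray
    fdr_threshold: float  # largest rejected p (NaN if none rejected)
    df_resid: int
    n_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": [f"IC{i + 1:02d}" for i in range(len(self.beta))],
                "beta": self.beta,
                "t": self.t,
                "p": self.p,
                "d": self.d,
                "fdr_significant": self.fdr_significant,
            }
        )


def build_design(
    table: pd.DataFrame, formula_terms=DEFAULT_TERMS
) -> DesignMatrix:
    """Build the GLM design from a phenotype table.

    Group is coded TD=0 / autism=1, sex female=0 / male=1, site by
    reference dummy coding (first site alphabetically dropped).  Rows
    with missing values in any required column are dropped listwise.
    Raises :class:`RankDeficiencyError` naming collinear columns if the
    coded matrix is rank deficient.
    """
    terms = list(formula_terms)
    if "group" not in terms:
        raise ValueError("the 'group' term is required")
    needed = sorted({c for t in terms for c in _TERM_COLUMNS[t]})
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise ValueError(f"phenotype table lacks columns: {missing_cols}")
    keep = ~table[needed].isna().any(axis=1)
    sub = table.loc[keep]
    row_index = np.flatnonzero(keep.to_numpy())

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sub))}
    group = (sub["diagnosis"].astype(str) == "autism").to_numpy(float)
    for term in terms:
        if term == "group":
            cols["group"] = group
        elif term == "age":
            cols["age"] = sub["age"].to_numpy(float)
        elif term == "age2":
            cols["age2"] = sub["age"].to_numpy(float) ** 2
        elif term == "sex":
            cols["sex"] = (sub["sex"].astype(str) == "male").to_numpy(float)
        elif term == "fsiq":
            cols["fsiq"] = sub["fsiq"].to_numpy(float)
        elif term == "adhd":
            cols["adhd"] = sub["adhd"].to_numpy(float)
        elif term == "site":
            levels = sorted(sub["site"].astype(str).unique())
            for lev in levels[1:]:  # first level is the reference
                cols[f"site[{lev}]"] = (sub["site"].astype(str) == lev).to_numpy(float)
        elif term == "age_by_group":
            cols["age_by_group"] = sub["age"].to_numpy(float) * group
        elif term == "age2_by_group":
            cols["age2_by_group"] = sub["age"].to_numpy(float) ** 2 * group
        elif term == "sex_by_group":
            cols["sex_by_group"] = (
                (sub["sex"].astype(str) == "male").to_numpy(float) * group
            )
        else:
            raise ValueError(f"unknown term {term!r}")

    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate offending columns via pivoted QR
        from scipy.linalg import qr as _qr

        _, _, piv = _qr(X, mode="economic", pivoting=True)
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )
    n_aut = int(group.sum())
    return DesignMatrix(
        matrix=X,
        columns=names,
        row_index=row_index,
        group_sizes=(len(sub) - n_aut, n_aut),
    )


def fit_loading_glm(loadings: np.ndarray, design: DesignMatrix, q: float = 0.05) -> GLMFit:
    """OLS of each loading column on the design; group-effect inference.

    ``loadings`` rows must already be aligned to ``design.row_index``
    (i.e. pass ``all_loadings[design.row_index]``).  Cohen's d is derived
    from the group t statistic as ``t * sqrt(1/n1 + 1/n2)``.
    """
    Y = np.asarray(loadings, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"loadings have {Y.shape[0]} rows but design has {X.shape[0]}"
        )
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Y)  # (p, d)
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / df
    j = design.group_col
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    beta = B[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    n0, n1 = design.group_sizes
    d = t * np.sqrt(1.0 / n0 + 1.0 / n1)
    rejected, threshold = fdr_bh(pvals, q)
    sig = np.zeros(len(pvals), dtype=bool)
    sig[rejected] = True
    return GLMFit(
        beta=beta, t=t, p=pvals, d=d, fdr_significant=sig,
        fdr_threshold=threshold, df_resid=df, n_used=n,
    )


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: rejected indices and largest rejected p.

    Rejects hypotheses with p <= p_(k*), where k* is the largest rank k
    with p_(k) <= k*q/m.  Empty input yields an empty rejection set.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return np.array([], dtype=int), float("nan")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.flatnonzero(ranked <= crit)
    if passing.size == 0:
        return np.array([], dtype=int), float("nan")
    k_star = passing[-1]
    threshold = float(ranked[k_star])
    rejected = np.flatnonzero(p <= threshold)
    return rejected, threshold
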