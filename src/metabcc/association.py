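"""Covariate-adjusted linear exposure-metabolite associations with FDR control.

Each metabolite (already log-transformed and scaled to SD 1) is regressed
on a standardized exposure plus covariates by ordinary least squares; the
exposure coefficient is therefore an SD difference in the metabolite per
1-SD higher exposure. P-values use the t distribution with residual
degrees of freedom, and one Benjamini-Hochberg correction is applied per
model specification across all metabolites tested.

Categorical covariates expand to reference-coded indicators with a
deterministic scheme: levels sorted lexicographically, first level is the
reference. The coding is logged in the fitted table's attributes so a run
is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import LOG_STANDARDIZED, MetaboliteMatrix


class DesignError(ValueError):
    """Ill-posed design matrix (rank deficiency, constant column...)."""


@dataclass
class ModelSpec:
    """Specification of one exposure-metabolome regression family.

    Parameters
    ----------
    exposure
        Column of the sample table to use as exposure; standardized to
        sample SD 1 before fitting so effects are per-SD.
    covariates
        Ordered covariate names. Names in ``categorical`` are expanded to
        sorted-level reference-coded indicators; the rest enter linearly.
    categorical
        Subset of ``covariates`` (plus possibly ``extra_adjustment``) to
        treat as categorical.
    extra_adjustment
        Additional adjustment columns (e.g. BMI added to a waist
        circumference model, or a sensitivity covariate set).
    """

    exposure: str
    covariates: list[str] = field(default_factory=list)
    categorical: frozenset[str] | set[str] = field(default_factory=frozenset)
    extra_adjustment: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.exposure in self.covariates or self.exposure in self.extra_adjustment:
            raise ValueError("exposure must not appear among covariates")
        self.categorical = frozenset(self.categorical)

    @property
    def adjustment(self) -> list[str]:
        return list(self.covariates) + list(self.extra_adjustment)


def expand_design(
    df: pd.DataFrame,
    columns: list[str],
    categorical: frozenset[str] | set[str] = frozenset(),
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Build a numeric design matrix with deterministic categorical coding.

    Levels are sorted by string representation; the first sorted level is
    the reference and gets no indicator.
    """
    parts: list[pd.DataFrame] = []
    if add_intercept:
        parts.append(pd.DataFrame({"const": np.ones(len(df))}, index=df.index))
    for col in columns:
        if col not in df.columns:
            raise DesignError(f"column {col!r} not present in sample table")
        if col in categorical:
            levels = sorted(pd.unique(df[col].dropna()).tolist(), key=str)
            for lev in levels[1:]:
                parts.append(
                    pd.DataFrame(
                        {f"{col}[{lev}]": (df[col] == lev).astype(float)},
                        index=df.index,
                    )
                )
        else:
            parts.append(df[[col]].astype(float))
    X = pd.concat(parts, axis=1)
    return X


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pinpoint offending columns for the error message
        sd = X.std(axis=0)
        const = [n for n, s in zip(names, sd) if s == 0 and n != "const"]
        detail = f"; constant columns: {const}" if const else ""
        raise DesignError(
            f"rank-deficient design (rank {rank} < {X.shape[1]} columns){detail}"
        )


def _multi_ols(X: np.ndarray, Y: np.ndarray, coef_idx: int) -> tuple[np.ndarray, ...]:
    """OLS of each column of Y on shared design X; effect/SE/t-p for one column.

    Returns (beta, se, p, df_resid) for the coefficient at ``coef_idx``.
    """
    n, k = X.shape
    if n <= k:
        raise DesignError(f"n={n} observations with {k} design columns")
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    coefs = XtX_inv @ (X.T @ Y)  # k x m
    resid = Y - X @ coefs
    dof = n - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(sigma2 * XtX_inv[coef_idx, coef_idx])
    beta = coefs[coef_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(tval), dof)
    return beta, se, p, dof


def bh_fdr(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, reported in the input order.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def fit_linear_assoc(
    samples: pd.DataFrame,
    m: MetaboliteMatrix,
    spec: ModelSpec,
) -> pd.DataFrame:
    """Per-metabolite OLS of metabolite on standardized exposure + covariates.

    Parameters
    ----------
    samples
        Sample table indexed like ``m.values`` (rows are the analysis
        sample, e.g. the subcohort); must contain the exposure and all
        adjustment columns.
    m
        Log-standardized metabolite matrix.

    Returns
    -------
    DataFrame indexed by metabolite id with columns ``effect`` (SD of
    metabolite per 1-SD exposure), ``se``, ``p``, ``q`` (BH within this
    table), ``n_used``. Complete-case per model; metabolites are assumed
    complete after LOD imputation, so a single casewise deletion on
    exposure + covariates applies to the whole family. The categorical
    coding used is stored in ``result.attrs["design_columns"]``.
    """
    if m.scale_state != LOG_STANDARDIZED:
        raise ValueError("metabolites must be log_standardized before association")
    common = samples.index.intersection(m.sample_ids)
    df = samples.loc[common]
    Y_all = m.values.loc[common]

    needed = [spec.exposure] + spec.adjustment
    cc = df[needed].notna().all(axis=1)
    df = df.loc[cc]
    Y = Y_all.loc[cc].to_numpy(dtype=float)

    exp_raw = df[spec.exposure].to_numpy(dtype=float)
    sd = exp_raw.std(ddof=1)
    if not sd > 0:
        raise DesignError(f"exposure {spec.exposure!r} is constant")
    exp_std = exp_raw / sd

    X_adj = expand_design(df, spec.adjustment, spec.categorical)
    X = np.column_stack([exp_std, X_adj.to_numpy(dtype=float)])
    names = [spec.exposure] + list(X_adj.columns)
    _check_rank(X, names)

    beta, se, p, _ = _multi_ols(X, Y, coef_idx=0)
    q = bh_fdr(p)
    out = pd.DataFrame(
        {
            "effect": beta,
            "se": se,
            "p": p,
            "q": q,
            "n_used": int(cc.sum()),
        },
        index=m.metabolite_ids,
    )
    out.index.name = "metabolite_id"
    out.attrs["design_columns"] = names
    out.attrs["exposure_sd"] = float(sd)
    return out


def concordance_r(
    a: pd.DataFrame, b: pd.DataFrame, column: str = "effect"
) -> tuple[float, list]:
    """Pearson correlation of point estimates over shared metabolite ids."""
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared metabolite ids, found {len(shared)}")
    col_b = column if column in b.columns else "estimate"
    r = float(np.corrcoef(a.loc[shared, column], b.loc[shared, col_b])[0, 1])
    return r, list(shared)


def pathway_summary(
    table: pd.DataFrame,
    annotations: pd.DataFrame | None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Counts and percentage of metabolites passing q < threshold per super-pathway."""
    if annotations is not None and "super_pathway" in annotations.columns:
        sp = annotations["super_pathway"].reindex(table.index).fillna("unknown")
    else:
        sp = pd.Series("unknown", index=table.index)
    df = pd.DataFrame({"super_pathway": sp, "pass": table["q"] < q_threshold})
    g = df.groupby("super_pathway", sort=True)["pass"]
    out = pd.DataFrame(
        {
            "n_metabolites": g.size(),
            "n_pass": g.sum().astype(int),
        }
    )
    out["pct_pass"] = 100.0 * out["n_pass"] / out["n_metabolites"]
    return out
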