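"""Mendelian randomization of an adiposity exposure on metabolites.

Covers the full instrument workflow: a weighted allele score built from
an external weight table (with allele harmonisation and a minor-allele-
frequency filter), the first-stage score-on-exposure regression with
instrument-strength diagnostics (F statistic, incremental R^2), two-stage
least squares on individual-participant data, summary-statistic
estimators (IVW, MR-Egger, weighted median), Cochran's Q concordance
between two estimates, and a score-confounder screen.

Estimates are reported per 1 SD of the exposure (default 3.4 kg/m^2 for
a BMI-like exposure) by post-hoc multiplication of the per-unit 2SLS
coefficient; the per-unit coefficient is also carried.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr, expand_design


class AlleleMismatchError(ValueError):
    """Weight-table allele cannot be reconciled with the panel coding."""


@dataclass
class DosagePanel:
    """Samples x SNPs dosage matrix with allele coding.

    ``dosages`` holds effect-allele counts in [0, 2]; ``effect_allele``
    and ``other_allele`` give the panel's coding per SNP.
    """

    dosages: pd.DataFrame
    effect_allele: pd.Series
    other_allele: pd.Series

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy()
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def frequency(self) -> pd.Series:
        """Observed effect-allele frequency (column mean / 2)."""
        return self.dosages.mean(axis=0) / 2.0

    @property
    def maf(self) -> pd.Series:
        f = self.frequency
        return np.minimum(f, 1.0 - f)


@dataclass
class Stage1Result:
    coef: float
    se: float
    f_stat: float
    r2_incremental: float
    n: int


@dataclass
class MREstimate:
    method: str
    estimate: float       # per 1 SD of exposure
    se: float             # on the same scale
    p: float
    estimate_per_unit: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    stage1: Stage1Result | None = None
    warnings: list[str] = field(default_factory=list)


def build_weighted_score(
    panel: DosagePanel,
    weights: pd.DataFrame,
    maf_threshold: float = 0.01,
) -> tuple[pd.Series, pd.DataFrame]:
    """Externally weighted allele score with MAF filter and allele flips.

    ``weights`` needs columns ``snp_id``, ``effect_allele``, ``weight``
    (SD of exposure per effect allele). A panel SNP contributes
    ``weight * dosage`` when the weight's effect allele matches the panel
    coding, ``weight * (2 - dosage)`` when it matches the other allele,
    and raises otherwise. SNPs with panel MAF strictly below the
    threshold, or with no weight, are excluded and itemized.
    """
    w = weights.set_index("snp_id")
    if w.index.has_duplicates:
        raise ValueError("duplicate snp_ids in weight table")
    maf = panel.maf
    exclusions = []
    score = pd.Series(0.0, index=panel.sample_ids, name="score")
    n_used = 0
    for snp in panel.snp_ids:
        if maf[snp] < maf_threshold:
            exclusions.append((snp, "low_maf", float(maf[snp])))
            continue
        if snp not in w.index:
            exclusions.append((snp, "missing_weight", np.nan))
            continue
        wt = float(w.loc[snp, "weight"])
        ea = w.loc[snp, "effect_allele"]
        d = panel.dosages[snp].astype(float)
        if ea == panel.effect_allele[snp]:
            score += wt * d
        elif ea == panel.other_allele[snp]:
            score += wt * (2.0 - d)
        else:
            raise AlleleMismatchError(
                f"SNP {snp!r}: weight effect allele {ea!r} matches neither panel "
                f"allele ({panel.effect_allele[snp]!r}/{panel.other_allele[snp]!r})"
            )
        n_used += 1
    report = pd.DataFrame(exclusions, columns=["snp_id", "reason", "maf"])
    score.attrs["n_snps_used"] = n_used
    return score, report


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Plain OLS: coefficients, standard errors, R^2, residual dof."""
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return beta, se, r2, dof


def _aligned_design(
    idx: pd.Index,
    covariates: pd.DataFrame | None,
    categorical: frozenset[str] | set[str],
) -> np.ndarray:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((len(idx), 1))
    cov = covariates.loc[idx]
    X = expand_design(cov, list(cov.columns), categorical, add_intercept=True)
    return X.to_numpy(dtype=float)


def stage1_fit(
    exposure: pd.Series,
    score: pd.Series,
    covariates: pd.DataFrame | None = None,
    categorical: frozenset[str] | set[str] = frozenset(),
) -> Stage1Result:
    """First-stage regression of exposure on the allele score + covariates.

    F = (coef/SE)^2; incremental R^2 is R^2(full) - R^2(covariates only).
    """
    idx = exposure.dropna().index.intersection(score.dropna().index)
    if covariates is not None:
        idx = idx.intersection(covariates.dropna().index)
    s = score.loc[idx].to_numpy(dtype=float)
    if s.std() == 0:
        raise ValueError("score is constant; first stage is undefined")
    y = exposure.loc[idx].to_numpy(dtype=float)
    X_cov = _aligned_design(idx, covariates, categorical)
    X = np.column_stack([s, X_cov])
    beta, se, r2_full, _ = _ols(y, X)
    if X_cov.shape[1] > 1:
        _, _, r2_cov, _ = _ols(y, X_cov)
    else:
        r2_cov = 0.0
    coef, coef_se = float(beta[0]), float(se[0])
    return Stage1Result(
        coef=coef,
        se=coef_se,
        f_stat=(coef / coef_se) ** 2,
        r2_incremental=max(0.0, r2_full - r2_cov),
        n=len(idx),
    )


def tsls_fit(
    metabolite: pd.Series,
    exposure: pd.Series,
    score: pd.Series,
    covariates: pd.DataFrame | None = None,
    sd_exposure: float = 3.4,
    categorical: frozenset[str] | set[str] = frozenset(),
    weak_f_floor: float = 10.0,
    stage1: Stage1Result | None = None,
) -> MREstimate:
    """Two-stage least squares on individual participant data.

    Stage 1 may be fitted on a larger sample than stage 2: it uses every
    sample with exposure + score (+ covariates), while stage 2 uses the
    samples with the metabolite measured. The predicted exposure is the
    stage-1 score coefficient times the score (covariate parts excluded,
    so covariates are not double counted in stage 2). Stage-2 SEs are
    naive OLS SEs, appropriate when the first-stage sample is much
    larger. The headline estimate is per ``sd_exposure`` units (SD of
    metabolite per 1 SD of exposure).
    """
    if stage1 is None:
        stage1 = stage1_fit(exposure, score, covariates, categorical)
    warnings = []
    if stage1.f_stat < weak_f_floor:
        warnings.append(
            f"weak instrument: first-stage F = {stage1.f_stat:.2f} < {weak_f_floor}"
        )
    idx = metabolite.dropna().index.intersection(score.dropna().index)
    if covariates is not None:
        idx = idx.intersection(covariates.dropna().index)
    pred = stage1.coef * score.loc[idx].to_numpy(dtype=float)
    if pred.std() == 0:
        raise ValueError("predicted exposure is constant (zero-weight score?)")
    y = metabolite.loc[idx].to_numpy(dtype=float)
    X_cov = _aligned_design(idx, covariates, categorical)
    X = np.column_stack([pred, X_cov])
    beta, se, _, dof = _ols(y, X)
    per_unit, per_unit_se = float(beta[0]), float(se[0])
    t = per_unit / per_unit_se
    return MREstimate(
        method="2SLS-IPD",
        estimate=per_unit * sd_exposure,
        se=per_unit_se * sd_exposure,
        p=2 * stats.t.sf(abs(t), dof),
        estimate_per_unit=per_unit,
        stage1=stage1,
        warnings=warnings,
    )


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float = 0.5) -> float:
    """Weighted percentile with standard interpolation at midpoints."""
    order = np.argsort(x, kind="mergesort")
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    pk = (cw - 0.5 * ws) / cw[-1]
    return float(np.interp(q, pk, xs))


def summary_mr(
    beta_exp: np.ndarray,
    se_exp: np.ndarray,
    beta_out: np.ndarray,
    se_out: np.ndarray,
    method: str = "ivw",
    egger_intercept: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Summary-statistic MR: IVW, MR-Egger, or weighted median.

    * IVW: inverse-variance-weighted mean of Wald ratios beta_out /
      beta_exp with weights (beta_exp / se_out)^2; fixed-effect SE.
    * Egger: weighted regression of beta_out on beta_exp with intercept,
      weights 1/se_out^2, SNPs oriented to positive beta_exp; the
      residual dispersion is floored at 1 (multiplicative random
      effects). Setting ``egger_intercept=False`` forces the line through
      the origin, which reproduces IVW.
    * weighted-median: 50th percentile of the inverse-variance-weighted
      ratio distribution; SE by seeded parametric bootstrap.
    """
    beta_exp = np.asarray(beta_exp, float)
    se_exp = np.asarray(se_exp, float)
    beta_out = np.asarray(beta_out, float)
    se_out = np.asarray(se_out, float)
    k = len(beta_exp)
    if np.any(se_out <= 0) or np.any(se_exp <= 0):
        raise ValueError("standard errors must be positive")
    if np.any(beta_exp == 0):
        bad = np.flatnonzero(beta_exp == 0)
        raise ValueError(f"zero exposure effect for SNP index {bad.tolist()}")

    if method == "ivw":
        if k < 1:
            raise ValueError("IVW needs >= 1 SNP")
        wts = (beta_exp / se_out) ** 2
        ratios = beta_out / beta_exp
        est = float(np.sum(wts * ratios) / np.sum(wts))
        se = float(np.sqrt(1.0 / np.sum(wts)))
        z = est / se
        return MREstimate("IVW", est, se, 2 * stats.norm.sf(abs(z)))

    if method == "egger":
        if k < 3:
            raise ValueError("MR-Egger needs >= 3 SNPs")
        flip = np.sign(beta_exp)
        bx, by = beta_exp * flip, beta_out * flip
        w = 1.0 / se_out**2
        if egger_intercept:
            X = np.column_stack([np.ones(k), bx])
        else:
            X = bx[:, None]
        W = np.diag(w)
        XtWX_inv = np.linalg.inv(X.T @ W @ X)
        coefs = XtWX_inv @ (X.T @ (w * by))
        resid = by - X @ coefs
        dof = k - X.shape[1]
        disp = max(1.0, float(resid @ (w * resid)) / dof) if dof > 0 else 1.0
        cov = XtWX_inv * disp
        if egger_intercept:
            icpt, slope = float(coefs[0]), float(coefs[1])
            icpt_se = float(np.sqrt(cov[0, 0]))
            slope_se = float(np.sqrt(cov[1, 1]))
        else:
            icpt, icpt_se = None, None
            slope, slope_se = float(coefs[0]), float(np.sqrt(cov[0, 0]))
        t = slope / slope_se
        p = 2 * stats.t.sf(abs(t), max(dof, 1))
        return MREstimate("Egger", slope, slope_se, p,
                          intercept=icpt, intercept_se=icpt_se)

    if method in ("wmedian", "weighted-median"):
        if k < 3:
            raise ValueError("weighted median needs >= 3 SNPs")
        ratios = beta_out / beta_exp
        ratio_se = np.abs(se_out / beta_exp)
        wts = 1.0 / ratio_se**2
        est = _weighted_quantile(ratios, wts)
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bx = rng.normal(beta_exp, se_exp)
            by = rng.normal(beta_out, se_out)
            with np.errstate(divide="ignore"):
                r = by / bx
            boots[b] = _weighted_quantile(r, wts)
        se = float(boots.std(ddof=1))
        z = est / se
        return MREstimate("weighted-median", est, se, 2 * stats.norm.sf(abs(z)))

    raise ValueError(f"unknown method {method!r}")


def cochran_q_two(
    beta_a: float, se_a: float, beta_b: float, se_b: float
) -> tuple[float, float]:
    """Cochran's Q comparing two estimates (1 df).

    Q = sum (beta_k - ivw_mean)^2 / se_k^2 over the two estimates; p from
    chi-square with 1 degree of freedom.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    w = np.array([1.0 / se_a**2, 1.0 / se_b**2])
    b = np.array([beta_a, beta_b])
    bhat = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - bhat) ** 2))
    return q, float(stats.chi2.sf(q, df=1))


def confounder_screen(
    score: pd.Series,
    confounders: pd.DataFrame,
    categorical: frozenset[str] | set[str] = frozenset(),
) -> pd.DataFrame:
    """Regress each potential confounder on the allele score.

    Categorical confounders expand to indicator columns, each screened
    separately. BH q-values are computed within the screen; the q column
    is a multiplicity note, not a gatekeeper.
    """
    if confounders.shape[1] == 0:
        return pd.DataFrame(columns=["effect", "se", "p", "q", "n"])
    X_conf = expand_design(confounders, list(confounders.columns), categorical,
                           add_intercept=False)
    rows = []
    for col in X_conf.columns:
        y = X_conf[col]
        idx = y.dropna().index.intersection(score.dropna().index)
        s = score.loc[idx].to_numpy(dtype=float)
        X = np.column_stack([s, np.ones(len(idx))])
        beta, se, _, dof = _ols(y.loc[idx].to_numpy(dtype=float), X)
        t = beta[0] / se[0]
        rows.append(dict(confounder=col, effect=beta[0], se=se[0],
                         p=2 * stats.t.sf(abs(t), dof), n=len(idx)))
    out = pd.DataFrame(rows).set_index("confounder")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out[["effect", "se", "p", "q", "n"]]
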