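"""Cox regression for case-cohort (case-subcohort) designs.

The estimator is the Prentice pseudo-partial likelihood: at each event
time the risk set consists of subcohort members still at risk, and a case
*outside* the subcohort enters only at its own event time. With the
subcohort equal to the whole cohort this reduces exactly to the standard
Cox partial likelihood (Breslow handling of ties), which is how the
implementation is verified.

Maximisation is Newton-Raphson from zero with step-halving. Two variance
estimates are produced: the model-based inverse Hessian and a grouped
infinitesimal-jackknife (dfbeta) sandwich, which is the default for
confidence intervals since the pseudo-likelihood is not a true partial
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import ModelSpec, bh_fdr, expand_design
from .preprocess import LOG_STANDARDIZED, MetaboliteMatrix


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class CaseCohortStudy:
    """All incident cases plus a random subcohort, on the time-in-study scale.

    Parameters
    ----------
    samples
        DataFrame indexed by sample id with at least ``event_time``
        (positive, entry at 0), ``event`` (bool) and ``in_subcohort``
        (bool) columns plus any covariates.
    sampling_fraction
        subcohort size / full cohort size, in (0, 1].
    """

    samples: pd.DataFrame
    sampling_fraction: float

    def __post_init__(self) -> None:
        req = {"event_time", "event", "in_subcohort"}
        missing = req - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample table lacks columns {sorted(missing)}")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must be in (0, 1]")
        ev = self.samples["event"].astype(bool)
        sc = self.samples["in_subcohort"].astype(bool)
        if not (ev | sc).all():
            raise ValueError("every record must be a case or a subcohort member")
        if not (self.samples["event_time"] > 0).all():
            raise ValueError("event_time must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def n_events(self) -> int:
        return int(self.samples["event"].sum())


@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray | None
    loglik: float
    iterations: int
    converged: bool
    n: int
    n_events: int
    warnings: list[str] = field(default_factory=list)

    @property
    def se_model(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_model))

    @property
    def se_robust(self) -> np.ndarray:
        cov = self.cov_robust if self.cov_robust is not None else self.cov_model
        return np.sqrt(np.diag(cov))

    def summary(self) -> pd.DataFrame:
        se = self.se_robust
        z = self.coef / se
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": se,
                "se_model": self.se_model,
                "hr": np.exp(self.coef),
                "lcl": np.exp(self.coef - 1.96 * se),
                "ucl": np.exp(self.coef + 1.96 * se),
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=self.names,
        )


class _PrenticeData:
    """Pre-sorted arrays shared across likelihood evaluations."""

    def __init__(self, X: np.ndarray, time: np.ndarray, event: np.ndarray,
                 subco: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=bool)
        self.subco = np.asarray(subco, dtype=bool)
        self.n, self.p = self.X.shape
        if self.event.sum() == 0:
            raise ValueError("no events in data")

        sub_idx = np.flatnonzero(self.subco)
        order = np.argsort(self.time[sub_idx], kind="mergesort")
        self.sub_sorted = sub_idx[order]              # subcohort, time ascending
        self.ts = self.time[self.sub_sorted]
        self.Xs = self.X[self.sub_sorted]

        ev_idx = np.flatnonzero(self.event)
        eorder = np.argsort(self.time[ev_idx], kind="mergesort")
        self.ev_sorted = ev_idx[eorder]               # events, time ascending
        self.te = self.time[self.ev_sorted]
        self.Xe = self.X[self.ev_sorted]
        self.ev_outside = ~self.subco[self.ev_sorted]
        # position of first subcohort member with t >= each event time
        self.pos = np.searchsorted(self.ts, self.te, side="left")

    def loglik_grad_hess(self, beta: np.ndarray, need_hess: bool = True):
        # extreme beta (e.g. during step-halving or separation) can underflow
        # the shifted exponentials; the resulting non-finite loglik is handled
        # by the caller, so the numpy warnings are suppressed here
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            return self._loglik_grad_hess(beta, need_hess)

    def _loglik_grad_hess(self, beta: np.ndarray, need_hess: bool = True):
        eta = self.X @ beta
        eta_max = eta.max()
        w = np.exp(eta - eta_max)  # stabilised; log S0 corrected below
        ws = w[self.sub_sorted]
        ns, p = len(ws), self.p

        # suffix sums over subcohort (index i -> sum over ts[i:])
        S0s = np.zeros(ns + 1)
        S0s[:ns] = np.cumsum(ws[::-1])[::-1]
        S1s = np.zeros((ns + 1, p))
        S1s[:ns] = np.cumsum((ws[:, None] * self.Xs)[::-1], axis=0)[::-1]

        S0 = S0s[self.pos].copy()
        S1 = S1s[self.pos].copy()
        we = w[self.ev_sorted]
        out = self.ev_outside
        S0[out] += we[out]
        S1[out] += we[out, None] * self.Xe[out]

        eta_e = eta[self.ev_sorted]
        ll = float(np.sum(eta_e - (np.log(S0) + eta_max)))
        xbar = S1 / S0[:, None]
        grad = (self.Xe - xbar).sum(axis=0)

        if not need_hess:
            return ll, grad, None, xbar, S0

        S2s = np.zeros((ns + 1, p, p))
        outer = ws[:, None, None] * (self.Xs[:, :, None] * self.Xs[:, None, :])
        S2s[:ns] = np.cumsum(outer[::-1], axis=0)[::-1]
        S2 = S2s[self.pos].copy()
        S2[out] += we[out, None, None] * (
            self.Xe[out, :, None] * self.Xe[out, None, :]
        )
        V = S2 / S0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]
        hess = -V.sum(axis=0)
        return ll, grad, hess, xbar, S0


def _newton(data: _PrenticeData, max_iter: int = 50, tol_score: float = 1e-8,
            tol_ll: float = 1e-10, max_halvings: int = 10):
    beta = np.zeros(data.p)
    ll, grad, hess, xbar, S0 = data.loglik_grad_hess(beta)
    trace = [ll]
    converged = False
    warnings: list[str] = []
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian at iteration {it}", trace) from exc
        new_beta = beta + step
        new_ll, new_grad, new_hess, new_xbar, new_S0 = data.loglik_grad_hess(new_beta)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < max_halvings:
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess, new_xbar, new_S0 = data.loglik_grad_hess(new_beta)
            halvings += 1
        rel_change = abs(new_ll - ll) / (abs(ll) + 1e-12)
        beta, ll, grad, hess, xbar, S0 = (
            new_beta, new_ll, new_grad, new_hess, new_xbar, new_S0,
        )
        trace.append(ll)
        if np.max(np.abs(grad)) < tol_score or rel_change < tol_ll:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(max |score| = {np.max(np.abs(grad)):.3g})",
            trace,
        )
    if np.any(np.abs(beta) > 20):
        warnings.append(
            "diverging coefficient (|beta| > 20): possible monotone likelihood / "
            "perfect separation"
        )
    return beta, ll, grad, hess, xbar, S0, it, warnings


def _score_residuals(data: _PrenticeData, beta: np.ndarray,
                     xbar: np.ndarray, S0: np.ndarray) -> np.ndarray:
    """Per-subject score contributions U_j of the pseudo-partial likelihood."""
    n, p = data.n, data.p
    eta = data.X @ beta
    eta_max = eta.max()
    w = np.exp(eta - eta_max)
    S0c = S0 * np.exp(-0.0)  # S0 already on the shifted scale; keep consistent
    inv_S0 = 1.0 / S0c
    # prefix sums over events (ascending time)
    cum_inv = np.concatenate([[0.0], np.cumsum(inv_S0)])
    cum_xb = np.vstack([np.zeros(p), np.cumsum(xbar * inv_S0[:, None], axis=0)])

    U = np.zeros((n, p))
    # event terms: delta_j * (x_j - xbar at own event)
    U[data.ev_sorted] += data.Xe - xbar

    # risk-set exposure terms
    sub = data.sub_sorted
    k = np.searchsorted(data.te, data.time[sub], side="right")
    A = cum_inv[k]                       # sum 1/S0 over events with t_i <= t_j
    B = cum_xb[k]
    U[sub] -= w[sub, None] * (A[:, None] * data.X[sub] - B)

    out_cases = data.ev_sorted[data.ev_outside]
    if len(out_cases):
        pos_own = np.searchsorted(data.te, data.time[out_cases], side="left")
        # each non-subcohort case sits only in its own risk set; tied event
        # times share a Breslow risk set, so include every tied event row
        for j, p0 in zip(out_cases, pos_own):
            ties = np.flatnonzero(data.te == data.time[j])
            U[j] -= w[j] * (
                inv_S0[ties].sum() * data.X[j] - (xbar[ties] * inv_S0[ties, None]).sum(axis=0)
            )
    return U


def fit_prentice_cox(
    study: CaseCohortStudy,
    design_columns: list[str],
    categorical: frozenset[str] | set[str] = frozenset(),
    max_iter: int = 50,
    robust: bool = True,
) -> CoxFit:
    """Fit the Prentice pseudo-partial-likelihood Cox model.

    ``design_columns`` are expanded (deterministic reference coding for
    names listed in ``categorical``) and entered without an intercept, as
    usual for Cox regression. Complete-case on the design columns.
    """
    df = study.samples
    cc = df[design_columns].notna().all(axis=1)
    df = df.loc[cc]
    Xd = expand_design(df, design_columns, categorical, add_intercept=False)
    names = list(Xd.columns)
    X = Xd.to_numpy(dtype=float)
    sd = X.std(axis=0)
    zero = [n for n, s in zip(names, sd) if s == 0]
    if zero:
        raise ValueError(f"constant design columns: {zero}")
    data = _PrenticeData(
        X,
        df["event_time"].to_numpy(),
        df["event"].to_numpy(bool),
        df["in_subcohort"].to_numpy(bool),
    )
    beta, ll, grad, hess, xbar, S0, it, warns = _newton(data, max_iter=max_iter)
    cov_model = np.linalg.inv(-hess)
    cov_robust = None
    if robust:
        U = _score_residuals(data, beta, xbar, S0)
        meat = U.T @ U
        cov_robust = cov_model @ meat @ cov_model
        cov_robust = (cov_robust + cov_robust.T) / 2.0
    return CoxFit(
        names=names,
        coef=beta,
        cov_model=cov_model,
        cov_robust=cov_robust,
        loglik=ll,
        iterations=it,
        converged=True,
        n=data.n,
        n_events=int(data.event.sum()),
        warnings=warns,
    )


def robust_variance(fit: CoxFit) -> np.ndarray:
    """Grouped infinitesimal-jackknife (dfbeta) sandwich covariance."""
    if not fit.converged:
        raise ValueError("robust variance requires a converged fit")
    if fit.cov_robust is None:
        raise ValueError("fit was computed with robust=False")
    return fit.cov_robust


def fit_cox_full(
    cohort: pd.DataFrame,
    design_columns: list[str],
    categorical: frozenset[str] | set[str] = frozenset(),
    **kwargs,
) -> CoxFit:
    """Standard full-cohort Cox partial likelihood (Breslow ties).

    Implemented as the Prentice fit with everyone in the subcohort, which
    is algebraically the ordinary partial likelihood. Used as the
    verification reference.
    """
    df = cohort.copy()
    df["in_subcohort"] = True
    study = CaseCohortStudy(samples=df, sampling_fraction=1.0)
    return fit_prentice_cox(study, design_columns, categorical, **kwargs)


def prentice_pseudo_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    in_subcohort: np.ndarray,
) -> float:
    """Evaluate the Prentice pseudo-partial log likelihood at ``beta``.

    Exposed so that tests can maximise the written likelihood by
    independent means (e.g. a grid search) and compare optima.
    """
    data = _PrenticeData(X, time, event, in_subcohort)
    ll, _, _, _, _ = data.loglik_grad_hess(np.asarray(beta, float), need_hess=False)
    return ll


def metabolome_wide_cox(
    study: CaseCohortStudy,
    m: MetaboliteMatrix,
    spec: ModelSpec,
) -> pd.DataFrame:
    """One Prentice Cox fit per metabolite: covariates + that metabolite.

    Returns a table on the HR scale (per 1 SD of metabolite): ``loghr``,
    ``se`` (robust), ``hr``, ``lcl``, ``ucl``, ``p``, ``q`` (BH over the
    successfully fitted family), ``n``, ``n_events``. Per-metabolite
    failures are recorded with NaN rows and excluded from the FDR family.
    """
    if m.scale_state != LOG_STANDARDIZED:
        raise ValueError("metabolites must be log_standardized")
    common = study.samples.index.intersection(m.sample_ids)
    df = study.samples.loc[common]
    needed = spec.adjustment
    cc = df[needed].notna().all(axis=1) if needed else pd.Series(True, index=df.index)
    df = df.loc[cc]
    Xadj = expand_design(df, needed, spec.categorical, add_intercept=False)
    X_cov = Xadj.to_numpy(dtype=float)
    time = df["event_time"].to_numpy()
    event = df["event"].to_numpy(bool)
    subco = df["in_subcohort"].to_numpy(bool)
    Y = m.values.loc[df.index]

    rows = []
    failures = []
    for met in m.metabolite_ids:
        x = Y[met].to_numpy(dtype=float)
        X = np.column_stack([x, X_cov])
        try:
            data = _PrenticeData(X, time, event, subco)
            beta, ll, grad, hess, xbar, S0, it, warns = _newton(data)
            cov_model = np.linalg.inv(-hess)
            U = _score_residuals(data, beta, xbar, S0)
            cov_rob = cov_model @ (U.T @ U) @ cov_model
            se = float(np.sqrt(cov_rob[0, 0]))
            b = float(beta[0])
            z = b / se
            rows.append(
                dict(metabolite_id=met, loghr=b, se=se, hr=np.exp(b),
                     lcl=np.exp(b - 1.96 * se), ucl=np.exp(b + 1.96 * se),
                     p=2 * stats.norm.sf(abs(z)), q=np.nan,
                     n=data.n, n_events=int(event.sum()))
            )
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            failures.append((met, str(exc)))
            rows.append(
                dict(metabolite_id=met, loghr=np.nan, se=np.nan, hr=np.nan,
                     lcl=np.nan, ucl=np.nan, p=np.nan, q=np.nan,
                     n=len(df), n_events=int(event.sum()))
            )
    out = pd.DataFrame(rows).set_index("metabolite_id")
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out.attrs["fdr_family_size"] = int(ok.sum())
    out.attrs["failures"] = failures
    return out
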