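"""Cuboid (Cox-Battey) variable selection for many predictors.

Variables are laid out uniformly at random on a d1 x d2 x d3 cuboid,
with empty cells padded by fresh standard-normal noise variables. For
every axis-parallel line of the cuboid, one joint regression of the
outcome on that line's variables (plus fixed covariates) is fitted, so
each variable is judged in exactly three small joint fits. A variable is
retained under a criterion — |z| > 2.5, rank <= 2 by |z|, or rank <= 3 —
only if it is flagged in *all three* of its fits. The procedure is run
twice: survivors of round 1 (union over criteria) are re-laid on a
smaller near-cubic box and re-screened, and the per-criterion round-2
sets are accumulated into nested models.

Backends: case-cohort Cox (default), linear (OLS), and logistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import expand_design
from .coxcc import (CaseCohortStudy, ConvergenceError, fit_prentice_cox)

CRITERIA = ("z_gt_2.5", "top2", "top3")


@dataclass
class CuboidAssignment:
    dims: tuple[int, int, int]
    cell_of: dict[str, tuple[int, int, int]]       # variable id -> (i, j, k)
    noise_ids: list[str]
    noise_values: pd.DataFrame                      # subjects x noise variables
    seed: int

    @property
    def n_cells(self) -> int:
        d1, d2, d3 = self.dims
        return d1 * d2 * d3


@dataclass
class SelectionResult:
    round1: dict[str, set[str]]            # criterion -> selected ids
    round2: dict[str, set[str]]
    nested_sets: dict[str, list[str]]      # "c1", "c1_2", "c1_3" cumulative unions
    final_coefficients: pd.DataFrame | None
    assignments: list[CuboidAssignment]
    z_tables: list[pd.DataFrame]
    noise_selected: dict[str, set[str]] = field(default_factory=dict)

    @property
    def round1_union(self) -> set[str]:
        return set().union(*self.round1.values()) if self.round1 else set()

    @property
    def round2_union(self) -> set[str]:
        return set().union(*self.round2.values()) if self.round2 else set()


def assign_to_cuboid(
    variable_ids: list[str],
    dims: tuple[int, int, int],
    seed: int,
    subject_index: pd.Index,
) -> CuboidAssignment:
    """Random (seeded) bijection of variables + fresh noise onto all cells.

    Noise variables are drawn standard normal per subject, one column per
    empty cell, named ``noise####``.
    """
    d1, d2, d3 = dims
    n_cells = d1 * d2 * d3
    n_var = len(variable_ids)
    if n_cells < n_var:
        need = near_cubic_dims(n_var)
        raise ValueError(
            f"cuboid {dims} has {n_cells} cells < {n_var} variables; "
            f"smallest near-cubic box would be {need}"
        )
    rng = np.random.default_rng(seed)
    n_noise = n_cells - n_var
    noise_ids = [f"noise{j:04d}" for j in range(n_noise)]
    noise_values = pd.DataFrame(
        rng.normal(size=(len(subject_index), n_noise)),
        index=subject_index,
        columns=noise_ids,
    )
    all_ids = list(variable_ids) + noise_ids
    perm = rng.permutation(n_cells)
    cells = [(c // (d2 * d3), (c // d3) % d2, c % d3) for c in range(n_cells)]
    cell_of = {all_ids[i]: cells[perm[i]] for i in range(n_cells)}
    return CuboidAssignment(dims=dims, cell_of=cell_of, noise_ids=noise_ids,
                            noise_values=noise_values, seed=seed)


def enumerate_lines(a: CuboidAssignment) -> list[list[str]]:
    """All axis-parallel lines as variable-id lists.

    d2*d3 lines of length d1, d1*d3 of length d2, d1*d2 of length d3;
    every cell lies on exactly 3 lines.
    """
    d1, d2, d3 = a.dims
    by_cell = {cell: vid for vid, cell in a.cell_of.items()}
    lines: list[list[str]] = []
    for j in range(d2):
        for k in range(d3):
            lines.append([by_cell[(i, j, k)] for i in range(d1)])
    for i in range(d1):
        for k in range(d3):
            lines.append([by_cell[(i, j, k)] for j in range(d2)])
    for i in range(d1):
        for j in range(d2):
            lines.append([by_cell[(i, j, k)] for k in range(d3)])
    return lines


def near_cubic_dims(k: int) -> tuple[int, int, int]:
    """Smallest near-cubic box (a, b, c) with a*b*c >= k."""
    if k <= 1:
        return (1, 1, 1)
    c0 = math.ceil(k ** (1 / 3))
    best = None
    for a in range(max(1, c0 - 2), c0 + 3):
        for b in range(a, c0 + 3):
            for c in range(b, c0 + 3):
                vol = a * b * c
                if vol < k:
                    continue
                key = (vol, c - a, (a, b, c))
                if best is None or key < best:
                    best = key
    return best[2][::-1] if best else (k, 1, 1)  # largest dim first


def _fit_linear(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    return beta, np.sqrt(sigma2 * np.diag(XtX_inv))


def _fit_logistic(y: np.ndarray, X: np.ndarray,
                  max_iter: int = 50) -> tuple[np.ndarray, np.ndarray]:
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (W[:, None] * X)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(grad)) < 1e-8:
            break
    else:
        raise ConvergenceError("logistic IRLS did not converge", [])
    cov = np.linalg.inv(hess)
    return beta, np.sqrt(np.diag(cov))


def run_line_regressions(
    study: CaseCohortStudy,
    variables: pd.DataFrame,
    assignment: CuboidAssignment,
    covariates: list[str] | None = None,
    categorical: frozenset[str] | set[str] = frozenset(),
    backend: str = "case-cohort-cox",
    outcome: str | None = None,
    max_failed_fraction: float = 0.10,
) -> pd.DataFrame:
    """Fit one joint regression per cuboid line; return the per-variable z table.

    Returns a long table with one row per (variable, line): columns
    ``variable``, ``dim`` (0/1/2), ``line_id``, ``z``, ``rank`` (1 =
    largest |z| within the line; NaN in non-converged lines), ``is_noise``,
    ``converged``. Non-converged lines contribute z = 0 and no ranks.
    """
    covariates = covariates or []
    df = study.samples
    idx = df.index.intersection(variables.index)
    df = df.loc[idx]
    allvars = pd.concat([variables.loc[idx], assignment.noise_values.loc[idx]], axis=1)

    lines = enumerate_lines(assignment)
    d1, d2, d3 = assignment.dims
    dim_of_line = [0] * (d2 * d3) + [1] * (d1 * d3) + [2] * (d1 * d2)

    if covariates:
        X_cov = expand_design(df, covariates, categorical,
                              add_intercept=(backend != "case-cohort-cox"))
    else:
        if backend == "case-cohort-cox":
            X_cov = pd.DataFrame(index=df.index)
        else:
            X_cov = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)

    time = df["event_time"].to_numpy() if "event_time" in df else None
    event = df["event"].to_numpy(bool) if "event" in df else None
    subco = df["in_subcohort"].to_numpy(bool) if "in_subcohort" in df else None
    if backend in ("linear", "logistic"):
        if outcome is None:
            outcome = "event"
        y = df[outcome].to_numpy(dtype=float)

    rows = []
    n_failed = 0
    noise_set = set(assignment.noise_ids)
    from .coxcc import _PrenticeData, _newton, _score_residuals  # local reuse

    for line_id, (line, dim) in enumerate(zip(lines, dim_of_line)):
        Xv = allvars[line].to_numpy(dtype=float)
        nv = len(line)
        try:
            if backend == "case-cohort-cox":
                X = np.column_stack([Xv, X_cov.to_numpy(dtype=float)]) \
                    if X_cov.shape[1] else Xv
                data = _PrenticeData(X, time, event, subco)
                beta, ll, grad, hess, xbar, S0 = None, None, None, None, None, None
                beta, ll, grad, hess, xbar, S0, it, _w = _newton(data)
                cov_model = np.linalg.inv(-hess)
                U = _score_residuals(data, beta, xbar, S0)
                cov = cov_model @ (U.T @ U) @ cov_model
                z = beta[:nv] / np.sqrt(np.diag(cov)[:nv])
            elif backend == "linear":
                X = np.column_stack([Xv, X_cov.to_numpy(dtype=float)])
                b, se = _fit_linear(y, X)
                z = b[:nv] / se[:nv]
            elif backend == "logistic":
                X = np.column_stack([Xv, X_cov.to_numpy(dtype=float)])
                b, se = _fit_logistic(y, X)
                z = b[:nv] / se[:nv]
            else:
                raise ValueError(f"unknown backend {backend!r}")
            order = np.argsort(-np.abs(z), kind="mergesort")
            rank = np.empty(nv, dtype=float)
            rank[order] = np.arange(1, nv + 1)
            converged = True
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            z = np.zeros(nv)
            rank = np.full(nv, np.nan)
            converged = False
        for v, zv, rv in zip(line, z, rank):
            rows.append((v, dim, line_id, float(zv), rv, v in noise_set, converged))
    if n_failed > max_failed_fraction * len(lines):
        raise RuntimeError(
            f"{n_failed}/{len(lines)} line fits failed "
            f"(> {max_failed_fraction:.0%}); aborting selection round"
        )
    out = pd.DataFrame(
        rows, columns=["variable", "dim", "line_id", "z", "rank",
                       "is_noise", "converged"]
    )
    out.attrs["n_lines"] = len(lines)
    out.attrs["n_failed"] = n_failed
    return out


def select_by_criterion(table: pd.DataFrame, criterion: str) -> set[str]:
    """Variables flagged by the criterion in all three of their line fits."""
    if criterion == "z_gt_2.5":
        flag = table["z"].abs() > 2.5
    elif criterion == "top2":
        flag = table["rank"] <= 2
    elif criterion == "top3":
        flag = table["rank"] <= 3
    else:
        raise ValueError(f"unknown criterion {criterion!r}; one of {CRITERIA}")
    flagged = table.loc[flag.fillna(False), "variable"]
    counts = flagged.value_counts()
    return set(counts.index[counts >= 3])


def two_round_selection(
    study: CaseCohortStudy,
    variables: pd.DataFrame,
    dims_round1: tuple[int, int, int] | None = None,
    covariates: list[str] | None = None,
    categorical: frozenset[str] | set[str] = frozenset(),
    backend: str = "case-cohort-cox",
    seed: int = 0,
    outcome: str | None = None,
    final_fit: bool = True,
) -> SelectionResult:
    """Two rounds of cuboid screening with nested-model construction.

    Round 1 screens all variables; the union of the three criteria's
    selections is re-laid on the smallest near-cubic box (fresh noise,
    fresh seeded assignment) and screened again. Nested sets accumulate
    the round-2 per-criterion selections in order: criterion 1; 1 union 2;
    1 union 2 union 3. A final joint fit on the round-2 union (plus
    covariates) supplies the coefficient table.
    """
    var_ids = list(variables.columns)
    if dims_round1 is None:
        dims_round1 = near_cubic_dims(len(var_ids))
    ss = np.random.SeedSequence(seed)
    s1, s2 = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]

    a1 = assign_to_cuboid(var_ids, dims_round1, s1, study.samples.index)
    t1 = run_line_regressions(study, variables, a1, covariates, categorical,
                              backend, outcome)
    round1 = {c: select_by_criterion(t1, c) for c in CRITERIA}
    union1 = sorted(set().union(*round1.values()))

    assignments = [a1]
    z_tables = [t1]
    noise1 = set(a1.noise_ids)
    noise_selected = {c: s & noise1 for c, s in round1.items()}

    if not union1:
        return SelectionResult(round1=round1, round2={c: set() for c in CRITERIA},
                               nested_sets={"c1": [], "c1_2": [], "c1_3": []},
                               final_coefficients=None, assignments=assignments,
                               z_tables=z_tables, noise_selected=noise_selected)

    # survivors that are themselves round-1 noise are dropped before round 2:
    # fresh noise is drawn for the new box
    survivors = [v for v in union1 if v not in noise1]
    surv_vals = variables[survivors] if survivors else variables.iloc[:, :0]
    dims2 = near_cubic_dims(max(len(survivors), 1))
    a2 = assign_to_cuboid(survivors, dims2, s2, study.samples.index)
    t2 = run_line_regressions(study, surv_vals, a2, covariates, categorical,
                              backend, outcome)
    round2 = {c: select_by_criterion(t2, c) for c in CRITERIA}
    assignments.append(a2)
    z_tables.append(t2)
    noise2 = set(a2.noise_ids)
    for c in CRITERIA:
        noise_selected[c] |= round2[c] & noise2

    c1 = sorted(round2["z_gt_2.5"])
    c12 = sorted(set(c1) | round2["top2"])
    c123 = sorted(set(c12) | round2["top3"])
    nested = {"c1": c1, "c1_2": c12, "c1_3": c123}

    final_coefs = None
    if final_fit and c123:
        real_final = [v for v in c123 if v not in noise2]
        if real_final:
            merged = study.samples.join(variables[real_final], how="inner")
            fit_study = CaseCohortStudy(samples=merged,
                                        sampling_fraction=study.sampling_fraction)
            if backend == "case-cohort-cox":
                fit = fit_prentice_cox(fit_study, real_final + (covariates or []),
                                       categorical)
                final_coefs = fit.summary().loc[
                    [n for n in fit.names if n in real_final]
                ]
            else:
                Xd = expand_design(merged, real_final + (covariates or []),
                                   categorical, add_intercept=True)
                y = merged[outcome or "event"].to_numpy(dtype=float)
                fitfun = _fit_linear if backend == "linear" else _fit_logistic
                b, se = fitfun(y, Xd.to_numpy(dtype=float))
                zv = b / se
                final_coefs = pd.DataFrame(
                    {"coef": b, "se": se, "z": zv,
                     "p": 2 * stats.norm.sf(np.abs(zv))},
                    index=Xd.columns,
                ).loc[[n for n in Xd.columns if n in real_final]]

    return SelectionResult(round1=round1, round2=round2, nested_sets=nested,
                           final_coefficients=final_coefs,
                           assignments=assignments, z_tables=z_tables,
                           noise_selected=noise_selected)
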