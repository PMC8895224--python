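"""Weighted concordance for case-cohort risk models.

The C-index is computed over usable pairs (i an event at t_i, j still at
risk after t_i) with Horvitz-Thompson sampling weights: cases weigh 1,
subcohort non-cases weigh 1/sampling_fraction, so the pair sum estimates
full-cohort concordance. Ties in risk count 0.5; pairs tied on event
time are unusable. Confidence intervals and the p-value for a change in
C against a base model come from a stratified paired bootstrap over
subjects (cases and non-case subcohort members resampled separately)
with risk scores held fixed (apparent discrimination).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import expand_design
from .coxcc import CaseCohortStudy, fit_prentice_cox
from .preprocess import MetaboliteMatrix


def ipw_weights(study: CaseCohortStudy) -> pd.Series:
    """Per-subject inverse-probability weights by sampling class.

    Cases (inside or outside the subcohort) weigh 1; subcohort non-cases
    weigh 1/sampling_fraction.
    """
    f = study.sampling_fraction
    event = study.samples["event"].astype(bool)
    w = np.where(event, 1.0, 1.0 / f)
    return pd.Series(w, index=study.samples.index, name="ipw")


def weighted_c_index(
    risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted concordance over usable pairs.

    C = sum over pairs (i event, t_j > t_i) of w_i w_j [1(r_i > r_j) +
    0.5 1(r_i = r_j)] / sum w_i w_j.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n = len(risk)
    if not np.all(np.isfinite(risk)):
        raise ValueError("risk scores must be finite")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    usable = event[:, None] & (time[None, :] > time[:, None])
    if not usable.any():
        raise ValueError("no usable pairs (all times tied or no events)")
    conc = (risk[:, None] > risk[None, :]).astype(float)
    conc += 0.5 * (risk[:, None] == risk[None, :])
    ww = w[:, None] * w[None, :]
    num = float((ww * conc)[usable].sum())
    den = float(ww[usable].sum())
    return num / den


def _model_risk(
    study: CaseCohortStudy,
    design_columns: list[str],
    categorical: frozenset[str] | set[str],
) -> tuple[np.ndarray, pd.Index]:
    fit = fit_prentice_cox(study, design_columns, categorical)
    df = study.samples
    cc = df[design_columns].notna().all(axis=1)
    X = expand_design(df.loc[cc], design_columns, categorical,
                      add_intercept=False).to_numpy(dtype=float)
    return X @ fit.coef, df.index[cc]


def nested_model_comparison(
    study: CaseCohortStudy,
    m: MetaboliteMatrix | pd.DataFrame | None,
    base_covariates: list[str],
    biomarker_sets: list[list[str]],
    categorical: frozenset[str] | set[str] = frozenset(),
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Weighted C for nested risk models: base, then base + each biomarker set.

    ``biomarker_sets`` must be nested (each set contains the previous).
    Risk scores are linear predictors of Prentice Cox fits on the same
    sample (apparent discrimination). Returns one row per model with the
    weighted C, percentile bootstrap CI, two-sided bootstrap p for the
    change in C versus the base model, and the unweighted C alongside.
    """
    for a, b in zip(biomarker_sets, biomarker_sets[1:]):
        if not set(a) <= set(b):
            raise ValueError("biomarker sets must be nested")

    if isinstance(m, MetaboliteMatrix):
        bio = m.values
    elif m is None:
        bio = pd.DataFrame(index=study.samples.index)
    else:
        bio = m
    merged = study.samples.join(
        bio[[c for c in bio.columns if c not in study.samples.columns]],
        how="inner",
    )
    full = CaseCohortStudy(samples=merged, sampling_fraction=study.sampling_fraction)

    model_cols = [list(base_covariates)] + [
        list(base_covariates) + list(s) for s in biomarker_sets
    ]
    labels = ["base"] + [f"base+{len(s)}" for s in biomarker_sets]

    risks, idxs = [], None
    for cols in model_cols:
        r, idx = _model_risk(full, cols, categorical)
        risks.append(pd.Series(r, index=idx))
        idxs = idx if idxs is None else idxs.intersection(idx)
    risks = [r.loc[idxs].to_numpy() for r in risks]
    sub = merged.loc[idxs]
    time = sub["event_time"].to_numpy()
    event = sub["event"].to_numpy(bool)
    w = ipw_weights(CaseCohortStudy(sub, study.sampling_fraction)).to_numpy()

    c_point = [weighted_c_index(r, time, event, w) for r in risks]
    c_unw = [weighted_c_index(r, time, event, None) for r in risks]

    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(event)
    ctrl_idx = np.flatnonzero(~event)
    n_models = len(risks)
    boot_c = np.empty((bootstrap_reps, n_models))
    for b in range(bootstrap_reps):
        bi = np.concatenate([
            rng.choice(case_idx, size=len(case_idx), replace=True),
            rng.choice(ctrl_idx, size=len(ctrl_idx), replace=True),
        ])
        tb, eb, wb = time[bi], event[bi], w[bi]
        for k in range(n_models):
            boot_c[b, k] = weighted_c_index(risks[k][bi], tb, eb, wb)

    rows = []
    for k in range(n_models):
        lcl, ucl = np.percentile(boot_c[:, k], [2.5, 97.5])
        if k == 0:
            p = np.nan
        else:
            dc = boot_c[:, k] - boot_c[:, 0]
            frac_le = (np.sum(dc < 0) + 0.5 * np.sum(dc == 0)) / bootstrap_reps
            p = 2 * min(frac_le, 1 - frac_le)
            p = min(max(p, 1.0 / bootstrap_reps), 1.0)
        rows.append(dict(
            model=labels[k],
            n_biomarkers=0 if k == 0 else len(biomarker_sets[k - 1]),
            c=c_point[k], lcl=lcl, ucl=ucl, p_vs_base=p,
            c_unweighted=c_unw[k],
            n=len(idxs), n_events=int(event.sum()),
            bootstrap_reps=bootstrap_reps, seed=seed,
        ))
    return pd.DataFrame(rows).set_index("model")
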