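import numpy as np
import pandas as pd
import pytest

from metabcc import CaseCohortStudy, MetaboliteMatrix, SimConfig, generate_study, qc_pipeline


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_cohort=4000,
        n_snps=40,
        n_metab=120,
        n_bmi_linked=25,
        n_causal_metab=5,
        subcohort_size=150,
        target_cases=110,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def qc_metab(small_study):
    metab, _ = qc_pipeline(small_study.metabolites)
    return metab


def make_survival_frame(
    rng: np.random.Generator,
    n: int,
    beta: np.ndarray,
    censor_q: float = 0.5,
    p: int | None = None,
) -> pd.DataFrame:
    """Full-cohort survival data with exponential event times."""
    beta = np.atleast_1d(beta)
    p = len(beta) if p is None else p
    X = rng.normal(size=(n, p))
    eta = X @ beta
    t = rng.exponential(np.exp(-eta))
    c = np.quantile(t, censor_q)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df["event_time"] = np.minimum(t, c)
    df["event"] = t <= c
    df["in_subcohort"] = True
    return df


def raw_matrix(values: np.ndarray, ids=None) -> MetaboliteMatrix:
    """Wrap a numeric array (NaN = missing) as a raw-scale matrix."""
    values = np.asarray(values, dtype=float)
    cols = ids or [f"m{j}" for j in range(values.shape[1])]
    return MetaboliteMatrix(
        values=pd.DataFrame(values, columns=cols), scale_state="raw"
    )
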