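"""Metabolite matrix QC and transformation.

The assay pipeline applies three forward-only steps to a raw intensity
matrix (samples x metabolites):

1. ``filter_missing`` — drop metabolites undetected in more than a given
   fraction of participants (default: strictly more than 95%).
2. ``impute_lod`` — replace below-limit-of-detection (missing) cells with
   the minimum observed intensity for that metabolite.
3. ``log_standardize`` — natural log, then scale each metabolite to unit
   sample standard deviation (the mean is *not* centred; regression
   intercepts absorb it, and effects stay interpretable per 1 SD).

The ``scale_state`` attribute enforces the ordering: any other
composition raises :class:`ScaleStateError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW = "raw"
LOD_IMPUTED = "lod_imputed"
LOG_STANDARDIZED = "log_standardized"

_STATE_ORDER = {RAW: 0, LOD_IMPUTED: 1, LOG_STANDARDIZED: 2}


class ScaleStateError(RuntimeError):
    """A transform was applied out of order."""


class DegenerateMatrixError(ValueError):
    """The operation would produce or received an unusable matrix."""


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites intensity matrix with missingness provenance.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are metabolite ids. On the
        raw scale, missing (below-LOD) cells are NaN.
    annotations
        Optional per-metabolite table (index = metabolite id) carrying
        ``super_pathway`` / ``sub_pathway`` labels.
    scale_state
        One of ``raw``, ``lod_imputed``, ``log_standardized``.
    missing_mask
        Boolean DataFrame, True where the raw value was below LOD. Kept
        through imputation/standardisation for provenance.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame | None = None
    scale_state: str = RAW
    missing_mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scale_state not in _STATE_ORDER:
            raise ValueError(f"unknown scale_state {self.scale_state!r}")
        if self.missing_mask is None:
            self.missing_mask = self.values.isna()
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask and values must be congruent in shape")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-metabolite fraction of below-LOD cells."""
        return self.missing_mask.mean(axis=0)

    def _require_state(self, *allowed: str) -> None:
        if self.scale_state not in allowed:
            raise ScaleStateError(
                f"operation requires scale_state in {allowed}, got {self.scale_state!r}"
            )


def filter_missing(
    m: MetaboliteMatrix, threshold: float = 0.95
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Drop metabolites missing in strictly more than ``threshold`` of samples.

    The rule is a strict inequality: a metabolite missing in exactly
    ``threshold`` of participants is retained.

    Returns the filtered matrix and an exclusion report with columns
    ``missing_fraction`` and ``action`` (``kept`` / ``dropped``), one row
    per input metabolite.
    """
    m._require_state(RAW)
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    frac = m.missing_fraction()
    dropped = frac.index[frac > threshold]
    report = pd.DataFrame(
        {
            "metabolite_id": frac.index,
            "missing_fraction": frac.values,
            "action": np.where(frac.values > threshold, "dropped", "kept"),
        }
    ).set_index("metabolite_id")
    keep = frac.index.difference(dropped, sort=False)
    if len(keep) == 0:
        raise DegenerateMatrixError(
            f"all {m.n_metabolites} metabolites exceed missingness threshold {threshold}"
        )
    out = MetaboliteMatrix(
        values=m.values[keep],
        annotations=None if m.annotations is None else m.annotations.loc[
            m.annotations.index.intersection(keep)
        ],
        scale_state=RAW,
        missing_mask=m.missing_mask[keep],
    )
    return out, report


def impute_lod(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Assign each below-LOD cell the minimum observed value of its metabolite."""
    m._require_state(RAW)
    n_obs = m.values.notna().sum(axis=0)
    empty = n_obs.index[n_obs == 0]
    if len(empty):
        raise DegenerateMatrixError(
            f"metabolites with no observed values reached LOD imputation "
            f"(should have been filtered): {list(empty[:5])}"
        )
    col_min = m.values.min(axis=0, skipna=True)
    values = m.values.fillna(col_min)
    return MetaboliteMatrix(
        values=values,
        annotations=m.annotations,
        scale_state=LOD_IMPUTED,
        missing_mask=m.missing_mask.copy(),
    )


def log_standardize(
    m: MetaboliteMatrix,
    base: float | None = None,
    sample_subset: pd.Index | None = None,
) -> MetaboliteMatrix:
    """Log-transform then scale each metabolite to sample SD 1.

    Parameters
    ----------
    base
        Logarithm base; natural log by default.
    sample_subset
        If given, SDs are computed over this subset of samples only (e.g.
        subcohort-only standardisation as a sensitivity choice); the
        transform is still applied to all rows. Default: all samples.

    SD uses the n-1 denominator. Only the scale is normalised; means are
    left alone.
    """
    m._require_state(LOD_IMPUTED)
    vals = m.values.to_numpy(dtype=float)
    if not np.all(vals > 0):
        r, c = np.argwhere(~(vals > 0))[0]
        raise DegenerateMatrixError(
            f"nonpositive value for metabolite {m.metabolite_ids[c]!r} "
            f"in sample {m.sample_ids[r]!r}; log transform undefined"
        )
    logged = np.log(vals)
    if base is not None:
        logged = logged / np.log(base)
    logged = pd.DataFrame(logged, index=m.sample_ids, columns=m.metabolite_ids)
    ref = logged if sample_subset is None else logged.loc[sample_subset]
    sd = ref.std(axis=0, ddof=1)
    zero = sd.index[~(sd > 0)]
    if len(zero):
        raise DegenerateMatrixError(
            f"zero-variance metabolites cannot be standardized: {list(zero[:5])}"
        )
    out = logged / sd
    return MetaboliteMatrix(
        values=out,
        annotations=m.annotations,
        scale_state=LOG_STANDARDIZED,
        missing_mask=m.missing_mask.copy(),
    )


def skewness_report(m: MetaboliteMatrix) -> pd.DataFrame:
    """Per-metabolite skewness diagnostics (informational; never filters)."""
    from scipy import stats

    sk = stats.skew(m.values.to_numpy(dtype=float), axis=0, nan_policy="omit")
    return pd.DataFrame({"skewness": sk}, index=m.metabolite_ids)


def qc_pipeline(
    m: MetaboliteMatrix,
    missing_threshold: float = 0.95,
    log_base: float | None = None,
    sample_subset: pd.Index | None = None,
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Run filter -> LOD imputation -> log-standardisation in order."""
    filtered, report = filter_missing(m, missing_threshold)
    imputed = impute_lod(filtered)
    return log_standardize(imputed, base=log_base, sample_subset=sample_subset), report
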