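"""TSV readers and writers for study inputs.

All files are tab-separated with a header row, UTF-8, and an *empty*
field for a missing value (never a sentinel number). ``write_study``
emits the full input set for a synthetic study plus its ground truth, in
a layout that round-trips losslessly through the readers here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .coxcc import CaseCohortStudy
from .mr import DosagePanel
from .preprocess import MetaboliteMatrix

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", na_rep="", float_format=_FLOAT_FMT,
              index_label=index_label)


def write_study(study, directory: str | Path, overwrite: bool = False) -> list[Path]:
    """Write a :class:`~metabcc.simulate.SyntheticStudy` as TSV files.

    Files: metabolites.tsv, annotations.tsv, samples.tsv (analysis
    sample), cohort.tsv (full cohort), dosages.tsv, snps.tsv (panel
    allele coding), weights.tsv, truth.tsv. Existing files are refused
    unless ``overwrite`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = ["metabolites.tsv", "annotations.tsv", "samples.tsv", "cohort.tsv",
             "dosages.tsv", "snps.tsv", "weights.tsv", "truth.tsv"]
    paths = [directory / n for n in names]
    clashes = [p for p in paths if p.exists()]
    if clashes and not overwrite:
        raise FileExistsError(
            f"refusing to overwrite existing files: {[p.name for p in clashes]}"
        )

    _write(study.metabolites.values, paths[0], "sample_id")
    _write(study.metabolites.annotations, paths[1], "metabolite_id")

    def _samples_frame(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in ("event", "in_subcohort"):
            if col in out:
                out[col] = out[col].astype(int)
        return out

    _write(_samples_frame(study.study.samples), paths[2], "sample_id")
    _write(_samples_frame(study.cohort), paths[3], "sample_id")
    _write(study.dosages.dosages, paths[4], "sample_id")
    snps = pd.DataFrame({
        "effect_allele": study.dosages.effect_allele,
        "other_allele": study.dosages.other_allele,
    })
    snps.index.name = "snp_id"
    _write(snps, paths[5], "snp_id")
    study.weights.to_csv(paths[6], sep="\t", index=False,
                         float_format=_FLOAT_FMT)
    truth = study.truth.copy()
    for col in ("is_bmi_linked", "is_causal"):
        truth[col] = truth[col].astype(int)
    _write(truth, paths[7], "metabolite_id")
    return paths


def read_metabolites(
    metabolites_path: str | Path,
    annotations_path: str | Path | None = None,
) -> MetaboliteMatrix:
    values = pd.read_csv(metabolites_path, sep="\t", index_col="sample_id")
    values.columns.name = "metabolite_id"
    annot = None
    if annotations_path is not None:
        annot = pd.read_csv(annotations_path, sep="\t", index_col="metabolite_id")
    return MetaboliteMatrix(values=values, annotations=annot, scale_state="raw")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    for col in ("event", "in_subcohort"):
        if col in df:
            df[col] = df[col].astype(bool)
    return df


def read_case_cohort(path: str | Path, sampling_fraction: float) -> CaseCohortStudy:
    return CaseCohortStudy(samples=read_samples(path),
                           sampling_fraction=sampling_fraction)


def read_dosages(dosages_path: str | Path,
                 snps_path: str | Path | None = None) -> DosagePanel:
    d = pd.read_csv(dosages_path, sep="\t", index_col="sample_id")
    if snps_path is not None:
        snps = pd.read_csv(snps_path, sep="\t", index_col="snp_id")
        ea, oa = snps["effect_allele"], snps["other_allele"]
    else:
        ea = pd.Series("A", index=d.columns)
        oa = pd.Series("B", index=d.columns)
    return DosagePanel(dosages=d, effect_allele=ea, other_allele=oa)


def read_weights(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="metabolite_id")
    for col in ("is_bmi_linked", "is_causal"):
        if col in df:
            df[col] = df[col].astype(bool)
    return df
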