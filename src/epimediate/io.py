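"""Readers and writers for the pipeline's tabular formats.

All matrices are delimited text with samples in rows (sample id in the
first column) and features in columns.  Readers validate rather than
coerce: duplicate ids, non-numeric cells and ragged rows are errors.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt

from .datamodel import Cohort, DataModelError, OmicsMatrix, ProbeAnnotation, SampleMeta

log = logging.getLogger(__name__)


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_matrix(path, feature_type: str, timepoint: str, sep: str | None = None) -> OmicsMatrix:
    """Read a samples x features matrix and validate it.

    Raises :class:`DataModelError` naming the offending ids/cells on
    malformed input.
    """
    path = Path(path)
    sep = _sep_for(path, sep)
    try:
        # pandas silently mangles duplicate header names; check them raw
        header = pd.read_csv(path, sep=sep, header=None, nrows=1).iloc[0].tolist()
        dup = pd.Index(header[1:])
        if dup.has_duplicates:
            raise DataModelError(
                f"{path}: duplicate feature ids: {dup[dup.duplicated()].unique().tolist()}"
            )
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise DataModelError(f"{path}: cannot parse as delimited table: {exc}") from exc
    try:
        df = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise DataModelError(f"{path}: non-numeric cell: {exc}") from exc
    matrix = OmicsMatrix(df, feature_type=feature_type, timepoint=timepoint)
    log.info(
        "read %s@%s: %d samples x %d features from %s",
        feature_type, timepoint, matrix.n_samples, matrix.n_features, path,
    )
    return matrix


def write_matrix(matrix: OmicsMatrix, path, sep: str | None = None) -> None:
    path = Path(path)
    matrix.values.to_csv(path, sep=_sep_for(path, sep), index_label="sample_id")


def read_sample_meta(path, sep: str | None = None) -> SampleMeta:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    return SampleMeta(df)


def write_sample_meta(meta: SampleMeta, path, sep: str | None = None) -> None:
    path = Path(path)
    meta.table.to_csv(path, sep=_sep_for(path, sep), index_label="sample_id")


def read_annotation(path, sep: str | None = None) -> ProbeAnnotation:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0, keep_default_na=False)
    df["position"] = pd.to_numeric(df["position"], errors="raise").astype(int)
    return ProbeAnnotation(df)


def write_annotation(annotation: ProbeAnnotation, path, sep: str | None = None) -> None:
    path = Path(path)
    annotation.table.to_csv(path, sep=_sep_for(path, sep), index_label="probe_id")


def read_gmt(path) -> dict[str, list[str]]:
    """Pathway name -> gene symbols, from a standard GMT file."""
    sets = _gseapy_read_gmt(str(path))
    if not sets:
        raise DataModelError(f"{path}: no gene sets parsed from GMT")
    return {name: list(genes) for name, genes in sets.items()}


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_cohort(cohort: Cohort, directory) -> dict[str, Path]:
    """Write a cohort's five (six with truth) tables into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "meth_psv": directory / "methylation_psv.tsv",
        "meth_sv": directory / "methylation_sv.tsv",
        "met_psv": directory / "metabolites_psv.tsv",
        "met_sv": directory / "metabolites_sv.tsv",
        "meta": directory / "samples.tsv",
    }
    write_matrix(cohort.meth_psv, paths["meth_psv"])
    write_matrix(cohort.meth_sv, paths["meth_sv"])
    write_matrix(cohort.met_psv, paths["met_psv"])
    write_matrix(cohort.met_sv, paths["met_sv"])
    write_sample_meta(cohort.meta, paths["meta"])
    if cohort.truth is not None:
        paths["truth"] = directory / "truth.tsv"
        cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_cohort(directory) -> Cohort:
    directory = Path(directory)
    truth_path = directory / "truth.tsv"
    cohort = Cohort(
        meth_psv=read_matrix(directory / "methylation_psv.tsv", "methylation", "PSV"),
        meth_sv=read_matrix(directory / "methylation_sv.tsv", "methylation", "SV"),
        met_psv=read_matrix(directory / "metabolites_psv.tsv", "metabolite", "PSV"),
        met_sv=read_matrix(directory / "metabolites_sv.tsv", "metabolite", "SV"),
        meta=read_sample_meta(directory / "samples.tsv"),
        truth=pd.read_csv(truth_path, sep="\t") if truth_path.exists() else None,
    )
    cohort.validate()
    return cohort
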