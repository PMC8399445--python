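"""Shared data model for the mediation pipeline.

Two omics layers (DNA methylation M-values and normalized metabolite
abundances), each measured at two visits — the last autoantibody-negative
visit ("PSV", pre-seroconversion) and the first positive visit ("SV",
seroconversion) — plus per-sample outcome/covariate metadata and a probe
annotation table used for gene mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIMEPOINTS = ("PSV", "SV")
FEATURE_TYPES = ("methylation", "metabolite")

#: covariate columns entering every adjusted model, in design-matrix order
COVARIATE_COLUMNS = ("dr34", "age_psv", "time_psv_sv", "sex_male")


class DataModelError(ValueError):
    """Raised when a table violates the pipeline's data contract."""


@dataclass
class OmicsMatrix:
    """Samples x features numeric matrix with timepoint and layer tags.

    ``values`` is a DataFrame indexed by sample id with feature ids as
    columns.  Methylation values are M-values (logit-scale methylation
    proportions); metabolite values are normalized abundances.
    """

    values: pd.DataFrame
    feature_type: str
    timepoint: str

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise DataModelError(
                f"feature_type must be one of {FEATURE_TYPES}, got {self.feature_type!r}"
            )
        if self.timepoint not in TIMEPOINTS:
            raise DataModelError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate feature ids: {dups}")
        non_numeric = [c for c in cols if not np.issubdtype(self.values[c].dtype, np.number)]
        if non_numeric:
            raise DataModelError(f"non-numeric feature columns: {non_numeric}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def require_finite(self) -> None:
        """Missing values are not imputed anywhere in the pipeline."""
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            bad = int((~np.isfinite(arr)).sum())
            raise DataModelError(
                f"{bad} non-finite cells in {self.feature_type}@{self.timepoint} matrix; "
                "complete cases are required"
            )

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        missing = [s for s in sample_ids if s not in self.values.index]
        if missing:
            raise DataModelError(f"samples absent from matrix: {missing[:5]}")
        return OmicsMatrix(self.values.loc[list(sample_ids)], self.feature_type, self.timepoint)


@dataclass
class SampleMeta:
    """Per-sample outcome and covariates.

    Columns: ``case`` (0/1 islet-autoimmunity outcome), ``sex`` (F/M),
    ``age_psv`` (years at PSV), ``time_psv_sv`` (years PSV to SV),
    ``dr34`` (0/1 HLA-DR3/4 haplotype), ``platform`` (450K/EPIC array).
    """

    table: pd.DataFrame

    REQUIRED = ("case", "sex", "age_psv", "time_psv_sv", "dr34", "platform")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate sample ids in metadata: {dups}")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataModelError(f"metadata missing columns: {missing}")
        if len(self.table):
            if not set(self.table["case"].unique()) <= {0, 1}:
                raise DataModelError("case must be 0/1")
            if not set(self.table["dr34"].unique()) <= {0, 1}:
                raise DataModelError("dr34 must be 0/1")
            if not set(self.table["sex"].unique()) <= {"F", "M"}:
                raise DataModelError("sex must be F/M")
            if (self.table["age_psv"] <= 0).any():
                raise DataModelError("age_psv must be positive")
            if (self.table["time_psv_sv"] <= 0).any():
                raise DataModelError("time_psv_sv must be positive")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def case(self) -> np.ndarray:
        return self.table["case"].to_numpy(dtype=int)

    def covariate_design(self, include_platform: bool = False) -> pd.DataFrame:
        """Numeric covariate columns in canonical order (sex coded M=1)."""
        design = pd.DataFrame(index=self.table.index)
        design["dr34"] = self.table["dr34"].astype(float)
        design["age_psv"] = self.table["age_psv"].astype(float)
        design["time_psv_sv"] = self.table["time_psv_sv"].astype(float)
        design["sex_male"] = (self.table["sex"] == "M").astype(float)
        if include_platform:
            # 450K is the reference level
            design["platform_epic"] = (self.table["platform"] == "EPIC").astype(float)
        return design

    def subset(self, sample_ids) -> "SampleMeta":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise DataModelError(f"samples absent from metadata: {missing[:5]}")
        return SampleMeta(self.table.loc[list(sample_ids)])


@dataclass
class ProbeAnnotation:
    """Probe -> (chromosome, 1-based position, CpG-island relation, gene symbol)."""

    table: pd.DataFrame

    REQUIRED = ("chromosome", "position", "island_relation", "gene_symbol")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate probe ids in annotation: {dups}")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataModelError(f"annotation missing columns: {missing}")
        if len(self.table) and (self.table["position"] <= 0).any():
            raise DataModelError("positions must be positive (1-based)")

    def gene_of(self, probe_id: str) -> str:
        """Gene symbol for a probe; empty string when unannotated."""
        gene = self.table.at[probe_id, "gene_symbol"]
        return "" if pd.isna(gene) else str(gene)


@dataclass
class Cohort:
    """The four analysis matrices plus metadata, sample-aligned."""

    meth_psv: OmicsMatrix
    meth_sv: OmicsMatrix
    met_psv: OmicsMatrix
    met_sv: OmicsMatrix
    meta: SampleMeta
    truth: pd.DataFrame | None = field(default=None)

    def validate(self) -> None:
        ids = self.meta.sample_ids
        for m in (self.meth_psv, self.meth_sv, self.met_psv, self.met_sv):
            if not m.sample_ids.equals(ids):
                raise DataModelError(
                    f"sample set of {m.feature_type}@{m.timepoint} does not match metadata"
                )
            m.require_finite()
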