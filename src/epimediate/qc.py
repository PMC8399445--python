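"""Metabolomics quality-control filters.

Two filters applied to the (already normalized) metabolite matrices before
analysis: a per-metabolite coefficient-of-variation outlier filter and a
per-sample low-total-abundance filter.  Both are robust median/MAD rules
and both are idempotent.
"""

from __future__ import annotations

import logging

import numpy as np

from .datamodel import DataModelError, OmicsMatrix

log = logging.getLogger(__name__)


def _mad(x: np.ndarray) -> float:
    """Unscaled median absolute deviation."""
    return float(np.median(np.abs(x - np.median(x))))


def filter_metabolite_cv(
    matrix: OmicsMatrix, n_dev: float = 2.0
) -> tuple[OmicsMatrix, list[str]]:
    """Drop metabolites whose CV is an outlier in the CV distribution.

    CV = sd/mean per metabolite (sample sd, ddof=1) on the provided scale.
    A metabolite is excluded iff ``|CV - median(CV)| > n_dev * MAD(CV)``,
    reading "more than two absolute deviations from the median" as a
    median +/- 2 MAD band.  With a single metabolite MAD is 0 and its own
    deviation is 0, so it is never excluded.
    """
    if matrix.feature_type != "metabolite":
        raise DataModelError("CV filter applies to metabolite matrices")
    if matrix.n_samples < 3:
        raise DataModelError("CV filter needs at least 3 samples")
    values = matrix.values.to_numpy(dtype=float)
    means = values.mean(axis=0)
    if np.any(means == 0):
        bad = matrix.feature_ids[means == 0].tolist()
        raise DataModelError(f"CV undefined for zero-mean metabolites: {bad[:5]}")
    cv = values.std(axis=0, ddof=1) / means
    center = np.median(cv)
    mad = _mad(cv)
    # absolute tolerance so exactly-tied CVs (MAD 0) are never flagged by
    # floating-point noise
    atol = 1e-10 * (1.0 + abs(center))
    excluded_mask = np.abs(cv - center) > n_dev * mad + atol
    excluded = matrix.feature_ids[excluded_mask].tolist()
    kept = OmicsMatrix(
        matrix.values.loc[:, ~excluded_mask], matrix.feature_type, matrix.timepoint
    )
    log.info(
        "CV filter (@%s): %d in, %d excluded, %d retained",
        matrix.timepoint, matrix.n_features, len(excluded), kept.n_features,
    )
    return kept, excluded


def filter_low_abundance_samples(
    matrix: OmicsMatrix, k_mad: float = 3.0
) -> tuple[OmicsMatrix, list[str]]:
    """Drop samples whose total metabolite abundance is anomalously low.

    A sample is excluded iff its total abundance falls below
    ``median(totals) - k_mad * MAD(totals)``.  ``k_mad=inf`` disables the
    filter.
    """
    if matrix.feature_type != "metabolite":
        raise DataModelError("low-abundance filter applies to metabolite matrices")
    totals = matrix.values.to_numpy(dtype=float).sum(axis=1)
    if matrix.n_samples == 0 or not np.isfinite(k_mad):
        return matrix, []
    cutoff = np.median(totals) - k_mad * _mad(totals) - 1e-10 * (1.0 + abs(np.median(totals)))
    excluded_mask = totals < cutoff
    excluded = matrix.sample_ids[excluded_mask].tolist()
    kept = OmicsMatrix(
        matrix.values.loc[~excluded_mask], matrix.feature_type, matrix.timepoint
    )
    log.info(
        "low-abundance filter (@%s): %d in, %d excluded",
        matrix.timepoint, matrix.n_samples, len(excluded),
    )
    return kept, excluded
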