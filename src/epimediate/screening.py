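"""Stage-1 candidate screening of probe-metabolite pairs.

A pair becomes a mediation candidate when (i) probe and metabolite are
associated with one another in simple linear regression, and (ii) each
feature is marginally associated with the outcome in unadjusted logistic
regression, all at a nominal screening level (default p < 0.01).  These
p-values are deliberately not multiplicity-adjusted: this is a
candidate-filtering step, and error control happens downstream (FCR on
the mediation estimates).

Two temporal directions are screened: exposure DNAm@PSV with mediator
metabolite@SV (``dnam_psv``), and exposure metabolite@PSV with mediator
DNAm@SV (``met_psv``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .datamodel import DataModelError, OmicsMatrix, SampleMeta
from .mediation import DIRECTIONS

log = logging.getLogger(__name__)


class SeparationWarning(UserWarning):
    """Perfect or quasi-separation in an outcome screen."""


@dataclass(frozen=True)
class CandidatePair:
    """One pair passing all three screens, with the screen p-values."""

    probe_id: str
    metabolite_id: str
    direction: str
    p_assoc: float
    p_probe_outcome: float
    p_met_outcome: float


def association_screen(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided slope p-value of simple linear regression of y on x.

    Identical to the Pearson correlation test; no covariate adjustment.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0] or x.shape[0] < 4:
        raise ValueError("need equal-length vectors with at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: association screen undefined")
    res = stats.linregress(x, y)
    return float(res.pvalue)


def outcome_screen(
    feature: np.ndarray, case: np.ndarray, platform: np.ndarray | None = None
) -> float:
    """Wald two-sided p for the feature in logistic regression of case status.

    Unadjusted by default; optionally adjusts for measurement platform
    (0/1 indicator).  On perfect or quasi-separation, emits
    :class:`SeparationWarning` and returns NaN so the caller can drop the
    feature with a logged reason.
    """
    feature = np.asarray(feature, dtype=float)
    case = np.asarray(case, dtype=float)
    if len(np.unique(case)) < 2:
        raise ValueError("both outcome classes must be present")
    cols = [np.ones_like(feature), feature]
    if platform is not None:
        cols.append(np.asarray(platform, dtype=float))
    X = np.column_stack(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(case, X).fit(disp=0, method="newton", maxiter=50)
        except Exception:
            warnings.warn("separation or non-convergence in outcome screen", SeparationWarning,
                          stacklevel=2)
            return float("nan")
    if not fit.mle_retvals.get("converged", False) or np.abs(fit.params[1]) > 30:
        warnings.warn("separation or non-convergence in outcome screen", SeparationWarning,
                      stacklevel=2)
        return float("nan")
    return float(fit.pvalues[1])


def _association_pvalues(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Slope p-values for every (column of X, column of Y) pair, vectorized.

    Equivalent to calling :func:`association_screen` per pair (Pearson
    correlation t-test with n-2 df).
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((Yc**2).sum(axis=0))
    if np.any(sx == 0):
        raise ValueError("constant probe column in association screen")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Yc) / np.outer(sx, sy)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def screen_all_pairs(
    methylation: OmicsMatrix,
    metabolites: OmicsMatrix,
    meta: SampleMeta,
    alpha_screen: float = 0.01,
    direction: str = "dnam_psv",
    adjust_platform: bool = False,
) -> list[CandidatePair]:
    """All candidate pairs passing the three screens at ``alpha_screen``.

    ``methylation``/``metabolites`` are the matrices supplying each pair's
    probe and metabolite values for this ``direction``.  Outcome screens
    are computed once per feature and cached; this reorders the screens
    relative to running them pair-by-pair but yields the identical pair
    set.  Features whose outcome screen separates are dropped with a
    logged reason.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if not methylation.sample_ids.equals(meta.sample_ids) or not metabolites.sample_ids.equals(
        meta.sample_ids
    ):
        raise DataModelError("matrices and metadata must share an identical sample set")
    case = meta.case.astype(float)
    platform = (
        (meta.table["platform"] == "EPIC").to_numpy(dtype=float) if adjust_platform else None
    )

    M = methylation.values.to_numpy(dtype=float)
    T = metabolites.values.to_numpy(dtype=float)
    n_pairs = methylation.n_features * metabolites.n_features
    log.info(
        "screening %d probes x %d metabolites = %d candidate pairs (%s)",
        methylation.n_features, metabolites.n_features, n_pairs, direction,
    )

    def outcome_p(values: np.ndarray, ids, label: str) -> dict:
        out = {}
        for j, fid in enumerate(ids):
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", SeparationWarning)
                p = outcome_screen(values[:, j], case, platform)
            if caught or np.isnan(p):
                log.warning("%s %s dropped from screen: separation/non-convergence", label, fid)
                p = float("nan")
            out[fid] = p
        return out

    p_probe = outcome_p(M, methylation.feature_ids, "probe")
    p_met = outcome_p(T, metabolites.feature_ids, "metabolite")

    probe_pass = [f for f in methylation.feature_ids if p_probe[f] < alpha_screen]
    met_pass = [f for f in metabolites.feature_ids if p_met[f] < alpha_screen]
    if not probe_pass or not met_pass:
        return []

    pi = [methylation.feature_ids.get_loc(f) for f in probe_pass]
    mi = [metabolites.feature_ids.get_loc(f) for f in met_pass]
    p_assoc = _association_pvalues(M[:, pi], T[:, mi])

    pairs: list[CandidatePair] = []
    for a, probe in enumerate(probe_pass):
        for b, met in enumerate(met_pass):
            if p_assoc[a, b] < alpha_screen:
                pairs.append(
                    CandidatePair(
                        probe_id=probe,
                        metabolite_id=met,
                        direction=direction,
                        p_assoc=float(p_assoc[a, b]),
                        p_probe_outcome=p_probe[probe],
                        p_met_outcome=p_met[met],
                    )
                )
    log.info("screen (%s): %d of %d pairs pass at p < %g", direction, len(pairs),
             n_pairs, alpha_screen)
    return pairs
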