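"""Regression-based counterfactual mediation with exposure-mediator interaction.

For each candidate probe-metabolite pair the exposure ``a`` (M-value at the
earlier visit) is related to the binary outcome ``y`` (islet autoimmunity)
through a continuous mediator ``m`` (metabolite abundance at the later
visit), adjusting for covariates ``c``:

    mediator model (linear):    m = beta0 + beta1*a + beta2'c + eps,  eps ~ N(0, sigma2)
    outcome model (logistic):   logit P(y=1) = theta0 + theta1*a + theta2*m
                                              + theta3*a*m + theta4'c

Because the study oversamples cases, the mediator model is fitted on
controls only, which approximates the source-population regression when
the outcome is rare.  Under the same rare-outcome approximation the
natural direct and indirect effects have closed forms on the log
odds-ratio scale for an exposure change a0 -> a1:

    log NIE = (theta2*beta1 + theta3*beta1*a1) * (a1 - a0)
    log NDE = (theta1 + theta3*(beta0 + beta1*a0 + beta2'c + theta2*sigma2)) * (a1 - a0)
              + 0.5 * theta3^2 * sigma2 * (a1^2 - a0^2)
    log TE  = log NDE + log NIE          (exactly, by construction)

Inference on log NIE comes two ways: a multivariate delta-method standard
error (used for Wald p-values and ranking) and a stratified percentile
bootstrap (used for confidence intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._fit import LogitResult, OlsResult, logit, ols

DIRECTIONS = ("dnam_psv", "met_psv")


@dataclass
class PairData:
    """One candidate pair's analysis vectors, sample-aligned."""

    exposure: np.ndarray
    mediator: np.ndarray
    case: np.ndarray
    covariates: np.ndarray            # n x c, may have 0 columns
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.mediator = np.asarray(self.mediator, dtype=float)
        self.case = np.asarray(self.case, dtype=int)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.exposure.shape[0]:
            self.covariates = self.covariates.reshape(self.exposure.shape[0], -1)
        n = self.exposure.shape[0]
        if not (self.mediator.shape[0] == self.case.shape[0] == n):
            raise ValueError("pair vectors must share length")

    @property
    def n(self) -> int:
        return self.exposure.shape[0]


@dataclass
class MediatorFit:
    beta0: float
    beta1: float
    beta2: np.ndarray
    sigma2: float
    cov: np.ndarray          # covariance of (beta0, beta1, beta2...)
    n_used: int


@dataclass
class OutcomeFit:
    theta0: float
    theta1: float
    theta2: float
    theta3: float
    theta4: np.ndarray
    cov: np.ndarray          # covariance of (theta0..theta3, theta4...)
    n_used: int
    converged: bool = True
    separated: bool = False


@dataclass(frozen=True)
class EffectContrast:
    """Exposure contrast a0 -> a1 with covariates held at ``cvec``."""

    a0: float = 0.0
    a1: float = 1.0
    cvec: tuple[float, ...] = ()


@dataclass
class MediationEstimate:
    """Fitted effects and inference for one pair."""

    probe_id: str
    metabolite_id: str
    direction: str
    log_nie: float
    log_nde: float
    log_te: float
    se_log_nie: float
    p_nie: float
    ci_level: float | None = None
    ci_low: float | None = None          # log scale
    ci_high: float | None = None
    n_boot: int = 0
    n_dropped: int = 0
    drop_warning: bool = False
    replicates: np.ndarray | None = field(default=None, repr=False)

    @property
    def nie_or(self) -> float:
        return float(np.exp(self.log_nie))


def fit_mediator(data: PairData, controls_only: bool = True) -> MediatorFit:
    """OLS of mediator on exposure + covariates, by default over controls only."""
    keep = np.ones(data.n, dtype=bool) if not controls_only else data.case == 0
    X = np.column_stack([np.ones(int(keep.sum())), data.exposure[keep], data.covariates[keep]])
    names = ["intercept", "exposure", *data.covariate_names] if data.covariate_names \
        else ["intercept", "exposure"] + [f"c{j}" for j in range(data.covariates.shape[1])]
    res: OlsResult = ols(X, data.mediator[keep], names=names)
    return MediatorFit(
        beta0=float(res.coef[0]),
        beta1=float(res.coef[1]),
        beta2=res.coef[2:].copy(),
        sigma2=res.sigma2,
        cov=res.cov,
        n_used=res.n,
    )


def fit_outcome(data: PairData) -> OutcomeFit:
    """Logistic regression of case on exposure, mediator, their product, covariates."""
    X = np.column_stack(
        [np.ones(data.n), data.exposure, data.mediator,
         data.exposure * data.mediator, data.covariates]
    )
    names = ["intercept", "exposure", "mediator", "exposure:mediator"] + (
        list(data.covariate_names) or [f"c{j}" for j in range(data.covariates.shape[1])]
    )
    res: LogitResult = logit(X, data.case.astype(float), names=names)
    return OutcomeFit(
        theta0=float(res.coef[0]),
        theta1=float(res.coef[1]),
        theta2=float(res.coef[2]),
        theta3=float(res.coef[3]),
        theta4=res.coef[4:].copy(),
        cov=res.cov,
        n_used=res.n,
        converged=res.converged,
        separated=res.separated,
    )


def effects(
    mfit: MediatorFit, ofit: OutcomeFit, contrast: EffectContrast
) -> tuple[float, float, float]:
    """(log NDE, log NIE, log TE) on the log odds-ratio scale.

    Rare-outcome closed forms with exposure-mediator interaction; the NIE
    does not involve the covariate conditioning values, the NDE does.
    """
    a0, a1 = contrast.a0, contrast.a1
    cvec = np.asarray(contrast.cvec, dtype=float)
    if cvec.shape[0] != mfit.beta2.shape[0]:
        raise ValueError(
            f"contrast cvec has {cvec.shape[0]} values but mediator model has "
            f"{mfit.beta2.shape[0]} covariates"
        )
    d = a1 - a0
    log_nie = (ofit.theta2 * mfit.beta1 + ofit.theta3 * mfit.beta1 * a1) * d
    log_nde = (
        ofit.theta1
        + ofit.theta3
        * (mfit.beta0 + mfit.beta1 * a0 + float(mfit.beta2 @ cvec) + ofit.theta2 * mfit.sigma2)
    ) * d + 0.5 * ofit.theta3**2 * mfit.sigma2 * (a1**2 - a0**2)
    return float(log_nde), float(log_nie), float(log_nde + log_nie)


def nie_gradient(mfit: MediatorFit, ofit: OutcomeFit, contrast: EffectContrast) -> np.ndarray:
    """Gradient of log NIE wrt (beta1, theta2, theta3)."""
    a0, a1 = contrast.a0, contrast.a1
    d = a1 - a0
    return np.array(
        [
            (ofit.theta2 + ofit.theta3 * a1) * d,
            mfit.beta1 * d,
            mfit.beta1 * a1 * d,
        ]
    )


def delta_se_log_nie(
    mfit: MediatorFit, ofit: OutcomeFit, contrast: EffectContrast
) -> tuple[float, float]:
    """Delta-method SE of log NIE and the two-sided normal Wald p-value.

    The parameter covariance is block-diagonal across the two independently
    fitted models: var(beta1) from the mediator fit, cov(theta2, theta3)
    from the outcome fit.  sigma2 is treated as fixed (it does not enter
    the NIE).
    """
    g = nie_gradient(mfit, ofit, contrast)
    sigma = np.zeros((3, 3))
    sigma[0, 0] = mfit.cov[1, 1]
    sigma[1:, 1:] = ofit.cov[2:4, 2:4]
    if not np.all(np.isfinite(sigma)):
        raise ValueError("non-finite parameter covariance")
    var = float(g @ sigma @ g)
    if var < -1e-12:
        raise ValueError("parameter covariance is not positive semidefinite")
    se = float(np.sqrt(max(var, 0.0)))
    _, log_nie, _ = effects(mfit, ofit, contrast)
    if se == 0.0:
        p = 1.0 if log_nie == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(log_nie) / se))
    return se, p


def default_contrast(data: PairData, a0: float = 0.0, a1: float = 1.0) -> EffectContrast:
    """Contrast conditioning covariates at their analysis-sample means."""
    cvec = tuple(data.covariates.mean(axis=0)) if data.covariates.shape[1] else ()
    return EffectContrast(a0=a0, a1=a1, cvec=cvec)


def bootstrap_ci(
    data: PairData,
    contrast: EffectContrast,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    drop_warn_frac: float = 0.05,
) -> tuple[float, float, np.ndarray, int]:
    """Stratified percentile bootstrap of log NIE.

    Participants are resampled with replacement within case and control
    strata, preserving the case-control design; both models are refitted
    per replicate (mediator on resampled controls only).  Replicates whose
    outcome fit fails to converge are dropped and counted.  Returns
    ``(ci_low, ci_high, replicate log NIE vector, n_dropped)`` with the
    percentile interval taken as empirical quantiles by linear
    interpolation of order statistics.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    case_idx = np.flatnonzero(data.case == 1)
    ctrl_idx = np.flatnonzero(data.case == 0)
    reps = np.empty(B)
    n_dropped = 0
    kept = 0
    for _ in range(B):
        idx = np.concatenate(
            [
                rng.choice(case_idx, size=case_idx.size, replace=True),
                rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True),
            ]
        )
        boot = PairData(
            exposure=data.exposure[idx],
            mediator=data.mediator[idx],
            case=data.case[idx],
            covariates=data.covariates[idx],
            covariate_names=data.covariate_names,
        )
        try:
            mfit = fit_mediator(boot)
            ofit = fit_outcome(boot)
        except (ValueError, np.linalg.LinAlgError):
            n_dropped += 1
            continue
        if ofit.separated or not ofit.converged:
            n_dropped += 1
            continue
        _, log_nie, _ = effects(mfit, ofit, contrast)
        reps[kept] = log_nie
        kept += 1
    reps = reps[:kept]
    if kept == 0:
        raise RuntimeError("all bootstrap replicates failed to converge")
    alpha = 1.0 - level
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0], method="linear")
    return float(lo), float(hi), reps, n_dropped


def mediate_pair(
    data: PairData,
    probe_id: str = "",
    metabolite_id: str = "",
    direction: str = "dnam_psv",
    contrast: EffectContrast | None = None,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    keep_replicates: bool = True,
) -> MediationEstimate:
    """Full per-pair mediation analysis: fits, effects, delta p, bootstrap CI."""
    if contrast is None:
        contrast = default_contrast(data)
    mfit = fit_mediator(data)
    ofit = fit_outcome(data)
    if ofit.separated or not ofit.converged:
        raise RuntimeError(
            f"outcome model for pair ({probe_id}, {metabolite_id}) "
            + ("separated" if ofit.separated else "did not converge")
        )
    log_nde, log_nie, log_te = effects(mfit, ofit, contrast)
    se, p = delta_se_log_nie(mfit, ofit, contrast)
    ci_low, ci_high, reps, n_dropped = bootstrap_ci(
        data, contrast, B=B, level=level, seed=seed
    )
    return MediationEstimate(
        probe_id=probe_id,
        metabolite_id=metabolite_id,
        direction=direction,
        log_nie=log_nie,
        log_nde=log_nde,
        log_te=log_te,
        se_log_nie=se,
        p_nie=p,
        ci_level=level,
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=B,
        n_dropped=n_dropped,
        drop_warning=n_dropped > 0.05 * B,
        replicates=reps if keep_replicates else None,
    )
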