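"""Synthetic cohorts with planted mediation structure and known ground truth.

The generator mirrors the statistical structure the analysis assumes:

* a source population of children with covariates (sex, HLA-DR3/4, age at
  the pre-seroconversion visit, time between visits),
* per-probe methylation M-values with an additive platform batch shift,
* metabolite abundances, with planted mediators generated from a linear
  model in the exposure probe,
* a rare binary outcome (islet autoimmunity) from a logistic model with
  exposure-mediator interaction,
* explicit case-control oversampling: exactly ``n_cases``/``n_controls``
  drawn without replacement from the realized cases/controls, so the
  controls-only mediator fit and the rare-outcome approximation are
  genuinely exercised.

Ground-truth natural effects for each planted pair are recorded on the
log odds-ratio scale.  They are computed from the generating coefficients
by the rare-outcome closed forms; an independent Monte-Carlo
potential-outcome oracle (:func:`monte_carlo_effects`) simulates
counterfactual mediators and outcomes directly from the generating models
and is used in the test suite to validate those closed forms.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as emio
from .datamodel import Cohort, OmicsMatrix, SampleMeta

TRUTH_COLUMNS = (
    "probe_id", "metabolite_id", "direction", "log_nie", "log_nde", "log_te", "a0", "a1"
)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generating model for one synthetic case-control study.

    Outcome model (log-odds units, per planted pair):
    ``theta0 + theta1*a + theta2*m + theta3*a*m + theta_cov'c``.
    Mediator model (mediator units): ``beta0 + beta1*a + beta_cov'c +
    N(0, sigma2)``.  Covariate order is (dr34, age_psv, time_psv_sv,
    sex_male).  Defaults give a rare outcome (source prevalence ~3%) and a
    planted log-OR NIE of -0.36 per pair, i.e. an NIE odds ratio ~0.70.
    """

    seed: int
    n_population: int = 20_000
    n_cases: int = 92
    n_controls: int = 91
    p_probes: int = 300
    q_metabolites: int = 60
    n_causal_pairs: int = 5
    n_causal_pairs_reverse: int = 0
    theta0: float = -4.5
    theta1: float = -0.4
    theta2: float = 0.4
    theta3: float = 0.2
    theta_cov: tuple[float, float, float, float] = (0.3, 0.02, 0.1, -0.1)
    beta0: float = 0.0
    beta1: float = -0.6
    beta_cov: tuple[float, float, float, float] = (0.1, 0.01, 0.05, -0.05)
    sigma2: float = 0.8
    batch_shift: float = 0.5
    met_baseline: float = 10.0
    a0: float = 0.0
    a1: float = 1.0

    def __post_init__(self) -> None:
        counts = {
            "n_population": self.n_population,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "p_probes": self.p_probes,
            "q_metabolites": self.q_metabolites,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.n_cases + self.n_controls > self.n_population:
            raise ValueError("n_cases + n_controls must not exceed n_population")
        if self.n_causal_pairs < 0 or self.n_causal_pairs_reverse < 0:
            raise ValueError("planted pair counts must be non-negative")
        total_planted = self.n_causal_pairs + self.n_causal_pairs_reverse
        if total_planted > min(self.p_probes, self.q_metabolites):
            raise ValueError("more planted pairs than available features")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["theta_cov"] = list(d["theta_cov"])
        d["beta_cov"] = list(d["beta_cov"])
        payload = {
            "seed": d.pop("seed"),
            "population": {k: d.pop(k) for k in
                           ("n_population", "n_cases", "n_controls")},
            "features": {k: d.pop(k) for k in
                         ("p_probes", "q_metabolites", "n_causal_pairs",
                          "n_causal_pairs_reverse", "batch_shift")},
            "effects": d,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "seed" not in payload:
            raise ValueError("simulation config must set a seed")
        flat: dict = {"seed": payload["seed"]}
        for section in ("population", "features", "effects"):
            flat.update(payload.get(section, {}))
        for key in ("theta_cov", "beta_cov"):
            if key in flat:
                flat[key] = tuple(flat[key])
        return cls(**flat)


def _closed_form_effects(cfg: SimConfig, cvec: np.ndarray) -> tuple[float, float, float]:
    """(log_nde, log_nie, log_te) from the generating coefficients."""
    d = cfg.a1 - cfg.a0
    log_nie = (cfg.theta2 * cfg.beta1 + cfg.theta3 * cfg.beta1 * cfg.a1) * d
    bcov = np.asarray(cfg.beta_cov, dtype=float)
    log_nde = (
        cfg.theta1
        + cfg.theta3
        * (cfg.beta0 + cfg.beta1 * cfg.a0 + float(bcov @ cvec) + cfg.theta2 * cfg.sigma2)
    ) * d + 0.5 * cfg.theta3**2 * cfg.sigma2 * (cfg.a1**2 - cfg.a0**2)
    return float(log_nde), float(log_nie), float(log_nde + log_nie)


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate one case-control cohort plus ground truth.

    Raises :class:`SimulationError` naming the achieved case count when
    the source population realizes fewer than ``n_cases`` cases (a sign
    that ``theta0`` is set too low for the requested design).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_population
    nf, nr = cfg.n_causal_pairs, cfg.n_causal_pairs_reverse

    # covariates (dr34, age_psv, time_psv_sv, sex_male), marginals chosen to
    # mimic the study cohort
    dr34 = rng.binomial(1, 0.23, size=n).astype(float)
    age = rng.uniform(0.7, 20.3, size=n)
    time_sv = rng.uniform(0.3, 2.0, size=n)
    sex_male = rng.binomial(1, 0.5, size=n).astype(float)
    platform = rng.binomial(1, 0.5, size=n)  # 1 = EPIC
    C = np.column_stack([dr34, age, time_sv, sex_male])
    tcov = np.asarray(cfg.theta_cov, dtype=float)
    bcov = np.asarray(cfg.beta_cov, dtype=float)

    meth_psv = rng.normal(size=(n, cfg.p_probes))
    meth_sv = meth_psv + rng.normal(scale=0.5, size=(n, cfg.p_probes))
    # abundances live on a positive scale (baseline + per-feature spread) so
    # the CV-based QC is meaningful; models operate on the centered scale,
    # to which the natural effects are invariant for a mediator shift
    met_scale = rng.uniform(0.5, 2.0, size=cfg.q_metabolites)
    met_psv = cfg.met_baseline + rng.normal(size=(n, cfg.q_metabolites)) * met_scale
    met_sv = cfg.met_baseline + rng.normal(size=(n, cfg.q_metabolites)) * met_scale

    lp = np.full(n, cfg.theta0) + C @ tcov
    cov_term = C @ bcov
    # forward pairs: probe i at PSV drives metabolite i at SV
    for i in range(nf):
        a = meth_psv[:, i]
        m = cfg.beta0 + cfg.beta1 * a + cov_term + rng.normal(scale=np.sqrt(cfg.sigma2), size=n)
        met_sv[:, i] = cfg.met_baseline + m
        lp += cfg.theta1 * a + cfg.theta2 * m + cfg.theta3 * a * m
    # reverse pairs: metabolite at PSV drives probe at SV (planted
    # symmetrically; exposure is the deviation from baseline abundance)
    for j in range(nr):
        a = rng.normal(size=n)
        met_psv[:, nf + j] = cfg.met_baseline + a
        m = cfg.beta0 + cfg.beta1 * a + cov_term + rng.normal(scale=np.sqrt(cfg.sigma2), size=n)
        meth_sv[:, nf + j] = m
        lp += cfg.theta1 * a + cfg.theta2 * m + cfg.theta3 * a * m

    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-lp)))
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    if case_idx.size < cfg.n_cases:
        raise SimulationError(
            f"population realized only {case_idx.size} cases "
            f"(< n_cases={cfg.n_cases}); theta0={cfg.theta0} is too low for this design"
        )
    if ctrl_idx.size < cfg.n_controls:
        raise SimulationError(
            f"population realized only {ctrl_idx.size} controls (< n_controls={cfg.n_controls})"
        )
    chosen = np.sort(
        np.concatenate(
            [
                rng.choice(case_idx, size=cfg.n_cases, replace=False),
                rng.choice(ctrl_idx, size=cfg.n_controls, replace=False),
            ]
        )
    )

    # platform batch shift is a measurement artifact on M-values
    shift = cfg.batch_shift * platform[:, None].astype(float)
    meth_psv = meth_psv + shift
    meth_sv = meth_sv + shift

    sample_ids = pd.Index([f"S{i:06d}" for i in chosen], name="sample_id")
    probe_ids = [f"cg{i:06d}" for i in range(cfg.p_probes)]
    met_ids = [f"met{j:04d}" for j in range(cfg.q_metabolites)]

    meta = SampleMeta(
        pd.DataFrame(
            {
                "case": y[chosen].astype(int),
                "sex": np.where(sex_male[chosen] == 1, "M", "F"),
                "age_psv": age[chosen],
                "time_psv_sv": time_sv[chosen],
                "dr34": dr34[chosen].astype(int),
                "platform": np.where(platform[chosen] == 1, "EPIC", "450K"),
            },
            index=sample_ids,
        )
    )

    cvec_means = C.mean(axis=0)
    truth_rows = []
    log_nde, log_nie, log_te = _closed_form_effects(cfg, cvec_means)
    for i in range(nf):
        truth_rows.append(
            (probe_ids[i], met_ids[i], "dnam_psv", log_nie, log_nde, log_te,
             cfg.a0, cfg.a1)
        )
    for j in range(nr):
        # reverse exposure is a metabolite: the unit contrast starts at the
        # baseline abundance
        truth_rows.append(
            (probe_ids[nf + j], met_ids[nf + j], "met_psv", log_nie, log_nde, log_te,
             cfg.met_baseline + cfg.a0, cfg.met_baseline + cfg.a1)
        )
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))

    def om(arr, ftype, tp, ids):
        return OmicsMatrix(
            pd.DataFrame(arr[chosen], index=sample_ids, columns=ids), ftype, tp
        )

    cohort = Cohort(
        meth_psv=om(meth_psv, "methylation", "PSV", probe_ids),
        meth_sv=om(meth_sv, "methylation", "SV", probe_ids),
        met_psv=om(met_psv, "metabolite", "PSV", met_ids),
        met_sv=om(met_sv, "metabolite", "SV", met_ids),
        meta=meta,
        truth=truth,
    )
    cohort.validate()
    return cohort


def population_prevalence(cfg: SimConfig, n: int = 100_000, seed: int | None = None) -> float:
    """Empirical outcome prevalence in the (unsampled) source population."""
    probe = max(cfg.n_causal_pairs + cfg.n_causal_pairs_reverse, 1)
    big = SimConfig(
        **{
            **asdict(cfg),
            "n_population": n,
            "n_cases": 1,
            "n_controls": 1,
            "p_probes": max(probe, 1),
            "q_metabolites": max(probe, 1),
            "seed": cfg.seed if seed is None else seed,
        }
    )
    rng = np.random.default_rng(big.seed)
    dr34 = rng.binomial(1, 0.23, size=n).astype(float)
    age = rng.uniform(0.7, 20.3, size=n)
    time_sv = rng.uniform(0.3, 2.0, size=n)
    sex_male = rng.binomial(1, 0.5, size=n).astype(float)
    C = np.column_stack([dr34, age, time_sv, sex_male])
    lp = np.full(n, cfg.theta0) + C @ np.asarray(cfg.theta_cov, dtype=float)
    cov_term = C @ np.asarray(cfg.beta_cov, dtype=float)
    for _ in range(cfg.n_causal_pairs + cfg.n_causal_pairs_reverse):
        a = rng.normal(size=n)
        m = cfg.beta0 + cfg.beta1 * a + cov_term + rng.normal(scale=np.sqrt(cfg.sigma2), size=n)
        lp += cfg.theta1 * a + cfg.theta2 * m + cfg.theta3 * a * m
    return float(np.mean(1.0 / (1.0 + np.exp(-lp))))


def monte_carlo_effects(
    theta: tuple[float, float, float, float],
    beta: tuple[float, float],
    sigma2: float,
    a0: float = 0.0,
    a1: float = 1.0,
    mediator_offset: float = 0.0,
    outcome_offset: float = 0.0,
    n_draws: int = 10_000_000,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Monte-Carlo potential-outcome estimate of the natural effects.

    Simulates counterfactual mediators ``M(a)`` and binary outcomes
    ``Y(a, M(a*))`` directly from the generating models — independent
    draws per counterfactual arm — and forms the odds ratios from the
    realized outcome counts.  Serves as an oracle for the rare-outcome
    closed forms, which it does not share any code with.

    Covariates enter only as the fixed offsets ``beta_cov'c`` and
    ``theta_cov'c``.  Returns log-scale effects with their Monte-Carlo
    standard errors (binomial, per arm, arms independent).
    """
    t0, t1, t2, t3 = theta
    b0, b1 = beta
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = float(np.sqrt(sigma2))

    def arm(a_exposure: float, a_mediator: float) -> tuple[float, float]:
        """log odds of Y(a_exposure, M(a_mediator)) and its MC variance."""
        m = b0 + b1 * a_mediator + mediator_offset + rng.normal(scale=sd, size=n_draws)
        lp = t0 + t1 * a_exposure + t2 * m + t3 * a_exposure * m + outcome_offset
        k = int(rng.binomial(1, 1.0 / (1.0 + np.exp(-lp))).sum())
        if k == 0 or k == n_draws:
            raise RuntimeError("degenerate arm: outcome count 0 or n; not a rare outcome")
        p = k / n_draws
        return float(np.log(p / (1.0 - p))), 1.0 / k + 1.0 / (n_draws - k)

    lo00, v00 = arm(a0, a0)
    lo10, v10 = arm(a1, a0)
    lo11, v11 = arm(a1, a1)
    return {
        "log_nie": lo11 - lo10,
        "se_log_nie": float(np.sqrt(v11 + v10)),
        "log_nde": lo10 - lo00,
        "se_log_nde": float(np.sqrt(v10 + v00)),
        "log_te": lo11 - lo00,
        "se_log_te": float(np.sqrt(v11 + v00)),
    }


def simulate_annotation(
    probe_ids, seed: int, gene_fraction: float = 0.6, probes_per_gene: float = 2.0
):
    """Synthetic probe annotation: chromosome/position/island relation/gene.

    Emulates the structure of an array manifest: a fraction of probes map
    to a gene symbol, several probes can share a gene, the rest are
    intergenic (empty symbol).  Purely synthetic labels.
    """
    from .datamodel import ProbeAnnotation

    rng = np.random.default_rng(seed)
    probe_ids = list(probe_ids)
    n = len(probe_ids)
    n_genes = max(int(np.ceil(n * gene_fraction / probes_per_gene)), 1)
    genes = [f"GENE{g:04d}" for g in range(n_genes)]
    has_gene = rng.random(n) < gene_fraction
    assigned = rng.choice(genes, size=n)
    relations = rng.choice(
        ["Island", "N_Shore", "S_Shore", "OpenSea"], size=n, p=[0.3, 0.15, 0.15, 0.4]
    )
    table = pd.DataFrame(
        {
            "chromosome": [f"chr{rng.integers(1, 23)}" for _ in range(n)],
            "position": rng.integers(1, 248_000_000, size=n),
            "island_relation": relations,
            "gene_symbol": np.where(has_gene, assigned, ""),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeAnnotation(table)


def simulate_gmt(
    genes, seed: int, n_pathways: int = 30, min_size: int = 3, max_size: int = 40
) -> dict[str, list[str]]:
    """Synthetic pathway gene sets over (a superset of) the given genes."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    # pad with off-universe genes so pathways are not subsets of the reference
    extra = [f"XGENE{g:04d}" for g in range(max(len(genes) // 2, 5))]
    pool = genes + extra
    gmt = {}
    for k in range(n_pathways):
        size = int(rng.integers(min_size, max_size + 1))
        members = rng.choice(pool, size=min(size, len(pool)), replace=False)
        gmt[f"PATHWAY_{k:03d}"] = sorted(members.tolist())
    return gmt


def write_fixture(directory, cohort: Cohort, cfg: SimConfig | None = None) -> dict:
    """Write a cohort (and optionally its config) as pipeline-readable files."""
    paths = emio.write_cohort(cohort, directory)
    if cfg is not None:
        cfg_path = Path(directory) / "sim_config.yaml"
        cfg.to_yaml(cfg_path)
        paths["config"] = cfg_path
    return paths
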