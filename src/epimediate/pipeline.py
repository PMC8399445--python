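"""End-to-end orchestration: simulate -> QC -> screen -> mediate -> FCR -> enrich.

Every stage reads its inputs from and writes its outputs to a results
directory as TSV, so any stage can be rerun from persisted intermediates;
a JSON run manifest records the config digest, seed, per-stage row counts
and timestamps (the manifest is written even on failure, naming the
failing stage).  All randomness derives deterministically from the single
mandatory seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as emio
from .cohort import render_cohort_table, summarize_cohort
from .datamodel import Cohort, DataModelError
from .enrichment import enrichment_table, over_representation, probes_to_genes, top_probes
from .fcr import FcrReport, fcr_intervals
from .mediation import (
    DIRECTIONS,
    EffectContrast,
    MediationEstimate,
    PairData,
    default_contrast,
    mediate_pair,
)
from .qc import filter_low_abundance_samples, filter_metabolite_cv
from .screening import screen_all_pairs
from .simulate import SimConfig, simulate_annotation, simulate_cohort, simulate_gmt, write_fixture

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "screen", "mediate", "fcr", "enrich")

MEDIATION_COLUMNS = (
    "probe_id", "metabolite_id", "direction", "log_nie", "log_nde", "log_te",
    "se_log_nie", "p_nie", "nie_or", "ci_level", "ci_low", "ci_high",
    "nie_or_ci_low", "nie_or_ci_high", "n_boot", "n_dropped", "drop_warning",
)


def pair_universe(n_probes: int, n_metabolites: int) -> int:
    """Total possible probe-metabolite pairs, computed arithmetically."""
    if n_probes < 0 or n_metabolites < 0:
        raise ValueError("feature counts must be non-negative")
    return int(n_probes) * int(n_metabolites)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: str, extra: str = "") -> int:
    """Deterministic per-stage seed derived from the global seed (< 2**31)."""
    h = hashlib.sha256(f"{seed}:{stage}:{extra}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


class PipelineError(RuntimeError):
    pass


class Pipeline:
    """One configured run rooted at an output directory."""

    def __init__(self, config: dict, outdir):
        if "seed" not in config:
            raise PipelineError("config must set a global seed")
        self.config = config
        self.seed = int(config["seed"])
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "seed": self.seed,
            "config_digest": hashlib.sha256(
                yaml.safe_dump(config, sort_keys=True).encode()
            ).hexdigest(),
            "stages": {},
            "status": "running",
        }

    # -- manifest -----------------------------------------------------------
    def _record(self, stage: str, **counts) -> None:
        self.manifest["stages"][stage] = {"timestamp": time.time(), **counts}
        self._write_manifest()

    def _write_manifest(self) -> None:
        (self.outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))

    def _directions(self) -> list[str]:
        dirs = self.config.get("screen", {}).get("directions", list(DIRECTIONS))
        bad = [d for d in dirs if d not in DIRECTIONS]
        if bad:
            raise PipelineError(f"unknown directions {bad}; valid: {DIRECTIONS}")
        return list(dirs)

    # -- stages -------------------------------------------------------------
    def stage_simulate(self) -> Cohort:
        sim_cfg = dict(self.config.get("simulate", {}))
        sim_cfg.setdefault("seed", _stage_seed(self.seed, "simulate"))
        for key in ("theta_cov", "beta_cov"):
            if key in sim_cfg:
                sim_cfg[key] = tuple(sim_cfg[key])
        cfg = SimConfig(**sim_cfg)
        cohort = simulate_cohort(cfg)
        write_fixture(self.outdir / "cohort", cohort, cfg)
        annot = simulate_annotation(
            cohort.meth_psv.feature_ids, seed=_stage_seed(self.seed, "annotation")
        )
        emio.write_annotation(annot, self.outdir / "cohort" / "annotation.tsv")
        genes = sorted(set(annot.table["gene_symbol"]) - {""})
        gmt = simulate_gmt(genes, seed=_stage_seed(self.seed, "gmt"))
        emio.write_gmt(gmt, self.outdir / "cohort" / "pathways.gmt")
        self._record(
            "simulate",
            n_samples=cohort.meta.table.shape[0],
            n_probes=cohort.meth_psv.n_features,
            n_metabolites=cohort.met_sv.n_features,
            n_planted=0 if cohort.truth is None else len(cohort.truth),
        )
        return cohort

    def _load_cohort(self) -> Cohort:
        src = self.config.get("inputs", {}).get("dir", self.outdir / "cohort")
        return emio.read_cohort(src)

    def stage_qc(self) -> Cohort:
        cohort = self._load_cohort()
        qc_cfg = self.config.get("qc", {})
        n_dev = float(qc_cfg.get("cv_n_dev", 2.0))
        k_mad = float(qc_cfg.get("low_abundance_k_mad", 3.0))

        met_sv, excl_cv_sv = filter_metabolite_cv(cohort.met_sv, n_dev=n_dev)
        met_psv, excl_cv_psv = filter_metabolite_cv(cohort.met_psv, n_dev=n_dev)
        # keep the metabolite panel identical at both visits
        common = [f for f in met_sv.feature_ids if f in set(met_psv.feature_ids)]
        met_sv = emio.OmicsMatrix(met_sv.values[common], "metabolite", "SV")
        met_psv = emio.OmicsMatrix(met_psv.values[common], "metabolite", "PSV")

        met_sv, low_sv = filter_low_abundance_samples(met_sv, k_mad=k_mad)
        met_psv, low_psv = filter_low_abundance_samples(met_psv, k_mad=k_mad)
        dropped_samples = sorted(set(low_sv) | set(low_psv))
        keep = [s for s in cohort.meta.sample_ids if s not in set(dropped_samples)]

        qc_cohort = Cohort(
            meth_psv=cohort.meth_psv.subset_samples(keep),
            meth_sv=cohort.meth_sv.subset_samples(keep),
            met_psv=met_psv.subset_samples(keep),
            met_sv=met_sv.subset_samples(keep),
            meta=cohort.meta.subset(keep),
            truth=cohort.truth,
        )
        qc_cohort.validate()
        emio.write_cohort(qc_cohort, self.outdir / "qc")
        exclusions = pd.DataFrame(
            [("metabolite_cv", f) for f in sorted(set(excl_cv_sv) | set(excl_cv_psv))]
            + [("low_abundance_sample", s) for s in dropped_samples],
            columns=["reason", "id"],
        )
        exclusions.to_csv(self.outdir / "qc" / "exclusions.tsv", sep="\t", index=False)
        cohort_table = summarize_cohort(qc_cohort.meta)
        cohort_table.to_csv(self.outdir / "qc" / "cohort_table.tsv", sep="\t", index=False)
        self._record(
            "qc",
            n_samples=len(keep),
            n_metabolites=met_sv.n_features,
            n_excluded_metabolites=len(set(excl_cv_sv) | set(excl_cv_psv)),
            n_excluded_samples=len(dropped_samples),
        )
        return qc_cohort

    def stage_screen(self) -> dict[str, pd.DataFrame]:
        cohort = emio.read_cohort(self.outdir / "qc")
        scr = self.config.get("screen", {})
        alpha = float(scr.get("alpha", 0.01))
        adjust_platform = bool(scr.get("adjust_platform", False))
        out = {}
        counts = {}
        declared = self.config.get("declared_universe")
        if declared:
            counts["declared_possible_pairs"] = pair_universe(
                int(declared["n_probes"]), int(declared["n_metabolites"])
            )
        for direction in self._directions():
            if direction == "dnam_psv":
                meth, mets = cohort.meth_psv, cohort.met_sv
            else:
                meth, mets = cohort.meth_sv, cohort.met_psv
            pairs = screen_all_pairs(
                meth, mets, cohort.meta, alpha_screen=alpha,
                direction=direction, adjust_platform=adjust_platform,
            )
            df = pd.DataFrame(
                [
                    (p.probe_id, p.metabolite_id, p.direction, p.p_assoc,
                     p.p_probe_outcome, p.p_met_outcome)
                    for p in pairs
                ],
                columns=["probe_id", "metabolite_id", "direction", "p_assoc",
                         "p_probe_outcome", "p_met_outcome"],
            )
            df.to_csv(self.outdir / f"candidates_{direction}.tsv", sep="\t", index=False)
            out[direction] = df
            counts[f"pairs_possible_{direction}"] = pair_universe(
                meth.n_features, mets.n_features
            )
            counts[f"pairs_screened_{direction}"] = len(df)
        self._record("screen", **counts)
        return out

    def stage_mediate(self) -> dict[str, list[MediationEstimate]]:
        cohort = emio.read_cohort(self.outdir / "qc")
        med = self.config.get("mediate", {})
        B = int(med.get("b_reps", 10_000))
        level = float(med.get("ci_level", 0.95))
        a0 = float(med.get("contrast", {}).get("a0", 0.0))
        a1 = float(med.get("contrast", {}).get("a1", 1.0))
        adjust_platform = bool(med.get("adjust_platform", True))
        cvec_mode = med.get("cvec", "means")
        covariates = cohort.meta.covariate_design(include_platform=adjust_platform)
        results: dict[str, list[MediationEstimate]] = {}
        counts = {}
        for direction in self._directions():
            cand_path = self.outdir / f"candidates_{direction}.tsv"
            if not cand_path.exists():
                raise PipelineError(f"missing screen output {cand_path}; run screen first")
            cands = pd.read_csv(cand_path, sep="\t")
            if direction == "dnam_psv":
                expo_m, medi_m = cohort.meth_psv, cohort.met_sv
            else:
                expo_m, medi_m = cohort.met_psv, cohort.meth_sv
            estimates = []
            n_failed = 0
            for _, row in cands.iterrows():
                probe, met = row["probe_id"], row["metabolite_id"]
                expo_id, medi_id = (probe, met) if direction == "dnam_psv" else (met, probe)
                data = PairData(
                    exposure=expo_m.values[expo_id].to_numpy(),
                    mediator=medi_m.values[medi_id].to_numpy(),
                    case=cohort.meta.case,
                    covariates=covariates.to_numpy(),
                    covariate_names=tuple(covariates.columns),
                )
                if cvec_mode == "zeros":
                    contrast = EffectContrast(a0, a1, (0.0,) * covariates.shape[1])
                else:
                    contrast = default_contrast(data, a0=a0, a1=a1)
                pair_seed = _stage_seed(self.seed, "mediate", f"{direction}:{probe}:{met}")
                try:
                    est = mediate_pair(
                        data, probe_id=probe, metabolite_id=met, direction=direction,
                        contrast=contrast, B=B, level=level, seed=pair_seed,
                    )
                except RuntimeError as exc:
                    log.warning("pair (%s, %s) excluded: %s", probe, met, exc)
                    n_failed += 1
                    continue
                estimates.append(est)
            results[direction] = estimates
            self._write_mediation(direction, estimates)
            counts[f"pairs_mediated_{direction}"] = len(estimates)
            counts[f"pairs_failed_{direction}"] = n_failed
        self._record("mediate", **counts)
        return results

    def _write_mediation(self, direction: str, estimates: list[MediationEstimate]) -> None:
        rows = []
        reps = {}
        for e in estimates:
            rows.append(
                {
                    "probe_id": e.probe_id, "metabolite_id": e.metabolite_id,
                    "direction": e.direction, "log_nie": e.log_nie, "log_nde": e.log_nde,
                    "log_te": e.log_te, "se_log_nie": e.se_log_nie, "p_nie": e.p_nie,
                    "nie_or": e.nie_or, "ci_level": e.ci_level, "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "nie_or_ci_low": float(np.exp(e.ci_low)),
                    "nie_or_ci_high": float(np.exp(e.ci_high)),
                    "n_boot": e.n_boot, "n_dropped": e.n_dropped,
                    "drop_warning": e.drop_warning,
                }
            )
            reps[f"{e.probe_id}|{e.metabolite_id}"] = e.replicates
        pd.DataFrame(rows, columns=list(MEDIATION_COLUMNS)).to_csv(
            self.outdir / f"mediation_{direction}.tsv", sep="\t", index=False
        )
        # replicate vectors persisted so FCR re-levelling never refits models
        if reps:
            max_len = max(len(v) for v in reps.values())
            rep_df = pd.DataFrame(
                {k: np.pad(v.astype(float), (0, max_len - len(v)), constant_values=np.nan)
                 for k, v in reps.items()}
            )
        else:
            rep_df = pd.DataFrame()
        rep_df.to_csv(self.outdir / f"replicates_{direction}.tsv", sep="\t", index=False)

    def _load_estimates(self, direction: str) -> list[MediationEstimate]:
        med_path = self.outdir / f"mediation_{direction}.tsv"
        rep_path = self.outdir / f"replicates_{direction}.tsv"
        if not med_path.exists():
            raise PipelineError(f"missing mediation output {med_path}; run mediate first")
        df = pd.read_csv(med_path, sep="\t")
        try:
            reps = pd.read_csv(rep_path, sep="\t") if rep_path.exists() else pd.DataFrame()
        except pd.errors.EmptyDataError:  # direction with zero mediated pairs
            reps = pd.DataFrame()
        estimates = []
        for _, row in df.iterrows():
            key = f"{row['probe_id']}|{row['metabolite_id']}"
            vec = reps[key].dropna().to_numpy() if key in reps.columns else None
            estimates.append(
                MediationEstimate(
                    probe_id=row["probe_id"], metabolite_id=row["metabolite_id"],
                    direction=row["direction"], log_nie=row["log_nie"],
                    log_nde=row["log_nde"], log_te=row["log_te"],
                    se_log_nie=row["se_log_nie"], p_nie=row["p_nie"],
                    ci_level=row["ci_level"], ci_low=row["ci_low"], ci_high=row["ci_high"],
                    n_boot=int(row["n_boot"]), n_dropped=int(row["n_dropped"]),
                    drop_warning=bool(row["drop_warning"]), replicates=vec,
                )
            )
        return estimates

    def stage_fcr(self) -> dict[str, FcrReport]:
        q = float(self.config.get("fcr", {}).get("q", 0.05))
        joint = bool(self.config.get("fcr", {}).get("joint", False))
        directions = self._directions()
        reports: dict[str, FcrReport] = {}
        counts = {}
        if joint:
            all_est = [e for d in directions for e in self._load_estimates(d)]
            report = fcr_intervals(all_est, q=q)
            for d in directions:
                reports[d] = report
            report.table.to_csv(self.outdir / "fcr_joint.tsv", sep="\t", index=False)
            counts["pairs_selected_joint"] = report.R
            counts["pairs_significant_joint"] = int(report.table["significant"].sum())
        else:
            for d in directions:
                report = fcr_intervals(self._load_estimates(d), q=q)
                reports[d] = report
                report.table.to_csv(self.outdir / f"fcr_{d}.tsv", sep="\t", index=False)
                counts[f"pairs_selected_{d}"] = report.R
                counts[f"pairs_significant_{d}"] = int(report.table["significant"].sum())
        self._record("fcr", **counts)
        return reports

    def stage_enrich(self) -> pd.DataFrame:
        enr = self.config.get("enrich", {})
        top_k = int(enr.get("top_k", 100))
        min_ref = int(enr.get("min_ref", 5))
        min_analysis = int(enr.get("min_analysis", 2))
        annot_path = enr.get("annotation", self.outdir / "cohort" / "annotation.tsv")
        gmt_path = enr.get("gmt", self.outdir / "cohort" / "pathways.gmt")
        annotation = emio.read_annotation(annot_path)
        gmt = emio.read_gmt(gmt_path)

        estimates = [e for d in self._directions() for e in self._load_estimates(d)]
        probes = top_probes(estimates, k=top_k)
        analysis_genes = probes_to_genes(probes, annotation)
        reference_genes = probes_to_genes(list(annotation.table.index), annotation)
        rows = over_representation(
            analysis_genes, reference_genes, gmt,
            min_ref=min_ref, min_analysis=min_analysis,
        )
        table = enrichment_table(rows)
        table.to_csv(self.outdir / "enrichment.tsv", sep="\t", index=False)
        self._record(
            "enrich",
            n_top_probes=len(probes),
            n_analysis_genes=len(analysis_genes),
            n_reference_genes=len(reference_genes),
            n_pathways_tested=len(rows),
        )
        return table

    # -- orchestration ------------------------------------------------------
    def run(self) -> Path:
        """Execute all configured stages; manifest names any failing stage."""
        stage_fns = {
            "simulate": self.stage_simulate,
            "qc": self.stage_qc,
            "screen": self.stage_screen,
            "mediate": self.stage_mediate,
            "fcr": self.stage_fcr,
            "enrich": self.stage_enrich,
        }
        stages = list(STAGES)
        if "simulate" not in self.config and "inputs" in self.config:
            stages.remove("simulate")
        try:
            for stage in stages:
                stage_fns[stage]()
        except Exception as exc:
            self.manifest["status"] = "failed"
            self.manifest["failed_stage"] = stage
            self.manifest["error"] = str(exc)
            self._write_manifest()
            raise
        self._check_counts()
        self.manifest["status"] = "complete"
        self._write_manifest()
        return self.outdir

    def _check_counts(self) -> None:
        stages = self.manifest["stages"]
        for d in self._directions():
            possible = stages.get("screen", {}).get(f"pairs_possible_{d}")
            screened = stages.get("screen", {}).get(f"pairs_screened_{d}")
            mediated = stages.get("mediate", {}).get(f"pairs_mediated_{d}")
            failed = stages.get("mediate", {}).get(f"pairs_failed_{d}", 0)
            if None in (possible, screened, mediated):
                continue
            if not (mediated + failed <= screened <= possible):
                raise PipelineError(
                    f"pair counts violate mediated <= screened <= possible for {d}"
                )

    def result_digests(self) -> dict[str, str]:
        """sha256 of every stage TSV/GMT output (manifest excluded: timestamps)."""
        out = {}
        for path in sorted(self.outdir.rglob("*")):
            if path.is_file() and path.suffix in (".tsv", ".gmt", ".yaml"):
                out[str(path.relative_to(self.outdir))] = _digest(path)
        return out


def report(outdir) -> str:
    """Human-readable summary of a completed run's persisted tables."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError(f"no manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    lines = [f"epimediate run (seed {manifest['seed']}, status {manifest['status']})", ""]

    cohort_path = outdir / "qc" / "cohort_table.tsv"
    if cohort_path.exists():
        lines.append("== Participant characteristics ==")
        lines.append(render_cohort_table(pd.read_csv(cohort_path, sep="\t").fillna("")))
    sig_any = False
    for fcr_path in sorted(outdir.glob("fcr_*.tsv")):
        df = pd.read_csv(fcr_path, sep="\t")
        sig = df[df["significant"].astype(bool)] if len(df) else df
        lines.append(f"== Significant pairs after FCR adjustment ({fcr_path.stem}) ==")
        if len(sig) == 0:
            lines.append("zero significant pairs")
        else:
            sig_any = True
            sig = sig.copy()
            sig["nie_or"] = np.exp(sig["log_nie"])
            sig["nie_or_ci_low"] = np.exp(sig["ci_low_adj"])
            sig["nie_or_ci_high"] = np.exp(sig["ci_high_adj"])
            lines.append(
                sig[["probe_id", "metabolite_id", "nie_or", "nie_or_ci_low",
                     "nie_or_ci_high", "p_nie"]].to_string(index=False)
            )
        lines.append("")
    enr_path = outdir / "enrichment.tsv"
    if enr_path.exists():
        df = pd.read_csv(enr_path, sep="\t")
        lines.append("== Pathway over-representation (top 10 by p) ==")
        lines.append(df.head(10).to_string(index=False) if len(df) else "no pathways retained")
        lines.append("")
    if not sig_any:
        lines.append("(no direction yielded significant pairs)")
    return "\n".join(lines) + "\n"
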