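"""End-to-end analysis pipeline.

Chains simulate -> impute -> fit -> stepwise -> diagnostics -> map-auc
-> target-scan, honouring a single master seed through named
substreams, and writes every artifact plus a JSON manifest to the
output directory.  A stage failure halts the run with the stage name
while keeping the artifacts of completed stages on disk.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import generate_cohort, impute_covariates
from .config import PipelineConfig, seed_for
from .dataio import write_dataset
from .diagnostics import npde, vpc
from .exposure import make_decision, sensitivity_specificity_scan
from .individual import auc_single_sample
from .saem import fit_saem, stepwise_covariates

log = logging.getLogger("pazopk")

STAGES = ("simulate", "impute", "fit", "stepwise", "diagnostics",
          "map-auc", "target-scan")


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _fit_to_dict(fit):
    est = dataclasses.asdict(fit.estimates)
    return {
        "estimates": est,
        "coefficients": {p: {k: float(v) for k, v in d.items()}
                         for p, d in fit.coefficients.items()},
        "rse_percent": {k: (None if np.isnan(v) else float(v))
                        for k, v in fit.rse.items()},
        "ofv": None if np.isnan(fit.ofv) else float(fit.ofv),
        "aic": None if np.isnan(fit.aic) else float(fit.aic),
        "n_params": fit.n_params,
        "converged": fit.converged,
        "shrinkage_percent": {k: (None if np.isnan(v) else float(v))
                              for k, v in fit.shrinkage.items()},
        "dropped_subjects": fit.dropped_subjects,
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full analysis; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.with_seed(config.seed)
    manifest = {"version": __version__, "seed": config.seed,
                "stages": {}, "files": []}

    def record(stage, **info):
        manifest["stages"][stage] = {"status": "complete", **info}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    def emit(name, frame: pd.DataFrame):
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        manifest["files"].append(name)
        return path

    state = {}
    try:
        stage = "simulate"
        t0 = time.time()
        cohort = generate_cohort(cfg.design, cfg.parameters)
        state["cohort_raw"] = cohort
        write_dataset(cohort, outdir / "dataset.csv")
        manifest["files"].append("dataset.csv")
        record(stage, n_subjects=cohort.n_subjects,
               n_observations=cohort.n_observations,
               seconds=round(time.time() - t0, 2))

        stage = "impute"
        cohort = impute_covariates(cohort)
        state["cohort"] = cohort
        write_dataset(cohort, outdir / "dataset_imputed.csv")
        manifest["files"].append("dataset_imputed.csv")
        record(stage)

        stage = "fit"
        if cfg.fit_enabled:
            t0 = time.time()
            log.info("fit start: init=%s covariates=%s", cfg.parameters,
                     cfg.fit_covariates)
            fit = fit_saem(cohort, cfg.parameters, cfg.fit,
                           covariates=list(cfg.fit_covariates))
            state["fit"] = fit
            pop = fit.estimates
            with open(outdir / "fit.json", "w") as fh:
                json.dump(_fit_to_dict(fit), fh, indent=2)
            manifest["files"].append("fit.json")
            record(stage, ofv=None if np.isnan(fit.ofv) else fit.ofv,
                   converged=fit.converged,
                   seconds=round(time.time() - t0, 2))
        else:
            # clinical mode: published parameters drive the downstream stages
            pop = cfg.parameters
            record(stage, skipped=True, reason="fit disabled; reference parameters used")

        stage = "stepwise"
        if cfg.stepwise_enabled and cfg.stepwise_candidates and "fit" in state:
            final, sel_log = stepwise_covariates(
                cohort, state["fit"], list(cfg.stepwise_candidates), cfg.fit)
            pop = final.estimates
            rows = [{"round": e["round"],
                     "parameter": e["candidate"].parameter,
                     "covariate": e["candidate"].covariate,
                     "d_ofv": e["d_ofv"], "d_aic": e["d_aic"],
                     "status": e["status"]} for e in sel_log]
            emit("selection_log.tsv", pd.DataFrame(rows))
            record(stage, n_tested=len(sel_log))
        else:
            record(stage, skipped=True)

        stage = "diagnostics"
        t0 = time.time()
        v = vpc(cohort, pop, n_replicates=cfg.vpc_replicates,
                seed=seed_for(cfg.seed, "vpc"), n_bins=cfg.vpc_bins)
        rows = []
        for j in range(len(v.bin_centers)):
            for q, pct in enumerate(v.percentiles):
                rows.append({"bin_center_h": v.bin_centers[j], "percentile": pct,
                             "observed": v.empirical[j, q],
                             "band_low": v.band_low[j, q],
                             "band_mid": v.band_mid[j, q],
                             "band_high": v.band_high[j, q]})
        emit("vpc.tsv", pd.DataFrame(rows))
        np_de = npde(cohort, pop, n_replicates=cfg.npde_replicates,
                     seed=seed_for(cfg.seed, "npde"))
        ids = np.concatenate([[s.id] * s.n_obs for s in cohort.subjects])
        times = np.concatenate([s.obs_time for s in cohort.subjects])
        emit("npde.tsv", pd.DataFrame({"ID": ids, "time_after_dose_h": times,
                                       "npde": np_de}))
        record(stage, npde_mean=float(np.nanmean(np_de)),
               npde_var=float(np.nanvar(np_de)),
               seconds=round(time.time() - t0, 2))

        stage = "map-auc"
        rows = []
        for s in cohort.subjects:
            for j in range(s.n_obs):
                if s.obs_blq[j]:
                    continue
                est = auc_single_sample(s, pop, j)
                verdict = make_decision(s.id, est.auc, cfg.target_auc).verdict
                rows.append({"ID": s.id, "OCC": s.obs_occ[j],
                             "time_after_dose_h": s.obs_time[j],
                             "conc": s.obs_conc[j],
                             "cl_est": est.individual.cl, "auc_est": est.auc,
                             "verdict": verdict,
                             "flags": ";".join(est.flags)})
        map_frame = pd.DataFrame(rows)
        emit("map_auc.tsv", map_frame)
        record(stage, n_estimates=len(rows))

        stage = "target-scan"
        pairs = []
        for s in cohort.subjects:
            for occ in s.occasions:
                if not s.regimens[occ].steady_state:
                    continue
                idx = [j for j in s.obs_in(occ) if not s.obs_blq[j]]
                if not idx:
                    continue
                # trough = the latest sample of the occasion (>= 20 h for
                # TDM visits; 24 h for rich profiles)
                j_tr = max(idx, key=lambda j: s.obs_time[j])
                if s.obs_time[j_tr] < 20.0:
                    continue
                sub = map_frame[(map_frame["ID"] == s.id)
                                & (map_frame["OCC"] == occ)]
                if sub.empty:
                    continue
                pairs.append((float(s.obs_conc[j_tr]),
                              float(sub["auc_est"].iloc[0])))
        start, stop, step = cfg.threshold_grid
        scan = sensitivity_specificity_scan(
            pairs, cfg.trough_criterion,
            thresholds=np.arange(start, stop + 1e-9, step))
        emit("target_scan.tsv", pd.DataFrame({
            "threshold": scan.thresholds,
            "sensitivity_pct": scan.sensitivity,
            "specificity_pct": scan.specificity}))
        record(stage, chosen_threshold=scan.chosen_threshold, n_pairs=len(pairs))
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise PipelineError(stage, exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
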