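"""End-to-end pipeline: simulate -> QC -> variability -> stats -> predict.

A single YAML-backed configuration drives every stage; one master seed
deterministically derives per-stage substreams, so identical config + seed
reproduce identical outputs (verified through the manifest checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dfcvar import group_stats
from dfcvar.core_io import write_roi_series
from dfcvar.prep import qc_exclude
from dfcvar.svr import SvrConfig, predict_response_pipeline
from dfcvar.synthetic import CohortDesign, SyntheticCohort, generate_cohort
from dfcvar.variability import (
    WindowScheme,
    mean_fc_matrix,
    min_window_length,
    roi_variability_matrix,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "variability", "stats", "predict")


@dataclass
class RunConfig:
    """Every tunable of an end-to-end run; unknown YAML keys are rejected."""

    out_dir: str = "dfcvar_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # cohort design
    n_per_group: int = 20
    n_hc: int = 12
    n_volumes: int = 255
    discard_volumes: int = 5
    tr_seconds: float = 2.0
    n_regions: int = 12
    effect_delta: float = 0.3
    noise_sd: float = 0.4
    qc_fail_fraction: float = 0.0
    # filtering / windows
    low_hz: float = 0.01
    high_hz: float = 0.08
    window_length_tr: int = 50
    window_step_tr: int = 1
    # statistics
    height_p: float = 0.005
    cluster_alpha: float = 0.05
    use_covariates: bool = True
    # prediction
    svr_kernel: str = "rbf"
    svr_epsilon: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def design(self) -> CohortDesign:
        return CohortDesign(
            n_per_group=self.n_per_group,
            n_hc=self.n_hc,
            T=self.n_volumes,
            discard_volumes=self.discard_volumes,
            tr_seconds=self.tr_seconds,
            n_regions=self.n_regions,
            effect_delta=self.effect_delta,
            noise_sd=self.noise_sd,
            qc_fail_fraction=self.qc_fail_fraction,
            seed=self.seed,
        )

    def scheme(self) -> WindowScheme:
        return WindowScheme(self.window_length_tr, self.window_step_tr)


def validate_config(config: RunConfig) -> list[str]:
    """Collect precondition violations; an empty list means the config is valid."""
    v: list[str] = []
    if config.window_length_tr < 2:
        v.append("window length must be >= 2 TR")
    if config.window_step_tr < 1:
        v.append("window step must be >= 1 TR")
    if config.tr_seconds <= 0:
        v.append("TR must be positive")
        return v
    nyquist = 0.5 / config.tr_seconds
    if not (0 < config.low_hz < config.high_hz):
        v.append("need 0 < low_hz < high_hz")
    elif config.high_hz >= nyquist:
        v.append(f"high_hz must be below Nyquist ({nyquist:.4f} Hz)")
    else:
        need = min_window_length(config.low_hz, config.tr_seconds)
        if config.window_length_tr < need:
            v.append(
                f"window ({config.window_length_tr} TR) shorter than 1/fmin "
                f"({need} TR at fmin={config.low_hz} Hz)"
            )
    if not (0 < config.effect_delta <= 1):
        v.append("effect_delta must be in (0, 1]")
    if config.n_per_group < 3:
        v.append("n_per_group must be >= 3")
    T_used = config.n_volumes - config.discard_volumes
    if T_used < config.window_length_tr:
        v.append("too few volumes after discarding for one window")
    if not (0 < config.height_p < 1) or not (0 < config.cluster_alpha < 1):
        v.append("height_p and cluster_alpha must be in (0, 1)")
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        v.append(f"unknown stages: {sorted(unknown)}")
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in fixed order and write a run manifest.

    Outputs land under ``config.out_dir``; the manifest records the config,
    the seeds, the QC exclusion list, and a checksum for every file written.
    On a stage failure, partial outputs are moved under ``quarantine/``.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "seed": config.seed,
        "stages_run": [],
        "qc_excluded": [],
        "outputs": {},
    }
    stage = "simulate"
    try:
        cohort = _stage_simulate(config, out, written)
        manifest["stages_run"].append("simulate")

        analysis = _stage_qc(cohort, manifest)

        results: dict = {}
        if "variability" in config.stages:
            stage = "variability"
            results = _stage_variability(config, cohort, analysis, out, written)
            manifest["stages_run"].append("variability")
        if "stats" in config.stages and results:
            stage = "stats"
            stats_out = _stage_stats(config, cohort, results, out, written)
            manifest["stages_run"].append("stats")
        else:
            stats_out = {}
        if "predict" in config.stages and results and stats_out.get("selected_pairs"):
            stage = "predict"
            _stage_predict(config, cohort, results, stats_out, out, written)
            manifest["stages_run"].append("predict")
    except Exception as exc:
        quarantine = out / "quarantine"
        quarantine.mkdir(exist_ok=True)
        for p in written:
            if p.exists():
                p.rename(quarantine / p.name)
        raise StageFailure(stage, exc) from exc

    manifest["outputs"] = {str(p.relative_to(out)): _sha256(p) for p in written}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_simulate(
    config: RunConfig, out: Path, written: list[Path]
) -> SyntheticCohort:
    cohort = generate_cohort(config.design())
    p = out / "cohort.tsv"
    cohort.cohort.to_csv(p, sep="\t", index=False)
    written.append(p)
    series_dir = out / "series"
    series_dir.mkdir(exist_ok=True)
    for (sid, tp), rois in cohort.roi_series.items():
        sp = series_dir / f"{sid}_{tp}.tsv"
        write_roi_series(rois, sp)
        written.append(sp)
    motion_dir = out / "motion"
    motion_dir.mkdir(exist_ok=True)
    for (sid, tp), mot in cohort.motion.items():
        mp = motion_dir / f"{sid}_{tp}.tsv"
        np.savetxt(mp, mot, delimiter="\t", fmt="%.6f")
        written.append(mp)
    gp = out / "ground_truth.json"
    gp.write_text(json.dumps(cohort.ground_truth, indent=2, sort_keys=True))
    written.append(gp)
    return cohort


def _stage_qc(cohort: SyntheticCohort, manifest: dict) -> list[str]:
    """Drop patients with any motion-excluded session; return kept patients."""
    excluded = set()
    for (sid, tp), mot in cohort.motion.items():
        if qc_exclude(mot).excluded:
            excluded.add(sid)
            logger.warning("QC: excluding %s (session %s over motion limits)", sid, tp)
    manifest["qc_excluded"] = sorted(excluded)
    return [s for s in cohort.patients() if s not in excluded]


def _stage_variability(
    config: RunConfig,
    cohort: SyntheticCohort,
    patients: list[str],
    out: Path,
    written: list[Path],
) -> dict:
    scheme = config.scheme()
    rows = []
    var = {}
    fc = {}
    keys = [(s, tp) for s in patients for tp in ("t1", "t2")]
    keys += [(s, "t1") for s in cohort.cohort.loc[cohort.cohort.group == "HC", "subject_id"]]
    for sid, tp in keys:
        rois = cohort.roi_series[(sid, tp)]
        vm = roi_variability_matrix(rois, scheme)
        fm = mean_fc_matrix(rois, scheme)
        var[(sid, tp)] = vm
        fc[(sid, tp)] = fm
        iu = np.triu_indices(rois.n_regions, k=1)
        for i, j in zip(*iu):
            rows.append(
                {
                    "subject_id": sid,
                    "timepoint": tp,
                    "region_a": vm.labels[i],
                    "region_b": vm.labels[j],
                    "variability": vm.values[i, j],
                    "mean_fc": fm[i, j],
                }
            )
    p = out / "variability_long.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    written.append(p)
    return {"var": var, "fc": fc, "patients": patients, "scheme": scheme}


def _pair_outcome_frame(
    cohort: SyntheticCohort, results: dict, i: int, j: int
) -> pd.DataFrame:
    rows = []
    clin = cohort.cohort.set_index(["subject_id", "timepoint"])
    for sid in results["patients"]:
        for tp in ("t1", "t2"):
            rec = clin.loc[(sid, tp)]
            rows.append(
                {
                    "subject_id": sid,
                    "group": rec["group"],
                    "timepoint": tp,
                    "outcome": results["var"][(sid, tp)].values[i, j],
                    "age_years": rec["age_years"],
                    "sex": rec["sex"],
                    "illness_duration_months": rec["illness_duration_months"],
                    "education_years": rec["education_years"],
                    "cpz_equiv_mg_per_day": rec["cpz_equiv_mg_per_day"],
                }
            )
    return pd.DataFrame(rows)


def _stage_stats(
    config: RunConfig,
    cohort: SyntheticCohort,
    results: dict,
    out: Path,
    written: list[Path],
) -> dict:
    R = cohort.design.n_regions
    labels = [f"roi{j:02d}" for j in range(R)]
    iu = list(zip(*np.triu_indices(R, k=1)))
    inter_rows = []
    selected = []
    for i, j in iu:
        data = _pair_outcome_frame(cohort, results, i, j)
        res = group_stats.rm_ancova_interaction(data, use_covariates=config.use_covariates)
        inter_rows.append(
            {
                "region_a": labels[i],
                "region_b": labels[j],
                "f_value": res.f_value,
                "p_value": res.p_value,
            }
        )
        if res.p_value < config.height_p:
            selected.append((int(i), int(j)))
    p = out / "interaction.tsv"
    pd.DataFrame(inter_rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    written.append(p)

    posthoc_rows = []
    for i, j in selected:
        data = _pair_outcome_frame(cohort, results, i, j)
        ph = group_stats.posthoc_tests(data)
        for grp, res in ph.paired_by_group.items():
            posthoc_rows.append(
                {
                    "region_a": labels[i],
                    "region_b": labels[j],
                    "contrast": f"paired_{grp}_t1_vs_t2",
                    "t_value": res.t_value,
                    "p_value": res.p_value,
                }
            )
    p = out / "posthoc.tsv"
    pd.DataFrame(posthoc_rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    written.append(p)

    # variability-FC coupling over patient baseline scans
    var_stack = np.mean(
        [results["var"][(s, "t1")].values for s in results["patients"]], axis=0
    )
    fc_stack = np.mean(
        [results["fc"][(s, "t1")] for s in results["patients"]], axis=0
    )
    r, pval = group_stats.variability_fc_coupling(var_stack, fc_stack)

    # brain-behavior: relative variability change vs negative remission ratio
    corr_rows = []
    tsz = [
        s
        for s in results["patients"]
        if cohort.cohort.loc[cohort.cohort.subject_id == s, "group"].iloc[0] == "TSZ"
    ]
    clin = cohort.cohort.set_index(["subject_id", "timepoint"])
    for i, j in selected:
        dv, rr, cov = [], [], []
        for sid in tsz:
            v1 = results["var"][(sid, "t1")].values[i, j]
            v2 = results["var"][(sid, "t2")].values[i, j]
            rec1 = clin.loc[(sid, "t1")]
            rec2 = clin.loc[(sid, "t2")]
            dv.append(group_stats.delta_variability(v1, v2))
            rr.append(
                group_stats.remission_ratio(
                    rec1["panss_negative"], rec2["panss_negative"]
                )
            )
            cov.append(
                [
                    rec1["age_years"],
                    1.0 if rec1["sex"] == "M" else 0.0,
                    rec1["illness_duration_months"],
                    rec1["education_years"],
                    rec1["cpz_equiv_mg_per_day"],
                ]
            )
        covar = np.asarray(cov)
        if len(dv) <= covar.shape[1] + 2:
            logger.warning(
                "too few treated subjects (%d) for covariate-adjusted "
                "correlation; reporting the unadjusted coefficient",
                len(dv),
            )
            covar = None
        rho, rho_p = group_stats.spearman_partial(dv, rr, covar)
        corr_rows.append(
            {
                "region_a": labels[i],
                "region_b": labels[j],
                "rho": rho,
                "p_value": rho_p,
            }
        )
    p = out / "clinical_correlation.tsv"
    pd.DataFrame(corr_rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    written.append(p)

    summary = {
        "selected_pairs": [[labels[i], labels[j]] for i, j in selected],
        "coupling_r": r,
        "coupling_p": pval,
    }
    sp = out / "stats_summary.json"
    sp.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(sp)
    return {"selected_pairs": selected, "tsz": tsz, "coupling": (r, pval)}


def _stage_predict(
    config: RunConfig,
    cohort: SyntheticCohort,
    results: dict,
    stats_out: dict,
    out: Path,
    written: list[Path],
) -> None:
    tsz = stats_out["tsz"]
    pairs = stats_out["selected_pairs"]
    X = np.array(
        [[results["var"][(s, "t1")].values[i, j] for i, j in pairs] for s in tsz]
    )
    svr_cfg = SvrConfig(kernel=config.svr_kernel, epsilon=config.svr_epsilon)
    preds = predict_response_pipeline(X, tsz, cohort.cohort, svr_cfg)
    payload = {
        sub: {
            "r": res.r,
            "p": res.p,
            "best_c": res.best_c,
            "best_gamma": res.best_gamma,
            "cv_mse": res.cv_mse,
            "n": int(res.actual.size),
            "predicted": res.predicted.tolist(),
            "actual": res.actual.tolist(),
            "excluded": res.excluded_subject_ids,
        }
        for sub, res in preds.items()
    }
    p = out / "predictions.json"
    p.write_text(json.dumps(payload, indent=2, sort_keys=True))
    written.append(p)
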