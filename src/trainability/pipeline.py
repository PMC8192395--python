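"""End-to-end orchestration on synthetic cohorts.

Runs the full analysis chain — simulate → CPET processing → lactate
thresholds and efficiency slopes → NIRS metrics → training prescription,
weekly monitoring and load metrics → POST test → ROPE+HDI responder
classification → Bayesian predictor regression → group comparison — and
writes every table plus a JSON run manifest (seeds, parameters, output
hashes) to an output directory.  Fully reproducible under a fixed seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes import BayesianLinearModel
from .cpet import process_cpet
from .nirs import NirsTrace, compute_nirs_metrics
from .responder import classify_cohort
from .simulate import (CohortSpec, NirsConfig, StepProtocol, TrainingLogConfig,
                       cohort_manifest, generate_cohort, generate_nirs_trace,
                       generate_step_test, generate_training_log,
                       post_training_truth)
from .stats import GroupSummary, cohens_d_ci, welch_test
from .thresholds import (compute_slopes, fit_two_breakpoint,
                         map_thresholds_to_vo2, summarize_stages)
from .training import (adjust_intensity, compute_session_metrics, ensemble_week,
                       fit_lactate_weighting, prescribe_hiit, prescribe_mict)

DEFAULT_CONFIG = {
    "seed": 1,
    "groups": ["HIIT", "MICT"],
    "n_per_group": 21,
    "weeks": 6,
    "sessions_per_week": 3,
    "noise": {
        "vo2_noise_sd": 80.0,
        "hr_noise_sd": 2.0,
        "spike_rate": 0.01,
        "lactate_noise_sd": 0.2,
        "nirs_noise_sd": 0.3,
        "session_anomaly_rate": 0.005,
    },
    "fitness_hr_drift_bpm_per_week": -1.5,
    "cv": 0.056,
    "credibility": 0.89,
    "rope": [-80.0, 80.0],
    "bayes": {
        "enabled": True,
        "predictors": ["baseline_vo2max", "ltp1_po", "oues_a", "nirs_slope2"],
        "chains": 4,
        "iterations": 2000,
        "warmup": 1000,
    },
}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage (and path if any)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    import yaml

    p = Path(path)
    if not p.exists():
        raise PipelineStageError("config", f"missing input file: {p}")
    with open(p) as fh:
        return _merge(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _participant_pipeline(p, cfg, rng):
    """PRE test → CPET, thresholds, slopes, NIRS, prescription for one participant."""
    noise = cfg["noise"]
    protocol = StepProtocol(vo2_noise_sd=noise["vo2_noise_sd"],
                            hr_noise_sd=noise["hr_noise_sd"],
                            spike_rate=noise["spike_rate"],
                            lactate_noise_sd=noise["lactate_noise_sd"])
    test = generate_step_test(p, protocol, rng=rng)
    summary, edited, binned = process_cpet(test.breath, lactate=test.lactate, age=p.age)

    stages = summarize_stages(edited, test.lactate)
    base_la = test.lactate.loc[test.lactate["stage_power_w"] == 0, "lactate_mmol_l"]
    fit = fit_two_breakpoint(stages, baseline_lactate=float(base_la.iloc[0])
                             if len(base_la) else None)
    fit = map_thresholds_to_vo2(fit, stages)
    slopes = compute_slopes(binned)

    nirs_data = generate_nirs_trace(p, NirsConfig(noise_sd=noise["nirs_noise_sd"]), rng=rng)
    nirs_metrics = compute_nirs_metrics(NirsTrace(nirs_data.trace,
                                                  nirs_data.occlusion_start,
                                                  nirs_data.occlusion_end))

    if p.id.startswith("HIIT"):
        rx = prescribe_hiit(stages["power_w"], stages["hr_bpm"], summary.hr_max)
    else:
        import scipy.stats as sps
        line = sps.linregress(stages["power_w"], stages["hr_bpm"])
        rx = prescribe_mict(fit.ltp1_po, line.slope, line.intercept)
    a, b, fallback = fit_lactate_weighting(stages["lactate_mmol_l"], stages["hr_bpm"],
                                           summary.hr_max, p.hr_rest)
    return dict(test=test, summary=summary, stages=stages, fit=fit, slopes=slopes,
                nirs=nirs_metrics, prescription=rx, weighting=(a, b),
                weighting_fallback=fallback)


def run_pipeline(config: dict | str | Path | None = None, out_dir="pipeline_out") -> dict:
    """Execute the full chain and write all tables plus a run manifest.

    ``config`` may be a dict (merged over the defaults), a YAML path, or
    None for the defaults.  Returns the manifest dict; any stage failure
    raises :class:`PipelineStageError` naming the stage, with partial
    outputs preserved on disk.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg["seed"])
    group_seeds = {g: s for g, s in zip(cfg["groups"], ss.spawn(len(cfg["groups"])))}

    manifest = {"config": cfg, "version": __version__, "outputs": {}, "warnings": []}
    cohorts, cpet_rows, thr_rows, nirs_rows, week_rows, resp_inputs = {}, [], [], [], [], []
    features_by_group = {}

    for group in cfg["groups"]:
        gseed = group_seeds[group]
        try:
            spec = CohortSpec.for_group(group, n=cfg["n_per_group"],
                                        seed=int(gseed.generate_state(1)[0] % 2**31),
                                        cv=cfg["cv"])
            cohort = generate_cohort(spec, screen=True)
            cohorts[group] = cohort
        except Exception as e:
            raise PipelineStageError("simulate", str(e)) from e

        rng = np.random.default_rng(gseed.spawn(1)[0])
        features = []
        for p in cohort:
            try:
                res = _participant_pipeline(p, cfg, rng)
            except Exception as e:
                raise PipelineStageError("cpet/thresholds", f"{p.id}: {e}") from e
            s = res["summary"]
            cpet_rows.append({"id": p.id, "group": group, "vo2max_ml_min": s.vo2max,
                              "po_peak_w": s.po_peak, "hr_max_bpm": s.hr_max,
                              "rer_max": s.rer_max, "lactate_max_mmol_l": s.lactate_max,
                              "attained": s.attainment.attained})
            f = res["fit"]
            sl = res["slopes"]
            thr_rows.append({"id": p.id, "group": group, "ltp1_po_w": f.ltp1_po,
                             "ltp2_po_w": f.ltp2_po, "vo2_at_ltp1": f.vo2_at_ltp1,
                             "vo2_at_ltp2": f.vo2_at_ltp2, "sse": f.sse,
                             "oues_a": sl.oues_a, "oues_b": sl.oues_b,
                             "dvo2_dpo": sl.dvo2_dpo, "dhr_dvo2": sl.dhr_dvo2})
            nm = res["nirs"]
            nirs_rows.append({"id": p.id, "group": group, "baseline_pct": nm.baseline,
                              "slope2_pct_s": nm.slope2, "auc_pct_s": nm.auc})

            # six weeks of training with weekly HR-guided adjustment
            try:
                rx = res["prescription"]
                noise = cfg["noise"]
                rel_works = []
                for week in range(1, cfg["weeks"] + 1):
                    drift = cfg["fitness_hr_drift_bpm_per_week"] * (week - 1)
                    logs = []
                    for _ in range(cfg["sessions_per_week"]):
                        logcfg = TrainingLogConfig(hr_noise_sd=noise["hr_noise_sd"],
                                                   anomaly_rate=noise["session_anomaly_rate"],
                                                   hr_offset=drift)
                        logs.append(generate_training_log(rx, p, logcfg, rng=rng).log)
                    metrics = [compute_session_metrics(
                        log, s.po_peak, s.hr_max, p.hr_rest, p.mass,
                        prescription=rx, itrimp_weighting=res["weighting"])
                        for log in logs]
                    rel_works.extend(m.relative_work_kj_kg for m in metrics)
                    decision = adjust_intensity(ensemble_week(logs), rx)
                    week_rows.append({
                        "id": p.id, "group": group, "week": week,
                        "observed_hr": decision.observed_hr,
                        "target_hr": decision.target_hr, "action": decision.action,
                        "mean_rel_work_kj_kg": float(np.mean(rel_works[-len(metrics):])),
                        "mean_pct_hr_max": float(np.mean([m.pct_hr_max for m in metrics])),
                        "mean_itrimp": float(np.mean([m.itrimp for m in metrics])),
                    })
                    rx = decision.next_prescription
            except Exception as e:
                raise PipelineStageError("training", f"{p.id}: {e}") from e

            # POST incremental test with the trained physiology
            try:
                post_p = post_training_truth(p)
                protocol = StepProtocol(vo2_noise_sd=noise["vo2_noise_sd"],
                                        hr_noise_sd=noise["hr_noise_sd"],
                                        spike_rate=noise["spike_rate"],
                                        lactate_noise_sd=noise["lactate_noise_sd"])
                post_test = generate_step_test(post_p, protocol, rng=rng)
                post_summary, _, _ = process_cpet(post_test.breath,
                                                  lactate=post_test.lactate, age=p.age)
            except Exception as e:
                raise PipelineStageError("post-test", f"{p.id}: {e}") from e

            resp_inputs.append({"id": p.id, "group": group,
                                "baseline_vo2max_ml_min": s.vo2max,
                                "post_vo2max_ml_min": post_summary.vo2max})
            features.append({"id": p.id, "baseline_vo2max": s.vo2max,
                             "ltp1_po": f.ltp1_po, "oues_a": sl.oues_a,
                             "nirs_slope2": nm.slope2,
                             "delta": post_summary.vo2max - s.vo2max})
        features_by_group[group] = pd.DataFrame(features)

    # responder classification per group
    try:
        resp_df = pd.DataFrame(resp_inputs)
        summaries = {}
        results = []
        for group in cfg["groups"]:
            sub = resp_df[resp_df["group"] == group]
            cc = classify_cohort(sub, rope=tuple(cfg["rope"]), cv=cfg["cv"],
                                 credibility=cfg["credibility"])
            res = cc.results.copy()
            res.insert(1, "group", group)
            results.append(res)
            summaries[group] = {"counts": cc.counts, "proportions": cc.proportions,
                                "rope": list(cc.rope)}
        responders = pd.concat(results, ignore_index=True)
    except Exception as e:
        raise PipelineStageError("classify", str(e)) from e

    # Bayesian predictor regression per group
    bayes_tables = []
    bcfg = cfg["bayes"]
    if bcfg.get("enabled", True):
        for group in cfg["groups"]:
            feats = features_by_group[group]
            preds = [c for c in bcfg["predictors"] if c in feats.columns]
            if len(feats) <= len(preds) + 1:
                manifest["warnings"].append(
                    f"bayes: skipped {group} (n={len(feats)} too small for "
                    f"{len(preds)} predictors)")
                continue
            try:
                model = BayesianLinearModel(
                    chains=bcfg["chains"], iterations=bcfg["iterations"],
                    warmup=bcfg["warmup"],
                    random_state=int(group_seeds[group].generate_state(1)[0] % 2**31))
                model.fit(feats[preds], feats["delta"].to_numpy(), names=preds)
                table = model.summary().table
                table.insert(0, "group", group)
                bayes_tables.append(table)
            except Exception as e:
                raise PipelineStageError("bayes", f"{group}: {e}") from e

    # group comparison of the training dose (relative total work)
    try:
        weeks_df = pd.DataFrame(week_rows)
        comparison = {}
        if len(cfg["groups"]) == 2:
            g1, g2 = cfg["groups"]
            per_part = weeks_df.groupby("id")["mean_rel_work_kj_kg"].mean()
            ids = {g: [p.id for p in cohorts[g]] for g in (g1, g2)}
            s1 = per_part.loc[ids[g1]]
            s2 = per_part.loc[ids[g2]]
            a = GroupSummary(len(s1), float(s1.mean()), float(s1.std(ddof=1)))
            b = GroupSummary(len(s2), float(s2.mean()), float(s2.std(ddof=1)))
            w = welch_test(a, b)
            d, ci = cohens_d_ci(a, b)
            comparison = {"groups": [g1, g2],
                          "relative_work_kj_kg": {g1: [a.mean, a.sd], g2: [b.mean, b.sd]},
                          "welch": {"t": w.t, "df": w.df, "p": w.p},
                          "cohens_d": d, "cohens_d_ci": list(ci)}
    except Exception as e:
        raise PipelineStageError("compare", str(e)) from e

    # ---- write everything -------------------------------------------------
    tables = {
        "cohort_manifest.csv": pd.concat(
            [cohort_manifest(cohorts[g]).assign(group=g) for g in cfg["groups"]],
            ignore_index=True),
        "cpet_summary.csv": pd.DataFrame(cpet_rows),
        "thresholds.csv": pd.DataFrame(thr_rows),
        "nirs_metrics.csv": pd.DataFrame(nirs_rows),
        "training_weekly.csv": weeks_df,
        "responders.csv": responders,
    }
    if bayes_tables:
        tables["bayes_coefficients.csv"] = pd.concat(bayes_tables, ignore_index=True)
    for name, df in tables.items():
        df.to_csv(out / name, index=False, float_format="%.6g")
    (out / "responder_summary.json").write_text(
        json.dumps(summaries, indent=2, sort_keys=True))
    (out / "group_comparison.json").write_text(
        json.dumps(comparison, indent=2, sort_keys=True))

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    manifest["responder_summaries"] = summaries
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
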