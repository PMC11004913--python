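"""End-to-end experiment orchestration: simulate -> fold -> fit -> score ->
evaluate, over a scenario matrix of methods x marker subsets.

Scenario tags follow the m(i,j,k)/u(i) convention: ``m(1,2)`` is the joint
multivariable test on markers 1 and 2 of the panel (1-based panel order,
e.g. CA125-HE4), ``u(1)`` the univariate test on marker 1.  Each scenario is
evaluated per outer fold and screening horizon, and summarised across folds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bcp.hyperparams import Hyperparams
from .bcp.model import BayesianChangePointModel
from .bcp.predictive import PrevalencePrior, score_cohort as bcp_score_cohort
from .cohort import Cohort
from .evaluation import (FoldPlan, auc, contingency, lead_time,
                         lead_time_summary, make_folds,
                         sensitivity_at_specificity, summarize_metric)
from .rnn.model import LSTMClassifier, LSTMConfig, tune
from .simulate import GeneratorConfig, generate_cohort

logger = logging.getLogger("ovascreen")

__all__ = ["parse_scenario", "default_scenarios", "fit_and_score",
           "evaluate_scenarios", "run_experiment"]

DEFAULT_SCENARIOS = ["m(1,2,3)", "m(1,2)", "m(1,3)", "u(1)", "u(2)", "u(3)"]


def parse_scenario(tag: str, biomarker_names) -> list[str]:
    """Resolve a scenario tag to the marker subset it denotes."""
    m = re.fullmatch(r"([mu])\(([\d,\s]+)\)", tag.strip())
    if not m:
        raise ValueError(f"bad scenario tag {tag!r}")
    idx = [int(x) for x in m.group(2).split(",")]
    if m.group(1) == "u" and len(idx) != 1:
        raise ValueError(f"univariate tag {tag!r} must name one marker")
    if m.group(1) == "m" and len(idx) < 2:
        raise ValueError(f"multivariable tag {tag!r} needs >= 2 markers")
    if any(i < 1 or i > len(biomarker_names) for i in idx):
        raise ValueError(f"marker index out of range in {tag!r}")
    if len(set(idx)) != len(idx):
        raise ValueError(f"repeated marker in {tag!r}")
    return [biomarker_names[i - 1] for i in idx]


def default_scenarios(biomarker_names) -> list[str]:
    if len(biomarker_names) == 3:
        return list(DEFAULT_SCENARIOS)
    tags = [f"u({i})" for i in range(1, len(biomarker_names) + 1)]
    if len(biomarker_names) >= 2:
        tags.insert(0, "m(" + ",".join(
            str(i) for i in range(1, len(biomarker_names) + 1)) + ")")
    return tags


def _derive_seed(base_seed: int, *labels) -> int:
    """Deterministic per-stage seed below 2^31 from a global seed."""
    digest = hashlib.sha256(
        ("|".join(map(str, labels)) + f"#{base_seed}").encode()
    ).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def fit_and_score(train: Cohort, test: Cohort, markers, method: str,
                  method_config: dict | None = None, seed: int = 0,
                  prevalence=None) -> pd.DataFrame:
    """Fit one model on ``train`` and return risk trajectories on ``test``."""
    cfg = dict(method_config or {})
    train_m = train.subset_markers(markers)
    test_m = test.subset_markers(markers)
    if method == "bcp":
        if prevalence is None:
            prevalence = PrevalencePrior.from_scalar(
                train.n_cases / max(train.n_patients, 1)
            )
        hyper = cfg.pop("hyper", None) or Hyperparams.default(K=len(markers))
        max_draws = cfg.pop("max_draws", 500)
        fit_kwargs = dict(n_iter=2000, burn_in=500, n_chains=2)
        fit_kwargs.update(cfg)
        res = BayesianChangePointModel(train_m, hyper=hyper).fit(
            seed=seed, **fit_kwargs
        )
        return bcp_score_cohort(test_m, res.samples, prevalence,
                                seed=seed, max_draws=max_draws)
    if method == "rnn":
        do_tune = cfg.pop("tune", False)
        grid = cfg.pop("grid", None)
        inner = {k: cfg.pop(k) for k in ("inner_k", "inner_reps")
                 if k in cfg}
        config = LSTMConfig(**cfg) if cfg else LSTMConfig()
        if do_tune:
            config = tune(train_m, grid=grid, base_config=config,
                          seed=seed, **inner)
        res = LSTMClassifier(train_m, config=config).fit(seed=seed)
        return res.score_cohort(test_m)
    raise ValueError(f"unknown method {method!r}")


def _horizon_eval(test: Cohort, risks: pd.DataFrame, horizon):
    """(labels, scores) at one horizon's evaluated visit per patient."""
    from .evaluation import screen_horizon

    eval_visit = screen_horizon(test, horizon)
    labels, scores = [], []
    for p in test.patients:
        j = eval_visit.get(p.patient_id)
        if j is None or j < 1:      # prefix of >= 2 visits required
            continue
        row = risks[(risks.patient_id == p.patient_id)
                    & (risks.visit_index == j)]
        if row.empty:
            continue
        labels.append(p.status)
        scores.append(float(row["risk"].iloc[0]))
    return np.asarray(labels), np.asarray(scores)


def evaluate_scenarios(cohort: Cohort, plan: FoldPlan, scenarios, methods,
                       method_configs: dict | None = None, horizons=("all",),
                       seed: int = 0, prevalence=None,
                       contingency_pairs=()) -> dict:
    """Run every (method, scenario) over the fold plan and aggregate.

    Returns a dict with ``metrics`` (per-fold rows), ``summary`` (across-fold
    means and CIs), ``lead_times`` (per-model LeadTimeStats rows),
    ``contingency`` (pooled diagnosed/missed tables) and ``risks``.
    """
    method_configs = method_configs or {}
    metrics_rows, risk_frames = [], []
    fold_leads = {}          # (method, scenario) -> list per fold
    detections = {}          # (method, scenario) -> {case_id: bool} pooled
    for fold_i, (train_ids, test_ids) in enumerate(plan):
        train = cohort.subset_patients(train_ids)
        test = cohort.subset_patients(test_ids)
        for method in methods:
            for tag in scenarios:
                markers = parse_scenario(tag, cohort.biomarker_names)
                t0 = time.time()
                risks = fit_and_score(
                    train, test, markers, method,
                    method_config=method_configs.get(method), seed=_derive_seed(
                        seed, "fit", method, tag, fold_i),
                    prevalence=prevalence,
                )
                logger.info("fold %d %s %s: fitted+scored in %.1fs",
                            fold_i, method, tag, time.time() - t0)
                risks = risks.assign(model=method, scenario=tag, fold=fold_i)
                risk_frames.append(risks)
                threshold_all = None
                for horizon in horizons:
                    labels, scores = _horizon_eval(test, risks, horizon)
                    if labels.size == 0 or len(set(labels)) < 2:
                        logger.warning("fold %d %s %s horizon %s: skipped "
                                       "(one class absent)", fold_i, method,
                                       tag, horizon)
                        continue
                    fold_auc = auc(labels, scores)
                    sens, thr = sensitivity_at_specificity(labels, scores)
                    if horizon in ("all", 0):
                        threshold_all = thr
                    metrics_rows.append({
                        "model": method, "scenario": tag,
                        "horizon": str(horizon), "fold": fold_i,
                        "auc": fold_auc, "sensitivity": sens,
                        "threshold": thr,
                    })
                # lead time at the fold's 90%-specificity threshold
                if threshold_all is not None:
                    leads, det = [], {}
                    for p in test.cases:
                        rows = risks[risks.patient_id == p.patient_id]
                        rows = rows.sort_values("visit_index")
                        lt = lead_time(rows["age_years"].to_numpy(),
                                       rows["risk"].to_numpy(),
                                       threshold_all, p.diagnosis_age)
                        det[p.patient_id] = lt is not None
                        if lt is not None:
                            leads.append(lt)
                    fold_leads.setdefault((method, tag), []).append(leads)
                    detections.setdefault((method, tag), {}).update(det)

    metrics = pd.DataFrame(metrics_rows)
    summary_rows = []
    if not metrics.empty:
        for (model, tag, horizon), g in metrics.groupby(
                ["model", "scenario", "horizon"]):
            for metric in ("auc", "sensitivity"):
                est, lo, hi = summarize_metric(g[metric].to_numpy())
                summary_rows.append({
                    "model": model, "scenario": tag, "horizon": horizon,
                    "metric": metric, "mean": est, "ci_lo": lo, "ci_hi": hi,
                })
    lead_rows = []
    for (method, tag), folds in fold_leads.items():
        try:
            stats = lead_time_summary(folds)
        except ValueError:
            continue
        lead_rows.append({"model": method, "scenario": tag,
                          **stats.as_dict()})
    conting = {}
    for method in methods:
        for tag_a, tag_b in contingency_pairs:
            da = detections.get((method, tag_a))
            db = detections.get((method, tag_b))
            if da and db and set(da) == set(db):
                conting[f"{method}:{tag_a}_vs_{tag_b}"] = contingency(da, db)
    return {
        "metrics": metrics,
        "summary": pd.DataFrame(summary_rows),
        "lead_times": pd.DataFrame(lead_rows),
        "contingency": conting,
        "risks": pd.concat(risk_frames, ignore_index=True)
        if risk_frames else pd.DataFrame(),
    }


def run_experiment(config: dict | str | Path, out_dir=None) -> Path:
    """Execute a full configured experiment and write its report directory.

    ``config`` is a dict or a YAML file path; see the README for the schema.
    Writes metrics.csv, summary.csv, leadtime.csv, contingency.json,
    risks.csv and a manifest echoing every setting used.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "ovascreen_run"))
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: cohort ----------------------------------------------------
    if "cohort_csv" in cfg:
        cohort = Cohort.read_csv(cfg["cohort_csv"])
        logger.info("loaded cohort from %s", cfg["cohort_csv"])
    else:
        gen_kwargs = dict(cfg.get("generator", {}))
        gen_kwargs.setdefault("seed", _derive_seed(seed, "simulate"))
        gen = GeneratorConfig(**gen_kwargs)
        cohort, truth = generate_cohort(gen)
        cohort.to_csv(out / "cohort.csv")
        truth.to_csv(out / "truth.csv")
        logger.info("simulated cohort: %d controls, %d cases",
                    cohort.n_controls, cohort.n_cases)

    # ---- stage 2: folds -----------------------------------------------------
    cv = dict(cfg.get("cv", {}))
    plan = make_folds(cohort, k=int(cv.get("k", 5)), reps=int(cv.get("reps", 2)),
                      seed=_derive_seed(seed, "folds"))

    # ---- stage 3-5: fit, score, evaluate ------------------------------------
    scenarios = cfg.get("scenarios") or default_scenarios(cohort.biomarker_names)
    methods = cfg.get("methods", ["bcp", "rnn"])
    horizons = cfg.get("horizons", ["all"])
    prevalence = cfg.get("prevalence")
    if prevalence is not None:
        prevalence = PrevalencePrior.from_scalar(float(prevalence))
    pairs = [tuple(p) for p in cfg.get("contingency_pairs", [])]
    results = evaluate_scenarios(
        cohort, plan, scenarios, methods,
        method_configs={"bcp": cfg.get("bcp", {}), "rnn": cfg.get("rnn", {})},
        horizons=horizons, seed=seed, prevalence=prevalence,
        contingency_pairs=pairs,
    )

    results["metrics"].to_csv(out / "metrics.csv", index=False)
    results["summary"].to_csv(out / "summary.csv", index=False)
    results["lead_times"].to_csv(out / "leadtime.csv", index=False)
    results["risks"].to_csv(out / "risks.csv", index=False)
    (out / "contingency.json").write_text(
        json.dumps(results["contingency"], indent=2))
    manifest = {
        "seed": seed,
        "scenarios": list(scenarios),
        "methods": list(methods),
        "horizons": [str(h) for h in horizons],
        "cv": {"k": plan.k, "reps": plan.reps, "seed": plan.seed},
        "n_controls": cohort.n_controls, "n_cases": cohort.n_cases,
        "config_echo": {k: v for k, v in cfg.items() if k != "cohort_csv"
                        or isinstance(v, (str, int, float))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out
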