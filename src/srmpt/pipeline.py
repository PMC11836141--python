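"""End-to-end analysis pipeline.

Stages: simulate (or load a participant CSV) -> behavioral scoring and
MAD-based exclusion -> ANOVA + planned contrasts -> aggregated ML MPT fits
and nested comparisons -> optional hierarchical Bayesian fits with
posterior-predictive checks and group differences -> consolidated JSON
report.  All outputs are plain CSV/JSON carrying a schema-version field;
two runs with identical config and seeds produce byte-identical reports.
"""

from __future__ import annotations

import copy
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes as bayes_mod
from . import behavior, ml, simulate
from .errors import DataError, SrmptError
from .model import read_eqn_file, storage_retrieval_model
from .simulate import CATEGORY_COLUMNS, ExperimentDesign, TrueParameters

SCHEMA_VERSION = 1

DEFAULT_CONFIG: dict = {
    "schema_version": SCHEMA_VERSION,
    "seed": 1,
    "alpha": 0.05,
    "session": 1,
    "input_csv": None,
    "model_file": None,
    "model_constraints": ["d:=s*r1"],
    "simulate": {"n_per_condition": 53, "sessions": 1},
    "outlier_rule": {"multiplier": 3.0, "scaled": True},
    "behavioral": {"enabled": True},
    "ml": {
        "enabled": True,
        "restarts": 10,
        "baseline_constraints": ["r1[waking_rest]=r1[social_media]"],
    },
    "bayes": {
        "enabled": False,
        "chains": 4,
        "burn_in": 2000,
        "iterations": 8000,
        "n_rep": 500,
    },
    "hypotheses": [
        {"parameter": "s", "larger": "waking_rest", "smaller": "social_media", "tail": "one"},
        {"parameter": "s", "larger": "waking_rest", "smaller": "vocabulary", "tail": "one"},
        {"parameter": "s", "larger": "social_media", "smaller": "vocabulary", "tail": "two"},
        {"parameter": "r2", "larger": "waking_rest", "smaller": "social_media", "tail": "one"},
        {"parameter": "r2", "larger": "waking_rest", "smaller": "vocabulary", "tail": "one"},
        {"parameter": "r2", "larger": "social_media", "smaller": "vocabulary", "tail": "one"},
        {"parameter": "g", "larger": "waking_rest", "smaller": "social_media", "tail": "two"},
        {"parameter": "g", "larger": "waking_rest", "smaller": "vocabulary", "tail": "two"},
        {"parameter": "g", "larger": "social_media", "smaller": "vocabulary", "tail": "two"},
    ],
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def resolve_config(config: dict | None) -> dict:
    resolved = _merge(DEFAULT_CONFIG, config or {})
    if resolved.get("schema_version") != SCHEMA_VERSION:
        raise SrmptError(f"unsupported schema_version {resolved.get('schema_version')}")
    return resolved


def _log(stage: str, t0: float) -> None:
    print(f"[srmpt] {stage}: {time.perf_counter() - t0:.2f}s", file=sys.stderr)



def load_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["id", "condition", "immediate_correct", *CATEGORY_COLUMNS.values()]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"input CSV is missing columns: {missing}")
    if "session" not in df.columns:
        df["session"] = 1
    return df


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Execute the configured stages and return the consolidated report.

    A stage failure aborts with the stage name prefixed to the error;
    artifacts already persisted by earlier stages are retained.
    """
    state = {"stage": "config"}
    try:
        return _run_pipeline(config, out_dir, state)
    except Exception as exc:
        try:
            raise type(exc)(f"[stage {state['stage']}] {exc}") from exc
        except TypeError:
            raise SrmptError(f"[stage {state['stage']}] {exc}") from exc


def _run_pipeline(config, out_dir, state) -> dict:
    cfg = resolve_config(config)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": SCHEMA_VERSION, "config": cfg}
    if cfg["model_file"]:
        spec = read_eqn_file(cfg["model_file"], cfg.get("model_constraints") or ())
    else:
        spec = storage_retrieval_model()

    # --- stage: data -------------------------------------------------------
    state["stage"] = "data"
    t0 = time.perf_counter()
    if cfg["input_csv"]:
        records = load_records(cfg["input_csv"])
        report["data"] = {"source": str(cfg["input_csv"])}
    else:
        sim_cfg = dict(cfg["simulate"])
        true_cfg = sim_cfg.pop("true_parameters", None)
        design = ExperimentDesign(**sim_cfg)
        true = TrueParameters(**true_cfg) if true_cfg else TrueParameters()
        records = simulate.simulate_experiment(design, true, seed=cfg["seed"])
        report["data"] = {"source": "simulated", "seed": cfg["seed"]}
    report["data"]["n_rows"] = int(len(records))
    if out_path is not None:
        records.to_csv(out_path / "records.csv", index=False)
    _log("data", t0)

    # --- stage: scoring + exclusion ---------------------------------------
    state["stage"] = "scoring"
    t0 = time.perf_counter()
    rule = behavior.OutlierRule(
        multiplier=cfg["outlier_rule"]["multiplier"], scaled=cfg["outlier_rule"]["scaled"]
    )
    scores = behavior.score_participants(records)
    scores = behavior.apply_exclusions(scores, rule)
    if out_path is not None:
        scores.to_csv(out_path / "scores.csv", index=False)
    session = cfg["session"]
    kept = scores[(scores["session"] == session) & ~scores["excluded"]]
    report["exclusions"] = {
        "criterion_failures": int(scores["excluded_at_source"].sum()),
        "outliers": int((scores["excluded"] & ~scores["excluded_at_source"]).sum()),
        "n_analyzed": int(len(kept)),
        "per_condition": {c: int(n) for c, n in kept.groupby("condition").size().items()},
    }
    _log("scoring", t0)

    conditions = list(dict.fromkeys(records["condition"]))

    # --- stage: ANOVA + planned contrasts ---------------------------------
    state["stage"] = "behavioral"
    if cfg["behavioral"]["enabled"]:
        t0 = time.perf_counter()
        block: dict = {}
        for var in ("retention", "recognition"):
            values = kept[var].to_numpy()
            groups = kept["condition"].to_numpy()
            anova = behavior.oneway_anova(values, groups)
            entry = {
                "anova": {
                    "F": anova.f,
                    "df1": anova.df1,
                    "df2": anova.df2,
                    "p": anova.p,
                    "eta_squared": anova.eta_squared,
                },
                "contrasts": [],
            }
            for a, b, tail in _condition_pairs(conditions):
                contrast = behavior.planned_contrast(
                    values, groups, {a: 1.0, b: -1.0}, tail=tail, direction=a if tail == "one" else None
                )
                entry["contrasts"].append(
                    {
                        "groups": [a, b],
                        "tail": tail,
                        "t": contrast.t,
                        "df": contrast.df,
                        "p": contrast.p,
                        "cohens_d": contrast.cohens_d,
                    }
                )
            block[var] = entry
        report["behavioral"] = block
        _log("behavioral", t0)

    counts = simulate.aggregate_counts(records, spec, session=session)

    # --- stage: aggregated ML ---------------------------------------------
    state["stage"] = "ml"
    if cfg["ml"]["enabled"]:
        t0 = time.perf_counter()
        restarts = cfg["ml"]["restarts"]
        baseline_constraints = list(cfg["ml"]["baseline_constraints"])
        baseline = ml.fit_ml(
            spec, counts, constraints=baseline_constraints, restarts=restarts, seed=cfg["seed"]
        )
        block = {
            "baseline": _fit_summary(baseline, with_ci=True),
            "comparisons": [],
        }
        for hyp in cfg["hypotheses"]:
            param, larger, smaller = hyp["parameter"], hyp["larger"], hyp["smaller"]
            if larger not in counts or smaller not in counts:
                continue
            extra = f"{param}[{larger}]={param}[{smaller}]"
            restricted = ml.fit_ml(
                spec,
                counts,
                constraints=baseline_constraints + [extra],
                restarts=restarts,
                seed=cfg["seed"],
            )
            comparison = ml.compare_nested(
                baseline,
                restricted,
                tail=hyp.get("tail", "two"),
                direction=(param, larger, smaller) if hyp.get("tail") == "one" else None,
            )
            block["comparisons"].append(
                {
                    "parameter": param,
                    "groups": [larger, smaller],
                    "tail": hyp.get("tail", "two"),
                    "delta_g2": comparison.delta_g2,
                    "delta_df": comparison.delta_df,
                    "z": comparison.z,
                    "p_two_tailed": comparison.p_two_tailed,
                    "p_one_tailed": comparison.p_one_tailed,
                }
            )
        report["ml"] = block
        _log("ml", t0)

    # --- stage: hierarchical Bayes ----------------------------------------
    state["stage"] = "bayes"
    if cfg["bayes"]["enabled"]:
        t0 = time.perf_counter()
        bcfg = cfg["bayes"]
        config_obj = bayes_mod.LatentTraitConfig(
            chains=bcfg["chains"],
            burn_in=bcfg["burn_in"],
            iterations=bcfg["iterations"],
            seed=cfg["seed"],
        )
        fits = {}
        block = {"conditions": {}, "differences": []}
        for condition in conditions:
            mat = simulate.participant_count_matrix(records, condition, session=session)
            fit = bayes_mod.fit_latent_trait(spec, mat, config_obj)
            fits[condition] = fit
            ppc = bayes_mod.posterior_predictive_check(
                fit, n_rep=min(bcfg["n_rep"], fit.n_retained), seed=cfg["seed"]
            )
            block["conditions"][condition] = {
                "summary": fit.summary.reset_index().to_dict(orient="records"),
                "converged": fit.converged,
                "ppc": {"p_t1": ppc.p_t1, "p_t2": ppc.p_t2, "satisfactory": ppc.satisfactory},
            }
        for hyp in cfg["hypotheses"]:
            larger, smaller = hyp["larger"], hyp["smaller"]
            if larger not in fits or smaller not in fits:
                continue
            diff = bayes_mod.group_difference(
                fits[larger], fits[smaller], hyp["parameter"], names=(larger, smaller)
            )
            block["differences"].append(
                {
                    "parameter": hyp["parameter"],
                    "groups": [larger, smaller],
                    "bayes_p": diff.bayes_p,
                    "bci": list(diff.bci),
                    "excludes_zero": diff.excludes_zero,
                }
            )
        report["bayes"] = block
        _log("bayes", t0)

    state["stage"] = "report"
    if out_path is not None:
        write_report(report, out_path / "report.json")
    return report


def _condition_pairs(conditions):
    """Pairwise contrasts; waking rest is tested one-tailed against the others."""
    pairs = []
    for i, a in enumerate(conditions):
        for b in conditions[i + 1 :]:
            tail = "one" if "rest" in str(a) or "rest" in str(b) else "two"
            if "rest" in str(b):
                a, b = b, a
            pairs.append((a, b, tail))
    return pairs


def _fit_summary(fit: ml.MlFitResult, with_ci: bool = False) -> dict:
    out = {
        "estimates": {
            str(grp): {p: round(v, 10) for p, v in vals.items()}
            for grp, vals in fit.estimates.items()
        },
        "g2": fit.g2,
        "df": fit.df,
        "p": fit.p_value,
        "converged": fit.converged,
    }
    if with_ci:
        out["ci"] = [
            {
                "parameter": c.parameter,
                "group": c.group,
                "estimate": c.estimate,
                "lower": c.lower,
                "upper": c.upper,
            }
            for c in ml.wald_ci(fit)
        ]
    return out


def write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
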