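"""End-to-end two-phase experiment orchestration.

``run_experiment`` executes the whole study design from one configuration:

1. simulate the model-building cohort and construct the criterion (RRI
   factor scores from the memory-decomposition model);
2. split 75/25, tune and train one gradient-boosted surrogate per feature
   tier, evaluate on the held-out quarter, and estimate each surrogate's
   correlation with the latent criterion;
3. simulate the external-validation cohort (with the features the validation
   studies never collected forced missing), generate surrogate scores, and
   run the four-model moderation ladder per tier plus education-only and
   word-reading-only comparison ladders;
4. export attribution tables and predicted trajectories, and write a run
   manifest with per-file checksums.

All randomness derives from one top-level seed, expanded deterministically
into per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
import warnings as _warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution, features, moderation, proxy, rri, synthetic

__all__ = ["load_config", "run_experiment", "report", "RunManifest"]

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

DEFAULT_CONFIG = {
    "seed": 0,
    "n_building": 1600,
    "n_validation": 1600,
    "tiers": ["minimal", "extended", "full"],
    "generator": {},
    "tuner": {
        "n_folds": 10,
        "max_iterations": 6,
        "patience": 6,
        # desk-scale search space: same shape as the full default space but
        # with the tree-count range reduced to keep a laptop run short
        "search_space": {
            "max_depth": [2, 6, "int"],
            "learning_rate": [0.02, 0.3, "log"],
            "min_child_weight": [1, 20, "linear"],
            "subsample": [0.6, 1.0, "linear"],
            "colsample_bytree": [0.6, 1.0, "linear"],
            "n_estimators": [100, 500, "int"],
            "reg_lambda": [0.001, 10.0, "log"],
        },
    },
    "split": {"train_fraction": 0.75},
    "trajectories": {
        "atrophy_rates": [-0.05, -0.10, -0.15],
        "reserve_levels": [-1.0, 0.0, 1.0],
        "horizon_years": 5.0,
    },
    "comparison_ladders": True,
    "plots": False,
}


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    files: dict[str, str]
    version: str
    started: str
    finished: str
    warnings: list[str]
    completed_stages: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def load_config(path) -> dict:
    """Load a YAML/JSON run configuration, merged over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (user or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    names = ["building", "validation", "split", "tune", "fit"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _tuner_config(cfg: dict, seed: int) -> proxy.TunerConfig:
    t = cfg["tuner"]
    space = {
        name: proxy.SearchDimension(low, high, scale)
        for name, (low, high, scale) in t["search_space"].items()
    }
    return proxy.TunerConfig(
        n_folds=t["n_folds"],
        max_iterations=t["max_iterations"],
        patience=t["patience"],
        search_space=space,
        seed=seed,
    )


def run_experiment(config: dict | str | Path, out_dir) -> RunManifest:
    """Run the full two-phase experiment; write all artifacts under out_dir."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = _time.strftime("%Y-%m-%dT%H:%M:%S")
    seeds = _stage_seeds(int(config["seed"]))
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()
    warnings_log: list[str] = []
    completed: list[str] = []
    files: dict[str, str] = {}
    _catcher = _warnings.catch_warnings(record=True)
    _captured = _catcher.__enter__()
    _warnings.simplefilter("always")

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        files[name] = _sha256(path)
        return path

    # ---- phase 1: model building -------------------------------------------
    gen_kwargs = dict(config["generator"])
    build_cfg = synthetic.GenerativeConfig(
        n_participants=int(config["n_building"]), seed=seeds["building"], **gen_kwargs
    )
    cohort, latents = synthetic.simulate_model_building_cohort(build_cfg)
    emit("building_cohort.csv", lambda p: cohort.to_csv(p, index=False))
    emit("building_latents.csv", lambda p: latents.to_frame().to_csv(p, index=False))
    completed.append("simulate_building")

    params = rri.fit_rri(cohort)
    scores = rri.score_rri(params, cohort)
    emit("rri_params.json", params.to_json)
    emit(
        "rri_scores.csv",
        lambda p: scores.rri.rename("rri").reset_index().to_csv(p, index=False),
    )
    completed.append("build_rri")

    train_ids, test_ids = proxy.split_train_test(
        cohort, proxy.SplitSpec(config["split"]["train_fraction"], seeds["split"])
    )
    criterion = scores.rri

    tier_summaries = {}
    proxies: dict[str, proxy.TrainedProxy] = {}
    for tier_name in config["tiers"]:
        tier = features.tier_spec(tier_name)
        X = features.assemble_feature_frame(cohort, tier)
        X_train, X_test = X.loc[train_ids], X.loc[test_ids]
        y_train = criterion.loc[train_ids].to_numpy()
        tuner = _tuner_config(config, seeds["tune"])
        best, best_rmse, log = proxy.tune(X_train, y_train, tuner)
        trained = proxy.fit_final(
            X_train, y_train, tier, best, cv_rmse_value=best_rmse, seed=seeds["fit"]
        )
        proxies[tier_name] = trained
        emit(f"tuning_log_{tier_name}.csv", lambda p, log=log: log.to_csv(p, index=False))
        emit(
            f"hyperparameters_{tier_name}.json",
            lambda p, best=best: Path(p).write_text(json.dumps(best, indent=2)),
        )
        trained.model.get_booster().save_model(str(out / f"model_{tier_name}.ubj"))

        held = proxy.evaluate(trained, X_test, criterion, split="held_out")
        latent_r, latent_se = rri.latent_correlation(
            params, cohort[cohort["id"].isin(test_ids)].set_index("id", drop=False),
            proxy.predict(trained, X_test),
        )
        tier_summaries[tier_name] = {
            "cv_rmse": trained.cv_rmse,
            "held_out_rmse": held.rmse,
            "held_out_r": held.pearson_r,
            "latent_r": latent_r,
            "latent_r_se": latent_se,
            "n_test": held.n,
        }

        imp = attribution.gain_importance(trained)
        emit(
            f"importance_{tier_name}.csv",
            lambda p, imp=imp: imp.table.to_csv(p, index=False),
        )
        attr = attribution.shap_attributions(trained, X_train)
        bees = attribution.beeswarm_export(attr, X_train)
        emit(
            f"beeswarm_{tier_name}.csv",
            lambda p, bees=bees: bees.to_csv(p, index=False),
        )
        if config.get("plots"):
            attribution.plot_importance(imp, out / f"importance_{tier_name}.png")
            attribution.plot_beeswarm(attr, X_train, out / f"beeswarm_{tier_name}.png")
        completed.append(f"train_{tier_name}")

    emit(
        "tier_summary.json",
        lambda p: Path(p).write_text(json.dumps(tier_summaries, indent=2)),
    )

    # ---- phase 2: external validation --------------------------------------
    val_cfg = build_cfg.replace(
        n_participants=int(config["n_validation"]), seed=seeds["validation"]
    )
    val_cohort, longitudinal, val_latents = synthetic.simulate_validation_cohort(val_cfg)
    emit("validation_cohort.csv", lambda p: val_cohort.to_csv(p, index=False))
    emit("validation_longitudinal.csv", lambda p: longitudinal.to_csv(p, index=False))
    completed.append("simulate_validation")

    ladder_results = {}
    traj_cfg = config["trajectories"]
    trajectory_frames = []
    default_covs = ("age0c", "educc", "sex", "word_reading_c")
    ladder_variants: list[tuple[str, str, tuple[str, ...], tuple[str, ...]]] = [
        (t, "approx_cr", default_covs, ("educc", "word_reading_c"))
        for t in config["tiers"]
    ]
    if config.get("comparison_ladders", True):
        # when a conventional proxy is itself under test it moves out of the
        # covariate/comparison sets and into the reserve slot
        ladder_variants += [
            ("education", "educc", ("age0c", "sex", "word_reading_c"),
             ("word_reading_c",)),
            ("word_reading", "word_reading_c", ("age0c", "educc", "sex"),
             ("educc",)),
        ]
    for name, reserve_var, covariates, comparisons in ladder_variants:
        data = longitudinal.copy()
        if reserve_var == "approx_cr":
            Xv = features.assemble_feature_frame(
                val_cohort, features.tier_spec(name)
            )
            pred = proxy.predict(proxies[name], Xv)
            data = data.merge(
                pred.rename("approx_cr").reset_index(), on="id", how="left"
            )
        spec = moderation.LadderSpec(
            reserve_var=reserve_var, covariates=covariates,
            comparison_proxies=comparisons,
        )
        fits, lrts = moderation.run_ladder(data, spec)
        ladder_results[name] = _ladder_payload(fits, lrts)
        e4 = fits[-1]
        if e4.converged:
            horizon = float(traj_cfg["horizon_years"])
            traj = moderation.predict_trajectories(
                e4,
                profile={"age0c": 0.0, "educc": 0.0, "sex": 0.0, "word_reading_c": 0.0},
                atrophy_rates=list(traj_cfg["atrophy_rates"]),
                reserve_levels=list(traj_cfg["reserve_levels"]),
                times=np.linspace(0.0, horizon, int(horizon * 2) + 1),
                reserve_var=reserve_var,
            )
            traj.insert(0, "proxy", name)
            trajectory_frames.append(traj)
        completed.append(f"ladder_{name}")

    emit(
        "ladders.json",
        lambda p: Path(p).write_text(json.dumps(ladder_results, indent=2)),
    )
    if trajectory_frames:
        all_traj = pd.concat(trajectory_frames, ignore_index=True)
        emit("trajectories.csv", lambda p: all_traj.to_csv(p, index=False))

    _catcher.__exit__(None, None, None)
    warnings_log.extend(str(w.message) for w in _captured)
    manifest = RunManifest(
        config_hash=config_hash,
        seeds=seeds,
        files=files,
        version=__version__,
        started=started,
        finished=_time.strftime("%Y-%m-%dT%H:%M:%S"),
        warnings=warnings_log,
        completed_stages=completed,
    )
    manifest.to_json(out / "manifest.json")
    (out / "config_resolved.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    return manifest


def _ladder_payload(fits, lrts) -> dict:
    n_obs = fits[0].n_obs
    payload = {"models": [], "tests": []}
    for fit in fits:
        payload["models"].append(
            {
                "label": fit.label,
                "n_params": fit.n_params,
                "AIC": fit.aic,
                "BIC": fit.bic(n_obs),
                "logLik": fit.loglik,
                "deviance": fit.deviance,
                "converged": fit.converged,
                "singular_fallback": fit.singular_fallback,
            }
        )
    for t in lrts:
        payload["tests"].append(
            {
                "comparison": f"{t.comparison[1]} versus {t.comparison[0]}",
                "delta_chisq": t.delta_deviance,
                "delta_df": t.delta_df,
                "p": t.p_value,
                "available": t.available,
            }
        )
    return payload


def report(out_dir) -> str:
    """Render a deterministic markdown summary of a completed run."""
    out = Path(out_dir)
    lines = ["# Reserve proxy experiment report", ""]
    missing = []

    tier_path = out / "tier_summary.json"
    if tier_path.exists():
        tiers = json.loads(tier_path.read_text())
        lines += [
            "## Surrogate accuracy and concurrent validity",
            "",
            "| Tier | CV RMSE | Held-out RMSE | Held-out r | Latent r (SE) |",
            "|---|---|---|---|---|",
        ]
        for name, s in tiers.items():
            lines.append(
                f"| {name} | {s['cv_rmse']:.3f} | {s['held_out_rmse']:.3f} "
                f"| {s['held_out_r']:.3f} | {s['latent_r']:.3f} ({s['latent_r_se']:.3f}) |"
            )
        lines.append("")
    else:
        missing.append("tier_summary.json")

    ladder_path = out / "ladders.json"
    if ladder_path.exists():
        ladders = json.loads(ladder_path.read_text())
        for name, payload in ladders.items():
            lines += [
                f"## Moderation ladder: {name}",
                "",
                "| Label | # Parameters | AIC | BIC | logLik | Deviance "
                "| Δχ² | Δdf | P | Comparison |",
                "|---|---|---|---|---|---|---|---|---|---|",
            ]
            tests = {t["comparison"].split(" versus ")[0]: t for t in payload["tests"]}
            for m in payload["models"]:
                t = tests.get(m["label"])
                if t is None:
                    tail = "| — | — | — | — |"
                else:
                    tail = (
                        f"| {t['delta_chisq']:.2f} | {t['delta_df']} "
                        f"| {t['p']:.3g} | {t['comparison']} |"
                    )
                lines.append(
                    f"| {m['label']} | {m['n_params']} | {m['AIC']:.1f} | {m['BIC']:.1f} "
                    f"| {m['logLik']:.1f} | {m['deviance']:.1f} " + tail
                )
            lines.append("")
    else:
        missing.append("ladders.json")

    if missing:
        lines += ["## Warnings", ""] + [f"- missing artifact: {m}" for m in missing]
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return text
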