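"""End-to-end analysis: simulate → preprocess → select → compare → rank → optimize.

``run_full_pipeline`` reproduces the whole analysis for both responses:

1. generate (or accept) replicate-level running-length and running-rate
   datasets;
2. Box–Cox-normalize each response (offset 1, power estimated once per
   dataset) and screen for multivariate outliers by PCA score distance;
3. GA-search the surrogate's hidden-layer width under a reduced CV plan
   (8 folds, 1 repeat), then re-evaluate the chosen width under the full
   8-fold × 10-repeat plan;
4. evaluate the five linear baselines under the same full plan;
5. rank input importance by VSE/VSR ablation;
6. GA-optimize the inputs on a surrogate refit to all rows.

Every stage seed derives deterministically from the master seed, and the
report echoes the full configuration, so one integer reproduces the run.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .baselines import BASELINE_METHODS, baseline_factory
from .ga import GAConfig
from .mlp import FitMetrics, TrainConfig, fit_surrogate
from .model_selection import CVPlan, cross_validate, search_hidden_neurons
from .optimize import OptimizationQuery, default_bounds, format_days, optimize_inputs
from .preprocess import fit_boxcox, fit_feature_scaler, pca_outlier_screen
from .sensitivity import compute_vsr
from .simulate import SimConfig, generate_rl_dataset, generate_rr_dataset
from .tables import StudyTables, load_study_tables

__all__ = ["PipelineConfig", "run_full_pipeline", "write_report", "RL_FEATURES", "RR_FEATURES", "dataset_xy"]

RL_FEATURES = ("bagasse_pct", "wheatbran_pct", "beechsawdust_pct", "time_days")
RR_FEATURES = ("bagasse_pct", "wheatbran_pct", "beechsawdust_pct")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the full analysis needs, with the study's settings as defaults."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    boxcox_offset: float = 1.0
    pca_sd_threshold: float = 3.0
    cv: CVPlan = field(default_factory=CVPlan)
    train: TrainConfig = field(default_factory=TrainConfig)
    hidden_range: tuple[int, int] = (1, 25)
    ga_generations: int = 500
    ga_population: int = 50
    ga_crossover: float = 0.85
    ga_mutation: float = 0.01
    kinds: tuple[str, ...] = ("rl", "rr")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        seed = int(doc.get("seed", 0))
        sim = doc.get("sim", {})
        cv = doc.get("cv", {})
        ga = doc.get("ga", {})
        train = doc.get("train", {})
        bounds_blk = doc.get("boxcox", {})
        return cls(
            seed=seed,
            sim=SimConfig(
                seed=int(sim.get("seed", seed)),
                n_replicates=int(sim.get("n_replicates", 4)),
                noise_sd_cm=float(sim.get("noise_sd_cm", 0.30)),
            ),
            boxcox_offset=float(bounds_blk.get("offset", 1.0)),
            pca_sd_threshold=float(doc.get("pca", {}).get("sd_threshold", 3.0)),
            cv=CVPlan(
                k=int(cv.get("k", 8)),
                repeats=int(cv.get("repeats", 10)),
                seed=int(cv.get("seed", seed)),
                group_by_substrate=bool(cv.get("group_by_substrate", False)),
            ),
            train=TrainConfig(seed=int(train.get("seed", seed)), max_epochs=int(train.get("max_epochs", 1500))),
            hidden_range=tuple(doc.get("hidden_range", (1, 25))),
            ga_generations=int(ga.get("generations", 500)),
            ga_population=int(ga.get("population_size", 50)),
            ga_crossover=float(ga.get("crossover_rate", 0.85)),
            ga_mutation=float(ga.get("mutation_rate", 0.01)),
        )


def _stage_seed(master: int, tag: str) -> int:
    """A stable per-stage integer seed below 2^31 derived from the master seed."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def dataset_xy(df: pd.DataFrame, kind: str) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Split a replicate-level dataset into (X, y, feature_names)."""
    if kind == "rl":
        feats, target = RL_FEATURES, "rl_cm"
    elif kind == "rr":
        feats, target = RR_FEATURES, "rr_cm_per_day"
    else:
        raise ValueError(f"kind must be 'rl' or 'rr', got {kind!r}")
    return df.loc[:, list(feats)].to_numpy(dtype=float), df[target].to_numpy(dtype=float), feats


def _metrics_dict(m: FitMetrics) -> dict:
    return {"r2": m.r2, "rmse": m.rmse, "mae": m.mae, "mape": m.mape}


def _analyze_kind(
    kind: str,
    df: pd.DataFrame,
    tables: StudyTables,
    config: PipelineConfig,
) -> dict:
    X, y, feats = dataset_xy(df, kind)
    bc = fit_boxcox(y, offset=config.boxcox_offset)

    # outlier screen on the scaled input+output matrix
    M = np.column_stack([fit_feature_scaler(X).apply(X), (y - y.mean()) / y.std(ddof=1)])
    flagged = pca_outlier_screen(M, sd_threshold=config.pca_sd_threshold)

    train_seed = _stage_seed(config.seed, f"train-{kind}")

    def factory_for_width(n_hidden: int):
        def factory(Xtr, ytr):
            cfg = dataclasses.replace(config.train, seed=train_seed)
            return fit_surrogate(Xtr, ytr, n_hidden, cfg, feature_names=feats,
                                 boxcox_offset=config.boxcox_offset, boxcox_lmbda=bc.lmbda)
        return factory

    search_plan = CVPlan(k=config.cv.k, repeats=1, seed=_stage_seed(config.seed, f"search-{kind}"))
    search_ga = GAConfig(
        bounds=(config.hidden_range,),
        population_size=config.ga_population,
        generations=config.ga_generations,
        crossover_rate=config.ga_crossover,
        mutation_rate=config.ga_mutation,
        seed=_stage_seed(config.seed, f"arch-{kind}"),
        encoding="integer",
    )
    best_width, width_scores, _ = search_hidden_neurons(
        X, y, factory_for_width, search_plan, gene_range=config.hidden_range, ga_config=search_ga
    )

    full_plan = dataclasses.replace(config.cv, seed=_stage_seed(config.seed, f"cv-{kind}"))
    groups = None
    if config.cv.group_by_substrate:
        groups = (df["bagasse_pct"] * 1e6 + df["wheatbran_pct"] * 1e3 + df["beechsawdust_pct"]).to_numpy()
    methods = {}
    mlp_cv = cross_validate(factory_for_width(best_width), X, y, full_plan, groups=groups, factory_name="mlp_ga")
    methods["mlp_ga"] = {"train": _metrics_dict(mlp_cv.pooled_train), "test": _metrics_dict(mlp_cv.pooled_test)}
    for method in BASELINE_METHODS:
        res = cross_validate(baseline_factory(method, y_transform=bc), X, y, full_plan, groups=groups, factory_name=method)
        methods[method] = {"train": _metrics_dict(res.pooled_train), "test": _metrics_dict(res.pooled_test)}

    vsr = compute_vsr(
        X, y, feats, best_width,
        dataclasses.replace(config.train, seed=_stage_seed(config.seed, f"vsr-{kind}")),
        boxcox_offset=config.boxcox_offset,
    )

    final_model = fit_surrogate(
        X, y, best_width,
        dataclasses.replace(config.train, seed=train_seed),
        feature_names=feats, boxcox_offset=config.boxcox_offset, boxcox_lmbda=bc.lmbda,
    )
    ga_cfg = GAConfig(
        bounds=default_bounds(len(feats)),
        population_size=config.ga_population,
        generations=config.ga_generations,
        crossover_rate=config.ga_crossover,
        mutation_rate=config.ga_mutation,
        seed=_stage_seed(config.seed, f"opt-{kind}"),
        encoding="real",
    )
    outcome = optimize_inputs(OptimizationQuery(model=final_model, ga=ga_cfg, grid_seed_tables=tables))
    optimum = dict(zip(feats, outcome.best_chromosome.tolist()))
    result = {
        "n_rows": int(len(df)),
        "boxcox": {"lambda": bc.lmbda, "offset": bc.offset},
        "pca_outliers_flagged": int(flagged.size),
        "n_hidden": int(best_width),
        "width_scores": {int(k): float(v) for k, v in width_scores.items()},
        "cv_splits": mlp_cv.n_splits,
        "methods": methods,
        "vsr": {
            "rmse_full": vsr.rmse_full,
            "vse": vsr.vse,
            "raw": vsr.vsr_raw,
            "rescaled": vsr.vsr_rescaled,
            "ranking": list(vsr.ranking),
        },
        "optimum": {
            "inputs": optimum,
            "predicted": outcome.best_fitness,
        },
    }
    if "time_days" in optimum:
        result["optimum"]["time_rendered"] = format_days(optimum["time_days"])
    return result


def run_full_pipeline(config: PipelineConfig, datasets: Optional[dict[str, pd.DataFrame]] = None) -> dict:
    """Run the whole analysis; returns a JSON-serializable report bundle.

    ``datasets`` may supply user data keyed 'rl'/'rr'; anything missing is
    simulated under ``config.sim``.
    """
    tables = load_study_tables()
    datasets = dict(datasets or {})
    if "rl" not in datasets and "rl" in config.kinds:
        datasets["rl"] = generate_rl_dataset(tables, config.sim)
    if "rr" not in datasets and "rr" in config.kinds:
        datasets["rr"] = generate_rr_dataset(tables, config.sim)

    report: dict = {
        "config": {
            "seed": config.seed,
            "sim": dataclasses.asdict(config.sim),
            "cv": dataclasses.asdict(config.cv),
            "train": dataclasses.asdict(config.train),
            "boxcox_offset": config.boxcox_offset,
            "hidden_range": list(config.hidden_range),
            "ga": {
                "population_size": config.ga_population,
                "generations": config.ga_generations,
                "crossover_rate": config.ga_crossover,
                "mutation_rate": config.ga_mutation,
                "elitism_count": 1,
            },
        },
        "models": {},
    }
    for kind in config.kinds:
        try:
            report["models"][kind] = _analyze_kind(kind, datasets[kind], tables, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage for kind={kind!r} failed: {exc}") from exc
    return report


def write_report(report: dict, out_dir) -> None:
    """Write report.json and a flat metrics.csv (one row per model × method)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    rows = []
    for kind, blk in report["models"].items():
        for method, m in blk["methods"].items():
            rows.append({
                "response": kind,
                "method": method,
                "train_r2": m["train"]["r2"], "train_rmse": m["train"]["rmse"], "train_mape": m["train"]["mape"],
                "test_r2": m["test"]["r2"], "test_rmse": m["test"]["rmse"], "test_mape": m["test"]["mape"],
            })
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
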