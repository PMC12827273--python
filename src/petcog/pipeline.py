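"""End-to-end orchestration: cohort -> confounders -> effects -> refutation
-> region selection -> regression model -> report."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discover import verify_confounders
from .effects import (
    SCOPES,
    cross_group_overlap,
    estimate_all_effects,
    rank_and_select,
    union_selection,
)
from .errors import ConfigurationError
from .refute import counterfactual_curve, compare_actual_vs_placebo, placebo_test
from .regressor import RegressorConfig, evaluate, split_data, train_model
from .synth import GROUPS, CohortConfig, generate_cohort, load_cohort, save_cohort

log = logging.getLogger(__name__)

RESERVED = {"subject_id", "age", "gender", "group", "mmse", "faq"}


def _stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), abs(hash_stable(stage)) % (2**31)])
    return int(ss.generate_state(1)[0])


def hash_stable(s: str) -> int:
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Exactly one input source: a synthetic :class:`CohortConfig` or a path to
    a feature/cohort table in delimited text.
    """

    outdir: str | Path = "petcog_run"
    seed: int = 0
    synthetic: CohortConfig | None = None
    cohort_path: str | Path | None = None
    outcomes: tuple[str, ...] = ("mmse", "faq")
    alpha: float = 0.05
    max_cond_size: int = 3
    #: number of regions included in the PC run (None = all; small values
    #: keep confounder verification fast since only the demographic edges
    #: matter for the backdoor check)
    discover_regions: int | None = 12
    k_whole: int = 30
    k_group: int = 20
    n_permutations: int = 100
    n_placebo_regions: int = 10
    run_discover: bool = True
    run_refute: bool = True
    run_model: bool = True
    model: dict = field(default_factory=dict)  # RegressorConfig overrides
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.synthetic is None) == (self.cohort_path is None):
            raise ConfigurationError(
                "exactly one input source required: synthetic or cohort_path"
            )


@dataclass
class RunReport:
    config_echo: dict
    version: str
    artifacts: dict[str, str]
    timings: dict[str, float]
    metrics: dict[str, dict]
    selections: dict[str, list[str]]

    def to_json(self, path: "str | Path | None" = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def _load_input(config: PipelineConfig, outdir: Path, artifacts, seed: int):
    if config.synthetic is not None:
        synth_cfg = dataclasses.replace(config.synthetic)
        synth_cfg.seed = seed
        data, truth = generate_cohort(synth_cfg)
        path = outdir / "cohort.csv"
        save_cohort(data, path)
        artifacts["cohort"] = str(path)
        return data, truth
    data = load_cohort(config.cohort_path)
    artifacts["cohort"] = str(config.cohort_path)
    return data, None


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every enabled stage in order, persisting one artifact each."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}
    metrics: dict[str, dict] = {}
    selections: dict[str, list[str]] = {}

    def timed(stage):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                log.info("stage %s started", stage)

            def __exit__(self_, *exc):
                timings[stage] = time.perf_counter() - self_.t0
                log.info("stage %s finished in %.2fs", stage, timings[stage])

        return _T()

    with timed("input"):
        data, _truth = _load_input(
            config, outdir, artifacts, _stage_seed(config.seed, "input")
        )
    regions = [c for c in data.columns if c not in RESERVED]

    if config.run_discover:
        with timed("discover"):
            if config.discover_regions is not None and config.discover_regions < len(regions):
                rng = np.random.default_rng(_stage_seed(config.seed, "discover"))
                treat = sorted(
                    rng.choice(regions, size=config.discover_regions, replace=False)
                )
            else:
                treat = regions
            report = verify_confounders(
                data,
                candidates=("age", "gender"),
                treatments=treat,
                outcomes=config.outcomes,
                alpha=config.alpha,
                max_cond_size=config.max_cond_size,
            )
            path = outdir / "confounders.json"
            report.to_json(path)
            artifacts["confounders"] = str(path)

    effect_tables: dict[str, dict[str, object]] = {}
    with timed("estimate"):
        for outcome in config.outcomes:
            effect_tables[outcome] = {}
            for scope in SCOPES:
                table = estimate_all_effects(data, outcome, scope)
                path = outdir / f"effects_{outcome}_{scope}.csv"
                table.save_csv(path)
                artifacts[f"effects_{outcome}_{scope}"] = str(path)
                effect_tables[outcome][scope] = table

    with timed("select"):
        for outcome in config.outcomes:
            sel = union_selection(
                effect_tables[outcome]["whole"],
                {g: effect_tables[outcome][g] for g in GROUPS},
                k_whole=config.k_whole,
                k_group=config.k_group,
            )
            path = outdir / f"selection_{outcome}.json"
            sel.to_json(path)
            artifacts[f"selection_{outcome}"] = str(path)
            selections[outcome] = sel.regions
            overlap = cross_group_overlap(
                {
                    g: rank_and_select(
                        effect_tables[outcome][g],
                        min(config.k_group, len(regions)),
                    )
                    for g in GROUPS
                }
            )
            path = outdir / f"overlap_{outcome}.json"
            path.write_text(json.dumps(overlap, indent=2))
            artifacts[f"overlap_{outcome}"] = str(path)

    if config.run_refute:
        with timed("refute"):
            seed = _stage_seed(config.seed, "refute")
            for outcome in config.outcomes:
                top = selections[outcome][: config.n_placebo_regions]
                rep = placebo_test(
                    data, top, outcome,
                    n_permutations=config.n_permutations, seed=seed,
                )
                path = outdir / f"placebo_{outcome}.csv"
                compare_actual_vs_placebo(rep).to_csv(path, index=False)
                artifacts[f"placebo_{outcome}"] = str(path)
                region = selections[outcome][0]
                frames = []
                for g in GROUPS:
                    curve = counterfactual_curve(data, region, outcome, scope=g)
                    df = curve.to_frame()
                    df["group"] = g
                    frames.append(df)
                path = outdir / f"counterfactual_{outcome}_{region}.csv"
                pd.concat(frames).to_csv(path, index=False)
                artifacts[f"counterfactual_{outcome}"] = str(path)

    if config.run_model:
        with timed("model"):
            seed = _stage_seed(config.seed, "model")
            for outcome in config.outcomes:
                feats = selections[outcome] + ["age", "gender"]
                overrides = dict(config.model)
                overrides.setdefault("seed", seed)
                cfg = RegressorConfig(n_features=len(feats), **overrides)
                train, test = split_data(data, cfg.split_ratio, seed=seed)
                model, history = train_model(train, outcome, feats, cfg)
                m = evaluate(model, test, outcome)
                metrics[outcome] = {"r2": m.r2, "mse": m.mse, "mae": m.mae}
                hist_path = outdir / f"history_{outcome}.csv"
                history.to_csv(hist_path, index=False)
                artifacts[f"history_{outcome}"] = str(hist_path)
                model_path = outdir / f"model_{outcome}.npz"
                model.save(model_path)
                artifacts[f"model_{outcome}"] = str(model_path)
                scatter = pd.DataFrame(
                    {
                        "subject_id": test["subject_id"]
                        if "subject_id" in test.columns
                        else np.arange(len(test)),
                        "actual": test[outcome].to_numpy(),
                        "predicted": model.predict(test[feats].to_numpy(float)),
                    }
                )
                path = outdir / f"scatter_{outcome}.csv"
                scatter.to_csv(path, index=False)
                artifacts[f"scatter_{outcome}"] = str(path)

    report = RunReport(
        config_echo=_config_echo(config),
        version=__version__,
        artifacts=artifacts,
        timings=timings,
        metrics=metrics,
        selections=selections,
    )
    report.to_json(outdir / "run_report.json")
    return report


def _config_echo(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.synthetic is not None:
        d["synthetic"] = {
            "n_per_group": config.synthetic.n_per_group,
            "n_regions": config.synthetic.n_regions,
            "seed": config.synthetic.seed,
            "effect_map": {k: list(v) for k, v in config.synthetic.effect_map.items()},
        }
    return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


def make_report_tables(report: RunReport, outdir: str | Path) -> dict[str, str]:
    """Re-derive human-readable summary tables from persisted artifacts."""
    outdir = Path(outdir)
    outputs = {}
    for key, path in report.artifacts.items():
        if key.startswith("effects_") and path.endswith(".csv"):
            df = pd.read_csv(path)
            k = min(30, len(df))
            out = outdir / f"ranked_{key.removeprefix('effects_')}.csv"
            df.nsmallest(k, "rank")[["rank", "region", "effect", "se", "p"]].to_csv(
                out, index=False
            )
            outputs[key] = str(out)
        elif key.startswith(("placebo_", "scatter_", "counterfactual_")):
            outputs[key] = path  # already human-readable delimited text
    return outputs
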