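"""End-to-end pipeline orchestration.

Runs the stages fixture -> simulate -> synthesize -> classify -> estimate
-> realign -> project -> report against a single YAML/JSON config, writing
every intermediate table as CSV plus a run manifest (seed, package
version, SHA-256 of each written file).  Outputs are deterministic given
the config, so re-runs are byte-identical and the manifest hashes double
as a regression check.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .classify import classify_respondents
from .exceptions import ConfigurationError, PipelineError
from .microsim import RateSchedule, SimConfig, run_simulation
from .model import CareGapModel
from .projection import round_half_up, run_scenario_suite
from .records import read_respondents, write_respondents
from .survey import default_params, generate_respondents

STAGE_ORDER = (
    "fixture",
    "simulate",
    "synthesize",
    "classify",
    "estimate",
    "realign",
    "project",
    "report",
)


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ("fixture", "project", "report")
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ConfigurationError(f"unknown pipeline stages {unknown}")
        order = [STAGE_ORDER.index(s) for s in self.stages]
        if order != sorted(order):
            raise ConfigurationError(
                f"stages out of order; expected subsequence of {STAGE_ORDER}"
            )

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"output_dir", "seed", "stages"}
        return cls(
            output_dir=raw.get("output_dir", "caregap_out"),
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", ("fixture", "project", "report"))),
            options={k: v for k, v in raw.items() if k not in known},
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    os.makedirs(config.output_dir, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "stages": list(config.stages),
        "files": {},
    }
    state: dict = {}
    for stage in config.stages:
        runner = _STAGES[stage]
        try:
            written = runner(config, state)
        except PipelineError:
            raise
        except Exception as err:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError(stage, str(err)) from err
        for name, path in written.items():
            manifest["files"][f"{stage}:{name}"] = {
                "path": os.path.relpath(path, config.output_dir),
                "sha256": _sha256(path),
            }
    manifest_path = os.path.join(config.output_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _stage_fixture(config: PipelineConfig, state: dict) -> dict:
    from .fixtures import build_fixture_files

    fixture_dir = os.path.join(config.output_dir, "fixture")
    paths = build_fixture_files(fixture_dir)
    state["fixture_dir"] = fixture_dir
    return paths


def _stage_simulate(config: PipelineConfig, state: dict) -> dict:
    opts = config.options.get("simulate", {})
    rates_path = opts.get("rates")
    rates = RateSchedule.from_csv(rates_path) if rates_path else RateSchedule.stylized()
    initial = opts.get("initial")
    if initial is None:
        n = int(opts.get("n_agents", 2000))
        initial = {(age, sex, race): n // 40
                   for age in (25, 30, 35, 40, 45)
                   for sex in ("female", "male")
                   for race in ("White", "Black")}
    else:
        initial = {
            (int(item["age"]), item["sex"], item["race"]): int(item["count"])
            for item in initial
        }
    start = int(opts.get("start_year", 1980))
    end = int(opts.get("end_year", 2040))
    output_years = tuple(int(y) for y in opts.get("output_years", (2022, 2030, 2040)))
    totals = {int(k): float(v) for k, v in opts.get("totals", {}).items()} or None
    sim = SimConfig(
        start_year=start,
        end_year=end,
        rates=rates,
        initial=initial,
        random_seed=config.seed,
        output_years=output_years,
        totals=totals,
    )
    tabs = run_simulation(sim)
    frames = [tab.to_frame() for tab in tabs.values()]
    path = os.path.join(config.output_dir, "kin_tabulation.csv")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    state["kin_tabulations"] = tabs
    return {"kin_tabulation": path}


def _stage_synthesize(config: PipelineConfig, state: dict) -> dict:
    opts = config.options.get("synthesize", {})
    n = int(opts.get("n", 10000))
    respondents = generate_respondents(n, seed=config.seed)
    state["respondents"] = respondents
    directory = os.path.join(config.output_dir, "survey")
    return write_respondents(respondents, directory)


def _stage_classify(config: PipelineConfig, state: dict) -> dict:
    opts = config.options.get("classify", {})
    if "respondents" in state:
        respondents = state["respondents"]
    elif "input_dir" in opts:
        respondents = read_respondents(opts["input_dir"])
    else:
        raise ConfigurationError(
            "classify stage needs the synthesize stage or classify.input_dir"
        )
    outcomes = classify_respondents(respondents)
    state["outcomes"] = outcomes
    path = os.path.join(config.output_dir, "outcomes.csv")
    outcomes.to_csv(path, index=False)
    return {"outcomes": path}


def _stage_estimate(config: PipelineConfig, state: dict) -> dict:
    opts = config.options.get("estimate", {})
    stratifier = opts.get("stratifier", "family_structure")
    if "outcomes" not in state:
        path = opts.get("outcomes")
        if path is None:
            raise ConfigurationError(
                "estimate stage needs the classify stage or estimate.outcomes"
            )
        state["outcomes"] = pd.read_csv(path)
    results = CareGapModel(state["outcomes"], stratifier=stratifier).fit()
    state["results"] = results
    path = os.path.join(config.output_dir, "probabilities.csv")
    tidy = results.params.rename_axis("stratum").reset_index().melt(
        id_vars="stratum", var_name="outcome", value_name="value"
    )
    tidy.insert(0, "stratifier", stratifier)
    tidy.to_csv(path, index=False)
    summary_path = os.path.join(config.output_dir, "estimates_summary.txt")
    with open(summary_path, "w") as fh:
        fh.write(results.summary())
        fh.write("\n")
    return {"probabilities": path, "summary": summary_path}


def _stage_realign(config: PipelineConfig, state: dict) -> dict:
    from .fixtures import benchmark_margins

    opts = config.options.get("realign", {})
    if "results" not in state:
        raise ConfigurationError("realign stage needs the estimate stage")
    results = state["results"]
    year = int(opts.get("target_year", 2022))
    target = benchmark_margins(results.stratifier, year)
    realigned = results.realign(target)
    state["realigned"] = realigned
    path = os.path.join(config.output_dir, "probabilities_realigned.csv")
    tidy = realigned.table.rename_axis("stratum").reset_index().melt(
        id_vars="stratum", var_name="outcome", value_name="value"
    )
    tidy.insert(0, "stratifier", realigned.stratifier)
    tidy.to_csv(path, index=False)
    return {"probabilities_realigned": path}


def _stage_project(config: PipelineConfig, state: dict) -> dict:
    from .fixtures import benchmark_inputs

    inputs = benchmark_inputs()
    suite = run_scenario_suite(inputs)
    state["scenario_table"] = suite
    path = os.path.join(config.output_dir, "scenario_projections.csv")
    suite.to_csv(path)
    return {"scenario_projections": path}


def _stage_report(config: PipelineConfig, state: dict) -> dict:
    if "scenario_table" not in state:
        raise ConfigurationError("report stage needs the project stage")
    suite = state["scenario_table"]
    rounded = suite.copy()
    year_cols = [c for c in rounded.columns if c != "pct_increase"]
    for col in year_cols:
        rounded[col] = rounded[col].map(lambda x: round_half_up(x, 1))
    rounded["pct_increase"] = rounded["pct_increase"].map(
        lambda x: None if x is None else round_half_up(x, 1)
    )
    path = os.path.join(config.output_dir, "scenario_report.csv")
    rounded.to_csv(path)
    json_path = os.path.join(config.output_dir, "scenario_report.json")
    payload = {
        " / ".join(str(k) for k in idx): {str(c): row[c] for c in rounded.columns}
        for idx, row in rounded.iterrows()
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"report_csv": path, "report_json": json_path}


_STAGES = {
    "fixture": _stage_fixture,
    "simulate": _stage_simulate,
    "synthesize": _stage_synthesize,
    "classify": _stage_classify,
    "estimate": _stage_estimate,
    "realign": _stage_realign,
    "project": _stage_project,
    "report": _stage_report,
}


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()
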