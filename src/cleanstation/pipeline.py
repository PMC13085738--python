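"""End-to-end orchestration: simulate/load -> metrics -> differencing ->
hierarchical inference -> report tables.

Two analysis arms mirror the study design:

* **arm 1** models the raw response variables of the experimental
  stations across all four observation levels (before, first, second,
  after) and tests a-priori directional contrasts (behaviours decline
  during the manipulation; FID rises);
* **arm 2** models the control-referenced difference scores
  (``rel_to_control``) of the experimental and sham (experimental-
  control) stations across the three post-baseline levels, testing each
  level's cell mean against zero — "C>E" when the treatment is
  hypothesised to fall below control expectation, "C<E" when above.

Observation labels are ordered categoricals throughout; every stage
logs row counts in and out, and dropped rows carry a reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as csvio
from .bayes import (
    ModelSpec,
    bin_surface_area,
    cell_mean_test,
    diagnostics,
    fit_hierarchical,
    one_sided_test,
    transform_policy,
)
from .differencing import POST_REPLICATES, difference_table
from .metrics import RESPONSE_VARIABLES, build_metric_table
from .rugosity import rugosity
from .synthetic import (
    REPLICATES,
    TREATMENTS,
    EffectProfile,
    StudyDesign,
    simulate_study,
)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "validate_inputs"]

log = logging.getLogger(__name__)

#: A-priori direction of change during the manipulation per variable:
#: "decline" tests before > during; "increase" tests during > before.
VARIABLE_DIRECTION = {v: "decline" for v in RESPONSE_VARIABLES}
VARIABLE_DIRECTION["responsiveness_cm"] = "increase"

ARM1_CONTRAST_PAIRS = (
    ("before", "first"),
    ("before", "second"),
    ("before", "after"),
    ("first", "second"),
)


@dataclass
class PipelineConfig:
    """Run configuration; either ``input_dir`` or a simulate block."""

    seed: int = 1
    input_dir: str | None = None
    simulate: bool = True
    scenario: str = "decline"  # "decline" | "null"
    design: StudyDesign = field(default_factory=StudyDesign)
    effects: EffectProfile | None = None
    sampler_profile: str = "paper"  # "paper" (4x15000) | "fast" (2x2000)
    transform_overrides: dict = field(default_factory=dict)
    n_area_bins: int = 4
    exclude_rows: tuple = ()  # (station_id, replicate) pairs dropped pre-fit
    output_dir: str = "results/pipeline"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.input_dir is None and not self.simulate:
            raise ValueError("config needs input paths or a simulate block")
        if self.sampler_profile not in ("paper", "fast"):
            raise ValueError("sampler_profile must be 'paper' or 'fast'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Build a config from a YAML file.

        Recognised keys mirror the dataclass fields; a ``design`` mapping
        is passed to :class:`StudyDesign` (``allocation`` as a
        treatment -> count mapping) and an ``effects`` mapping to
        :meth:`EffectProfile.default_decline` (keys ``decline``,
        ``fid_shift``) when ``scenario`` is 'decline'.
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {
            k: raw[k]
            for k in (
                "seed", "input_dir", "simulate", "scenario", "sampler_profile",
                "transform_overrides", "n_area_bins", "output_dir", "log_level",
            )
            if k in raw
        }
        if "exclude_rows" in raw:
            kw["exclude_rows"] = tuple(tuple(x) for x in raw["exclude_rows"])
        if "design" in raw:
            d = dict(raw["design"])
            if "allocation" in d:
                d["allocation"] = tuple(d["allocation"].items())
            if "replicate_labels" in d:
                d["replicate_labels"] = tuple(d["replicate_labels"])
            if "obs_duration_range_min" in d:
                d["obs_duration_range_min"] = tuple(d["obs_duration_range_min"])
            kw["design"] = StudyDesign(**d)
        if "effects" in raw:
            kw["effects"] = EffectProfile.default_decline(**raw["effects"])
        return cls(**kw)

    def resolved_effects(self) -> EffectProfile:
        if self.effects is not None:
            return self.effects
        return (
            EffectProfile.default_decline()
            if self.scenario == "decline"
            else EffectProfile.null()
        )

    def model_spec(self, response: str, levels: tuple) -> ModelSpec:
        transform = transform_policy(response, overrides=self.transform_overrides)
        if self.sampler_profile == "fast":
            return ModelSpec.fast(response, levels, transform=transform)
        return ModelSpec(response=response, levels=levels, transform=transform)


@dataclass
class ReportBundle:
    """All output tables of one pipeline run."""

    metrics: pd.DataFrame
    differences: pd.DataFrame
    station_rugosity: pd.DataFrame
    arm1_results: pd.DataFrame
    arm2_results: pd.DataFrame
    diagnostics: pd.DataFrame
    manifest: dict

    def write(self, outdir, seed=None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        csvio.write_table(self.metrics, outdir / "metric_table.csv", seed=seed)
        csvio.write_table(self.differences, outdir / "difference_table.csv", seed=seed)
        csvio.write_table(self.station_rugosity, outdir / "station_rugosity.csv", seed=seed)
        csvio.write_table(self.arm1_results, outdir / "experimental_results.csv", seed=seed)
        csvio.write_table(self.arm2_results, outdir / "relative_to_control_results.csv", seed=seed)
        csvio.write_table(self.diagnostics, outdir / "model_diagnostics.csv", seed=seed)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    surveys: pd.DataFrame,
    clean_events: pd.DataFrame,
    pose_events: pd.DataFrame,
    frame_censuses: pd.DataFrame,
    fid_trials: pd.DataFrame,
    stations: pd.DataFrame | None = None,
) -> ValidationReport:
    """Schema and invariant checks; fatal errors vs non-fatal warnings."""
    rep = ValidationReport()
    known_reps = set(REPLICATES)

    for name, df in (
        ("surveys", surveys),
        ("clean_events", clean_events),
        ("pose_events", pose_events),
        ("frame_censuses", frame_censuses),
        ("fid_trials", fid_trials),
    ):
        bad = set(df["replicate"]) - known_reps if "replicate" in df else set()
        if bad:
            rep.errors.append(
                f"{name}: unknown replicate labels {sorted(bad)}; "
                f"allowed: {sorted(known_reps)}"
            )

    if stations is not None:
        bad_t = set(stations["treatment"]) - set(TREATMENTS)
        if bad_t:
            rep.errors.append(
                f"stations: unknown treatment labels {sorted(bad_t)}; "
                f"allowed: {list(TREATMENTS)}"
            )

    if (surveys["obs_duration_min"] <= 0).any():
        bad = surveys.loc[surveys["obs_duration_min"] <= 0, "station_id"].tolist()
        rep.errors.append(f"surveys: non-positive obs_duration_min at stations {bad}")

    neg = clean_events["end_s"] < clean_events["start_s"]
    if neg.any():
        for i, row in clean_events[neg].iterrows():
            rep.errors.append(
                f"clean_events row {i}: end_s < start_s at station "
                f"{row['station_id']} ({row['replicate']})"
            )

    fid = pd.to_numeric(fid_trials["fid_cm"], errors="coerce")
    if (fid.dropna() < 0).any():
        rep.errors.append("fid_trials: negative fid_cm values")
    n_missing_fid = int(fid.isna().sum())
    if n_missing_fid:
        rep.warnings.append(f"fid_trials: {n_missing_fid} missing fid_cm values")

    survey_keys = set(zip(surveys["station_id"], surveys["replicate"]))
    for name, df in (("clean_events", clean_events), ("pose_events", pose_events)):
        if len(df):
            orphans = set(zip(df["station_id"], df["replicate"])) - survey_keys
            if orphans:
                rep.errors.append(
                    f"{name}: events reference unknown surveys {sorted(orphans)[:5]}"
                )
    return rep


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_or_simulate(config: PipelineConfig):
    if config.input_dir is not None:
        d = Path(config.input_dir)
        surveys = csvio.read_surveys(d / "surveys.csv")
        stations = csvio.read_stations(d / "stations.csv")
        if "treatment" not in surveys:
            surveys = surveys.merge(
                stations[["station_id", "treatment"]], on="station_id"
            )
        return (
            stations,
            surveys,
            csvio.read_clean_events(d / "clean_events.csv"),
            csvio.read_pose_events(d / "pose_events.csv"),
            csvio.read_frame_censuses(d / "frame_censuses.csv"),
            csvio.read_fid_trials(d / "fid_trials.csv"),
            csvio.read_profiles(d / "profiles.csv"),
        )
    ds = simulate_study(config.design, config.resolved_effects(), config.seed)
    return (
        ds.stations, ds.surveys, ds.clean_events, ds.pose_events,
        ds.frame_censuses, ds.fid_trials, ds.profiles,
    )


def _fit_and_summarise(
    df, response, levels, config, seed_child, arm, treatment, contrasts
):
    """Fit one model, emit hypothesis rows + one diagnostics row."""
    spec = config.model_spec(response, levels)
    sub = df.dropna(subset=[response])
    n_used = len(sub)
    if n_used < 4 or sub["replicate"].nunique() < 2:
        log.warning("%s/%s: too few rows (%d); model skipped", arm, response, n_used)
        return [], None
    draws = fit_hierarchical(sub, spec, seed_child)
    diag = diagnostics(draws)
    rows = []
    for c in contrasts:
        if c["kind"] == "pair":
            a, b = c["pair"]
            if a not in draws.levels or b not in draws.levels:
                continue
            res = one_sided_test(draws, (a, b), c["direction"])
            label = f"{a} {c['direction']} {b}"
        else:
            if c["level"] not in draws.levels:
                continue
            res = cell_mean_test(draws, c["level"], c["direction"])
            label = c["label"]
        row = res.as_row()
        row.update(
            {
                "arm": arm,
                "treatment": treatment,
                "variable": response,
                "observation": c.get("observation", ""),
                "hypothesis": label,
                "transform": spec.transform,
            }
        )
        if not diag.converged:
            row["flags"] = (row["flags"] + ";" if row["flags"] else "") + "rhat_above_1.01"
        rows.append(row)
    drow = {
        "arm": arm,
        "treatment": treatment,
        "variable": response,
        "n_rows": n_used,
        "max_rhat": diag.max_rhat,
        "min_ess_bulk": min(diag.ess_bulk.values()),
        "icc_station": diag.icc["station"][0],
        "icc_station_category": diag.icc["station"][1],
        "icc_area": diag.icc["area_group"][0],
        "icc_area_category": diag.icc["area_group"][1],
        "icc_total": diag.icc["total"][0],
        "icc_total_category": diag.icc["total"][1],
        "bayes_r2": diag.bayes_r2,
        "converged": diag.converged,
    }
    return rows, drow


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis; deterministic for a fixed config/seed."""
    logging.basicConfig(level=config.log_level)
    stations, surveys, cleans, poses, frames, fid, profiles = _load_or_simulate(config)
    report = validate_inputs(surveys, cleans, poses, frames, fid, stations)
    if not report.ok:
        raise ValueError("input validation failed:\n" + "\n".join(report.errors))
    for w in report.warnings:
        log.warning("%s", w)

    metrics = build_metric_table(surveys, cleans, poses, frames, fid)
    metrics["replicate"] = pd.Categorical(
        metrics["replicate"], categories=list(REPLICATES), ordered=True
    )
    metrics = metrics.sort_values(["station_id", "replicate"]).reset_index(drop=True)
    metrics["replicate"] = metrics["replicate"].astype(str)
    log.info("metric table: %d survey rows", len(metrics))

    if config.exclude_rows:
        mask = metrics.set_index(["station_id", "replicate"]).index.isin(
            [tuple(x) for x in config.exclude_rows]
        )
        log.info("excluding %d flagged rows from models", int(mask.sum()))
        metrics = metrics[~mask].reset_index(drop=True)

    rug = pd.DataFrame(
        {
            "station_id": list(profiles),
            "rugosity": [rugosity(p) for p in profiles.values()],
        }
    )
    stations = stations.merge(rug, on="station_id")
    area_groups = bin_surface_area(
        stations.set_index("station_id")["surface_area_m2"], config.n_area_bins
    )
    metrics["area_group"] = metrics["station_id"].map(area_groups)

    diffs = difference_table(metrics)
    log.info("difference table: %d rows", len(diffs))

    ss = np.random.SeedSequence(config.seed)
    n_models = len(RESPONSE_VARIABLES) * 3  # arm1 + arm2 x 2 treatments
    children = iter(ss.spawn(n_models))
    all_rows, diag_rows = [], []

    # arm 1: experimental stations, raw metrics, four observation levels
    exp = metrics[metrics["treatment"] == "experimental"].copy()
    for v in RESPONSE_VARIABLES:
        direction = VARIABLE_DIRECTION[v]
        contrasts = [
            {
                "kind": "pair",
                "pair": (a, b) if direction == "decline" else (b, a),
                "direction": ">",
                "observation": b,
            }
            for a, b in ARM1_CONTRAST_PAIRS
        ]
        rows, drow = _fit_and_summarise(
            exp, v, REPLICATES, config, next(children), "experimental", "experimental",
            contrasts,
        )
        all_rows += rows
        if drow:
            diag_rows.append(drow)

    # arm 2: rel_to_control difference scores, three post-baseline levels
    diffs_w = diffs.merge(
        metrics[["station_id", "replicate", "area_group"]],
        on=["station_id", "replicate"],
        how="left",
    )
    for trt in ("experimental", "experimental_control"):
        sub_t = diffs_w[diffs_w["treatment"] == trt]
        for v in RESPONSE_VARIABLES:
            direction = VARIABLE_DIRECTION[v]
            # decline: treatment below control expectation -> C>E (mean < 0)
            sign = "<" if direction == "decline" else ">"
            clabel = "C>E" if direction == "decline" else "C<E"
            contrasts = [
                {
                    "kind": "cell",
                    "level": lev,
                    "direction": sign,
                    "label": clabel,
                    "observation": lev,
                }
                for lev in POST_REPLICATES
            ]
            sub = sub_t[sub_t["variable"] == v].rename(
                columns={"rel_to_control": f"rel_{v}"}
            )
            rows, drow = _fit_and_summarise(
                sub, f"rel_{v}", POST_REPLICATES, config, next(children),
                "relative_to_control", trt, contrasts,
            )
            for r in rows:
                r["variable"] = v
            all_rows += rows
            if drow:
                drow["variable"] = v
                diag_rows.append(drow)

    results = pd.DataFrame(all_rows)
    col_order = [
        "arm", "treatment", "variable", "observation", "hypothesis", "transform",
        "estimate", "ci75_low", "ci75_high", "ci95_low", "ci95_high",
        "evidence_ratio", "posterior_probability", "flags",
    ]
    results = results[col_order]
    arm1 = results[results["arm"] == "experimental"].reset_index(drop=True)
    arm2 = results[results["arm"] == "relative_to_control"].reset_index(drop=True)

    import arviz
    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "sampler_profile": config.sampler_profile,
        "n_surveys": len(metrics),
        "n_difference_rows": len(diffs),
        "n_models": len(diag_rows),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "arviz": arviz.__version__,
        },
    }
    bundle = ReportBundle(
        metrics=metrics.astype({"replicate": str}),
        differences=diffs,
        station_rugosity=stations[
            ["station_id", "treatment", "surface_area_m2", "rugosity"]
        ],
        arm1_results=arm1,
        arm2_results=arm2,
        diagnostics=pd.DataFrame(diag_rows),
        manifest=manifest,
    )
    if config.output_dir:
        bundle.write(config.output_dir, seed=config.seed)
    return bundle
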