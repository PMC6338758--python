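"""End-to-end orchestration: simulate → detect → metrics → stats → report.

A run is a pure function of (configuration, seed): the global seed fans out to
per-stage seeds through ``numpy.random.SeedSequence(seed, spawn_key=(stage,))``
so each stage can be rerun independently, and the emitted report is
byte-identical across reruns of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detect import detect_assay, write_call
from .metrics import assay_metrics, summarize_groups
from .stats import (
    anova_tukey,
    fisher_exact_from_counts,
    kruskal_wallis,
    results_frame,
    steel_dwass,
)
from .synth import ArenaSpec, ClassProbabilities, SimConfig, simulate_assay

__all__ = ["RunConfig", "run_pipeline"]

# stage indices for seed derivation
_STAGE_SYNTH_ASSAYS = 0
_STAGE_SYNTH_OUTCOMES = 1


@dataclass(frozen=True)
class AssayGroupSpec:
    """A batch of simulated assays sharing a label and copulation propensity."""

    label: str
    n_assays: int
    copulation_prob: float


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults are the study conditions: one-hour assays, frames analysed every
    10 s, copulation counted above a strict one-minute mount, courtship
    initiation window and CI window of 10 minutes, α = 0.05.
    """

    seed: int = 0
    out_dir: str = "run_out"
    duration_s: float = 3600.0
    frame_interval_s: float = 1.0
    sampling_interval_s: float = 10.0
    min_copulation_s: float = 60.0
    initiation_window_s: float = 600.0
    assay_window_s: float = 3600.0
    alpha: float = 0.05
    pixels_per_mm: float = 10.0
    noise_sigma: float = 6.0
    n_per_class: int = 60
    assay_groups: tuple[AssayGroupSpec, ...] = (
        AssayGroupSpec("normal", 3, 0.9),
        AssayGroupSpec("deviant", 3, 0.0),
    )
    write_frames: bool = False
    run_synth: bool = True
    run_detect: bool = True
    run_metrics: bool = True
    run_stats: bool = True
    events_csv: str | None = None  # external inputs when synth is disabled
    outcomes_csv: str | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        from .io import load_toml

        raw = load_toml(path)
        groups = raw.pop("assay_groups", None)
        cfg = cls(**raw)
        if groups is not None:
            cfg.assay_groups = tuple(AssayGroupSpec(**g) for g in groups)
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        d.pop("write_frames", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(seed: int, stage: int, index: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed, spawn_key=(stage, index))


def _json_ready(obj):
    """Round floats for byte-stable report serialization."""
    if isinstance(obj, float):
        return None if np.isnan(obj) else round(obj, 9)
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return None if np.isnan(obj) else round(float(obj), 9)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return (and write) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        }
    }

    assays = []  # (assay_id, group_label, recording|None, event_log)
    outcomes = None

    if config.run_synth:
        arena = ArenaSpec(
            pixels_per_mm=config.pixels_per_mm, frame_interval_s=config.frame_interval_s
        )
        idx = 0
        for group in config.assay_groups:
            for _ in range(group.n_assays):
                sub_seed = int(
                    _stage_seed(config.seed, _STAGE_SYNTH_ASSAYS, idx).generate_state(1)[0]
                    % (2**31)
                )
                sim = SimConfig(
                    arena=arena,
                    duration_s=config.duration_s,
                    seed=sub_seed,
                    noise_sigma=config.noise_sigma,
                    copulation_prob=group.copulation_prob,
                    assay_id=f"{group.label}_{idx:03d}",
                )
                rec, log = simulate_assay(sim)
                log.to_csv(out / f"events_{sim.assay_id}.csv")
                if config.write_frames:
                    from .io import write_recording

                    write_recording(rec, out / "frames" / f"{sim.assay_id}.tif")
                assays.append((sim.assay_id, group.label, rec, log))
                idx += 1
        outcome_seed = int(
            _stage_seed(config.seed, _STAGE_SYNTH_OUTCOMES).generate_state(1)[0] % (2**31)
        )
        from .synth import make_outcome_table

        outcomes = make_outcome_table(
            ClassProbabilities.defaults(), config.n_per_class, seed=outcome_seed
        )
        outcomes.to_csv(out / "outcomes.csv", index=False)
    else:
        from .metrics import EventLog

        if config.events_csv is None and config.run_metrics:
            raise FileNotFoundError(
                "synth disabled and no events_csv given; expected a CSV with columns "
                "assay_id, fly, event_type, start_s, end_s, truncated"
            )
        if config.events_csv is not None:
            df = pd.read_csv(config.events_csv)
            for assay_id, sub in df.groupby("assay_id", sort=True):
                log = EventLog(df=sub.reset_index(drop=True), assay_id=str(assay_id))
                assays.append((str(assay_id), str(assay_id).rsplit("_", 1)[0], None, log))
        if config.outcomes_csv is not None:
            outcomes = pd.read_csv(config.outcomes_csv)
        elif config.run_stats:
            raise FileNotFoundError(
                "synth disabled and no outcomes_csv given; expected a CSV with columns "
                "male_id, angle_class, measured_angle_deg, female_genotype, mating_days, "
                "copulated, offspring"
            )

    calls: dict[str, object] = {}
    if config.run_detect:
        for assay_id, _, rec, _log in assays:
            if rec is None:
                continue
            call, _volume = detect_assay(
                rec,
                sampling_interval_s=config.sampling_interval_s,
                min_duration_s=config.min_copulation_s,
            )
            calls[assay_id] = call
            write_call(call, out / f"call_{assay_id}", assay_id=assay_id)

    per_assay_rows = []
    if config.run_metrics:
        for assay_id, group_label, _rec, log in assays:
            m = assay_metrics(
                log,
                call=calls.get(assay_id),
                initiation_window_s=config.initiation_window_s,
                assay_window_s=config.assay_window_s,
            )
            per_assay_rows.append(
                {
                    "assay_id": assay_id,
                    "group": group_label,
                    "latency_s": m.latency_s,
                    "ci_pct": m.courtship_index_pct,
                    "copulated": int(m.copulation_success),
                    "excluded_reason": m.excluded_reason or "",
                }
            )
        per_assay = pd.DataFrame(per_assay_rows)
        per_assay.to_csv(out / "per_assay_metrics.csv", index=False)
        report["per_assay"] = per_assay.to_dict(orient="records")

        if outcomes is not None:
            summary = summarize_groups(outcomes)
            summary.to_csv(out / "group_summaries.csv", index=False)
            report["group_summaries"] = summary.to_dict(orient="records")

    if config.run_stats and outcomes is not None:
        tests = []
        # reproduction: small-deviation classes vs each high-deviation class
        cls_tab = outcomes[outcomes["angle_class"] != "normal"]
        for genotype, sub in cls_tab.groupby("female_genotype", sort=True):
            agg = sub.groupby("angle_class", observed=True)["offspring"].agg(["sum", "count"])
            small = [c for c in ("0°", "Right 45°", "Left 45°") if c in agg.index]
            high = [c for c in agg.index if c not in small]
            if small and high:
                s = agg.loc[small]
                h = agg.loc[high]
                tests.append(
                    fisher_exact_from_counts(
                        int(s["sum"].sum()), int(s["count"].sum()),
                        int(h["sum"].sum()), int(h["count"].sum()),
                        groups=(f"{genotype}:small_deviation", f"{genotype}:high_deviation"),
                    )
                )
        # latency / CI group comparisons on the simulated assays
        if per_assay_rows:
            per_assay = pd.DataFrame(per_assay_rows)
            usable = per_assay[per_assay["excluded_reason"] == ""]
            lat_groups = {
                lbl: sub["latency_s"].dropna().to_numpy()
                for lbl, sub in usable.groupby("group", sort=True)
            }
            lat_groups = {k: v for k, v in lat_groups.items() if len(v) >= 2}
            if len(lat_groups) >= 2:
                tests.append(kruskal_wallis(lat_groups))
                if len(lat_groups) >= 3:
                    tests.extend(steel_dwass(lat_groups))
                ci_groups = {
                    lbl: sub["ci_pct"].dropna().to_numpy()
                    for lbl, sub in usable.groupby("group", sort=True)
                }
                ci_groups = {
                    k: v for k, v in ci_groups.items() if len(v) >= 2 and np.ptp(v) > 0
                }
                if len(ci_groups) >= 2:
                    omnibus, pairwise = anova_tukey(ci_groups)
                    tests.append(omnibus)
                    tests.extend(pairwise)
        tdf = results_frame(tests)
        tdf.to_csv(out / "test_results.csv", index=False)
        report["tests"] = tdf.to_dict(orient="records")

    report = _json_ready(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
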