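"""End-to-end orchestration: simulate -> QC -> classify -> mix -> report.

Every stage is a plain function over the library types; the CLI in
:mod:`synmix.cli` is a thin wrapper.  One seed in :class:`RunConfig` fixes
every number in the final report, and no cell is silently dropped: counts in
equal counts out plus the listed exclusions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassificationParams, classify_recording
from .errors import ParameterError
from .mixing import DEFAULT_S_GRID, sweep_segregation
from .qc import QCThresholds, qc_experiment
from .stats import f_test_variance, ks_two_sample, shapiro_wilk, t_two_sample
from .synth import (
    DEFAULT_OUTCOME_PROBS,
    ExperimentRecording,
    GeneratorParams,
    ProtocolParams,
    generate_ecs_dataset,
    generate_scs_database,
    read_connections,
    read_recordings,
    write_connections,
    write_recordings,
)

log = logging.getLogger("synmix")

# Printed outcome compositions of the two ECS datasets:
# (outcome, count, group mean delta %, group SD %)
BICUCULLINE_COMPOSITION = [
    ("LTP", 7, 39.9, 14.7),
    ("LTD", 9, -38.5, 20.4),
    ("NC", 10, -3.0, 7.6),
]
# The control dataset's plastic cells (1 LTP, 3 LTD of 28) have no printed
# group statistics; they are given well-separated +/-30% effects and NC cells
# a null effect.
CONTROL_COMPOSITION = [
    ("LTP", 1, 30.0, 0.0),
    ("LTD", 3, -30.0, 0.0),
    ("NC", 24, 0.0, 0.0),
]


@dataclass
class RunConfig:
    seed: int = 0
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    qc: QCThresholds = field(default_factory=QCThresholds)
    classify: ClassificationParams = field(default_factory=ClassificationParams)
    control_composition: list = field(default_factory=lambda: list(CONTROL_COMPOSITION))
    bicuculline_composition: list = field(
        default_factory=lambda: list(BICUCULLINE_COMPOSITION)
    )
    scs_n: int = 43
    scs_outcome_probs: tuple = DEFAULT_OUTCOME_PROBS
    stop_threshold_pa: float = 350.0
    n_scr: int = 26
    s_grid: tuple = DEFAULT_S_GRID
    output_dir: str = "synmix_out"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key, typ in (
            ("protocol", ProtocolParams),
            ("generator", GeneratorParams),
            ("qc", QCThresholds),
            ("classify", ClassificationParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # hash of the scientific parameters only; where outputs land is not
        # part of a run's identity
        d = self.to_dict()
        d.pop("output_dir", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _seeded(config: RunConfig, offset: int) -> int:
    # stable per-stage substreams from the one run seed
    return int(np.random.SeedSequence([config.seed, offset]).generate_state(1)[0] % (2**31))


def simulate(config: RunConfig, out_dir: str | Path | None = None) -> dict[str, Path]:
    """Write the synthetic control + bicuculline datasets and SCS database."""
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for offset, (name, composition, clamp) in enumerate(
        (
            ("control", config.control_composition, config.protocol.clamp_mode),
            ("bicuculline", config.bicuculline_composition, "V-clamp"),
        ),
        start=1,
    ):
        gen = dataclasses.replace(config.generator, seed=_seeded(config, offset))
        protocol = dataclasses.replace(config.protocol, clamp_mode=clamp)
        recs = generate_ecs_dataset(
            [tuple(c) for c in composition], protocol, gen, condition=name
        )
        manifest = {
            "seed": gen.seed,
            "condition": name,
            "n_cells": len(recs),
            "generator": dataclasses.asdict(gen),
            "protocol": dataclasses.asdict(protocol),
            "config_hash": config.config_hash(),
        }
        paths[name] = write_recordings(recs, out / f"{name}.csv", manifest=manifest)
        log.info("simulate: wrote %d %s recordings -> %s", len(recs), name, paths[name])
    db = generate_scs_database(
        n=config.scs_n,
        outcome_probs=config.scs_outcome_probs,
        seed=_seeded(config, 3),
    )
    paths["scs_database"] = write_connections(db, out / "scs_database.csv")
    log.info("simulate: wrote %d-entry SCS database -> %s", len(db), paths["scs_database"])
    return paths


def analyze(
    recordings: Sequence[ExperimentRecording], config: RunConfig
) -> pd.DataFrame:
    """QC then classify every recording; QC-failed cells keep their row but
    are excluded from downstream statistics (``qc_passed`` False)."""
    if not recordings:
        raise ParameterError("empty dataset")
    rows = []
    for rec in recordings:
        report = qc_experiment(rec, config.qc)
        row = {
            "cell_id": rec.cell_id,
            "condition": rec.condition,
            "clamp_mode": rec.clamp_mode,
            "qc_passed": report.passed,
            "qc_failures": ";".join(report.failures),
        }
        if report.passed:
            res = classify_recording(rec, config.classify)
            row.update(
                n_pre=res.n_pre,
                n_post=res.n_post,
                pre_mean=res.pre_mean,
                post_mean=res.post_mean,
                delta_n_pct=res.delta_n_pct,
                p_value=res.p_value,
                label=res.label,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    n_fail = int((~df["qc_passed"]).sum())
    log.info("analyze: %d cells in, %d excluded by QC", len(df), n_fail)
    return df


def _condition_summary(df: pd.DataFrame) -> dict:
    kept = df[df["qc_passed"]]
    counts = kept["label"].value_counts().to_dict()
    deltas = kept["delta_n_pct"].to_numpy(dtype=float)
    return {
        "n_total": int(len(df)),
        "n_kept": int(len(kept)),
        "excluded": df.loc[~df["qc_passed"], "cell_id"].tolist(),
        "outcome_counts": {o: int(counts.get(o, 0)) for o in ("LTP", "LTD", "NC")},
        "delta_mean_pct": float(np.mean(deltas)) if deltas.size else float("nan"),
        "delta_sd_pct": float(np.std(deltas, ddof=1)) if deltas.size > 1 else float("nan"),
    }


def build_report(
    results: pd.DataFrame,
    config: RunConfig,
    *,
    scs_deltas=None,
    mixing_table: pd.DataFrame | None = None,
) -> dict:
    """Assemble the run-level report mirroring the analysis sequence:
    per-condition summaries, condition comparisons, distribution comparisons
    against the unitary (SCS) changes, and the segregation sweep table."""
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "synmix_version": __version__,
        },
        "conditions": {},
        "comparisons": {},
    }
    kept = results[results["qc_passed"]]
    by_cond = {c: g for c, g in results.groupby("condition")}
    for cond, g in by_cond.items():
        report["conditions"][cond] = _condition_summary(g)

    conds = sorted(by_cond)
    if len(conds) == 2:
        a, b = (
            kept.loc[kept["condition"] == conds[0], "delta_n_pct"].to_numpy(),
            kept.loc[kept["condition"] == conds[1], "delta_n_pct"].to_numpy(),
        )
        if a.size >= 3 and b.size >= 3:
            report["comparisons"] = {
                "pair": conds,
                "shapiro": [shapiro_wilk(a).to_dict(), shapiro_wilk(b).to_dict()],
                "t_means": t_two_sample(a, b).to_dict(),
                "f_variances": f_test_variance(a, b).to_dict(),
            }
    if scs_deltas is not None:
        scs = np.asarray(scs_deltas, dtype=float)
        report["scs_vs_ecs_ks"] = {
            cond: ks_two_sample(
                scs, kept.loc[kept["condition"] == cond, "delta_n_pct"].to_numpy()
            ).to_dict()
            for cond in conds
            if (kept["condition"] == cond).sum() >= 2
        }
    if mixing_table is not None:
        report["segregation_sweep"] = mixing_table.to_dict(orient="records")
    return report


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Full run: simulate both datasets and the SCS database, QC + classify,
    sweep the segregation parameter against the bicuculline reference, and
    write per-cell results, the S-table and the JSON report."""
    out = Path(out_dir or config.output_dir)
    paths = simulate(config, out)
    recs = read_recordings(paths["control"]) + read_recordings(paths["bicuculline"])
    results = analyze(recs, config)
    results.to_csv(out / "per_cell_results.csv", index=False)

    db = read_connections(paths["scs_database"])
    kept = results[results["qc_passed"]]
    reference = kept.loc[kept["condition"] == "bicuculline", "delta_n_pct"].to_numpy()
    table = sweep_segregation(
        db,
        reference,
        s_grid=config.s_grid,
        n_scr=config.n_scr,
        stop_threshold_pa=config.stop_threshold_pa,
        outcome_probs=config.scs_outcome_probs,
        seed=_seeded(config, 4),
    )
    table.to_csv(out / "segregation_sweep.csv", index=False)

    scs_deltas = db.to_frame()["delta_n_pct"].to_numpy()
    report = build_report(results, config, scs_deltas=scs_deltas, mixing_table=table)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    log.info("pipeline: report written to %s", out / "report.json")
    return report
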