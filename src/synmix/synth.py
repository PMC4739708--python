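"""Synthetic electrophysiology data with the structure the pipeline assumes.

Two kinds of objects are generated:

* **ECS experiments** — sweep time series for extracellular-stimulation
  pairing experiments: a 120-sweep baseline at 0.2 Hz, a pairing epoch of 60
  events at 0.1 Hz during which no test responses are collected, and a
  120-sweep post-pairing test epoch at 0.2 Hz.  Baseline amplitudes sit
  around a target response size (~375 pA under voltage clamp, ~4 mV under
  current clamp) with multiplicative Gaussian sweep noise; the post epoch is
  scaled by a per-cell ground-truth plasticity effect.
* **SCS connection databases** — tables of unitary single-cell-stimulation
  connections with pre/post-pairing strengths and an LTP/LTD/NC outcome
  label, used by the input-mixing Monte Carlo.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, SchemaError

OUTCOMES = ("LTP", "LTD", "NC")

#: classification boundary (percent change) separating plastic from NC cells
PLASTICITY_BOUNDARY_PCT = 15.0

RECORDING_COLUMNS = [
    "cell_id",
    "condition",
    "clamp_mode",
    "epoch",
    "time_s",
    "amplitude",
    "unit",
    "ra_mohm",
    "vm_mv",
    "ri_mohm",
]

CONNECTION_COLUMNS = [
    "conn_id",
    "strength_pre_pa",
    "strength_post_pa",
    "outcome",
    "delta_n_pct",
]


@dataclass(frozen=True)
class ProtocolParams:
    """Timing constants of the pairing protocol.

    The pairing itself is not simulated at the biophysical level; the pairing
    epoch only partitions the recording into pre and post test epochs.
    """

    n_pre_sweeps: int = 120
    pre_rate_hz: float = 0.2
    n_pairings: int = 60
    pairing_rate_hz: float = 0.1
    post_lead_ms: float = 10.0
    n_ap_per_pairing: tuple[int, int] = (6, 9)
    n_post_sweeps: int = 120
    clamp_mode: str = "V-clamp"

    def __post_init__(self):
        if self.n_pre_sweeps <= 0 or self.n_pairings <= 0 or self.n_post_sweeps <= 0:
            raise ParameterError("all protocol counts must be > 0")
        if self.pre_rate_hz <= 0 or self.pairing_rate_hz <= 0:
            raise ParameterError("stimulation rates must be > 0")
        if self.post_lead_ms < 0:
            raise ParameterError("post_lead_ms must be >= 0")
        if self.clamp_mode not in ("V-clamp", "I-clamp"):
            raise ParameterError(f"unknown clamp_mode {self.clamp_mode!r}")

    @property
    def unit(self) -> str:
        return "pA" if self.clamp_mode == "V-clamp" else "mV"


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the sweep generator.

    ``baseline_mean=None`` resolves to the clamp-mode default target response
    (375 pA in V-clamp, 4 mV in I-clamp).  ``true_delta_pct`` is the
    ground-truth percent change applied to the post epoch; ``drift_slope``
    (amplitude units per test sweep) and ``ra_drift_pct`` create QC-failing
    cells when nonzero.
    """

    baseline_mean: float | None = None
    sweep_noise_cv: float = 0.10
    true_delta_pct: float = 0.0
    drift_slope: float = 0.0
    ra_initial_mohm: float = 12.0
    ra_drift_pct: float = 0.0
    vm_mv: float = -70.0
    input_resistance_mohm: float = 150.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_mean is not None and self.baseline_mean <= 0:
            raise ParameterError("baseline_mean must be > 0")
        if self.sweep_noise_cv < 0:
            raise ParameterError("sweep_noise_cv must be >= 0")
        if self.ra_initial_mohm <= 0:
            raise ParameterError("ra_initial_mohm must be > 0")

    def resolve_baseline(self, clamp_mode: str) -> float:
        if self.baseline_mean is not None:
            return self.baseline_mean
        return 375.0 if clamp_mode == "V-clamp" else 4.0


@dataclass
class ExperimentRecording:
    """One cell's sweep time series with epoch labels and QC fields.

    ``sweeps`` has columns ``time_s, amplitude, epoch``; pairing rows carry no
    amplitude (NaN) — the protocol does not test during pairing.  ``ra_series``
    has columns ``time_s, ra_mohm``.  ``true_delta_pct`` is generator ground
    truth (None for data read from external files).
    """

    cell_id: str
    condition: str
    clamp_mode: str
    sweeps: pd.DataFrame
    ra_series: pd.DataFrame
    vm_mv: float
    input_resistance_mohm: float
    true_delta_pct: float | None = None

    @property
    def unit(self) -> str:
        return "pA" if self.clamp_mode == "V-clamp" else "mV"

    def epoch_amplitudes(self, epoch: str) -> np.ndarray:
        sel = self.sweeps[self.sweeps["epoch"] == epoch]
        return sel["amplitude"].to_numpy(dtype=float)

    @property
    def pre(self) -> np.ndarray:
        return self.epoch_amplitudes("pre")

    @property
    def post(self) -> np.ndarray:
        return self.epoch_amplitudes("post")

    def pre_series(self) -> tuple[np.ndarray, np.ndarray]:
        sel = self.sweeps[self.sweeps["epoch"] == "pre"]
        return sel["time_s"].to_numpy(dtype=float), sel["amplitude"].to_numpy(dtype=float)


@dataclass(frozen=True)
class ConnectionEntry:
    """One unitary connection: pre/post-pairing strength and outcome label."""

    conn_id: str
    strength_pre_pa: float
    strength_post_pa: float
    outcome: str

    def __post_init__(self):
        if self.strength_pre_pa <= 0:
            raise ParameterError("strength_pre_pa must be > 0")
        if self.outcome not in OUTCOMES:
            raise ParameterError(f"unknown outcome {self.outcome!r}")

    @property
    def delta_n_pct(self) -> float:
        return 100.0 * (self.strength_post_pa - self.strength_pre_pa) / self.strength_pre_pa


@dataclass
class ConnectionDatabase:
    """A set of unitary connections sampled by the mixing Monte Carlo."""

    entries: list[ConnectionEntry]
    provenance: str = ""

    def __post_init__(self):
        if not self.entries:
            raise ParameterError("connection database must be non-empty")

    def __len__(self) -> int:
        return len(self.entries)

    def by_outcome(self) -> dict[str, list[ConnectionEntry]]:
        groups: dict[str, list[ConnectionEntry]] = {o: [] for o in OUTCOMES}
        for e in self.entries:
            groups[e.outcome].append(e)
        return groups

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "conn_id": [e.conn_id for e in self.entries],
                "strength_pre_pa": [e.strength_pre_pa for e in self.entries],
                "strength_post_pa": [e.strength_post_pa for e in self.entries],
                "outcome": [e.outcome for e in self.entries],
                "delta_n_pct": [e.delta_n_pct for e in self.entries],
            }
        )


def _class_bounds(outcome: str) -> tuple[float, float]:
    b = PLASTICITY_BOUNDARY_PCT
    if outcome == "LTP":
        return b, np.inf
    if outcome == "LTD":
        return -np.inf, -b
    return -b, b


def _draw_class_deltas(
    outcome: str, mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ground-truth percent changes truncated to the outcome's class.

    The printed group means/SDs describe cells *after* classification, so the
    generating distribution must respect the class definition: LTP draws stay
    above +15%, LTD below -15%, NC within +/-15%.
    """
    lo, hi = _class_bounds(outcome)
    if sd < 0:
        raise ParameterError("group delta SD must be >= 0")
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ParameterError(
                f"fixed delta {mean}% is outside the {outcome} class bounds ({lo}, {hi})"
            )
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    if stats.norm.cdf(b) - stats.norm.cdf(a) <= 0:
        raise ParameterError(f"delta model ({mean}, {sd}) has no mass in the {outcome} class")
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_experiment(
    protocol: ProtocolParams,
    gen: GeneratorParams,
    *,
    rng: np.random.Generator | None = None,
    cell_id: str = "cell-000",
    condition: str = "control",
) -> ExperimentRecording:
    """Simulate one ECS pairing experiment as a sweep time series.

    Pre-epoch amplitudes are i.i.d. around the baseline mean with the given
    coefficient of variation plus an optional linear drift; post-epoch
    amplitudes are scaled by ``(1 + true_delta_pct/100)``.  Epoch timing
    follows the protocol: each epoch starts one inter-stimulus interval after
    the previous epoch's last event.
    """
    if rng is None:
        rng = np.random.default_rng(gen.seed)
    baseline = gen.resolve_baseline(protocol.clamp_mode)

    pre_isi = 1.0 / protocol.pre_rate_hz
    pair_isi = 1.0 / protocol.pairing_rate_hz
    t_pre = np.arange(protocol.n_pre_sweeps) * pre_isi
    t_pair = t_pre[-1] + pre_isi + np.arange(protocol.n_pairings) * pair_isi
    t_post = t_pair[-1] + pair_isi + np.arange(protocol.n_post_sweeps) * pre_isi

    n_pre, n_post = protocol.n_pre_sweeps, protocol.n_post_sweeps
    noise = rng.normal(0.0, gen.sweep_noise_cv, size=n_pre + n_post)
    test_idx = np.arange(n_pre + n_post)
    post_mean = baseline * (1.0 + gen.true_delta_pct / 100.0)
    amp = np.concatenate(
        [
            baseline * (1.0 + noise[:n_pre]),
            post_mean * (1.0 + noise[n_pre:]),
        ]
    ) + gen.drift_slope * test_idx

    sweeps = pd.DataFrame(
        {
            "time_s": np.concatenate([t_pre, t_pair, t_post]),
            "amplitude": np.concatenate(
                [amp[:n_pre], np.full(protocol.n_pairings, np.nan), amp[n_pre:]]
            ),
            "epoch": (
                ["pre"] * n_pre + ["pairing"] * protocol.n_pairings + ["post"] * n_post
            ),
        }
    )

    t_test = np.concatenate([t_pre, t_post])
    total_t = t_post[-1] if t_post[-1] > 0 else 1.0
    ra = gen.ra_initial_mohm * (1.0 + gen.ra_drift_pct / 100.0 * t_test / total_t)
    ra_series = pd.DataFrame({"time_s": t_test, "ra_mohm": ra})

    return ExperimentRecording(
        cell_id=cell_id,
        condition=condition,
        clamp_mode=protocol.clamp_mode,
        sweeps=sweeps,
        ra_series=ra_series,
        vm_mv=gen.vm_mv,
        input_resistance_mohm=gen.input_resistance_mohm,
        true_delta_pct=gen.true_delta_pct,
    )


def generate_ecs_dataset(
    composition: Sequence[tuple[str, int, float, float]],
    protocol: ProtocolParams,
    gen: GeneratorParams,
    *,
    condition: str = "control",
) -> list[ExperimentRecording]:
    """Generate a count-exact ECS dataset from a per-outcome composition.

    ``composition`` is a list of ``(outcome, count, group_mean_delta_pct,
    group_sd_delta_pct)``; each experiment's ground-truth effect is drawn from
    the group distribution truncated at the +/-15% class boundary so that the
    generated labels are recoverable by the classifier.
    """
    if not composition:
        raise ParameterError("composition must be non-empty")
    rng = np.random.default_rng(gen.seed)
    recordings: list[ExperimentRecording] = []
    for outcome, count, mean, sd in composition:
        if outcome not in OUTCOMES:
            raise ParameterError(f"unknown outcome {outcome!r}")
        if count < 0:
            raise ParameterError("composition counts must be >= 0")
        deltas = _draw_class_deltas(outcome, mean, sd, count, rng)
        children = rng.spawn(count)
        for k, (delta, child) in enumerate(zip(deltas, children)):
            gen_k = dataclasses.replace(gen, true_delta_pct=float(delta))
            recordings.append(
                generate_experiment(
                    protocol,
                    gen_k,
                    rng=child,
                    cell_id=f"{condition}-{outcome}-{k:02d}",
                    condition=condition,
                )
            )
    return recordings


DEFAULT_OUTCOME_PROBS = (7.0 / 43.0, 18.0 / 43.0, 18.0 / 43.0)

# Unitary strength scale: compound responses of ~350 pA built from an average
# of ~18.05 inputs imply a mean unitary strength of 350/18.05 ~= 19.4 pA.
DEFAULT_STRENGTH_MODEL = (19.4, 6.0)

DEFAULT_GROUP_DELTA_MODELS: dict[str, tuple[float, float]] = {
    "LTP": (39.9, 14.7),
    "LTD": (-38.5, 20.4),
    "NC": (-3.0, 7.6),
}


def generate_scs_database(
    n: int = 43,
    outcome_probs: Sequence[float] = DEFAULT_OUTCOME_PROBS,
    strength_model: tuple[float, float] = DEFAULT_STRENGTH_MODEL,
    group_delta_models: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> ConnectionDatabase:
    """Generate a synthetic unitary-connection (SCS) database.

    Outcome labels are multinomial with ``outcome_probs`` (default: the
    empirical LTP/LTD/NC class frequencies 7/43, 18/43, 18/43); pre-pairing
    strengths come from a positive-truncated normal ``strength_model``; the
    post-pairing strength applies a class-truncated group effect.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    probs = np.asarray(outcome_probs, dtype=float)
    if probs.shape != (3,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ParameterError("outcome_probs must be 3 non-negative values summing to 1")
    mean_pa, sd_pa = strength_model
    if mean_pa <= 0 or sd_pa < 0:
        raise ParameterError("strength model mean must be > 0 and SD >= 0")
    models = dict(DEFAULT_GROUP_DELTA_MODELS)
    if group_delta_models:
        models.update(group_delta_models)
    # fail fast on impossible models for any class that can actually be drawn
    rng_probe = np.random.default_rng(0)
    for o, p in zip(OUTCOMES, probs):
        if p > 0:
            _draw_class_deltas(o, *models[o], size=0, rng=rng_probe)

    rng = np.random.default_rng(seed)
    labels = rng.choice(OUTCOMES, size=n, p=probs)
    if sd_pa == 0:
        strengths = np.full(n, float(mean_pa))
    else:
        a = (0.0 - mean_pa) / sd_pa
        strengths = stats.truncnorm.rvs(
            a, np.inf, loc=mean_pa, scale=sd_pa, size=n, random_state=rng
        )
    entries = []
    for i, (label, s_pre) in enumerate(zip(labels, strengths)):
        delta = float(_draw_class_deltas(label, *models[label], size=1, rng=rng)[0])
        entries.append(
            ConnectionEntry(
                conn_id=f"scs-{i:03d}",
                strength_pre_pa=float(s_pre),
                strength_post_pa=float(s_pre) * (1.0 + delta / 100.0),
                outcome=str(label),
            )
        )
    return ConnectionDatabase(entries=entries, provenance=f"synthetic (seed={seed}, n={n})")


# ---------------------------------------------------------------------------
# CSV round-trip


def recordings_to_frame(recordings: Sequence[ExperimentRecording]) -> pd.DataFrame:
    """Flatten recordings into the long-format sweep table."""
    frames = []
    for rec in recordings:
        df = rec.sweeps.copy()
        ra = rec.ra_series.set_index("time_s")["ra_mohm"]
        df["ra_mohm"] = df["time_s"].map(ra)
        df.insert(0, "cell_id", rec.cell_id)
        df.insert(1, "condition", rec.condition)
        df.insert(2, "clamp_mode", rec.clamp_mode)
        df["unit"] = rec.unit
        df["vm_mv"] = rec.vm_mv
        df["ri_mohm"] = rec.input_resistance_mohm
        frames.append(df[RECORDING_COLUMNS])
    return pd.concat(frames, ignore_index=True)


def write_recordings(
    recordings: Sequence[ExperimentRecording],
    csv_path: str | Path,
    *,
    manifest: dict | None = None,
) -> Path:
    csv_path = Path(csv_path)
    recordings_to_frame(recordings).to_csv(csv_path, index=False)
    if manifest is not None:
        manifest_path = csv_path.with_suffix(".manifest.json")
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return csv_path


def read_recordings(csv_path: str | Path) -> list[ExperimentRecording]:
    df = pd.read_csv(csv_path)
    missing = set(RECORDING_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"recording CSV missing columns: {sorted(missing)}")
    recordings = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("time_s")
        test = g[g["epoch"] != "pairing"]
        recordings.append(
            ExperimentRecording(
                cell_id=str(cell_id),
                condition=str(g["condition"].iloc[0]),
                clamp_mode=str(g["clamp_mode"].iloc[0]),
                sweeps=g[["time_s", "amplitude", "epoch"]].reset_index(drop=True),
                ra_series=test[["time_s", "ra_mohm"]].reset_index(drop=True),
                vm_mv=float(g["vm_mv"].iloc[0]),
                input_resistance_mohm=float(g["ri_mohm"].iloc[0]),
            )
        )
    return recordings


def write_connections(db: ConnectionDatabase, csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    db.to_frame().to_csv(csv_path, index=False)
    return csv_path


def read_connections(csv_path: str | Path) -> ConnectionDatabase:
    df = pd.read_csv(csv_path)
    missing = set(CONNECTION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"connection CSV missing columns: {sorted(missing)}")
    entries = [
        ConnectionEntry(
            conn_id=str(r.conn_id),
            strength_pre_pa=float(r.strength_pre_pa),
            strength_post_pa=float(r.strength_post_pa),
            outcome=str(r.outcome),
        )
        for r in df.itertuples(index=False)
    ]
    return ConnectionDatabase(entries=entries, provenance=f"read from {csv_path}")
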