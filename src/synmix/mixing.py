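"""Simulated compound responses (SCRs) by Monte Carlo mixing of unitary inputs.

An SCR models an extracellularly evoked compound response as a sum of
unitary connections drawn from a single-cell-stimulation (SCS) database:
connections are sampled sequentially until their combined pre-pairing
strength reaches 350 pA (the typical compound response size), then the same
connections' post-pairing strengths are summed and the normalized change
Delta_N = 100 * (SCR_post - SCR_pre) / SCR_pre is recorded.

A segregation parameter S in [0, 1] biases sampling by plasticity class:
after an unbiased first draw, each subsequent connection matches the first
draw's outcome class with probability S and is otherwise drawn from the
marginal class frequencies.  S = 0 is fully random mixing; S = 1 builds
every SCR from a single plasticity class.  P(same class as first) is
therefore S + (1 - S) * p(first class), linear in S.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ClassExhaustedError, ParameterError
from .stats import f_test_variance
from .synth import OUTCOMES, ConnectionDatabase, ConnectionEntry, DEFAULT_OUTCOME_PROBS


@dataclass(frozen=True)
class MixingParams:
    stop_threshold_pa: float = 350.0
    n_scr: int = 26
    segregation_s: float = 0.0
    outcome_probs: tuple[float, float, float] = DEFAULT_OUTCOME_PROBS
    replacement: str = "with"  # or "without_within_scr"
    seed: int = 0

    def __post_init__(self):
        if self.stop_threshold_pa <= 0:
            raise ParameterError("stop_threshold_pa must be > 0")
        if self.n_scr < 1:
            raise ParameterError("n_scr must be >= 1")
        if not (0.0 <= self.segregation_s <= 1.0):
            raise ParameterError("segregation_s must be in [0, 1]")
        p = np.asarray(self.outcome_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ParameterError("outcome_probs must be 3 non-negative values summing to 1")
        if self.replacement not in ("with", "without_within_scr"):
            raise ParameterError(f"unknown replacement mode {self.replacement!r}")


@dataclass
class SCRSample:
    member_ids: list[str]
    scr_pre_pa: float
    scr_post_pa: float
    delta_n_pct: float
    n_inputs: int
    first_outcome: str
    homogeneous: bool


@dataclass
class MixingRunResult:
    params: MixingParams
    samples: list[SCRSample]

    @property
    def deltas(self) -> np.ndarray:
        return np.array([s.delta_n_pct for s in self.samples])

    @property
    def variance(self) -> float:
        return float(np.var(self.deltas, ddof=1))

    @property
    def mean(self) -> float:
        return float(np.mean(self.deltas))

    @property
    def n_inputs_summary(self) -> tuple[float, float]:
        n = np.array([s.n_inputs for s in self.samples], dtype=float)
        return float(n.mean()), float(n.std(ddof=1)) if n.size > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scr_id": np.arange(len(self.samples)),
                "s": self.params.segregation_s,
                "n_inputs": [s.n_inputs for s in self.samples],
                "scr_pre_pa": [s.scr_pre_pa for s in self.samples],
                "scr_post_pa": [s.scr_post_pa for s in self.samples],
                "delta_n_pct": [s.delta_n_pct for s in self.samples],
                "first_outcome": [s.first_outcome for s in self.samples],
                "homogeneous": [s.homogeneous for s in self.samples],
            }
        )


def draw_outcome(
    first_outcome: str | None,
    s: float,
    outcome_probs: Sequence[float],
    rng: np.random.Generator,
) -> str:
    """Draw one connection's outcome class.

    The first draw of an SCR (``first_outcome=None``) is always unbiased.
    Later draws return the first draw's class with probability ``s`` and fall
    back to the marginal class frequencies otherwise, so
    P(same class) = s + (1 - s) * p(first class).
    """
    if not (0.0 <= s <= 1.0):
        raise ParameterError("segregation parameter must be in [0, 1]")
    if first_outcome is not None and first_outcome not in OUTCOMES:
        raise ParameterError(f"unknown outcome {first_outcome!r}")
    if first_outcome is not None and rng.random() < s:
        return first_outcome
    cum = np.cumsum(outcome_probs)
    return OUTCOMES[int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))]


def draw_outcomes(
    first_outcome: str,
    s: float,
    outcome_probs: Sequence[float],
    rng: np.random.Generator,
    size: int,
) -> np.ndarray:
    """Vectorized :func:`draw_outcome` for non-first draws (Monte Carlo checks)."""
    if not (0.0 <= s <= 1.0):
        raise ParameterError("segregation parameter must be in [0, 1]")
    if first_outcome not in OUTCOMES:
        raise ParameterError(f"unknown outcome {first_outcome!r}")
    cum = np.cumsum(np.asarray(outcome_probs, dtype=float))
    marginal = np.searchsorted(cum, rng.random(size) * cum[-1], side="right")
    same = rng.random(size) < s
    idx = np.where(same, OUTCOMES.index(first_outcome), marginal)
    return np.asarray(OUTCOMES, dtype=object)[idx]


def build_scr(
    db: ConnectionDatabase,
    params: MixingParams,
    rng: np.random.Generator,
) -> SCRSample:
    """Build one simulated compound response by sequential sampling.

    Outcome classes are drawn via :func:`draw_outcome` and a member is then
    drawn uniformly within the class (with replacement by default).  Sampling
    stops at the first draw bringing the cumulative pre-pairing strength to
    the stop threshold, so SCR_pre >= threshold and removing the last member
    would fall below it.
    """
    groups = db.by_outcome()
    for o, p in zip(OUTCOMES, params.outcome_probs):
        if p > 0 and not groups[o]:
            raise ParameterError(f"outcome class {o!r} has probability > 0 but no entries")

    without = params.replacement == "without_within_scr"
    pools = {o: list(v) for o, v in groups.items()} if without else groups
    members: list[ConnectionEntry] = []
    first_outcome: str | None = None
    total_pre = 0.0
    while total_pre < params.stop_threshold_pa:
        outcome = draw_outcome(first_outcome, params.segregation_s, params.outcome_probs, rng)
        pool = pools[outcome]
        if not pool:
            raise ClassExhaustedError(outcome)
        idx = int(rng.integers(len(pool)))
        entry = pool.pop(idx) if without else pool[idx]
        if first_outcome is None:
            first_outcome = entry.outcome
        members.append(entry)
        total_pre += entry.strength_pre_pa

    scr_pre = sum(m.strength_pre_pa for m in members)
    scr_post = sum(m.strength_post_pa for m in members)
    return SCRSample(
        member_ids=[m.conn_id for m in members],
        scr_pre_pa=scr_pre,
        scr_post_pa=scr_post,
        delta_n_pct=100.0 * (scr_post - scr_pre) / scr_pre,
        n_inputs=len(members),
        first_outcome=first_outcome,
        homogeneous=all(m.outcome == first_outcome for m in members),
    )


def run_mixing(
    db: ConnectionDatabase,
    params: MixingParams,
    rng: np.random.Generator | None = None,
) -> MixingRunResult:
    """Build ``n_scr`` independent SCRs from one seeded stream."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    samples = [build_scr(db, params, rng) for _ in range(params.n_scr)]
    return MixingRunResult(params=params, samples=samples)


DEFAULT_S_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


def sweep_segregation(
    db: ConnectionDatabase,
    reference_deltas,
    *,
    s_grid: Sequence[float] = DEFAULT_S_GRID,
    n_scr: int = 26,
    stop_threshold_pa: float = 350.0,
    outcome_probs: Sequence[float] = DEFAULT_OUTCOME_PROBS,
    replacement: str = "with",
    seed: int = 0,
) -> pd.DataFrame:
    """Run the mixing simulation over a grid of segregation values.

    For each S the variance of the SCR Delta_N distribution is compared to
    the variance of ``reference_deltas`` (typically the per-cell Delta_N of
    the ECS experiments) with the two-sided variance F-test.  Returns one row
    per S: ``s, mean, variance, n_inputs_mean, n_inputs_sd, f_statistic,
    p_value, variance_lower``.
    """
    ref = np.asarray(reference_deltas, dtype=float)
    if ref.size < 2:
        raise ParameterError("need >= 2 reference deltas")
    rng = np.random.default_rng(seed)
    rows = []
    for s in s_grid:
        params = MixingParams(
            stop_threshold_pa=stop_threshold_pa,
            n_scr=n_scr,
            segregation_s=float(s),
            outcome_probs=tuple(outcome_probs),
            replacement=replacement,
            seed=seed,
        )
        run = run_mixing(db, params, rng=rng)
        test = f_test_variance(run.deltas, ref)
        n_mean, n_sd = run.n_inputs_summary
        rows.append(
            {
                "s": float(s),
                "mean": run.mean,
                "variance": run.variance,
                "n_inputs_mean": n_mean,
                "n_inputs_sd": n_sd,
                "f_statistic": test.statistic,
                "p_value": test.p_value,
                "variance_lower": bool(run.variance < np.var(ref, ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def between_class_variance(
    db: ConnectionDatabase, outcome_probs: Sequence[float] = DEFAULT_OUTCOME_PROBS
) -> float:
    """Analytic large-input limit of Var(SCR Delta_N) at S = 1.

    At S = 1 every SCR draws all members from the first draw's class, so with
    many inputs its Delta_N concentrates at the class's strength-weighted mean
    change 100 * (sum post - sum pre) / sum pre.  The S = 1 variance therefore
    approaches the between-class variance of these class means under the
    first-draw probabilities.
    """
    groups = db.by_outcome()
    probs = np.asarray(outcome_probs, dtype=float)
    means = np.zeros(3)
    for i, o in enumerate(OUTCOMES):
        if probs[i] == 0:
            continue
        if not groups[o]:
            raise ParameterError(f"outcome class {o!r} has probability > 0 but no entries")
        pre = sum(e.strength_pre_pa for e in groups[o])
        post = sum(e.strength_post_pa for e in groups[o])
        means[i] = 100.0 * (post - pre) / pre
    grand = float(np.dot(probs, means))
    return float(np.dot(probs, (means - grand) ** 2))
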