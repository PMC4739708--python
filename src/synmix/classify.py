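"""Two-criterion plasticity classification of pre/post sweep amplitudes.

An experiment is called LTP (LTD) only if the normalized strength change
Delta_N = 100 * (post_mean - pre_mean) / pre_mean strictly exceeds +15%
(falls below -15%) **and** the pre-vs-post two-sample t-test is significant
at alpha = 0.05; everything else is NC.  Significance alone is not
plasticity, and a large but noisy change is not plasticity either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError
from .stats import t_two_sample
from .synth import ExperimentRecording


@dataclass(frozen=True)
class ClassificationParams:
    plasticity_threshold_pct: float = 15.0
    alpha: float = 0.05
    test_variant: str = "student"  # or "welch"
    tails: str = "two"

    def __post_init__(self):
        if self.plasticity_threshold_pct <= 0:
            raise ParameterError("plasticity threshold must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError("alpha must be in (0, 1)")
        if self.test_variant not in ("student", "welch"):
            raise ParameterError(f"unknown test_variant {self.test_variant!r}")
        if self.tails != "two":
            raise ParameterError("only two-tailed tests are supported")


@dataclass
class ClassificationResult:
    delta_n_pct: float
    p_value: float
    label: str
    pre_mean: float
    post_mean: float
    n_pre: int
    n_post: int

    def to_dict(self) -> dict:
        return {
            "delta_n_pct": self.delta_n_pct,
            "p_value": self.p_value,
            "label": self.label,
            "pre_mean": self.pre_mean,
            "post_mean": self.post_mean,
            "n_pre": self.n_pre,
            "n_post": self.n_post,
        }


def delta_n(pre_mean: float, post_mean: float) -> float:
    """Normalized strength change, in percent of the pre-pairing mean."""
    if pre_mean <= 0:
        raise ParameterError("pre_mean must be > 0")
    return 100.0 * (post_mean - pre_mean) / pre_mean


def _label(delta: float, p: float, params: ClassificationParams) -> str:
    thr = params.plasticity_threshold_pct
    if p < params.alpha and delta > thr:
        return "LTP"
    if p < params.alpha and delta < -thr:
        return "LTD"
    return "NC"


def classify_plasticity(
    pre_amplitudes,
    post_amplitudes,
    params: ClassificationParams = ClassificationParams(),
) -> ClassificationResult:
    """Classify one experiment from its pre and post epoch amplitudes.

    Amplitudes are compared on their absolute value so inward-current (pA,
    negative) and depolarizing-potential (mV, positive) conventions classify
    identically.
    """
    pre = np.abs(np.asarray(pre_amplitudes, dtype=float))
    post = np.abs(np.asarray(post_amplitudes, dtype=float))
    if pre.size < 2 or post.size < 2:
        raise InsufficientDataError("need >= 2 amplitudes in each epoch")
    test = t_two_sample(pre, post, equal_var=(params.test_variant == "student"))
    d = delta_n(float(pre.mean()), float(post.mean()))
    return ClassificationResult(
        delta_n_pct=d,
        p_value=test.p_value,
        label=_label(d, test.p_value, params),
        pre_mean=float(pre.mean()),
        post_mean=float(post.mean()),
        n_pre=pre.size,
        n_post=post.size,
    )


def classify_recording(
    rec: ExperimentRecording, params: ClassificationParams = ClassificationParams()
) -> ClassificationResult:
    return classify_plasticity(rec.pre, rec.post, params)


def bin_timeplot(
    sweeps: pd.DataFrame, bin_s: float = 60.0, *, normalize_to: str = "pre"
) -> pd.DataFrame:
    """Minute-average timeplot normalized to the pre-epoch mean.

    Returns one row per time bin with the bin's mean and SEM of normalized
    amplitude and the dominant epoch label.  Pairing rows (no amplitude) are
    excluded.  With the default protocol (0.2 Hz, 60 s bins) each pre-epoch
    bin averages 12 sweeps and the pre-epoch normalized mean is 1 by
    construction.
    """
    if bin_s <= 0:
        raise ParameterError("bin_s must be > 0")
    if sweeps.empty:
        raise InsufficientDataError("no sweeps to bin")
    df = sweeps.dropna(subset=["amplitude"]).copy()
    pre = df[df["epoch"] == normalize_to]
    if pre.empty:
        raise InsufficientDataError(f"no {normalize_to!r} epoch sweeps to normalize to")
    base = pre["amplitude"].abs().mean()
    df["norm"] = df["amplitude"].abs() / base
    df["bin"] = (df["time_s"] // bin_s).astype(int)
    out = (
        df.groupby("bin")
        .agg(
            time_s=("time_s", "mean"),
            epoch=("epoch", lambda e: e.mode().iloc[0]),
            mean=("norm", "mean"),
            sem=("norm", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0),
            n=("norm", "size"),
        )
        .reset_index()
    )
    return out
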