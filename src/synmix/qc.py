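"""Recording-quality exclusions for whole-cell pairing experiments.

A recording is kept only if all five checks pass:

* membrane potential more negative than -60 mV;
* access resistance (Ra) never above 40 MOhm;
* Ra never above 20% of the cell's input resistance;
* Ra drift over the recording at most 20% of the first reading;
* no significant linear trend in the pre-pairing baseline (OLS slope test,
  p >= 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, MissingDataError, ParameterError
from .synth import ExperimentRecording

FAILURE_CODES = ("ra_absolute", "ra_relative", "ra_drift", "vm", "baseline_trend")


@dataclass(frozen=True)
class QCThresholds:
    max_ra_mohm: float = 40.0
    max_ra_fraction_of_ri: float = 0.20
    max_ra_drift: float = 0.20
    max_vm_mv: float = -60.0  # Vm must be more negative than this
    baseline_trend_alpha: float = 0.05

    def __post_init__(self):
        for v in (self.max_ra_mohm, self.max_ra_fraction_of_ri, self.max_ra_drift):
            if not np.isfinite(v) or v <= 0:
                raise ParameterError("Ra thresholds must be finite and > 0")
        if not np.isfinite(self.max_vm_mv):
            raise ParameterError("max_vm_mv must be finite")
        if not (0.0 < self.baseline_trend_alpha < 1.0):
            raise ParameterError("baseline_trend_alpha must be in (0, 1)")


@dataclass
class QCReport:
    cell_id: str
    passed: bool
    failures: list[str] = field(default_factory=list)
    trend_p: float = float("nan")
    trend_slope: float = float("nan")
    ra_drift: float = float("nan")

    def __post_init__(self):
        assert self.passed == (not self.failures)


def baseline_stability(
    time_s, amplitude, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """OLS slope of baseline amplitude on time; stable when p >= alpha.

    Returns ``(slope, p_value, stable)``.  The p-value is the two-tailed test
    of slope != 0.  A perfectly constant baseline has zero slope and is
    stable by definition (its slope test is degenerate).
    """
    t = np.asarray(time_s, dtype=float)
    a = np.asarray(amplitude, dtype=float)
    if t.size != a.size:
        raise ParameterError("time and amplitude must have equal length")
    if t.size < 3:
        raise InsufficientDataError("baseline stability needs >= 3 sweeps")
    if np.ptp(a) == 0:
        return 0.0, 1.0, True
    res = stats.linregress(t, a)
    p = float(res.pvalue)
    if np.isnan(p):  # perfect fit: slope exactly explains the data
        p = 0.0 if res.slope != 0 else 1.0
    return float(res.slope), p, p >= alpha


def qc_experiment(
    rec: ExperimentRecording, th: QCThresholds = QCThresholds()
) -> QCReport:
    """Apply all five exclusion rules to one recording."""
    if rec.vm_mv is None or not np.isfinite(rec.vm_mv):
        raise MissingDataError(f"{rec.cell_id}: membrane potential missing")
    ra = np.asarray(rec.ra_series["ra_mohm"], dtype=float)
    if ra.size < 2 or np.any(~np.isfinite(ra)):
        raise MissingDataError(f"{rec.cell_id}: need >= 2 finite Ra readings")
    if not np.isfinite(rec.input_resistance_mohm) or rec.input_resistance_mohm <= 0:
        raise MissingDataError(f"{rec.cell_id}: input resistance missing")

    t_pre, a_pre = rec.pre_series()
    if a_pre.size < 3:
        raise InsufficientDataError(f"{rec.cell_id}: too few pre-epoch sweeps for QC")
    slope, trend_p, stable = baseline_stability(t_pre, a_pre, th.baseline_trend_alpha)

    failures = []
    if np.max(ra) > th.max_ra_mohm:
        failures.append("ra_absolute")
    if np.max(ra) > th.max_ra_fraction_of_ri * rec.input_resistance_mohm:
        failures.append("ra_relative")
    drift = abs(ra[-1] - ra[0]) / ra[0]
    if drift > th.max_ra_drift:
        failures.append("ra_drift")
    if rec.vm_mv > th.max_vm_mv:
        failures.append("vm")
    if not stable:
        failures.append("baseline_trend")

    return QCReport(
        cell_id=rec.cell_id,
        passed=not failures,
        failures=failures,
        trend_p=trend_p,
        trend_slope=slope,
        ra_drift=float(drift),
    )
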