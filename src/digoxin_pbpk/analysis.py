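"""PK metrics, fold-ratio validation, and local sensitivity analysis.

Metrics are deliberately simple: linear-trapezoid AUC(0–t), grid-maximum
Cmax, and the steady-state trough Cmin,ss detected from successive dosing
intervals.  Validation uses the observed/predicted ratio with the standard
0.5–2-fold acceptance band.  Sensitivity coefficients are dimensionless
relative derivatives estimated by central finite differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PKMetrics",
    "ValidationRecord",
    "SensitivityResult",
    "auc_0t",
    "auc_inf",
    "cmax",
    "cmin_ss",
    "pk_metrics",
    "fold_ratio",
    "local_sensitivity",
    "sensitivity_screen",
]

FOLD_BAND = (0.5, 2.0)


@dataclass(frozen=True)
class PKMetrics:
    auc_0t: float                   # ng·h/mL
    cmax: float                     # ng/mL
    tmax: float                     # h
    cmin_ss: float | None = None    # ng/mL
    steady_state_reached: bool = False

    def __post_init__(self) -> None:
        if self.auc_0t < 0:
            raise ValueError("auc_0t must be >= 0")
        if self.cmin_ss is not None and self.cmax < self.cmin_ss:
            raise ValueError("cmax must be >= cmin_ss")


@dataclass(frozen=True)
class ValidationRecord:
    regimen: str
    metric: str
    observed: float
    predicted: float
    ratio: float
    within_band: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        flag = "ok" if self.within_band else "OUT"
        return (f"{self.regimen} {self.metric}: obs={self.observed} "
                f"pred={self.predicted:.4g} ratio={self.ratio:.2f} [{flag}]")


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    output: str
    epsilon: float
    coefficient: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.coefficient):
            raise ValueError("sensitivity coefficient must be finite")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _as_profile(result_or_times, conc=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept a SimulationResult or explicit (times, conc) arrays."""
    if conc is None:
        return np.asarray(result_or_times.time, float), np.asarray(
            result_or_times.plasma_concentration, float
        )
    return np.asarray(result_or_times, float), np.asarray(conc, float)


def auc_0t(result, t_end: float, conc=None) -> float:
    """Linear trapezoidal AUC of plasma concentration on [0, t_end], ng·h/mL."""
    t, c = _as_profile(result, conc)
    if t.size == 0:
        raise ValueError("empty concentration profile")
    if t_end > t[-1] + 1e-9:
        raise ValueError(f"t_end={t_end} beyond simulated range {t[-1]}")
    mask = t <= t_end + 1e-12
    tt, cc = t[mask], c[mask]
    if tt[-1] < t_end - 1e-9:  # interpolate the endpoint
        c_end = np.interp(t_end, t, c)
        tt = np.append(tt, t_end)
        cc = np.append(cc, c_end)
    return float(np.trapezoid(cc, tt))


def auc_inf(result, conc=None, tail_fraction: float = 0.25) -> float:
    """AUC extrapolated to infinity: trapezoid plus log-linear tail C/λz."""
    t, c = _as_profile(result, conc)
    auc = float(np.trapezoid(c, t))
    n_tail = max(int(len(t) * tail_fraction), 4)
    tt, cc = t[-n_tail:], c[-n_tail:]
    pos = cc > 0
    if pos.sum() < 3:
        return auc
    slope = np.polyfit(tt[pos], np.log(cc[pos]), 1)[0]
    if slope >= 0:
        return auc
    return auc + float(c[-1] / (-slope))


def cmax(result, conc=None) -> tuple[float, float]:
    """(Cmax, tmax) from the profile grid."""
    t, c = _as_profile(result, conc)
    i = int(np.argmax(c))
    return float(c[i]), float(t[i])


def cmin_ss(
    result,
    dosing_interval: float,
    tolerance: float = 0.01,
    conc=None,
    first_dose_time: float = 0.0,
) -> tuple[float | None, bool]:
    """Steady-state trough: concentration at the end of a dosing interval once
    successive-interval troughs differ by less than ``tolerance`` (relative).

    Returns ``(trough, converged)``; if convergence is not reached by the end
    of the profile the last trough is returned with ``converged=False``.
    """
    t, c = _as_profile(result, conc)
    t_end = t[-1]
    trough_times = np.arange(
        first_dose_time + dosing_interval, t_end + 1e-9, dosing_interval
    )
    if trough_times.size < 2:
        raise ValueError("repeated-dose regimen required for Cmin,ss")
    # trough = concentration just before the next administration; take the
    # minimum over the tail of the interval so a sample carrying the
    # post-dose jump at exactly the dose time is never mistaken for it
    troughs = np.array([
        c[(t > tt - 0.25 * dosing_interval) & (t <= tt + 1e-9)].min()
        for tt in trough_times
    ])
    for i in range(1, len(troughs)):
        prev, cur = troughs[i - 1], troughs[i]
        if cur > 0 and abs(cur - prev) / cur < tolerance:
            return float(cur), True
    return float(troughs[-1]), False


def pk_metrics(
    result,
    t_end: float | None = None,
    dosing_interval: float | None = None,
    ss_tolerance: float = 0.01,
) -> PKMetrics:
    t = np.asarray(result.time)
    t_end = float(t[-1]) if t_end is None else t_end
    cm, tm = cmax(result)
    trough, converged = (None, False)
    if dosing_interval is not None:
        trough, converged = cmin_ss(result, dosing_interval, ss_tolerance)
    return PKMetrics(
        auc_0t=auc_0t(result, t_end),
        cmax=cm,
        tmax=tm,
        cmin_ss=trough,
        steady_state_reached=converged,
    )


# ---------------------------------------------------------------------------
# Validation ratio
# ---------------------------------------------------------------------------


def fold_ratio(
    observed: float,
    predicted: float,
    regimen: str = "",
    metric: str = "",
) -> ValidationRecord:
    """Observed/predicted ratio with the 0.5–2.0-fold acceptance band."""
    if predicted <= 0:
        raise ValueError("predicted value must be > 0")
    ratio = observed / predicted
    lo, hi = FOLD_BAND
    return ValidationRecord(
        regimen=regimen,
        metric=metric,
        observed=observed,
        predicted=predicted,
        ratio=ratio,
        within_band=lo <= ratio <= hi,
    )


def validation_table(records: Iterable[ValidationRecord],
                     population: str = "") -> pd.DataFrame:
    rows = [
        {
            "population": population,
            "regimen": r.regimen,
            "metric": r.metric,
            "observed": r.observed,
            "predicted": r.predicted,
            "ratio": round(r.ratio, 2),
            "within_band": r.within_band,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Local sensitivity
# ---------------------------------------------------------------------------


def local_sensitivity(
    metric_fn: Callable[[float], float],
    p0: float,
    parameter: str = "p",
    output: str = "PK",
    epsilon: float = 0.01,
) -> SensitivityResult:
    """Dimensionless local sensitivity (ΔPK/Δp)·(p/PK), central difference.

    ``metric_fn(p)`` recomputes the PK output at parameter value ``p``; the
    coefficient is estimated at relative perturbation ``epsilon`` around
    ``p0``.  A coefficient of −1.0 means a 10% parameter increase lowers the
    output by 10%; +0.5 means a 10% increase raises it by 5%.
    """
    if p0 <= 0:
        raise ValueError("parameter must be strictly positive")
    base = metric_fn(p0)
    if base == 0:
        raise ValueError("baseline PK output is zero; sensitivity undefined")
    hi = metric_fn(p0 * (1.0 + epsilon))
    lo = metric_fn(p0 * (1.0 - epsilon))
    coeff = (hi - lo) / (2.0 * epsilon * p0) * (p0 / base)
    return SensitivityResult(
        parameter=parameter, output=output, epsilon=epsilon, coefficient=coeff
    )


def sensitivity_screen(
    evaluate: Callable[[dict[str, float]], dict[str, float]],
    baseline: dict[str, float],
    parameters: Sequence[str],
    outputs: Sequence[str] = ("cmax", "auc"),
    epsilon: float = 0.01,
) -> pd.DataFrame:
    """Coefficient per (parameter, output), ranked by |coefficient|.

    ``evaluate(params)`` runs the pipeline at the given parameter values and
    returns the named outputs.  Per-row failures are recorded, not fatal.
    """
    if not parameters:
        raise ValueError("at least one parameter required")
    base_out = evaluate(dict(baseline))
    rows = []
    for p in parameters:
        try:
            p0 = baseline[p]
            up = dict(baseline)
            up[p] = p0 * (1.0 + epsilon)
            down = dict(baseline)
            down[p] = p0 * (1.0 - epsilon)
            out_up = evaluate(up)
            out_down = evaluate(down)
            for o in outputs:
                if base_out[o] == 0:
                    raise ZeroDivisionError(f"baseline {o} is zero")
                coeff = (
                    (out_up[o] - out_down[o]) / (2.0 * epsilon * p0) * (p0 / base_out[o])
                )
                rows.append(
                    {"parameter": p, "output": o, "epsilon": epsilon,
                     "coefficient": coeff, "error": ""}
                )
        except Exception as exc:  # recorded per row
            for o in outputs:
                rows.append(
                    {"parameter": p, "output": o, "epsilon": epsilon,
                     "coefficient": float("nan"), "error": str(exc)}
                )
    df = pd.DataFrame(rows)
    df["abs_coefficient"] = df["coefficient"].abs()
    df = df.sort_values("abs_coefficient", ascending=False, kind="stable")
    return df.drop(columns="abs_coefficient").reset_index(drop=True)
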