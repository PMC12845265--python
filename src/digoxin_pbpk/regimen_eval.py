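"""FDA label-style pediatric digoxin regimens and therapeutic-window verdicts.

The label's digitalization protocol: a total loading dose delivered in two
divided doses 6 h apart, followed by twice-daily maintenance starting 12 h
after the second loading administration, each maintenance dose equal to 25%
of the total loading dose.  IV doses are 75% of the corresponding oral dose.
A regimen is judged by whether the steady-state trough Cmin,ss falls inside
the digoxin therapeutic window, 0.5–2 ng/mL (bounds inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .analysis import cmin_ss
from .drug_model import DrugParameters, digoxin_parameters
from .engine import DoseEvent, ModelSystem, Regimen, build_model, simulate
from .physiology import (
    PhysiologyProfile,
    apply_heart_failure,
    reference_adult_profile,
    scale_to_age,
)

__all__ = [
    "AgeGroupSpec",
    "RegimenVerdict",
    "AGE_GROUPS",
    "THERAPEUTIC_WINDOW",
    "build_fda_regimen",
    "evaluate_regimen",
    "age_group_sweep",
    "pediatric_profile",
]

THERAPEUTIC_WINDOW = (0.5, 2.0)  # ng/mL
MAINTENANCE_FRACTION = 0.25      # of total loading dose, per administration
MAINTENANCE_INTERVAL_H = 12.0
LOADING_SPLIT = (0.5, 0.5)
LOADING_INTERVAL_H = 6.0
DEFAULT_HORIZON_DAYS = 7.0       # clinical steady-state assessment point


@dataclass(frozen=True)
class AgeGroupSpec:
    """One pediatric age group of the label's loading-dose table."""

    label: str
    age_range_days: tuple[float, float]
    po_loading_mg_per_kg: tuple[float, float]   # (low, high)
    iv_loading_mg_per_kg: tuple[float, float]
    representative_weight_kg: float
    representative_age_days: float

    def __post_init__(self) -> None:
        for po, iv in zip(self.po_loading_mg_per_kg, self.iv_loading_mg_per_kg):
            if abs(iv - 0.75 * po) > 5e-5:
                raise ValueError(
                    f"{self.label}: IV loading must be 75% of PO ({iv} vs {po})"
                )

    def loading_mg_per_kg(self, route: str, dose_level: str) -> float:
        if dose_level not in ("low", "high"):
            raise ValueError("dose_level must be 'low' or 'high'")
        table = (
            self.po_loading_mg_per_kg if route == "oral"
            else self.iv_loading_mg_per_kg
        )
        return table[0] if dose_level == "low" else table[1]


AGE_GROUPS = {
    "term_neonate": AgeGroupSpec(
        label="term_neonate",
        age_range_days=(0, 30),
        po_loading_mg_per_kg=(0.02, 0.03),
        iv_loading_mg_per_kg=(0.0150, 0.0225),
        representative_weight_kg=3.5,
        representative_age_days=3,
    ),
    "infant": AgeGroupSpec(
        label="infant",
        age_range_days=(30, 730),
        po_loading_mg_per_kg=(0.03, 0.04),
        iv_loading_mg_per_kg=(0.0225, 0.0300),
        representative_weight_kg=6.0,
        representative_age_days=180,
    ),
    "child": AgeGroupSpec(
        label="child",
        age_range_days=(730, 6570),
        po_loading_mg_per_kg=(0.02, 0.03),
        iv_loading_mg_per_kg=(0.0150, 0.0225),
        representative_weight_kg=20.0,
        representative_age_days=6 * 365,
    ),
}


@dataclass(frozen=True)
class RegimenVerdict:
    group: str
    route: str
    dose_level: str
    cmin_ss: float               # ng/mL
    verdict: str                 # below_window | within_window | above_window
    window: tuple[float, float] = THERAPEUTIC_WINDOW
    steady_state_reached: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.window
        expected = (
            "below_window" if self.cmin_ss < lo
            else "above_window" if self.cmin_ss > hi
            else "within_window"
        )
        if self.verdict != expected:
            raise ValueError("verdict inconsistent with cmin_ss and window")


def classify_trough(trough: float,
                    window: tuple[float, float] = THERAPEUTIC_WINDOW) -> str:
    lo, hi = window
    if trough < lo:
        return "below_window"
    if trough > hi:
        return "above_window"
    return "within_window"


def pediatric_profile(age_days: float, weight_kg: float,
                      sex: str = "male") -> PhysiologyProfile:
    """Pediatric heart-failure physiology via the two stepwise translations."""
    adult = reference_adult_profile()
    hf = apply_heart_failure(adult)
    return scale_to_age(hf, age=age_days, body_weight=weight_kg, sex=sex)


def build_fda_regimen(
    group: AgeGroupSpec | str,
    route: str,
    dose_level: str,
    body_weight: float,
    horizon_h: float = DEFAULT_HORIZON_DAYS * 24.0,
    iv_infusion_duration_h: float = 0.25,
) -> Regimen:
    """Loading + maintenance regimen per the label's digitalization protocol.

    Loading: two equal halves at 0 h and 6 h.  Maintenance: starts 12 h after
    the second loading administration, every 12 h through ``horizon_h``, each
    dose exactly 25% of the total loading dose.  IV administrations are
    modeled as short infusions; amounts are resolved by ``body_weight``.
    """
    if isinstance(group, str):
        group = AGE_GROUPS[group]
    if route not in ("oral", "iv"):
        raise ValueError("route must be 'oral' or 'iv'")
    total_loading = group.loading_mg_per_kg(route, dose_level) * body_weight

    if route == "oral":
        ev_route, duration = "oral", 0.0
    else:
        ev_route, duration = "iv_infusion", iv_infusion_duration_h

    events: list[DoseEvent] = []
    t = 0.0
    for frac in LOADING_SPLIT:
        events.append(
            DoseEvent(route=ev_route, amount=total_loading * frac,
                      start_time=t, duration=duration)
        )
        t += LOADING_INTERVAL_H
    maintenance = MAINTENANCE_FRACTION * total_loading
    t = LOADING_INTERVAL_H * (len(LOADING_SPLIT) - 1) + 12.0
    while t < horizon_h:
        events.append(
            DoseEvent(route=ev_route, amount=maintenance, start_time=t,
                      duration=duration)
        )
        t += MAINTENANCE_INTERVAL_H
    label = f"{group.label}_{route}_{dose_level}"
    return Regimen(events=tuple(events), label=label)


def evaluate_regimen(
    drug: DrugParameters,
    profile: PhysiologyProfile,
    regimen: Regimen,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
    dosing_interval_h: float = MAINTENANCE_INTERVAL_H,
    model: ModelSystem | None = None,
) -> RegimenVerdict:
    """Simulate a regimen to steady state (or the horizon) and classify the
    trough against the therapeutic window.

    A zero-dose (empty) regimen is classified below the window directly.
    """
    if not regimen.events:
        return RegimenVerdict(
            group=regimen.label or "custom", route="none", dose_level="none",
            cmin_ss=0.0, verdict="below_window", steady_state_reached=True,
        )
    horizon_h = horizon_days * 24.0
    if model is None:
        model = build_model(drug, profile)
    result = simulate(model, regimen, t_end=horizon_h)
    first = regimen.events[0].start_time
    trough, converged = cmin_ss(
        result, dosing_interval=dosing_interval_h, first_dose_time=first
    )
    parts = regimen.label.split("_")
    route = "iv" if "iv" in parts else ("oral" if "oral" in parts else "custom")
    level = parts[-1] if parts and parts[-1] in ("low", "high") else "custom"
    group = regimen.label or "custom"
    return RegimenVerdict(
        group=group,
        route=route,
        dose_level=level,
        cmin_ss=float(trough),
        verdict=classify_trough(float(trough)),
        steady_state_reached=converged,
    )


def evaluate_fda_regimen(
    group: str,
    route: str,
    dose_level: str,
    body_weight: float | None = None,
    age_days: float | None = None,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
) -> RegimenVerdict:
    """End-to-end: pediatric profile + label regimen + window verdict."""
    spec = AGE_GROUPS[group]
    weight = spec.representative_weight_kg if body_weight is None else body_weight
    age = spec.representative_age_days if age_days is None else age_days
    profile = pediatric_profile(age, weight)
    drug = digoxin_parameters("pediatric_hf")
    regimen = build_fda_regimen(spec, route, dose_level, weight,
                                horizon_h=horizon_days * 24.0)
    verdict = evaluate_regimen(drug, profile, regimen, horizon_days)
    return RegimenVerdict(
        group=group, route=route, dose_level=dose_level,
        cmin_ss=verdict.cmin_ss, verdict=verdict.verdict,
        steady_state_reached=verdict.steady_state_reached,
    )


def age_group_sweep(
    groups: Sequence[str] = ("term_neonate", "infant", "child"),
    routes: Sequence[str] = ("iv", "oral"),
    levels: Sequence[str] = ("low", "high"),
    horizon_days: float = DEFAULT_HORIZON_DAYS,
) -> pd.DataFrame:
    """Full factorial verdict table; per-cell failures recorded, not fatal."""
    rows = []
    for g in groups:
        for r in routes:
            for lvl in levels:
                try:
                    v = evaluate_fda_regimen(g, r, lvl, horizon_days=horizon_days)
                    rows.append(
                        {"group": g, "route": r, "dose_level": lvl,
                         "cmin_ss_ng_per_ml": v.cmin_ss, "verdict": v.verdict,
                         "steady_state_reached": v.steady_state_reached,
                         "error": ""}
                    )
                except Exception as exc:
                    rows.append(
                        {"group": g, "route": r, "dose_level": lvl,
                         "cmin_ss_ng_per_ml": float("nan"), "verdict": "error",
                         "steady_state_reached": False, "error": str(exc)}
                    )
    return pd.DataFrame(rows)
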