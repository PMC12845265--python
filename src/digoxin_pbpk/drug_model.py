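"""Digoxin-specific constants and mechanistic rate laws.

Holds the three population parameter sets (healthy adult, heart-failure
adult, pediatric heart failure), composition-based tissue:plasma partition
coefficients for a weak acid (Rodgers–Rowland neutrals/weak-acids relation),
glomerular-filtration renal clearance, linear target-binding rate constants,
and the saturable P-glycoprotein efflux rate law.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

from .physiology import PhysiologyProfile

__all__ = [
    "DrugParameters",
    "PartitionSet",
    "digoxin_parameters",
    "partition_coefficients",
    "renal_clearance",
    "binding_rate_constants",
    "pgp_flux",
    "POPULATIONS",
]

POPULATIONS = ("healthy_adult", "hf_adult", "pediatric_hf")

PLASMA_PH = 7.4
INTRACELLULAR_PH = 7.0
# plasma neutral-lipid / neutral-phospholipid fractions used by the
# partitioning relation
PLASMA_F_NL = 0.0023
PLASMA_F_NP = 0.0013


@dataclass(frozen=True)
class DrugParameters:
    """All digoxin-specific physicochemical, transport, binding and
    clearance constants for one population parameter set."""

    population: str
    log_p: float                     # lipophilicity (log octanol:water)
    fu: float                        # fraction unbound in plasma
    mw: float                        # g/mol
    pka_acid: float
    solubility: float                # mg/mL
    intestinal_permeability: float   # cm/min
    cellular_permeability: float     # cm/min
    kd: float                        # µmol/L, Na+/K+-ATPase dissociation constant
    koff: float                      # 1/min, dissociation rate
    pgp_vmax: float                  # µmol/L/min
    pgp_km: float                    # µmol/L
    gfr_fraction: float
    pgp_expression: Mapping[str, float] | None = None  # per-GI-segment scalar

    def __post_init__(self) -> None:
        if not 0.0 < self.fu <= 1.0:
            raise ValueError("fu must be in (0, 1]")
        for name in ("kd", "koff", "pgp_km", "mw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("pgp_vmax", "intestinal_permeability",
                     "cellular_permeability", "solubility"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.gfr_fraction <= 1.0:
            raise ValueError("gfr_fraction must be in [0, 1]")

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        d = asdict(self)
        if d["pgp_expression"] is not None:
            d["pgp_expression"] = dict(d["pgp_expression"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DrugParameters":
        return cls(**json.loads(text))

    def with_overrides(self, **kwargs) -> "DrugParameters":
        """Return a copy with named parameters replaced (unknown keys rejected)."""
        valid = set(self.__dataclass_fields__)
        unknown = set(kwargs) - valid
        if unknown:
            raise KeyError(f"unknown drug parameter(s): {sorted(unknown)}")
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PartitionSet:
    """Tissue:plasma partition coefficients (Kp), one per organ."""

    kp: Mapping[str, float]

    def __post_init__(self) -> None:
        for organ, v in self.kp.items():
            if v <= 0:
                raise ValueError(f"Kp[{organ}] must be > 0")

    def __getitem__(self, organ: str) -> float:
        return self.kp[organ]


# physicochemical block identical across populations
_PHYSCHEM = dict(
    log_p=2.36,
    fu=0.71,
    mw=780.0,
    pka_acid=7.15,
    solubility=0.1,
    cellular_permeability=3e-4,
)

_POPULATION_SPECIFIC = {
    "healthy_adult": dict(kd=0.01, intestinal_permeability=2.3e-5),
    "hf_adult": dict(kd=0.5, intestinal_permeability=2.7e-5),
    "pediatric_hf": dict(kd=0.005, intestinal_permeability=2.7e-5),
}


def digoxin_parameters(population: str) -> DrugParameters:
    """Digoxin parameter set for one of the three populations.

    The physicochemical block (LogP, fu, MW, pKa, solubility) and cellular
    permeability are identical across populations; the target dissociation
    constant Kd and the specific intestinal permeability differ:
    Kd = 0.01 / 0.5 / 0.005 µmol/L and intestinal permeability
    2.3e-5 / 2.7e-5 / 2.7e-5 cm/min for healthy adults, heart-failure adults
    and pediatric heart-failure patients respectively.
    """
    if population not in POPULATIONS:
        raise ValueError(
            f"unknown population {population!r}; expected one of {POPULATIONS}"
        )
    spec = _POPULATION_SPECIFIC[population]
    return DrugParameters(
        population=population,
        koff=1e-3,
        pgp_vmax=20.0,
        pgp_km=177.0,
        gfr_fraction=1.0,
        **_PHYSCHEM,
        **spec,
    )


def _kpu_weak_acid(
    log_p: float,
    pka: float,
    fu: float,
    f_ew: float,
    f_iw: float,
    f_nl: float,
    f_np: float,
    albumin_ratio: float,
) -> float:
    """Unbound tissue:plasma partition coefficient for a neutral/weak acid.

    Composition-based relation: extracellular water, pH-partitioned
    intracellular water, neutral-lipid/phospholipid partitioning of the
    neutral species, and albumin-mediated residual binding scaled by the
    tissue:plasma albumin ratio.
    """
    p = 10.0**log_p
    x_p = 1.0 + 10.0 ** (PLASMA_PH - pka)       # plasma ionization term
    x_iw = 1.0 + 10.0 ** (INTRACELLULAR_PH - pka)
    lipid_t = (p * f_nl + (0.3 * p + 0.7) * f_np) / x_p
    lipid_p = (p * PLASMA_F_NL + (0.3 * p + 0.7) * PLASMA_F_NP) / x_p
    protein = max(1.0 / fu - 1.0 - lipid_p, 0.0) * albumin_ratio
    return f_ew + (x_iw / x_p) * f_iw + lipid_t + protein


def partition_coefficients(
    drug: DrugParameters, profile: PhysiologyProfile
) -> PartitionSet:
    """Kp per organ from tissue composition and the drug's LogP/pKa/fu."""
    kp: dict[str, float] = {}
    for organ in profile.organs:
        comp = organ.tissue_composition
        required = ("extracellular_water", "intracellular_water",
                    "neutral_lipid", "neutral_phospholipid")
        missing = [k for k in required if k not in comp]
        if missing:
            raise ValueError(
                f"organ {organ.name!r} lacks tissue composition entries {missing}"
            )
        kpu = _kpu_weak_acid(
            drug.log_p,
            drug.pka_acid,
            drug.fu,
            comp["extracellular_water"],
            comp["intracellular_water"],
            comp["neutral_lipid"],
            comp["neutral_phospholipid"],
            comp.get("albumin_ratio", 0.0),
        )
        kp[organ.name] = kpu * drug.fu
    return PartitionSet(kp=kp)


def renal_clearance(drug: DrugParameters, profile: PhysiologyProfile) -> float:
    """Renal filtration clearance, mL/min: GFR_fraction × fu × GFR.

    Only unbound drug is filtered; digoxin's GFR fraction is 1 (purely
    filtration-driven renal elimination, no metabolism).
    """
    return drug.gfr_fraction * drug.fu * profile.gfr


def binding_rate_constants(kd: float, koff: float) -> tuple[float, float]:
    """(kon, koff) for the linear, non-saturable Na+/K+-ATPase binding.

    kon = koff / Kd.  The unprinted target concentration is folded into the
    effective association rate, so kon acts on tissue concentration directly
    and Kd functions as an equilibrium tissue-retention constant
    (bound:tissue ratio = 1/Kd at equilibrium).
    """
    if kd <= 0 or koff <= 0:
        raise ValueError("kd and koff must be > 0")
    return koff / kd, koff


def pgp_flux(c_enterocyte: float, drug: DrugParameters,
             segment: str | None = None) -> float:
    """P-gp efflux rate (µmol/L/min) at enterocyte concentration c (µmol/L).

    Michaelis–Menten: vmax·c/(km + c), optionally scaled by the relative
    P-gp expression of the GI segment.
    """
    if c_enterocyte < 0:
        raise ValueError("enterocyte concentration must be >= 0")
    expr = 1.0
    if segment is not None and drug.pgp_expression:
        expr = drug.pgp_expression.get(segment, 1.0)
    return expr * drug.pgp_vmax * c_enterocyte / (drug.pgp_km + c_enterocyte)
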