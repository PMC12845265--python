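"""Reference physiology and the two population translations.

The package ships a single documented adult reference individual (organ
volumes and tissue compositions from standard published reference tables;
organ blood flows and GFR as printed for the healthy-adult parameterization
of the digoxin model).  Two transforms derive the other populations:

* :func:`apply_heart_failure` — halves every organ blood flow and lowers GFR,
  reflecting the reduced systemic perfusion of moderate heart failure.
* :func:`scale_to_age` — allometric rescaling of flows, volumes and GFR to a
  pediatric individual, anchored so that a 3.5-kg, 3-day-old term neonate
  reproduces the published pediatric parameter column.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "OrganSpec",
    "PhysiologyProfile",
    "reference_adult_profile",
    "apply_heart_failure",
    "scale_to_age",
    "GI_SEGMENTS",
    "REFERENCE_BODY_WEIGHT_KG",
    "REFERENCE_AGE_DAYS",
]

#: GI mucosa segments (duodenum ... rectum) that carry enterocyte pools.
GI_SEGMENTS = (
    "duodenum",
    "upper_jejunum",
    "lower_jejunum",
    "upper_ileum",
    "lower_ileum",
    "cecum",
    "colon",
    "rectum",
)

REFERENCE_BODY_WEIGHT_KG = 73.0
REFERENCE_AGE_DAYS = 30 * 365.25
#: anchor used to back out allometric exponents from the published
#: pediatric column (term neonate, ~3 days old)
NEONATE_ANCHOR_WEIGHT_KG = 3.5
NEONATE_ANCHOR_AGE_DAYS = 3.0

# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------

# Tissue composition: fractional extracellular water, intracellular water,
# neutral lipid, neutral phospholipid, and the tissue:plasma albumin ratio.
# Values are the standard composition-based partitioning constants used for
# neutral/weak-acid drugs (Rodgers & Rowland-type reference data).
_COMPOSITION = {
    # organ: (f_ew, f_iw, f_nl, f_np, albumin_ratio)
    "fat": (0.135, 0.017, 0.790, 0.0020, 0.049),
    "bone": (0.100, 0.346, 0.074, 0.0011, 0.100),
    "brain": (0.162, 0.620, 0.051, 0.0565, 0.048),
    "gonads": (0.141, 0.595, 0.0047, 0.0130, 0.095),
    "heart": (0.320, 0.456, 0.0115, 0.0166, 0.157),
    "kidney": (0.273, 0.483, 0.0207, 0.0162, 0.130),
    "large_intestine": (0.282, 0.475, 0.0487, 0.0163, 0.158),
    "small_intestine": (0.282, 0.475, 0.0487, 0.0163, 0.158),
    "liver": (0.161, 0.573, 0.0348, 0.0252, 0.086),
    "lung": (0.336, 0.446, 0.0030, 0.0090, 0.212),
    "muscle": (0.118, 0.630, 0.0238, 0.0072, 0.064),
    "pancreas": (0.120, 0.664, 0.0403, 0.0090, 0.060),
    "skin": (0.382, 0.291, 0.0284, 0.0111, 0.277),
    "spleen": (0.207, 0.579, 0.0201, 0.0198, 0.097),
    "stomach": (0.282, 0.475, 0.0487, 0.0163, 0.158),
}
# GI mucosa segments share gut composition
for _seg in GI_SEGMENTS:
    _COMPOSITION[_seg] = _COMPOSITION["small_intestine"]

# Adult reference organ volumes (L, ~73 kg adult male, ICRP-style reference
# anatomy) and fractional vascular volumes.  Not printed in the model's
# parameter table; shipped here as the documented reference set.
_ADULT_VOLUMES_L = {
    "bone": 10.5,
    "brain": 1.45,
    "fat": 13.0,
    "gonads": 0.035,
    "heart": 0.33,
    "kidney": 0.31,
    "large_intestine": 0.37,
    "small_intestine": 0.64,
    "liver": 1.82,
    "lung": 0.53,
    "muscle": 29.0,
    "pancreas": 0.14,
    "skin": 3.41,
    "spleen": 0.19,
    "stomach": 0.15,
}
# mucosa (enterocyte) volumes per GI segment, L (~0.8 L total mucosa)
_ADULT_MUCOSA_VOLUMES_L = {
    "duodenum": 0.08,
    "upper_jejunum": 0.15,
    "lower_jejunum": 0.15,
    "upper_ileum": 0.12,
    "lower_ileum": 0.12,
    "cecum": 0.05,
    "colon": 0.10,
    "rectum": 0.03,
}

_VASCULAR_FRACTION = {
    "bone": 0.03, "brain": 0.04, "fat": 0.02, "gonads": 0.02,
    "heart": 0.10, "kidney": 0.16, "large_intestine": 0.02,
    "small_intestine": 0.02, "liver": 0.11, "lung": 0.36, "muscle": 0.01,
    "pancreas": 0.06, "skin": 0.02, "spleen": 0.28, "stomach": 0.03,
}

# Healthy-adult organ blood flows, L/min (printed parameterization).
_ADULT_FLOWS_L_PER_MIN = {
    "bone": 2.42,
    "brain": 0.68,
    "fat": 0.28,
    "gonads": 2.84e-3,
    "heart": 0.22,
    "kidney": 1.46,
    "large_intestine": 0.26,
    "small_intestine": 0.65,
    "liver": 0.46,          # hepatic artery
    "muscle": 0.98,
    "pancreas": 0.06,
    "skin": 0.28,
    "spleen": 0.14,
    "stomach": 0.06,
}
_ADULT_MUCOSA_FLOW_L_PER_MIN = 0.02  # per GI segment

_ADULT_GFR_ML_PER_MIN = 116.45
_ADULT_BLOOD_L_PER_KG = 5.3 / 73.0
_ADULT_HEMATOCRIT = 0.45

# Per-organ allometric exponents for blood flows, backed out of the two
# printed anchor columns (heart-failure adult vs 3-day-old / 3.5-kg term
# neonate): b = ln(Q_neonate / Q_hf_adult) / ln(3.5 / 73).  The printed
# neonate values are thereby reproduced exactly at the anchor.
_NEONATE_FLOW_ANCHORS = {
    # organ: printed neonate flow (L/min); HF base = adult flow / 2 exactly
    "bone": 0.02,
    "brain": 0.09,
    "fat": 0.02,
    "gonads": 6.07e-5,
    "heart": 0.01,
    "kidney": 0.06,
    "large_intestine": 0.01,
    "small_intestine": 0.03,
    "liver": 0.02,
    "muscle": 0.02,
    "pancreas": 3.05e-3,
    "skin": 0.02,
    "spleen": 7.76e-3,
    "stomach": 3.04e-3,
}
_NEONATE_MUCOSA_FLOW = 2.12e-3
_NEONATE_GFR_ML_PER_MIN = 4.2

_LOG_WEIGHT_RATIO = math.log(NEONATE_ANCHOR_WEIGHT_KG / REFERENCE_BODY_WEIGHT_KG)


def _flow_exponent(organ: str) -> float:
    if organ in GI_SEGMENTS:
        ratio = _NEONATE_MUCOSA_FLOW / (_ADULT_MUCOSA_FLOW_L_PER_MIN / 2.0)
    else:
        ratio = _NEONATE_FLOW_ANCHORS[organ] / (_ADULT_FLOWS_L_PER_MIN[organ] / 2.0)
    return math.log(ratio) / _LOG_WEIGHT_RATIO


# GFR combines a sigmoidal maturation function of postmenstrual age (Hill
# form with the standard renal-maturation constants TM50 = 55.4 weeks,
# gamma = 3.4) with a weight-allometric size term whose exponent is
# calibrated so the 3-day-old, 3.5-kg term neonate reproduces the published
# pediatric GFR of 4.2 mL/min.
GFR_MATURATION_TM50_WEEKS = 55.4
GFR_MATURATION_HILL = 3.4
TERM_GESTATION_WEEKS = 40.0


def postnatal_maturation(age_days: float) -> float:
    """Sigmoidal postnatal maturation factor (0→1) as a function of
    postmenstrual age; used for GFR and for the absorptive mucosal area
    (intestinal villi are immature at birth)."""
    pma_weeks = TERM_GESTATION_WEEKS + age_days / 7.0
    x = (pma_weeks / GFR_MATURATION_TM50_WEEKS) ** GFR_MATURATION_HILL
    return x / (1.0 + x)


_gfr_maturation = postnatal_maturation


_ANCHOR_MATURATION = _gfr_maturation(NEONATE_ANCHOR_AGE_DAYS)

GFR_ALLOMETRIC_EXPONENT = (
    math.log(_NEONATE_GFR_ML_PER_MIN / 43.85 / _ANCHOR_MATURATION)
    / _LOG_WEIGHT_RATIO
)

# lung receives the whole cardiac output; scale its flow with the summed CO
_LUNG_VOLUME_EXPONENT = 1.0
_BRAIN_VOLUME_EXPONENT = None  # filled below from the brain flow exponent


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrganSpec:
    """One organ (or GI-mucosa segment) of a physiological individual."""

    name: str
    volume: float              # L
    blood_flow: float          # L/min
    tissue_composition: Mapping[str, float] = field(default_factory=dict)
    surface_area_factor: float = 1.0
    vascular_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"{self.name}: volume must be > 0")
        if self.blood_flow < 0:
            raise ValueError(f"{self.name}: blood_flow must be >= 0")
        comp = self.tissue_composition
        for key, val in comp.items():
            if key == "albumin_ratio":
                continue
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{self.name}: composition fraction {key}={val}")
        frac_sum = sum(v for k, v in comp.items() if k != "albumin_ratio")
        if frac_sum > 1.0 + 1e-9:
            raise ValueError(f"{self.name}: composition fractions sum to {frac_sum}")


@dataclass(frozen=True)
class PhysiologyProfile:
    """Organ set plus whole-body fields for one (possibly virtual) individual."""

    organs: tuple[OrganSpec, ...]
    gfr: float                 # mL/min
    hematocrit: float
    body_weight: float         # kg
    age: float                 # days
    sex: str
    population: str            # healthy_adult | hf_adult | pediatric_hf
    blood_volume: float = 5.3  # L

    def __post_init__(self) -> None:
        if self.gfr < 0:
            raise ValueError("gfr must be >= 0")
        names = [o.name for o in self.organs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate organ names in profile")
        flows = sum(o.blood_flow for o in self.organs if o.name != "lung")
        if flows > self.cardiac_output + 1e-9:
            raise ValueError("organ blood flows exceed cardiac output")

    @property
    def cardiac_output(self) -> float:
        """Cardiac output (L/min) = sum of systemic organ flows."""
        return sum(o.blood_flow for o in self.organs if o.name != "lung")

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(f"no organ named {name!r} in profile")

    @property
    def organ_names(self) -> tuple[str, ...]:
        return tuple(o.name for o in self.organs)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "gfr_ml_per_min": self.gfr,
            "hematocrit": self.hematocrit,
            "body_weight_kg": self.body_weight,
            "age_days": self.age,
            "sex": self.sex,
            "population": self.population,
            "blood_volume_L": self.blood_volume,
            "organs": [
                {
                    "name": o.name,
                    "volume_L": o.volume,
                    "flow_L_per_min": o.blood_flow,
                    "tissue_composition": dict(o.tissue_composition),
                    "surface_area_factor": o.surface_area_factor,
                    "vascular_fraction": o.vascular_fraction,
                }
                for o in self.organs
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhysiologyProfile":
        d = json.loads(text)
        organs = tuple(
            OrganSpec(
                name=o["name"],
                volume=o["volume_L"],
                blood_flow=o["flow_L_per_min"],
                tissue_composition=o.get("tissue_composition", {}),
                surface_area_factor=o.get("surface_area_factor", 1.0),
                vascular_fraction=o.get("vascular_fraction", 0.05),
            )
            for o in d["organs"]
        )
        return cls(
            organs=organs,
            gfr=d["gfr_ml_per_min"],
            hematocrit=d["hematocrit"],
            body_weight=d["body_weight_kg"],
            age=d["age_days"],
            sex=d["sex"],
            population=d["population"],
            blood_volume=d.get("blood_volume_L", 5.3),
        )

    def organs_to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "organ": [o.name for o in self.organs],
                "volume_L": [o.volume for o in self.organs],
                "flow_L_per_min": [o.blood_flow for o in self.organs],
                "vascular_fraction": [o.vascular_fraction for o in self.organs],
                "surface_area_factor": [o.surface_area_factor for o in self.organs],
            }
        )
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _make_organ(name: str, volume: float, flow: float, vasc: float) -> OrganSpec:
    f_ew, f_iw, f_nl, f_np, ar = _COMPOSITION[name]
    comp = {
        "extracellular_water": f_ew,
        "intracellular_water": f_iw,
        "neutral_lipid": f_nl,
        "neutral_phospholipid": f_np,
        "albumin_ratio": ar,
    }
    return OrganSpec(
        name=name,
        volume=volume,
        blood_flow=flow,
        tissue_composition=comp,
        vascular_fraction=vasc,
    )


def reference_adult_profile() -> PhysiologyProfile:
    """Healthy-adult reference individual (73 kg, 30 y, male).

    Organ blood flows and GFR are the healthy-adult column of the digoxin
    model parameterization; volumes, compositions and vascular fractions are
    the documented reference set shipped with the package.  The lung carries
    the full cardiac output.
    """
    organs: list[OrganSpec] = []
    for name, vol in _ADULT_VOLUMES_L.items():
        if name == "lung":
            continue
        organs.append(
            _make_organ(name, vol, _ADULT_FLOWS_L_PER_MIN[name],
                        _VASCULAR_FRACTION[name])
        )
    for seg in GI_SEGMENTS:
        organs.append(
            _make_organ(seg, _ADULT_MUCOSA_VOLUMES_L[seg],
                        _ADULT_MUCOSA_FLOW_L_PER_MIN, 0.1)
        )
    co = sum(o.blood_flow for o in organs)
    organs.append(
        _make_organ("lung", _ADULT_VOLUMES_L["lung"], co,
                    _VASCULAR_FRACTION["lung"])
    )
    return PhysiologyProfile(
        organs=tuple(organs),
        gfr=_ADULT_GFR_ML_PER_MIN,
        hematocrit=_ADULT_HEMATOCRIT,
        body_weight=REFERENCE_BODY_WEIGHT_KG,
        age=REFERENCE_AGE_DAYS,
        sex="male",
        population="healthy_adult",
        blood_volume=_ADULT_BLOOD_L_PER_KG * REFERENCE_BODY_WEIGHT_KG,
    )


def apply_heart_failure(
    profile: PhysiologyProfile,
    flow_fraction: float = 0.5,
    gfr_target: float = 43.85,
) -> PhysiologyProfile:
    """First translation: moderate heart failure.

    Every organ blood flow is multiplied by ``flow_fraction`` (systemic
    perfusion roughly halves in moderate heart failure) and GFR is set to
    ``gfr_target`` (mL/min).  All other fields are unchanged.
    """
    if not 0.0 < flow_fraction <= 1.0:
        raise ValueError("flow_fraction must be in (0, 1]")
    if gfr_target < 0:
        raise ValueError("gfr_target must be >= 0")
    organs = tuple(
        replace(o, blood_flow=o.blood_flow * flow_fraction) for o in profile.organs
    )
    return replace(profile, organs=organs, gfr=gfr_target, population="hf_adult")


def scale_to_age(
    profile: PhysiologyProfile,
    age: float,
    body_weight: float,
    sex: str = "male",
) -> PhysiologyProfile:
    """Second translation: rescale a (heart-failure) adult to a child.

    Blood flows and GFR follow organ-specific allometric functions of body
    weight whose exponents are anchored so the 3.5-kg / 3-day-old term
    neonate reproduces the published pediatric column.  Organ volumes scale
    linearly with body weight except the brain, which matures early and uses
    its flow exponent.  ``age`` (days) is recorded and validated but the
    scaling itself is weight-driven.
    """
    if age < 0:
        raise ValueError("age must be >= 0 days")
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0 kg")

    w_ratio = body_weight / REFERENCE_BODY_WEIGHT_KG
    organs: list[OrganSpec] = []
    systemic: list[OrganSpec] = []
    for o in profile.organs:
        if o.name == "lung":
            continue
        b_q = _flow_exponent(o.name)
        if o.name == "brain":
            b_v = b_q
        else:
            b_v = 1.0
        systemic.append(
            replace(
                o,
                volume=o.volume * w_ratio**b_v,
                blood_flow=o.blood_flow * w_ratio**b_q,
            )
        )
    organs.extend(systemic)
    co = sum(o.blood_flow for o in systemic)
    lung = profile.organ("lung")
    organs.append(
        replace(lung, volume=lung.volume * w_ratio**_LUNG_VOLUME_EXPONENT,
                blood_flow=co)
    )
    return replace(
        profile,
        organs=tuple(organs),
        gfr=(profile.gfr * w_ratio**GFR_ALLOMETRIC_EXPONENT
             * _gfr_maturation(age) / _gfr_maturation(profile.age)),
        body_weight=body_weight,
        age=age,
        sex=sex,
        population="pediatric_hf",
        blood_volume=_ADULT_BLOOD_L_PER_KG * body_weight,
    )
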