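"""Green analytical chemistry scoring: Eco-Scale, AGREE and NEMI.

Analytical Eco-Scale subtracts penalty points (PPs) from an ideal 100.
Reagent PPs multiply an amount sub-penalty (1 / 2 / 3 for < 10, 10-100,
> 100 mL or g per analysis) by a hazard sub-penalty (number of GHS
pictograms times 1 for signal word "warning", 2 for "danger").  Instrument
energy, occupational hazard and waste contribute their own PPs; scores above
75 grade "excellent", above 50 "acceptable", otherwise "inadequate".

AGREE aggregates twelve per-principle scores in [0, 1] into a weighted mean.
NEMI colours four quadrants green when the procedure avoids PBT-listed and
RCRA-listed chemicals, stays non-corrosive (2 <= pH <= 12) and produces less
than 50 g of waste per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = [
    "Reagent",
    "Waste",
    "EcoScaleProfile",
    "EcoScaleResult",
    "AgreeProfile",
    "NemiProfile",
    "eco_scale",
    "reagent_penalty",
    "waste_penalty",
    "agree_score",
    "nemi",
    "load_profile",
]

AMOUNT_SUB_PP = {"<10": 1, "10-100": 2, ">100": 3}
SIGNAL_MULT = {"none": 0, "warning": 1, "danger": 2}
WASTE_AMOUNT_PP = {"none": 0, "<1": 1, "1-10": 3, ">10": 5}
# Treatment add-ons per the Eco-Scale penalty table: untreated waste is worst,
# recycling is free, degradation/passivation in between.
WASTE_TREATMENT_PP = {"none": 3, "recycling": 0, "degradation/passivation": 1}
ENERGY_PP = {"<=0.1 kWh": 0, "<=1.5 kWh": 1, ">1.5 kWh": 2}


@dataclass(frozen=True)
class Reagent:
    name: str
    pictogram_count: int
    signal_word: str = "danger"
    amount_class: str = "<10"

    def __post_init__(self) -> None:
        if self.pictogram_count < 0:
            raise ValueError("pictogram count must be >= 0")
        if self.signal_word not in SIGNAL_MULT:
            raise ValueError(f"unknown signal word {self.signal_word!r}")
        if self.amount_class not in AMOUNT_SUB_PP:
            raise ValueError(f"unknown amount class {self.amount_class!r}")


@dataclass(frozen=True)
class Waste:
    amount_class: str = "1-10"
    treatment: str = "none"

    def __post_init__(self) -> None:
        if self.amount_class not in WASTE_AMOUNT_PP:
            raise ValueError(f"unknown waste amount class {self.amount_class!r}")
        if self.treatment not in WASTE_TREATMENT_PP:
            raise ValueError(f"unknown waste treatment {self.treatment!r}")


@dataclass(frozen=True)
class EcoScaleProfile:
    reagents: tuple[Reagent, ...]
    instrument_energy_class: str = "<=0.1 kWh"
    occupational_hazard: bool = False
    waste: Waste = field(default_factory=Waste)

    def __post_init__(self) -> None:
        if self.instrument_energy_class not in ENERGY_PP:
            raise ValueError(
                f"unknown energy class {self.instrument_energy_class!r}")


@dataclass(frozen=True)
class EcoScaleResult:
    total_score: float
    per_item_pps: dict[str, float]
    grade: str


def reagent_penalty(reagent: Reagent) -> int:
    """Amount sub-penalty times (pictograms x signal-word multiplier)."""
    return AMOUNT_SUB_PP[reagent.amount_class] * (
        reagent.pictogram_count * SIGNAL_MULT[reagent.signal_word])


def waste_penalty(waste: Waste) -> int:
    """Amount-class penalty plus the treatment add-on."""
    return WASTE_AMOUNT_PP[waste.amount_class] + WASTE_TREATMENT_PP[waste.treatment]


def eco_scale(profile: EcoScaleProfile) -> EcoScaleResult:
    """Total Eco-Scale score (100 minus all penalty points) and its grade."""
    pps: dict[str, float] = {}
    for reagent in profile.reagents:
        pps[f"reagent:{reagent.name}"] = reagent_penalty(reagent)
    pps["instrument_energy"] = ENERGY_PP[profile.instrument_energy_class]
    pps["occupational_hazard"] = 3 if profile.occupational_hazard else 0
    pps["waste"] = waste_penalty(profile.waste)
    total = 100.0 - sum(pps.values())
    if total > 75:
        grade = "excellent"
    elif total > 50:
        grade = "acceptable"
    else:
        grade = "inadequate"
    return EcoScaleResult(total_score=total, per_item_pps=pps, grade=grade)


@dataclass(frozen=True)
class AgreeProfile:
    """Twelve per-principle scores in [0, 1], optionally weighted."""

    scores: tuple[float, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.scores) != 12:
            raise ValueError("AGREE requires exactly 12 principle scores")
        if any(not 0.0 <= s <= 1.0 for s in self.scores):
            raise ValueError("principle scores must lie in [0, 1]")
        if self.weights is not None:
            if len(self.weights) != 12:
                raise ValueError("weights must have length 12")
            if any(w <= 0 for w in self.weights):
                raise ValueError("weights must be positive")


def agree_score(profile: AgreeProfile, ndigits: int = 2) -> float:
    """Weighted mean of the twelve principle scores, rounded for reporting."""
    w = profile.weights or (1.0,) * 12
    raw = sum(s * wi for s, wi in zip(profile.scores, w)) / sum(w)
    return round(raw, ndigits)


@dataclass(frozen=True)
class NemiProfile:
    pbt_listed: bool
    hazardous_listed: bool  # RCRA lists
    ph: float
    waste_g_per_sample: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError("pH must lie in [0, 14]")
        if self.waste_g_per_sample < 0:
            raise ValueError("waste must be >= 0")


def nemi(profile: NemiProfile) -> dict[str, bool]:
    """Quadrant flags (True = green): PBT, hazardous (RCRA), corrosive, waste."""
    return {
        "pbt": not profile.pbt_listed,
        "hazardous": not profile.hazardous_listed,
        "corrosive": 2.0 <= profile.ph <= 12.0,
        "waste": profile.waste_g_per_sample < 50.0,
    }


def load_profile(path=None):
    """Load a greenness profile YAML; the bundled file describes the shipped
    TCB/LVM procedure (methanolic HCl, spectrophotometer, recycled waste)."""
    if path is None:
        from importlib import resources
        text = resources.files("specres").joinpath("data/greenness_profile.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    eco = EcoScaleProfile(
        reagents=tuple(Reagent(**r) for r in doc["eco_scale"]["reagents"]),
        instrument_energy_class=doc["eco_scale"].get("instrument_energy_class", "<=0.1 kWh"),
        occupational_hazard=doc["eco_scale"].get("occupational_hazard", False),
        waste=Waste(**doc["eco_scale"].get("waste", {})),
    )
    agree = AgreeProfile(scores=tuple(float(s) for s in doc["agree"]["scores"]),
                         weights=tuple(float(w) for w in doc["agree"]["weights"])
                         if doc["agree"].get("weights") else None)
    nemi_p = NemiProfile(**doc["nemi"])
    return eco, agree, nemi_p
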