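"""Pigment and fatty-acid composition bookkeeping.

De-epoxidation state (DES) indices quantify the photoprotective
conversion of xanthophyll-cycle pigments: diadinoxanthin (Ddx) to
diatoxanthin (Dtx) in most chromophytes, violaxanthin (Vx) through
antheraxanthin (Ax) to zeaxanthin (Zx) in raphidophytes and green
lineages. Fatty acids are classified by double-bond count into SFA
(0), MUFA (1) and PUFA (>= 2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

from salgae.errors import DomainError

#: Controlled pigment vocabulary. np-chl-c2 is a chlorophyll and is
#: tracked but excluded from carotenoid totals.
PIGMENT_VOCABULARY = frozenset(
    {
        "fucoxanthin",
        "hex-fucoxanthin",
        "4-keto-hex-fucoxanthin",
        "but-fucoxanthin",
        "diadinoxanthin",
        "diatoxanthin",
        "diadinochrome",
        "antheraxanthin",
        "np-chl-c2",
        "peridinin",
        "peridinol",
        "peridinin-ester",
        "dinoxanthin",
        "violaxanthin",
        "zeaxanthin",
        "beta-carotene",
    }
)

#: Fucoxanthin plus its acyloxy derivatives.
FUCOXANTHIN_FAMILY = frozenset(
    {"fucoxanthin", "hex-fucoxanthin", "4-keto-hex-fucoxanthin", "but-fucoxanthin"}
)

_NON_CAROTENOIDS = frozenset({"np-chl-c2"})

_FA_NAME = re.compile(r"^(\d{1,2}):(\d{1,2})(?:n(\d{1,2}))?$")


@dataclass(frozen=True)
class PigmentProfile:
    """Pigment composition as % of dry weight, on a controlled vocabulary."""

    components: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        comp = dict(self.components)
        unknown = set(comp) - PIGMENT_VOCABULARY
        if unknown:
            raise DomainError(f"unknown pigment name(s): {sorted(unknown)}")
        if any(v < 0 for v in comp.values()):
            raise DomainError("pigment percentages must be >= 0")
        if sum(comp.values()) > 100:
            raise DomainError("pigment percentages exceed 100% of dry weight")
        object.__setattr__(self, "components", comp)


@dataclass(frozen=True)
class FattyAcidProfile:
    """Fatty-acid composition as % of dry weight, keyed by Cx:y(nZ) names."""

    components: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        comp = dict(self.components)
        for name, v in comp.items():
            parse_fatty_acid(name)  # raises on malformed names
            if v < 0:
                raise DomainError(f"fatty-acid percentage must be >= 0 ({name})")
        object.__setattr__(self, "components", comp)


def des_diadinoxanthin(ddx: float, dtx: float) -> float:
    """DES% of the diadinoxanthin cycle: 100·Dtx/(Dtx + Ddx).

    Inputs are concentrations in % of dry weight; 100% means complete
    conversion to the photoprotective diatoxanthin form.
    """
    if ddx < 0 or dtx < 0:
        raise DomainError("pigment concentrations must be >= 0")
    if ddx + dtx == 0:
        raise DomainError("DES undefined: diadinoxanthin pool is empty")
    return 100.0 * dtx / (dtx + ddx)


def des_violaxanthin(vx: float, ax: float, zx: float) -> float:
    """DES% of the violaxanthin cycle: 100·(0.5·Ax + Zx)/(Vx + Ax + Zx).

    The intermediate antheraxanthin carries half weight (one of the two
    epoxide groups removed).
    """
    if vx < 0 or ax < 0 or zx < 0:
        raise DomainError("pigment concentrations must be >= 0")
    total = vx + ax + zx
    if total == 0:
        raise DomainError("DES undefined: violaxanthin pool is empty")
    return 100.0 * (0.5 * ax + zx) / total


def parse_fatty_acid(name: str) -> tuple[int, int, int | None]:
    """Parse 'Cx:y' or 'Cx:ynZ' into (carbons, double_bonds, omega or None)."""
    m = _FA_NAME.match(name.strip())
    if not m:
        raise DomainError(f"cannot parse fatty-acid name {name!r} (expected e.g. '16:1n7')")
    carbons, dbonds = int(m.group(1)), int(m.group(2))
    omega = int(m.group(3)) if m.group(3) else None
    return carbons, dbonds, omega


def classify_fatty_acid(name: str) -> str:
    """Classify a fatty acid as 'SFA', 'MUFA' or 'PUFA' by double-bond count.

    The omega position (nZ suffix) is parsed but does not affect the class.
    """
    _, dbonds, _ = parse_fatty_acid(name)
    if dbonds == 0:
        return "SFA"
    if dbonds == 1:
        return "MUFA"
    return "PUFA"


def aggregate_classes(profile: FattyAcidProfile) -> dict[str, dict[str, float]]:
    """Sum a fatty-acid profile into SFA/MUFA/PUFA classes.

    Returns ``{'percent_dw': {...}, 'percent_of_total': {...}}``; the
    percent-of-total shares sum to 100.
    """
    if not profile.components:
        raise DomainError("empty fatty-acid profile")
    dw = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0}
    for name, v in profile.components.items():
        dw[classify_fatty_acid(name)] += v
    total = sum(dw.values())
    if total == 0:
        raise DomainError("total fatty acids is zero: percent-of-total undefined")
    of_total = {k: 100.0 * v / total for k, v in dw.items()}
    return {"percent_dw": dw, "percent_of_total": of_total}


def total_carotenoids(profile: PigmentProfile) -> float:
    """Total carotenoids in % dry weight (chlorophyll-type pigments excluded)."""
    if not profile.components:
        raise DomainError("empty pigment profile")
    return sum(
        v for k, v in profile.components.items() if k not in _NON_CAROTENOIDS
    )


def fucoxanthin_family_fraction(profile: PigmentProfile) -> float:
    """Fucoxanthin and its derivatives as % of total carotenoids."""
    total = total_carotenoids(profile)
    if total == 0:
        raise DomainError("total carotenoids is zero: fraction undefined")
    family = sum(
        v for k, v in profile.components.items() if k in FUCOXANTHIN_FAMILY
    )
    return 100.0 * family / total
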