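"""Haemolytic-activity scoring.

The equivalent saponin potential (ESP) expresses the haemolytic potency
of a biomass methanolic extract as the mass of saponin (pg) with the
same 50%-haemolysis effect as 1 μg of extract:
ESP = EC50(saponin, pg·mL⁻¹) / EC50(extract, μg·mL⁻¹). Extracts with no
detectable haemolysis carry no score (None), never ESP = 0, so summary
statistics are not silently deflated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from salgae.errors import DomainError


@dataclass(frozen=True)
class DoseResponse:
    """Haemolysis fraction measured over an ascending dose series."""

    concentrations: tuple[float, ...]
    response: tuple[float, ...]

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in self.concentrations)
        r = tuple(float(x) for x in self.response)
        if len(c) != len(r):
            raise DomainError("concentrations and response must have equal length")
        if len(c) < 3:
            raise DomainError("need at least 3 dose levels")
        if any(x <= 0 for x in c):
            raise DomainError("doses must be > 0")
        if any(b <= a for a, b in zip(c, c[1:])):
            raise DomainError("doses must be strictly increasing")
        if any(not 0 <= x <= 1 for x in r):
            raise DomainError("response must be a fraction in [0, 1]")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "response", r)


@dataclass(frozen=True)
class EspScore:
    """Equivalent saponin potential for one species × stage × salinity."""

    esp: float
    species: str = ""
    stage: str = ""
    salinity: float = float("nan")

    def __post_init__(self) -> None:
        if self.esp < 0:
            raise DomainError("ESP must be >= 0")


def ec50(dr: DoseResponse) -> float:
    """Dose at 50% haemolysis by monotone linear interpolation on log dose.

    The first crossing from low dose is used. Raises when the response
    never brackets 0.5 ("EC50 not bracketed").
    """
    c = np.asarray(dr.concentrations)
    r = np.asarray(dr.response)
    for i in range(len(r)):
        if r[i] == 0.5:
            return float(c[i])
        if i + 1 < len(r) and (r[i] - 0.5) * (r[i + 1] - 0.5) < 0:
            lc = np.log10(c)
            frac = (0.5 - r[i]) / (r[i + 1] - r[i])
            return float(10.0 ** (lc[i] + frac * (lc[i + 1] - lc[i])))
    raise DomainError("EC50 not bracketed: response never crosses 0.5")


def esp(
    ec50_saponin: float,
    ec50_extract: float | None,
    species: str = "",
    stage: str = "",
    salinity: float = float("nan"),
) -> EspScore | None:
    """ESP = EC50(saponin, pg·mL⁻¹) / EC50(extract, μg·mL⁻¹), pg per μg.

    ``ec50_extract=None`` (no haemolytic activity observed) returns None:
    the score is absent, not zero.
    """
    if ec50_extract is None:
        return None
    if ec50_saponin <= 0 or ec50_extract <= 0:
        raise DomainError("EC50 values must be > 0")
    return EspScore(
        esp=ec50_saponin / ec50_extract,
        species=species,
        stage=stage,
        salinity=salinity,
    )


def esp_from_curves(
    saponin: DoseResponse,
    extract: DoseResponse | None,
    **meta,
) -> EspScore | None:
    """Convenience wrapper: interpolate both EC50s, then form the ratio."""
    if extract is None:
        return None
    try:
        e_ext = ec50(extract)
    except DomainError as exc:
        if "not bracketed" in str(exc):
            return None
        raise
    return esp(ec50(saponin), e_ext, **meta)
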