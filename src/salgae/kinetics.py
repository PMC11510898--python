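"""Endpoint productivity computations over culture windows.

Biomass productivity is defined on endpoints, Pb = (Cb_f − Cb_i)/(t_f − t_i),
not as a regression slope; it may be negative under growth inhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from salgae.culture_io import CultureTimeSeries
from salgae.errors import DomainError


@dataclass(frozen=True)
class ProductivityResult:
    """Biomass productivity over an explicit culture window.

    ``pb`` is in mg·L⁻¹·day⁻¹ and equals ``(cb_f − cb_i)/(t_f − t_i)``
    exactly; negative values indicate net biomass loss.
    """

    pb: float
    t_i: float
    t_f: float
    cb_i: float
    cb_f: float

    def __post_init__(self) -> None:
        if self.t_f <= self.t_i:
            raise DomainError(f"t_f ({self.t_f}) must exceed t_i ({self.t_i})")


def biomass_productivity(
    series: CultureTimeSeries, t_i: float, t_f: float
) -> ProductivityResult:
    """Endpoint biomass productivity over [t_i, t_f], mg·L⁻¹·day⁻¹.

    Both bounds must coincide with sampled time points carrying biomass;
    no interpolation is performed.
    """
    if t_f <= t_i:
        raise DomainError(f"t_f ({t_f}) must exceed t_i ({t_i})")
    cb_i = series.biomass_at(t_i)
    cb_f = series.biomass_at(t_f)
    pb = (cb_f - cb_i) / (t_f - t_i)
    return ProductivityResult(pb=pb, t_i=t_i, t_f=t_f, cb_i=cb_i, cb_f=cb_f)


def product_productivity(
    pb: float, x: float, percent: bool = False
) -> tuple[float, float]:
    """Productivity of a compound present at mass fraction ``x`` of dry weight.

    Returns ``(mg·L⁻¹·day⁻¹, μg·L⁻¹·day⁻¹)``. With ``percent=True``, ``x``
    is given in percent of dry weight (0–100) and divided by 100 first.
    """
    if percent:
        if not 0 <= x <= 100:
            raise DomainError(f"percent fraction must be in [0, 100], got {x}")
        x = x / 100.0
    elif not 0 <= x <= 1:
        raise DomainError(f"mass fraction must be in [0, 1], got {x}")
    pp = pb * x
    return pp, pp * 1000.0


def detect_stationary_onset(
    series: CultureTimeSeries, window: float = 3.0, mu_threshold: float = 0.05
) -> float | None:
    """Earliest sampled day where the rolling specific growth rate stalls.

    μ = Δln(Cb)/Δt is evaluated over each trailing span of at least
    ``window`` days ending at a sampled point; the first endpoint with
    μ < ``mu_threshold`` (day⁻¹) is returned, or None if growth never slows.
    """
    if len(series.points) < 4:
        raise DomainError("need at least 4 time points to detect stationary onset")
    pts = [(p.t, p.biomass) for p in series.points]
    if any(b is None or b <= 0 for _, b in pts):
        raise DomainError("all biomass values must be positive (log undefined)")
    for j, (t_j, b_j) in enumerate(pts):
        # trailing span closest to `window` days, ending at t_j
        spans = [(t_j - t, b) for t, b in pts[:j] if t_j - t >= window]
        if not spans:
            continue
        dt, b_i = min(spans, key=lambda s: s[0])
        mu = (math.log(b_j) - math.log(b_i)) / dt
        if mu < mu_threshold:
            return t_j
    return None


def stage2_productivity(
    series: CultureTimeSeries, shock_day: float, duration: float = 2.0
) -> ProductivityResult:
    """Productivity of a stage-2 (salt-shock) culture over the shock window.

    The window is [shock_day, shock_day + duration]; the 48 h (2-day)
    default matches the standard two-stage shock protocol. Both endpoints
    must be sampled.
    """
    if series.stage != "S2":
        raise DomainError(f"stage2_productivity expects an S2 series, got {series.stage}")
    return biomass_productivity(series, shock_day, shock_day + duration)
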