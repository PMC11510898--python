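"""Domain types and delimited-text I/O for culture records.

Biomass is carried internally in mg·L⁻¹ dry weight. Calibration lines are
stored in g·L⁻¹ per OD unit exactly as laboratories report them and the
unit conversion happens once, at :func:`od_to_biomass`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from salgae.errors import DomainError, ParseError

logger = logging.getLogger(__name__)

Stage = Literal["S1", "S2"]

#: Columns of the canonical culture table, in on-disk order.
CULTURE_COLUMNS = ("species", "stage", "salinity_psu", "t_days", "od720", "biomass_mg_l")

#: Columns of the calibration table.
CALIBRATION_COLUMNS = ("species", "slope_g_per_l_per_od", "r2", "n")


@dataclass(frozen=True)
class TimePoint:
    """One sampling instant of a batch culture.

    Parameters
    ----------
    t : float
        Time since inoculation, days (>= 0).
    od720 : float or None
        Optical density at 720 nm, dimensionless.
    biomass : float or None
        Dry-weight biomass concentration, mg·L⁻¹.

    At least one of ``od720`` and ``biomass`` must be present.
    """

    t: float
    od720: float | None = None
    biomass: float | None = None

    def __post_init__(self) -> None:
        if self.t < 0 or not math.isfinite(self.t):
            raise DomainError(f"time must be finite and >= 0, got {self.t}")
        if self.od720 is None and self.biomass is None:
            raise DomainError("a time point needs od720 or biomass (or both)")
        if self.od720 is not None and self.od720 < 0:
            raise DomainError(f"od720 must be >= 0, got {self.od720}")
        if self.biomass is not None and self.biomass < 0:
            raise DomainError(f"biomass must be >= 0, got {self.biomass}")


@dataclass(frozen=True)
class CultureTimeSeries:
    """Ordered biomass/OD record of one species × salinity × stage culture."""

    species: str
    salinity: float
    stage: Stage
    points: tuple[TimePoint, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 < self.salinity <= 100:
            raise DomainError(
                f"salinity must be in (0, 100] PSU, got {self.salinity}"
            )
        if self.stage not in ("S1", "S2"):
            raise DomainError(f"stage must be 'S1' or 'S2', got {self.stage!r}")
        ts = [p.t for p in self.points]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise DomainError("time points must be strictly increasing in t")
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def times(self) -> list[float]:
        return [p.t for p in self.points]

    def biomass_at(self, t: float) -> float:
        """Biomass at a sampled time; raises if t is not sampled or biomass absent."""
        for p in self.points:
            if p.t == t:
                if p.biomass is None:
                    raise DomainError(f"no biomass recorded at t={t}")
                return p.biomass
        raise DomainError(
            f"t={t} not sampled; available times: {self.times}"
        )


@dataclass(frozen=True)
class CalibrationLine:
    """Dry weight vs OD720 proportionality for one species.

    The line passes through the origin; ``slope`` is in g·L⁻¹ per OD unit,
    the unit in which such calibrations are reported.
    """

    species: str
    slope: float
    r2: float = float("nan")
    n_points: int = 2

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DomainError(f"calibration slope must be > 0, got {self.slope}")
        if not math.isnan(self.r2) and not 0 <= self.r2 <= 1:
            raise DomainError(f"r2 must lie in [0, 1], got {self.r2}")
        if self.n_points < 2:
            raise DomainError("a calibration line needs at least 2 points")


@dataclass(frozen=True)
class NutrientRecord:
    """Initial/final macronutrient concentrations (μM) for one salinity."""

    salinity: float
    no3_initial: float
    no3_final: float
    po4_initial: float
    po4_final: float

    def __post_init__(self) -> None:
        for name in ("no3_initial", "no3_final", "po4_initial", "po4_final"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    @property
    def no3_consumed(self) -> float:
        """NO₃⁻ drawdown, clamped at zero (final may exceed initial by noise)."""
        return max(self.no3_initial - self.no3_final, 0.0)

    @property
    def po4_consumed(self) -> float:
        return max(self.po4_initial - self.po4_final, 0.0)


def od_to_biomass(od: float, calib: CalibrationLine) -> float:
    """Convert an OD720 reading to dry-weight biomass in mg·L⁻¹.

    The calibration is a pure proportion through the origin:
    ``biomass = od × slope × 1000`` (slope in g·L⁻¹/OD, result in mg·L⁻¹).
    """
    if od < 0:
        raise DomainError(f"od must be >= 0, got {od}")
    return od * calib.slope * 1000.0


def _detect_sep(path: Path) -> str:
    header = path.read_text(encoding="utf-8").splitlines()[0]
    return "\t" if "\t" in header else ","


def read_culture_table(
    path: str | Path,
    calibrations: dict[str, CalibrationLine] | None = None,
) -> list[CultureTimeSeries]:
    """Read a delimited culture table into grouped, time-sorted series.

    The table must carry ``species, stage, salinity_psu, t_days`` and at
    least one of ``od720`` / ``biomass_mg_l``. Comma or tab delimiting is
    auto-detected from the header row. When a calibration is supplied and a
    row has od720 but no biomass, biomass is computed on load; when both are
    present the measured biomass wins and a >10% discrepancy is logged.
    """
    path = Path(path)
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"species": str, "stage": str})
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc

    mandatory = {"species", "stage", "salinity_psu", "t_days"}
    missing = mandatory - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    if "od720" not in df.columns and "biomass_mg_l" not in df.columns:
        raise ParseError(f"{path}: need at least one of od720 / biomass_mg_l columns")
    for col in ("od720", "biomass_mg_l"):
        if col not in df.columns:
            df[col] = float("nan")

    for col in ("salinity_psu", "t_days", "od720", "biomass_mg_l"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric value in column {col!r}: {exc}") from exc

    dup = df.duplicated(subset=["species", "stage", "salinity_psu", "t_days"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ParseError(f"{path}: duplicate (series, t) at data row {row}")

    series: list[CultureTimeSeries] = []
    for (sp, st, sal), grp in df.groupby(["species", "stage", "salinity_psu"], sort=True):
        grp = grp.sort_values("t_days")
        pts = []
        for _, row in grp.iterrows():
            od = None if pd.isna(row["od720"]) else float(row["od720"])
            bm = None if pd.isna(row["biomass_mg_l"]) else float(row["biomass_mg_l"])
            calib = (calibrations or {}).get(str(sp))
            if calib is not None and od is not None:
                derived = od_to_biomass(od, calib)
                if bm is None:
                    bm = derived
                elif bm > 0 and abs(derived - bm) / bm > 0.10:
                    logger.warning(
                        "%s %s %.4g PSU t=%.4g: measured biomass %.4g differs "
                        ">10%% from OD-derived %.4g; keeping measurement",
                        sp, st, sal, row["t_days"], bm, derived,
                    )
            pts.append(TimePoint(t=float(row["t_days"]), od720=od, biomass=bm))
        series.append(
            CultureTimeSeries(species=str(sp), salinity=float(sal), stage=str(st), points=tuple(pts))
        )
    return series


def write_culture_table(
    series: Iterable[CultureTimeSeries], path: str | Path, sep: str = ","
) -> None:
    """Write series to the canonical long-format delimited table."""
    rows = []
    for s in series:
        for p in s.points:
            rows.append(
                {
                    "species": s.species,
                    "stage": s.stage,
                    "salinity_psu": s.salinity,
                    "t_days": p.t,
                    "od720": p.od720,
                    "biomass_mg_l": p.biomass,
                }
            )
    pd.DataFrame(rows, columns=list(CULTURE_COLUMNS)).to_csv(path, sep=sep, index=False)


def read_calibration_table(path: str | Path) -> dict[str, CalibrationLine]:
    """Read a calibration file (species, slope_g_per_l_per_od, r2, n)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    missing = {"species", "slope_g_per_l_per_od"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[str, CalibrationLine] = {}
    for _, row in df.iterrows():
        out[str(row["species"])] = CalibrationLine(
            species=str(row["species"]),
            slope=float(row["slope_g_per_l_per_od"]),
            r2=float(row.get("r2", float("nan"))),
            n_points=int(row.get("n", 2)),
        )
    return out


def write_calibration_table(
    calibs: Sequence[CalibrationLine], path: str | Path, sep: str = ","
) -> None:
    rows = [
        {"species": c.species, "slope_g_per_l_per_od": c.slope, "r2": c.r2, "n": c.n_points}
        for c in calibs
    ]
    pd.DataFrame(rows, columns=list(CALIBRATION_COLUMNS)).to_csv(path, sep=sep, index=False)
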