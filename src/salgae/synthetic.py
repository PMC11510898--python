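"""Synthetic culture datasets with the statistical structure the analysis assumes.

Growth curves are lagged logistics: biomass stays at the inoculum level
cb0 through a lag phase, then rises logistically toward a salinity-
dependent carrying capacity. The capacity is solved so that the
noiseless endpoint productivity over [0, t_final] equals the true
salinity-response model's prediction *exactly* — this endpoint
consistency is what makes parameter recovery on generated data a
meaningful check of the fitting pipeline rather than of the growth
shape. Salinities whose predicted productivity is negative are realised
as exponential decay toward a plateau below cb0, so the endpoint
identity holds there too.

Measurement noise is multiplicative lognormal (biomass is positive and
OD error scales with signal): Cb_obs = Cb · exp(σ·z), z ~ N(0,1).
Per-series seeds derive from the master seed as seed·1000 + grid index,
so any cited simulation is exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from salgae.culture_io import CultureTimeSeries, TimePoint
from salgae.errors import DomainError
from salgae.profiles import FattyAcidProfile, PigmentProfile
from salgae.salinity_model import SalinityResponseModel, optimum, predict

DEFAULT_SALINITY_GRID = tuple(range(5, 55, 5))


@dataclass(frozen=True)
class TwoStageConfig:
    """Stage-2 shock settings: when to shock and the response model."""

    stage2_model: SalinityResponseModel
    shock_day: float = 17.0
    duration: float = 2.0  # 48 h harvest window

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise DomainError("shock window duration must be > 0")


@dataclass(frozen=True)
class SyntheticExperimentConfig:
    """Full design of a synthetic salinity-screening experiment.

    Defaults emulate a small-volume discontinuous culture screen:
    ~10% inoculum (50 mg·L⁻¹), 2-day adaptation lag, 22-day harvest with
    daily sampling, salinity grid 5–50 PSU in steps of 5, and 5%
    multiplicative lognormal measurement noise.
    """

    true_model: SalinityResponseModel
    cb0: float = 50.0
    lag: float = 2.0
    mu_max: float = 0.5
    t_final: float = 22.0
    sample_times: tuple[float, ...] = ()
    salinity_grid: tuple[float, ...] = DEFAULT_SALINITY_GRID
    noise_sigma: float = 0.05
    seed: int = 0
    stage2: TwoStageConfig | None = None
    species: str = "synthetic"

    def __post_init__(self) -> None:
        if self.cb0 <= 0:
            raise DomainError("inoculum biomass cb0 must be > 0")
        if self.lag < 0:
            raise DomainError("lag must be >= 0")
        if self.mu_max <= 0:
            raise DomainError("mu_max must be > 0")
        if self.t_final <= self.lag:
            raise DomainError("t_final must exceed the lag phase")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")
        times = self.sample_times or tuple(
            float(t) for t in np.arange(0.0, self.t_final + 1e-9, 1.0)
        )
        if times[-1] < self.t_final:
            times = times + (self.t_final,)
        if any(t < 0 or t > self.t_final for t in times):
            raise DomainError("sample_times must lie in [0, t_final]")
        object.__setattr__(self, "sample_times", tuple(times))
        object.__setattr__(self, "salinity_grid", tuple(float(s) for s in self.salinity_grid))


def _noiseless_trajectory(
    cfg: SyntheticExperimentConfig, salinity: float, times: np.ndarray
) -> np.ndarray:
    """Lagged logistic (or decay) curve hitting the endpoint target exactly."""
    pb_target = predict(cfg.true_model, salinity)
    if not math.isfinite(pb_target):
        raise DomainError(f"true model predicts non-finite productivity at S={salinity}")
    endpoint = cfg.cb0 + pb_target * cfg.t_final
    if endpoint <= 0:
        raise DomainError(
            f"endpoint biomass {endpoint:.3g} <= 0 at S={salinity}: "
            "target productivity too negative for this cb0/t_final"
        )
    tau = cfg.t_final - cfg.lag
    u = np.clip(times - cfg.lag, 0.0, None)
    if endpoint == cfg.cb0:
        return np.full_like(times, cfg.cb0, dtype=float)
    if endpoint > cfg.cb0:
        # logistic toward capacity K solved so Cb(t_final) = endpoint
        d = math.exp(-cfg.mu_max * tau)
        if cfg.cb0 <= endpoint * d:
            raise DomainError(
                "mu_max too small to reach the target endpoint within t_final"
            )
        cap = endpoint * cfg.cb0 * (1.0 - d) / (cfg.cb0 - endpoint * d)
        return cap * cfg.cb0 / (cfg.cb0 + (cap - cfg.cb0) * np.exp(-cfg.mu_max * u))
    # negative productivity: exponential decay toward a plateau below cb0
    d = math.exp(-cfg.mu_max * tau)
    plateau = (endpoint - cfg.cb0 * d) / (1.0 - d)
    return plateau + (cfg.cb0 - plateau) * np.exp(-cfg.mu_max * u)


def simulate_growth_curve(
    cfg: SyntheticExperimentConfig, salinity: float, seed: int | None = None
) -> CultureTimeSeries:
    """One batch growth curve at the given salinity, stage S1.

    With ``noise_sigma=0`` the endpoint productivity over [0, t_final]
    equals ``predict(true_model, salinity)`` to machine precision.
    """
    if salinity <= 0:
        raise DomainError(f"salinity must be > 0 PSU, got {salinity}")
    times = np.asarray(cfg.sample_times, dtype=float)
    cb = _noiseless_trajectory(cfg, salinity, times)
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        cb = cb * np.exp(cfg.noise_sigma * rng.standard_normal(cb.shape))
    points = tuple(TimePoint(t=float(t), biomass=float(b)) for t, b in zip(times, cb))
    return CultureTimeSeries(
        species=cfg.species, salinity=float(salinity), stage="S1", points=points
    )


def series_seed(master_seed: int, grid_index: int) -> int:
    """Fixed per-series seed derivation: master·1000 + index."""
    return master_seed * 1000 + grid_index


def simulate_s1_experiment(cfg: SyntheticExperimentConfig) -> list[CultureTimeSeries]:
    """One S1 series per grid salinity, seeded deterministically."""
    grid = cfg.salinity_grid
    if not grid:
        raise DomainError("salinity grid is empty")
    if len(set(grid)) != len(grid):
        raise DomainError("duplicate salinities in grid")
    return [
        simulate_growth_curve(cfg, s, seed=series_seed(cfg.seed, i))
        for i, s in enumerate(grid)
    ]


def simulate_two_stage(
    cfg: SyntheticExperimentConfig,
) -> tuple[CultureTimeSeries, list[CultureTimeSeries]]:
    """Stage-1 run at the true optimum plus a 48 h shock series per salinity.

    Returns ``(s1_series, s2_series_list)``. Each S2 series starts from
    the stage-1 biomass at the shock day and ends (noiselessly) exactly
    at the stage-2 model's predicted productivity over the shock window.
    """
    if cfg.stage2 is None:
        raise DomainError("config has no stage2 block")
    st2 = cfg.stage2
    if st2.shock_day >= cfg.t_final:
        raise DomainError("shock_day must precede t_final")

    sopt_psu, _ = optimum(cfg.true_model)
    s1_times = np.asarray(
        sorted(set(t for t in cfg.sample_times if t <= st2.shock_day) | {st2.shock_day}),
        dtype=float,
    )
    s1_cb = _noiseless_trajectory(
        cfg, sopt_psu, np.asarray(cfg.sample_times, dtype=float)
    )
    # biomass at shock from the same noiseless trajectory evaluated at shock_day
    cb_shock = float(
        _noiseless_trajectory(cfg, sopt_psu, np.array([st2.shock_day]))[0]
    )
    rng = np.random.default_rng(series_seed(cfg.seed, 999))
    s1_vals = _noiseless_trajectory(cfg, sopt_psu, s1_times)
    if cfg.noise_sigma > 0:
        s1_vals = s1_vals * np.exp(cfg.noise_sigma * rng.standard_normal(s1_vals.shape))
    s1 = CultureTimeSeries(
        species=cfg.species,
        salinity=float(sopt_psu),
        stage="S1",
        points=tuple(
            TimePoint(t=float(t), biomass=float(b)) for t, b in zip(s1_times, s1_vals)
        ),
    )

    s2_list: list[CultureTimeSeries] = []
    t_grid = np.array([st2.shock_day, st2.shock_day + st2.duration / 2.0, st2.shock_day + st2.duration])
    for i, s in enumerate(cfg.salinity_grid):
        pb2 = predict(st2.stage2_model, s)
        end = cb_shock + pb2 * st2.duration
        if end <= 0:
            raise DomainError(f"stage-2 endpoint biomass <= 0 at S={s}")
        # linear segment within the 48 h window; endpoints carry the signal
        cb = cb_shock + (t_grid - st2.shock_day) * pb2
        if cfg.noise_sigma > 0:
            rng2 = np.random.default_rng(series_seed(cfg.seed, i) + 500_000)
            cb = cb * np.exp(cfg.noise_sigma * rng2.standard_normal(cb.shape))
        s2_list.append(
            CultureTimeSeries(
                species=cfg.species,
                salinity=float(s),
                stage="S2",
                points=tuple(
                    TimePoint(t=float(t), biomass=float(b)) for t, b in zip(t_grid, cb)
                ),
            )
        )
    return s1, s2_list


# ---------------------------------------------------------------------------
# Composition presets
#
# Each entry maps a component name to (value at 5 PSU, value at 50 PSU) in
# % of dry weight; values are interpolated linearly in salinity. Trends
# follow the qualitative patterns of the three source organisms: a
# haptophyte whose saturated-fatty-acid share falls with salinity while
# polyunsaturates rise, a dinoflagellate with the opposite SFA trend and a
# peridinin-dominated pigment pool, and a raphidophyte with a
# fucoxanthin-dominated pool and a violaxanthin-cycle DES that is high at
# extreme salinities and lowest near 20 PSU.
# ---------------------------------------------------------------------------

_FA_PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "rotalis-like": {
        "14:0": (2.00, 1.20), "16:0": (1.20, 0.80), "18:0": (0.60, 0.35),
        "16:1n7": (0.80, 0.90), "18:1n7": (0.40, 0.50), "20:1n9": (0.40, 0.40),
        "18:4n3": (0.90, 1.30), "20:5n3": (0.50, 0.90), "22:6n3": (0.85, 1.25),
    },
    "carterae-like": {
        "14:0": (0.50, 0.80), "16:0": (1.20, 2.00), "18:0": (0.30, 0.50),
        "18:1n9": (0.50, 0.55), "20:1n9": (0.20, 0.25),
        "18:4n3": (0.60, 0.60), "20:5n3": (1.00, 0.90), "22:6n3": (1.60, 1.50),
    },
    "akashiwo-like": {
        "14:0": (0.70, 0.50), "16:0": (1.80, 1.20),
        "16:1n7": (0.50, 0.60),
        "18:4n3": (0.80, 0.70), "20:5n3": (1.00, 1.30), "22:6n3": (0.40, 0.50),
    },
}

_PIGMENT_PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "rotalis-like": {
        "fucoxanthin": (0.50, 0.80), "hex-fucoxanthin": (0.20, 0.30),
        "4-keto-hex-fucoxanthin": (0.10, 0.15), "np-chl-c2": (0.10, 0.10),
        "beta-carotene": (0.05, 0.08),
    },
    "carterae-like": {
        "peridinin": (0.60, 0.90), "peridinol": (0.05, 0.08),
        "dinoxanthin": (0.05, 0.05), "beta-carotene": (0.04, 0.06),
    },
    "akashiwo-like": {
        "fucoxanthin": (1.20, 0.90), "hex-fucoxanthin": (0.10, 0.10),
        "beta-carotene": (0.05, 0.05),
    },
}

#: Xanthophyll-cycle pool size (% d.w.) and DES trend endpoints per preset.
_DES_PRESETS: dict[str, dict] = {
    "rotalis-like": {"cycle": "ddx", "pool": 0.30, "des_5": 40.0, "des_50": 80.0},
    "carterae-like": {"cycle": "ddx", "pool": 0.20, "des_5": 35.0, "des_50": 70.0},
    # U-shaped: photoprotective conversion maximal at extreme salinities
    "akashiwo-like": {"cycle": "vx", "pool": 0.25, "des_min": 55.0, "des_edge": 95.0, "s_min": 20.0},
}

#: Stage-2 class multipliers (salt shock shifts composition, not totals).
_S2_CLASS_FACTOR = {"SFA": 0.90, "MUFA": 1.00, "PUFA": 1.15}


def _interp(lo_hi: tuple[float, float], salinity: float) -> float:
    lo, hi = lo_hi
    frac = (salinity - 5.0) / 45.0
    return lo + (hi - lo) * frac


def simulate_composition(
    salinity: float,
    stage: str,
    preset: str,
    seed: int = 0,
    noise_sigma: float = 0.05,
) -> tuple[PigmentProfile, FattyAcidProfile]:
    """Pigment and fatty-acid profiles for one salinity × stage condition.

    Component means follow the preset's linear (or, for the DES index,
    U-shaped) salinity trends; noise is relative Gaussian truncated at
    zero. With ``noise_sigma=0`` the profiles are deterministic and the
    de-epoxidation indices follow the preset trend exactly.
    """
    from salgae.profiles import classify_fatty_acid  # local to avoid cycle confusion

    if preset not in _FA_PRESETS:
        raise DomainError(
            f"unknown preset {preset!r}; choose from {sorted(_FA_PRESETS)}"
        )
    if stage not in ("S1", "S2"):
        raise DomainError(f"stage must be 'S1' or 'S2', got {stage!r}")
    if not 0 < salinity <= 100:
        raise DomainError("salinity must be in (0, 100] PSU")
    rng = np.random.default_rng(seed)

    fa: dict[str, float] = {}
    for name, lo_hi in _FA_PRESETS[preset].items():
        mean = _interp(lo_hi, salinity)
        if stage == "S2":
            mean *= _S2_CLASS_FACTOR[classify_fatty_acid(name)]
        val = mean * (1.0 + noise_sigma * rng.standard_normal()) if noise_sigma > 0 else mean
        fa[name] = max(val, 0.0)

    pig: dict[str, float] = {}
    for name, lo_hi in _PIGMENT_PRESETS[preset].items():
        mean = _interp(lo_hi, salinity)
        val = mean * (1.0 + noise_sigma * rng.standard_normal()) if noise_sigma > 0 else mean
        pig[name] = max(val, 0.0)

    des_cfg = _DES_PRESETS[preset]
    pool = des_cfg["pool"]
    if des_cfg["cycle"] == "ddx":
        des = _interp((des_cfg["des_5"], des_cfg["des_50"]), salinity)
        des = float(np.clip(des, 0.0, 100.0))
        pig["diatoxanthin"] = pool * des / 100.0
        pig["diadinoxanthin"] = pool * (1.0 - des / 100.0)
    else:
        half_span = max(des_cfg["s_min"] - 5.0, 50.0 - des_cfg["s_min"])
        rel = ((salinity - des_cfg["s_min"]) / half_span) ** 2
        des = des_cfg["des_min"] + (des_cfg["des_edge"] - des_cfg["des_min"]) * rel
        des = float(np.clip(des, 0.0, 100.0))
        pig["zeaxanthin"] = pool * des / 100.0
        pig["violaxanthin"] = pool * (1.0 - des / 100.0)
        pig["antheraxanthin"] = 0.0
    if noise_sigma > 0:
        for k in ("diatoxanthin", "diadinoxanthin", "zeaxanthin", "violaxanthin"):
            if k in pig:
                pig[k] = max(pig[k] * (1.0 + noise_sigma * rng.standard_normal()), 0.0)

    return PigmentProfile(components=pig), FattyAcidProfile(components=fa)
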