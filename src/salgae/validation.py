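"""Goodness-of-fit and predictive-microbiology validation statistics.

The bias factor Bf = 10^(mean log10(pred/obs)) measures systematic over-
or under-prediction; the accuracy factor Af = 10^(mean |log10(pred/obs)|)
measures absolute deviation and satisfies Af >= max(Bf, 1/Bf) >= 1
(Ross 1996 convention). Pairs where either productivity is non-positive
are excluded from Bf/Af (their log-ratio is undefined) and counted;
RMSE and r² use all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from salgae.errors import DomainError


@dataclass
class FitDiagnostics:
    """Validation statistics for predicted-vs-observed productivities."""

    rmse: float
    bf: float
    af: float
    r2: float
    n_used: int
    n_excluded_nonpositive: int = 0
    warnings: tuple[str, ...] = field(default_factory=tuple)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise DomainError("rmse must be >= 0")


def _as_pair(predicted, observed) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise DomainError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise DomainError("empty input")
    return p, o


def rmse(predicted, observed) -> float:
    """Root mean square error sqrt(Σ(pred − obs)²/n)."""
    p, o = _as_pair(predicted, observed)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def _log_ratios(predicted, observed) -> tuple[np.ndarray, int]:
    p, o = _as_pair(predicted, observed)
    keep = (p > 0) & (o > 0)
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise DomainError("no strictly positive predicted/observed pairs remain")
    return np.log10(p[keep] / o[keep]), n_excluded


def bias_factor(predicted, observed) -> float:
    """Bf = 10^(Σ log10(pred/obs)/n); 1 means no systematic bias."""
    lr, _ = _log_ratios(predicted, observed)
    return float(10.0 ** lr.mean())


def accuracy_factor(predicted, observed) -> float:
    """Af = 10^(Σ |log10(pred/obs)|/n); 1 means perfect agreement."""
    lr, _ = _log_ratios(predicted, observed)
    return float(10.0 ** np.abs(lr).mean())


def r_squared(predicted, observed) -> float:
    """Coefficient of determination 1 − SSres/SStot against the observed mean.

    This is not the squared Pearson correlation; for a biased predictor
    the two differ, and r² here can be negative.
    """
    p, o = _as_pair(predicted, observed)
    if p.size < 2:
        raise DomainError("r² needs at least 2 pairs")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise DomainError("observed values all equal: r² undefined")
    ss_res = float(np.sum((p - o) ** 2))
    return 1.0 - ss_res / ss_tot


def diagnostics(
    predicted, observed, seed: int | None = None, warnings: tuple[str, ...] = ()
) -> FitDiagnostics:
    """Bundle RMSE, Bf, Af and r² for one predicted/observed set."""
    p, o = _as_pair(predicted, observed)
    keep = (p > 0) & (o > 0)
    n_excluded = int((~keep).sum())
    warn = tuple(warnings)
    if keep.any():
        lr = np.log10(p[keep] / o[keep])
        bf = float(10.0 ** lr.mean())
        af = float(10.0 ** np.abs(lr).mean())
        n_used = int(keep.sum())
    else:
        bf = af = float("nan")
        n_used = 0
        warn = warn + ("no positive pairs: Bf/Af undefined",)
    try:
        r2 = r_squared(p, o)
    except DomainError as exc:
        r2 = float("nan")
        warn = warn + (str(exc),)
    return FitDiagnostics(
        rmse=rmse(p, o),
        bf=bf,
        af=af,
        r2=r2,
        n_used=n_used,
        n_excluded_nonpositive=n_excluded,
        warnings=warn,
        seed=seed,
    )
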