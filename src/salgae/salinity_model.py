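"""Gaussian-type salinity–productivity response model.

The response of endpoint biomass productivity Pb to culture-medium
salinity S is modelled as

    Pb(S) = Pmax + a · (exp(−((S' − Sopt)/b)²) − 1)

where S' is S itself or log10(S) (the decimal-log variant suits
halotolerant organisms whose productivity responds weakly over wide
salinity ranges). Pmax is the productivity at the optimum Sopt; a >= 0 is
the depth of suppression far from the optimum (far-field limit
Pmax − a, which may be negative: growth inhibition); b > 0 is the
response width in the units of S'.

Fitting is nonlinear least squares with a deterministic multi-start over
(Sopt, b), the pair in which the objective is multimodal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from salgae.errors import DomainError, UnderdeterminedError
from salgae.validation import FitDiagnostics, diagnostics

logger = logging.getLogger(__name__)

Transform = Literal["identity", "log10"]

#: Jacobian condition number above which a confounding warning is attached.
_COND_WARN = 1e8


@dataclass(frozen=True)
class SalinityResponseModel:
    """Fitted or assumed parameters of the salinity-response curve.

    ``sopt`` is stored on the transformed scale (log10 PSU when
    ``transform == 'log10'``); :func:`optimum` back-transforms it.
    """

    pmax: float
    a: float
    b: float
    sopt: float
    transform: Transform = "identity"

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise DomainError(f"width b must be > 0, got {self.b}")
        if self.a < 0:
            raise DomainError(f"suppression depth a must be >= 0, got {self.a}")
        if self.transform not in ("identity", "log10"):
            raise DomainError(f"unknown transform {self.transform!r}")

    def to_dict(self) -> dict:
        return {
            "pmax": self.pmax,
            "a": self.a,
            "b": self.b,
            "sopt": self.sopt,
            "transform": self.transform,
        }


@dataclass(frozen=True)
class SalinityObservation:
    """One (salinity, endpoint productivity) design point."""

    salinity: float
    pb: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.salinity <= 0:
            raise DomainError(f"salinity must be > 0 PSU, got {self.salinity}")
        if self.weight <= 0:
            raise DomainError("weight must be > 0")


def _transform_s(s: np.ndarray, transform: Transform) -> np.ndarray:
    if np.any(s <= 0):
        raise DomainError("salinity must be > 0 PSU")
    return np.log10(s) if transform == "log10" else s


def predict(model: SalinityResponseModel, s) -> float | np.ndarray:
    """Predicted productivity Pb(S), mg·L⁻¹·day⁻¹, for salinity s in PSU."""
    s_arr = np.asarray(s, dtype=float)
    sp = _transform_s(s_arr, model.transform)
    out = model.pmax + model.a * (np.exp(-(((sp - model.sopt) / model.b) ** 2)) - 1.0)
    return float(out) if np.isscalar(s) or s_arr.ndim == 0 else out


def optimum(model: SalinityResponseModel) -> tuple[float, float]:
    """(optimal salinity in PSU, maximum productivity).

    On the decimal-log transform the stored optimum is back-transformed
    with 10^sopt.
    """
    sopt_psu = 10.0 ** model.sopt if model.transform == "log10" else model.sopt
    return sopt_psu, model.pmax


def _residuals(x: np.ndarray, sp: np.ndarray, pb: np.ndarray, w: np.ndarray) -> np.ndarray:
    pmax, a, b, sopt = x
    pred = pmax + a * (np.exp(-(((sp - sopt) / b) ** 2)) - 1.0)
    return w * (pred - pb)


def fit(
    data: Sequence[SalinityObservation],
    transform: Transform = "identity",
    bounds: dict[str, tuple[float, float]] | None = None,
    n_random_starts: int = 8,
    seed: int = 0,
) -> tuple[SalinityResponseModel, FitDiagnostics]:
    """Least-squares fit of the salinity-response model.

    Multi-start initialisation: Sopt at the salinities of the three
    highest observed productivities; b at a quarter, half and the full
    observed salinity span; Pmax at max(pb); a at the observed Pb range —
    plus ``n_random_starts`` seeded draws inside the bounds. The start
    with the lowest residual sum of squares wins.

    Default bounds: a in [0, 10·range(pb)], b in [0.1, 10·span(S')],
    Sopt within the tested span widened by one b-bound, Pmax free.
    Pass ``bounds={'a': (lo, hi), ...}`` to override any of them (e.g.
    to enforce a <= pmax and forbid negative far-field productivity).

    Raises UnderdeterminedError with fewer than 4 distinct salinities.
    """
    if len(data) < 4:
        raise UnderdeterminedError(
            f"need >= 4 observations for 4 free parameters, got {len(data)}"
        )
    s = np.array([d.salinity for d in data], dtype=float)
    pb = np.array([d.pb for d in data], dtype=float)
    w = np.sqrt(np.array([d.weight for d in data], dtype=float))
    if len(np.unique(s)) < 4:
        raise UnderdeterminedError(
            f"need >= 4 distinct salinities, got {len(np.unique(s))}"
        )
    sp = _transform_s(s, transform)

    pb_range = float(pb.max() - pb.min())
    span = float(sp.max() - sp.min())
    degenerate = pb_range == 0.0
    warn: tuple[str, ...] = ()

    default_bounds = {
        "pmax": (-np.inf, np.inf),
        "a": (0.0, 10.0 * pb_range if pb_range > 0 else 1.0),
        "b": (0.1, 10.0 * span),
        "sopt": (float(sp.min()) - 10.0 * span, float(sp.max()) + 10.0 * span),
    }
    if bounds:
        default_bounds.update(bounds)
    lo = np.array([default_bounds[k][0] for k in ("pmax", "a", "b", "sopt")])
    hi = np.array([default_bounds[k][1] for k in ("pmax", "a", "b", "sopt")])

    if degenerate:
        model = SalinityResponseModel(
            pmax=float(pb[0]), a=0.0, b=max(span / 2.0, 0.1) if span > 0 else 1.0,
            sopt=float(sp.mean()), transform=transform,
        )
        pred = predict(model, s)
        warn = ("all observed productivities identical: a ~ 0, b unidentifiable",)
        logger.warning(warn[0])
        diag = diagnostics(pred, pb, seed=seed, warnings=warn)
        return model, diag

    # deterministic starts: top-3 pb salinities × three widths
    order = np.argsort(pb)[::-1]
    sopt_starts = [float(sp[i]) for i in order[:3]]
    b_starts = [max(span / 4.0, 0.15), max(span / 2.0, 0.3), max(span, 0.6)]
    pmax0 = float(pb.max())
    a0 = max(pb_range, 1e-3)
    starts = [
        np.array([pmax0, a0, b0, s0]) for s0 in sopt_starts for b0 in b_starts
    ]
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        starts.append(
            np.array(
                [
                    pmax0 * (1 + 0.2 * rng.standard_normal()),
                    a0 * rng.uniform(0.2, 2.0),
                    rng.uniform(max(span / 8.0, 0.15), max(2.0 * span, 1.0)),
                    rng.uniform(float(sp.min()), float(sp.max())),
                ]
            )
        )

    best = None
    for x0 in starts:
        x0 = np.maximum(x0, lo + 1e-12)
        x0 = np.where(np.isfinite(hi), np.minimum(x0, hi - 1e-12), x0)
        try:
            res = least_squares(
                _residuals, x0, args=(sp, pb, w), bounds=(lo, hi),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimisation starts failed")

    pmax_f, a_f, b_f, sopt_f = best.x
    model = SalinityResponseModel(
        pmax=float(pmax_f), a=float(a_f), b=float(b_f), sopt=float(sopt_f),
        transform=transform,
    )

    # identifiability: all observations within one width of the optimum
    # confounds a with pmax; flag via the Jacobian condition number
    jac = best.jac
    sv = np.linalg.svd(jac, compute_uv=False)
    if sv[-1] == 0 or sv[0] / max(sv[-1], 1e-300) > _COND_WARN:
        warn = warn + (
            "ill-conditioned fit (observations may all lie within one width "
            "of the optimum; a and pmax confounded)",
        )
        logger.warning(warn[-1])

    pred = predict(model, s)
    diag = diagnostics(pred, pb, seed=seed, warnings=warn)
    return model, diag


def fit_log_salinity(
    data: Sequence[SalinityObservation], **kwargs
) -> tuple[SalinityResponseModel, FitDiagnostics]:
    """Fit with the decimal-log salinity transform (halotolerant variant)."""
    kwargs.pop("transform", None)
    return fit(data, transform="log10", **kwargs)
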