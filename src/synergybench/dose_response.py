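"""Monotherapy Hill-curve fitting, Loewe-additive reference surfaces and synergy scoring.

A combination experiment is a 6x6 viability matrix (% of untreated control):
row 0 and column 0 hold the two monotherapies, cell (0, 0) the untreated
control, and the inner 5x5 block the true combination measurements.  The
scoring pipeline is

1. fit a Hill curve to each monotherapy,
2. build the Loewe-additive reference surface from the two fits,
3. subtract the observed surface from the reference (synergy distribution),
4. integrate the distribution over log10-concentration space, normalised by
   the integration area, and cap the result to [-100, 100].

Positive scores mean the observed viability lies below the additive
expectation (synergy); scores >= 20 are classed synergistic and <= -20
antagonistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SCORE_CAP",
    "SYNERGY_THRESHOLD",
    "ANTAGONISM_THRESHOLD",
    "UnreachableEffectError",
    "HillCurve",
    "DoseResponseMatrix",
    "SynergyRecord",
    "fit_hill",
    "hill_response",
    "inverse_hill",
    "loewe_surface",
    "synergy_distribution",
    "synergy_score",
    "classify_in_vitro",
    "fit_monotherapies",
    "score_experiment",
    "score_screen",
]

SCORE_CAP = 100.0
SYNERGY_THRESHOLD = 20.0
ANTAGONISM_THRESHOLD = -20.0

#: Loewe bisection: residual tolerance on the additivity equation and
#: iteration cap.
_BISECT_TOL = 1e-8
_BISECT_MAXITER = 200


class UnreachableEffectError(ValueError):
    """The requested effect lies outside the curve's open range (e_inf, e0)."""


@dataclass(frozen=True)
class HillCurve:
    """Four-parameter sigmoidal viability model.

    ``E(d) = e_inf + (e0 - e_inf) / (1 + (d / ec50) ** h)``

    Viability is non-increasing with dose, so ``e0 >= e_inf``.
    """

    e0: float
    e_inf: float
    ec50: float
    h: float
    no_effect: bool = False
    rmse: float = 0.0

    def __post_init__(self) -> None:
        if not self.no_effect:
            if self.ec50 <= 0:
                raise ValueError(f"ec50 must be positive, got {self.ec50}")
            if self.h <= 0:
                raise ValueError(f"Hill slope must be positive, got {self.h}")
            if self.e0 < self.e_inf:
                raise ValueError("e0 must be >= e_inf (viability non-increasing)")


@dataclass
class DoseResponseMatrix:
    """One combination experiment on a 6x6 dose grid.

    ``viability[i, j]`` is measured at ``(doses_a[i], doses_b[j])``; index 0
    of each dose vector is dose 0, so row 0 is the drug-B monotherapy,
    column 0 the drug-A monotherapy and (0, 0) the untreated control.
    """

    combo_id: str
    cell_id: str
    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        _validate_dose_vector(self.doses_a, "doses_a")
        _validate_dose_vector(self.doses_b, "doses_b")
        if self.viability.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValueError(
                f"viability shape {self.viability.shape} does not match dose "
                f"vectors ({len(self.doses_a)}, {len(self.doses_b)})"
            )
        if not np.all(np.isfinite(self.viability)):
            raise ValueError("viability contains non-finite values")


@dataclass(frozen=True)
class SynergyRecord:
    """Per-experiment capped Loewe score plus fit diagnostics."""

    combo_id: str
    cell_id: str
    drug_a: str
    drug_b: str
    score: float
    synergy_class: str
    rmse_a: float
    rmse_b: float
    flags: tuple = field(default_factory=tuple)


def _validate_dose_vector(doses: np.ndarray, name: str) -> None:
    if doses[0] != 0:
        raise ValueError(f"{name}[0] must be 0 (untreated)")
    if np.any(np.diff(doses) <= 0):
        raise ValueError(f"{name} must be strictly increasing")


def hill_response(curve: HillCurve, dose):
    """Viability (% control) at ``dose``; accepts scalars or arrays."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    if curve.no_effect:
        out = np.full_like(d, curve.e0, dtype=float)
        return float(out) if np.isscalar(dose) else out
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d / curve.ec50) ** curve.h, 0.0)
    out = curve.e_inf + (curve.e0 - curve.e_inf) / (1.0 + ratio)
    return float(out) if np.isscalar(dose) else out


def inverse_hill(curve: HillCurve, effect: float) -> float:
    """Unique dose producing ``effect``, the closed-form Hill inverse.

    Raises :class:`UnreachableEffectError` when no finite dose can reach the
    effect, i.e. outside the open interval (e_inf, e0).
    """
    if curve.no_effect or not (curve.e_inf < effect < curve.e0):
        raise UnreachableEffectError(
            f"effect {effect} not in ({curve.e_inf}, {curve.e0})"
        )
    return curve.ec50 * ((curve.e0 - effect) / (effect - curve.e_inf)) ** (1.0 / curve.h)


def _hill_model(params: np.ndarray, doses: np.ndarray) -> np.ndarray:
    e0, e_inf, log_ec50, h = params
    ratio = np.where(doses > 0, (doses / 10.0 ** log_ec50) ** h, 0.0)
    return e_inf + (e0 - e_inf) / (1.0 + ratio)


def fit_hill(doses, viability) -> HillCurve:
    """Bounded multi-start least-squares Hill fit to one monotherapy series.

    Bounds: e0 in [80, 120], e_inf in [0, 110], h in [0.1, 10], ec50 within
    [min positive dose / 100, max dose * 100].  A response that is constant
    (or increasing with dose) collapses to a flat curve flagged ``no_effect``.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.shape != viability.shape:
        raise ValueError("doses and viability must have equal length")
    if len(np.unique(doses)) < 4 or 0 not in doses:
        raise ValueError("need >=4 distinct doses including dose 0")
    if not np.all(np.isfinite(viability)):
        raise ValueError("viability must be finite")

    order = np.argsort(doses)
    doses, viability = doses[order], viability[order]
    pos = doses[doses > 0]

    if float(np.ptp(viability)) < 1e-6:
        mean = float(np.mean(viability))
        return HillCurve(mean, mean, float(np.sqrt(pos[0] * pos[-1])), 1.0,
                         no_effect=True, rmse=float(np.std(viability)))

    lo_ec, hi_ec = pos[0] / 100.0, pos[-1] * 100.0
    lower = np.array([80.0, 0.0, np.log10(lo_ec), 0.1])
    upper = np.array([120.0, 110.0, np.log10(hi_ec), 10.0])

    e0_guess = float(np.clip(viability[0], 80.0, 120.0))
    einf_guess = float(np.clip(viability[-1], 0.0, 110.0))
    lec_lo, lec_hi = np.log10(pos[0]), np.log10(pos[-1])
    starts = [np.array([e0_guess, einf_guess, lec, h0]) for lec, h0 in
              ((0.5 * (lec_lo + lec_hi), 1.0), (lec_lo, 0.8),
               (lec_hi, 0.8), (0.5 * (lec_lo + lec_hi), 3.0))]

    best, best_cost = None, np.inf
    for x0 in starts:
        x0 = np.clip(x0, lower + 1e-9, upper - 1e-9)
        res = least_squares(
            lambda p: _hill_model(p, doses) - viability,
            x0, bounds=(lower, upper), method="trf", xtol=1e-12, ftol=1e-12,
        )
        if res.cost < best_cost:
            best, best_cost = res, res.cost
        if best_cost < 1e-12:  # exact fit found; further starts cannot improve
            break
    e0, e_inf, log_ec50, h = best.x
    rmse = float(np.sqrt(np.mean(best.fun ** 2)))
    if e_inf >= e0 - 1e-9:
        # increasing / flat fit: no dose effect recoverable
        mean = float(np.mean(viability))
        return HillCurve(mean, mean, float(np.sqrt(pos[0] * pos[-1])), 1.0,
                         no_effect=True, rmse=rmse)
    return HillCurve(float(e0), float(e_inf), float(10.0 ** log_ec50), float(h),
                     rmse=rmse)


def _loewe_cell(curve_a: HillCurve, curve_b: HillCurve, a: float, b: float):
    """Solve a/D_A(E) + b/D_B(E) = 1 for the additive effect E by bisection.

    Returns ``(effect, fallback)`` where ``fallback`` marks cells for which no
    solution exists in the common reachable effect interval; those take the
    highest-single-agent effect instead.
    """
    hsa = min(hill_response(curve_a, a), hill_response(curve_b, b))
    if curve_a.no_effect or curve_b.no_effect:
        return hsa, True
    lo = max(curve_a.e_inf, curve_b.e_inf)
    hi = min(curve_a.e0, curve_b.e0)
    if hi <= lo:
        return hsa, True

    def residual(effect: float) -> float:
        return (a / inverse_hill(curve_a, effect)
                + b / inverse_hill(curve_b, effect) - 1.0)

    span = hi - lo
    e_lo = lo + 1e-12 * span
    e_hi = hi - 1e-12 * span
    f_lo = residual(e_lo)
    if f_lo > 0:  # even the strongest common effect cannot satisfy additivity
        return hsa, True
    f_hi = residual(e_hi)
    if f_hi < 0:  # doses too large for the common interval (should not occur)
        return hsa, True
    for _ in range(_BISECT_MAXITER):
        mid = 0.5 * (e_lo + e_hi)
        f_mid = residual(mid)
        if abs(f_mid) < _BISECT_TOL and (e_hi - e_lo) < 1e-9 * span:
            return mid, False
        if f_mid < 0:
            e_lo = mid
        else:
            e_hi = mid
    return 0.5 * (e_lo + e_hi), False


def loewe_surface(curve_a: HillCurve, curve_b: HillCurve, doses_a, doses_b):
    """Loewe-additive reference surface on the experiment's dose grid.

    Returns ``(surface, fallback)``: a matrix of additive % viability whose
    monotherapy row/column equal the fitted curves and whose (0, 0) entry is
    ``min(e0_a, e0_b)``, plus a boolean mask of combination cells where the
    additivity equation had no solution and the highest-single-agent effect
    was used.
    """
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    _validate_dose_vector(doses_a, "doses_a")
    _validate_dose_vector(doses_b, "doses_b")
    na, nb = len(doses_a), len(doses_b)
    surface = np.empty((na, nb))
    fallback = np.zeros((na, nb), dtype=bool)
    surface[0, 0] = min(curve_a.e0, curve_b.e0)
    surface[1:, 0] = hill_response(curve_a, doses_a[1:])
    surface[0, 1:] = hill_response(curve_b, doses_b[1:])
    for i in range(1, na):
        for j in range(1, nb):
            surface[i, j], fallback[i, j] = _loewe_cell(
                curve_a, curve_b, doses_a[i], doses_b[j]
            )
    return surface, fallback


def synergy_distribution(observed: np.ndarray, additive: np.ndarray) -> np.ndarray:
    """Additive minus observed viability over the inner combination block.

    Positive entries indicate synergy (observed viability below the additive
    expectation).
    """
    observed = np.asarray(observed, dtype=float)
    additive = np.asarray(additive, dtype=float)
    if observed.shape != additive.shape:
        raise ValueError(
            f"shape mismatch: observed {observed.shape} vs additive {additive.shape}"
        )
    if observed.ndim != 2 or observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError("matrices must be 2-D with at least 2 doses per axis")
    return additive[1:, 1:] - observed[1:, 1:]


def synergy_score(dist: np.ndarray, doses_a, doses_b) -> float:
    """Area-normalised trapezoidal integral of the synergy distribution in
    log10-concentration space, capped to [-100, 100]."""
    dist = np.asarray(dist, dtype=float)
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    la = np.log10(doses_a[doses_a > 0])
    lb = np.log10(doses_b[doses_b > 0])
    if len(la) < 2 or len(lb) < 2:
        raise ValueError("need at least 2 positive doses on each axis")
    if dist.shape != (len(la), len(lb)):
        raise ValueError(
            f"distribution shape {dist.shape} does not match positive-dose "
            f"grid ({len(la)}, {len(lb)})"
        )
    inner = np.trapezoid(dist, x=lb, axis=1)
    integral = float(np.trapezoid(inner, x=la))
    area = (la[-1] - la[0]) * (lb[-1] - lb[0])
    return float(np.clip(integral / area, -SCORE_CAP, SCORE_CAP))


def classify_in_vitro(score: float) -> str:
    """Threshold classes: >=20 synergistic, <=-20 antagonistic, else additive."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    if score >= SYNERGY_THRESHOLD:
        return "synergistic"
    if score <= ANTAGONISM_THRESHOLD:
        return "antagonistic"
    return "additive"


def fit_monotherapies(matrix: DoseResponseMatrix):
    """Fit both monotherapy Hill curves of one experiment."""
    return (fit_hill(matrix.doses_a, matrix.viability[:, 0]),
            fit_hill(matrix.doses_b, matrix.viability[0, :]))


def score_experiment(matrix: DoseResponseMatrix, curves=None) -> SynergyRecord:
    """Run the full scoring pipeline on one experiment.

    ``curves`` may carry pre-fitted monotherapy curves ``(curve_a, curve_b)``
    to share fits with other per-experiment computations.
    """
    curve_a, curve_b = curves if curves is not None else fit_monotherapies(matrix)
    additive, fb = loewe_surface(curve_a, curve_b, matrix.doses_a, matrix.doses_b)
    dist = synergy_distribution(matrix.viability, additive)
    score = synergy_score(dist, matrix.doses_a, matrix.doses_b)
    flags = []
    if curve_a.no_effect:
        flags.append("no-effect-a")
    if curve_b.no_effect:
        flags.append("no-effect-b")
    if fb.any():
        flags.append(f"loewe-fallback:{int(fb.sum())}")
    return SynergyRecord(
        combo_id=matrix.combo_id,
        cell_id=matrix.cell_id,
        drug_a=matrix.drug_a,
        drug_b=matrix.drug_b,
        score=score,
        synergy_class=classify_in_vitro(score),
        rmse_a=curve_a.rmse,
        rmse_b=curve_b.rmse,
        flags=tuple(flags),
    )


def score_screen(matrices, curves=None) -> "pandas.DataFrame":
    """Score a collection of experiments into a tidy synergy table.

    ``curves`` optionally maps experiment index to pre-fitted monotherapy
    curve pairs.
    """
    import pandas as pd

    records = [score_experiment(m, curves[i] if curves is not None else None)
               for i, m in enumerate(matrices)]
    return pd.DataFrame(
        {
            "combo_id": [r.combo_id for r in records],
            "cell_id": [r.cell_id for r in records],
            "drug_a": [r.drug_a for r in records],
            "drug_b": [r.drug_b for r in records],
            "score": [r.score for r in records],
            "synergy_class": [r.synergy_class for r in records],
            "rmse_a": [r.rmse_a for r in records],
            "rmse_b": [r.rmse_b for r in records],
            "flags": [";".join(r.flags) for r in records],
        }
    )
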