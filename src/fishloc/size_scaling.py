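"""RNA size-scaling models and the selected-fraction power calculation.

The radius of gyration of an RNA of N nucleotides is modeled as the
power law R_g = a * N**nu, fit by nonlinear least squares in linear
(untransformed) R_g space.  Utilities convert R_g to an equivalent
solid-sphere diameter (2 * sqrt(5/3) * R_g), classify expected nucleoid
penetrance, solve for the pixel fraction F_T that a one-sample
proportion test needs for a given power, and compute the lower bound on
the chaperone-bound fraction implied by a concentration drop upon
chaperone deletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SPHERE_FACTOR",
    "RgDatum",
    "RgModel",
    "PowerCalcSpec",
    "fit_power_law",
    "predict_rg",
    "sphere_diameter",
    "penetrance_class",
    "selected_fraction_power",
    "hfq_bound_lower_bound",
]

#: sphere diameter per unit radius of gyration for a uniform solid sphere
SPHERE_FACTOR = 2.0 * np.sqrt(5.0 / 3.0)


@dataclass(frozen=True)
class RgDatum:
    """One literature measurement: RNA label, length (nt), R_g (angstrom)."""

    label: str
    n_nt: int
    rg: float
    rna_class: str = "other"

    def __post_init__(self) -> None:
        if self.n_nt < 1:
            raise ValueError("n_nt must be >= 1")
        if self.rg <= 0:
            raise ValueError("rg must be positive")


@dataclass(frozen=True)
class RgModel:
    """Fitted power-law parameters (angstrom scale)."""

    a: float
    nu: float
    a_sd: float = float("nan")
    nu_sd: float = float("nan")
    adj_r2: float = float("nan")
    n_points: int = 0

    def predict(self, n_nt: float) -> float:
        return self.a * float(n_nt) ** self.nu


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if len(data) and isinstance(data[0], RgDatum):
        n = np.array([d.n_nt for d in data], dtype=float)
        rg = np.array([d.rg for d in data], dtype=float)
    else:
        n, rg = (np.asarray(x, dtype=float) for x in zip(*data))
    return n, rg


def fit_power_law(data: Sequence) -> RgModel:
    """Fit R_g = a * N**nu by Levenberg-Marquardt least squares.

    ``data`` is a sequence of :class:`RgDatum` or (N, rg) pairs.
    Parameter standard deviations come from the covariance of the fit;
    adjusted R^2 uses p = 2 parameters (undefined, NaN, for n < 4).
    The fit is deterministic: the initial guess is (a, nu) = (1, 0.5).
    """
    n, rg = _as_arrays(data)
    if n.size < 3:
        raise ValueError("need at least 3 data points")
    if np.unique(n).size < 3:
        raise ValueError("need at least 3 distinct N values")

    def model(x, a, nu):
        return a * x**nu

    try:
        popt, pcov = optimize.curve_fit(
            model, n, rg, p0=(1.0, 0.5), method="lm", maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"power-law fit did not converge: {exc}") from exc
    if not np.all(np.isfinite(popt)):
        raise RuntimeError("power-law fit produced non-finite parameters")

    residuals = rg - model(n, *popt)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((rg - rg.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    size = n.size
    adj_r2 = (
        1.0 - (1.0 - r2) * (size - 1) / (size - 2 - 1) if size > 3 else float("nan")
    )
    sds = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return RgModel(
        a=float(popt[0]),
        nu=float(popt[1]),
        a_sd=float(sds[0]),
        nu_sd=float(sds[1]),
        adj_r2=adj_r2,
        n_points=int(size),
    )


def predict_rg(model: RgModel, n_nt: float) -> float:
    """Predicted radius of gyration (angstrom, unrounded) for N nucleotides."""
    if n_nt < 1:
        raise ValueError("n_nt must be >= 1")
    return model.predict(n_nt)


def sphere_diameter(rg: float) -> float:
    """Solid-sphere diameter equivalent of a radius of gyration."""
    if rg <= 0:
        raise ValueError("rg must be positive")
    return SPHERE_FACTOR * rg


def penetrance_class(
    rg: float, high_below: float = 80.0, low_at_or_above: float = 114.3
) -> str:
    """Classify expected nucleoid penetrance from R_g (angstrom).

    Below ~80 angstrom RNAs behave like the small regulatory RNAs that
    enter the nucleoid freely ("high"); at or above the full-length
    untranslated reporter benchmark (114.3 angstrom) they are strongly
    excluded ("low"); in between is "intermediate".
    """
    if rg <= 0:
        raise ValueError("rg must be positive")
    if high_below >= low_at_or_above:
        raise ValueError("high_below must be < low_at_or_above")
    if rg < high_below:
        return "high"
    if rg >= low_at_or_above:
        return "low"
    return "intermediate"


@dataclass(frozen=True)
class PowerCalcSpec:
    """Assumptions for the selected-fraction power calculation."""

    alpha: float = 0.05
    power: float = 0.8
    n_cells: int = 30
    pixels_per_cell: int = 300
    effect_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.n_cells < 1 or self.pixels_per_cell < 1:
            raise ValueError("n_cells and pixels_per_cell must be >= 1")
        if not 0 < self.effect_fraction < 1:
            raise ValueError("effect_fraction must be in (0, 1)")


def _n_required(p0: float, p1: float, alpha: float, power: float) -> float:
    """Sample size for a two-sided one-sample proportion test (normal
    approximation) to detect p0 -> p1 with the given alpha and power."""
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    num = z_a * np.sqrt(p0 * (1.0 - p0)) + z_b * np.sqrt(p1 * (1.0 - p1))
    return float((num / abs(p1 - p0)) ** 2)


def selected_fraction_power(
    spec: PowerCalcSpec = PowerCalcSpec(),
    bracket: tuple[float, float] = (0.001, 0.5),
    tol: float = 1e-5,
) -> float:
    """Smallest selected fraction F_T with adequate statistical power.

    Solves the fixed point where the number of selected reference pixels
    n(F) = F * n_cells * pixels_per_cell equals the sample size a
    two-sided one-sample proportion test needs to detect a shift of
    ``effect_fraction`` of the maximum possible decrease (p0 = F to
    p1 = F - effect * F) or increase (p1 = F + effect * (1 - F)) from
    the null proportion p0 = F.  Both sides are solved by bisection and
    the larger required fraction is returned; the decrease side binds
    under the default assumptions, giving F_T ~ 0.089 (rounded to 0.1
    in practice).
    """
    total = spec.n_cells * spec.pixels_per_cell

    def surplus(f: float, side: str) -> float:
        p0 = f
        if side == "decrease":
            p1 = f - spec.effect_fraction * f
        else:
            p1 = f + spec.effect_fraction * (1.0 - f)
        return f * total - _n_required(p0, p1, spec.alpha, spec.power)

    required: list[float] = []
    for side in ("decrease", "increase"):
        lo, hi = bracket
        s_lo, s_hi = surplus(lo, side), surplus(hi, side)
        if s_lo > 0:
            # already adequately powered at the lower bracket edge
            required.append(lo)
            continue
        if s_hi < 0:
            raise ValueError(
                f"no root in bracket {bracket} for the {side} side of the "
                "power calculation"
            )
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if surplus(mid, side) < 0:
                lo = mid
            else:
                hi = mid
        required.append(0.5 * (lo + hi))
    return max(required)


def hfq_bound_lower_bound(ratio: float) -> float:
    """Lower bound on the chaperone-bound sRNA fraction.

    Under the steady-state protection model (bound sRNA fully protected
    from degradation; free sRNA degrades identically with or without the
    chaperone, so the deletion-strain level equals the wild-type free
    pool), a deletion/wild-type concentration ratio r implies a bound
    fraction of at least 1 - r.  Ratios above 1 imply no bound (returns
    0 with a warning).
    """
    if ratio <= 0:
        raise ValueError("concentration ratio must be positive")
    if ratio > 1:
        warnings.warn(
            "concentration ratio > 1 implies no lower bound on the bound "
            "fraction; returning 0",
            stacklevel=2,
        )
        return 0.0
    return 1.0 - ratio
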