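"""Constitutive viscosity models for shear-thinning embolic agents.

The central object is the Sisko model

    mu_eff(U) = mu0 + k * U**(n - 1)

with ``mu0`` the high-shear Newtonian plateau (mPa·s), ``k`` the consistency
coefficient (mPa·s·s^(n-1)) and ``n`` the flow index.  For pseudoplastic
agents ``n < 1``, so viscosity rises steeply as shear rate ``U`` (1/s) falls
and approaches ``mu0`` at high shear.  The classic Ostwald–de Waele power law
``mu_eff = k * U**(n-1)`` is kept as the degenerate ``mu0 = 0`` case.

The module also provides:

* nonlinear least-squares fitting of Sisko coefficients to a measured flow
  curve (log-viscosity objective, non-negativity bounds on ``mu0`` and ``k``);
* a continuous three-segment piecewise-linear approximation of the flow curve
  in log10–log10 space, the form used to feed tabulated viscosity into CFD;
* log-linear temperature interpolation between a cold (20 °C) and a warm
  (37 °C) Sisko fit, the "thermal activation" law of the viscosity;
* a detector for the nonmonotonic zone — a local viscosity dip near 1 1/s
  that the measured curves show at physiological temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SiskoParams",
    "PowerLawParams",
    "RheometryCurve",
    "PiecewiseLogLinearViscosity",
    "TemperatureViscosityLaw",
    "NonmonotonicZone",
    "SiskoFitResult",
    "eval_sisko",
    "eval_power_law",
    "fit_sisko",
    "fit_piecewise",
    "eval_temperature_interpolated",
    "detect_nonmonotonic_zone",
    "read_flow_curves",
    "write_flow_curves",
]

FLOW_CURVE_COLUMNS = [
    "shear_rate_per_s",
    "viscosity_mPas",
    "temperature_C",
    "polymer",
    "mixed_tantalum",
]


@dataclass(frozen=True)
class SiskoParams:
    """Sisko coefficients at a single temperature.

    Parameters
    ----------
    mu0 : float
        High-shear limiting viscosity, mPa·s.  Must be >= 0.
    k : float
        Consistency coefficient, mPa·s·s^(n-1).  Must be >= 0.
    n : float
        Flow index.  Unconstrained in sign; published fits for these agents
        include slightly negative values.
    temperature : float
        Temperature of the fit, °C.
    polymer_label : str
        Free-text sample label.
    """

    mu0: float
    k: float
    n: float
    temperature: float = 20.0
    polymer_label: str = ""

    def __post_init__(self) -> None:
        if not self.mu0 >= 0.0:
            raise ValueError(f"mu0 must be >= 0, got {self.mu0}")
        if not self.k >= 0.0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if not np.isfinite(self.temperature):
            raise ValueError("temperature must be finite")


@dataclass(frozen=True)
class PowerLawParams:
    """Ostwald–de Waele coefficients: mu_eff = k * U**(n-1)."""

    k: float
    n: float

    def __post_init__(self) -> None:
        if not self.k >= 0.0:
            raise ValueError(f"k must be >= 0, got {self.k}")


@dataclass(frozen=True)
class RheometryCurve:
    """A flow curve: effective viscosity versus shear rate at one temperature.

    ``shear_rates`` must be strictly increasing and positive (1/s);
    ``viscosities`` positive (mPa·s), same length, at least 3 points.
    """

    shear_rates: np.ndarray
    viscosities: np.ndarray
    temperature: float = 20.0
    polymer_label: str = ""
    mixed_tantalum: bool = True

    def __post_init__(self) -> None:
        sr = np.asarray(self.shear_rates, dtype=float)
        mu = np.asarray(self.viscosities, dtype=float)
        object.__setattr__(self, "shear_rates", sr)
        object.__setattr__(self, "viscosities", mu)
        if sr.ndim != 1 or mu.ndim != 1 or sr.size != mu.size:
            raise ValueError("shear_rates and viscosities must be 1-D, equal length")
        if sr.size < 3:
            raise ValueError("a flow curve needs at least 3 points")
        if not np.all(sr > 0):
            raise ValueError("all shear rates must be positive")
        if not np.all(np.diff(sr) > 0):
            raise ValueError("shear rates must be strictly increasing")
        if not np.all(mu > 0):
            raise ValueError("all viscosities must be positive")

    def __len__(self) -> int:
        return int(self.shear_rates.size)

    def restrict(self, window: tuple[float, float]) -> "RheometryCurve":
        """Sub-curve with shear rates inside the closed interval ``window``."""
        lo, hi = window
        mask = (self.shear_rates >= lo) & (self.shear_rates <= hi)
        if mask.sum() < 3:
            raise ValueError(
                f"window {window} leaves {int(mask.sum())} points (< 3)"
            )
        return replace(
            self,
            shear_rates=self.shear_rates[mask],
            viscosities=self.viscosities[mask],
        )


@dataclass(frozen=True)
class PiecewiseLogLinearViscosity:
    """Continuous 3-segment linear fit of log10(viscosity) vs log10(shear).

    ``breakpoints`` are the two interior shear rates (1/s).  ``slopes`` and
    ``intercepts`` describe each segment in log10–log10 coordinates;
    continuity at the breakpoints is enforced by construction.  Evaluation
    outside the fitted range extrapolates the end segments (clamped slope).
    """

    breakpoints: tuple[float, float]
    slopes: tuple[float, float, float]
    intercepts: tuple[float, float, float]

    def __post_init__(self) -> None:
        b1, b2 = self.breakpoints
        if not b1 < b2:
            raise ValueError("breakpoints must be strictly increasing")
        # continuity check at both knots
        for b, left, right in (
            (b1, 0, 1),
            (b2, 1, 2),
        ):
            x = np.log10(b)
            yl = self.slopes[left] * x + self.intercepts[left]
            yr = self.slopes[right] * x + self.intercepts[right]
            if abs(yl - yr) > 1e-9 * max(1.0, abs(yl)):
                raise ValueError("segments are discontinuous at a breakpoint")

    def __call__(self, shear_rate) -> np.ndarray:
        u = np.asarray(shear_rate, dtype=float)
        if np.any(u <= 0):
            raise ValueError("shear rate must be positive")
        x = np.log10(u)
        b1, b2 = np.log10(self.breakpoints)
        seg = np.where(x < b1, 0, np.where(x < b2, 1, 2))
        s = np.asarray(self.slopes)[seg]
        c = np.asarray(self.intercepts)[seg]
        return np.power(10.0, s * x + c)


@dataclass(frozen=True)
class TemperatureViscosityLaw:
    """Viscosity as a function of temperature between two Sisko anchors.

    Between the cold (20 °C) and warm (37 °C) anchor fits, log-viscosity is
    interpolated linearly in temperature at a fixed shear rate.  This is a
    modeling choice (only the endpoints were measured); it is exact at the
    anchors and positive everywhere.
    """

    params_cold: SiskoParams
    params_warm: SiskoParams
    mode: str = "log-linear"

    def __post_init__(self) -> None:
        if not self.params_cold.temperature < self.params_warm.temperature:
            raise ValueError("cold anchor must be at the lower temperature")

    @property
    def polymer_label(self) -> str:
        return self.params_cold.polymer_label


@dataclass(frozen=True)
class NonmonotonicZone:
    """A detected local viscosity dip on a flow curve.

    On a shear-thinning curve the dip appears as a local minimum (near
    1 1/s) followed, at higher shear, by a local maximum where the curve
    recovers toward the Newtonian plateau — so
    ``shear_at_local_min < shear_at_local_max`` in shear-rate coordinates.
    During delivery the agent moves from the catheter (high shear) into a
    wider vessel (low shear), i.e. it encounters the maximum first and then
    the dip.  ``relative_drop`` is the depth of the dip relative to the
    monotone constitutive baseline at the dip location (a fraction in
    [0, 1)).
    """

    shear_at_local_max: float
    shear_at_local_min: float
    relative_drop: float

    def __post_init__(self) -> None:
        if not self.shear_at_local_min < self.shear_at_local_max:
            raise ValueError(
                "the dip (local min) must lie below the recovery maximum "
                "in shear rate"
            )
        if not 0.0 <= self.relative_drop < 1.0:
            raise ValueError("relative_drop must lie in [0, 1)")


@dataclass(frozen=True)
class SiskoFitResult:
    """Outcome of a Sisko fit: parameters plus diagnostics."""

    params: SiskoParams
    residual_norm: float
    converged: bool
    n_points: int
    message: str = ""


def eval_sisko(params: SiskoParams, shear_rate) -> np.ndarray | float:
    """Effective viscosity mu0 + k * U**(n-1), mPa·s.

    Raises ``ValueError`` for non-positive shear rate: with ``n < 1`` the
    power-law term diverges as U -> 0 and is undefined at U = 0.
    """
    u = np.asarray(shear_rate, dtype=float)
    if np.any(u <= 0):
        raise ValueError("shear rate must be positive")
    mu = params.mu0 + params.k * np.power(u, params.n - 1.0)
    return float(mu) if np.isscalar(shear_rate) else mu


def eval_power_law(params: PowerLawParams, shear_rate) -> np.ndarray | float:
    """Ostwald–de Waele viscosity k * U**(n-1), mPa·s."""
    u = np.asarray(shear_rate, dtype=float)
    if np.any(u <= 0):
        raise ValueError("shear rate must be positive")
    mu = params.k * np.power(u, params.n - 1.0)
    return float(mu) if np.isscalar(shear_rate) else mu


def fit_sisko(
    curve: RheometryCurve,
    shear_window: Optional[tuple[float, float]] = None,
) -> SiskoFitResult:
    """Fit Sisko coefficients to a flow curve by nonlinear least squares.

    The objective is the residual of log(viscosity) — the flow curves span
    three decades of shear and roughly one decade of viscosity, and a linear
    objective would let the low-shear points dominate.  ``mu0`` and ``k`` are
    bounded below by 0; ``n`` is free.  Fitting is restricted to
    ``shear_window`` when given (the Sisko form represents the 0.1–10 1/s
    range well; above ~10 1/s the plateau term alone carries the curve).

    Returns a :class:`SiskoFitResult`; ``converged`` is False if the
    trust-region solver fails to reach its tolerance.
    """
    sub = curve.restrict(shear_window) if shear_window is not None else curve
    if len(sub) < 4:
        raise ValueError(f"need >= 4 points to fit 3 parameters, got {len(sub)}")
    u = sub.shear_rates
    log_mu = np.log(sub.viscosities)

    mu0_guess = float(sub.viscosities[-1])  # plateau ~ viscosity at max shear
    k_guess = max(float(sub.viscosities[0]) - mu0_guess, 1e-6)
    x0 = np.array([mu0_guess, k_guess, 0.0])

    def residuals(p: np.ndarray) -> np.ndarray:
        mu0, k, n = p
        model = mu0 + k * np.power(u, n - 1.0)
        # keep the log defined if the solver probes mu0 = k = 0
        return np.log(np.maximum(model, 1e-300)) - log_mu

    sol = least_squares(
        residuals,
        x0,
        bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=2000,
    )
    params = SiskoParams(
        mu0=float(sol.x[0]),
        k=float(sol.x[1]),
        n=float(sol.x[2]),
        temperature=sub.temperature,
        polymer_label=sub.polymer_label,
    )
    return SiskoFitResult(
        params=params,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        n_points=len(sub),
        message=str(sol.message),
    )


def fit_piecewise(
    curve: RheometryCurve,
    breakpoints: tuple[float, float] = (1.0, 10.0),
) -> PiecewiseLogLinearViscosity:
    """Continuous 3-segment linear least-squares fit in log10–log10 space.

    Continuity at the two knots is built into the regression basis
    (truncated hinge functions), so the constrained problem stays an
    ordinary linear least-squares solve.  Each segment must contain at
    least 2 data points.
    """
    b1, b2 = breakpoints
    if not 0 < b1 < b2:
        raise ValueError("breakpoints must be positive and increasing")
    x = np.log10(curve.shear_rates)
    y = np.log10(curve.viscosities)
    xb1, xb2 = np.log10(b1), np.log10(b2)
    seg_counts = [
        int(np.sum(x < xb1)),
        int(np.sum((x >= xb1) & (x < xb2))),
        int(np.sum(x >= xb2)),
    ]
    if min(seg_counts) < 2:
        raise ValueError(
            f"each segment needs >= 2 points, got counts {seg_counts} "
            f"for breakpoints {breakpoints}"
        )
    # y = a + b*x + c1*max(x-xb1,0) + c2*max(x-xb2,0): continuous by design.
    A = np.column_stack(
        [
            np.ones_like(x),
            x,
            np.maximum(x - xb1, 0.0),
            np.maximum(x - xb2, 0.0),
        ]
    )
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a, b, c1, c2 = coef
    slopes = (b, b + c1, b + c1 + c2)
    # intercepts chosen so segments agree at the knots
    i0 = a
    i1 = i0 - c1 * xb1
    i2 = i1 - c2 * xb2
    return PiecewiseLogLinearViscosity(
        breakpoints=(float(b1), float(b2)),
        slopes=tuple(float(s) for s in slopes),
        intercepts=(float(i0), float(i1), float(i2)),
    )


def eval_temperature_interpolated(
    law: TemperatureViscosityLaw, temperature: float, shear_rate
) -> np.ndarray | float:
    """Viscosity at an intermediate temperature, mPa·s.

    log(mu) is linear in T between the cold and warm anchors, evaluated at
    the given shear rate.  Valid for 15 °C <= T <= 45 °C (mild extrapolation
    past the anchors is permitted within that range).
    """
    if not 15.0 <= temperature <= 45.0:
        raise ValueError(f"temperature {temperature} °C outside [15, 45] °C")
    t_c = law.params_cold.temperature
    t_w = law.params_warm.temperature
    mu_c = np.log(np.asarray(eval_sisko(law.params_cold, shear_rate), dtype=float))
    mu_w = np.log(np.asarray(eval_sisko(law.params_warm, shear_rate), dtype=float))
    w = (temperature - t_c) / (t_w - t_c)
    mu = np.exp((1.0 - w) * mu_c + w * mu_w)
    return float(mu) if np.isscalar(shear_rate) else mu


def _moving_median(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving median with edge windows shrunk symmetrically."""
    half = window // 2
    out = np.empty_like(y)
    for i in range(y.size):
        lo = max(0, i - half)
        hi = min(y.size, i + half + 1)
        out[i] = np.median(y[lo:hi])
    return out


def _fit_dip_amplitude(curve: RheometryCurve, center_guess: float) -> Optional[float]:
    """Depth of a Gaussian (in log-shear) dip riding on a Sisko baseline.

    Fits mu(U) = [mu0 + k U**(n-1)] * (1 - A exp(-(log10 U - c)^2 / 2 s^2))
    by least squares on log-viscosity and returns the fitted amplitude A.
    Returns ``None`` on optimizer failure.
    """
    u = curve.shear_rates
    log_mu = np.log(curve.viscosities)
    x = np.log10(u)

    mu0_g = float(curve.viscosities[-1])
    k_g = max(float(curve.viscosities[0]) - mu0_g, 1e-6)
    p0 = np.array([mu0_g, k_g, 0.0, 0.1, np.log10(center_guess), 0.3])

    def residuals(p: np.ndarray) -> np.ndarray:
        mu0, k, n, amp, c, s = p
        base = mu0 + k * np.power(u, n - 1.0)
        dip = 1.0 - amp * np.exp(-((x - c) ** 2) / (2.0 * s**2))
        return np.log(np.maximum(base * dip, 1e-300)) - log_mu

    sol = least_squares(
        residuals,
        p0,
        bounds=(
            [0.0, 0.0, -np.inf, 0.0, np.log10(center_guess) - 1.0, 0.05],
            [np.inf, np.inf, np.inf, 0.999, np.log10(center_guess) + 1.0, 1.5],
        ),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        max_nfev=5000,
    )
    if not sol.success:
        return None
    return float(sol.x[3])


def detect_nonmonotonic_zone(
    curve: RheometryCurve,
    search_window: tuple[float, float] = (0.1, 10.0),
    smoothing_window: int = 5,
) -> Optional[NonmonotonicZone]:
    """Detect a local viscosity dip on an otherwise shear-thinning curve.

    The viscosity is first smoothed by a centered moving median of
    ``smoothing_window`` points (robust to single-point instrument noise)
    and scanned inside ``search_window`` for a fall-then-rise pattern: a
    local minimum (the dip) followed at higher shear by a recovery toward
    the plateau.  Returns ``None`` when the smoothed curve is monotone in
    the window — the absence of a dip is a valid result, not an error.

    Because the constitutive baseline itself falls with shear rate, the raw
    difference between the recovery maximum and the dip minimum understates
    the dip depth.  ``relative_drop`` is therefore estimated by fitting a
    Sisko baseline times a Gaussian dip (in log shear) to the full curve,
    which measures the decrease relative to the monotone law at the dip
    location.  If that refinement fails to converge, the raw smoothed
    (mu_max - mu_min)/mu_max is reported instead.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    lo, hi = search_window
    mask = (curve.shear_rates >= lo) & (curve.shear_rates <= hi)
    if mask.sum() < 3:
        return None
    u = curve.shear_rates[mask]
    mu = _moving_median(curve.viscosities[mask], smoothing_window)

    # dip: the smoothed minimum must have strictly higher values on BOTH
    # sides (a fall into it and a recovery after it); median smoothing can
    # flatten neighbours, so compare against the extremes of each side
    # rather than requiring strict monotonicity at adjacent points.
    i_min = int(np.argmin(mu))
    if i_min == 0 or i_min == mu.size - 1:
        return None
    if not (mu[:i_min].max() > mu[i_min] and mu[i_min + 1 :].max() > mu[i_min]):
        return None
    # recovery maximum: largest smoothed value at higher shear in the window
    i_max = i_min + int(np.argmax(mu[i_min:]))
    if i_max == i_min or mu[i_max] <= mu[i_min]:
        return None
    raw_drop = float((mu[i_max] - mu[i_min]) / mu[i_max])
    if raw_drop <= 1e-12:
        return None
    amp = _fit_dip_amplitude(curve, center_guess=float(u[i_min]))
    drop = amp if amp is not None and 0.0 < amp < 1.0 else raw_drop
    return NonmonotonicZone(
        shear_at_local_max=float(u[i_max]),
        shear_at_local_min=float(u[i_min]),
        relative_drop=drop,
    )


def read_flow_curves(path) -> list[RheometryCurve]:
    """Read flow curves from the package CSV dialect.

    Expected header: ``shear_rate_per_s,viscosity_mPas,temperature_C,polymer,
    mixed_tantalum``.  Rows are grouped by (polymer, temperature,
    mixed_tantalum); each group becomes one curve sorted by shear rate.
    """
    df = pd.read_csv(path)
    missing = set(FLOW_CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"flow-curve CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("flow-curve CSV contains no data rows")
    curves = []
    for (polymer, temp, mixed), grp in df.groupby(
        ["polymer", "temperature_C", "mixed_tantalum"], sort=True
    ):
        grp = grp.sort_values("shear_rate_per_s")
        curves.append(
            RheometryCurve(
                shear_rates=grp["shear_rate_per_s"].to_numpy(float),
                viscosities=grp["viscosity_mPas"].to_numpy(float),
                temperature=float(temp),
                polymer_label=str(polymer),
                mixed_tantalum=bool(mixed),
            )
        )
    return curves


def write_flow_curves(curves: Sequence[RheometryCurve], path) -> None:
    """Write curves in the flow-curve CSV dialect (UTF-8, dot decimal)."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "shear_rate_per_s": c.shear_rates,
                    "viscosity_mPas": c.viscosities,
                    "temperature_C": c.temperature,
                    "polymer": c.polymer_label,
                    "mixed_tantalum": c.mixed_tantalum,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
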