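"""Reduced-order (1D) steady flow of a Sisko fluid through a catheter + AVM
vessel network.

The arteriovenous malformation is modeled as a hydraulic circuit: a catheter
and a feeding artery in series, then a parallel stage — a racemose bundle of
``n_parallel`` identical small tubes and, optionally, a single large-caliber
fistula — followed by a draining vein.  Each tube is a straight circular
segment in laminar Poiseuille flow, so its hydraulic resistance is
``R = 128 mu l / (pi d^4)``.  The non-Newtonian coupling (viscosity depends
on the wall shear rate, which depends on the flow split) is closed by
fixed-point iteration.

All quantities are SI internally; wall shear stress is reported in dyne/cm²
(1 Pa = 10 dyne/cm²) to match clinical convention, and viscosity in mPa·s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .rheology import (
    SiskoParams,
    TemperatureViscosityLaw,
    eval_sisko,
    eval_temperature_interpolated,
)

__all__ = [
    "VesselSegment",
    "AVMNetwork",
    "SegmentResult",
    "NetworkSolution",
    "mean_velocity",
    "wall_shear_rate",
    "poiseuille_pressure_drop",
    "darcy_weisbach_head_loss",
    "reynolds_number",
    "wall_shear_stress",
    "solve_network",
    "sweep_diameters",
    "default_network",
]

PA_TO_DYNE_CM2 = 10.0


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


def mean_velocity(Q: float, d: float) -> float:
    """Mean velocity (m/s) of flow Q (m³/s) in a circular tube of diameter d (m)."""
    _require_positive(Q=Q, d=d)
    return Q / (math.pi * d**2 / 4.0)


def wall_shear_rate(Q: float, d: float) -> float:
    """Poiseuille wall shear rate 8 u / d = 32 Q / (pi d³), in 1/s."""
    _require_positive(Q=Q, d=d)
    return 32.0 * Q / (math.pi * d**3)


def poiseuille_pressure_drop(mu: float, l: float, c: float, d: float) -> float:
    """Laminar pressure drop 32 mu l c / d² (Pa); mu in Pa·s, c mean velocity."""
    _require_positive(mu=mu, l=l, c=c, d=d)
    return 32.0 * mu * l * c / d**2


def darcy_weisbach_head_loss(
    lambda_f: float, l: float, d: float, c: float, g: float = 9.80665
) -> float:
    """Darcy–Weisbach head loss h = lambda (l/d) c²/(2g), meters of fluid.

    With the laminar friction factor lambda = 64/Re this reproduces the
    Poiseuille pressure drop exactly: rho g h = 32 mu l c / d².
    """
    _require_positive(lambda_f=lambda_f, l=l, d=d, c=c, g=g)
    return lambda_f * (l / d) * c**2 / (2.0 * g)


def reynolds_number(rho: float, u: float, L: float, mu: float) -> float:
    """Re = rho u L / mu with the hydraulic diameter as length scale."""
    _require_positive(rho=rho, u=u, L=L, mu=mu)
    return rho * u * L / mu


def wall_shear_stress(mu: float, gamma_wall: float) -> float:
    """Wall shear stress tau = mu * gamma (mu in Pa·s), reported in dyne/cm²."""
    if mu < 0 or gamma_wall < 0:
        raise ValueError("mu and gamma_wall must be non-negative")
    return mu * gamma_wall * PA_TO_DYNE_CM2


ViscosityLaw = Union[SiskoParams, TemperatureViscosityLaw]


@dataclass(frozen=True)
class VesselSegment:
    """A straight circular conduit; ``n_parallel`` identical copies in parallel."""

    label: str
    length: float
    diameter: float
    n_parallel: int = 1

    def __post_init__(self) -> None:
        _require_positive(length=self.length, diameter=self.diameter)
        if self.n_parallel < 1:
            raise ValueError("n_parallel must be >= 1")


@dataclass(frozen=True)
class AVMNetwork:
    """Catheter + feeder in series, racemose bundle ∥ optional fistula, drainer.

    ``viscosity_law`` is either a single-temperature :class:`SiskoParams`
    (isothermal network) or a :class:`TemperatureViscosityLaw` evaluated at
    ``temperature``.

    Viscosity evaluations clamp the shear rate at ``min_shear_clamp``
    (default 0.1 1/s, the lower end of the rheometer range).  The Sisko law
    with a negative flow index diverges as shear -> 0, which is an
    extrapolation artifact: left unclamped it makes a branch's pressure
    drop decrease with increasing flow and destabilizes the flow split in
    nearly-stagnant branches (e.g. a racemose bundle shunted by a fistula).
    """

    catheter: VesselSegment
    feeder: VesselSegment
    racemose: VesselSegment
    drainer: VesselSegment
    fistula: Optional[VesselSegment] = None
    inflow: float = 0.6e-6 / 60.0  # 0.6 mL/min
    fluid_density: float = 1100.0  # DMSO-dominated agent, kg/m³
    viscosity_law: ViscosityLaw = None  # type: ignore[assignment]
    temperature: float = 37.0
    min_shear_clamp: float = 0.1  # 1/s

    def __post_init__(self) -> None:
        _require_positive(inflow=self.inflow, fluid_density=self.fluid_density)
        if self.viscosity_law is None:
            raise ValueError("viscosity_law is required")

    def viscosity_mPas(self, shear_rate: float) -> float:
        """Effective viscosity (mPa·s) at a wall shear rate, for the network fluid."""
        shear_rate = max(shear_rate, self.min_shear_clamp)
        if isinstance(self.viscosity_law, TemperatureViscosityLaw):
            return float(
                eval_temperature_interpolated(
                    self.viscosity_law, self.temperature, shear_rate
                )
            )
        return float(eval_sisko(self.viscosity_law, shear_rate))


@dataclass(frozen=True)
class SegmentResult:
    """Solved state of one segment (per single tube for parallel bundles)."""

    label: str
    flow: float  # m³/s through ONE tube
    n_parallel: int
    mean_velocity: float  # m/s
    wall_shear_rate: float  # 1/s
    viscosity_mPas: float
    pressure_drop: float  # Pa
    wall_shear_stress_dyne_cm2: float
    reynolds: float

    @property
    def total_flow(self) -> float:
        return self.flow * self.n_parallel


@dataclass(frozen=True)
class NetworkSolution:
    """Converged network state plus iteration diagnostics."""

    segments: dict[str, SegmentResult]
    total_pressure_drop: float
    iterations: int
    converged: bool
    mass_defect: float  # relative, at the parallel junction
    parallel_pressure_defect: float  # relative mismatch across branches

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.segments.values():
            rows.append(
                {
                    "label": s.label,
                    "flow_m3_s": s.flow,
                    "n_parallel": s.n_parallel,
                    "mean_velocity_m_s": s.mean_velocity,
                    "wall_shear_rate_per_s": s.wall_shear_rate,
                    "viscosity_mPas": s.viscosity_mPas,
                    "pressure_drop_Pa": s.pressure_drop,
                    "wss_dyne_cm2": s.wall_shear_stress_dyne_cm2,
                    "reynolds": s.reynolds,
                }
            )
        return pd.DataFrame(rows)


def _segment_state(
    net: AVMNetwork, seg: VesselSegment, q_tube: float
) -> SegmentResult:
    u = mean_velocity(q_tube, seg.diameter)
    gamma = wall_shear_rate(q_tube, seg.diameter)
    mu_mPas = net.viscosity_mPas(gamma)
    mu = mu_mPas * 1e-3
    dp = poiseuille_pressure_drop(mu, seg.length, u, seg.diameter)
    return SegmentResult(
        label=seg.label,
        flow=q_tube,
        n_parallel=seg.n_parallel,
        mean_velocity=u,
        wall_shear_rate=gamma,
        viscosity_mPas=mu_mPas,
        pressure_drop=dp,
        wall_shear_stress_dyne_cm2=wall_shear_stress(mu, gamma),
        reynolds=reynolds_number(net.fluid_density, u, seg.diameter, mu),
    )


def _resistance(mu_Pas: float, seg: VesselSegment) -> float:
    """Hydraulic resistance of ONE tube: 128 mu l / (pi d^4), Pa·s/m³."""
    return 128.0 * mu_Pas * seg.length / (math.pi * seg.diameter**4)


def solve_network(
    net: AVMNetwork, tol: float = 1e-8, max_iter: int = 200
) -> NetworkSolution:
    """Solve the steady non-Newtonian network by fixed-point iteration.

    Series segments carry the full inflow; the parallel stage splits the
    flow between the racemose bundle and the fistula so their pressure
    drops match.  Each iteration evaluates every segment's viscosity at its
    current wall shear rate, rebuilds the resistances, and re-splits the
    parallel flow; iteration stops when the largest relative viscosity
    change falls below ``tol``.  A damping factor of 0.5 is applied to the
    flow split when the iterates oscillate.  A Newtonian fluid (k = 0)
    converges in one iteration.

    Identical parallel racemose tubes are symmetric by construction: the
    bundle is solved as one representative tube carrying 1/n of the bundle
    flow.
    """
    Q = net.inflow
    series = [net.catheter, net.feeder, net.drainer]
    has_fistula = net.fistula is not None

    def viscosities_at(frac: float) -> dict[str, float]:
        out: dict[str, float] = {}
        for seg in series:
            gamma = wall_shear_rate(Q / seg.n_parallel, seg.diameter)
            out[seg.label] = net.viscosity_mPas(gamma)
        q_rac_tube = Q * frac / net.racemose.n_parallel
        gamma_rac = wall_shear_rate(max(q_rac_tube, 1e-30), net.racemose.diameter)
        out[net.racemose.label] = net.viscosity_mPas(gamma_rac)
        if has_fistula:
            q_fist = Q * (1.0 - frac) / net.fistula.n_parallel
            gamma_f = wall_shear_rate(max(q_fist, 1e-30), net.fistula.diameter)
            out[net.fistula.label] = net.viscosity_mPas(gamma_f)
        return out

    frac_rac = 0.5 if has_fistula else 1.0
    prev_frac = frac_rac
    visc = viscosities_at(frac_rac)
    iterations = 0
    converged = False

    for iterations in range(1, max_iter + 1):
        if has_fistula:
            r_rac = (
                _resistance(visc[net.racemose.label] * 1e-3, net.racemose)
                / net.racemose.n_parallel
            )
            r_fist = (
                _resistance(visc[net.fistula.label] * 1e-3, net.fistula)
                / net.fistula.n_parallel
            )
            frac_new = r_fist / (r_rac + r_fist)
            # damp on oscillation of the split
            if (frac_new - frac_rac) * (frac_rac - prev_frac) < 0:
                frac_new = 0.5 * (frac_new + frac_rac)
            prev_frac, frac_rac = frac_rac, frac_new

        new_visc = viscosities_at(frac_rac)
        delta = max(abs(new_visc[k] - visc[k]) / visc[k] for k in new_visc)
        visc = new_visc
        if delta < tol:
            converged = True
            break

    results: dict[str, SegmentResult] = {}
    for seg in series:
        results[seg.label] = _segment_state(net, seg, Q / seg.n_parallel)
    q_rac_tube = Q * frac_rac / net.racemose.n_parallel
    results[net.racemose.label] = _segment_state(net, net.racemose, q_rac_tube)
    if has_fistula:
        q_fist = Q * (1.0 - frac_rac) / net.fistula.n_parallel
        results[net.fistula.label] = _segment_state(net, net.fistula, q_fist)

    # diagnostics
    parallel_flow = results[net.racemose.label].total_flow
    dp_parallel = results[net.racemose.label].pressure_drop
    pressure_defect = 0.0
    if has_fistula:
        parallel_flow += results[net.fistula.label].total_flow
        dp_f = results[net.fistula.label].pressure_drop
        pressure_defect = abs(dp_f - dp_parallel) / max(dp_f, dp_parallel)
        dp_parallel = max(dp_parallel, dp_f)
    mass_defect = abs(parallel_flow - Q) / Q

    total_dp = (
        sum(results[s.label].pressure_drop for s in series) + dp_parallel
    )
    return NetworkSolution(
        segments=results,
        total_pressure_drop=total_dp,
        iterations=iterations,
        converged=converged,
        mass_defect=mass_defect,
        parallel_pressure_defect=pressure_defect,
    )


def default_network(
    viscosity_law: ViscosityLaw,
    racemose_diameter: float = 1.0e-3,
    with_fistula: bool = False,
    inflow: float = 0.6e-6 / 60.0,
    catheter_diameter: float = 2.0e-3,
    temperature: float = 37.0,
) -> AVMNetwork:
    """The default catheter + AVM geometry.

    Feeder 20 mm × 3 mm, racemose bundle of 10 tubes × 10 mm at the given
    diameter, optional fistula 10 mm × 4 mm, drainer 20 mm × 3 mm, catheter
    1 m at the given lumen.  Segment lengths and tube count are plausible
    AVM-scale choices (small AVM vessels run ~0.2–2 mm); all are
    configurable through :class:`AVMNetwork` directly.
    """
    return AVMNetwork(
        catheter=VesselSegment("catheter", 1.0, catheter_diameter),
        feeder=VesselSegment("feeder", 20e-3, 3e-3),
        racemose=VesselSegment("racemose", 10e-3, racemose_diameter, n_parallel=10),
        fistula=VesselSegment("fistula", 10e-3, 4e-3) if with_fistula else None,
        drainer=VesselSegment("drainer", 20e-3, 3e-3),
        inflow=inflow,
        viscosity_law=viscosity_law,
        temperature=temperature,
    )


def sweep_diameters(
    net_template: AVMNetwork,
    diameters: Sequence[float],
    with_and_without_fistula: bool = True,
) -> pd.DataFrame:
    """Solve the network over a set of racemose diameters.

    Returns one row per (diameter, fistula) case with the racemose pressure
    drop, racemose wall shear stress, maximum segment velocity and maximum
    Reynolds number.  Solver failures are recorded in the ``converged``
    column; the sweep continues.  Rows are ordered by diameter then fistula
    state (deterministic).
    """
    for d in diameters:
        if not 0.1e-3 < d < 5e-3:
            raise ValueError(f"diameter {d} m outside the supported (0.1, 5) mm")
    fistula_states = [False, True] if with_and_without_fistula else [
        net_template.fistula is not None
    ]
    template_fistula = net_template.fistula or VesselSegment("fistula", 10e-3, 4e-3)
    polymer = (
        net_template.viscosity_law.polymer_label
        if net_template.viscosity_law is not None
        else ""
    )
    rows = []
    for d in diameters:
        for fist in fistula_states:
            net = replace(
                net_template,
                racemose=replace(net_template.racemose, diameter=d),
                fistula=template_fistula if fist else None,
            )
            sol = solve_network(net)
            rac = sol.segments[net.racemose.label]
            rows.append(
                {
                    "diameter_mm": d * 1e3,
                    "fistula": fist,
                    "polymer": polymer,
                    "pressure_Pa": rac.pressure_drop,
                    "wss_dyne_cm2": rac.wall_shear_stress_dyne_cm2,
                    # summarize the AVM itself; the catheter state does not
                    # change across the sweep
                    "max_velocity_m_s": max(
                        s.mean_velocity
                        for s in sol.segments.values()
                        if s.label != net.catheter.label
                    ),
                    "reynolds": max(
                        s.reynolds
                        for s in sol.segments.values()
                        if s.label != net.catheter.label
                    ),
                    "converged": sol.converged,
                }
            )
    return pd.DataFrame(rows)
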