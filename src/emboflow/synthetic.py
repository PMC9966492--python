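"""Seeded generator of synthetic rheometry flow curves.

Real flow-curve data for these agents is scarce (the material reaches the
lab only as surgical leftovers), so the analysis pipeline is exercised on
synthetic curves with the statistical structure the method assumes:

    mu(U) = Sisko(U) * dip(U) * noise

* ``Sisko(U)`` — the constitutive baseline at the configured temperature;
* ``dip(U) = 1 - A * exp(-(log10 U - log10 c)^2 / (2 s^2))`` — an optional
  local viscosity dip (the nonmonotonic zone near 1 1/s), Gaussian in
  log-shear with fractional depth ``A``;
* ``noise`` — multiplicative lognormal with median 1 and sigma ``noise_sd``
  (viscosity is positive and spans decades, so scatter is multiplicative).

Every curve is reproducible from its integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .rheology import RheometryCurve, SiskoParams, eval_sisko, write_flow_curves

__all__ = ["SyntheticRheometryConfig", "generate_curve", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticRheometryConfig:
    """Recipe for one synthetic flow curve.

    Defaults reproduce the measurement design of the rheometer study: a
    30-point log-spaced grid over 0.1–100 1/s and 5 % multiplicative
    scatter.  ``bump_amplitude = 0`` disables the dip; the nonmonotonic-zone
    scenario uses 0.3 (a ~30 % dip) centered at 1 1/s with a width of 0.3
    decades.
    """

    base_params: SiskoParams
    n_points: int = 30
    shear_min: float = 0.1
    shear_max: float = 100.0
    noise_sd: float = 0.05
    bump_amplitude: float = 0.0
    bump_center: float = 1.0
    bump_width: float = 0.3
    seed: int = 0
    mixed_tantalum: bool = True

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("grid needs at least 3 points")
        if not 0 < self.shear_min < self.shear_max:
            raise ValueError("require 0 < shear_min < shear_max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.bump_amplitude < 1.0:
            raise ValueError("bump_amplitude must lie in [0, 1)")
        if self.bump_center <= 0:
            raise ValueError("bump_center must be positive")
        if self.bump_width <= 0:
            raise ValueError("bump_width must be positive")


def dip_factor(config: SyntheticRheometryConfig, shear_rate) -> np.ndarray:
    """The multiplicative dip factor 1 - A*exp(-(log10 U - log10 c)^2/2s^2)."""
    x = np.log10(np.asarray(shear_rate, dtype=float))
    c = np.log10(config.bump_center)
    return 1.0 - config.bump_amplitude * np.exp(
        -((x - c) ** 2) / (2.0 * config.bump_width**2)
    )


def generate_curve(config: SyntheticRheometryConfig) -> RheometryCurve:
    """Generate one synthetic flow curve (deterministic for a fixed seed)."""
    u = np.logspace(
        np.log10(config.shear_min), np.log10(config.shear_max), config.n_points
    )
    mu = np.asarray(eval_sisko(config.base_params, u)) * dip_factor(config, u)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        # lognormal with median exactly 1: exp(sigma * Z)
        mu = mu * np.exp(config.noise_sd * rng.standard_normal(u.size))
    return RheometryCurve(
        shear_rates=u,
        viscosities=mu,
        temperature=config.base_params.temperature,
        polymer_label=config.base_params.polymer_label,
        mixed_tantalum=config.mixed_tantalum,
    )


def generate_dataset(
    configs: Sequence[SyntheticRheometryConfig],
    csv_path=None,
) -> list[RheometryCurve]:
    """Generate one curve per config; optionally write the flow-curve CSV.

    Duplicate (polymer, temperature, mixed_tantalum) labels trigger a
    warning (the CSV reader would merge such groups) but are not an error.
    """
    if len(configs) == 0:
        raise ValueError("configs must be non-empty")
    keys = [
        (c.base_params.polymer_label, c.base_params.temperature, c.mixed_tantalum)
        for c in configs
    ]
    if len(set(keys)) != len(keys):
        warnings.warn(
            "duplicate (polymer, temperature, mixed_tantalum) labels in dataset",
            stacklevel=2,
        )
    curves = [generate_curve(c) for c in configs]
    if csv_path is not None:
        write_flow_curves(curves, csv_path)
    return curves
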