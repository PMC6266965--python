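"""Forward evaluation of the Randles/CPE equivalent circuit and extensions.

The electrode–electrolyte interface is modelled as an access (solution)
resistance ``R_S`` in series with the parallel combination of a charge
transfer resistance ``R_E`` and a constant phase element (CPE),

    Z_CPE(w) = 1 / (Q * (j*w)**n),       Z(w) = R_S + R_E / (1 + R_E*Q*(j*w)**n),

with ``w`` the angular frequency in rad/s (w = 2*pi*f), ``Q`` the CPE
admittance magnitude in S*s^n and ``n in [0, 1]`` interpolating between a
resistor (n=0) and an ideal capacitor (n=1).

Degraded electrodes show two additional conduction pathways: a parasitic
shunt resistance ``R_p`` through damaged encapsulation or a broken lead
(dominant at low frequencies, where it produces the flat resistive plateau
of "ski-slope" spectra) and a dielectric coupling capacitance ``C_d``
through degraded insulation (dominant at high frequencies, producing the
high-frequency phase roll-off).  Both are placed in parallel with the whole
Randles branch:

    Z_ext(w) = 1 / ( 1/Z(w) + 1/R_p + j*w*C_d ).

With ``R_p = inf`` and ``C_d = 0`` the extended model reduces *exactly* to
the Randles circuit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectra import FrequencyGrid, ImpedanceSpectrum, SessionMeta, from_complex

__all__ = [
    "RandlesParams",
    "ExtendedParams",
    "z_cpe",
    "z_randles",
    "z_extended",
    "simulate_spectrum",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class RandlesParams:
    """Parameters of the Randles/CPE circuit.

    R_E : charge-transfer resistance, ohm (> 0)
    Q   : CPE admittance magnitude, S*s^n (> 0)
    n   : CPE exponent, dimensionless (0..1)
    R_S : access/solution resistance, ohm (> 0)
    """

    R_E: float
    Q: float
    n: float
    R_S: float

    def __post_init__(self) -> None:
        if self.R_E <= 0:
            raise ValueError("R_E must be > 0")
        if self.Q <= 0:
            raise ValueError("Q must be > 0")
        if not 0.0 <= self.n <= 1.0:
            raise ValueError("n must be within [0, 1]")
        if self.R_S <= 0:
            raise ValueError("R_S must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.R_E, self.Q, self.n, self.R_S])


@dataclass(frozen=True)
class ExtendedParams:
    """Randles branch plus parasitic shunt R_p and dielectric capacitance C_d.

    ``R_p = inf`` and ``C_d = 0`` denote absent elements; the model then
    coincides with the plain Randles circuit.
    """

    base: RandlesParams
    R_p: float = math.inf
    C_d: float = 0.0

    def __post_init__(self) -> None:
        if not self.R_p > 0:
            raise ValueError("R_p must be > 0 (use inf for absent)")
        if self.C_d < 0:
            raise ValueError("C_d must be >= 0")

    @property
    def is_randles(self) -> bool:
        return math.isinf(self.R_p) and self.C_d == 0.0

    @classmethod
    def randles(cls, base: RandlesParams) -> "ExtendedParams":
        return cls(base=base)


def _check_w(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("angular frequency must be > 0")
    return w


def z_cpe(w, Q: float, n: float):
    """Impedance of a constant phase element, 1/(Q*(j*w)^n).

    Uses the principal branch of the complex power, j^n = exp(j*n*pi/2),
    so the phase is exactly -n*90 degrees at every frequency.
    """
    w = _check_w(w)
    if Q <= 0:
        raise ValueError("Q must be > 0")
    if not 0.0 <= n <= 1.0:
        raise ValueError("n must be within [0, 1]")
    jw_n = w**n * np.exp(1j * n * math.pi / 2.0)
    return 1.0 / (Q * jw_n)


def z_randles(w, p: RandlesParams):
    """Impedance of the Randles/CPE circuit at angular frequency w (rad/s)."""
    w = _check_w(w)
    jw_n = w**p.n * np.exp(1j * p.n * math.pi / 2.0)
    return p.R_S + p.R_E / (1.0 + p.R_E * p.Q * jw_n)


def z_extended(w, p: ExtendedParams):
    """Randles branch in parallel with the shunt R_p and capacitance C_d."""
    zr = z_randles(w, p.base)
    if p.is_randles:
        return zr
    w = np.asarray(w, dtype=float)
    y = 1.0 / zr + 1j * w * p.C_d
    if math.isfinite(p.R_p):
        y = y + 1.0 / p.R_p
    return 1.0 / y


def simulate_spectrum(
    p: ExtendedParams, grid: FrequencyGrid, meta: SessionMeta
) -> ImpedanceSpectrum:
    """Noiseless spectrum of the extended circuit on ``grid`` (w = 2*pi*f)."""
    z = z_extended(TWO_PI * grid.values, p)
    return from_complex(grid, z, meta)
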