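"""Closed-form physical characterization of hydrogel networks.

Three standard formulas connect bulk measurements to network parameters:
the volume swelling degree Q = (d/d0)^3 from gel-disc diameters, the
rubber-elasticity mesh size xi = (G' N_A / (R T))^(-1/3) from the storage
modulus, and the isotropic-rubber conversion G = E / (2 (1 + nu)) between
Young's and shear modulus (nu = 0.5 for incompressible gels, so G = E/3).
SI units internally; interfaces take Pa and K and report mesh sizes in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.constants import Avogadro, R

ROOM_TEMPERATURE_K = 298.15


@dataclass
class ElasticityParams:
    """Bundle of elasticity-related quantities for one hydrogel state."""

    G_prime_Pa: float | None = None
    E_Pa: float | None = None
    T_K: float = ROOM_TEMPERATURE_K
    nu: float = 0.5
    xi_nm: float | None = None


@dataclass
class SwellingMeasurement:
    d0_mm: float
    d_mm: float

    @property
    def Q(self) -> float:
        return swelling_degree(self.d_mm, self.d0_mm)


def swelling_degree(d: float, d0: float) -> float:
    """Volume swelling degree Q = (d/d0)^3 from swollen and cast diameters."""
    if d <= 0 or d0 <= 0:
        raise ValueError("diameters must be positive")
    return (d / d0) ** 3


def mesh_size_from_modulus(G_prime_Pa: float,
                           T_K: float = ROOM_TEMPERATURE_K) -> float:
    """Rubber-elasticity mesh size in nm: xi = (G' N_A / (R T))^(-1/3).

    One elastically active strand per xi^3 stores k_B T of elastic energy;
    a 1 kPa gel at room temperature has xi of roughly 16 nm.
    """
    if G_prime_Pa <= 0 or T_K <= 0:
        raise ValueError("modulus and temperature must be positive")
    xi_m = (R * T_K / (Avogadro * G_prime_Pa)) ** (1.0 / 3.0)
    return xi_m * 1e9


def modulus_from_mesh_size(xi_nm: float,
                           T_K: float = ROOM_TEMPERATURE_K) -> float:
    """Inverse of :func:`mesh_size_from_modulus`: G' = R T / (N_A xi^3)."""
    if xi_nm <= 0 or T_K <= 0:
        raise ValueError("mesh size and temperature must be positive")
    return R * T_K / (Avogadro * (xi_nm * 1e-9) ** 3)


def young_to_shear(E_Pa: float, nu: float = 0.5) -> float:
    """Shear modulus from Young's modulus: G = E / (2 (1 + nu))."""
    if E_Pa <= 0:
        raise ValueError("Young's modulus must be positive")
    if not 0.0 <= nu <= 0.5:
        raise ValueError("Poisson's ratio must lie in [0, 0.5]")
    return E_Pa / (2.0 * (1.0 + nu))
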