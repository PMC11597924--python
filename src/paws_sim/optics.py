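"""Optical formulas: scattering model, wavenumbers, attenuation, interfaces.

Every closed-form relation the transport engines rely on lives here:
the Rayleigh-regime particle scattering coefficient, vacuum and in-medium
wavenumbers, Beer--Lambert attenuation, absorbed energy density, Snell
refraction and unpolarized Fresnel reflectance, plus wavelength-resolved
property lookup (constant baseline values or piecewise-linear curves).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScatteringParticleModel",
    "PropertyCurve",
    "OpticalProperties",
    "mie_scattering_coefficient",
    "vacuum_wavenumber",
    "medium_propagation_constant",
    "beer_lambert_intensity",
    "absorbed_energy_density",
    "snell_refract",
    "fresnel_reflectance",
]


@dataclass(frozen=True)
class ScatteringParticleModel:
    """Rayleigh-regime particle suspension: diameter, index contrast, density."""

    particle_diameter_m: float
    n_particle: float
    n_medium: float
    number_density_per_m3: float

    def __post_init__(self) -> None:
        if self.particle_diameter_m <= 0:
            raise ValueError("particle diameter must be > 0")
        if self.n_particle < 1 or self.n_medium < 1:
            raise ValueError("refractive indices must be >= 1")
        if self.number_density_per_m3 < 0:
            raise ValueError("number density must be >= 0")


def mie_scattering_coefficient(model: ScatteringParticleModel, wavelength_m: float) -> float:
    """Scattering coefficient of a dilute particle suspension (1/m).

    mu_s = (2 pi^5 d^6) / (3 lambda^4) * (n_particle - n_medium)^2 * N

    The lambda^-4 dependence is the Rayleigh limit of Mie theory; it is the
    scaling used to extrapolate baseline scattering values across the
    red/near-infrared sweep band.
    """
    if wavelength_m <= 0:
        raise ValueError("wavelength must be > 0")
    d = model.particle_diameter_m
    dn = model.n_particle - model.n_medium
    return (2.0 * math.pi**5 * d**6) / (3.0 * wavelength_m**4) * dn * dn * model.number_density_per_m3


def vacuum_wavenumber(wavelength_m: float) -> float:
    """Vacuum wavenumber k0 = 2 pi / lambda (rad/m)."""
    if wavelength_m <= 0:
        raise ValueError("wavelength must be > 0")
    return 2.0 * math.pi / wavelength_m


def medium_propagation_constant(wavelength_m: float, refractive_index: float) -> float:
    """In-medium propagation constant k = 2 pi eta / lambda = eta * k0 (rad/m)."""
    if refractive_index < 1:
        raise ValueError("refractive index must be >= 1")
    return refractive_index * vacuum_wavenumber(wavelength_m)


def beer_lambert_intensity(i0: float, mu_a: float, depth_m: float) -> float:
    """Intensity after traversing ``depth_m`` of a medium: I = I0 exp(-mu_a x)."""
    if i0 < 0 or mu_a < 0:
        raise ValueError("intensity and absorption coefficient must be >= 0")
    if depth_m < 0:
        raise ValueError("depth must be >= 0")
    return i0 * math.exp(-mu_a * depth_m)


def absorbed_energy_density(mu_a: float, intensity: float) -> float:
    """Volumetric absorbed energy density u = mu_a * I."""
    if mu_a < 0 or intensity < 0:
        raise ValueError("inputs must be >= 0")
    return mu_a * intensity


def snell_refract(n1: float, n2: float, incidence_deg: float) -> Optional[float]:
    """Refraction angle (degrees) across an n1 -> n2 interface.

    Returns ``None`` on total internal reflection.  Angles are measured from
    the interface normal and must lie in [0, 90).
    """
    if not (0.0 <= incidence_deg < 90.0):
        raise ValueError("incidence angle must lie in [0, 90) degrees")
    s = n1 / n2 * math.sin(math.radians(incidence_deg))
    if s > 1.0:
        return None
    return math.degrees(math.asin(s))


def fresnel_reflectance(n1: float, n2: float, incidence_deg: float) -> float:
    """Unpolarized Fresnel power reflectance; 1.0 under total internal reflection."""
    if not (0.0 <= incidence_deg < 90.0):
        raise ValueError("incidence angle must lie in [0, 90) degrees")
    ti = math.radians(incidence_deg)
    ci = math.cos(ti)
    s2 = (n1 / n2) ** 2 * (1.0 - ci * ci)
    if s2 >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - s2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@dataclass(frozen=True)
class PropertyCurve:
    """Wavelength-resolved (mu_a, mu_s) for one tissue, linear between knots.

    Lookups outside the knot range are clamped to the end values; a lookup
    exactly at a knot returns the knot value.
    """

    wavelengths_nm: np.ndarray
    mu_a_per_m: np.ndarray
    mu_s_per_m: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ma = np.asarray(self.mu_a_per_m, dtype=float)
        ms = np.asarray(self.mu_s_per_m, dtype=float)
        if wl.size == 0:
            raise ValueError("property curve needs at least one knot")
        if wl.size != ma.size or wl.size != ms.size:
            raise ValueError("knot arrays must have equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength knots must be strictly increasing")
        if np.any(ma < 0) or np.any(ms < 0):
            raise ValueError("coefficients must be >= 0")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "mu_a_per_m", ma)
        object.__setattr__(self, "mu_s_per_m", ms)

    def lookup(self, wavelength_nm: float) -> tuple[float, float]:
        mu_a = float(np.interp(wavelength_nm, self.wavelengths_nm, self.mu_a_per_m))
        mu_s = float(np.interp(wavelength_nm, self.wavelengths_nm, self.mu_s_per_m))
        return mu_a, mu_s


class OpticalProperties:
    """Per-layer optical coefficient lookup for the transport engines.

    In *constant* mode the baseline values stored on each
    :class:`~paws_sim.phantom.TissueLayer` are returned at every wavelength
    (this makes a wavelength sweep exactly flat).  In *curve* mode each
    layer carries a :class:`PropertyCurve` interpolated at the requested
    wavelength.  ``anisotropy`` is the scattering anisotropy g of the
    Henyey--Greenstein phase function per layer (g = 0 gives isotropic
    scattering, used by the analytic oracles).
    """

    def __init__(self, layers, curves: Optional[Sequence[Optional[PropertyCurve]]] = None,
                 anisotropy: float | Sequence[float] = 0.9):
        self.layers = tuple(layers)
        n = len(self.layers)
        if curves is not None:
            curves = list(curves)
            if len(curves) != n:
                raise ValueError("need one curve (or None) per layer")
        self.curves = curves
        g = np.broadcast_to(np.asarray(anisotropy, dtype=float), (n,)).copy()
        if np.any(np.abs(g) >= 1):
            raise ValueError("anisotropy must lie in (-1, 1)")
        self.anisotropy = g

    @classmethod
    def constant(cls, layers, anisotropy: float | Sequence[float] = 0.9) -> "OpticalProperties":
        return cls(layers, curves=None, anisotropy=anisotropy)

    @classmethod
    def from_curves(cls, layers, curves, anisotropy: float | Sequence[float] = 0.9) -> "OpticalProperties":
        return cls(layers, curves=curves, anisotropy=anisotropy)

    @property
    def is_constant(self) -> bool:
        return self.curves is None

    def coefficients(self, layer_index: int, wavelength_nm: float) -> tuple[float, float]:
        """(mu_a, mu_s) in 1/m for one layer at one wavelength."""
        layer = self.layers[layer_index]
        if self.curves is None or self.curves[layer_index] is None:
            return layer.mu_a, layer.mu_s
        return self.curves[layer_index].lookup(wavelength_nm)

    def arrays(self, wavelength_nm: float) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (mu_a[], mu_s[]) arrays over layers at one wavelength."""
        pairs = [self.coefficients(i, wavelength_nm) for i in range(len(self.layers))]
        mu_a = np.array([p[0] for p in pairs], dtype=float)
        mu_s = np.array([p[1] for p in pairs], dtype=float)
        return mu_a, mu_s

    # -- serialisation ---------------------------------------------------

    def curves_to_csv(self, path) -> None:
        """Long-format CSV: layer,wavelength_nm,mu_a_per_m,mu_s_per_m."""
        if self.curves is None:
            raise ValueError("constant-mode properties carry no curves")
        rows = []
        for layer, curve in zip(self.layers, self.curves):
            if curve is None:
                continue
            for wl, ma, ms in zip(curve.wavelengths_nm, curve.mu_a_per_m, curve.mu_s_per_m):
                rows.append([layer.name, wl, ma, ms])
        pd.DataFrame(rows, columns=["layer", "wavelength_nm", "mu_a_per_m", "mu_s_per_m"]).to_csv(
            path, index=False
        )

    @classmethod
    def curves_from_csv(cls, layers, path, anisotropy: float | Sequence[float] = 0.9) -> "OpticalProperties":
        df = pd.read_csv(path)
        curves: list[Optional[PropertyCurve]] = []
        for layer in layers:
            sub = df[df["layer"] == layer.name].sort_values("wavelength_nm")
            if sub.empty:
                curves.append(None)
            else:
                curves.append(
                    PropertyCurve(
                        sub["wavelength_nm"].to_numpy(),
                        sub["mu_a_per_m"].to_numpy(),
                        sub["mu_s_per_m"].to_numpy(),
                    )
                )
        return cls(layers, curves=curves, anisotropy=anisotropy)
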