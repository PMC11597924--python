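"""Curved layered brain phantom and implanted diode-array geometry.

The phantom is a 2D cross-section of the tissue stack facing an implanted
LED module: the polyurethane device case, the cerebrospinal fluid (CSF)
film, combined gray--white matter, and the cerebellum target layer.  Layer
interfaces are concentric circular arcs emulating head curvature; a
``curvature_radius_mm`` of ``inf`` (or ``None``) selects a flat-slab
geometry whose closed-form behaviour anchors the analytic tests.

Coordinate convention: ``x`` is the lateral coordinate (mm, midline at 0),
``y`` increases with depth into tissue, ``y = 0`` at the outer (device)
surface on the midline.  The arcs share a centre of curvature at
``(0, R)`` so that *radial depth* ``R - |P - C|`` reduces to ``y`` in the
flat limit.  All lengths are millimetres at this API surface; the physics
engines convert to metres.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TissueLayer",
    "LayeredPhantom",
    "DiodeSource",
    "SourceArray",
    "DEFAULT_LAYERS",
    "build_default_phantom",
    "locate_layer",
    "build_source_array",
    "layers_to_csv",
    "layers_from_csv",
    "phantom_to_config",
    "phantom_from_config",
]


class InvalidGeometryError(ValueError):
    """Raised when a phantom or source specification is geometrically invalid."""


@dataclass(frozen=True)
class TissueLayer:
    """One stratum of the phantom: geometric, optical and thermal parameters.

    ``mu_a``/``mu_s`` are the baseline (wavelength-independent) absorption
    and scattering coefficients in 1/m; wavelength-resolved curves may
    override them at run time (see :mod:`paws_sim.optics`).
    """

    name: str
    thickness_mm: float
    refractive_index: float
    mu_a: float  # 1/m
    mu_s: float  # 1/m
    thermal_conductivity: float  # W/(m K)
    density: float  # kg/m^3
    heat_capacity: float  # J/(kg K)

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        if self.refractive_index < 1:
            raise ValueError(f"layer {self.name!r}: refractive index must be >= 1")
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError(f"layer {self.name!r}: mu_a and mu_s must be >= 0")
        if self.thermal_conductivity <= 0 or self.density <= 0 or self.heat_capacity <= 0:
            raise ValueError(f"layer {self.name!r}: thermal parameters must be > 0")


#: Default four-layer stack (device case plus three tissue strata).
DEFAULT_LAYERS: tuple[TissueLayer, ...] = (
    TissueLayer("polyurethane", 0.8, 1.60, 0.0001, 0.50, 0.15, 1.1, 1800.0),
    TissueLayer("csf", 0.5, 1.33, 0.0013, 0.01, 0.50, 1007.0, 3850.0),
    TissueLayer("gray_white", 2.5, 1.50, 0.0009, 0.05, 0.50, 1045.0, 3500.0),
    TissueLayer("cerebellum", 3.5, 1.42, 0.0002, 0.10, 0.51, 1045.0, 3653.0),
)

DEFAULT_CURVATURE_RADIUS_MM = 80.0
DEFAULT_LATERAL_EXTENT_MM = 16.5
DEFAULT_GRID_RESOLUTION_MM = 0.05


@dataclass(frozen=True)
class LayeredPhantom:
    """Ordered curved layer stack with a Cartesian tally grid.

    ``curvature_radius_mm=inf`` gives parallel plane interfaces.  The tally
    grid spans ``x in [-L/2, L/2]``, ``y in [0, total depth]``; each cell is
    labelled with the layer containing its centre (``-1`` outside the
    tissue band, which only occurs in curved mode near the lateral edges).
    """

    layers: tuple[TissueLayer, ...] = DEFAULT_LAYERS
    curvature_radius_mm: float = DEFAULT_CURVATURE_RADIUS_MM
    lateral_extent_mm: float = DEFAULT_LATERAL_EXTENT_MM
    grid_resolution_mm: float = DEFAULT_GRID_RESOLUTION_MM

    def __post_init__(self) -> None:
        if not self.layers:
            raise InvalidGeometryError("phantom needs at least one layer")
        if self.grid_resolution_mm <= 0:
            raise InvalidGeometryError("grid resolution must be > 0")
        if self.lateral_extent_mm <= 0:
            raise InvalidGeometryError("lateral extent must be > 0")
        r = self.curvature_radius_mm
        if r is None:
            object.__setattr__(self, "curvature_radius_mm", math.inf)
        elif not math.isinf(r) and r <= self.total_depth_mm:
            raise InvalidGeometryError(
                f"curvature radius {r} mm must exceed the stack depth "
                f"{self.total_depth_mm} mm"
            )
        if self.nx < 50 or self.ny < 50:
            raise InvalidGeometryError(
                f"grid resolution {self.grid_resolution_mm} mm yields a "
                f"{self.nx} x {self.ny} grid; at least 50 x 50 cells required"
            )

    # -- derived geometry ------------------------------------------------

    @property
    def is_flat(self) -> bool:
        return math.isinf(self.curvature_radius_mm)

    @property
    def boundaries_mm(self) -> np.ndarray:
        """Cumulative interface depths, ``[0, d1, d1+d2, ...]`` (mm)."""
        return np.concatenate(
            [[0.0], np.cumsum([l.thickness_mm for l in self.layers])]
        )

    @property
    def total_depth_mm(self) -> float:
        return float(sum(l.thickness_mm for l in self.layers))

    @property
    def nx(self) -> int:
        return int(round(self.lateral_extent_mm / self.grid_resolution_mm))

    @property
    def ny(self) -> int:
        return int(round(self.total_depth_mm / self.grid_resolution_mm))

    @property
    def cell_area_m2(self) -> float:
        h = self.grid_resolution_mm * 1e-3
        return h * h

    def x_centers_mm(self) -> np.ndarray:
        h = self.grid_resolution_mm
        return -self.lateral_extent_mm / 2 + h * (np.arange(self.nx) + 0.5)

    def y_centers_mm(self) -> np.ndarray:
        h = self.grid_resolution_mm
        return h * (np.arange(self.ny) + 0.5)

    def radial_depth_mm(self, x_mm, y_mm):
        """Depth below the outer surface measured along the curvature radius."""
        if self.is_flat:
            return np.asarray(y_mm, dtype=float) + 0.0 * np.asarray(x_mm)
        r = self.curvature_radius_mm
        return r - np.sqrt(np.asarray(x_mm, dtype=float) ** 2 + (r - np.asarray(y_mm, dtype=float)) ** 2)

    def layer_map(self) -> np.ndarray:
        """Integer layer label per grid cell (``-1`` = outside the tissue band)."""
        xx, yy = np.meshgrid(self.x_centers_mm(), self.y_centers_mm())
        d = self.radial_depth_mm(xx, yy)
        b = self.boundaries_mm
        idx = np.searchsorted(b, d, side="right") - 1
        idx[(d < 0) | (idx >= len(self.layers))] = -1
        return idx.astype(np.int32)

    def surface_point(self, arc_offset_mm: float) -> tuple[float, float]:
        """Point on the outer surface at a signed arc-length offset from the midline."""
        if self.is_flat:
            return (arc_offset_mm, 0.0)
        r = self.curvature_radius_mm
        phi = arc_offset_mm / r
        return (r * math.sin(phi), r - r * math.cos(phi))

    def inward_normal(self, arc_offset_mm: float) -> tuple[float, float]:
        """Unit normal at a surface point, pointing into the tissue."""
        if self.is_flat:
            return (0.0, 1.0)
        phi = arc_offset_mm / self.curvature_radius_mm
        return (-math.sin(phi), math.cos(phi))


def build_default_phantom(
    curvature_radius_mm: float = DEFAULT_CURVATURE_RADIUS_MM,
    grid_resolution_mm: float = DEFAULT_GRID_RESOLUTION_MM,
    lateral_extent_mm: float = DEFAULT_LATERAL_EXTENT_MM,
) -> LayeredPhantom:
    """Phantom with the default four-layer property stack."""
    return LayeredPhantom(
        layers=DEFAULT_LAYERS,
        curvature_radius_mm=curvature_radius_mm,
        lateral_extent_mm=lateral_extent_mm,
        grid_resolution_mm=grid_resolution_mm,
    )


def locate_layer(phantom: LayeredPhantom, point_mm: Sequence[float]) -> Optional[int]:
    """Layer index containing ``point_mm = (x, y)``; ``None`` if outside.

    Points exactly on an interface belong to the deeper layer (deterministic
    tie-break); a point exactly on the deep boundary is therefore outside.
    """
    x, y = float(point_mm[0]), float(point_mm[1])
    if abs(x) > phantom.lateral_extent_mm / 2:
        return None
    d = float(phantom.radial_depth_mm(x, y))
    if d < 0 or d >= phantom.total_depth_mm:
        return None
    idx = int(np.searchsorted(phantom.boundaries_mm, d, side="right")) - 1
    if idx < 0 or idx >= len(phantom.layers):
        return None
    return idx


@dataclass(frozen=True)
class DiodeSource:
    """One emitter: Gaussian spot, truncated-uniform emission cone, tilted axis.

    ``tilt_angle_deg`` is measured from the local surface normal; all four
    diodes of an array share the same tilt sense, so a tilt sweep rotates
    the whole emission pattern coherently.  ``power_W`` is radiant power per
    unit out-of-plane depth (2D convention).
    """

    arc_offset_mm: float
    tilt_angle_deg: float
    wavelength_nm: float
    power_W: float
    spot_size_mm: float = 0.3
    emission_half_angle_deg: float = 60.0
    launch_depth_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tilt_angle_deg <= 90.0):
            raise ValueError("tilt angle must lie in [0, 90] degrees")
        if self.spot_size_mm <= 0:
            raise ValueError("spot size must be > 0")
        if not (0.0 < self.emission_half_angle_deg <= 90.0):
            raise ValueError("emission half angle must lie in (0, 90] degrees")
        if self.power_W < 0:
            raise ValueError("power must be >= 0")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be > 0")


@dataclass(frozen=True)
class SourceArray:
    """The implanted multi-diode array (default four diodes, 1.5 mm pitch)."""

    diodes: tuple[DiodeSource, ...]
    pitch_mm: float = 1.5

    def __post_init__(self) -> None:
        if not self.diodes:
            raise ValueError("source array needs at least one diode")
        offs = [d.arc_offset_mm for d in self.diodes]
        for a, b in zip(offs, offs[1:]):
            if not math.isclose(b - a, self.pitch_mm, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError("adjacent diode centers must be separated by the pitch")

    @property
    def tilt_angle_deg(self) -> float:
        return self.diodes[0].tilt_angle_deg

    @property
    def wavelength_nm(self) -> float:
        return self.diodes[0].wavelength_nm

    @property
    def total_power_W(self) -> float:
        return float(sum(d.power_W for d in self.diodes))


def build_source_array(
    phantom: LayeredPhantom,
    tilt_angle_deg: float,
    wavelength_nm: float,
    power_per_diode_W: float,
    n_diodes: int = 4,
    pitch_mm: float = 1.5,
    spot_size_mm: float = 0.3,
    emission_half_angle_deg: float = 60.0,
    launch_surface: str = "case-tissue",
) -> SourceArray:
    """Diode array centred on the phantom midline.

    With four diodes at 1.5 mm pitch the centres sit at arc offsets
    -2.25, -0.75, +0.75, +2.25 mm, mirror-symmetric about the midline.
    ``launch_surface`` selects where the emitting faces sit:

    * ``"case-tissue"`` (default) — on the tissue-facing boundary of the
      polyurethane case, emitting directly into the CSF; the case still
      participates in transport for back-scattered light.
    * ``"outer"`` — on the outer face of the case, so emitted light
      traverses the polyurethane before reaching tissue.
    """
    if not (0.0 <= tilt_angle_deg <= 90.0):
        raise ValueError("tilt angle must lie in [0, 90] degrees")
    if launch_surface == "case-tissue":
        launch_depth_mm = phantom.layers[0].thickness_mm
    elif launch_surface == "outer":
        launch_depth_mm = 0.0
    else:
        raise ValueError("launch_surface must be 'case-tissue' or 'outer'")
    offsets = (np.arange(n_diodes) - (n_diodes - 1) / 2.0) * pitch_mm
    half_width = phantom.lateral_extent_mm / 2
    if np.any(np.abs(offsets) >= half_width):
        raise InvalidGeometryError("diode array wider than the phantom")
    diodes = tuple(
        DiodeSource(
            arc_offset_mm=float(o),
            tilt_angle_deg=tilt_angle_deg,
            wavelength_nm=wavelength_nm,
            power_W=power_per_diode_W,
            spot_size_mm=spot_size_mm,
            emission_half_angle_deg=emission_half_angle_deg,
            launch_depth_mm=launch_depth_mm,
        )
        for o in offsets
    )
    return SourceArray(diodes=diodes, pitch_mm=pitch_mm)


# -- serialisation ------------------------------------------------------

_CSV_HEADER = [
    "name",
    "thickness_mm",
    "n",
    "mu_a_per_m",
    "mu_s_per_m",
    "k_W_per_mK",
    "rho_kg_per_m3",
    "cp_J_per_kgK",
]


def layers_to_csv(layers: Sequence[TissueLayer], path) -> None:
    df = pd.DataFrame(
        [
            [l.name, l.thickness_mm, l.refractive_index, l.mu_a, l.mu_s,
             l.thermal_conductivity, l.density, l.heat_capacity]
            for l in layers
        ],
        columns=_CSV_HEADER,
    )
    df.to_csv(path, index=False)


def layers_from_csv(path) -> tuple[TissueLayer, ...]:
    df = pd.read_csv(path)
    missing = set(_CSV_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"layer CSV missing columns: {sorted(missing)}")
    return tuple(
        TissueLayer(
            name=str(r["name"]),
            thickness_mm=float(r["thickness_mm"]),
            refractive_index=float(r["n"]),
            mu_a=float(r["mu_a_per_m"]),
            mu_s=float(r["mu_s_per_m"]),
            thermal_conductivity=float(r["k_W_per_mK"]),
            density=float(r["rho_kg_per_m3"]),
            heat_capacity=float(r["cp_J_per_kgK"]),
        )
        for _, r in df.iterrows()
    )


def phantom_to_config(phantom: LayeredPhantom, source: Optional[SourceArray] = None) -> dict:
    cfg = {
        "layers": [
            {
                "name": l.name,
                "thickness_mm": l.thickness_mm,
                "n": l.refractive_index,
                "mu_a_per_m": l.mu_a,
                "mu_s_per_m": l.mu_s,
                "k_W_per_mK": l.thermal_conductivity,
                "rho_kg_per_m3": l.density,
                "cp_J_per_kgK": l.heat_capacity,
            }
            for l in phantom.layers
        ],
        "curvature_radius_mm": None if phantom.is_flat else phantom.curvature_radius_mm,
        "lateral_extent_mm": phantom.lateral_extent_mm,
        "grid_resolution_mm": phantom.grid_resolution_mm,
    }
    if source is not None:
        d0 = source.diodes[0]
        cfg["diodes"] = {
            "count": len(source.diodes),
            "pitch_mm": source.pitch_mm,
            "spot_mm": d0.spot_size_mm,
            "half_angle_deg": d0.emission_half_angle_deg,
            "launch_surface": "outer" if d0.launch_depth_mm == 0.0 else "case-tissue",
            "tilt_deg": d0.tilt_angle_deg,
            "wavelength_nm": d0.wavelength_nm,
            "power_W": d0.power_W,
        }
    return cfg


def phantom_from_config(cfg: dict) -> tuple[LayeredPhantom, Optional[SourceArray]]:
    layers = tuple(
        TissueLayer(
            name=d["name"],
            thickness_mm=d["thickness_mm"],
            refractive_index=d["n"],
            mu_a=d["mu_a_per_m"],
            mu_s=d["mu_s_per_m"],
            thermal_conductivity=d["k_W_per_mK"],
            density=d["rho_kg_per_m3"],
            heat_capacity=d["cp_J_per_kgK"],
        )
        for d in cfg["layers"]
    )
    r = cfg.get("curvature_radius_mm")
    phantom = LayeredPhantom(
        layers=layers,
        curvature_radius_mm=math.inf if r is None else float(r),
        lateral_extent_mm=float(cfg.get("lateral_extent_mm", DEFAULT_LATERAL_EXTENT_MM)),
        grid_resolution_mm=float(cfg.get("grid_resolution_mm", DEFAULT_GRID_RESOLUTION_MM)),
    )
    source = None
    if "diodes" in cfg:
        d = cfg["diodes"]
        source = build_source_array(
            phantom,
            tilt_angle_deg=float(d.get("tilt_deg", 0.0)),
            wavelength_nm=float(d.get("wavelength_nm", 660.0)),
            power_per_diode_W=float(d.get("power_W", 3e-3)),
            n_diodes=int(d.get("count", 4)),
            pitch_mm=float(d.get("pitch_mm", 1.5)),
            spot_size_mm=float(d.get("spot_mm", 0.3)),
            emission_half_angle_deg=float(d.get("half_angle_deg", 60.0)),
            launch_surface=str(d.get("launch_surface", "case-tissue")),
        )
    return phantom, source


def save_config(path, phantom: LayeredPhantom, source: Optional[SourceArray] = None) -> None:
    with open(path, "w") as fh:
        json.dump(phantom_to_config(phantom, source), fh, indent=2)


def load_config(path) -> tuple[LayeredPhantom, Optional[SourceArray]]:
    with open(path) as fh:
        return phantom_from_config(json.load(fh))
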