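"""Light-transport engines and absorbed-energy accounting.

Two engines compute the spatial distribution of absorbed optical power in
the layered phantom:

* ``mc`` — a weighted Monte Carlo photon random walk (exponential free
  paths, Henyey--Greenstein scattering, stochastic Fresnel interface
  splits, Russian-roulette termination).  This is the physical engine for
  scattering media.
* ``ray`` — a deterministic fan of refracted rays, each attenuated by
  Beer--Lambert along its geometric path.  Scattering removes power from
  the beam into a ``scattered_out`` account instead of redirecting it, so
  this engine is exact (to floating-point precision) in low-scattering
  media and serves as the closed-form oracle for the Monte Carlo engine.

Power bookkeeping follows a two-port convention: power escaping back
through the entry (device-side) surface is the reflected port (S11
numerator), power leaving through the deep surface is the transmitted
port (S21 numerator); the lateral walls are tracked separately.  Every
launched watt ends up in exactly one account, so global conservation is
testable to Monte Carlo precision.

2D convention: all powers are per unit out-of-plane depth (W/m of depth,
written W below); the deposition grid therefore holds W per cell and the
volumetric density ``u`` is obtained by dividing by the cell area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from . import _kernel
from .optics import OpticalProperties, fresnel_reflectance
from .phantom import DiodeSource, LayeredPhantom, SourceArray

__all__ = [
    "Photon",
    "AbsorptionField",
    "PortSummary",
    "sample_emission",
    "propagate",
    "run_transport",
    "ray_engine",
    "port_summary",
    "absorption_rate",
    "absorptance_profile",
]

_MM = 1e-3


@dataclass
class Photon:
    """State of one Monte Carlo packet (positions in metres)."""

    x: float
    y: float
    ux: float
    uy: float
    weight: float = 1.0
    layer: int = 0
    alive: bool = True

    def __post_init__(self) -> None:
        norm = math.hypot(self.ux, self.uy)
        if not math.isclose(norm, 1.0, rel_tol=1e-9):
            raise ValueError("direction must be a unit vector")
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("weight must lie in [0, 1]")


@dataclass
class AbsorptionField:
    """Absorbed power distribution plus port/escape accounts.

    ``grid`` holds absorbed power per cell (W per unit out-of-plane depth);
    ``per_layer_totals`` the same integrated per layer.  ``entered`` tracks
    the power flux into each layer (every crossing counted), the
    denominator of the per-layer absorption rate.  ``per_diode_tissue``
    attributes tissue-absorbed power (all layers below the case) to each
    diode of the array.
    """

    phantom: LayeredPhantom
    grid: np.ndarray
    per_layer_totals: np.ndarray
    entered: np.ndarray
    launched_power: float
    port_reflected: float
    port_transmitted: float
    escaped_lateral: float
    scattered_out: float = 0.0
    residual: float = 0.0
    per_diode_tissue: Optional[np.ndarray] = None
    engine: str = "mc"
    n_photons: int = 0
    seed: Optional[int] = None
    wavelength_nm: Optional[float] = None

    @property
    def total_absorbed(self) -> float:
        return float(self.per_layer_totals.sum())

    @property
    def u_density_W_per_m3(self) -> np.ndarray:
        """Absorbed power density u on the tally grid (W/m^3 per unit depth)."""
        return self.grid / self.phantom.cell_area_m2

    def conservation_residual(self) -> float:
        """|launched - (absorbed + ports + lateral + scattered)| / launched."""
        if self.launched_power == 0:
            return 0.0
        total = (
            self.total_absorbed
            + self.port_reflected
            + self.port_transmitted
            + self.escaped_lateral
            + self.scattered_out
            + self.residual
        )
        return abs(self.launched_power - total) / self.launched_power

    def scaled(self, factor: float) -> "AbsorptionField":
        """Field for the same run at ``factor`` times the diode power."""
        return AbsorptionField(
            phantom=self.phantom,
            grid=self.grid * factor,
            per_layer_totals=self.per_layer_totals * factor,
            entered=self.entered * factor,
            launched_power=self.launched_power * factor,
            port_reflected=self.port_reflected * factor,
            port_transmitted=self.port_transmitted * factor,
            escaped_lateral=self.escaped_lateral * factor,
            scattered_out=self.scattered_out * factor,
            residual=self.residual * factor,
            per_diode_tissue=None if self.per_diode_tissue is None else self.per_diode_tissue * factor,
            engine=self.engine,
            n_photons=self.n_photons,
            seed=self.seed,
            wavelength_nm=self.wavelength_nm,
        )


@dataclass(frozen=True)
class PortSummary:
    """Incoherent power fractions at the two ports."""

    s11_power_fraction: float
    s21_power_fraction: float


def _geometry_args(phantom: LayeredPhantom):
    curved = not phantom.is_flat
    R = phantom.curvature_radius_mm * _MM if curved else -1.0
    bounds = phantom.boundaries_mm * _MM
    half_width = phantom.lateral_extent_mm / 2 * _MM
    h = phantom.grid_resolution_mm * _MM
    return curved, R, bounds, half_width, h


def _layer_arrays(phantom: LayeredPhantom, props: OpticalProperties, wavelength_nm: float):
    n_arr = np.array([l.refractive_index for l in phantom.layers], dtype=float)
    mu_a, mu_s = props.arrays(wavelength_nm)
    g_arr = np.asarray(props.anisotropy, dtype=float)
    return n_arr, mu_a, mu_s, g_arr


def sample_emission(diode: DiodeSource, phantom: LayeredPhantom, seed: int) -> Photon:
    """Draw one launch state from a diode's emission model.

    Launch positions are Gaussian along the surface arc about the diode
    centre (sigma = spot/2, truncated at two sigma); directions are uniform
    within the emission half-angle about the tilted axis.
    """
    curved, R, _, _, _ = _geometry_args(phantom)
    _kernel._seed(int(seed) % 2147483647)
    x, y, ux, uy = _kernel._launch(
        diode.arc_offset_mm * _MM,
        diode.spot_size_mm / 2 * _MM,
        math.radians(diode.emission_half_angle_deg),
        math.radians(diode.tilt_angle_deg),
        R,
        curved,
        diode.launch_depth_mm * _MM,
    )
    return Photon(
        x=float(x), y=float(y), ux=float(ux), uy=float(uy), weight=1.0,
        layer=_launch_layer(phantom, diode),
    )


def _launch_layer(phantom: LayeredPhantom, diode: DiodeSource) -> int:
    idx = int(np.searchsorted(phantom.boundaries_mm, diode.launch_depth_mm, side="right")) - 1
    return min(max(idx, 0), len(phantom.layers) - 1)


def propagate(
    photon: Photon,
    phantom: LayeredPhantom,
    props: OpticalProperties,
    seed: int,
    tally: AbsorptionField,
    wavelength_nm: float = 660.0,
) -> Photon:
    """Trace a single photon to termination, accumulating into ``tally``.

    Thin wrapper over the compiled single-photon tracer used by
    :func:`run_transport`; useful for stepwise tests and debugging.
    """
    curved, R, bounds, half_width, h = _geometry_args(phantom)
    n_arr, mu_a, mu_s, g_arr = _layer_arrays(phantom, props, wavelength_nm)
    accounts = np.zeros(4)
    _kernel._seed(int(seed) % 2147483647)
    w = _kernel._trace(
        photon.x, photon.y, photon.ux, photon.uy, photon.weight, photon.layer,
        R, curved, bounds, n_arr, mu_a, mu_s, g_arr,
        half_width, h, phantom.nx, phantom.ny,
        tally.grid, tally.per_layer_totals, tally.entered, accounts,
    )
    tally.port_reflected += accounts[0]
    tally.port_transmitted += accounts[1]
    tally.escaped_lateral += accounts[2]
    tally.residual += accounts[3]
    photon.weight = float(w)
    photon.alive = False
    return photon


def _empty_field(phantom: LayeredPhantom, engine: str, n_photons: int,
                 seed: Optional[int], wavelength_nm: float, n_diodes: int) -> AbsorptionField:
    nl = len(phantom.layers)
    return AbsorptionField(
        phantom=phantom,
        grid=np.zeros((phantom.ny, phantom.nx)),
        per_layer_totals=np.zeros(nl),
        entered=np.zeros(nl),
        launched_power=0.0,
        port_reflected=0.0,
        port_transmitted=0.0,
        escaped_lateral=0.0,
        per_diode_tissue=np.zeros(n_diodes),
        engine=engine,
        n_photons=n_photons,
        seed=seed,
        wavelength_nm=wavelength_nm,
    )


def run_transport(
    phantom: LayeredPhantom,
    source_array: SourceArray,
    props: OpticalProperties,
    n_photons: int = 100_000,
    seed: int = 0,
    engine: str = "mc",
    rays_per_diode: tuple[int, int] = (9, 181),
) -> AbsorptionField:
    """Compute the absorbed-power field for a diode array.

    ``n_photons`` is the total Monte Carlo packet count, split evenly over
    the diodes; it is ignored by the ray engine, which instead traces a
    deterministic fan of ``rays_per_diode = (spot nodes, angular nodes)``.
    Identical arguments (including ``seed``) give bit-identical results.
    """
    if engine == "ray":
        return ray_engine(phantom, source_array, props, rays_per_diode=rays_per_diode)
    if engine != "mc":
        raise ValueError(f"unknown engine {engine!r}; expected 'mc' or 'ray'")
    if n_photons < 1:
        raise ValueError("Monte Carlo engine needs n_photons >= 1")

    wavelength = source_array.wavelength_nm
    field = _empty_field(phantom, "mc", n_photons, seed, wavelength, len(source_array.diodes))
    if source_array.total_power_W == 0.0:
        return field

    curved, R, bounds, half_width, h = _geometry_args(phantom)
    n_arr, mu_a, mu_s, g_arr = _layer_arrays(phantom, props, wavelength)

    tissue = slice(1, None)  # layers below the device case
    n_per = n_photons // len(source_array.diodes)
    extra = n_photons - n_per * len(source_array.diodes)
    for k, diode in enumerate(source_array.diodes):
        n_k = n_per + (1 if k < extra else 0)
        if n_k == 0 or diode.power_W == 0.0:
            continue
        weight = diode.power_W / n_k
        accounts = np.zeros(4)
        before = field.per_layer_totals[tissue].sum()
        # decorrelate diodes by folding the diode index into the seed base
        seed_base = (int(seed) + 1_000_003 * (k + 1)) % 2147483647
        _kernel.run_photons(
            seed_base, n_k, weight,
            diode.arc_offset_mm * _MM,
            diode.spot_size_mm / 2 * _MM,
            math.radians(diode.emission_half_angle_deg),
            math.radians(diode.tilt_angle_deg),
            diode.launch_depth_mm * _MM,
            _launch_layer(phantom, diode),
            R, curved, bounds, n_arr, mu_a, mu_s, g_arr,
            half_width, h, phantom.nx, phantom.ny,
            field.grid, field.per_layer_totals, field.entered, accounts,
        )
        field.per_diode_tissue[k] = field.per_layer_totals[tissue].sum() - before
        field.launched_power += diode.power_W
        field.port_reflected += accounts[0]
        field.port_transmitted += accounts[1]
        field.escaped_lateral += accounts[2]
        field.residual += accounts[3]
    return field


# -- deterministic ray engine --------------------------------------------


def _ray_fan(diode: DiodeSource, n_spot: int, n_ang: int):
    """Quadrature nodes/weights over the Gaussian spot and uniform cone."""
    sigma = diode.spot_size_mm / 2 * _MM
    if n_spot <= 1 or sigma == 0.0:
        offsets = np.array([0.0])
        w_spot = np.array([1.0])
    else:
        edges = np.linspace(-2.0 * sigma, 2.0 * sigma, n_spot + 1)
        offsets = 0.5 * (edges[:-1] + edges[1:])
        w_spot = np.exp(-0.5 * (offsets / sigma) ** 2)
        w_spot = w_spot / w_spot.sum()
    half = math.radians(diode.emission_half_angle_deg)
    if n_ang <= 1 or half == 0.0:
        angles = np.array([0.0])
        w_ang = np.array([1.0])
    else:
        edges = np.linspace(-half, half, n_ang + 1)
        angles = 0.5 * (edges[:-1] + edges[1:])
        w_ang = np.full(n_ang, 1.0 / n_ang)
    return offsets, w_spot, angles, w_ang


def ray_engine(
    phantom: LayeredPhantom,
    source_array: SourceArray,
    props: OpticalProperties,
    rays_per_diode: tuple[int, int] = (9, 181),
    collimated: bool = False,
) -> AbsorptionField:
    """Deterministic layered Beer--Lambert engine.

    Each diode is represented by a fan of rays (Gaussian-weighted over the
    spot, uniform over the emission cone; ``collimated=True`` collapses the
    fan to a single axial ray).  Rays refract at every interface; the
    Fresnel-reflected fraction is credited to the reflected port without
    further tracing (first-order treatment, exact for index-matched
    stacks), total internal reflection terminates the ray into the same
    account.  Scattering attenuates the beam into ``scattered_out``.
    """
    wavelength = source_array.wavelength_nm
    field = _empty_field(phantom, "ray", 0, None, wavelength, len(source_array.diodes))
    if source_array.total_power_W == 0.0:
        return field

    curved, R, bounds, half_width, h = _geometry_args(phantom)
    n_arr, mu_a, mu_s, g_arr = _layer_arrays(phantom, props, wavelength)
    nl = len(phantom.layers)
    nx_cells, ny_cells = phantom.nx, phantom.ny
    tissue = slice(1, None)
    sub = h / 2.0  # deposition substep; layer totals are exact regardless

    for k, diode in enumerate(source_array.diodes):
        if diode.power_W == 0.0:
            continue
        before = field.per_layer_totals[tissue].sum()
        field.launched_power += diode.power_W
        if collimated:
            offsets, w_spot = np.array([0.0]), np.array([1.0])
            angles, w_ang = np.array([0.0]), np.array([1.0])
        else:
            offsets, w_spot, angles, w_ang = _ray_fan(diode, *rays_per_diode)
        tilt = math.radians(diode.tilt_angle_deg)
        d_launch = diode.launch_depth_mm * _MM
        layer0 = _launch_layer(phantom, diode)
        for off, ws in zip(offsets, w_spot):
            s = diode.arc_offset_mm * _MM + off
            if curved:
                r_launch = R - d_launch
                phi = s / r_launch
                x0, y0 = r_launch * math.sin(phi), R - r_launch * math.cos(phi)
                nx0, ny0 = -math.sin(phi), math.cos(phi)
            else:
                x0, y0 = s, d_launch
                nx0, ny0 = 0.0, 1.0
            for ang, wa in zip(angles, w_ang):
                a = tilt + ang
                ca, sa = math.cos(a), math.sin(a)
                ux, uy = ca * nx0 - sa * ny0, sa * nx0 + ca * ny0
                w = diode.power_W * ws * wa
                field.entered[layer0] += w
                _trace_ray(
                    x0, y0, ux, uy, w, field, layer0,
                    R, curved, bounds, n_arr, mu_a, mu_s,
                    half_width, h, sub, nx_cells, ny_cells, nl,
                )
        field.per_diode_tissue[k] = field.per_layer_totals[tissue].sum() - before
    return field


def _trace_ray(x, y, ux, uy, w, field, layer0, R, curved, bounds, n_arr, mu_a, mu_s,
               half_width, h, sub, nx_cells, ny_cells, nl):
    # small enough that the skipped optical depth stays below 1e-9 relative
    nudge = 1e-12
    layer = layer0
    x += ux * nudge
    y += uy * nudge
    while w > 1e-15:
        db, which = _kernel._dist_to_boundary(
            x, y, ux, uy, R, curved, bounds[layer], bounds[layer + 1], half_width
        )
        if which == -1:
            field.residual += w
            return
        mt = mu_a[layer] + mu_s[layer]
        if mt > 0.0 and db > 0.0:
            # exact per-layer attenuation; grid deposition on substeps
            w_end = w * math.exp(-mt * db)
            absorbed = (w - w_end) * (mu_a[layer] / mt)
            field.per_layer_totals[layer] += absorbed
            field.scattered_out += (w - w_end) * (mu_s[layer] / mt)
            n_sub = max(1, int(math.ceil(db / sub)))
            t_edges = np.linspace(0.0, db, n_sub + 1)
            w_edges = w * np.exp(-mt * t_edges)
            dep = (w_edges[:-1] - w_edges[1:]) * (mu_a[layer] / mt)
            t_mid = 0.5 * (t_edges[:-1] + t_edges[1:])
            xs = x + ux * t_mid
            ys = y + uy * t_mid
            ix = np.clip(((xs + half_width) / h).astype(np.int64), 0, nx_cells - 1)
            iy = np.clip((ys / h).astype(np.int64), 0, ny_cells - 1)
            np.add.at(field.grid, (iy, ix), dep)
            w = w_end
        x += ux * db
        y += uy * db
        if which == 2:
            field.escaped_lateral += w
            return
        if which == 0 and layer == 0:
            field.port_reflected += w
            return
        if which == 1 and layer == nl - 1:
            field.port_transmitted += w
            return
        m = layer - 1 if which == 0 else layer + 1
        if curved:
            ox, oy = x, y - R
            on = math.hypot(ox, oy)
            nhx, nhy = ox / on, oy / on
        else:
            nhx, nhy = 0.0, -1.0
        dot = ux * nhx + uy * nhy
        if dot > 0.0:
            nhx, nhy, dot = -nhx, -nhy, -dot
        ci = -dot
        n1, n2 = n_arr[layer], n_arr[m]
        eta = n1 / n2
        s2 = eta * eta * (1.0 - ci * ci)
        if s2 >= 1.0:
            field.port_reflected += w  # TIR: first-order credit to the entry port
            return
        ct = math.sqrt(1.0 - s2)
        rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
        rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
        rf = 0.5 * (rs * rs + rp * rp)
        field.port_reflected += w * rf
        w *= 1.0 - rf
        ux = eta * ux + (eta * ci - ct) * nhx
        uy = eta * uy + (eta * ci - ct) * nhy
        norm = math.hypot(ux, uy)
        ux, uy = ux / norm, uy / norm
        layer = m
        field.entered[layer] += w
        x += ux * nudge
        y += uy * nudge


# -- derived summaries ----------------------------------------------------


def port_summary(field: AbsorptionField) -> PortSummary:
    """S11/S21-style power fractions of the launched power."""
    if field.launched_power <= 0.0:
        raise ValueError("port summary undefined for zero launched power")
    return PortSummary(
        s11_power_fraction=field.port_reflected / field.launched_power,
        s21_power_fraction=field.port_transmitted / field.launched_power,
    )


def absorption_rate(field: AbsorptionField, region) -> float:
    """Absorbed power in a region divided by the power that entered it.

    ``region`` is a layer index or ``"all"`` (whole phantom, denominator =
    launched power).
    """
    if region == "all":
        if field.launched_power <= 0.0:
            raise ValueError("absorption rate undefined: no launched power")
        return field.total_absorbed / field.launched_power
    i = int(region)
    if not (0 <= i < len(field.phantom.layers)):
        raise ValueError(f"invalid layer index {region}")
    if field.entered[i] <= 0.0:
        raise ValueError(f"no power ever entered layer {i}; rate undefined")
    return float(field.per_layer_totals[i] / field.entered[i])


def absorptance_profile(field: AbsorptionField) -> tuple[np.ndarray, np.ndarray]:
    """Depth-integrated absorbed power vs lateral position.

    Returns (x centers in mm, per-column absorbed power); the column sum
    equals the total absorbed power.
    """
    return field.phantom.x_centers_mm(), field.grid.sum(axis=0)
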