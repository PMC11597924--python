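"""Multi-parameter sweep: incident angle x wavelength x power.

One transport run is performed per (angle, wavelength) grid point at unit
diode power; the power axis is filled in by exact scaling, which is valid
because the transport model is strictly linear in source power (and keeps
the power column free of independent Monte Carlo noise).  Per-point seeds
are derived by hashing (run seed, angle, wavelength), so adding grid
points never perturbs existing ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bioheat import max_temperature_rise, run_transient
from .optics import OpticalProperties
from .phantom import LayeredPhantom, build_source_array
from .transport import AbsorptionField, absorption_rate, port_summary, run_transport

__all__ = ["SweepSpec", "SweepResult", "run_sweep", "find_optimum", "thermal_safety_report", "derive_seed"]

DEFAULT_ANGLES = tuple(float(a) for a in range(0, 91, 10))
DEFAULT_WAVELENGTHS = tuple(float(w) for w in range(660, 871, 30))
DEFAULT_POWERS = tuple(k * 1e-3 for k in range(1, 9))  # 1-8 mW per diode


def derive_seed(seed: int, *parts) -> int:
    """Deterministic 31-bit seed from a base seed and grid-point labels."""
    key = "|".join([str(int(seed))] + [repr(float(p)) for p in parts])
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


@dataclass(frozen=True)
class SweepSpec:
    """Grid definition plus engine configuration for one sweep."""

    angles_deg: tuple[float, ...] = DEFAULT_ANGLES
    wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS
    powers_W: tuple[float, ...] = DEFAULT_POWERS
    engine: str = "mc"
    n_photons: int = 100_000
    seed: int = 0
    target_layer: int = 3  # cerebellum in the default stack

    def __post_init__(self) -> None:
        if not self.angles_deg or not self.wavelengths_nm or not self.powers_W:
            raise ValueError("sweep grids must be non-empty")
        if self.engine not in ("mc", "ray"):
            raise ValueError("engine must be 'mc' or 'ray'")
        if any(not (0.0 <= a <= 90.0) for a in self.angles_deg):
            raise ValueError("angles must lie in [0, 90] degrees")
        if any(w <= 0 for w in self.wavelengths_nm):
            raise ValueError("wavelengths must be > 0")
        if any(p < 0 for p in self.powers_W):
            raise ValueError("powers must be >= 0")


@dataclass
class SweepResult:
    """Long-format sweep table plus provenance."""

    table: pd.DataFrame
    spec: SweepSpec
    phantom: LayeredPhantom

    @property
    def optimum(self) -> tuple[float, float]:
        return find_optimum(self, self.spec.target_layer)

    def provenance(self) -> dict:
        from . import __version__

        d = asdict(self.spec)
        d["software_version"] = __version__
        d["curvature_radius_mm"] = (
            None if self.phantom.is_flat else self.phantom.curvature_radius_mm
        )
        d["grid_resolution_mm"] = self.phantom.grid_resolution_mm
        return d

    def save(self, csv_path, sidecar_path=None) -> None:
        self.table.to_csv(csv_path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.provenance(), fh, indent=2)


def run_sweep(
    spec: SweepSpec,
    phantom: LayeredPhantom,
    props: OpticalProperties,
    keep_fields: bool = False,
) -> SweepResult:
    """Run the full angle x wavelength x power grid.

    Returns a :class:`SweepResult` whose table has one row per grid point
    with per-layer absorbed power (W per unit depth), the target layer's
    absorption rate, and the port fractions.  ``keep_fields=True`` attaches
    the unit-power :class:`AbsorptionField` per (angle, wavelength) under
    ``result.fields`` for downstream thermal analysis.
    """
    rows = []
    fields: dict[tuple[float, float], AbsorptionField] = {}
    layer_names = [l.name for l in phantom.layers]
    for angle in spec.angles_deg:
        for wl in spec.wavelengths_nm:
            source = build_source_array(
                phantom, tilt_angle_deg=angle, wavelength_nm=wl, power_per_diode_W=1.0
            )
            point_seed = derive_seed(spec.seed, angle, wl)
            field = run_transport(
                phantom, source, props,
                n_photons=spec.n_photons, seed=point_seed, engine=spec.engine,
            )
            if keep_fields:
                fields[(angle, wl)] = field
            ports = port_summary(field)
            try:
                rate = absorption_rate(field, spec.target_layer)
            except ValueError:
                rate = np.nan
            for power in spec.powers_W:
                row = {
                    "angle_deg": angle,
                    "wavelength_nm": wl,
                    "power_W": power,
                    "seed": point_seed,
                }
                for name, tot in zip(layer_names, field.per_layer_totals):
                    row[f"abs_{name}_W"] = tot * power
                row["target_absorbed_W"] = field.per_layer_totals[spec.target_layer] * power
                row["target_absorption_rate"] = rate
                row["S11"] = ports.s11_power_fraction
                row["S21"] = ports.s21_power_fraction
                rows.append(row)
    result = SweepResult(table=pd.DataFrame(rows), spec=spec, phantom=phantom)
    if keep_fields:
        result.fields = fields
    return result


def find_optimum(result: SweepResult, layer: Optional[int] = None) -> tuple[float, float]:
    """(angle*, wavelength*) maximising the layer's absorbed power.

    Ties break toward the smaller angle, then the smaller wavelength.
    """
    df = result.table
    if df.empty:
        raise ValueError("empty sweep table")
    layer = result.spec.target_layer if layer is None else layer
    name = result.phantom.layers[layer].name
    col = f"abs_{name}_W"
    ordered = df.sort_values(["angle_deg", "wavelength_nm"], kind="stable")
    best = ordered[ordered[col] == ordered[col].max()].iloc[0]
    return float(best["angle_deg"]), float(best["wavelength_nm"])


def thermal_safety_report(
    result: SweepResult,
    phantom: LayeredPhantom,
    props: OpticalProperties,
    duration_s: float = 300.0,
    dt: float = 1.0,
    points: Optional[Sequence[tuple[float, float, float]]] = None,
) -> pd.DataFrame:
    """Maximum temperature rise per sweep grid point.

    Re-runs transport (same per-point seed as the sweep) and the transient
    heat solver for each requested ``(angle, wavelength, power)`` point;
    by default every point in the sweep table is evaluated, which can be
    slow — pass ``points`` to restrict to the rows of interest.
    """
    spec = result.spec
    if points is None:
        points = list(
            result.table[["angle_deg", "wavelength_nm", "power_W"]].itertuples(index=False, name=None)
        )
    cache: dict[tuple[float, float], AbsorptionField] = getattr(result, "fields", {}) or {}
    rows = []
    for angle, wl, power in points:
        key = (float(angle), float(wl))
        if key not in cache:
            source = build_source_array(
                phantom, tilt_angle_deg=angle, wavelength_nm=wl, power_per_diode_W=1.0
            )
            cache[key] = run_transport(
                phantom, source, props,
                n_photons=spec.n_photons, seed=derive_seed(spec.seed, angle, wl),
                engine=spec.engine,
            )
        field = cache[key].scaled(float(power))
        series = run_transient(phantom, field, duration_s=duration_s, dt=dt)
        rows.append(
            {
                "angle_deg": float(angle),
                "wavelength_nm": float(wl),
                "power_W": float(power),
                "max_rise_K": max_temperature_rise(series),
            }
        )
    return pd.DataFrame(rows)
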