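"""Transient heat conduction in the phantom driven by absorbed light power.

The temperature field obeys the conduction equation

    rho c dT/dt = div(k grad T) + u,

with layer-wise thermal conductivity k, density rho and heat capacity c,
and the absorbed optical power density u as the volumetric source.  No
perfusion or metabolic terms are included by default (a uniform constant
source can be folded into ``extra_source``); conduction is therefore
linear in the source power, which the tests exploit.

Discretisation: finite volumes on the phantom's tally grid with
harmonic-mean conductivity at cell faces.  Two time steppers are
provided: an explicit scheme (with an automatic stability bound, used by
small analytic tests) and an implicit backward-Euler scheme (one sparse
factorisation, unconditionally stable, the default for long transients).

Boundary conditions: the device face (top edge) is insulated, the deep
and lateral edges are held at body temperature (310.15 K) by default;
each edge is configurable as fixed-temperature or insulated.  Grid cells
outside the curved tissue band are excluded (treated as insulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .phantom import LayeredPhantom
from .transport import AbsorptionField

__all__ = [
    "ThermalField",
    "BoundaryConditions",
    "step_heat",
    "run_transient",
    "solve_steady_state",
    "max_temperature_rise",
    "BODY_TEMPERATURE_K",
]

BODY_TEMPERATURE_K = 310.15


@dataclass(frozen=True)
class BoundaryConditions:
    """Per-edge condition: a float fixes the edge temperature, None insulates."""

    top: Optional[float] = None  # device face: insulated
    bottom: Optional[float] = BODY_TEMPERATURE_K
    left: Optional[float] = BODY_TEMPERATURE_K
    right: Optional[float] = BODY_TEMPERATURE_K


@dataclass
class ThermalField:
    """Temperature grid (K) over the phantom plus its volumetric source."""

    phantom: LayeredPhantom
    temperature: np.ndarray  # (ny, nx), K
    source: np.ndarray  # (ny, nx), W per cell per unit depth
    time_s: float = 0.0
    bc: BoundaryConditions = dc_field(default_factory=BoundaryConditions)

    def __post_init__(self) -> None:
        shape = (self.phantom.ny, self.phantom.nx)
        if self.temperature.shape != shape or self.source.shape != shape:
            raise ValueError(f"grids must have the phantom shape {shape}")

    @classmethod
    def from_absorption(
        cls,
        phantom: LayeredPhantom,
        absorption: Optional[AbsorptionField] = None,
        initial_temperature: float = BODY_TEMPERATURE_K,
        bc: Optional[BoundaryConditions] = None,
        extra_source: float = 0.0,
    ) -> "ThermalField":
        """Initial isothermal field driven by an absorbed-power grid.

        ``extra_source`` (W/m^3) adds a uniform volumetric term, e.g. a
        constant metabolic heat generation rate.
        """
        source = np.zeros((phantom.ny, phantom.nx))
        if absorption is not None:
            source = absorption.grid.copy()
        if extra_source:
            source = source + extra_source * phantom.cell_area_m2
        return cls(
            phantom=phantom,
            temperature=np.full((phantom.ny, phantom.nx), float(initial_temperature)),
            source=source,
            bc=bc or BoundaryConditions(),
        )


class _Discretisation:
    """Face conductances, heat capacities and boundary coupling for a phantom."""

    def __init__(self, phantom: LayeredPhantom, bc: BoundaryConditions):
        self.phantom = phantom
        self.bc = bc
        h = phantom.grid_resolution_mm * 1e-3
        self.h = h
        lm = phantom.layer_map()
        self.inside = lm >= 0
        k = np.array([l.thermal_conductivity for l in phantom.layers])
        rhoc = np.array([l.density * l.heat_capacity for l in phantom.layers])
        safe = np.where(lm >= 0, lm, 0)
        self.k = np.where(self.inside, k[safe], 0.0)
        # heat capacity per cell per unit depth: rho c * h^2
        self.cap = np.where(self.inside, rhoc[safe], 1.0) * h * h

    @staticmethod
    def _harmonic(ka, kb):
        s = ka + kb
        out = np.zeros_like(ka)
        nz = s > 0
        out[nz] = 2.0 * ka[nz] * kb[nz] / s[nz]
        return out

    def face_conductances(self):
        """(G_south, G_east) interior face conductances, W/K per unit depth.

        For unit cell size the face conductance reduces to the harmonic-mean
        conductivity; faces touching outside cells carry zero conductance.
        """
        k = self.k
        g_s = self._harmonic(k[:-1, :], k[1:, :])  # between row j and j+1
        g_e = self._harmonic(k[:, :-1], k[:, 1:])  # between col i and i+1
        return g_s, g_e

    def boundary_terms(self):
        """Dirichlet edge conductance grid and its target-temperature grid."""
        ny, nx = self.k.shape
        g = np.zeros((ny, nx))
        t = np.zeros((ny, nx))

        def fix(rows, cols, temp):
            if temp is None:
                return
            gg = 2.0 * self.k[rows, cols]  # half-cell distance to the wall
            g[rows, cols] += gg
            t[rows, cols] += gg * temp

        fix(0, slice(None), self.bc.top)
        fix(-1, slice(None), self.bc.bottom)
        fix(slice(None), 0, self.bc.left)
        fix(slice(None), -1, self.bc.right)
        return g, t


def stable_dt(phantom: LayeredPhantom, bc: Optional[BoundaryConditions] = None) -> float:
    """Largest stable explicit time step (s) for this phantom/boundary setup."""
    disc = _Discretisation(phantom, bc or BoundaryConditions())
    g_s, g_e = disc.face_conductances()
    g_b, _ = disc.boundary_terms()
    total = g_b.copy()
    total[:-1, :] += g_s
    total[1:, :] += g_s
    total[:, :-1] += g_e
    total[:, 1:] += g_e
    with np.errstate(divide="ignore"):
        bound = np.where(total > 0, disc.cap / np.maximum(total, 1e-300), np.inf)
    return float(bound[disc.inside].min())


def step_heat(field: ThermalField, dt: float) -> ThermalField:
    """Advance the temperature grid one explicit time step.

    Raises ``ValueError`` with the computed stable bound when ``dt``
    violates the explicit stability criterion.
    """
    bound = stable_dt(field.phantom, field.bc)
    if dt > bound:
        raise ValueError(
            f"explicit step dt={dt:g} s unstable; stable bound is {bound:.6g} s"
        )
    disc = _Discretisation(field.phantom, field.bc)
    T = field.temperature
    g_s, g_e = disc.face_conductances()
    g_b, gt_b = disc.boundary_terms()

    flux = np.zeros_like(T)
    d = g_s * (T[1:, :] - T[:-1, :])
    flux[:-1, :] += d
    flux[1:, :] -= d
    d = g_e * (T[:, 1:] - T[:, :-1])
    flux[:, :-1] += d
    flux[:, 1:] -= d
    flux += gt_b - g_b * T
    flux += field.source

    T_new = T + dt * flux / disc.cap
    T_new[~disc.inside] = T[~disc.inside]
    return ThermalField(
        phantom=field.phantom,
        temperature=T_new,
        source=field.source,
        time_s=field.time_s + dt,
        bc=field.bc,
    )


def _assemble(disc: _Discretisation):
    """Sparse conduction operator K (W/K) with Dirichlet terms folded in."""
    ny, nx = disc.k.shape
    n = ny * nx

    def idx(j, i):
        return j * nx + i

    g_s, g_e = disc.face_conductances()
    g_b, gt_b = disc.boundary_terms()

    diag = g_b.ravel().copy()
    rows, cols, vals = [], [], []

    jj, ii = np.nonzero(g_s)
    a = jj * nx + ii
    b = (jj + 1) * nx + ii
    g = g_s[jj, ii]
    rows += [a, b]
    cols += [b, a]
    vals += [-g, -g]
    np.add.at(diag, a, g)
    np.add.at(diag, b, g)

    jj, ii = np.nonzero(g_e)
    a = jj * nx + ii
    b = jj * nx + ii + 1
    g = g_e[jj, ii]
    rows += [a, b]
    cols += [b, a]
    vals += [-g, -g]
    np.add.at(diag, a, g)
    np.add.at(diag, b, g)

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)

    K = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return K, gt_b.ravel()


def run_transient(
    phantom: LayeredPhantom,
    absorption: Optional[AbsorptionField],
    duration_s: float,
    dt: float = 1.0,
    initial_temperature: float = BODY_TEMPERATURE_K,
    bc: Optional[BoundaryConditions] = None,
    method: str = "implicit",
    record_every: int = 1,
    extra_source: float = 0.0,
) -> pd.DataFrame:
    """Per-layer mean temperature time series under a constant source.

    Returns a DataFrame with columns ``time_s``, ``T_mean_<layer>_K`` for
    every layer and ``T_max_K``.  The implicit (backward Euler) stepper is
    the default; ``method="explicit"`` uses :func:`step_heat` and requires
    ``dt`` below the stability bound.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    field = ThermalField.from_absorption(
        phantom, absorption, initial_temperature, bc, extra_source
    )
    n_steps = int(round(duration_s / dt))
    if n_steps < 1:
        raise ValueError("duration must cover at least one step")

    disc = _Discretisation(field.phantom, field.bc)
    lm = phantom.layer_map()
    masks = [(lm == i) for i in range(len(phantom.layers))]
    names = [l.name for l in phantom.layers]
    inside = disc.inside

    records = []

    def record(t, T):
        row = {"time_s": t}
        for name, m in zip(names, masks):
            row[f"T_mean_{name}_K"] = float(T[m].mean()) if m.any() else np.nan
        row["T_max_K"] = float(T[inside].max())
        records.append(row)

    record(0.0, field.temperature)

    if method == "explicit":
        for s in range(n_steps):
            field = step_heat(field, dt)
            if (s + 1) % record_every == 0 or s == n_steps - 1:
                record(field.time_s, field.temperature)
    elif method == "implicit":
        K, bvec = _assemble(disc)
        cap = disc.cap.ravel()
        A = sp.diags(cap / dt) + K
        lu = spla.splu(A.tocsc())
        T = field.temperature.ravel().copy()
        src = field.source.ravel()
        t = 0.0
        for s in range(n_steps):
            rhs = cap / dt * T + src + bvec
            T = lu.solve(rhs)
            t += dt
            if (s + 1) % record_every == 0 or s == n_steps - 1:
                record(t, T.reshape(field.temperature.shape))
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame.from_records(records)


def solve_steady_state(
    phantom: LayeredPhantom,
    absorption: Optional[AbsorptionField] = None,
    bc: Optional[BoundaryConditions] = None,
    extra_source: float = 0.0,
) -> np.ndarray:
    """Steady-state temperature grid (direct sparse solve of K T = S)."""
    field = ThermalField.from_absorption(phantom, absorption, BODY_TEMPERATURE_K, bc, extra_source)
    disc = _Discretisation(field.phantom, field.bc)
    K, bvec = _assemble(disc)
    rhs = field.source.ravel() + bvec
    # pin cells outside the tissue band (zero conductance) at body temperature
    outside = ~disc.inside.ravel()
    if outside.any():
        K = K.tolil()
        idx = np.nonzero(outside)[0]
        K[idx, :] = 0.0
        K[idx, idx] = 1.0
        K = K.tocsc()
        rhs = rhs.copy()
        rhs[idx] = BODY_TEMPERATURE_K
    # insulated-everywhere problems are singular; require a Dirichlet edge
    T = spla.spsolve(K.tocsc(), rhs)
    return T.reshape(field.temperature.shape)


def max_temperature_rise(series: pd.DataFrame, initial_temperature: float = BODY_TEMPERATURE_K) -> float:
    """Maximum of T_max over the series relative to the initial temperature (K)."""
    if series.empty:
        raise ValueError("empty time series")
    return float(series["T_max_K"].max() - initial_temperature)
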