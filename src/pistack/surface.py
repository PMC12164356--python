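"""2-D interaction-energy surfaces: scanning, MEPs, stationary points.

A surface is a lattice of dimer displacement coordinates (x, z) with one
energy matrix per component.  The minimum-energy path (MEP) relaxes z at
every x (argmin over the grid refined by a local quadratic through the
bracketing triple).  Stationary points are classified on the grid against
the 8 surrounding nodes; statements about minima and saddles are therefore
grid-resolution statements, which is how such surfaces are normally read.

The relative-energy composition ("starred" surfaces) replaces a model's
defective description of the benzene dimer with a reference surface while
keeping the model's *differential* heteroatom or substituent effect:

    E*(X)(x, z) = E_ref(benzene)(x, z) + [E_model(X)(x, z) - E_model(benzene)(x, z)]

computed nodewise on identical lattices, never resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import GridAlignmentError, PiStackError
from .hs_potential import EnergyBreakdown

__all__ = [
    "Grid2D",
    "MEPPath",
    "StationaryPoint",
    "BoundaryMinimumWarning",
    "scan",
    "slice_at_z",
    "mep",
    "stationary_points",
    "hs_star",
    "grid_to_csv",
    "grid_from_csv",
    "mep_to_csv",
]


class BoundaryMinimumWarning(UserWarning):
    """The per-x minimum fell on the z-grid boundary; the grid is too small."""


@dataclass
class Grid2D:
    """Energies on an (x, z) lattice, one layer per component."""

    x_values: np.ndarray  # sorted, Angstrom
    z_values: np.ndarray  # sorted, Angstrom
    layers: dict[str, np.ndarray]  # name -> (nx, nz) kcal/mol
    provenance: dict = field(default_factory=dict)
    clamped: np.ndarray | None = None  # (nx, nz) bool, z below model floor
    undefined: np.ndarray | None = None  # (nx, nz) bool, evaluation failed

    def __post_init__(self):
        self.x_values = np.asarray(self.x_values, dtype=float)
        self.z_values = np.asarray(self.z_values, dtype=float)
        if np.any(np.diff(self.x_values) <= 0) or np.any(np.diff(self.z_values) <= 0):
            raise PiStackError("grid axes must be strictly increasing")
        shape = (len(self.x_values), len(self.z_values))
        for name, layer in self.layers.items():
            if np.asarray(layer).shape != shape:
                raise PiStackError(f"layer {name!r} shape {np.asarray(layer).shape} != {shape}")

    @property
    def total(self) -> np.ndarray:
        return self.layers["total"]

    def min_node(self) -> tuple[float, float, float]:
        """(x, z, energy) of the lowest grid node (smaller x wins ties)."""
        t = np.where(np.isnan(self.total), np.inf, self.total)
        flat = int(np.argmin(t))  # np.argmin returns the first (smallest x) tie
        i, j = np.unravel_index(flat, t.shape)
        return float(self.x_values[i]), float(self.z_values[j]), float(self.total[i, j])


@dataclass
class MEPPath:
    """Per-x vertically relaxed path: (x, z_star, energy) triples."""

    points: list[tuple[float, float, float]]
    boundary_flags: list[bool] = field(default_factory=list)

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def z_star(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def energy(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])


@dataclass(frozen=True)
class StationaryPoint:
    kind: Literal["minimum", "saddle", "maximum"]
    x: float
    z: float
    energy: float


def scan(
    dimer_family: Callable[[float, float], object],
    potential: Callable[[object], EnergyBreakdown],
    x_values: Sequence[float],
    z_values: Sequence[float],
) -> Grid2D:
    """Evaluate a potential over every (x, z) node of the lattice.

    Nodes where the potential raises (guard radius, singular geometry) are
    recorded as NaN in every layer and flagged in ``undefined`` rather than
    aborting the scan.  For models with a z floor, nodes below the floor are
    evaluated as-is but flagged in ``clamped`` so slice-level conventions can
    be applied downstream.
    """
    xs = np.asarray(x_values, dtype=float)
    zs = np.asarray(z_values, dtype=float)
    if xs.size == 0 or zs.size == 0:
        raise PiStackError("empty scan axes")
    components = list(getattr(potential, "components", ("elec", "vdw", "pauli", "disp")))
    layers = {name: np.zeros((xs.size, zs.size)) for name in components + ["total"]}
    undefined = np.zeros((xs.size, zs.size), dtype=bool)
    z_floor = getattr(getattr(potential, "params", None), "z_floor", None)
    clamped = None
    if z_floor is not None:
        clamped = np.zeros((xs.size, zs.size), dtype=bool)
        clamped[:, zs < z_floor] = True
    for i, x in enumerate(xs):
        for j, z in enumerate(zs):
            try:
                bd = potential(dimer_family(float(x), float(z)))
            except PiStackError:
                undefined[i, j] = True
                for name in layers:
                    layers[name][i, j] = np.nan
                continue
            d = bd.as_dict()
            for name in components:
                layers[name][i, j] = d[name]
            layers["total"][i, j] = d["total"]
    prov = {"x_step": float(xs[1] - xs[0]) if xs.size > 1 else 0.0,
            "z_step": float(zs[1] - zs[0]) if zs.size > 1 else 0.0}
    if hasattr(potential, "provenance"):
        prov.update(potential.provenance())
    return Grid2D(x_values=xs, z_values=zs, layers=layers, provenance=prov,
                  clamped=clamped, undefined=undefined)


def slice_at_z(grid: Grid2D, z: float, component: str = "total") -> np.ndarray:
    """The 1-D energy curve E(x) at a fixed grid z (exact match required)."""
    j = np.where(np.isclose(grid.z_values, z, atol=1e-9))[0]
    if j.size == 0:
        raise PiStackError(f"z = {z} is not a grid value")
    return grid.layers[component][:, int(j[0])].copy()


def _quadratic_refine(z: np.ndarray, e: np.ndarray, j: int) -> tuple[float, float]:
    """Vertex of the parabola through the bracketing triple around node j."""
    z0, z1, z2 = z[j - 1], z[j], z[j + 1]
    e0, e1, e2 = e[j - 1], e[j], e[j + 1]
    denom = (z0 - z1) * (z0 - z2) * (z1 - z2)
    a = (z2 * (e1 - e0) + z1 * (e0 - e2) + z0 * (e2 - e1)) / denom
    b = (z2**2 * (e0 - e1) + z1**2 * (e2 - e0) + z0**2 * (e1 - e2)) / denom
    if a <= 0:  # flat or concave triple: keep the node
        return float(z1), float(e1)
    zv = -b / (2 * a)
    if not (z0 <= zv <= z2):
        return float(z1), float(e1)
    c = e1 - a * z1**2 - b * z1
    return float(zv), float(a * zv**2 + b * zv + c)


def mep(grid: Grid2D, component: str = "total") -> MEPPath:
    """Minimum-energy path: relax z at every x.

    The on-grid argmin is refined by a quadratic through the bracketing
    triple; minima on the z boundary are kept on-grid and flagged (with a
    :class:`BoundaryMinimumWarning`) since they indicate the grid does not
    bracket the true minimum.
    """
    if grid.z_values.size < 3:
        raise PiStackError("mep requires at least 3 z values per x")
    layer = grid.layers[component]
    points: list[tuple[float, float, float]] = []
    flags: list[bool] = []
    warned = False
    for i, x in enumerate(grid.x_values):
        col = layer[i]
        safe = np.where(np.isnan(col), np.inf, col)
        j = int(np.argmin(safe))
        if j == 0 or j == len(col) - 1 or np.isnan(col[j - 1]) or np.isnan(col[j + 1]):
            if not warned:
                warnings.warn(
                    f"z-minimum on grid boundary at x = {x:.3f}; enlarge the z range",
                    BoundaryMinimumWarning,
                    stacklevel=2,
                )
                warned = True
            points.append((float(x), float(grid.z_values[j]), float(col[j])))
            flags.append(True)
        else:
            zs, es = _quadratic_refine(grid.z_values, col, j)
            points.append((float(x), zs, es))
            flags.append(False)
    return MEPPath(points=points, boundary_flags=flags)


def _classify_node(t: np.ndarray, i: int, j: int) -> str | None:
    e = t[i, j]
    block = t[i - 1 : i + 2, j - 1 : j + 2]
    if np.any(np.isnan(block)):
        return None
    others = np.delete(block.ravel(), 4)
    if np.all(e < others):
        return "minimum"
    if np.all(e > others):
        return "maximum"
    ex_lo, ex_hi = t[i - 1, j], t[i + 1, j]
    ez_lo, ez_hi = t[i, j - 1], t[i, j + 1]
    if e < ex_lo and e < ex_hi and e > ez_lo and e > ez_hi:
        return "saddle"
    if e > ex_lo and e > ex_hi and e < ez_lo and e < ez_hi:
        return "saddle"
    return None


def stationary_points(grid: Grid2D, component: str = "total") -> list[StationaryPoint]:
    """Classify interior grid nodes against their 8 neighbours.

    Strict comparisons everywhere; a connected plateau that is strictly
    below (above) its surrounding nodes is reported once, at the plateau
    node nearest its centroid, smaller x winning ties.
    """
    t = grid.layers[component]
    nx, nz = t.shape
    if nx < 3 or nz < 3:
        raise PiStackError("stationary_points requires a grid of at least 3 x 3")
    found: list[StationaryPoint] = []
    for i in range(1, nx - 1):
        for j in range(1, nz - 1):
            kind = _classify_node(t, i, j)
            if kind:
                found.append(
                    StationaryPoint(kind, float(grid.x_values[i]), float(grid.z_values[j]), float(t[i, j]))
                )
    found.extend(_plateau_extrema(grid, t))
    found.sort(key=lambda p: (p.x, p.z))
    return found


def _plateau_extrema(grid: Grid2D, t: np.ndarray) -> list[StationaryPoint]:
    """Flat connected regions strictly below/above their boundary."""
    nx, nz = t.shape
    visited = np.zeros_like(t, dtype=bool)
    out: list[StationaryPoint] = []
    for i0 in range(1, nx - 1):
        for j0 in range(1, nz - 1):
            if visited[i0, j0]:
                continue
            e = t[i0, j0]
            if np.isnan(e):
                continue
            # flood-fill the equal-valued component
            stack, comp = [(i0, j0)], []
            seen = set()
            while stack:
                i, j = stack.pop()
                if (i, j) in seen:
                    continue
                seen.add((i, j))
                comp.append((i, j))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < nx and 0 <= jj < nz and (ii, jj) not in seen:
                            if t[ii, jj] == e:
                                stack.append((ii, jj))
            for i, j in comp:
                if 0 < i < nx - 1 and 0 < j < nz - 1:
                    visited[i, j] = True
            if len(comp) < 2:
                continue
            if any(i in (0, nx - 1) or j in (0, nz - 1) for i, j in comp):
                continue
            boundary = []
            comp_set = set(comp)
            for i, j in comp:
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if (ii, jj) not in comp_set:
                            boundary.append(t[ii, jj])
            boundary = np.array(boundary)
            if np.any(np.isnan(boundary)):
                continue
            if np.all(boundary > e):
                kind = "minimum"
            elif np.all(boundary < e):
                kind = "maximum"
            else:
                continue
            ci = np.mean([i for i, _ in comp])
            cj = np.mean([j for _, j in comp])
            best = min(comp, key=lambda ij: ((ij[0] - ci) ** 2 + (ij[1] - cj) ** 2, ij[0]))
            out.append(
                StationaryPoint(kind, float(grid.x_values[best[0]]), float(grid.z_values[best[1]]), float(e))
            )
    return out


def hs_star(grid_x_model: Grid2D, grid_bz_model: Grid2D, grid_bz_ref: Grid2D) -> Grid2D:
    """Compose the starred relative-energy surface nodewise.

    total*(x, z) = ref_bz(x, z) + [model_X(x, z) - model_bz(x, z)].  All three
    grids must share the lattice exactly; there is no resampling.  Component
    layers present in all three grids are composed the same way.
    """
    for other in (grid_bz_model, grid_bz_ref):
        if not (
            np.array_equal(grid_x_model.x_values, other.x_values)
            and np.array_equal(grid_x_model.z_values, other.z_values)
        ):
            raise GridAlignmentError("hs_star grids do not share a lattice")
    shared = (
        set(grid_x_model.layers) & set(grid_bz_model.layers) & set(grid_bz_ref.layers)
    )
    layers = {
        name: grid_bz_ref.layers[name] + (grid_x_model.layers[name] - grid_bz_model.layers[name])
        for name in shared
    }
    if "total" not in layers:
        layers["total"] = grid_bz_ref.total + (grid_x_model.total - grid_bz_model.total)
    prov = {
        "composition": "starred",
        "model_system": grid_x_model.provenance,
        "model_baseline": grid_bz_model.provenance,
        "reference": grid_bz_ref.provenance,
    }
    return Grid2D(
        x_values=grid_x_model.x_values.copy(),
        z_values=grid_x_model.z_values.copy(),
        layers=layers,
        provenance=prov,
    )


# --------------------------------------------------------------------------
# CSV I/O (long format: x, z, component, energy_kcal_mol)


def grid_to_csv(grid: Grid2D, path: str | Path) -> None:
    rows = []
    for name, layer in sorted(grid.layers.items()):
        for i, x in enumerate(grid.x_values):
            for j, z in enumerate(grid.z_values):
                rows.append((x, z, name, layer[i, j]))
    pd.DataFrame(rows, columns=["x", "z", "component", "energy_kcal_mol"]).to_csv(
        path, index=False
    )


def grid_from_csv(path: str | Path) -> Grid2D:
    df = pd.read_csv(path)
    required = {"x", "z", "component", "energy_kcal_mol"}
    if not required <= set(df.columns):
        raise PiStackError(f"grid CSV must have columns {sorted(required)}")
    xs = np.sort(df["x"].unique())
    zs = np.sort(df["z"].unique())
    layers = {}
    for name, sub in df.groupby("component"):
        mat = (
            sub.pivot(index="x", columns="z", values="energy_kcal_mol")
            .reindex(index=xs, columns=zs)
            .to_numpy()
        )
        layers[str(name)] = mat
    return Grid2D(x_values=xs, z_values=zs, layers=layers, provenance={"source": str(path)})


def mep_to_csv(path_obj: MEPPath, path: str | Path) -> None:
    pd.DataFrame(path_obj.points, columns=["x", "z_star", "energy"]).to_csv(path, index=False)
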