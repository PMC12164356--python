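"""Shipped fixtures: charge sets, parameter sets, and a surrogate surface.

Everything the analysis pipeline needs to run end to end without external
data lives here:

* template monomers (via :mod:`pistack.geometry`) paired with shipped charge
  sets for benzene, pyridine and s-triazine (plus a geometry-free
  hexafluorobenzene set for validator exercises);
* default van der Waals and Gaussian-Pauli/dispersion parameter sets — these
  are calibration sets validated against the qualitative surface shapes the
  models are known for (double-well fixed-z slices, T-shape minimum near
  z = 5 Angstrom), not fitted to any external data;
* synthetic charge sets for monosubstituted benzenes, built by a documented
  heuristic perturbation of the benzene set (see
  :func:`synthetic_substituted_chargeset`) — these exist to exercise the
  substituent-statistics pipeline, not to reproduce any particular molecule;
* an analytic surrogate reference surface with brute-force-known topography
  standing in for external high-level reference grids in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .charge_model import ChargeSet, read_chargeset, validate_chargeset
from .cfh_potential import CFHParams, read_cfh_params
from .errors import CoverageError, PiStackError, UnknownTemplateError
from .geometry import Monomer, build_monomer
from .hs_potential import VdWParams, read_vdw_params
from .surface import Grid2D, StationaryPoint

__all__ = [
    "DATA_DIR",
    "FixtureBundle",
    "load_fixture",
    "default_vdw_params",
    "default_cfh_params",
    "load_chargeset",
    "synthetic_substituted_chargeset",
    "SurrogateSpec",
    "surrogate_energy",
    "surrogate_surface",
    "surrogate_ground_truth",
]

DATA_DIR = Path(__file__).parent / "data"

_FIXTURE_TEMPLATES = {
    "benzene": ("benzene", None),
    "pyridine": ("pyridine", None),
    "s-triazine": ("s-triazine", None),
}


@dataclass
class FixtureBundle:
    monomer: Monomer
    chargeset: ChargeSet
    vdw_params: VdWParams
    cfh_params: CFHParams


def default_vdw_params() -> VdWParams:
    return read_vdw_params(DATA_DIR / "vdw_default.txt")


def default_cfh_params() -> CFHParams:
    return read_cfh_params(DATA_DIR / "cfh_default.txt")


def load_chargeset(name: str) -> ChargeSet:
    path = DATA_DIR / f"{name}.charges"
    if not path.exists():
        raise UnknownTemplateError(f"no shipped charge set named {name!r}")
    return read_chargeset(path)


def load_fixture(name: str) -> FixtureBundle:
    """Monomer + charge set + default parameter sets, validated."""
    if name not in _FIXTURE_TEMPLATES:
        raise UnknownTemplateError(
            f"unknown fixture {name!r}; have {sorted(_FIXTURE_TEMPLATES)}"
        )
    template, sub = _FIXTURE_TEMPLATES[name]
    monomer = build_monomer(template, sub)
    charges = load_chargeset(name)
    report = validate_chargeset(charges)
    if not report.ok:
        raise PiStackError(f"shipped charge set failed validation:\n{report.summary()}")
    return FixtureBundle(
        monomer=monomer,
        chargeset=charges,
        vdw_params=default_vdw_params(),
        cfh_params=default_cfh_params(),
    )


# --------------------------------------------------------------------------
# synthetic substituted-benzene charge sets

# per-substituent pi shift w (e): total pi charge moved from the ring onto
# the substituent (negative = donated into the ring), and sigma charges for
# the substituent atoms in build order.  These are heuristic, synthetic
# values chosen to satisfy the sum rules and give chemically sensible signs
# (withdrawing groups deplete the ring pi cloud, donors enrich it); they are
# NOT transcribed from any quantum-chemical calculation.
_SYNTH = {
    # name: (w, ipso_sigma, [substituent sigmas...])
    "H": (0.00, 0.96, [0.04]),
    "F": (0.03, 1.30, [-0.30]),
    "CH3": (-0.02, 0.96, [-0.26, 0.10, 0.10, 0.10]),
    "NH2": (-0.10, 0.96, [-0.56, 0.30, 0.30]),
    "OH": (-0.06, 0.96, [-0.31, 0.35]),
    "OCH3": (-0.07, 0.96, [-0.41, 0.15, 0.10, 0.10, 0.10]),
    "CN": (0.08, 0.96, [0.29, -0.25]),
    "NO2": (0.10, 0.96, [0.44, -0.20, -0.20]),
    "CCH": (0.03, 0.96, [0.00, -0.06, 0.10]),
}

# fraction of the ring pi shift landing on each ring position
_RING_SHIFT = {0: 0.20, 1: 0.25, 2: 0.0, 3: 0.30, 4: 0.0, 5: 0.25}  # ipso/ortho/para


def synthetic_substituted_chargeset(substituent: str) -> ChargeSet:
    """Synthetic sigma/pi charge set for C6H5X (heuristic, not ab initio).

    Starts from the benzene set (ring C sigma +0.96, H +0.04, pi sites
    -0.50) and moves a substituent-specific amount ``w`` of pi charge
    between the ring (concentrated at ipso/ortho/para) and a pi-site pair on
    the substituent's attachment atom, keeping the total pi charge at -6 and
    the molecule neutral.  Intended for exercising the substituent-effect
    pipeline; labelled synthetic throughout.
    """
    if substituent not in _SYNTH:
        raise UnknownTemplateError(f"no synthetic charge set for {substituent!r}")
    if substituent == "H":
        return load_chargeset("benzene")
    w, ipso_sigma, sub_sigmas = _SYNTH[substituent]
    monomer = build_monomer("C6H5X", substituent)
    n_ring_h = 5
    q_sigma: dict[int, float] = {}
    q_pi: dict[int, float] = {}
    for i in range(6):  # ring carbons
        q_sigma[i] = ipso_sigma if i == 0 else 0.96
        q_pi[i] = -0.50 + _RING_SHIFT[i] * (w / 2.0)
    for i in range(6, 6 + n_ring_h):  # ring hydrogens
        q_sigma[i] = 0.04
    sub_start = 6 + n_ring_h
    n_sub = len(monomer.atoms) - sub_start
    if n_sub != len(sub_sigmas):
        raise PiStackError(
            f"substituent {substituent!r}: {n_sub} atoms but {len(sub_sigmas)} sigma values"
        )
    for offset, qs in enumerate(sub_sigmas):
        q_sigma[sub_start + offset] = qs
    # attachment atom carries the complementary pi pair
    q_pi[sub_start] = -w / 2.0
    # ipso sigma adjustments must keep the molecule neutral
    q_sigma[0] += -(sum(q_sigma.values()) + 2.0 * sum(q_pi.values()))
    return ChargeSet(
        name=f"C6H5{substituent}-synthetic",
        q_sigma=q_sigma,
        q_pi=q_pi,
        delta=load_chargeset("benzene").delta,
        n_pi_electrons=6,
    )


# --------------------------------------------------------------------------
# surrogate reference surface


@dataclass(frozen=True)
class SurrogateSpec:
    """Analytic double-well surface parameters (all positive)."""

    x0: float = 1.7  # well position, Angstrom
    D: float = 1.6  # well depth scale, kcal/mol; default gives a ~1 kcal/mol saddle
    w: float = 0.9  # well width, Angstrom
    z_w: float = 3.5  # vertical well center, Angstrom
    kz: float = 8.0  # vertical curvature, kcal/mol/Angstrom^2
    wall: float = 500.0  # short-range repulsion scale, kcal/mol

    def __post_init__(self):
        if min(self.D, self.w, self.kz, self.wall) <= 0:
            raise PiStackError("D, w, kz and wall must be positive")


def surrogate_energy(spec: SurrogateSpec, x, z):
    """total(x, z) = wall e^{-2z} - D (g(x-x0) + g(x+x0)) e^{-kz (z-z_w)^2 / 2D}."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    g = lambda u: np.exp(-(u**2) / (2.0 * spec.w**2))
    well = -spec.D * (g(x - spec.x0) + g(x + spec.x0))
    return spec.wall * np.exp(-2.0 * z) + well * np.exp(
        -spec.kz * (z - spec.z_w) ** 2 / (2.0 * spec.D)
    )


def surrogate_surface(
    spec: SurrogateSpec,
    x_values: Sequence[float],
    z_values: Sequence[float],
) -> Grid2D:
    """Evaluate the surrogate on a lattice (coverage-checked)."""
    xs = np.asarray(x_values, dtype=float)
    zs = np.asarray(z_values, dtype=float)
    reach = spec.x0 + 3.0 * spec.w
    if xs.min() > -reach or xs.max() < reach:
        raise CoverageError(
            f"x grid [{xs.min()}, {xs.max()}] does not cover the wells (+/-{reach:.2f})"
        )
    total = surrogate_energy(spec, xs[:, None], zs[None, :])
    return Grid2D(
        x_values=xs,
        z_values=zs,
        layers={"total": total},
        provenance={"potential": "surrogate", **spec.__dict__},
    )


def surrogate_ground_truth(
    spec: SurrogateSpec,
    x_range: tuple[float, float],
    z_range: tuple[float, float],
    n_dense: int = 1200,
) -> list[StationaryPoint]:
    """Brute-force topography of the surrogate on a dense lattice.

    Independent of the grid classifier: the two minima are located as the
    lowest dense node in each half-plane, and the saddle as the highest
    point of the z-relaxed path between them.
    """
    xs = np.linspace(*x_range, n_dense)
    zs = np.linspace(*z_range, n_dense)
    e = surrogate_energy(spec, xs[:, None], zs[None, :])
    out: list[StationaryPoint] = []
    for half in (xs < 0, xs > 0):
        sub = np.where(half[:, None], e, np.inf)
        i, j = np.unravel_index(int(np.argmin(sub)), sub.shape)
        out.append(StationaryPoint("minimum", float(xs[i]), float(zs[j]), float(e[i, j])))
    path_e = e.min(axis=1)
    path_j = e.argmin(axis=1)
    lo, hi = sorted((out[0].x, out[1].x))
    between = (xs > lo) & (xs < hi)
    idx = np.where(between)[0]
    i_saddle = idx[int(np.argmax(path_e[idx]))]
    out.append(
        StationaryPoint(
            "saddle",
            float(xs[i_saddle]),
            float(zs[path_j[i_saddle]]),
            float(path_e[i_saddle]),
        )
    )
    return out
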