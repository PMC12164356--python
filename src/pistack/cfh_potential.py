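"""Gaussian-Pauli plus damped-dispersion stacking potential.

Replacement-style vdW-only model:

    E_int = E_pauli + E_disp
    E_pauli = sum_{ij} A_ij(R_ij) e^{-alpha_ij R_ij^2}
    E_disp  = -sum_{ij} [ f6(beta_ij R_ij) C_ij / R_ij^6
                          + f8(beta_ij R_ij) D_ij / R_ij^8 ]

The Pauli term models steric repulsion as overlap of spherical Gaussian
densities on the atoms; the dispersion term uses Tang--Toennies damping
f_n(x) = 1 - e^{-x} sum_{m<=n} x^m/m!.  There is no electrostatic term by
construction.  The prefactor A_ij may be taken constant or proportional to
1/R_ij (``prefactor_form``).

The model is conventionally not defined for vertical separations below
3.5 Angstrom; :func:`clamp_slice_z` implements the convention of evaluating
fixed-z slices at z = 3.5 Angstrom for any requested value below that floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from .errors import PiStackError, SingularGeometryError
from .geometry import PlacedMonomer
from .hs_potential import EnergyBreakdown

__all__ = [
    "PairParams",
    "CFHParams",
    "tang_toennies",
    "cfh_interaction",
    "clamp_slice_z",
    "CFHPotential",
    "read_cfh_params",
    "Z_FLOOR_DEFAULT",
]

Z_FLOOR_DEFAULT = 3.5  # Angstrom


@dataclass(frozen=True)
class PairParams:
    """Parameters for one unordered atom-class pair."""

    a: float  # Pauli prefactor coefficient, kcal/mol (or kcal*A/mol for inverse_r)
    alpha: float  # Gaussian exponent, 1/Angstrom^2
    beta: float  # damping range, 1/Angstrom
    C6: float  # kcal*Angstrom^6/mol
    C8: float  # kcal*Angstrom^8/mol

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise PiStackError("alpha and beta must be positive")
        if self.C6 < 0 or self.C8 < 0:
            raise PiStackError("dispersion coefficients must be non-negative")


@dataclass
class CFHParams:
    """Per-pair-class parameter table plus global conventions."""

    pairs: dict[tuple[str, str], PairParams]
    prefactor_form: Literal["constant", "inverse_r"] = "constant"
    z_floor: float = Z_FLOOR_DEFAULT

    def __post_init__(self):
        if self.z_floor <= 0:
            raise PiStackError("z_floor must be positive")
        # normalize keys to sorted order
        self.pairs = {tuple(sorted(k)): v for k, v in self.pairs.items()}

    def pair_for(self, class_a: str, class_b: str) -> PairParams:
        key = tuple(sorted((class_a, class_b)))
        try:
            return self.pairs[key]
        except KeyError:
            raise PiStackError(f"no pair parameters for classes {key}") from None


def tang_toennies(n: int, x) -> np.ndarray | float:
    """Tang--Toennies damping f_n(x) = 1 - e^{-x} sum_{m=0..n} x^m / m!.

    Monotone non-decreasing on x >= 0 with range [0, 1).  Computed via the
    regularized upper incomplete gamma function Q(n+1, x), which equals the
    truncated exponential sum e^{-x} sum_{m<=n} x^m/m! exactly — numerically
    safer than the naive alternating series at large x.
    """
    from scipy.special import gammaincc

    if n not in (6, 8):
        raise PiStackError(f"damping order must be 6 or 8, got {n}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise PiStackError("tang_toennies requires x >= 0")
    out = 1.0 - gammaincc(n + 1, x)
    return float(out) if out.ndim == 0 else out


def cfh_interaction(a: PlacedMonomer, b: PlacedMonomer, params: CFHParams) -> EnergyBreakdown:
    """Pauli + damped-dispersion breakdown for a placed pair; elec = 0."""
    na, nb = len(a.elements), len(b.elements)
    r = cdist(a.positions, b.positions)
    if np.any(r < 1e-10):
        raise SingularGeometryError("coincident inter-molecular atoms")

    amat = np.empty((na, nb))
    alpha = np.empty((na, nb))
    beta = np.empty((na, nb))
    c6 = np.empty((na, nb))
    c8 = np.empty((na, nb))
    for i, ca in enumerate(a.vdw_classes):
        for j, cb in enumerate(b.vdw_classes):
            p = params.pair_for(ca, cb)
            amat[i, j], alpha[i, j], beta[i, j] = p.a, p.alpha, p.beta
            c6[i, j], c8[i, j] = p.C6, p.C8

    pref = amat / r if params.prefactor_form == "inverse_r" else amat
    pauli = float(np.sum(pref * np.exp(-alpha * r**2)))
    f6 = tang_toennies(6, beta * r)
    f8 = tang_toennies(8, beta * r)
    disp = -float(np.sum(f6 * c6 / r**6 + f8 * c8 / r**8))
    return EnergyBreakdown(pauli=pauli, disp=disp)


def clamp_slice_z(z_requested: float, params: CFHParams) -> tuple[float, bool]:
    """Apply the z-floor convention for fixed-z slices.

    Returns ``(z_effective, clamped)``: requests below the floor evaluate at
    the floor and are flagged.
    """
    if z_requested <= 0:
        raise PiStackError(f"z must be positive, got {z_requested}")
    if z_requested < params.z_floor:
        return params.z_floor, True
    return z_requested, False


class CFHPotential:
    """Callable wrapper evaluating the model on placed dimers."""

    name = "cfh"
    components = ("pauli", "disp")

    def __init__(self, params: CFHParams):
        self.params = params

    def __call__(self, dimer) -> EnergyBreakdown:
        return cfh_interaction(dimer.a, dimer.b, self.params)

    def provenance(self) -> dict:
        return {
            "potential": "cfh",
            "prefactor_form": self.params.prefactor_form,
            "z_floor": self.params.z_floor,
            "pairs": {
                "-".join(k): [p.a, p.alpha, p.beta, p.C6, p.C8]
                for k, p in sorted(self.params.pairs.items())
            },
        }


# --------------------------------------------------------------------------
# parameter files: plain-text per-pair table
#   prefactor_form constant
#   z_floor 3.5
#   # class1 class2 a alpha beta C6 C8
#   pair C C  90000.0 0.9 1.6 500.0 6000.0


def read_cfh_params(path: str | Path) -> CFHParams:
    path = Path(path)
    pairs: dict[tuple[str, str], PairParams] = {}
    form: str = "constant"
    z_floor = Z_FLOOR_DEFAULT
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "prefactor_form":
            if parts[1] not in ("constant", "inverse_r"):
                raise PiStackError(f"unknown prefactor_form {parts[1]!r}")
            form = parts[1]
        elif parts[0] == "z_floor":
            z_floor = float(parts[1])
        elif parts[0] == "pair":
            try:
                key = (parts[1], parts[2])
                vals = [float(v) for v in parts[3:8]]
                pairs[key] = PairParams(*vals)
            except (ValueError, IndexError):
                raise PiStackError(f"bad pair record {raw!r} in {path}") from None
        else:
            raise PiStackError(f"unrecognized record {raw!r} in {path}")
    if not pairs:
        raise PiStackError(f"no pair parameters found in {path}")
    return CFHParams(pairs=pairs, prefactor_form=form, z_floor=z_floor)
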