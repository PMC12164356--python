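"""The classic sigma/pi point-charge stacking potential.

Total interaction energy of two rigid monomers A and B:

    E_int = E_elec + E_vdW
    E_elec = k_e * sum_{i in A} sum_{j in B} q_i q_j / R_ij
    E_vdW  = sum_{i in A} sum_{j in B} k_i k_j (C e^{-alpha R_ij} - A R_ij^{-6})

The electrostatic sum runs over all sigma and pi charge *sites* of the two
monomers; the van der Waals (Buckingham exp-6) sum runs over the *atoms*
only, scaled by dimensionless per-class factors k_i.  Both sums are strictly
inter-molecular.  The exp-6 form diverges to -infinity as R -> 0, so an
explicit guard radius rejects unphysically close contacts instead of
silently returning garbage.

This potential neglects charge penetration: at stacking distances its
electrostatic term is repulsive wherever the pi clouds overlap, which is the
model's historically important (and incorrect) picture of why stacked rings
slip sideways.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .charge_model import ChargedMonomer, ChargeSite
from .errors import GuardDistanceError, PiStackError, SingularGeometryError
from .geometry import PlacedMonomer

__all__ = [
    "COULOMB_CONSTANT",
    "VdWParams",
    "EnergyBreakdown",
    "coulomb_energy",
    "buckingham_energy",
    "hs_interaction",
    "HSPotential",
    "read_vdw_params",
]

# kcal*Angstrom/(mol*e^2)
COULOMB_CONSTANT = 332.0637


@dataclass
class VdWParams:
    """Global exp-6 parameters plus per-class scale factors k_i."""

    k: dict[str, float]
    C: float  # repulsion prefactor, kcal/mol
    alpha: float  # repulsion exponent, 1/Angstrom
    A: float  # dispersion coefficient, kcal*Angstrom^6/mol
    r_min_guard: float = 1.0  # Angstrom

    def __post_init__(self):
        if self.C <= 0 or self.alpha <= 0 or self.A <= 0:
            raise PiStackError("C, alpha and A must all be positive")
        if any(v <= 0 for v in self.k.values()):
            raise PiStackError("k scale factors must be positive")
        if self.r_min_guard < 0:
            raise PiStackError("r_min_guard must be non-negative")

    def k_for(self, vdw_class: str) -> float:
        try:
            return self.k[vdw_class]
        except KeyError:
            raise PiStackError(f"no vdW scale factor for class {vdw_class!r}") from None


@dataclass
class EnergyBreakdown:
    """Per-component interaction energy in kcal/mol."""

    elec: float = 0.0
    vdw: float = 0.0
    pauli: float = 0.0
    disp: float = 0.0

    @property
    def total(self) -> float:
        return self.elec + self.vdw + self.pauli + self.disp

    def as_dict(self) -> dict[str, float]:
        return {
            "elec": self.elec,
            "vdw": self.vdw,
            "pauli": self.pauli,
            "disp": self.disp,
            "total": self.total,
        }


def coulomb_energy(
    sites_a: Sequence[ChargeSite],
    sites_b: Sequence[ChargeSite],
    coulomb_constant: float = COULOMB_CONSTANT,
) -> float:
    """Inter-molecular Coulomb energy over all site pairs, kcal/mol."""
    qa = np.array([s.value for s in sites_a])
    qb = np.array([s.value for s in sites_b])
    pa = np.array([s.position for s in sites_a])
    pb = np.array([s.position for s in sites_b])
    r = cdist(pa, pb)
    if np.any(r < 1e-10):
        raise SingularGeometryError("coincident inter-molecular charge sites")
    return float(coulomb_constant * np.sum(np.outer(qa, qb) / r))


def buckingham_energy(
    atoms_a: PlacedMonomer,
    atoms_b: PlacedMonomer,
    params: VdWParams,
) -> float:
    """Inter-molecular exp-6 van der Waals energy, kcal/mol."""
    ka = np.array([params.k_for(c) for c in atoms_a.vdw_classes])
    kb = np.array([params.k_for(c) for c in atoms_b.vdw_classes])
    r = cdist(atoms_a.positions, atoms_b.positions)
    if np.any(r <= params.r_min_guard):
        rmin = float(r.min())
        raise GuardDistanceError(
            f"inter-atomic distance {rmin:.3f} A below guard radius "
            f"{params.r_min_guard:.3f} A; exp-6 is divergent there"
        )
    pair = params.C * np.exp(-params.alpha * r) - params.A / r**6
    return float(np.sum(np.outer(ka, kb) * pair))


def hs_interaction(
    a: ChargedMonomer,
    b: ChargedMonomer,
    params: VdWParams,
    coulomb_constant: float = COULOMB_CONSTANT,
) -> EnergyBreakdown:
    """Full breakdown: elec + vdw (pauli and disp are identically zero here)."""
    elec = coulomb_energy(a.sites, b.sites, coulomb_constant)
    vdw = buckingham_energy(a.monomer, b.monomer, params)
    return EnergyBreakdown(elec=elec, vdw=vdw)


class HSPotential:
    """Callable wrapper evaluating the potential on placed dimers.

    Binds a pair of charge sets and a vdW parameter set; calling it on a
    :class:`~pistack.geometry.PlacedDimer` attaches the charge sites to the
    current placement and returns the energy breakdown.
    """

    name = "hs"
    components = ("elec", "vdw")

    def __init__(self, chargeset_a, chargeset_b, params: VdWParams,
                 coulomb_constant: float = COULOMB_CONSTANT):
        self.chargeset_a = chargeset_a
        self.chargeset_b = chargeset_b
        self.params = params
        self.coulomb_constant = coulomb_constant

    def __call__(self, dimer) -> EnergyBreakdown:
        from .charge_model import place_sites

        ca = place_sites(dimer.a, self.chargeset_a)
        cb = place_sites(dimer.b, self.chargeset_b)
        return hs_interaction(ca, cb, self.params, self.coulomb_constant)

    def provenance(self) -> dict:
        return {
            "potential": "hs",
            "coulomb_constant": self.coulomb_constant,
            "C": self.params.C,
            "alpha": self.params.alpha,
            "A": self.params.A,
            "k": dict(self.params.k),
            "delta_a": self.chargeset_a.delta,
            "delta_b": self.chargeset_b.delta,
            "chargeset_a": self.chargeset_a.name,
            "chargeset_b": self.chargeset_b.name,
        }


# --------------------------------------------------------------------------
# parameter files: plain-text key-value
#   C 61416.0
#   alpha 3.6
#   A 482.7
#   r_min_guard 1.0
#   k C 1.0
#   k H 0.35


def read_vdw_params(path: str | Path) -> VdWParams:
    path = Path(path)
    scalars: dict[str, float] = {}
    k: dict[str, float] = {}
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "k":
            k[parts[1]] = float(parts[2])
        else:
            scalars[parts[0]] = float(parts[1])
    try:
        return VdWParams(
            k=k,
            C=scalars["C"],
            alpha=scalars["alpha"],
            A=scalars["A"],
            r_min_guard=scalars.get("r_min_guard", 1.0),
        )
    except KeyError as exc:
        raise PiStackError(f"vdW parameter file {path} missing {exc}") from None
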