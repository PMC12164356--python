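"""Monomer templates and rigid dimer assembly.

Planar aromatic monomers are built from idealized templates (or read from XYZ
files) in a standard body frame: ring-atom centroid at the origin, ring plane
= xy, ring normal = +z, and the C1--C4 displacement axis = +x with the unique
atom (heteroatom or substituted carbon) on the +x side.  Dimers are assembled
rigidly from two monomers plus displacement coordinates (x, z):

* ``parallel`` -- cofacial rings, monomer B's centroid at (x, 0, z) relative
  to A's; x = 0 is the sandwich (eclipsed) configuration, x != 0 the
  parallel-displaced one.
* ``tshaped`` -- B rotated edge-on so one of its C-H bonds points at A's
  face; its centroid sits at (x, 0, z).

With this convention a positive x displacement moves the heteroatom or
substituent of the displaced ring *away* from the partner ring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidGeometryError, UnknownTemplateError, XYZParseError

__all__ = [
    "Atom3D",
    "Monomer",
    "DimerConfiguration",
    "PlacedMonomer",
    "PlacedDimer",
    "build_monomer",
    "place_dimer",
    "read_xyz",
    "write_xyz",
    "SUBSTITUENTS",
    "RING_TEMPLATES",
]

Mode = Literal["parallel", "tshaped"]
Orientation = Literal["aligned", "antialigned", "substituent_opposite", "default"]


@dataclass(frozen=True)
class Atom3D:
    """One atom: chemical symbol, Cartesian position (Angstrom), vdW class.

    ``vdw_class`` keys into the van der Waals parameter tables; it defaults
    to the element symbol.
    """

    element: str
    position: np.ndarray
    vdw_class: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise InvalidGeometryError(f"bad atom position {self.position!r}")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise InvalidGeometryError("empty element symbol")
        if not self.vdw_class:
            object.__setattr__(self, "vdw_class", self.element)


@dataclass
class Monomer:
    """A rigid planar aromatic monomer in its standard body frame."""

    name: str
    atoms: list[Atom3D]
    ring_atoms: list[int]
    c1_c4_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.c1_c4_axis = np.asarray(self.c1_c4_axis, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = len(self.atoms)
        if any(i < 0 or i >= n for i in self.ring_atoms):
            raise InvalidGeometryError("ring_atoms outside atom index range")
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise InvalidGeometryError("monomer normal must be a unit vector")
        if abs(float(self.normal @ self.c1_c4_axis)) > 1e-6:
            raise InvalidGeometryError("c1_c4_axis must be perpendicular to normal")

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def ring_centroid(self) -> np.ndarray:
        return self.positions[self.ring_atoms].mean(axis=0)


@dataclass(frozen=True)
class DimerConfiguration:
    """Two monomers plus displacement coordinates and orientation."""

    monomer_a: Monomer
    monomer_b: Monomer
    mode: Mode = "parallel"
    x: float = 0.0
    z: float = 3.5
    orientation: Orientation = "default"

    def __post_init__(self):
        if self.z <= 0:
            raise InvalidGeometryError(f"vertical separation z must be > 0, got {self.z}")
        if self.mode not in ("parallel", "tshaped"):
            raise InvalidGeometryError(f"unknown mode {self.mode!r}")
        if self.orientation not in ("aligned", "antialigned", "substituent_opposite", "default"):
            raise InvalidGeometryError(f"unknown orientation {self.orientation!r}")


@dataclass
class PlacedMonomer:
    """A monomer's atoms after rigid placement, with its placed ring normal."""

    name: str
    elements: list[str]
    vdw_classes: list[str]
    positions: np.ndarray  # (n, 3)
    ring_atoms: list[int]
    normal: np.ndarray


@dataclass
class PlacedDimer:
    """Positioned atom lists for both monomers; what the potentials consume."""

    a: PlacedMonomer
    b: PlacedMonomer
    config: DimerConfiguration


# --------------------------------------------------------------------------
# templates

# idealized bond lengths, Angstrom; validated by symmetry, not fitted
R_CC_RING = 1.39
R_CN_RING = 1.34
R_CH = 1.08

# ring element sequence starting at the unique (C1 / heteroatom) position
RING_TEMPLATES: dict[str, list[str]] = {
    "benzene": ["C"] * 6,
    "pyridine": ["N", "C", "C", "C", "C", "C"],
    "s-triazine": ["N", "C", "N", "C", "N", "C"],
}


def _ring_bond(e1: str, e2: str) -> float:
    return R_CN_RING if "N" in (e1, e2) else R_CC_RING


def _solve_ring(bonds: Sequence[float]) -> np.ndarray:
    """Place a closed planar 6-ring with the given bond lengths on a circle.

    Atoms sit on a common circumscribed circle; the circle radius is the root
    of sum_i 2*asin(b_i / 2R) = 2*pi, which preserves every bond length
    exactly while keeping the ring closed and planar.
    """
    bonds = np.asarray(bonds, dtype=float)

    def gap(radius: float) -> float:
        return float(np.sum(2.0 * np.arcsin(bonds / (2.0 * radius))) - 2.0 * math.pi)

    r_lo = float(bonds.max()) / 2.0 + 1e-9
    radius = brentq(gap, r_lo, 10.0 * float(bonds.max()))
    theta = np.concatenate([[0.0], np.cumsum(2.0 * np.arcsin(bonds / (2.0 * radius)))])[:6]
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.zeros(6)])


def _methyl_hydrogens(c_pos: np.ndarray, axis: np.ndarray, r_ch: float = 1.09) -> list[np.ndarray]:
    """Three tetrahedral hydrogens on a methyl carbon about the bond axis."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    tilt = math.radians(180.0 - 109.47)  # angle of C-H from the bond axis
    out = []
    for az in (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0):
        d = math.cos(tilt) * axis + math.sin(tilt) * (math.cos(az) * u + math.sin(az) * v)
        out.append(c_pos + r_ch * d)
    return out


def _substituent_atoms(name: str, ring_c: np.ndarray, direction: np.ndarray) -> list[Atom3D]:
    """Build substituent atoms attached at ``ring_c`` along ``direction``.

    ``direction`` is the in-plane exocyclic bond direction (unit vector);
    the ring plane is xy, so out-of-plane substituent atoms use +/-z.
    """
    x = direction / np.linalg.norm(direction)
    # in-plane perpendicular
    y = np.cross(np.array([0.0, 0.0, 1.0]), x)

    def at(elem: str, pos: np.ndarray) -> Atom3D:
        return Atom3D(elem, pos)

    if name == "H":
        return [at("H", ring_c + R_CH * x)]
    if name == "F":
        return [at("F", ring_c + 1.35 * x)]
    if name == "CN":
        c = ring_c + 1.43 * x
        return [at("C", c), at("N", c + 1.16 * x)]
    if name == "CCH":
        c1 = ring_c + 1.43 * x
        c2 = c1 + 1.20 * x
        return [at("C", c1), at("C", c2), at("H", c2 + 1.06 * x)]
    if name == "NO2":
        n = ring_c + 1.47 * x
        half = math.radians(124.0 / 2.0)
        d1 = math.cos(half) * x + math.sin(half) * y
        d2 = math.cos(half) * x - math.sin(half) * y
        return [at("N", n), at("O", n + 1.22 * d1), at("O", n + 1.22 * d2)]
    if name == "NH2":
        n = ring_c + 1.40 * x
        d1 = math.cos(math.radians(60)) * x + math.sin(math.radians(60)) * y
        d2 = math.cos(math.radians(60)) * x - math.sin(math.radians(60)) * y
        return [at("N", n), at("H", n + 1.01 * d1), at("H", n + 1.01 * d2)]
    if name == "OH":
        o = ring_c + 1.36 * x
        d = math.cos(math.radians(71)) * x + math.sin(math.radians(71)) * y
        return [at("O", o), at("H", o + 0.96 * d)]
    if name == "CH3":
        c = ring_c + 1.51 * x
        return [at("C", c)] + [at("H", p) for p in _methyl_hydrogens(c, x)]
    if name == "OCH3":
        o = ring_c + 1.36 * x
        d = math.cos(math.radians(63)) * x + math.sin(math.radians(63)) * y
        c = o + 1.42 * d
        return [at("O", o), at("C", c)] + [at("H", p) for p in _methyl_hydrogens(c, c - o)]
    raise UnknownTemplateError(f"unknown substituent {name!r}")


SUBSTITUENTS = ("H", "F", "CH3", "NH2", "OH", "OCH3", "CN", "NO2", "CCH")


def build_monomer(template: str, substituent: str | None = None) -> Monomer:
    """Build a template monomer in the standard body frame.

    Parameters
    ----------
    template : str
        One of ``benzene``, ``pyridine``, ``s-triazine`` or ``C6H5X``.
    substituent : str, optional
        Required for ``C6H5X``: the X group name (one of ``SUBSTITUENTS``),
        attached at C1 on the +x side of the ring.
    """
    if template == "C6H5X":
        if substituent is None:
            raise UnknownTemplateError("template C6H5X requires a substituent name")
        if substituent not in SUBSTITUENTS:
            raise UnknownTemplateError(f"unknown substituent {substituent!r}")
        ring_elems = RING_TEMPLATES["benzene"]
        name = f"C6H5{substituent}" if substituent != "H" else "benzene"
    elif template in RING_TEMPLATES:
        if substituent not in (None, "H"):
            raise UnknownTemplateError(f"template {template!r} takes no substituent")
        ring_elems = RING_TEMPLATES[template]
        name = template
        substituent = None
    else:
        raise UnknownTemplateError(f"unknown template {template!r}")

    bonds = [_ring_bond(ring_elems[i], ring_elems[(i + 1) % 6]) for i in range(6)]
    ring = _solve_ring(bonds)

    # atom order: ring atoms, then ring hydrogens, then substituent atoms
    atoms: list[Atom3D] = [Atom3D(e, p) for e, p in zip(ring_elems, ring)]
    ring_idx = list(range(6))
    tail: list[Atom3D] = []
    for i, elem in enumerate(ring_elems):
        if elem != "C":
            continue  # ring N carries no H
        direction = ring[i] / np.linalg.norm(ring[i])
        if template == "C6H5X" and i == 0:
            tail.extend(_substituent_atoms(substituent, ring[i], direction))
        else:
            atoms.append(Atom3D("H", ring[i] + R_CH * direction))
    atoms.extend(tail)

    centroid = ring.mean(axis=0)
    atoms = [replace(a, position=a.position - centroid) for a in atoms]
    return Monomer(name=name, atoms=atoms, ring_atoms=ring_idx)


# --------------------------------------------------------------------------
# dimer placement


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# maps local +x (the donated C1-H direction) onto -z: edge-on ring
_ROT_TSHAPE = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])


def _as_placed(m: Monomer, rot: np.ndarray, shift: np.ndarray) -> PlacedMonomer:
    pos = m.positions @ rot.T + shift
    return PlacedMonomer(
        name=m.name,
        elements=m.elements,
        vdw_classes=[a.vdw_class for a in m.atoms],
        positions=pos,
        ring_atoms=list(m.ring_atoms),
        normal=rot @ m.normal,
    )


def place_dimer(config: DimerConfiguration) -> PlacedDimer:
    """Rigidly place both monomers of a dimer configuration.

    Monomer A stays in its body frame (ring centroid at the origin).  For
    ``antialigned``/``substituent_opposite`` orientations monomer B is first
    rotated 180 degrees about its ring normal so its unique atom points along
    -x; then it is tipped edge-on for T-shaped mode and translated so its
    ring centroid sits at (x, 0, z).
    """
    if config.z <= 0:
        raise InvalidGeometryError(f"z must be positive, got {config.z}")
    rot = np.eye(3)
    if config.orientation in ("antialigned", "substituent_opposite"):
        rot = _rot_z(math.pi) @ rot
    if config.mode == "tshaped":
        rot = _ROT_TSHAPE @ rot
    shift = np.array([config.x, 0.0, config.z])
    a = _as_placed(config.monomer_a, np.eye(3), np.zeros(3))
    b = _as_placed(config.monomer_b, rot, shift)
    return PlacedDimer(a=a, b=b, config=config)


def dimer_family(
    monomer_a: Monomer,
    monomer_b: Monomer,
    mode: Mode = "parallel",
    orientation: Orientation = "default",
) -> Callable[[float, float], PlacedDimer]:
    """Return a parametric (x, z) -> PlacedDimer constructor for scanning."""

    def make(x: float, z: float) -> PlacedDimer:
        return place_dimer(
            DimerConfiguration(monomer_a, monomer_b, mode=mode, x=x, z=z, orientation=orientation)
        )

    return make


# --------------------------------------------------------------------------
# XYZ I/O


def read_xyz(path: str | Path, ring_atoms: Sequence[int] | None = None) -> Monomer:
    """Read one monomer from a standard XYZ file.

    The comment line becomes the monomer name.  If ``ring_atoms`` is not
    given, ring membership is inferred as the heavy (non-H) atoms having at
    least two heavy neighbours within 1.1--1.7 Angstrom; the ring normal and
    C1--C4 axis are taken from the best-fit ring plane and the first ring
    atom.  Pass explicit indices for anything unusual.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError("empty XYZ file", line=1)
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"bad atom count {lines[0]!r}", line=1) from None
    if len(lines) < count + 2:
        raise XYZParseError(f"expected {count} atom records, file has {len(lines) - 2}", line=len(lines))
    name = lines[1].strip() or path.stem
    atoms: list[Atom3D] = []
    for k in range(count):
        ln = 3 + k
        parts = lines[2 + k].split()
        if len(parts) < 4:
            raise XYZParseError(f"short atom record {lines[2 + k]!r}", line=ln)
        try:
            pos = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
        except ValueError:
            raise XYZParseError(f"non-numeric coordinate in {lines[2 + k]!r}", line=ln) from None
        atoms.append(Atom3D(parts[0], pos))

    pos = np.array([a.position for a in atoms])
    if ring_atoms is None:
        heavy = [i for i, a in enumerate(atoms) if a.element != "H"]
        ring_atoms = []
        for i in heavy:
            d = np.linalg.norm(pos[heavy] - pos[i], axis=1)
            if np.sum((d > 1.1) & (d < 1.7)) >= 2:
                ring_atoms.append(i)
    ring_atoms = list(ring_atoms)
    if len(ring_atoms) < 3:
        raise XYZParseError("could not identify a ring; pass ring_atoms explicitly")

    centroid = pos[ring_atoms].mean(axis=0)
    pos = pos - centroid
    atoms = [replace(a, position=p) for a, p in zip(atoms, pos)]
    # best-fit plane normal via SVD of the centered ring coordinates
    _, _, vt = np.linalg.svd(pos[ring_atoms])
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    axis = pos[ring_atoms[0]] - (pos[ring_atoms[0]] @ normal) * normal
    nrm = np.linalg.norm(axis)
    axis = axis / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
    return Monomer(name=name, atoms=atoms, ring_atoms=ring_atoms,
                   c1_c4_axis=axis, normal=normal / np.linalg.norm(normal))


def write_xyz(obj: Monomer | PlacedDimer, path: str | Path) -> None:
    """Write a monomer or a placed dimer to a standard XYZ file."""
    path = Path(path)
    if isinstance(obj, Monomer):
        elements = obj.elements
        positions = obj.positions
        comment = obj.name
    else:
        elements = obj.a.elements + obj.b.elements
        positions = np.vstack([obj.a.positions, obj.b.positions])
        cfg = obj.config
        comment = (f"{obj.a.name}...{obj.b.name} {cfg.mode} x={cfg.x:.3f} z={cfg.z:.3f}")
    with path.open("w") as fh:
        fh.write(f"{len(elements)}\n{comment}\n")
        for e, p in zip(elements, positions):
            fh.write(f"{e} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n")
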