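"""Sigma/pi point-charge representation of planar aromatic monomers.

Each monomer's in-plane framework is modelled by positive point charges
``q_sigma`` at the nuclear positions, and its pi-electron cloud by pairs of
negative charges ``q_pi`` placed at +/-delta along the ring normal above and
below every atom that belongs to the pi system.  The out-of-plane offset
delta = 0.47 Angstrom is the standard calibration that makes the benzene
charge model reproduce the experimental molecular quadrupole moment.

Two sum rules constrain every physically meaningful charge set:

* pi rule:  2 * sum(q_pi) = -(number of pi electrons)
* neutrality:  sum(q_sigma) + 2 * sum(q_pi) = net molecular charge

The validator reports violations; it never repairs a set silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .errors import IncompleteChargeSetError, PiStackError
from .geometry import Monomer, PlacedMonomer

__all__ = [
    "ChargeSet",
    "ChargeSite",
    "ChargedMonomer",
    "ValidationReport",
    "place_sites",
    "validate_chargeset",
    "read_chargeset",
    "write_chargeset",
    "DELTA_DEFAULT",
]

DELTA_DEFAULT = 0.47  # Angstrom; pi-site offset along the ring normal


@dataclass
class ChargeSet:
    """Per-atom sigma charges plus per-pi-site charges for one molecule."""

    name: str
    q_sigma: dict[int, float]
    q_pi: dict[int, float]  # atom index -> charge of EACH of its two pi sites
    delta: float = DELTA_DEFAULT
    n_pi_electrons: int = 6

    def pi_sum(self) -> float:
        """Total pi charge, counting both sites of every pair."""
        return 2.0 * sum(self.q_pi.values())

    def net_charge(self) -> float:
        return sum(self.q_sigma.values()) + self.pi_sum()


@dataclass(frozen=True)
class ChargeSite:
    value: float  # e
    position: np.ndarray  # Angstrom
    kind: Literal["sigma", "pi"]


@dataclass
class ChargedMonomer:
    """A placed monomer together with its sigma/pi charge sites."""

    monomer: PlacedMonomer
    sites: list[ChargeSite]
    chargeset: ChargeSet


@dataclass
class ValidationReport:
    name: str
    pi_sum: float
    pi_residual: float  # pi_sum - (-n_pi_electrons)
    net_charge: float
    net_residual: float  # net_charge - expected
    delta_positive: bool
    tol: float = 1e-6

    @property
    def pi_rule_ok(self) -> bool:
        return abs(self.pi_residual) <= self.tol

    @property
    def net_rule_ok(self) -> bool:
        return abs(self.net_residual) <= self.tol

    @property
    def ok(self) -> bool:
        return self.pi_rule_ok and self.net_rule_ok and self.delta_positive

    def summary(self) -> str:
        lines = [f"charge set {self.name!r}:"]
        lines.append(
            f"  pi-sum rule:  2*sum(q_pi) = {self.pi_sum:+.6f}  "
            f"(residual {self.pi_residual:+.6f})  "
            f"{'pass' if self.pi_rule_ok else 'FAIL'}"
        )
        lines.append(
            f"  neutrality:   net charge = {self.net_charge:+.6f}  "
            f"(residual {self.net_residual:+.6f})  "
            f"{'pass' if self.net_rule_ok else 'FAIL'}"
        )
        lines.append(f"  delta > 0:    {'pass' if self.delta_positive else 'FAIL'}")
        return "\n".join(lines)


def validate_chargeset(charges: ChargeSet, expected_net_charge: float = 0.0) -> ValidationReport:
    """Check the pi-sum and neutrality rules; return a report, never raise."""
    pi_sum = charges.pi_sum()
    return ValidationReport(
        name=charges.name,
        pi_sum=pi_sum,
        pi_residual=pi_sum + charges.n_pi_electrons,
        net_charge=charges.net_charge(),
        net_residual=charges.net_charge() - expected_net_charge,
        delta_positive=charges.delta > 0,
    )


def place_sites(monomer: Monomer | PlacedMonomer, charges: ChargeSet) -> ChargedMonomer:
    """Attach sigma sites at the nuclei and pi-site pairs at +/-delta.

    Works on a monomer in its body frame or on a placed monomer: pi sites
    always go along the monomer's *current* ring normal, so placing sites is
    equivariant under rigid motion of the monomer.
    """
    if isinstance(monomer, Monomer):
        placed = PlacedMonomer(
            name=monomer.name,
            elements=monomer.elements,
            vdw_classes=[a.vdw_class for a in monomer.atoms],
            positions=monomer.positions,
            ring_atoms=list(monomer.ring_atoms),
            normal=monomer.normal,
        )
    else:
        placed = monomer

    n = len(placed.elements)
    sites: list[ChargeSite] = []
    for i in range(n):
        if i not in charges.q_sigma:
            raise IncompleteChargeSetError(
                f"charge set {charges.name!r} lacks q_sigma for atom {i} ({placed.elements[i]})"
            )
        sites.append(ChargeSite(charges.q_sigma[i], placed.positions[i].copy(), "sigma"))
    off = charges.delta * placed.normal
    for i in sorted(charges.q_pi):
        if i < 0 or i >= n:
            raise IncompleteChargeSetError(
                f"charge set {charges.name!r} has q_pi for nonexistent atom {i}"
            )
        q = charges.q_pi[i]
        sites.append(ChargeSite(q, placed.positions[i] + off, "pi"))
        sites.append(ChargeSite(q, placed.positions[i] - off, "pi"))
    return ChargedMonomer(monomer=placed, sites=sites, chargeset=charges)


# --------------------------------------------------------------------------
# plain-text charge-set files
#
# Format (one molecule per file):
#   name <label>
#   delta <Angstrom>
#   n_pi_electrons <int>
#   # index element q_sigma q_pi   (q_pi '-' for atoms without pi sites)
#   0 C  0.850 -0.500
#   ...


def read_chargeset(path: str | Path) -> ChargeSet:
    """Read a charge set from its plain-text tabular file."""
    path = Path(path)
    name = path.stem
    delta = DELTA_DEFAULT
    n_pi = 6
    q_sigma: dict[int, float] = {}
    q_pi: dict[int, float] = {}
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "name":
            name = parts[1]
        elif parts[0] == "delta":
            delta = float(parts[1])
        elif parts[0] == "n_pi_electrons":
            n_pi = int(parts[1])
        else:
            try:
                idx = int(parts[0])
                qs = float(parts[2])
            except (ValueError, IndexError):
                raise PiStackError(f"bad charge-set record {raw!r} in {path}") from None
            q_sigma[idx] = qs
            if len(parts) > 3 and parts[3] != "-":
                q_pi[idx] = float(parts[3])
    if not q_sigma:
        raise PiStackError(f"no charge records found in {path}")
    return ChargeSet(name=name, q_sigma=q_sigma, q_pi=q_pi, delta=delta, n_pi_electrons=n_pi)


def write_chargeset(charges: ChargeSet, monomer: Monomer, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"name {charges.name}\n")
        fh.write(f"delta {charges.delta}\n")
        fh.write(f"n_pi_electrons {charges.n_pi_electrons}\n")
        fh.write("# index element q_sigma q_pi\n")
        for i, atom in enumerate(monomer.atoms):
            qp = f"{charges.q_pi[i]:.6f}" if i in charges.q_pi else "-"
            fh.write(f"{i} {atom.element} {charges.q_sigma.get(i, 0.0):.6f} {qp}\n")
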