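"""Coulomb + exp-6 energy evaluation against brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from pistack.charge_model import ChargeSite, place_sites
from pistack.errors import GuardDistanceError, SingularGeometryError
from pistack.geometry import DimerConfiguration, PlacedMonomer, place_dimer
from pistack.hs_potential import (
    COULOMB_CONSTANT,
    VdWParams,
    buckingham_energy,
    coulomb_energy,
    hs_interaction,
)


def _site(q, x, y, z, kind="sigma"):
    return ChargeSite(q, np.array([x, y, z], dtype=float), kind)


def _toy_monomer(rng, n=10, shift=(0.0, 0.0, 0.0)):
    pos = rng.uniform(-1.5, 1.5, size=(n, 3)) + np.asarray(shift)
    classes = rng.choice(["C", "H"], size=n).tolist()
    return PlacedMonomer(
        name="toy", elements=classes, vdw_classes=classes, positions=pos,
        ring_atoms=[], normal=np.array([0.0, 0.0, 1.0]),
    )


def test_unit_charges_give_coulomb_constant():
    e = coulomb_energy([_site(1.0, 0, 0, 0)], [_site(-1.0, 1.0, 0, 0)])
    assert e == pytest.approx(-332.0637, abs=1e-10)


def test_coulomb_exchange_symmetric(benzene):
    cm = place_sites(benzene.monomer, benzene.chargeset)
    d = place_dimer(DimerConfiguration(benzene.monomer, benzene.monomer, x=1.0, z=3.6))
    other = place_sites(d.b, benzene.chargeset)
    assert coulomb_energy(cm.sites, other.sites) == pytest.approx(
        coulomb_energy(other.sites, cm.sites), abs=1e-12
    )


def test_coulomb_singular_geometry():
    with pytest.raises(SingularGeometryError):
        coulomb_energy([_site(1.0, 0, 0, 0)], [_site(1.0, 0, 0, 0)])


def test_cofacial_decay_is_quadrupole_quadrupole(benzene, parallel_family):
    """log-log slope of |E_elec(z)| is -5 for two neutral, dipole-free rings."""
    zs = np.geomspace(20.0, 100.0, 12)
    es = []
    for z in zs:
        d = parallel_family(0.0, float(z))
        es.append(
            abs(
                coulomb_energy(
                    place_sites(d.a, benzene.chargeset).sites,
                    place_sites(d.b, benzene.chargeset).sites,
                )
            )
        )
    slope = np.polyfit(np.log(zs), np.log(es), 1)[0]
    assert slope == pytest.approx(-5.0, abs=0.05)


def test_coulomb_matches_double_loop_oracle():
    rng = np.random.default_rng(7)
    for _ in range(5):
        qa = rng.uniform(-1, 1, 10)
        qb = rng.uniform(-1, 1, 10)
        pa = rng.uniform(-2, 2, (10, 3))
        pb = rng.uniform(-2, 2, (10, 3)) + np.array([0, 0, 6.0])
        sites_a = [_site(q, *p) for q, p in zip(qa, pa)]
        sites_b = [_site(q, *p) for q, p in zip(qb, pb)]
        oracle = sum(
            COULOMB_CONSTANT * qi * qj / np.linalg.norm(pi - pj)
            for qi, pi in zip(qa, pa)
            for qj, pj in zip(qb, pb)
        )
        assert coulomb_energy(sites_a, sites_b) == pytest.approx(oracle, abs=1e-10)


@pytest.fixture(scope="module")
def toy_vdw():
    return VdWParams(k={"C": 1.0, "H": 0.5}, C=16743.0, alpha=3.2, A=534.93)


def test_buckingham_matches_double_loop_oracle(toy_vdw):
    rng = np.random.default_rng(11)
    a = _toy_monomer(rng)
    b = _toy_monomer(rng, shift=(0, 0, 6.0))
    oracle = 0.0
    for ci, pi in zip(a.vdw_classes, a.positions):
        for cj, pj in zip(b.vdw_classes, b.positions):
            r = np.linalg.norm(pi - pj)
            oracle += (
                toy_vdw.k[ci]
                * toy_vdw.k[cj]
                * (toy_vdw.C * math.exp(-toy_vdw.alpha * r) - toy_vdw.A / r**6)
            )
    assert buckingham_energy(a, b, toy_vdw) == pytest.approx(oracle, abs=1e-10)


def test_buckingham_pair_minimum_location(toy_vdw):
    """Grid minimum agrees with the root of alpha*C e^{-alpha R} = 6A/R^7."""
    p = toy_vdw
    rstar = brentq(
        lambda r: p.alpha * p.C * math.exp(-p.alpha * r) - 6 * p.A / r**7, 2.0, 8.0
    )

    def pair_energy(r):
        a = _mono([("C", (0, 0, 0))])
        b = _mono([("C", (r, 0, 0))])
        return buckingham_energy(a, b, p)

    rs = np.linspace(2.0, 8.0, 6001)
    es = [pair_energy(r) for r in rs]
    assert rs[int(np.argmin(es))] == pytest.approx(rstar, abs=2e-3)
    assert rstar == pytest.approx(3.8, abs=1e-3)  # the calibrated well position


def _mono(spec):
    classes = [c for c, _ in spec]
    pos = np.array([p for _, p in spec], dtype=float)
    return PlacedMonomer("m", classes, classes, pos, [], np.array([0.0, 0.0, 1.0]))


def test_buckingham_linear_in_k(toy_vdw):
    a = _mono([("C", (0, 0, 0))])
    b = _mono([("C", (4.0, 0, 0))])
    e1 = buckingham_energy(a, b, toy_vdw)
    doubled = VdWParams(k={"C": 2.0, "H": 0.5}, C=toy_vdw.C, alpha=toy_vdw.alpha, A=toy_vdw.A)
    # doubling k on both atoms of the pair quadruples the term
    assert buckingham_energy(a, b, doubled) == pytest.approx(4 * e1, rel=1e-12)


def test_buckingham_long_range_negative(toy_vdw):
    a = _mono([("C", (0, 0, 0))])
    b = _mono([("C", (12.0, 0, 0))])
    e = buckingham_energy(a, b, toy_vdw)
    assert -1e-3 < e < 0  # dispersion-dominated tail


def test_buckingham_guard_radius(toy_vdw):
    a = _mono([("C", (0, 0, 0))])
    b = _mono([("C", (0.5, 0, 0))])
    with pytest.raises(GuardDistanceError):
        buckingham_energy(a, b, toy_vdw)


def test_breakdown_additivity_and_zero_fields(benzene, hs_benzene, parallel_family):
    bd = hs_benzene(parallel_family(1.0, 3.8))
    assert bd.pauli == 0.0 and bd.disp == 0.0
    assert bd.total == bd.elec + bd.vdw


def test_far_separation_vanishes(benzene, hs_benzene, parallel_family):
    bd = hs_benzene(parallel_family(0.0, 500.0))
    assert abs(bd.total) < 1e-4


def test_rigid_motion_invariance(benzene, hs_benzene):
    """Translating/rotating the assembled dimer as a whole changes nothing."""
    d = place_dimer(
        DimerConfiguration(benzene.monomer, benzene.monomer, x=1.5, z=3.7)
    )
    ref = hs_interaction(
        place_sites(d.a, benzene.chargeset),
        place_sites(d.b, benzene.chargeset),
        benzene.vdw_params,
    ).total
    theta = 0.83
    rot = np.array(
        [
            [math.cos(theta), 0, math.sin(theta)],
            [0, 1, 0],
            [-math.sin(theta), 0, math.cos(theta)],
        ]
    )
    shift = np.array([3.0, -2.0, 7.0])
    moved = []
    for pm in (d.a, d.b):
        moved.append(
            PlacedMonomer(
                pm.name, pm.elements, pm.vdw_classes,
                pm.positions @ rot.T + shift, pm.ring_atoms, rot @ pm.normal,
            )
        )
    e2 = hs_interaction(
        place_sites(moved[0], benzene.chargeset),
        place_sites(moved[1], benzene.chargeset),
        benzene.vdw_params,
    ).total
    assert e2 == pytest.approx(ref, abs=1e-9)


def test_homodimer_swap_invariance(benzene, hs_benzene, parallel_family):
    d = parallel_family(1.3, 3.9)
    e_ab = hs_interaction(
        place_sites(d.a, benzene.chargeset),
        place_sites(d.b, benzene.chargeset),
        benzene.vdw_params,
    ).total
    e_ba = hs_interaction(
        place_sites(d.b, benzene.chargeset),
        place_sites(d.a, benzene.chargeset),
        benzene.vdw_params,
    ).total
    assert e_ab == pytest.approx(e_ba, abs=1e-12)
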