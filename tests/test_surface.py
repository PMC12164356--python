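"""Surface scanning, MEP extraction, stationary points and composition."""

import numpy as np
import pytest

from pistack.errors import GridAlignmentError, PiStackError
from pistack.fixtures import (
    SurrogateSpec,
    surrogate_energy,
    surrogate_ground_truth,
    surrogate_surface,
)
from pistack.hs_potential import EnergyBreakdown
from pistack.surface import (
    BoundaryMinimumWarning,
    Grid2D,
    grid_from_csv,
    grid_to_csv,
    hs_star,
    mep,
    scan,
    slice_at_z,
    stationary_points,
)


class AnalyticPotential:
    """Adapter turning f(x, z) into a scan-compatible potential."""

    components = ("elec",)

    def __init__(self, fn):
        self.fn = fn

    def __call__(self, xz):
        return EnergyBreakdown(elec=float(self.fn(*xz)))


def _passthrough(x, z):
    return (x, z)


def _grid_from_fn(fn, xs, zs):
    return scan(_passthrough, AnalyticPotential(fn), xs, zs)


def test_scan_equals_direct_calls(hs_benzene, parallel_family):
    xs, zs = [0.0, 1.0], [3.5, 4.0]
    grid = scan(parallel_family, hs_benzene, xs, zs)
    for i, x in enumerate(xs):
        for j, z in enumerate(zs):
            bd = hs_benzene(parallel_family(x, z))
            assert grid.total[i, j] == bd.total
            assert grid.layers["elec"][i, j] == bd.elec
            assert grid.layers["vdw"][i, j] == bd.vdw


def test_total_layer_is_component_sum(hs_parallel_grid, cfh_parallel_grid):
    g = hs_parallel_grid
    assert np.abs(g.total - (g.layers["elec"] + g.layers["vdw"])).max() < 1e-9
    g = cfh_parallel_grid
    assert np.abs(g.total - (g.layers["pauli"] + g.layers["disp"])).max() < 1e-9


def test_cfh_scan_records_clamp_flags(cfh_benzene, parallel_family):
    grid = scan(parallel_family, cfh_benzene, [0.0], [3.2, 3.5, 4.0])
    assert grid.clamped is not None
    assert grid.clamped[0].tolist() == [True, False, False]


def test_mep_recovers_analytic_bowl():
    xs = np.linspace(-2, 2, 11)
    zs = np.linspace(3.0, 5.0, 21)
    grid = _grid_from_fn(lambda x, z: (z - 4.0) ** 2, xs, zs)
    path = mep(grid)
    assert np.abs(path.z_star - 4.0).max() < 1e-9
    assert np.abs(path.energy).max() < 1e-12


def test_mep_quadratic_refinement_beats_grid():
    # minimum at z = 3.97, off-node on a 0.1 grid
    xs = np.array([0.0])
    zs = np.arange(3.0, 5.01, 0.1)
    grid = _grid_from_fn(lambda x, z: (z - 3.97) ** 2, xs, zs)
    path = mep(grid)
    assert path.z_star[0] == pytest.approx(3.97, abs=1e-9)


def test_mep_boundary_warning():
    xs = np.array([0.0, 1.0])
    zs = np.linspace(3.0, 5.0, 11)
    grid = _grid_from_fn(lambda x, z: z, xs, zs)  # monotone in z
    with pytest.warns(BoundaryMinimumWarning):
        path = mep(grid)
    assert all(path.boundary_flags)


def test_mep_lower_bounds_fixed_z_slices(hs_parallel_grid):
    path = mep(hs_parallel_grid)
    for z in (3.5, 4.0, 5.0):
        sl = slice_at_z(hs_parallel_grid, z)
        assert np.all(path.energy <= sl + 1e-12)


def test_stationary_single_bowl():
    xs = np.linspace(-2, 2, 21)
    zs = np.linspace(3, 5, 21)
    grid = _grid_from_fn(lambda x, z: x**2 + (z - 4.0) ** 2, xs, zs)
    pts = stationary_points(grid)
    kinds = [p.kind for p in pts]
    assert kinds.count("minimum") == 1 and kinds.count("saddle") == 0
    p = next(p for p in pts if p.kind == "minimum")
    assert (p.x, p.z) == (0.0, 4.0)


def test_stationary_points_on_surrogate_match_brute_force():
    spec = SurrogateSpec()
    xs = np.round(np.arange(-4.5, 4.5001, 0.1), 10)
    zs = np.round(np.arange(3.0, 5.0001, 0.05), 10)
    grid = surrogate_surface(spec, xs, zs)
    pts = stationary_points(grid)
    minima = [p for p in pts if p.kind == "minimum"]
    saddles = [p for p in pts if p.kind == "saddle"]
    assert len(minima) == 2 and len(saddles) == 1
    truth = surrogate_ground_truth(spec, (-4.5, 4.5), (3.0, 5.0))
    for want in truth:
        pool = minima if want.kind == "minimum" else saddles
        got = min(pool, key=lambda p: (p.x - want.x) ** 2 + (p.z - want.z) ** 2)
        assert abs(got.x - want.x) <= 0.1 + 1e-9
        assert abs(got.z - want.z) <= 0.05 + 1e-9
    # saddle sits about 1 kcal/mol above the minima (spec default shape)
    gap = saddles[0].energy - minima[0].energy
    assert gap == pytest.approx(1.0, abs=0.2)


def test_hs_star_identity_and_linearity():
    xs = np.linspace(-2, 2, 9)
    zs = np.linspace(3, 5, 9)
    ref = _grid_from_fn(lambda x, z: np.sin(x) + z, xs, zs)
    model_bz = _grid_from_fn(lambda x, z: x * z, xs, zs)
    # X = benzene: the bracket vanishes identically, bit-exact
    out = hs_star(model_bz, model_bz, ref)
    assert np.array_equal(out.total, ref.total)
    # all-zero reference: output = model_X - model_bz
    zero = _grid_from_fn(lambda x, z: 0.0, xs, zs)
    model_x = _grid_from_fn(lambda x, z: x * z + 2.0, xs, zs)
    out = hs_star(model_x, model_bz, zero)
    assert np.allclose(out.total, 2.0)
    # constant -1 offset between the two model grids shifts ref by -1
    model_x = _grid_from_fn(lambda x, z: x * z - 1.0, xs, zs)
    out = hs_star(model_x, model_bz, ref)
    assert np.allclose(out.total, ref.total - 1.0)


def test_hs_star_rejects_lattice_mismatch():
    xs = np.linspace(-2, 2, 9)
    zs = np.linspace(3, 5, 9)
    a = _grid_from_fn(lambda x, z: x, xs, zs)
    b = _grid_from_fn(lambda x, z: x, xs + 0.01, zs)
    with pytest.raises(GridAlignmentError):
        hs_star(a, b, a)


def test_grid_csv_round_trip(tmp_path, hs_benzene, parallel_family):
    grid = scan(parallel_family, hs_benzene, [0.0, 0.5, 1.0], [3.5, 4.0, 4.5])
    path = tmp_path / "grid.csv"
    grid_to_csv(grid, path)
    back = grid_from_csv(path)
    assert np.allclose(back.x_values, grid.x_values)
    for name, layer in grid.layers.items():
        assert np.abs(back.layers[name] - layer).max() < 1e-12


def test_undefined_nodes_recorded_not_fatal(hs_benzene, parallel_family):
    # z = 0.5 puts atoms inside the exp-6 guard radius
    grid = scan(parallel_family, hs_benzene, [0.0], [0.5, 3.5, 4.0])
    assert grid.undefined[0, 0]
    assert np.isnan(grid.total[0, 0])
    assert np.isfinite(grid.total[0, 1:]).all()
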