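"""Reaction–diffusion chemokine field: conservation, analytic profiles,
steady states and the model-1/model-2 parameterizations."""
import numpy as np
import pytest

from follisim.field import (
    ChemokineGrid,
    ConvergenceError,
    FieldParams,
    StabilityError,
    make_grid_for_network,
    model_parameterization,
    rasterize_sources,
    run_to_steady_state,
    steady_state_direct,
    step,
)
from follisim.synthesis import SynthesisParams, synthesize_follicle_network
from conftest import make_network


def _grid(shape=(9, 9, 9), spacing=3.0, **params):
    return ChemokineGrid(spacing=spacing, shape=shape,
                         params=FieldParams(**params))


# -- rasterization -----------------------------------------------------------

def test_single_node_single_voxel():
    net = make_network([[3, 3, 3]], [], rates=[2.5])
    g = _grid(spacing=3.0)
    out = rasterize_sources(net, g, rates="nodes")
    assert out.source.sum() == pytest.approx(2.5)
    assert (out.source > 0).sum() == 1


def test_two_nodes_same_voxel_rates_sum():
    net = make_network([[3, 3, 3], [3.4, 3.1, 2.8]], [],
                       rates=[1.0, 2.0])
    out = rasterize_sources(net, _grid(spacing=3.0), rates="nodes")
    assert out.source.max() == pytest.approx(3.0)


def test_full_network_rate_conservation():
    net = synthesize_follicle_network(SynthesisParams(seed=1))
    grid = make_grid_for_network(net, spacing=8.0,
                                 params=FieldParams(secretion_fdc=1.3,
                                                    secretion_rc=0.4))
    out = rasterize_sources(net, grid)
    subtypes = net.subtypes()
    expected = 1.3 * (subtypes == "FDC").sum() + 0.4 * (subtypes != "FDC").sum()
    assert out.source.sum() == pytest.approx(expected, rel=1e-12)


def test_node_outside_grid_rejected():
    net = make_network([[100, 0, 0]], [])
    with pytest.raises(ValueError, match="outside"):
        rasterize_sources(net, _grid())


# -- stepping ----------------------------------------------------------------

def test_pure_decay_matches_exponential():
    g = _grid(D=0.0, lam=1e-3)
    g.soluble[:] = 2.0
    m0 = g.total_mass()
    dt = 1.0
    for _ in range(1000):
        g = step(g, dt)
    assert g.total_mass() == pytest.approx(m0 * np.exp(-1e-3 * 1000), rel=0.01)


def test_mass_conserved_without_decay():
    g = _grid(D=0.8, lam=0.0)
    rng = np.random.default_rng(0)
    g.soluble[:] = rng.random(g.shape)
    m0 = g.total_mass()
    dt = 0.9 * g.max_stable_dt()
    for _ in range(200):
        g = step(g, dt)
    assert g.total_mass() == pytest.approx(m0, rel=1e-9)


def test_stability_guard_suggests_dt():
    g = _grid(D=1.0, lam=0.0)
    with pytest.raises(StabilityError) as err:
        step(g, dt=1e6)
    assert err.value.suggested_dt == pytest.approx(g.max_stable_dt())


def test_nonnegativity_under_random_stable_steps():
    rng = np.random.default_rng(1)
    g = _grid(D=0.5, lam=5e-3, k_on_ecm=2e-3, k_off_ecm=1e-3)
    g.soluble[:] = rng.random(g.shape)
    g.source[:] = rng.random(g.shape) * 0.01
    dt = 0.9 * g.max_stable_dt()
    for _ in range(500):
        g = step(g, dt * rng.random())
        assert (g.soluble >= 0).all() and (g.immobilized >= 0).all()


def test_screened_point_source_profile():
    """Steady field around a point source follows exp(-r/ell)/r."""
    D, ell = 1.0, 8.0
    lam = D / ell**2
    g = ChemokineGrid(spacing=2.0, shape=(41, 41, 41),
                      params=FieldParams(D=D, lam=lam))
    g.source[20, 20, 20] = 1.0
    ss = steady_state_direct(g)
    center = np.array([20, 20, 20]) * 2.0
    idx = np.indices(g.shape).reshape(3, -1).T * 2.0
    r = np.linalg.norm(idx - center, axis=1)
    c = ss.soluble.ravel()
    # shell-averaged radial profile over r in [3h, 10h]
    h = 2.0
    edges = np.arange(3 * h - h / 2, 10 * h + h / 2 + 1e-9, h)
    vals = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (r > lo) & (r <= hi)
        rm = r[sel].mean()
        vals.append(c[sel].mean() * rm / np.exp(-rm / ell))
    vals = np.asarray(vals)
    assert np.abs(vals / np.median(vals) - 1).max() < 0.05


def test_linearity_of_sources():
    a = _grid(D=0.5, lam=2e-3)
    b = _grid(D=0.5, lam=2e-3)
    a.source[2, 2, 2] = 1.0
    b.source[6, 6, 6] = 0.7
    both = _grid(D=0.5, lam=2e-3)
    both.source = a.source + b.source
    sa = steady_state_direct(a).soluble
    sb = steady_state_direct(b).soluble
    sab = steady_state_direct(both).soluble
    assert np.abs(sab - (sa + sb)).max() <= 1e-6 * sab.max()


# -- steady state ------------------------------------------------------------

def test_zero_source_steady_state_is_zero():
    g = _grid(D=0.5, lam=1e-3)
    ss, elapsed = run_to_steady_state(g, tol=1e-8, max_t=1e5)
    assert ss.soluble.max() == 0.0
    assert elapsed > 0


def test_steady_mass_balance_single_source():
    g = _grid(D=0.5, lam=0.01)
    g.source[4, 4, 4] = 1.0
    ss, _ = run_to_steady_state(g, tol=1e-8, max_t=1e5)
    expected = g.source.sum() * g.voxel_volume / 0.01
    assert ss.total_mass() == pytest.approx(expected, rel=0.01)


def test_direct_solver_agrees_with_time_stepping():
    g = _grid(D=0.5, lam=5e-3, k_on_ecm=2e-3, k_off_ecm=1e-3)
    g.source[4, 4, 4] = 1.0
    ss_time, _ = run_to_steady_state(g, tol=1e-9, max_t=1e6)
    ss_dir = steady_state_direct(g)
    assert np.allclose(ss_time.soluble, ss_dir.soluble, rtol=1e-3)
    assert np.allclose(ss_time.immobilized, ss_dir.immobilized, rtol=1e-3)


def test_immobilized_soluble_steady_ratio():
    p = dict(D=0.5, lam=5e-3, k_on_ecm=3e-3, k_off_ecm=1e-3)
    g = _grid(**p)
    g.source[4, 4, 4] = 1.0
    ss, _ = run_to_steady_state(g, tol=1e-9, max_t=1e6)
    expected = p["k_on_ecm"] / (p["k_off_ecm"] + p["lam"])
    inner = ss.soluble[2:-2, 2:-2, 2:-2]
    ratio = ss.immobilized[2:-2, 2:-2, 2:-2][inner > 0] / inner[inner > 0]
    assert ratio == pytest.approx(expected, rel=1e-3)


def test_no_sink_has_no_steady_state():
    g = _grid(D=0.5, lam=0.0)
    with pytest.raises(ValueError):
        run_to_steady_state(g)
    with pytest.raises(ValueError):
        steady_state_direct(g)


def test_non_convergence_reports_residual():
    g = _grid(D=0.5, lam=1e-5)
    g.source[4, 4, 4] = 1.0
    with pytest.raises(ConvergenceError):
        run_to_steady_state(g, tol=1e-12, max_t=10.0)


# -- model 1 / model 2 -------------------------------------------------------

@pytest.fixture(scope="module")
def follicle_and_fields():
    net = synthesize_follicle_network(SynthesisParams(seed=5))
    lo, hi = np.asarray(net.bounds[0]), np.asarray(net.bounds[1])
    mass = 0.15 * float(np.prod(hi - lo))
    out = {}
    for m in (1, 2):
        p = model_parameterization(m, mass, net=net, spacing=8.0)
        grid = rasterize_sources(net, make_grid_for_network(net, 8.0, p))
        out[m] = steady_state_direct(grid)
    return net, mass, out


def test_models_have_equal_total_mass(follicle_and_fields):
    _, mass, fields = follicle_and_fields
    assert fields[1].total_mass() == pytest.approx(mass, rel=0.01)
    assert fields[2].total_mass() == pytest.approx(mass, rel=0.01)


def test_model1_field_is_more_heterogeneous(follicle_and_fields):
    _, _, fields = follicle_and_fields
    assert fields[1].soluble.var() > 10 * fields[2].soluble.var()


def test_mass_scales_linearly_with_reference(follicle_and_fields):
    net, mass, _ = follicle_and_fields
    p = model_parameterization(1, 2 * mass, net=net, spacing=8.0)
    grid = rasterize_sources(net, make_grid_for_network(net, 8.0, p))
    ss = steady_state_direct(grid)
    assert ss.total_mass() == pytest.approx(2 * mass, rel=0.01)


def test_chemokine_localization_near_sparse_sources():
    """Sharp gradients keep >=80% of chemokine within 50 µm of sources;
    the soluble parameterization spreads it more broadly (<50%)."""
    net = make_network([[100, 100, 20], [220, 220, 20]], [],
                       rates=[1.0, 1.0])
    net.bounds = ((0.0, 0.0, 0.0), (320.0, 320.0, 40.0))
    fracs = {}
    for m in (1, 2):
        p = model_parameterization(m, 1000.0, net=net, spacing=8.0)
        grid = rasterize_sources(net, make_grid_for_network(net, 8.0, p))
        ss = steady_state_direct(grid)
        idx = np.indices(ss.shape).reshape(3, -1).T * 8.0
        d = np.minimum(
            np.linalg.norm(idx - np.array([100, 100, 20]), axis=1),
            np.linalg.norm(idx - np.array([220, 220, 20]), axis=1),
        )
        c = (ss.soluble + ss.immobilized).ravel()
        fracs[m] = c[d <= 50].sum() / c.sum()
    assert fracs[1] >= 0.80
    assert fracs[2] < 0.50


def test_invalid_model_id_and_mass():
    with pytest.raises(ValueError):
        model_parameterization(3, 1.0)
    with pytest.raises(ValueError):
        model_parameterization(1, -1.0)
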