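import math

import numpy as np
import pytest

from dualmlc.fluence import (
    FluenceMap,
    GridSpec,
    accumulate_dynamic_fluence,
    combined_aperture_map,
    combined_fluence,
    layer_transmission_map,
)
from dualmlc.mlc_model import (
    ControlPoint,
    Layer,
    LeafPair,
    MLCParameters,
    Plan,
)
from dualmlc.virtual_lab import band_aperture, sweep_plan

T = 0.0047


def open_square(machine, half=5.0, layer=Layer.PROXIMAL):
    from dualmlc.virtual_lab import rows_covering
    return [LeafPair(-half, half, i, layer)
            for i in rows_covering(-half, half, layer, machine)]


def test_open_field_interior_is_unity(machine):
    grid = GridSpec(-7, 7, -7, 7, 0.1)
    m = layer_transmission_map(open_square(machine), MLCParameters(),
                               machine, grid)
    interior = m.values[(np.abs(m.y) < 4)[:, None] & (np.abs(m.x) < 4)[None, :]]
    assert np.allclose(interior, 1.0)


def test_closed_pair_is_layer_transmission(machine):
    grid = GridSpec(-3, 3, -3, 3, 0.1)
    pairs = [LeafPair(0.0, 0.0, i, Layer.PROXIMAL) for i in range(10, 18)]
    m = layer_transmission_map(pairs, MLCParameters(tng_width=0.0),
                               machine, grid)
    assert np.allclose(m.values, T)


def test_tip_strip_value_is_sqrt_transmission(machine):
    """Half leaf height halves the attenuation exponent: the tip zone
    transmits sqrt(T) = 0.0686 for T = 0.47%."""
    grid = GridSpec(-3, 3, -1, 1, 0.02)
    p = MLCParameters(tip_width=0.4, tng_width=0.0)
    pairs = [LeafPair(-1.0, 1.0, i, Layer.PROXIMAL) for i in range(12, 16)]
    m = layer_transmission_map(pairs, p, machine, grid)
    prof = m.profile_x(0.0)
    in_tip = (m.x > -1.35) & (m.x < -1.05)
    assert np.allclose(prof[in_tip], math.sqrt(T), atol=1e-9)
    assert math.sqrt(T) == pytest.approx(0.0686, abs=2e-4)
    under_leaf = m.x < -1.5
    assert np.allclose(prof[under_leaf], T)


def test_combined_fluence_products(machine):
    grid = GridSpec(-2, 2, -2, 2, 0.1)
    ones = FluenceMap(grid.x, grid.y, np.ones((grid.y.size, grid.x.size)))
    closed = FluenceMap(grid.x, grid.y,
                        np.full((grid.y.size, grid.x.size), T))
    both_open = combined_fluence(ones, ones)
    assert np.allclose(both_open.values, 1.0)
    both_closed = combined_fluence(closed, closed)
    assert np.allclose(both_closed.values, 2.209e-5, rtol=1e-6)
    one_closed = combined_fluence(ones, closed)
    assert np.allclose(one_closed.values, T)


def test_combined_fluence_grid_mismatch_rejected(machine):
    a = FluenceMap(np.arange(3.0), np.arange(3.0), np.ones((3, 3)))
    b = FluenceMap(np.arange(4.0), np.arange(4.0), np.ones((4, 4)))
    with pytest.raises(ValueError, match="grid"):
        combined_fluence(a, b)


def test_static_plan_equals_aperture_map(machine):
    pairs = band_aperture(-2, 2, -2, 2, machine)
    plan = Plan((ControlPoint(pairs, 1.0),))
    grid = GridSpec(-4, 4, -4, 4, 0.1)
    acc = accumulate_dynamic_fluence(plan, MLCParameters(), machine, grid)
    direct = combined_aperture_map(pairs, MLCParameters(), machine, grid)
    assert np.allclose(acc.values, direct.values)


@pytest.mark.parametrize("offset", [0.0, 0.02])
def test_sweep_average_fluence_matches_time_integral(machine, offset):
    """A gap sweeping uniformly gives a central fluence of
    (gap + 2*offset)/sweep_length (plus stacked leakage elsewhere), the
    exact fine-time-step integral; the offset widens the effective gap by
    2*offset."""
    p = MLCParameters(offset=offset, tng_width=0.0)
    gap = 2.0
    plan, length = sweep_plan(gap, 0.0, machine)
    grid = GridSpec(-3, 3, -3, 3, 0.1)
    f = accumulate_dynamic_fluence(plan, p, machine, grid)
    central = f.values[np.argmin(np.abs(f.y)), np.argmin(np.abs(f.x))]
    open_frac = (gap + 2 * offset) / length
    expected = open_frac + (1 - open_frac) * T * T
    assert central == pytest.approx(expected, rel=2e-3)


def test_zero_mu_plan_rejected(machine):
    pairs = band_aperture(-2, 2, -2, 2, machine)
    plan = Plan((ControlPoint(pairs, 0.0), ControlPoint(pairs, 1.0)))
    object.__setattr__(plan.control_points[1], "mu_weight", 0.0)
    with pytest.raises(ValueError, match="zero total MU"):
        accumulate_dynamic_fluence(plan, MLCParameters(), machine,
                                   GridSpec(-3, 3, -3, 3, 0.1))


def test_monotonicity_under_aperture_enlargement(machine):
    """Opening any leaf pair wider never decreases fluence anywhere."""
    rng = np.random.default_rng(7)
    grid = GridSpec(-6, 6, -6, 6, 0.1)
    p = MLCParameters(offset=0.007)
    for _ in range(5):
        pairs, larger = [], []
        for i in range(10, 18):
            lo = rng.uniform(-4, 0)
            hi = rng.uniform(0.5, 4)
            d = rng.uniform(0, 1, 2)
            pairs.append(LeafPair(lo, hi, i, Layer.PROXIMAL))
            larger.append(LeafPair(lo - d[0], hi + d[1], i, Layer.PROXIMAL))
        small = layer_transmission_map(pairs, p, machine, grid)
        big = layer_transmission_map(larger, p, machine, grid)
        assert np.all(big.values >= small.values - 1e-12)


def test_mirror_symmetry(machine):
    """Left-right symmetric aperture with gain = curvature = 0 gives a
    map symmetric about x = 0."""
    grid = GridSpec(-5, 5, -5, 5, 0.1)
    p = MLCParameters(offset=0.01, gain=0.0, curvature=0.0)
    pairs = band_aperture(-2.5, 2.5, -2.5, 2.5, machine)
    m = combined_aperture_map(pairs, p, machine, grid)
    assert np.allclose(m.values, m.values[:, ::-1], atol=1e-12)


def test_complementary_bars_sum_uniform_without_tng(machine):
    p = MLCParameters(tng_width=0.0)
    grid = GridSpec(-3, 3, -4, 4, 0.05)
    rows = list(range(9, 19))
    a = [LeafPair(-2.0, 2.0, i, Layer.PROXIMAL) if i % 2 == 0
         else LeafPair(-9.0, -9.0, i, Layer.PROXIMAL) for i in rows]
    b = [LeafPair(-2.0, 2.0, i, Layer.PROXIMAL) if i % 2 == 1
         else LeafPair(-9.0, -9.0, i, Layer.PROXIMAL) for i in rows]
    ma = layer_transmission_map(a, p, machine, grid)
    mb = layer_transmission_map(b, p, machine, grid)
    s = ma.values + mb.values
    interior = s[(np.abs(grid.y) < 3)[:, None] & (np.abs(grid.x) < 1.5)[None, :]]
    assert np.allclose(interior, 1.0 + T, atol=1e-9)


def test_complementary_bars_show_tng_dips(machine):
    """With a T&G width the summed complementary bars dip below the
    plateau only in strips at the leaf borders."""
    p = MLCParameters(tng_width=0.05)
    grid = GridSpec(-3, 3, -4, 4, 0.05)
    rows = list(range(9, 19))
    a = [LeafPair(-2.0, 2.0, i, Layer.PROXIMAL) if i % 2 == 0
         else LeafPair(-9.0, -9.0, i, Layer.PROXIMAL) for i in rows]
    b = [LeafPair(-2.0, 2.0, i, Layer.PROXIMAL) if i % 2 == 1
         else LeafPair(-9.0, -9.0, i, Layer.PROXIMAL) for i in rows]
    s = (layer_transmission_map(a, p, machine, grid).values
         + layer_transmission_map(b, p, machine, grid).values)
    prof = s[:, np.argmin(np.abs(grid.x))]
    y = grid.y
    at_border = np.min(np.abs(y[:, None]
                              - np.arange(-3.0, 3.1, 1.0)[None, :]),
                       axis=1) < 0.1  # strip plus the partially covered pixel
    central = np.abs(y) < 3
    assert prof[central & at_border].min() < 1.0 + T - 0.3
    assert np.allclose(prof[central & ~at_border], 1.0 + T, atol=1e-6)


def test_coarse_grid_warns_for_narrow_strips(machine):
    grid = GridSpec(-3, 3, -3, 3, 0.1)
    p = MLCParameters(tip_width=0.02, tng_width=0.0)
    pairs = [LeafPair(-1, 1, i, Layer.PROXIMAL) for i in range(12, 16)]
    with pytest.warns(UserWarning, match="too coarse"):
        layer_transmission_map(pairs, p, machine, grid)
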