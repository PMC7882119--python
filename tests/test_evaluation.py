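import math

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from dualmlc.evaluation import (
    ConfidenceLimit,
    GammaCriteria,
    confidence_limit,
    confidence_limit_from_stats,
    gamma,
    gamma_points,
    local_error_stats,
    parse_criteria,
)
from dualmlc.fluence import FluenceMap


def brute_force_gamma(ev, ref, crit):
    """Independent oracle: exhaustive search over the full finely
    resampled reference grid (no radius shortcuts)."""
    dta = crit.dta_mm / 10.0
    step = dta / 10.0
    itp = RegularGridInterpolator((ref.y, ref.x), ref.values,
                                  method="linear", bounds_error=False,
                                  fill_value=None)
    fx = np.arange(ref.x[0], ref.x[-1] + step / 2, step)
    fy = np.arange(ref.y[0], ref.y[-1] + step / 2, step)
    gx, gy = np.meshgrid(fx, fy)
    fv = itp(np.column_stack([gy.ravel(), gx.ravel()]))
    gx, gy = gx.ravel(), gy.ravel()
    rmax = ref.values.max()
    exx, eyy = np.meshgrid(ev.x, ev.y)
    pts = np.column_stack([exx.ravel(), eyy.ravel()])
    ref_at = itp(np.column_stack([pts[:, 1], pts[:, 0]]))
    mask = ref_at >= crit.threshold / 100 * rmax
    out = []
    for (x0, y0), de in zip(pts[mask], ev.values.ravel()[mask]):
        d2 = (gx - x0) ** 2 + (gy - y0) ** 2
        dd = de - fv
        if crit.normalization == "global":
            dt = (dd / (crit.dose_tolerance / 100 * rmax)) ** 2
        else:
            tol = crit.dose_tolerance / 100 * fv
            with np.errstate(divide="ignore", invalid="ignore"):
                dt = np.where(tol > 0, (dd / tol) ** 2, np.inf)
        out.append(math.sqrt(np.min(dt + d2 / dta**2)))
    return np.array(out)


def _random_pair(rng, n=20, spacing=0.2, noise=0.03):
    x = np.arange(n) * spacing
    y = np.arange(n) * spacing
    cx, cy = rng.uniform(1, 3, 2)
    base = 50 + 50 * np.exp(-((x[None, :] - cx) ** 2
                              + (y[:, None] - cy) ** 2) / 3)
    ref = FluenceMap(x, y, base)
    ev = FluenceMap(x, y, base * (1 + noise * rng.standard_normal((n, n))))
    return ev, ref


def test_identical_distributions_pass_perfectly():
    rng = np.random.default_rng(0)
    ev, ref = _random_pair(rng, noise=0.0)
    res = gamma(ev, ref, GammaCriteria(3, 2, "global"))
    assert np.all(res.gamma <= 1e-9)
    assert res.passing_rate == 100.0
    assert np.all(res.local_errors == 0.0)


def test_boundary_point_gamma_is_one():
    """A single point 3% high at the global maximum scores gamma exactly
    1 under 3%G criteria."""
    x = np.arange(11) * 0.2
    vals = np.full((11, 11), 50.0)
    vals[5, 5] = 100.0
    ref = FluenceMap(x, x, vals)
    ev_vals = vals.copy()
    ev_vals[5, 5] = 103.0
    ev = FluenceMap(x, x, ev_vals)
    res = gamma(ev, ref, GammaCriteria(3, 2, "global", threshold=10))
    worst = res.gamma.max()
    assert worst == pytest.approx(1.0, abs=1e-9)
    assert res.passing_rate == 100.0


def test_gamma_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(3):
        ev, ref = _random_pair(rng)
        for crit in (GammaCriteria(3, 2, "global"),
                     GammaCriteria(2, 2, "local")):
            res = gamma(ev, ref, crit)
            oracle = brute_force_gamma(ev, ref, crit)
            assert np.max(np.abs(res.gamma - oracle)) < 1e-6


def test_gamma_monotone_in_criteria():
    """Loosening either tolerance never decreases the passing rate."""
    rng = np.random.default_rng(3)
    ev, ref = _random_pair(rng, noise=0.05)
    rates = {}
    for tol, dta in ((2, 1), (3, 1), (2, 2), (3, 2), (4, 3)):
        rates[(tol, dta)] = gamma(
            ev, ref, GammaCriteria(tol, dta, "global")).passing_rate
    assert rates[(2, 1)] <= rates[(3, 1)] <= rates[(3, 2)] <= rates[(4, 3)]
    assert rates[(2, 1)] <= rates[(2, 2)] <= rates[(3, 2)]


def test_local_passing_never_exceeds_global():
    rng = np.random.default_rng(4)
    for _ in range(3):
        ev, ref = _random_pair(rng, noise=0.04)
        g = gamma(ev, ref, GammaCriteria(3, 2, "global")).passing_rate
        l = gamma(ev, ref, GammaCriteria(3, 2, "local")).passing_rate
        assert l <= g + 1e-9


def test_gamma_threshold_excludes_low_dose():
    x = np.arange(11) * 0.2
    vals = np.full((11, 11), 1.0)
    vals[5, 5] = 100.0
    ref = FluenceMap(x, x, vals)
    res = gamma(ref, ref, GammaCriteria(3, 2, "global", threshold=10))
    assert res.n == 1  # only the hot pixel clears 10% of max
    with pytest.raises(ValueError, match="threshold"):
        gamma_points(np.array([[0.0, 0.0]]), np.array([1.0]), ref,
                     GammaCriteria(3, 2, "global", threshold=50))


def test_gamma_points_against_map():
    """Detector doses sampled from the reference itself score gamma 0 at
    grid nodes and well below 1 everywhere."""
    rng = np.random.default_rng(5)
    ev, ref = _random_pair(rng, noise=0.02)
    ii = rng.integers(2, 18, (40, 2))
    pts = np.column_stack([ref.x[ii[:, 0]], ref.y[ii[:, 1]]])
    doses = ref.values[ii[:, 1], ii[:, 0]]
    res = gamma_points(pts, doses, ref, GammaCriteria(3, 2, "global"))
    assert np.all(res.gamma <= 1e-9)
    off = pts + rng.uniform(-0.05, 0.05, pts.shape)
    itp = RegularGridInterpolator((ref.y, ref.x), ref.values)
    doses_off = itp(np.column_stack([off[:, 1], off[:, 0]]))
    res_off = gamma_points(off, doses_off, ref, GammaCriteria(3, 2, "global"))
    assert res_off.passing_rate == 100.0


def test_local_error_stats_trivial_cases():
    ref = np.linspace(10, 100, 50)
    s = local_error_stats(ref, ref)
    assert s.mean == s.median == s.sd == 0.0
    s2 = local_error_stats(1.02 * ref, ref)
    assert s2.mean == pytest.approx(2.0, abs=1e-9)
    assert s2.sd == pytest.approx(0.0, abs=1e-9)


def test_local_error_stats_threshold():
    ref = np.array([1.0, 5.0, 50.0, 100.0])
    ev = ref * 1.1
    s = local_error_stats(ev, ref, threshold=10.0)
    assert s.n == 2  # 50 and 100 clear 10% of max


def test_criteria_validation_and_parse():
    with pytest.raises(ValueError):
        GammaCriteria(dose_tolerance=-1)
    with pytest.raises(ValueError):
        GammaCriteria(threshold=0)
    c = parse_criteria("2L2")
    assert (c.dose_tolerance, c.dta_mm, c.normalization) == (2.0, 2.0, "local")
    assert parse_criteria("3G2").label == "3%G/2mm"


@pytest.mark.parametrize("mean,sd,direction,raw,style", [
    (0.0, 1.1, "two_sided_error", (-2.156, 2.156), (-2.1, 2.1)),
    (99.3, 0.5, "lower_passing", 98.32, 98.3),
])
def test_confidence_limit_examples(mean, sd, direction, raw, style):
    cl = confidence_limit_from_stats(mean, sd, direction)
    if direction == "two_sided_error":
        assert cl.raw[0] == pytest.approx(raw[0], abs=1e-9)
        assert cl.raw[1] == pytest.approx(raw[1], abs=1e-9)
    else:
        assert cl.raw == pytest.approx(raw, abs=1e-9)
    assert cl.paper_style == style


def test_confidence_limit_constant_list():
    cl = confidence_limit([5.0, 5.0, 5.0])
    assert cl.raw == (5.0, 5.0)


def test_confidence_limit_lower_passing_capped_at_100():
    cl = confidence_limit_from_stats(100.0, 0.0, "lower_passing")
    assert cl.raw == 100.0


def test_confidence_limit_needs_two_values():
    with pytest.raises(ValueError):
        confidence_limit([1.0])
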