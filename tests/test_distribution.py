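"""Closed-form distributional functions: consistency, stability, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from uasrd import cdf, hazard, mode, pdf, quantile, reliability, sample
from uasrd.distribution import UnitSample

ZETA_GRID = [0.03, 0.25, 0.95, 2.25, 5.0, 14.0, 31.0]


@pytest.mark.parametrize("zeta", [0.25, 0.95, 2.25, 14.0])
def test_density_normalises(zeta):
    # break points at the quartiles help the integrator localise the density
    # mass, which concentrates in a narrow log-scale band at extreme shapes
    pts = list(quantile(np.array([0.01, 0.25, 0.75, 0.99]), zeta))
    val, err = integrate.quad(lambda z: pdf(z, zeta), 0, 1, epsabs=1e-12, limit=400, points=pts)
    assert val == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize("zeta", [0.25, 1.0, 5.0])
def test_cdf_quantile_round_trip(zeta):
    q = np.linspace(0.1, 0.9, 9)
    z = quantile(q, zeta)
    assert np.max(np.abs(cdf(z, zeta) - q)) < 1e-10
    # reverse composition where the CDF is comfortably interior (a tail
    # probability of 1e-7 carries too little float information to invert
    # back to z at full precision)
    zg = np.linspace(0.05, 0.95, 19)
    F = cdf(zg, zeta)
    keep = (F > 1e-4) & (F < 1 - 1e-4)
    assert np.max(np.abs(quantile(F[keep], zeta) - zg[keep])) < 1e-8


def test_pdf_is_cdf_derivative():
    rs = np.random.default_rng(7)
    for _ in range(40):
        zeta = float(rs.uniform(0.2, 5.0))
        z = float(rs.uniform(0.05, 0.95))
        h = 1e-4 * z
        d = lambda step: (cdf(z + step, zeta) - cdf(z - step, zeta)) / (2 * step)
        richardson = (4 * d(h / 2) - d(h)) / 3.0  # O(h^4) central difference
        assert richardson == pytest.approx(pdf(z, zeta), rel=1e-6)


def test_pdf_upper_limit_is_sqrt2_over_pi_zeta():
    # 0/0 at the upper support limit; analytic limit sqrt(2)/(pi*zeta)
    for zeta in (0.5, 1.0, 3.0):
        assert pdf(1 - 1e-12, zeta) == pytest.approx(math.sqrt(2) / (math.pi * zeta), rel=1e-6)


def test_median_closed_form():
    # sin^2(pi/4) = 1/2, so Q(1/2) = exp(-zeta*sqrt(-2 log(1/2)))
    for zeta in (0.42, 0.95, 3.0):
        assert quantile(0.5, zeta) == pytest.approx(
            math.exp(-zeta * math.sqrt(-2 * math.log(0.5))), rel=1e-14
        )
    assert quantile(0.5, 0.95) == pytest.approx(0.3268, abs=5e-5)


def test_reliability_complements_cdf_exactly():
    zg = np.linspace(0.01, 0.99, 50)
    for zeta in (0.3, 1.0, 4.0):
        np.testing.assert_allclose(reliability(zg, zeta) + cdf(zg, zeta), 1.0, atol=5e-16)


def test_hazard_is_pdf_over_reliability():
    rs = np.random.default_rng(11)
    z = rs.uniform(0.02, 0.98, 100)
    zeta = rs.uniform(0.2, 6.0, 100)
    for zi, ti in zip(z, zeta):
        assert hazard(zi, ti) == pytest.approx(pdf(zi, ti) / reliability(zi, ti), rel=1e-12)


@pytest.mark.parametrize("bad", [-0.1, 0.0, 1.0, 1.5, float("nan")])
def test_domain_errors(bad):
    for fun in (cdf, pdf, reliability, hazard):
        with pytest.raises(ValueError):
            fun(bad, 1.0)
    with pytest.raises(ValueError):
        quantile(bad, 1.0)


def test_boundary_flag_returns_limits():
    assert cdf(0.0, 1.0, allow_boundary=True) == 0.0
    assert cdf(1.0, 1.0, allow_boundary=True) == 1.0
    assert reliability(0.0, 1.0, allow_boundary=True) == 1.0


@given(
    z=st.floats(0.01, 0.99),
    z1=st.floats(0.05, 10.0),
    z2=st.floats(0.05, 10.0),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_identifiability_distinct_shapes_give_distinct_cdfs(z, z1, z2):
    """Different shapes must be distinguishable from the CDF (identifiability)."""
    if abs(z1 - z2) < 1e-3:
        return
    grid = np.linspace(0.05, 0.95, 41)
    gap = np.max(np.abs(cdf(grid, z1) - cdf(grid, z2)))
    assert gap > 0.0


def test_cdf_monotone_pdf_nonnegative_hazard_positive():
    grid = np.linspace(1e-4, 1 - 1e-4, 400)
    for zeta in ZETA_GRID:
        F = cdf(grid, zeta)
        assert np.all(np.diff(F) >= -1e-15)
        f = pdf(grid, zeta)
        assert np.all(f >= 0)
        # at extreme shapes the density underflows to exactly 0 deep in the
        # tail; the hazard must be positive wherever the density is
        h = hazard(grid, zeta)
        assert np.all(h[f > 0] > 0)


def test_sampling_deterministic_and_matches_cdf():
    s1 = sample(1000, 0.95, seed=123)
    s2 = sample(1000, 0.95, seed=123)
    np.testing.assert_array_equal(s1, s2)
    big = sample(100_000, 0.95, seed=5)
    assert stats.kstest(big, lambda x: cdf(x, 0.95)).pvalue > 0.01


def test_sample_mean_matches_exact_mean():
    # The exact mean at zeta=0.95 is 0.38646 (quadrature == inverse-CDF
    # Monte Carlo); see the methods note for why the reference table's
    # truncated-series value differs.
    from uasrd import raw_moment

    big = sample(1_000_000, 0.95, seed=99)
    se = big.std() / math.sqrt(big.size)
    assert abs(big.mean() - raw_moment(1, 0.95)) < 3 * se


def test_sample_quartiles_match_quantiles():
    big = sample(1_000_000, 0.42, seed=17)
    emp = np.quantile(big, [0.25, 0.5, 0.75])
    expect = quantile(np.array([0.25, 0.5, 0.75]), 0.42)
    assert np.max(np.abs(emp - expect)) < 5e-3
    # those quantile values are (0.4390, 0.6099, 0.7895) to 4 d.p.
    np.testing.assert_allclose(expect, [0.4390, 0.6099, 0.7895], atol=5e-5)


def test_sample_rejects_bad_n():
    with pytest.raises(ValueError):
        sample(0, 1.0, seed=1)


@pytest.mark.parametrize("zeta", [0.3, 0.95, 2.0])
def test_mode_matches_grid_argmax(zeta):
    res = mode(zeta)
    assert res.interior
    # stationarity of the log-density at the root
    h = 1e-6 * res.z
    dlog = (math.log(pdf(res.z + h, zeta)) - math.log(pdf(res.z - h, zeta))) / (2 * h)
    assert abs(dlog) < 1e-4
    grid = np.exp(np.linspace(math.log(1e-8), math.log(1 - 1e-8), 1_000_000))
    brute = grid[np.argmax(pdf(grid, zeta))]
    assert abs(brute - res.z) < 5e-5


def test_mode_boundary_case_reports_side():
    # for very large shapes the stationary point underflows past any
    # representable z; the brute-force argmax then sits at the grid edge
    res = mode(31.0)
    assert not res.interior and res.boundary == "lower"
    grid = np.exp(np.linspace(math.log(1e-8), math.log(1 - 1e-8), 200_000))
    vals = pdf(grid, 31.0)
    assert np.argmax(vals) == 0


def test_unit_sample_validation_names_offenders():
    with pytest.raises(ValueError, match="positions"):
        UnitSample([0.2, 1.0, 0.5])
    with pytest.raises(ValueError):
        UnitSample([])
    s = UnitSample([0.5, 0.2, 0.9])
    np.testing.assert_array_equal(s.sorted(), [0.2, 0.5, 0.9])
    assert s.n == 3
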