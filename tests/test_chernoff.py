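"""Poisson Chernoff distance and the iso-discrimination tradeoff."""

import math
import warnings

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from obcode.chernoff import (
    chernoff_poisson,
    chernoff_poisson_array,
    expected_dc,
    iso_discrimination,
    monte_carlo_dc,
)
from obcode.network import NetworkParams, effective_params, silence


def _poisson_chernoff_numeric(l1, l2, truncate=200):
    """Independent oracle: maximize -log sum_x P^a(x) Q^(1-a)(x) directly."""
    from scipy.stats import poisson

    x = np.arange(truncate)
    logp = poisson.logpmf(x, l1)
    logq = poisson.logpmf(x, l2)

    def neg_d(a):
        from scipy.special import logsumexp

        return -(-logsumexp(a * logp + (1 - a) * logq))

    res = minimize_scalar(neg_d, bounds=(1e-9, 1 - 1e-9), method="bounded")
    return -res.fun


class TestChernoffPoisson:
    def test_identical_rates_zero(self):
        assert chernoff_poisson(3.0, 3.0).d_c == 0.0

    def test_hand_derived_example(self):
        r = chernoff_poisson(4.0, 1.0)
        assert r.alpha_star == pytest.approx(0.557, abs=1e-3)
        assert r.d_c == pytest.approx(0.506, abs=1e-3)

    def test_matches_direct_distribution_optimization(self):
        for l1, l2 in [(4.0, 1.0), (0.3, 0.05), (10.0, 12.0)]:
            assert chernoff_poisson(l1, l2).d_c == pytest.approx(
                _poisson_chernoff_numeric(l1, l2), rel=1e-6
            )

    def test_symmetry(self):
        assert chernoff_poisson(2.0, 7.0).d_c == pytest.approx(
            chernoff_poisson(7.0, 2.0).d_c, rel=1e-12
        )

    def test_small_gap_quadratic_limit(self):
        l1 = 5.0
        eps = 0.01
        l2 = l1 * (1 + eps)
        quad = (l1 - l2) ** 2 / (8 * (0.5 * (l1 + l2)))
        assert chernoff_poisson(l1, l2).d_c == pytest.approx(quad, rel=0.01)

    def test_zero_rate_conventions(self):
        assert chernoff_poisson(0.0, 0.0).d_c == 0.0
        assert chernoff_poisson(0.0, 0.0).degenerate
        assert chernoff_poisson(3.0, 0.0).d_c == pytest.approx(3.0)

    def test_additivity_over_independent_neurons(self):
        """D_c of a 3-neuron independent Poisson vector is the sum of the
        per-neuron distances at a common optimal alpha; verify against the
        truncated joint distribution."""
        from itertools import product

        from scipy.special import logsumexp
        from scipy.stats import poisson

        lam_p = np.array([2.0, 4.0, 1.0])
        lam_q = np.array([2.0, 1.0, 4.0])
        # the per-neuron exponent is concave in alpha and additive, so the
        # joint optimum maximizes the summed exponent
        grid = np.linspace(1e-6, 1 - 1e-6, 2001)
        per = [
            a * lam_p + (1 - a) * lam_q - lam_p**a * lam_q ** (1 - a)
            for a in grid
        ]
        joint_closed = max(p.sum() for p in per)

        x = np.arange(40)
        best = -np.inf
        for a in np.linspace(0.3, 0.7, 81):
            lp = sum(
                logsumexp(a * poisson.logpmf(x, p) + (1 - a) * poisson.logpmf(x, q))
                for p, q in zip(lam_p, lam_q)
            )
            best = max(best, -lp)
        assert joint_closed == pytest.approx(best, rel=1e-4)

    def test_array_form_matches_scalar(self, rng):
        l1 = rng.uniform(0, 5, size=20)
        l2 = rng.uniform(0, 5, size=20)
        arr = chernoff_poisson_array(l1, l2)
        for i in range(20):
            assert arr[i] == pytest.approx(chernoff_poisson(l1[i], l2[i]).d_c,
                                           rel=1e-12, abs=1e-15)


class TestExpectedDc:
    def test_uncoupled_limit(self):
        p = NetworkParams(j_peak=0.0)
        assert expected_dc(p) == pytest.approx(p.i1**2 / (4 * p.i0))

    def test_default_plug_in(self):
        p = NetworkParams()
        eff = effective_params(p)
        assert expected_dc(p) == pytest.approx(
            p.i1**2 / (4 * p.i0) * eff.sharpening_all_gcs
        )
        assert eff.sharpening_all_gcs == pytest.approx(6.372, abs=2e-3)

    def test_quadratic_in_input_scale(self):
        p1, p2 = NetworkParams(i1=0.1), NetworkParams(i1=0.2)
        assert expected_dc(p2) == pytest.approx(4 * expected_dc(p1))

    def test_silencing_ratio_equals_sharpening(self, rng):
        """D_c(before)/D_c(abGC-silenced) is the sharpening ratio exactly."""
        for _ in range(100):
            p = NetworkParams(
                n_mc=100,
                n_gc=int(rng.integers(500, 5000)),
                n_abgc=int(rng.integers(1, 300)),
                j_peak=float(rng.uniform(1, 20)),
                sigma_gc_mc=float(rng.uniform(0.1, 1.0)),
                sigma_mc_gc=float(rng.uniform(0.1, 1.0)),
                b=float(rng.uniform(1, 5)),
                g=float(rng.uniform(1, 8)),
                i0=float(rng.uniform(0.5, 2)),
                i1=float(rng.uniform(0.01, 0.5)),
            )
            ratio = expected_dc(p) / expected_dc(silence(p, "abgc", 1.0))
            assert ratio == pytest.approx(effective_params(p).sharpening_abgcs,
                                          abs=1e-12)


class TestMonteCarlo:
    def test_no_odor_input_gives_zero(self):
        p = NetworkParams(n_mc=40, n_gc=800, n_abgc=20, i1=0.0)
        val, _ = monte_carlo_dc(p, n_odors=5, seed=1)
        assert val == 0.0

    def test_small_signal_agreement_with_closed_form(self):
        p = NetworkParams(n_mc=200, n_gc=3900, n_abgc=100, i1=0.02)
        val, clipped = monte_carlo_dc(p, n_odors=20, seed=3)
        assert clipped == 0.0
        assert val == pytest.approx(expected_dc(p), rel=0.15)

    def test_seed_reproducibility(self):
        p = NetworkParams(n_mc=60, n_gc=1170, n_abgc=30, i1=0.02)
        a, _ = monte_carlo_dc(p, n_odors=6, seed=9)
        b, _ = monte_carlo_dc(p, n_odors=6, seed=9)
        assert a == b


class TestIsoDiscrimination:
    def test_half_benefit_fraction(self):
        curve = iso_discrimination(NetworkParams())
        assert curve.f_half == pytest.approx(0.0758, abs=2e-4)
        assert curve.f_half_numeric == pytest.approx(curve.f_half, abs=1e-9)

    def test_flat_curve_when_abgcs_are_ordinary(self):
        p = NetworkParams(b=1.0, g=1.0)
        curve = iso_discrimination(p)
        assert curve.f_half is None
        np.testing.assert_allclose(curve.n_mc, curve.n_mc[0])

    def test_strictly_decreasing_mc_requirement(self):
        curve = iso_discrimination(NetworkParams())
        assert np.all(np.diff(curve.n_mc) < 0)

    def test_f_half_independent_of_input_scales(self):
        a = iso_discrimination(NetworkParams(i0=1.0, i1=0.1))
        b = iso_discrimination(NetworkParams(i0=2.5, i1=0.7))
        assert a.f_half == pytest.approx(b.f_half, abs=1e-15)

    def test_f_half_insensitive_to_peak_strength(self):
        base = iso_discrimination(NetworkParams()).f_half
        lo = iso_discrimination(NetworkParams(j_peak=8.0)).f_half
        hi = iso_discrimination(NetworkParams(j_peak=12.0)).f_half
        assert abs(lo - base) < 0.01 and abs(hi - base) < 0.01
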