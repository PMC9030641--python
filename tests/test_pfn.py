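"""Pythagorean fuzzy number algebra, defuzzification and distances."""

import numpy as np
import pytest
from scipy.integrate import quad

from fuzzymoth import pfn as pf
from conftest import random_pfns


class TestConstruction:
    def test_boundary_case_zero_hesitancy(self):
        p = pf.make_pfn(0.6, 0.6, 0.8, 0.8)
        assert p.pi_lo == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("args,fragment", [
        ((0.9, 0.95, 0.4, 0.5), "Pythagorean"),
        ((0.5, 0.3, 0.1, 0.2), "ordering"),
        ((0.5, 0.6, 0.1, 1.2), "outside"),
    ])
    def test_invalid_inputs_name_the_violated_invariant(self, args, fragment):
        with pytest.raises(ValueError, match=fragment):
            pf.make_pfn(*args)

    def test_project_valid_is_idempotent_and_identity_on_valid(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(-0.5, 1.5, (500, 4))
        once = pf.arr_project_valid(raw)
        assert pf.is_valid_arr(once).all()
        np.testing.assert_allclose(pf.arr_project_valid(once), once, atol=1e-12)
        valid = random_pfns(200, 1)
        np.testing.assert_allclose(pf.arr_project_valid(valid), valid, atol=1e-12)

    def test_project_valid_radial_rescaling(self):
        p = pf.project_valid(1.0, 1.0, 1.0, 1.0)
        assert p.mu_hi == pytest.approx(np.sqrt(0.5))
        assert p.nu_hi == pytest.approx(np.sqrt(0.5))


class TestCentroid:
    def test_degenerate_interval(self):
        c = pf.centroid(pf.make_pfn(0.6, 0.6, 0.3, 0.3))
        assert (c.c_mu, c.c_nu) == (0.6, 0.3)

    @pytest.mark.parametrize("bounds,expected", [
        (((0.2, 0.8), (0.1, 0.5)), (0.5, 0.3)),
        (((0.0, 1.0), (0.0, 0.0)), (0.5, 0.0)),
    ])
    def test_matches_uniform_density_quadrature(self, bounds, expected):
        (ml, mh), (nl, nh) = bounds
        # ratio-of-integrals centroid with uniform density over the interval
        def ratio(lo, hi):
            if hi == lo:
                return lo
            num, _ = quad(lambda x: x, lo, hi)
            den, _ = quad(lambda x: 1.0, lo, hi)
            return num / den
        c = pf.centroid(pf.make_pfn(ml, mh, nl, nh))
        assert c.c_mu == pytest.approx(ratio(ml, mh), abs=1e-9)
        assert c.c_nu == pytest.approx(ratio(nl, nh), abs=1e-9)
        assert (c.c_mu, c.c_nu) == pytest.approx(expected)


class TestCrispDistance:
    def test_identity(self):
        assert pf.crisp_distance(0.5, pf.make_pfn(0.5, 0.5, 0.0, 0.0)) == 0.0

    def test_unit_membership_from_zero(self):
        d = pf.crisp_distance(0.0, pf.make_pfn(1.0, 1.0, 0.0, 0.0))
        assert d == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_nonmembership_only_term(self):
        d = pf.crisp_distance(0.2, pf.make_pfn(0.2, 0.2, 0.3, 0.3))
        assert d == pytest.approx(0.3, abs=1e-12)

    def test_centroid_alpha_reduces_to_c_nu(self):
        for p in random_pfns(200, 3):
            c = pf.arr_centroid(p)
            d = pf.crisp_distance(float(c[0]), pf.PFN(*p))
            assert d == pytest.approx(float(c[1]), abs=1e-12)

    def test_both_typographic_variants_agree_when_nu_zero(self):
        p = pf.make_pfn(0.3, 0.7, 0.0, 0.0)
        a = pf.crisp_distance(0.1, p, variant="half_mu")
        b = pf.crisp_distance(0.1, p, variant="half_both")
        assert a == pytest.approx(b)

    def test_vector_rms_aggregation(self):
        # per-coordinate distances (0.3, 0.4) -> sqrt((0.09+0.16)/2)
        xf = np.stack([pf.make_pfn(0.2, 0.2, 0.3, 0.3).as_array(),
                       pf.make_pfn(0.3, 0.3, 0.4, 0.4).as_array()])
        d = pf.crisp_fuzzy_vector_distance(np.array([0.2, 0.3]), xf)
        assert d == pytest.approx(np.sqrt((0.09 + 0.16) / 2), abs=1e-12)

    def test_vector_distance_d1_reduces_to_scalar(self):
        p = pf.make_pfn(0.2, 0.6, 0.1, 0.4)
        d1 = pf.crisp_fuzzy_vector_distance(np.array([0.3]), p.as_array()[None])
        assert d1 == pytest.approx(pf.crisp_distance(0.3, p))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pf.crisp_fuzzy_vector_distance(np.zeros(3), random_pfns(2, 0))


class TestPFNDistance:
    def test_identity_and_simplex_vertices(self):
        b = pf.make_pfn(0.3, 0.5, 0.2, 0.4)
        assert pf.pfn_distance(b, b) == 0.0
        one = pf.make_pfn(1, 1, 0, 0)
        zero = pf.make_pfn(0, 0, 1, 1)
        assert pf.pfn_distance(one, zero) == pytest.approx(1.0)

    def test_hand_value(self):
        d = pf.pfn_distance(pf.make_pfn(0.6, 0.6, 0.8, 0.8),
                            pf.make_pfn(0.8, 0.8, 0.6, 0.6))
        assert d == pytest.approx(0.28, abs=1e-12)

    def test_metric_properties_on_random_triples(self):
        P1, P2, P3 = (random_pfns(10_000, s) for s in (10, 11, 12))
        d12 = pf.arr_pfn_distance(P1, P2)
        d21 = pf.arr_pfn_distance(P2, P1)
        d13 = pf.arr_pfn_distance(P1, P3)
        d23 = pf.arr_pfn_distance(P2, P3)
        assert (d12 >= 0).all() and (d12 <= 1 + 1e-12).all()
        np.testing.assert_allclose(d12, d21, atol=1e-12)
        assert (d12 <= d13 + d23 + 1e-12).all()
        assert pf.arr_pfn_distance(P1, P1).max() == 0.0

    def test_degenerate_zero_hesitancy_reduces_to_scaled_euclidean(self):
        rng = np.random.default_rng(5)
        mu = rng.random((200, 2))
        nu = np.sqrt(1 - mu**2)          # pi = 0 exactly
        P = np.stack([mu, mu, nu, nu], axis=-1)  # (200, 2, 4)
        d = pf.arr_pfn_distance(P[:, 0], P[:, 1])
        brute = np.sqrt(((mu[:, 0]**2 - mu[:, 1]**2) ** 2
                         + (nu[:, 0]**2 - nu[:, 1]**2) ** 2) / 2)
        np.testing.assert_allclose(d, brute, atol=1e-12)

    def test_vector_distance_rms(self):
        one = pf.make_pfn(1, 1, 0, 0).as_array()
        zero = pf.make_pfn(0, 0, 1, 1).as_array()
        x = np.stack([one, zero])
        v = np.stack([zero, zero])       # per-coordinate distances (1, 0)
        assert pf.pfn_vector_distance(x, v) == pytest.approx(np.sqrt(0.5))
        assert pf.pfn_vector_distance(x, x) == 0.0


class TestOperationalLaws:
    def test_add_identity(self):
        b = pf.make_pfn(0.3, 0.5, 0.2, 0.4)
        out = pf.pfn_add(b, pf.make_pfn(0, 0, 1, 1))
        np.testing.assert_allclose(out.as_array(), b.as_array(), atol=1e-12)

    def test_scale_zero_collapses(self):
        out = pf.pfn_scale(0.0, pf.make_pfn(0.3, 0.5, 0.2, 0.4))
        np.testing.assert_allclose(out.as_array(), [0, 0, 1, 1], atol=1e-12)

    def test_scale_half_hand_value(self):
        out = pf.pfn_scale(0.5, pf.make_pfn(0.8, 0.8, 0.6, 0.6))
        assert out.mu_hi == pytest.approx(np.sqrt(0.4), abs=1e-12)
        assert out.nu_hi == pytest.approx(np.sqrt(0.6), abs=1e-12)

    def test_closure_of_add_scale_activate(self):
        P1 = random_pfns(10_000, 20)
        P2 = random_pfns(10_000, 21)
        lam = np.random.default_rng(22).random(10_000) * 3
        assert pf.is_valid_arr(pf.arr_add(P1, P2)).all()
        assert pf.is_valid_arr(pf.arr_scale(lam, P1)).all()
        assert pf.is_valid_arr(pf.arr_activate(P1)).all()

    def test_activation_fixed_point_and_monotonicity(self):
        out = pf.activate(pf.make_pfn(1, 1, 0, 0))
        assert out.mu_hi == pytest.approx(1.0)
        P = random_pfns(2_000, 23)
        Q = pf.arr_project_valid(P * 0.8)   # element-wise smaller degrees
        aP, aQ = pf.arr_activate(P), pf.arr_activate(Q)
        assert (aQ[..., 0:2] <= aP[..., 0:2] + 1e-12).all()


class TestFuzzify:
    def test_extremes_and_hesitancy(self):
        assert pf.fuzzify(1.0).as_array() == pytest.approx([1, 1, 0, 0])
        half = pf.fuzzify(0.5)
        assert half.as_array() == pytest.approx([0.5, 0.5, 0.5, 0.5])
        assert half.pi_lo == pytest.approx(np.sqrt(0.5))

    def test_centroid_round_trip(self):
        x = np.random.default_rng(30).random(500)
        c = pf.arr_centroid(pf.arr_fuzzify(x))
        np.testing.assert_allclose(c[..., 0], x, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pf.fuzzify(1.2)
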