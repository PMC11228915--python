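import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from crystinv.invariants import (ada, amd, density_and_atm, invariant_record,
                                 knn_distances, nda, pdd, ppc,
                                 unit_ball_volume, pdd_from_json, pdd_to_json)
from crystinv.metrics import emd
from crystinv.periodic_model import (Motif, PeriodicCrystal, PeriodicSet,
                                     UnitCell, to_cartesian)
from crystinv.synthetic import make_lattice, random_periodic_set, supercell


def brute_force_knn(ps, k, reach=6):
    """Independent oracle: enumerate all lattice translates with integer
    coefficients in [-reach, reach]^n and sort the distances directly."""
    cart = to_cartesian(ps)
    coeffs = np.array(list(itertools.product(range(-reach, reach + 1),
                                             repeat=ps.dim)))
    cloud = (cart[None] + (coeffs @ ps.cell.basis)[:, None]).reshape(-1, ps.dim)
    dist = np.sort(cdist(cart, cloud), axis=1)
    return dist[:, 1:k + 1]


class TestKnnDistances:
    def test_square_lattice_shells(self):
        sq = make_lattice("square")
        assert np.allclose(knn_distances(sq, 4).distances, [[1, 1, 1, 1]])
        got = knn_distances(sq, 8).distances[0]
        assert np.allclose(got, [1] * 4 + [math.sqrt(2)] * 4)

    def test_simple_cubic_coordination(self):
        sc = make_lattice("cubic-sc")
        assert np.allclose(knn_distances(sc, 6).distances, [[1] * 6])

    def test_fcc_coordination_twelve(self):
        fcc = make_lattice("cubic-fcc")
        got = knn_distances(fcc, 12).distances
        assert np.allclose(got, math.sqrt(2) / 2)

    def test_agrees_with_brute_force_on_random_sets(self, random_sets):
        for ps in random_sets:
            got = knn_distances(ps, 20).distances
            assert np.allclose(got, brute_force_knn(ps, 20), atol=1e-9)

    def test_rows_are_nondecreasing_and_positive(self, random_sets):
        for ps in random_sets[:10]:
            d = knn_distances(ps, 15).distances
            assert (d > 0).all()
            assert (np.diff(d, axis=1) >= 0).all()


class TestPDD:
    def test_single_orbit_lattice_has_one_row(self):
        p = pdd(make_lattice("square"), 4)
        assert p.rows.shape == (1, 4)
        assert p.weights[0] == pytest.approx(1.0)

    def test_weights_sum_to_one_and_are_multiples_of_inv_m(self, random_sets):
        for ps in random_sets[:10]:
            p = pdd(ps, 8)
            assert abs(p.weights.sum() - 1) < 1e-12
            assert np.allclose(p.weights * ps.m, np.round(p.weights * ps.m))

    def test_rows_in_lexicographic_order(self, random_sets):
        for ps in random_sets[:10]:
            rows = pdd(ps, 8).rows
            for a, b in zip(rows, rows[1:]):
                assert tuple(a) <= tuple(b)

    def test_supercell_description_gives_same_pdd(self, random_sets):
        for ps in random_sets[:5]:
            doubled = supercell(ps, (2, 1, 2))
            dist, _ = emd(pdd(ps, 8), pdd(doubled, 8))
            assert dist < 1e-9

    def test_increasing_k_only_appends_columns(self, random_sets):
        for ps in random_sets[:5]:
            full = knn_distances(ps, 12).distances
            assert np.allclose(knn_distances(ps, 7).distances, full[:, :7])


class TestAMD:
    def test_square_lattice_amd_equals_its_distances(self):
        # m=1, so AMD_j is just the j-th neighbour distance; the fifth
        # neighbour of the square lattice is diagonal at sqrt(2)
        values = amd(make_lattice("square"), 5).values
        assert np.allclose(values, [1, 1, 1, 1, math.sqrt(2)])

    def test_amd_is_weighted_pdd_column_average(self, random_sets):
        for ps in random_sets[:8]:
            direct = knn_distances(ps, 10).distances.mean(axis=0)
            assert np.allclose(amd(ps, 10).values, direct, atol=1e-12)

    def test_monotone_nondecreasing(self, random_sets):
        for ps in random_sets[:10]:
            assert (np.diff(amd(ps, 12).values) >= -1e-12).all()

    def test_scales_linearly(self):
        ps = random_periodic_set(3, 4, seed=5)
        scaled = PeriodicSet(UnitCell(2.5 * ps.cell.basis), ps.motif)
        assert np.allclose(amd(scaled, 8).values, 2.5 * amd(ps, 8).values)


class TestPPC:
    def test_known_lattice_values(self):
        assert ppc(make_lattice("square")) == pytest.approx((1 / math.pi) ** 0.5)
        assert ppc(make_lattice("cubic-sc")) == pytest.approx((3 / (4 * math.pi)) ** (1 / 3))

    def test_unit_ball_volumes(self):
        assert unit_ball_volume(1) == pytest.approx(2)
        assert unit_ball_volume(2) == pytest.approx(math.pi)
        assert unit_ball_volume(3) == pytest.approx(4 * math.pi / 3)

    def test_intensive_under_supercell(self, random_sets):
        for ps in random_sets[:5]:
            assert ppc(supercell(ps, (3, 1, 2))) == pytest.approx(ppc(ps), abs=1e-12)

    def test_scales_linearly(self):
        ps = random_periodic_set(3, 2, seed=9)
        scaled = PeriodicSet(UnitCell(0.5 * ps.cell.basis), ps.motif)
        assert ppc(scaled) == pytest.approx(0.5 * ppc(ps))


class TestADAandNDA:
    def test_square_lattice_first_deviation(self):
        sq = make_lattice("square")
        assert ada(sq, 1)[0] == pytest.approx(1 - 1 / math.sqrt(math.pi), abs=1e-9)
        assert nda(sq, 1)[0] == pytest.approx(
            (1 - 1 / math.sqrt(math.pi)) / (1 / math.sqrt(math.pi)), abs=1e-9)

    def test_ada_scales_linearly_nda_invariant(self):
        ps = random_periodic_set(3, 3, seed=21)
        for u in (0.5, 2.0, 10.0):
            scaled = PeriodicSet(UnitCell(u * ps.cell.basis), ps.motif)
            assert np.allclose(ada(scaled, 6), u * ada(ps, 6), atol=1e-9)
            assert np.allclose(nda(scaled, 6), nda(ps, 6), atol=1e-10)

    def test_nda_decays_towards_asymptote(self):
        # AMD_k approaches PPC * k^(1/n), so the normalized deviation must
        # shrink (slowly) with k: the k~400 tail is well below the head
        for ps in (make_lattice("cubic-sc"), random_periodic_set(3, 4, seed=3)):
            values = nda(ps, 400)
            head = np.abs(values[:20]).mean()
            tail = np.abs(values[-100:]).mean()
            assert tail < 0.6 * head
            assert tail < 0.1


def toy_crystal(a=2.0, element="C", mass=12.011):
    geometry = PeriodicSet(UnitCell(a * np.eye(3)), Motif([[0, 0, 0]]), "toy")
    return PeriodicCrystal(geometry, (element,), (mass,))


class TestDensityAndATM:
    def test_carbon_cube(self):
        rho, atm = density_and_atm(toy_crystal())
        assert rho == pytest.approx(12.011 / 8 * 1.66053906660, rel=1e-12)
        assert atm == pytest.approx(12.011)

    def test_intensive_under_supercell(self):
        crystal = toy_crystal()
        big = PeriodicCrystal(supercell(crystal.geometry, (2, 2, 2)),
                              ("C",) * 8, (12.011,) * 8)
        assert density_and_atm(big) == pytest.approx(density_and_atm(crystal))

    def test_cubic_hyperbola_under_scaling(self):
        base = toy_crystal()
        rho0, _ = density_and_atm(base)
        const0 = rho0 * ppc(base.geometry) ** 3
        for u in (0.7, 1.3, 2.0):
            scaled = PeriodicCrystal(
                PeriodicSet(UnitCell(2.0 * u * np.eye(3)), base.geometry.motif),
                ("C",), (12.011,))
            rho, _ = density_and_atm(scaled)
            assert rho * ppc(scaled.geometry) ** 3 == pytest.approx(const0, rel=1e-12)


class TestSerialization:
    def test_pdd_json_round_trip(self):
        p = pdd(random_periodic_set(3, 3, seed=2), 6)
        back = pdd_from_json(pdd_to_json(p))
        assert back.k == p.k
        assert np.allclose(back.weights, p.weights)
        assert np.allclose(back.rows, p.rows)

    def test_invariant_record_coordinates(self):
        rec = invariant_record(toy_crystal(), k=5)
        assert rec.coordinate("ppc") == pytest.approx(ppc(toy_crystal().geometry))
        assert rec.coordinate("amd_1") == pytest.approx(rec.amd[0])
        with pytest.raises(KeyError):
            rec.coordinate("amd_9")
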