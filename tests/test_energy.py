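"""Hamiltonian, local delta-energy, Metropolis rule, polarity, motility."""

import math

import numpy as np
import pytest

from invadopotts.cpm import (
    Simulation,
    metropolis_accept,
    motility_delta,
    total_energy,
    update_polarity,
)
from invadopotts.params import (
    ID_FIBRE,
    ID_FLUID,
    TYPE_CELL,
    TYPE_FIBRE,
    TYPE_FLUID,
    EnergyParams,
)


def brute_force_energy(sigma: np.ndarray, params: EnergyParams) -> float:
    """Independent oracle: explicit loop over every lattice edge and cell."""
    J = params.j_matrix()

    def ptype(s):
        return TYPE_CELL if s > 0 else (TYPE_FLUID if s == 0 else TYPE_FIBRE)

    W, H = sigma.shape
    e = 0.0
    perim = {}
    for x in range(W):
        for y in range(H):
            for dx, dy in ((1, 0), (0, 1)):
                nx, ny = x + dx, y + dy
                if nx >= W or ny >= H:
                    continue
                a, b = sigma[x, y], sigma[nx, ny]
                if a != b:
                    e += J[ptype(a), ptype(b)]
                    for s in (a, b):
                        if s > 0:
                            perim[s] = perim.get(s, 0) + 1
    for cid in np.unique(sigma[sigma > 0]):
        area = int((sigma == cid).sum())
        e += params.lam_a * (area - params.a0) ** 2
        e += params.lam_p * (perim.get(int(cid), 0) - params.p0) ** 2
    return e


class TestTotalEnergy:
    def test_empty_lattice_zero(self):
        sigma = np.zeros((20, 20), dtype=np.int32)
        assert total_energy(sigma, EnergyParams()) == 0.0

    def test_single_square_cell_closed_form(self):
        sigma = np.zeros((20, 20), dtype=np.int32)
        sigma[5:15, 5:15] = 1
        p = EnergyParams()
        # 40 boundary edges at J_cf, zero area penalty, (40 - p0)^2 perimeter
        expect = 40 * p.j_cf + p.lam_p * (40 - p.p0) ** 2
        assert total_energy(sigma, p) == pytest.approx(expect)
        assert total_energy(sigma, p) == pytest.approx(brute_force_energy(sigma, p))

    def test_two_adjacent_cells_share_jcc_wall(self, two_cells):
        sigma, meta = two_cells
        p = EnergyParams(j_cc=5.0)
        e = total_energy(sigma, p)
        assert e == pytest.approx(brute_force_energy(sigma, p))
        # the shared 10-edge wall is charged J_cc, not J_cf
        expect = (
            meta["outer_edges"] * p.j_cf
            + meta["shared_edges"] * p.j_cc
            + 2 * p.lam_p * (40 - p.p0) ** 2
        )
        assert e == pytest.approx(expect)

    def test_matches_brute_force_on_mixed_lattice(self, toy_lattice):
        p = EnergyParams(j_cc=7.0)
        assert total_energy(toy_lattice, p) == pytest.approx(
            brute_force_energy(toy_lattice, p)
        )


class TestDeltaEnergy:
    def test_contract_violations_raise(self, toy_lattice):
        sim = Simulation(toy_lattice.copy(), EnergyParams(), proteolysis=False)
        with pytest.raises(ValueError):
            sim.delta_energy((0, 0), (5, 5))  # not neighbours
        with pytest.raises(ValueError):
            sim.delta_energy((15, 1), (15, 2))  # fibre involved
        with pytest.raises(ValueError):
            sim.delta_energy((3, 3), (3, 4))  # same cell

    def test_local_equals_global_plus_work(self, toy_lattice):
        """Local dE = static recompute difference + independent motility work."""
        p = EnergyParams(j_cc=9.0)
        sim = Simulation(toy_lattice.copy(), p, proteolysis=False, seed=4)
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 200:
            x = int(rng.integers(0, 29))
            y = int(rng.integers(0, 29))
            dx, dy = ((1, 0), (-1, 0), (0, 1), (0, -1))[int(rng.integers(0, 4))]
            nx, ny = x + dx, y + dy
            if not (0 <= nx < 30 and 0 <= ny < 30):
                continue
            s_src, s_tgt = sim.sigma[x, y], sim.sigma[nx, ny]
            if ID_FIBRE in (s_src, s_tgt) or s_src == s_tgt:
                continue
            local = sim.delta_energy((x, y), (nx, ny))
            after = sim.sigma.copy()
            after[nx, ny] = s_src
            static = total_energy(after, p) - total_energy(sim.sigma, p)
            work = motility_delta(
                (x, y), (nx, ny),
                (sim.polx[s_src], sim.poly[s_src]) if s_src > 0 else None,
                (sim.polx[s_tgt], sim.poly[s_tgt]) if s_tgt > 0 else None,
                p.mu0,
            )
            assert local == pytest.approx(static + work, abs=1e-9)
            checked += 1

    def test_shrink_to_zero_area_quantum(self):
        # isolated one-pixel cell, a0 = 100: pure area contribution 199*lam_a
        sigma = np.zeros((9, 9), dtype=np.int32)
        sigma[4, 4] = 1
        p = EnergyParams(j_cc=0, j_ce=0, j_cf=0, j_ef=0, j_ee=0, j_ff=0,
                         lam_p=0.0, mu0=0.0)
        sim = Simulation(sigma, p, proteolysis=False)
        assert sim.delta_energy((3, 4), (4, 4)) == pytest.approx(199 * p.lam_a)


class TestMetropolis:
    def test_negative_always_accepted(self):
        assert metropolis_accept(-5.0, 0.01, 0.999999)

    def test_zero_always_accepted(self):
        assert metropolis_accept(0.0, 0.01, 0.999999)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, 0.5)

    def test_boltzmann_rate_at_unit_ratio(self):
        # dE/T_m = 1: acceptance probability e^-1 ~ 0.3679
        rng = np.random.default_rng(123)
        u = rng.random(100_000)
        rate = np.mean([metropolis_accept(0.01, 0.01, ui) for ui in u])
        assert rate == pytest.approx(math.exp(-1), abs=0.01)

    def test_acceptance_law_binwise(self):
        """Empirical frequency matches min(1, exp(-dE/T)) within 3 sigma."""
        rng = np.random.default_rng(7)
        t_m = 0.01
        n = 20_000
        for de in (-0.5, 0.0, 0.002, 0.005, 0.01, 0.02, 0.05):
            u = rng.random(n)
            emp = np.mean([metropolis_accept(de, t_m, ui) for ui in u])
            p = min(1.0, math.exp(-de / t_m))
            sd = math.sqrt(p * (1 - p) / n)
            assert abs(emp - p) <= 3 * sd + 1e-12


class TestPolarity:
    def test_identical_displacements(self):
        p = update_polarity(np.tile([1.0, 0.0], (10, 1)))
        assert np.allclose(p, [1, 0])

    def test_cancelling_displacements_zero(self):
        p = update_polarity(np.array([[1.0, 2.0], [-1.0, -2.0]]))
        assert np.allclose(p, [0, 0])

    def test_single_early_displacement(self):
        assert np.allclose(update_polarity(np.array([[3.0, 4.0]])), [0.6, 0.8])

    def test_unit_norm(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            h = rng.normal(size=(rng.integers(1, 11), 2))
            p = update_polarity(h)
            assert abs(np.linalg.norm(p) - 1) < 1e-9 or np.allclose(p, 0)


class TestMotilityDelta:
    def test_aligned_copy_favoured(self):
        w = motility_delta((5, 5), (6, 5), (1.0, 0.0), None, 50.0)
        assert w == pytest.approx(-50.0)

    def test_zero_polarity_inert(self):
        assert motility_delta((5, 5), (6, 5), (0.0, 0.0), (0.0, 0.0), 50.0) == 0.0

    def test_both_cells_accumulate(self):
        w = motility_delta((5, 5), (5, 6), (0.6, 0.8), (0.0, -1.0), 50.0)
        assert w == pytest.approx(-50 * 0.8 + 50 * 1.0)
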