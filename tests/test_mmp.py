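"""MMP field: secretion rule, forward-Euler PDE, threshold degradation."""

import numpy as np
import pytest

from invadopotts.cpm import Simulation
from invadopotts.ecm import build_initial_aggregate, compose_lattice, generate_fibre_mesh
from invadopotts.fixtures import make_fixture
from invadopotts.mmp import (
    contact_fibre_pixels,
    degrade_ecm,
    diffuse_decay_step,
    secrete,
)
from invadopotts.params import ID_FIBRE, ID_FLUID, EnergyParams, MMPParams


class TestSecretion:
    def test_no_contact_no_secretion(self):
        sigma = np.zeros((9, 9), dtype=np.int32)
        sigma[0, 0] = ID_FIBRE
        sigma[8, 8] = 1
        field = np.zeros((9, 9))
        secrete(field, sigma, 0.05)
        assert not field.any()

    def test_unit_contact_accumulates_lambda_per_substep(self):
        sigma, meta = make_fixture("secretion_unit")
        field = np.zeros(sigma.shape)
        for _ in range(36):
            secrete(field, sigma, 0.05)
        # one contacted fibre pixel: 36 substeps x 0.05 = 1.8 per MCS
        assert field[4, 4] == pytest.approx(1.8)
        assert np.count_nonzero(field) == meta["n_contact_pixels"]

    def test_moore_neighbourhood_contact(self):
        sigma = np.zeros((9, 9), dtype=np.int32)
        sigma[4, 4] = ID_FIBRE
        sigma[5, 5] = 7  # diagonal cell counts as contact
        xs, ys = contact_fibre_pixels(sigma)
        assert list(zip(xs, ys)) == [(4, 4)]

    def test_deposit_is_per_fibre_pixel_not_per_pair(self):
        sigma = np.zeros((9, 9), dtype=np.int32)
        sigma[4, 4] = ID_FIBRE
        sigma[3, 4] = 1
        sigma[5, 4] = 2  # two cells touching the same fibre pixel
        field = np.zeros((9, 9))
        secrete(field, sigma, 0.05)
        assert field[4, 4] == pytest.approx(0.05)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            secrete(np.zeros((4, 4)), np.zeros((4, 4), dtype=np.int32), -0.1)

    def test_denser_mesh_secretes_more(self):
        """ECM-density-dependent secretion: more fibres -> more contact sites
        -> more enzyme released (5 paired seeds)."""
        totals = {}
        for xi in (100, 250):
            per_seed = []
            for seed in range(5):
                mesh = generate_fibre_mesh(xi, "random", seed, 250)
                layout = build_initial_aggregate(lattice_px=250)
                sigma = compose_lattice(mesh, layout, 250)
                mmp = MMPParams(secretion_per_s=0.05, decay_per_s=0.0)
                sim = Simulation(sigma, EnergyParams(), mmp=mmp, seed=seed)
                sim.run(5)
                per_seed.append(sim.field.sum() + sim.degradation_events)
            totals[xi] = np.array(per_seed)
        assert np.all(totals[250] > totals[100])


class TestDiffusionDecay:
    def test_uniform_field_invariant_without_decay(self):
        field = np.full((12, 12), 3.7)
        diffuse_decay_step(field, MMPParams(decay_per_s=0.0))
        assert np.allclose(field, 3.7, atol=1e-12)

    def test_pure_decay_matches_scalar_recurrence(self):
        # D = 0: value after n substeps is v0 * (1 - delta*dt)^n
        field = np.zeros((7, 7))
        field[3, 3] = 5.0
        m = MMPParams(diffusion_um2_s=0.0)
        for _ in range(36):
            diffuse_decay_step(field, m)
        assert field[3, 3] == pytest.approx(5.0 * 0.998**36, rel=1e-12)
        assert 0.998**36 == pytest.approx(0.9305, abs=1e-4)

    def test_mass_conserved_with_zero_flux_boundaries(self):
        rng = np.random.default_rng(3)
        field = rng.random((15, 15)) * 4
        mass0 = field.sum()
        m = MMPParams(decay_per_s=0.0)
        for _ in range(1000):
            diffuse_decay_step(field, m)
        assert field.sum() == pytest.approx(mass0, abs=1e-9)
        assert field.min() >= 0

    def test_stability_number_guard(self):
        with pytest.raises(ValueError):
            MMPParams(diffusion_um2_s=1.5)  # r = 0.375 > 0.25
        assert MMPParams().stability_number == pytest.approx(0.025)

    def test_runaway_field_aborts(self):
        field = np.full((6, 6), 2e6)
        with pytest.raises(FloatingPointError):
            diffuse_decay_step(field, MMPParams())


class TestDegradation:
    def test_threshold_and_decrement(self):
        sigma = np.zeros((5, 5), dtype=np.int32)
        sigma[2, 2] = ID_FIBRE
        field = np.zeros((5, 5))
        field[2, 2] = 1.2
        new_sigma, new_field, events = degrade_ecm(field, sigma)
        assert new_sigma[2, 2] == ID_FLUID
        assert new_field[2, 2] == pytest.approx(0.2)
        assert events == [(2, 2)]

    def test_below_threshold_untouched(self):
        sigma = np.zeros((5, 5), dtype=np.int32)
        sigma[2, 2] = ID_FIBRE
        field = np.zeros((5, 5))
        field[2, 2] = 0.99
        new_sigma, new_field, events = degrade_ecm(field, sigma)
        assert new_sigma[2, 2] == ID_FIBRE and not events

    def test_non_fibre_pixels_never_degraded(self):
        sigma = np.zeros((5, 5), dtype=np.int32)
        sigma[1, 1] = 3  # a cell
        field = np.full((5, 5), 2.0)
        new_sigma, new_field, events = degrade_ecm(field, sigma)
        assert new_sigma[1, 1] == 3
        assert np.allclose(new_field, 2.0)  # only fibre pixels decremented
        assert not events

    def test_event_count_by_enumeration(self):
        rng = np.random.default_rng(5)
        sigma = np.zeros((10, 10), dtype=np.int32)
        coords = [(i, j) for i in range(10) for j in range(10)]
        rng.shuffle(coords)
        field = np.zeros((10, 10))
        for (x, y) in coords[:7]:
            sigma[x, y] = ID_FIBRE
            field[x, y] = 1.0 + rng.random()
        for (x, y) in coords[7:12]:
            sigma[x, y] = ID_FIBRE
            field[x, y] = rng.random() * 0.99
        _, _, events = degrade_ecm(field, sigma)
        assert len(events) == 7


def test_secretion_mass_balance_through_engine():
    """With decay off and below-threshold fields, the engine's total MMP mass
    equals lambda * dt * (contact pixels) * substeps.

    The cell is walled in by fibres so no copy attempt is ever legal and the
    contact count stays exactly constant.
    """
    sigma = np.zeros((12, 12), dtype=np.int32)
    sigma[4:9, 4:9] = ID_FIBRE
    sigma[5:8, 5:8] = 1
    n_contacts = contact_fibre_pixels(sigma)[0].size
    assert n_contacts == 16
    lam = 1e-4  # small enough that no pixel ever reaches the threshold
    sim = Simulation(
        sigma, EnergyParams(),
        mmp=MMPParams(secretion_per_s=lam, decay_per_s=0.0), seed=1,
    )
    sim.run(10)
    assert sim.degradation_events == 0
    assert sim.accepted_total == 0
    assert sim.field.sum() == pytest.approx(10 * 36 * lam * n_contacts, abs=1e-9)
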