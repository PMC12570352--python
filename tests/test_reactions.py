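"""Reaction machinery: rate conversion, Gillespie lifetime sampling,
Doi firing probabilities, and execution semantics."""

import numpy as np
import pytest
from scipy import stats

from ridsim.molecules import define_molecule_type
from ridsim.propagation import Simulation
from ridsim.reactions import (
    BiChannel,
    BiPath,
    ReactionRegistry,
    UniChannel,
    UniPath,
    check_reaction_radius,
    k_macro,
    lambda_AB,
    sample_next_reaction_time,
    solve_k_micro,
)


class TestRateConversion:
    def test_lambda_zero_without_diffusion(self):
        assert lambda_AB(0.0, 0.0, 0.1) == 0.0

    def test_lambda_hand_value(self):
        # sqrt(4 * 1 * 0.25) = 1 nm
        assert lambda_AB(0.6, 0.4, 0.25) == pytest.approx(1.0)

    def test_warns_when_lambda_exceeds_reaction_radius(self):
        with pytest.warns(UserWarning, match="reaction"):
            check_reaction_radius(R_react=0.5, D_A=1.0, D_B=1.0, dt=1.0)

    def test_smoluchowski_limit(self):
        # k -> inf: k_macro -> 4 pi (DA+DB) R = 56.549 for D=1, R=4.5
        val = k_macro(1e12, 0.5, 0.5, 4.5)
        assert val == pytest.approx(4 * np.pi * 4.5, rel=1e-4)
        assert val == pytest.approx(56.549, abs=5e-3)

    def test_reaction_limited_limit(self):
        # k -> 0: k_macro -> (4/3) pi R^3 k
        k = 1e-8
        val = k_macro(k, 0.5, 0.5, 4.5)
        assert val == pytest.approx(4 / 3 * np.pi * 4.5**3 * k, rel=1e-4)

    def test_round_trip_inversion_over_log_grid(self):
        for k in np.logspace(-6, 3, 25):
            km = k_macro(k, 0.3, 0.7, 4.5)
            assert solve_k_micro(km, 0.3, 0.7, 4.5) == pytest.approx(k, rel=1e-9)

    def test_above_smoluchowski_bound_rejected(self):
        bound = 4 * np.pi * 1.0 * 4.5
        with pytest.raises(ValueError):
            solve_k_micro(bound * 1.01, 0.5, 0.5, 4.5)


class TestGillespieSampling:
    def test_plug_in_inverse_transform(self):
        class FixedU:
            def random(self):
                return float(np.exp(-2.0))

        # tau = ln(1/U)/k_t = 2/2 = 1 ns
        assert sample_next_reaction_time(2.0, FixedU()) == pytest.approx(1.0)

    def test_zero_rate_never_fires(self, rng):
        assert sample_next_reaction_time(0.0, rng) == np.inf

    def test_samples_exponential_by_ks(self, rng):
        draws = np.array([sample_next_reaction_time(2.0, rng)
                          for _ in range(50_000)])
        assert draws.mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(50_000))
        res = stats.ks_1samp(draws, stats.expon(scale=0.5).cdf)
        assert res.pvalue > 0.01

    def test_molecule_timers_exponential(self):
        # timers drawn at creation are exactly exponential (evaluated once,
        # not per step)
        sim = Simulation(box=[100.0] * 3, dt=0.1, seed=5)
        sim.register_species(define_molecule_type(
            "X", [[0, 0, 0]], [1.0], diffusion_constant=0.1))
        sim.reactions.add_uni(UniChannel("X", [UniPath("decay", rate=0.25)]))
        rng = np.random.default_rng(1)
        sim.add_molecules("X", rng.uniform(0, 100, size=(20_000, 3)))
        timers = sim.next_event[: sim.n].copy()
        res = stats.ks_1samp(timers, stats.expon(scale=4.0).cdf)
        assert res.pvalue > 0.01

    def test_two_equal_paths_chosen_evenly(self):
        sim = Simulation(box=[50.0] * 3, dt=1.0, seed=2)
        for name in ("X", "P", "Q"):
            sim.register_species(define_molecule_type(
                name, [[0, 0, 0]], [1.0], diffusion_constant=1e-6))
        sim.reactions.add_uni(UniChannel("X", [
            UniPath("conversion", rate=0.5, products=("P",)),
            UniPath("conversion", rate=0.5, products=("Q",)),
        ]))
        rng = np.random.default_rng(3)
        sim.add_molecules("X", rng.uniform(0, 50, size=(2000, 3)))
        sim.run(40)
        counts = sim.counts()
        n_p, n_q = counts["P"], counts["Q"]
        assert n_p + n_q + counts["X"] == 2000
        total = n_p + n_q
        assert total > 1800  # nearly all converted after 40 ns at k_t=1
        assert abs(n_p - total / 2) < 3 * np.sqrt(total * 0.25)


def _held_pairs_sim(n_pairs, r, k_doi, dt, R_react=2.0, seed=0):
    """Independent A-B pairs at fixed distance r, effectively frozen."""
    L = 12.0 * max(1, int(np.ceil(np.sqrt(n_pairs))))
    sim = Simulation(box=[L] * 3, dt=dt, seed=seed)
    for name in ("A", "B", "C"):
        sim.register_species(define_molecule_type(
            name, [[0, 0, 0]], [1.0], diffusion_constant=1e-12))
    sim.reactions.add_bi(BiChannel(("A", "B"), [
        BiPath("fusion", rate=k_doi, R_react=R_react, products=("C",)),
    ]))
    side = int(np.ceil(np.sqrt(n_pairs)))
    k = 0
    for i in range(side):
        for j in range(side):
            if k >= n_pairs:
                break
            base = np.array([6.0 + 12.0 * i, 6.0 + 12.0 * j, 6.0])
            sim.add_molecule("A", base)
            sim.add_molecule("B", base + [r, 0.0, 0.0])
            k += 1
    return sim


class TestDoiScheme:
    def test_zero_rate_gives_zero_probability(self):
        reg = ReactionRegistry()
        reg.add_bi(BiChannel(("A", "B"), [
            BiPath("fusion", rate=0.0, R_react=2.0, products=("C",))]))
        p, _ = reg.bi_probability("A", "B", 1.0, 0.1)
        assert p == 0.0

    def test_out_of_range_pair_never_fires(self):
        reg = ReactionRegistry()
        reg.add_bi(BiChannel(("A", "B"), [
            BiPath("fusion", rate=5.0, R_react=2.0, products=("C",))]))
        p, applicable = reg.bi_probability("A", "B", 2.5, 0.1)
        assert p == 0.0 and applicable == []

    def test_probability_half_at_k_dt_ln2(self):
        reg = ReactionRegistry()
        reg.add_bi(BiChannel(("A", "B"), [
            BiPath("fusion", rate=np.log(2.0), R_react=2.0, products=("C",))]))
        p, _ = reg.bi_probability("A", "B", 1.0, 1.0)
        assert p == pytest.approx(0.5)

    def test_empirical_firing_frequency_on_held_pairs(self):
        # k dt = ln 2 -> each in-range pair fires with p = 1/2 per step
        sim = _held_pairs_sim(400, r=1.0, k_doi=np.log(2.0), dt=1.0, seed=7)
        sim.initialize_forces()
        sim.step()
        n_c = sim.counts()["C"]
        assert abs(n_c - 200) < 3 * np.sqrt(400 * 0.25)

    def test_multiple_radii_gate_the_rate_sum(self):
        reg = ReactionRegistry()
        reg.add_bi(BiChannel(("A", "B"), [
            BiPath("fusion", rate=1.0, R_react=1.0, products=("C",)),
            BiPath("fusion", rate=3.0, R_react=3.0, products=("D",)),
        ]))
        p_near, app_near = reg.bi_probability("A", "B", 0.5, 0.1)
        p_far, app_far = reg.bi_probability("A", "B", 2.0, 0.1)
        assert len(app_near) == 2 and len(app_far) == 1
        assert p_near == pytest.approx(1 - np.exp(-0.4))
        assert p_far == pytest.approx(1 - np.exp(-0.3))


class TestExecutionSemantics:
    def test_fusion_stoichiometry_and_midpoint(self):
        sim = _held_pairs_sim(1, r=1.0, k_doi=50.0, dt=1.0, seed=1)
        a_pos = sim.pos[0].copy()
        sim.initialize_forces()
        sim.step()
        counts = sim.counts()
        assert (counts["A"], counts["B"], counts["C"]) == (0, 0, 1)
        np.testing.assert_allclose(sim.pos[0], a_pos + [0.5, 0, 0], atol=1e-5)

    def test_fission_places_products_at_dissociation_radius(self):
        sim = Simulation(box=[30.0] * 3, dt=0.5, seed=4)
        for name in ("C", "A", "B"):
            sim.register_species(define_molecule_type(
                name, [[0, 0, 0]], [1.0], diffusion_constant=1e-12))
        sim.reactions.add_uni(UniChannel("C", [
            UniPath("fission", rate=50.0, products=("A", "B"), radius=3.0)]))
        sim.add_molecule("C", [15.0, 15.0, 15.0])
        sim.run(10)
        counts = sim.counts()
        assert (counts["A"], counts["B"], counts["C"]) == (1, 1, 0)
        d = sim.pos[0] - sim.pos[1]
        assert np.linalg.norm(d) == pytest.approx(3.0, rel=1e-4)

    def test_particle_decay_retypes_in_place(self):
        sim = Simulation(box=[20.0] * 3, dt=0.5, seed=4)
        m = define_molecule_type("M", [[-1.0, 0, 0], [1.0, 0, 0]], [1.0, 1.0],
                                 particle_types=["m1", "m2"])
        sim.register_species(m)
        sim.reactions.add_uni(UniChannel("m2", level="particle",
                                         paths=[UniPath("decay", rate=50.0)]))
        mid = sim.add_molecule("M", [10.0, 10.0, 10.0])
        sim.run(10)
        assert sim.alive(mid)  # parent molecule survives
        names = sim._particle_type_names(int(sim.type_id[0]), mid)
        assert names == ["m1", "void"]

    def test_enzymatic_converts_substrate_keeps_enzyme(self):
        sim = Simulation(box=[20.0] * 3, dt=1.0, seed=2)
        for name in ("S", "E", "P"):
            sim.register_species(define_molecule_type(
                name, [[0, 0, 0]], [1.0], diffusion_constant=1e-12))
        sim.reactions.add_bi(BiChannel(("S", "E"), [
            BiPath("enzymatic", rate=50.0, R_react=2.0, products=("P",))]))
        sim.add_molecule("S", [10.0, 10, 10])
        sim.add_molecule("E", [11.0, 10, 10])
        sim.run(3)
        counts = sim.counts()
        assert (counts["S"], counts["E"], counts["P"]) == (0, 1, 1)

    def test_binding_registers_bond_and_unbinds(self):
        sim = Simulation(box=[20.0] * 3, dt=1.0, seed=2)
        for name in ("X", "Y"):
            sim.register_species(define_molecule_type(
                name, [[0, 0, 0]], [1.0], diffusion_constant=1e-12))
        sim.reactions.add_bi(BiChannel(("X", "Y"), [
            BiPath("binding", rate=50.0, R_react=2.0, bond_k=10.0,
                   unbind_rate=0.0)]))
        sim.add_molecule("X", [10.0, 10, 10])
        sim.add_molecule("Y", [11.2, 10, 10])
        sim.run(3)
        assert len(sim.bonds) == 1
        bond = next(iter(sim.bonds.values()))
        assert bond["k"] == 10.0 and bond["r0"] == pytest.approx(1.2, abs=0.15)

    def test_conflicting_events_one_reaction_per_molecule(self):
        # one A flanked by two in-range Bs with certain firing: exactly one
        # fusion happens, the other B survives
        sim = Simulation(box=[30.0] * 3, dt=1.0, seed=6)
        for name in ("A", "B", "C"):
            sim.register_species(define_molecule_type(
                name, [[0, 0, 0]], [1.0], diffusion_constant=1e-12))
        sim.reactions.add_bi(BiChannel(("A", "B"), [
            BiPath("fusion", rate=100.0, R_react=2.0, products=("C",))]))
        sim.add_molecule("A", [15.0, 15, 15])
        sim.add_molecule("B", [16.0, 15, 15])
        sim.add_molecule("B", [14.0, 15, 15])
        sim.initialize_forces()
        sim.step()
        counts = sim.counts()
        assert (counts["A"], counts["B"], counts["C"]) == (0, 1, 1)

    def test_production_emits_products_and_keeps_educt(self):
        sim = Simulation(box=[30.0] * 3, dt=0.5, seed=8)
        for name in ("F", "P"):
            sim.register_species(define_molecule_type(
                name, [[0, 0, 0]], [1.0], diffusion_constant=1e-12))
        sim.reactions.add_uni(UniChannel("F", [
            UniPath("production", rate=2.0, products=("P",), radius=1.5,
                    n_products=2)]))
        sim.add_molecule("F", [15.0, 15, 15])
        sim.run(20)
        counts = sim.counts()
        assert counts["F"] == 1
        assert counts["P"] >= 2
        # products placed on the shell at the emission radius
        d = np.linalg.norm(sim.pos[1: sim.n] - [15.0, 15, 15], axis=1)


class TestReactionGraph:
    def test_multipath_graph_has_four_fusion_paths_and_one_fission(self):
        from ridsim.systems import multipath_two_bead_system

        sim = multipath_two_bead_system()
        graph = sim.reactions.to_graph()
        fusion_edges = [e for e in graph["edges"] if e["kind"] == "fusion"]
        fission_edges = [e for e in graph["edges"] if e["kind"] == "fission"]
        assert len(fusion_edges) == 4
        assert len(fission_edges) == 1
        for e in graph["edges"]:
            for node in e["educts"] + e["products"]:
                assert node in graph["nodes"]

    def test_empty_registry_empty_graph(self):
        graph = ReactionRegistry().to_graph()
        assert graph == {"nodes": [], "edges": []}
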