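import numpy as np
import pytest

from gluebridge import forge
from gluebridge.bridges import (WaterBridge, count_direct_interface_hbonds,
                                enumerate_water_bridges)
from gluebridge.hbond import HBond, HBondCriteria, assign_donors_acceptors, detect_hbonds
from gluebridge.structio import select_atoms

from helpers import make_topology, networkx_bridge_oracle, water_coords, water_rows


def single_bridge_frame(order):
    """A noise-free frame whose only planted bridge has the given order."""
    spec = forge.InterfaceSpec(
        n_residues_per_chain=3,
        donor_sites={"A": (2,)}, acceptor_sites={"B": (2,)},
        n_bulk_waters=3, noise_sigma=0.0,
        bridges=(forge.PlantedBridge(2, 2, order=order, occupancy_target=1.0),))
    model = forge.build_interface_topology(spec)
    manifest = forge.simulate_bridge_schedule(spec.bridges, 1, seed=1)
    traj = forge.render_trajectory(model, manifest)
    topo = model.topology
    table = assign_donors_acceptors(topo, traj.coords[0])
    hbonds = detect_hbonds(traj.coords[0], table)
    g1 = select_atoms(topo, "chain A and not water")
    g2 = select_atoms(topo, "chain B and not water")
    return topo, hbonds, g1, g2


def linear_water_chain(n_waters):
    """Protein O ... n collinear waters ... protein O, every link 2.7 A, linear H's."""
    rows = [("OG", "O", "SER", "A", 1, False)]
    coords = [np.zeros(3)]
    x = 0.0
    for i in range(n_waters):
        x += 2.7
        rows.extend(water_rows(i + 1))
        # one H donated back along the chain, one donated forward
        coords.extend(water_coords([x, 0, 0], [-1, 0, 0], [1, 0.05, 0]))
    x += 2.7
    rows.append(("OG", "O", "SER", "B", 2, False))
    coords.append(np.array([x, 0.0, 0.0]))
    coords = np.asarray(coords)
    topo = make_topology(rows, coords)
    table = assign_donors_acceptors(topo, coords)
    hbonds = detect_hbonds(coords, table)
    g1 = [0]
    g2 = [topo.n_atoms - 1]
    return topo, hbonds, g1, g2


def random_hbond_graph(rng, n_waters=10):
    """A fabricated per-frame hydrogen-bond list over a tiny interface."""
    rows = []
    for r in range(1, 4):
        rows.append(("O", "O", "GLY", "A", r, False))
    for r in range(1, 4):
        rows.append(("O", "O", "GLY", "B", r, False))
    for w in range(1, n_waters + 1):
        rows.extend(water_rows(w))
    topo = make_topology(rows)
    prot = list(range(6))
    water_o = [6 + 3 * k for k in range(n_waters)]
    hbonds = []
    for p in prot:
        for wo in water_o:
            if rng.random() < 0.25:
                d, a = (p, wo) if rng.random() < 0.5 else (wo, p)
                hbonds.append(HBond(d, None, a, 0, 2.8, 160.0))
    for i, w1 in enumerate(water_o):
        for w2 in water_o[i + 1:]:
            if rng.random() < 0.2:
                hbonds.append(HBond(w1, None, w2, 0, 2.8, 160.0))
    for p1 in prot[:3]:
        for p2 in prot[3:]:
            if rng.random() < 0.15:  # direct inter-protein bonds
                hbonds.append(HBond(p1, None, p2, 0, 2.9, 150.0))
    return topo, hbonds, prot[:3], prot[3:]


class TestEnumerateWaterBridges:
    def test_planted_order1_bridge_found_exactly_once(self):
        topo, hbonds, g1, g2 = single_bridge_frame(order=1)
        bridges = enumerate_water_bridges(hbonds, topo, g1, g2)
        assert len(bridges) == 1
        assert bridges[0].order == 1

    def test_planted_order2_bridge_has_mutually_bonded_waters(self):
        topo, hbonds, g1, g2 = single_bridge_frame(order=2)
        bridges = enumerate_water_bridges(hbonds, topo, g1, g2)
        assert len(bridges) == 1
        (b,) = bridges
        assert b.order == 2 and len(b.waters) == 2
        w1, w2 = b.waters
        wmap = topo.water_molecules()
        o1, o2 = wmap[w1][0], wmap[w2][0]
        linked = any({hb.donor, hb.acceptor} == {o1, o2} for hb in hbonds)
        assert linked, "the two mediating waters must be hydrogen-bonded to each other"

    def test_three_water_chain_is_not_a_bridge(self):
        topo, hbonds, g1, g2 = linear_water_chain(3)
        assert enumerate_water_bridges(hbonds, topo, g1, g2) == []

    def test_two_water_chain_is_a_bridge(self):
        topo, hbonds, g1, g2 = linear_water_chain(2)
        bridges = enumerate_water_bridges(hbonds, topo, g1, g2)
        assert len(bridges) == 1 and bridges[0].order == 2

    def test_matches_exhaustive_path_oracle_on_random_graphs(self, rng):
        for _ in range(50):
            topo, hbonds, g1, g2 = random_hbond_graph(rng, n_waters=int(rng.integers(4, 13)))
            got = {(b.atom1, b.atom2, b.water_set)
                   for b in enumerate_water_bridges(hbonds, topo, g1, g2)}
            assert got == networkx_bridge_oracle(hbonds, topo, g1, g2)

    def test_symmetric_under_group_swap(self, rng):
        topo, hbonds, g1, g2 = random_hbond_graph(rng)
        fwd = {(b.atom1, b.atom2, b.water_set)
               for b in enumerate_water_bridges(hbonds, topo, g1, g2)}
        rev = {(b.atom2, b.atom1, b.water_set)
               for b in enumerate_water_bridges(hbonds, topo, g2, g1)}
        assert fwd == rev

    def test_shared_fork_interpretation_is_optional(self):
        # two waters each bonded to one side, no mutual water-water bond
        rows = [("O", "O", "GLY", "A", 1, False), ("O", "O", "GLY", "B", 1, False)]
        rows += water_rows(1) + water_rows(2)
        topo = make_topology(rows)
        hbonds = [HBond(0, None, 2, 0, 2.8, 160.0), HBond(5, None, 1, 0, 2.8, 160.0)]
        assert enumerate_water_bridges(hbonds, topo, [0], [1]) == []
        forked = enumerate_water_bridges(hbonds, topo, [0], [1],
                                         require_water_water_link=False)
        assert len(forked) == 1 and forked[0].order == 2

    def test_reported_links_are_verifiable_hbonds(self, holo_run):
        """Every link of every reported bridge re-checks as a geometric H-bond."""
        model, manifest, traj = holo_run
        topo = model.topology
        table = assign_donors_acceptors(topo, traj.coords[0])
        g1 = select_atoms(topo, "chain A and not water")
        g2 = select_atoms(topo, "chain B and not water")
        wmap = topo.water_molecules()
        checked = 0
        for f in range(0, 50):
            hbonds = detect_hbonds(traj.coords[f], table, frame=f)
            pairs = {frozenset((hb.donor, hb.acceptor)) for hb in hbonds}
            for b in enumerate_water_bridges(hbonds, topo, g1, g2):
                chain = [b.atom1] + [wmap[w][0] for w in b.waters] + [b.atom2]
                for u, v in zip(chain, chain[1:]):
                    assert frozenset((u, v)) in pairs
                    checked += 1
        assert checked > 0

    def test_rejects_overlapping_groups(self, rng):
        topo, hbonds, g1, g2 = random_hbond_graph(rng)
        with pytest.raises(ValueError):
            enumerate_water_bridges(hbonds, topo, g1, g1)


class TestDirectInterfaceHbonds:
    def test_separated_chains_have_no_direct_bonds(self, holo_run):
        model, _, traj = holo_run
        topo = model.topology
        table = assign_donors_acceptors(topo, traj.coords[0])
        g1 = select_atoms(topo, "chain A and not water")
        g2 = select_atoms(topo, "chain B and not water")
        hbonds = detect_hbonds(traj.coords[0], table)
        assert count_direct_interface_hbonds(hbonds, g1, g2) == 0

    def test_engineered_direct_contact_counts_once(self):
        rows = [("OG", "O", "SER", "A", 1, False), ("HG", "H", "SER", "A", 1, False),
                ("O", "O", "GLY", "B", 2, False)]
        coords = np.array([[0.0, 0, 0], [0.96, 0, 0], [2.8, 0, 0]])
        topo = make_topology(rows, coords)
        table = assign_donors_acceptors(topo, coords)
        hbonds = detect_hbonds(coords, table)
        assert count_direct_interface_hbonds(hbonds, [0], [2]) == 1

    def test_equals_manual_filter_on_random_frames(self, rng):
        for _ in range(50):
            topo, hbonds, g1, g2 = random_hbond_graph(rng)
            got = count_direct_interface_hbonds(hbonds, g1, g2)
            g1s, g2s = set(g1), set(g2)
            want = sum(1 for hb in hbonds
                       if (hb.donor in g1s and hb.acceptor in g2s)
                       or (hb.donor in g2s and hb.acceptor in g1s))
            assert got == want
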