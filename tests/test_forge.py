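import numpy as np
import pytest

from gluebridge import forge
from gluebridge.flex import rmsf_profile
from gluebridge.pipeline import analyze_replica
from gluebridge.structio import select_atoms


class TestInterfaceSpecValidation:
    def test_negative_noise_rejected_with_named_invariant(self):
        with pytest.raises(ValueError, match="noise_sigma"):
            forge.InterfaceSpec(noise_sigma=-1.0)

    def test_too_small_separation_rejected(self):
        with pytest.raises(ValueError, match="chain_separation"):
            forge.InterfaceSpec(chain_separation=5.0)

    def test_bridge_endpoint_must_be_declared_site(self):
        with pytest.raises(ValueError, match="site"):
            forge.InterfaceSpec(bridges=(forge.PlantedBridge(2, 2),))

    def test_markov_stationarity_enforced(self):
        with pytest.raises(ValueError, match="stationary"):
            forge.PlantedBridge(1, 1, schedule_kind="markov",
                                occupancy_target=0.5, p_on=0.1, p_off=0.3)
        b = forge.PlantedBridge.markov(1, 1, occupancy=0.25, mean_on_frames=10)
        assert b.p_on / (b.p_on + b.p_off) == pytest.approx(0.25, abs=1e-12)


class TestBuildInterfaceTopology:
    def test_minimal_build_matches_spec(self):
        spec = forge.InterfaceSpec(n_residues_per_chain=2, n_bulk_waters=5)
        model = forge.build_interface_topology(spec)
        topo = model.topology
        assert set(topo.chain) == {"A", "B", "W"}
        assert len(topo.water_molecules()) == 5
        # every donor (N/O with H) has at least one attached hydrogen
        for heavy, hs in topo.h_attach.items():
            assert len(hs) >= 1
            assert topo.element[heavy] in ("N", "O")
        # residue numbering is 1-based per chain
        for chain in ("A", "B"):
            nums = sorted({int(topo.resnum[i]) for i in range(topo.n_atoms)
                           if topo.chain[i] == chain})
            assert nums == [1, 2]

    def test_same_spec_builds_identical_topologies(self):
        spec = forge.paper_like_scenario("apo")
        m1 = forge.build_interface_topology(spec)
        m2 = forge.build_interface_topology(spec)
        assert np.array_equal(m1.base_coords, m2.base_coords)
        assert list(m1.topology.name) == list(m2.topology.name)
        assert m1.bridge_waters == m2.bridge_waters

    def test_geometrically_infeasible_bridge_rejected_at_build(self):
        # endpoints five residues apart: far beyond an order-1 water's reach
        spec = dict(
            n_residues_per_chain=6,
            donor_sites={"A": (1,)}, acceptor_sites={"B": (6,)},
            bridges=(forge.PlantedBridge(1, 6, order=1, occupancy_target=0.5),))
        with pytest.raises(forge.GeometryError, match="order-1"):
            forge.build_interface_topology(forge.InterfaceSpec(**spec))


class TestBridgeSchedule:
    def test_full_occupancy_is_always_on(self):
        b = forge.PlantedBridge(1, 1, occupancy_target=1.0)
        man = forge.simulate_bridge_schedule([b], 100, seed=2)
        assert man.on[0].all() and man.realized_occupancy[0] == 1.0

    def test_bernoulli_realized_occupancy_within_binomial_bound(self):
        b = forge.PlantedBridge(1, 1, occupancy_target=0.7)
        man = forge.simulate_bridge_schedule([b], 2000, seed=11)
        assert abs(man.realized_occupancy[0] - 0.7) <= 3 * np.sqrt(0.7 * 0.3 / 2000)

    def test_same_seed_gives_identical_records(self):
        bridges = [forge.PlantedBridge(1, 1, occupancy_target=0.4),
                   forge.PlantedBridge.markov(2, 2, 0.3, mean_on_frames=8)]
        m1 = forge.simulate_bridge_schedule(bridges, 500, seed=9)
        m2 = forge.simulate_bridge_schedule(bridges, 500, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(m1.on, m2.on))

    def test_markov_schedule_hits_target_occupancy(self):
        b = forge.PlantedBridge.markov(1, 1, 0.4, mean_on_frames=10)
        man = forge.simulate_bridge_schedule([b], 5000, seed=13)
        # autocorrelated draws: allow a generous tolerance
        assert abs(man.realized_occupancy[0] - 0.4) < 0.08

    def test_manifest_round_trips_through_text_file(self, tmp_path):
        bridges = (forge.PlantedBridge(2, 2, order=2, occupancy_target=0.5),)
        man = forge.simulate_bridge_schedule(bridges, 50, seed=4)
        man.water_ids = [(("W", 1), ("W", 2))]
        path = tmp_path / "m.txt"
        man.save(path)
        back = forge.TruthManifest.load(path)
        assert back.seed == man.seed and back.n_frames == 50
        assert back.pairs == man.pairs and back.orders == man.orders
        assert back.water_ids == man.water_ids
        assert np.array_equal(back.on[0], man.on[0])


class TestRenderTrajectory:
    def test_always_on_bridge_found_in_every_frame(self):
        spec = forge.InterfaceSpec(
            n_residues_per_chain=3, donor_sites={"A": (2,)},
            acceptor_sites={"B": (2,)}, n_bulk_waters=2, noise_sigma=0.0,
            bridges=(forge.PlantedBridge(2, 2, occupancy_target=1.0),))
        model = forge.build_interface_topology(spec)
        man = forge.simulate_bridge_schedule(spec.bridges, 20, seed=1)
        traj = forge.render_trajectory(model, man)
        (stat,), _ = analyze_replica(model, traj.coords)
        assert stat.occupancy == 1.0

    def test_static_limit_all_frames_identical_rmsf_zero(self):
        spec = forge.InterfaceSpec(
            n_residues_per_chain=3, donor_sites={"A": (2,)},
            acceptor_sites={"B": (2,)}, n_bulk_waters=2, noise_sigma=0.0,
            rigid_body_amplitude=0.0,
            bridges=(forge.PlantedBridge(2, 2, occupancy_target=1.0),))
        model = forge.build_interface_topology(spec)
        man = forge.simulate_bridge_schedule(spec.bridges, 10, seed=1)
        traj = forge.render_trajectory(model, man)
        assert np.all(traj.coords == traj.coords[0])
        sel = select_atoms(model.topology, "backbone")
        prof = rmsf_profile(traj.coords, model.topology, sel)
        assert np.allclose(prof.rmsf_per_residue, 0.0)

    def test_seed_determinism_gives_byte_identical_files(self, tmp_path, holo_model):
        spec = holo_model.spec
        paths = []
        for name in ("a.pdb", "b.pdb"):
            man = forge.simulate_bridge_schedule(spec.bridges, 15, seed=21)
            p = tmp_path / name
            forge.render_trajectory(holo_model, man, out_path=p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_modest_wobble_does_not_break_planted_bridges(self):
        """Waters are placed after the rigid-body move, so a wobble small
        relative to the cutoff margin leaves the planted links intact."""
        spec = forge.InterfaceSpec(
            n_residues_per_chain=3, donor_sites={"A": (2,)},
            acceptor_sites={"B": (2,)}, n_bulk_waters=2, noise_sigma=0.0,
            rigid_body_amplitude=0.2,
            bridges=(forge.PlantedBridge(2, 2, occupancy_target=1.0),))
        model = forge.build_interface_topology(spec)
        man = forge.simulate_bridge_schedule(spec.bridges, 30, seed=3)
        traj = forge.render_trajectory(model, man)
        (stat,), _ = analyze_replica(model, traj.coords)
        assert stat.occupancy == 1.0

    @pytest.mark.parametrize("seed", [101, 202, 303, 404, 505])
    def test_manifest_statistics_equal_pipeline_statistics_noise_free(self, seed):
        """Round trip: manifest-only statistics == full-pipeline statistics at sigma=0."""
        rng = np.random.default_rng(seed)
        spec, manifest, model = forge.random_scenario(rng, n_frames=150,
                                                      noise_sigma=0.0)
        traj = forge.render_trajectory(model, manifest)
        stats, _ = analyze_replica(model, traj.coords)
        truth = forge.manifest_pair_statistics(manifest, model)
        est = {s.pair.label: (s.occupancy, s.frequency) for s in stats}
        truth = {k: v for k, v in truth.items() if v[0] > 0}
        assert est.keys() == truth.keys()
        for k, (occ, freq) in truth.items():
            assert est[k][0] == pytest.approx(occ, abs=1e-12)
            assert est[k][1] == pytest.approx(freq, abs=1e-12)
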