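import numpy as np
import pytest

from gluebridge import forge
from gluebridge.bridges import WaterBridge
from gluebridge.bridgestats import (PairStatistic, apply_persistence_filter,
                                    compare_apo_holo, pair_statistics)
from gluebridge.pipeline import analyze_replica

from helpers import make_topology, water_rows


@pytest.fixture()
def tiny_topology():
    rows = [("O", "O", "SER", "A", 1, False), ("O", "O", "THR", "B", 7, False)]
    rows += water_rows(1) + water_rows(2)
    return make_topology(rows)


def make_stat(label_res1, occupancy, frequency, n_frames=100, **kw):
    from gluebridge.bridges import PairKey
    counts = np.zeros(n_frames, dtype=int)
    n_on = round(occupancy * n_frames)
    counts[:n_on] = 1
    extra = round((frequency - occupancy) * n_frames)
    counts[:extra] += 1
    pk = PairKey("A", "SER", label_res1, "B", "THR", 7)
    return PairStatistic(pair=pk, n_frames=n_frames,
                         occupancy=np.count_nonzero(counts) / n_frames,
                         frequency=counts.sum() / n_frames,
                         mean_order=1.0, path_counts=counts, **kw)


class TestPairStatistics:
    def test_two_waters_on_same_pair_give_frequency_above_one(self, tiny_topology):
        # w1 bridges in all 100 frames, w2 additionally in the first 50
        bridges = [WaterBridge(0, 1, (("W", 1),), f) for f in range(100)]
        bridges += [WaterBridge(0, 1, (("W", 2),), f) for f in range(50)]
        (stat,) = pair_statistics(bridges, tiny_topology, 100)
        assert stat.occupancy == pytest.approx(1.0)
        assert stat.frequency == pytest.approx(1.5)
        assert stat.pair.label == "Ser1-Thr7"

    def test_no_bridges_yield_empty_list(self, tiny_topology):
        assert pair_statistics([], tiny_topology, 10) == []

    def test_duplicate_water_sets_within_frame_count_once(self, tiny_topology):
        # same water path reported between two atom pairs of one residue pair
        bridges = [WaterBridge(0, 1, (("W", 1),), 0),
                   WaterBridge(0, 1, (("W", 1),), 0)]
        (stat,) = pair_statistics(bridges, tiny_topology, 1)
        assert stat.frequency == pytest.approx(1.0)

    def test_order1_and_order2_paths_via_same_first_water_are_distinct(self, tiny_topology):
        bridges = [WaterBridge(0, 1, (("W", 1),), 0),
                   WaterBridge(0, 1, (("W", 1), ("W", 2)), 0)]
        (stat,) = pair_statistics(bridges, tiny_topology, 1)
        assert stat.frequency == pytest.approx(2.0)

    def test_frequency_never_below_occupancy(self, rng, tiny_topology):
        for _ in range(20):
            n_frames = 50
            bridges = []
            for f in range(n_frames):
                for w in (1, 2):
                    if rng.random() < 0.4:
                        bridges.append(WaterBridge(0, 1, (("W", w),), f))
            for stat in pair_statistics(bridges, tiny_topology, n_frames):
                assert stat.frequency >= stat.occupancy

    def test_invariant_under_frame_reordering(self, rng, tiny_topology):
        bridges = [WaterBridge(0, 1, (("W", 1),), f) for f in range(0, 60, 3)]
        shuffled = list(bridges)
        rng.shuffle(shuffled)
        a = pair_statistics(bridges, tiny_topology, 60)[0]
        b = pair_statistics(shuffled, tiny_topology, 60)[0]
        assert (a.occupancy, a.frequency) == (b.occupancy, b.frequency)

    def test_rejects_zero_frames(self, tiny_topology):
        with pytest.raises(ValueError):
            pair_statistics([], tiny_topology, 0)

    def test_bernoulli_planted_occupancy_within_99pct_ci(self):
        spec = forge.InterfaceSpec(
            n_residues_per_chain=3, donor_sites={"A": (2,)}, acceptor_sites={"B": (2,)},
            n_bulk_waters=4,
            bridges=(forge.PlantedBridge(2, 2, occupancy_target=0.6),))
        model = forge.build_interface_topology(spec)
        manifest = forge.simulate_bridge_schedule(spec.bridges, 2000, seed=5)
        traj = forge.render_trajectory(model, manifest)
        (stat,), _ = analyze_replica(model, traj.coords)
        ci = 2.576 * np.sqrt(0.6 * 0.4 / 2000)
        assert abs(stat.occupancy - 0.6) <= ci


class TestPersistenceFilter:
    def test_twenty_percent_boundary_is_inclusive(self):
        below = make_stat(1, occupancy=0.19, frequency=0.19)
        at = make_stat(2, occupancy=0.20, frequency=0.20)
        kept = apply_persistence_filter([below, at], threshold=0.20)
        assert [s.pair.resnum1 for s in kept] == [2]

    def test_zero_threshold_is_identity(self):
        stats = [make_stat(1, 0.05, 0.05), make_stat(2, 0.9, 1.2)]
        assert apply_persistence_filter(stats, threshold=0.0) == stats

    def test_filter_is_idempotent(self):
        stats = [make_stat(i, occ, occ) for i, occ in enumerate([0.1, 0.2, 0.5, 0.9])]
        once = apply_persistence_filter(stats, 0.2)
        assert apply_persistence_filter(once, 0.2) == once

    def test_longest_run_mode_differs_from_occupancy_mode(self):
        counts = np.zeros(100, dtype=int)
        counts[::2] = 1  # 50% occupancy but no run longer than 1 frame
        from gluebridge.bridges import PairKey
        s = PairStatistic(PairKey("A", "SER", 1, "B", "THR", 7), 100,
                          occupancy=0.5, frequency=0.5, mean_order=1.0,
                          path_counts=counts)
        assert apply_persistence_filter([s], 0.2, mode="occupancy") == [s]
        assert apply_persistence_filter([s], 0.2, mode="longest_run") == []

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_persistence_filter([], threshold=1.5)


class TestCompareApoHolo:
    def test_identical_inputs_give_zero_differences(self):
        reps = [[make_stat(1, 0.5, 0.7)], [make_stat(1, 0.4, 0.6)]]
        table = compare_apo_holo(reps, reps)
        assert np.allclose(table["dfreq_mean"], 0.0)

    def test_pair_present_only_in_holo_is_retained_with_zero_apo(self):
        apo = [[make_stat(1, 0.5, 0.5)]]
        holo = [[make_stat(1, 0.5, 0.5), make_stat(2, 0.8, 1.1)]]
        table = compare_apo_holo(apo, holo)
        assert "Ser2-Thr7" in table.index
        assert table.loc["Ser2-Thr7", "apo_freq_mean"] == 0.0
        assert table.loc["Ser2-Thr7", "dfreq_mean"] == pytest.approx(1.1)

    def test_table_contains_only_persistent_pairs(self):
        apo = [[make_stat(1, 0.05, 0.05)]]
        holo = [[make_stat(1, 0.10, 0.10)]]
        table = compare_apo_holo(apo, holo, persistence_threshold=0.2)
        assert len(table) == 0

    def test_disjoint_residue_numbering_warns(self):
        from gluebridge.bridges import PairKey
        a = make_stat(1, 0.5, 0.5)
        counts = np.ones(100, dtype=int)
        b = PairStatistic(PairKey("A", "SER", 900, "B", "THR", 950), 100,
                          occupancy=1.0, frequency=1.0, mean_order=1.0,
                          path_counts=counts)
        with pytest.warns(UserWarning, match="disjoint"):
            compare_apo_holo([[a]], [[b]])

    def test_planted_apo_holo_contrast_recovered_in_every_replica(self):
        """A pair planted at high holo / low apo occupancy shows dfreq > 0."""
        stats = {}
        for condition, occ in (("apo", 0.2), ("holo", 0.8)):
            spec = forge.InterfaceSpec(
                n_residues_per_chain=3, donor_sites={"A": (2,)},
                acceptor_sites={"B": (2,)}, n_bulk_waters=4,
                bridges=(forge.PlantedBridge(2, 2, occupancy_target=occ),))
            model = forge.build_interface_topology(spec)
            reps = []
            for rep in range(3):
                manifest = forge.simulate_bridge_schedule(spec.bridges, 300,
                                                          seed=37 + rep)
                traj = forge.render_trajectory(model, manifest)
                s, _ = analyze_replica(model, traj.coords, replica=f"rep{rep}",
                                       condition=condition)
                reps.append(s)
            stats[condition] = reps
        table = compare_apo_holo(stats["apo"], stats["holo"], persistence_threshold=0.0)
        dcols = [c for c in table.columns if c.startswith("dfreq_rep")]
        assert (table[dcols].to_numpy() > 0).all()
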