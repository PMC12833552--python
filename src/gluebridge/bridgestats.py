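"""Summary statistics of water-mediated bridges and apo/holo comparison.

For each residue pair the *occupancy* is the fraction of frames in which at
least one water path connects the two residues, and the *frequency of
occurrence* is the mean number of distinct water paths per frame.  A
frequency above one means that two (or more) separate water molecules bridge
the same residue pair simultaneously.  A persistence filter keeps only pairs
whose bridge lasted for at least a given fraction (default 20%) of the
simulation length.  Replicas are never pooled: statistics are computed per
replica and combined across replicas as mean +/- SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from gluebridge.bridges import PairKey, WaterBridge
from gluebridge.structio import Topology

__all__ = [
    "PairStatistic",
    "pair_statistics",
    "apply_persistence_filter",
    "compare_apo_holo",
    "stats_to_frame",
]


@dataclass(eq=False)
class PairStatistic:
    """Per residue-pair bridge statistics over one trajectory (one replica).

    ``path_counts[f]`` is the number of distinct water paths (distinct water
    sets, any atoms of the two residues) bridging the pair in frame ``f``;
    it is retained so that run-length-based persistence variants can be
    computed without re-reading the trajectory.
    """

    pair: PairKey
    n_frames: int
    occupancy: float
    frequency: float
    mean_order: float
    path_counts: np.ndarray = field(repr=False)
    replica: Optional[str] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must be in [0, 1]")
        if self.frequency + 1e-12 < self.occupancy:
            raise ValueError("frequency of occurrence cannot be below occupancy")

    @property
    def longest_run(self) -> int:
        """Longest contiguous stretch of frames with the bridge present."""
        present = self.path_counts > 0
        best = cur = 0
        for p in present:
            cur = cur + 1 if p else 0
            best = max(best, cur)
        return best


def pair_statistics(bridges: Iterable[WaterBridge], topology: Topology, n_frames: int,
                    replica: Optional[str] = None,
                    condition: Optional[str] = None) -> List[PairStatistic]:
    """Aggregate per-frame bridges into residue-pair statistics.

    Distinctness of paths is judged by the set of mediating waters: within a
    frame, an order-1 path through w1 and an order-2 path through {w1, w2}
    between the same residue pair are two distinct paths, while the same
    water set connecting two different atom pairs of the same residue pair
    counts once.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    per_pair_frame_paths: Dict[PairKey, Dict[int, set]] = {}
    per_pair_orders: Dict[PairKey, List[int]] = {}
    for b in bridges:
        if not (0 <= b.frame < n_frames):
            raise ValueError(f"bridge frame {b.frame} outside [0, {n_frames})")
        pk = b.pair_key(topology)
        frame_paths = per_pair_frame_paths.setdefault(pk, {})
        paths = frame_paths.setdefault(b.frame, set())
        if b.water_set not in paths:
            paths.add(b.water_set)
            per_pair_orders.setdefault(pk, []).append(b.order)

    out: List[PairStatistic] = []
    for pk in sorted(per_pair_frame_paths):
        counts = np.zeros(n_frames, dtype=int)
        for f, paths in per_pair_frame_paths[pk].items():
            counts[f] = len(paths)
        out.append(PairStatistic(
            pair=pk,
            n_frames=n_frames,
            occupancy=float(np.count_nonzero(counts) / n_frames),
            frequency=float(counts.sum() / n_frames),
            mean_order=float(np.mean(per_pair_orders[pk])),
            path_counts=counts,
            replica=replica,
            condition=condition,
        ))
    return out


def apply_persistence_filter(stats: Sequence[PairStatistic], threshold: float = 0.20,
                             mode: str = "occupancy") -> List[PairStatistic]:
    """Keep pairs that persisted for at least ``threshold`` of the trajectory.

    ``mode="occupancy"`` (default) reads persistence as total occupancy >=
    threshold, inclusive -- the standard reading of "lasted for at least 20%
    of the simulation length" in trajectory hydrogen-bond analysis.
    ``mode="longest_run"`` instead requires a single contiguous run of at
    least ``threshold * n_frames`` frames.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("persistence threshold must be in [0, 1]")
    if mode == "occupancy":
        return [s for s in stats if s.occupancy >= threshold]
    if mode == "longest_run":
        return [s for s in stats if s.longest_run >= threshold * s.n_frames]
    raise ValueError(f"unknown persistence mode {mode!r}")


def _warn_on_numbering_mismatch(apo_pairs: Iterable[PairKey], holo_pairs: Iterable[PairKey]) -> None:
    """Warn when the same chain uses disjoint residue ranges in the two inputs."""
    def ranges(pairs):
        r: Dict[str, List[int]] = {}
        for p in pairs:
            r.setdefault(p.chain1, []).append(p.resnum1)
            r.setdefault(p.chain2, []).append(p.resnum2)
        return r

    ra, rh = ranges(apo_pairs), ranges(holo_pairs)
    for chain in set(ra) & set(rh):
        if min(ra[chain]) > max(rh[chain]) or min(rh[chain]) > max(ra[chain]):
            warnings.warn(
                f"chain {chain}: apo and holo residue numbers occupy disjoint ranges "
                f"({min(ra[chain])}-{max(ra[chain])} vs {min(rh[chain])}-{max(rh[chain])}); "
                "check that both conditions use the same numbering convention"
            )


def compare_apo_holo(stats_apo: Sequence[Sequence[PairStatistic]],
                     stats_holo: Sequence[Sequence[PairStatistic]],
                     persistence_threshold: float = 0.20) -> pd.DataFrame:
    """Build the apo-vs-holo comparison table over replicas.

    Parameters
    ----------
    stats_apo, stats_holo : one list of :class:`PairStatistic` per replica.
    persistence_threshold : the filter is applied per replica per condition;
        a pair enters the table if it passes in at least one replica of at
        least one condition.  Frequencies of absent pairs are reported as 0.

    Returns
    -------
    DataFrame indexed by pair label with per-replica apo/holo frequencies,
    per-condition mean +/- SD, per-replica ``dfreq`` (holo - apo, replicas
    paired positionally) and its mean +/- SD.  SDs use ddof=1 and are 0 for
    a single replica.
    """
    all_apo = [s for rep in stats_apo for s in rep]
    all_holo = [s for rep in stats_holo for s in rep]
    _warn_on_numbering_mismatch((s.pair for s in all_apo), (s.pair for s in all_holo))

    kept: set = set()
    for rep in list(stats_apo) + list(stats_holo):
        for s in apply_persistence_filter(rep, persistence_threshold):
            kept.add(s.pair)
    kept_sorted = sorted(kept)

    def freq_matrix(stats_reps, pairs) -> np.ndarray:
        m = np.zeros((len(pairs), len(stats_reps)))
        index = {p: i for i, p in enumerate(pairs)}
        for r, rep in enumerate(stats_reps):
            for s in rep:
                if s.pair in index:
                    m[index[s.pair], r] = s.frequency
        return m

    fa = freq_matrix(stats_apo, kept_sorted)
    fh = freq_matrix(stats_holo, kept_sorted)

    def sd(m):
        return m.std(axis=1, ddof=1) if m.shape[1] > 1 else np.zeros(m.shape[0])

    data: Dict[str, np.ndarray] = {}
    for r in range(fa.shape[1]):
        data[f"apo_freq_rep{r + 1}"] = fa[:, r]
    for r in range(fh.shape[1]):
        data[f"holo_freq_rep{r + 1}"] = fh[:, r]
    data["apo_freq_mean"] = fa.mean(axis=1) if fa.size else np.zeros(len(kept_sorted))
    data["apo_freq_sd"] = sd(fa) if fa.size else np.zeros(len(kept_sorted))
    data["holo_freq_mean"] = fh.mean(axis=1) if fh.size else np.zeros(len(kept_sorted))
    data["holo_freq_sd"] = sd(fh) if fh.size else np.zeros(len(kept_sorted))
    if fa.shape[1] == fh.shape[1] and fa.shape[1] > 0:
        d = fh - fa
        for r in range(d.shape[1]):
            data[f"dfreq_rep{r + 1}"] = d[:, r]
        data["dfreq_mean"] = d.mean(axis=1)
        data["dfreq_sd"] = sd(d)
    else:
        data["dfreq_mean"] = data["holo_freq_mean"] - data["apo_freq_mean"]

    df = pd.DataFrame(data, index=[p.label for p in kept_sorted])
    df.index.name = "pair"
    return df


def stats_to_frame(stats: Sequence[PairStatistic]) -> pd.DataFrame:
    """Tabulate PairStatistics (one row per pair) for TSV export."""
    rows = []
    for s in stats:
        rows.append({
            "pair": s.pair.label,
            "chain1": s.pair.chain1, "resnum1": s.pair.resnum1,
            "chain2": s.pair.chain2, "resnum2": s.pair.resnum2,
            "condition": s.condition, "replica": s.replica,
            "n_frames": s.n_frames,
            "occupancy": s.occupancy,
            "frequency": s.frequency,
            "mean_order": s.mean_order,
        })
    return pd.DataFrame(rows)
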