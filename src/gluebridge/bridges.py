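"""Water-mediated hydrogen-bond bridges across a protein-protein interface.

A bridge of order *k* connects an atom of one protein to an atom of the
other protein through *k* intervening water molecules, every consecutive
link being a geometric hydrogen bond in that frame.  Orders 1 and 2 are
enumerated (a path through three or more waters is not a bridge).  Direction
along the path is ignored by default: either member of a link may be the
donor, because the interaction names an atom pair, not a directed chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from gluebridge.hbond import HBond
from gluebridge.structio import Topology

__all__ = [
    "WaterBridge",
    "PairKey",
    "enumerate_water_bridges",
    "count_direct_interface_hbonds",
    "bridges_to_rows",
]

ResidueKey = Tuple[str, str, int]  # (chain, resname, resnum)
WaterId = Tuple[str, int]          # (chain, resnum) of the water molecule


@dataclass(frozen=True, order=True)
class PairKey:
    """Canonically ordered residue-level identifier of an interface pair.

    The group-1 residue (by convention the effector protein, e.g. FKBP12)
    comes first, matching the field's naming scheme "Lys48-Tyr2105" (first
    residue in the effector, second in the target protein).
    """

    chain1: str
    resname1: str
    resnum1: int
    chain2: str
    resname2: str
    resnum2: int

    @classmethod
    def from_residues(cls, res1: ResidueKey, res2: ResidueKey) -> "PairKey":
        return cls(res1[0], res1[1], res1[2], res2[0], res2[1], res2[2])

    @property
    def label(self) -> str:
        return (f"{self.resname1.capitalize()}{self.resnum1}-"
                f"{self.resname2.capitalize()}{self.resnum2}")

    def swapped(self) -> "PairKey":
        return PairKey(self.chain2, self.resname2, self.resnum2,
                       self.chain1, self.resname1, self.resnum1)


@dataclass(frozen=True)
class WaterBridge:
    """One water-mediated path between the two proteins in one frame.

    ``atom1``/``atom2`` are topology indices of the protein heavy atoms
    (atom1 in group 1); ``waters`` is the ordered path of water molecule ids
    from the group-1 side to the group-2 side (length = order, 1 or 2).
    """

    atom1: int
    atom2: int
    waters: Tuple[WaterId, ...]
    frame: int

    @property
    def order(self) -> int:
        return len(self.waters)

    @property
    def water_set(self) -> FrozenSet[WaterId]:
        return frozenset(self.waters)

    def pair_key(self, topology: Topology) -> PairKey:
        return PairKey.from_residues(topology.residue_key(self.atom1),
                                     topology.residue_key(self.atom2))


def _water_id_map(topology: Topology) -> Dict[int, WaterId]:
    """Map water atom index -> water molecule id."""
    out: Dict[int, WaterId] = {}
    for i in np.nonzero(topology.is_water)[0]:
        out[int(i)] = (str(topology.chain[i]), int(topology.resnum[i]))
    return out


def enumerate_water_bridges(frame_hbonds: Sequence[HBond], topology: Topology,
                            group1: Iterable[int], group2: Iterable[int],
                            max_order: int = 2,
                            require_water_water_link: bool = True) -> List[WaterBridge]:
    """Enumerate water-mediated bridges of order <= ``max_order`` in one frame.

    Parameters
    ----------
    frame_hbonds : hydrogen bonds of a single frame
    group1, group2 : disjoint protein atom index sets (non-water)
    max_order : maximum number of mediating waters (1 or 2)
    require_water_water_link : bool
        For order-2 bridges, require the two mediating waters to be
        hydrogen-bonded to each other (chain interpretation).  When False,
        two waters each bonded to an opposite protein atom count as a bridge
        without a mutual water-water bond (shared-fork interpretation) --
        provided the two waters are distinct.

    A distinct (endpoint atom pair, water set) is reported once per frame;
    an order-1 and an order-2 path between the same endpoints coexist as
    separate bridges.  Donor/acceptor roles along the path are not
    constrained.
    """
    if max_order not in (1, 2):
        raise ValueError("max_order must be 1 or 2")
    g1 = set(int(i) for i in group1)
    g2 = set(int(i) for i in group2)
    if g1 & g2:
        raise ValueError("group1 and group2 must be disjoint")
    wmap = _water_id_map(topology)
    if any(i in wmap for i in g1 | g2):
        raise ValueError("interface groups must not contain water atoms")

    frames = {hb.frame for hb in frame_hbonds}
    if len(frames) > 1:
        raise ValueError("enumerate_water_bridges expects hydrogen bonds of a single frame")
    frame = frames.pop() if frames else 0

    # adjacency: water molecule -> protein atoms of each group; water -> water
    w_to_g1: Dict[WaterId, Set[int]] = {}
    w_to_g2: Dict[WaterId, Set[int]] = {}
    w_to_w: Dict[WaterId, Set[WaterId]] = {}
    for hb in frame_hbonds:
        dw = wmap.get(hb.donor)
        aw = wmap.get(hb.acceptor)
        if dw is not None and aw is not None:
            if dw != aw:
                w_to_w.setdefault(dw, set()).add(aw)
                w_to_w.setdefault(aw, set()).add(dw)
        elif dw is not None or aw is not None:
            w = dw if dw is not None else aw
            p = hb.acceptor if dw is not None else hb.donor
            if p in g1:
                w_to_g1.setdefault(w, set()).add(p)
            elif p in g2:
                w_to_g2.setdefault(w, set()).add(p)

    seen: Set[Tuple[int, int, FrozenSet[WaterId]]] = set()
    out: List[WaterBridge] = []

    def emit(a1: int, a2: int, path: Tuple[WaterId, ...]) -> None:
        key = (a1, a2, frozenset(path))
        if key not in seen:
            seen.add(key)
            out.append(WaterBridge(a1, a2, path, frame))

    # order 1
    for w, atoms1 in w_to_g1.items():
        atoms2 = w_to_g2.get(w)
        if not atoms2:
            continue
        for a1 in atoms1:
            for a2 in atoms2:
                emit(a1, a2, (w,))

    # order 2
    if max_order >= 2:
        if require_water_water_link:
            for w1, atoms1 in w_to_g1.items():
                for w2 in w_to_w.get(w1, ()):
                    atoms2 = w_to_g2.get(w2)
                    if not atoms2:
                        continue
                    for a1 in atoms1:
                        for a2 in atoms2:
                            emit(a1, a2, (w1, w2))
        else:
            for w1, atoms1 in w_to_g1.items():
                for w2, atoms2 in w_to_g2.items():
                    if w1 == w2:
                        continue
                    for a1 in atoms1:
                        for a2 in atoms2:
                            emit(a1, a2, (w1, w2))
    return out


def count_direct_interface_hbonds(frame_hbonds: Sequence[HBond],
                                  group1: Iterable[int], group2: Iterable[int]) -> int:
    """Number of hydrogen bonds with one endpoint in each protein group."""
    g1 = set(int(i) for i in group1)
    g2 = set(int(i) for i in group2)
    n = 0
    for hb in frame_hbonds:
        if (hb.donor in g1 and hb.acceptor in g2) or (hb.donor in g2 and hb.acceptor in g1):
            n += 1
    return n


def bridges_to_rows(bridges: Sequence[WaterBridge], topology: Topology) -> List[dict]:
    """Flatten bridges into TSV-ready dict rows."""
    rows = []
    for b in bridges:
        pk = b.pair_key(topology)
        rows.append({
            "frame": b.frame,
            "atom1": f"{topology.chain[b.atom1]}/{topology.resname[b.atom1]}"
                     f"{topology.resnum[b.atom1]}/{topology.name[b.atom1]}",
            "atom2": f"{topology.chain[b.atom2]}/{topology.resname[b.atom2]}"
                     f"{topology.resnum[b.atom2]}/{topology.name[b.atom2]}",
            "pair": pk.label,
            "waters": ";".join(f"{c}{r}" for c, r in b.waters),
            "order": b.order,
        })
    return rows
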