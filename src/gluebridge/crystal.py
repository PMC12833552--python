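"""Water-bridge inventory of a single crystallographic model.

Deposited crystal structures usually lack hydrogen positions, so the bridge
machinery is applied in heavy-atom mode: a distance-only hydrogen-bond
criterion (default 3.5 A between polar heavy atoms, the standard
crystallographic practice, looser than the 3.0 A trajectory criterion
because the hydrogen cannot tighten the geometry).  The classic use case is
the effector/target interface of a glue-bound ternary complex, e.g. chains
A (FKBP12) and B (FRAP) of PDB entry 1FAP, whose interface carries three
crystallographic water bridges (Lys48-Tyr2105, Thr89-Arg2042,
Gly87-Arg2042).  Structures are supplied by the user; nothing is downloaded.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from gluebridge.bridges import PairKey, WaterBridge, enumerate_water_bridges
from gluebridge.hbond import HBondCriteria, assign_donors_acceptors, detect_hbonds
from gluebridge.structio import Topology, select_atoms

__all__ = ["crystal_bridge_inventory"]


def crystal_bridge_inventory(topology: Topology, coords: np.ndarray,
                             group1_query: str, group2_query: str,
                             heavy_cutoff: float = 3.5,
                             max_order: int = 2) -> List[Tuple[PairKey, List[WaterBridge]]]:
    """Residue-pair water-bridge inventory of a hydrogen-free structure.

    Parameters
    ----------
    topology, coords : single-model structure (coords shape (n_atoms, 3))
    group1_query, group2_query : selections of the two protein groups,
        e.g. ``"chain A and not water"`` and ``"chain B and not water"``
    heavy_cutoff : distance-only hydrogen-bond cutoff (A)

    Returns
    -------
    Sorted list of (residue pair, bridges) with group-1 residues first in
    each pair.  An empty list (with a warning) if the structure contains no
    waters.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 3:
        if coords.shape[0] != 1:
            raise ValueError("crystal inventory expects a single-model structure")
        coords = coords[0]
    if not np.any(topology.is_water):
        warnings.warn("structure contains no water molecules; bridge inventory is empty")
        return []
    criteria = HBondCriteria(heavy_only=True, heavy_cutoff=heavy_cutoff)
    table = assign_donors_acceptors(topology, coords, criteria)
    hbonds = detect_hbonds(coords, table, criteria, topology=topology)
    g1 = select_atoms(topology, group1_query)
    g2 = select_atoms(topology, group2_query)
    g1 = g1[~topology.is_water[g1]]
    g2 = g2[~topology.is_water[g2]]
    bridges = enumerate_water_bridges(hbonds, topology, g1, g2, max_order=max_order)
    by_pair: Dict[PairKey, List[WaterBridge]] = {}
    for b in bridges:
        by_pair.setdefault(b.pair_key(topology), []).append(b)
    return sorted(by_pair.items(), key=lambda kv: kv[0])
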