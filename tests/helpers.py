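"""Shared test utilities: independent oracles and synthetic-topology builders.

The oracles here are deliberately naive (all-pairs loops, exhaustive path
enumeration, quaternion superposition) and share no code path with the
package implementations they check.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np

from gluebridge.hbond import DonorTable, HBond, HBondCriteria
from gluebridge.structio import Topology, infer_hydrogen_attachment


def make_topology(rows: Sequence[Tuple[str, str, str, str, int, bool]],
                  coords: np.ndarray | None = None) -> Topology:
    """Build a Topology from (name, element, resname, chain, resnum, is_water) rows."""
    topo = Topology(
        serial=np.arange(1, len(rows) + 1),
        name=np.array([r[0] for r in rows], dtype=object),
        element=np.array([r[1] for r in rows], dtype=object),
        resname=np.array([r[2] for r in rows], dtype=object),
        chain=np.array([r[3] for r in rows], dtype=object),
        resnum=np.array([r[4] for r in rows], dtype=int),
        is_water=np.array([r[5] for r in rows], dtype=bool),
    )
    if coords is not None:
        topo.h_attach = infer_hydrogen_attachment(topo, np.asarray(coords, dtype=float))
    return topo


def water_rows(resnum: int, chain: str = "W"):
    return [("OW", "O", "HOH", chain, resnum, True),
            ("HW1", "H", "HOH", chain, resnum, True),
            ("HW2", "H", "HOH", chain, resnum, True)]


def water_coords(opos, d1, d2, oh: float = 0.96) -> List[np.ndarray]:
    """Water coordinates with O at ``opos`` and hydrogens along unit d1/d2."""
    opos = np.asarray(opos, dtype=float)
    d1 = np.asarray(d1, dtype=float) / np.linalg.norm(d1)
    d2 = np.asarray(d2, dtype=float) / np.linalg.norm(d2)
    return [opos, opos + oh * d1, opos + oh * d2]


def random_water_frame(rng: np.random.Generator, n_waters: int = 40,
                       box: float = 12.0) -> Tuple[Topology, np.ndarray]:
    """Random dense water droplet (no periodic box) for detection tests."""
    rows, coords = [], []
    for i in range(n_waters):
        rows.extend(water_rows(i + 1))
        o = rng.uniform(0, box, 3)
        v1 = rng.normal(size=3)
        v2 = rng.normal(size=3)
        coords.extend(water_coords(o, v1, v2))
    coords = np.asarray(coords)
    return make_topology(rows, coords), coords


def brute_force_hbonds(coords: np.ndarray, table: DonorTable,
                       criteria: HBondCriteria = HBondCriteria(),
                       frame: int = 0) -> set:
    """All-pairs reference detector; returns (donor, hydrogen, acceptor) triples."""
    out = set()
    for k in range(len(table.donor_heavy)):
        d = int(table.donor_heavy[k])
        h = int(table.donor_hydrogen[k])
        for a in table.acceptors:
            a = int(a)
            if a == d:
                continue
            dist = float(np.linalg.norm(coords[a] - coords[d]))
            if criteria.heavy_only:
                if (criteria.heavy_min_dist <= dist <= criteria.heavy_cutoff
                        and a > d):
                    out.add((d, None, a))
                continue
            if dist > criteria.da_cutoff:
                continue
            v1 = coords[d] - coords[h]
            v2 = coords[a] - coords[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = math.degrees(math.acos(np.clip(cosang, -1, 1)))
            if angle >= criteria.dha_min_angle - 1e-9:
                out.add((d, h, a))
    return out


def networkx_bridge_oracle(hbonds: Sequence[HBond], topology: Topology,
                           group1, group2) -> set:
    """Exhaustive simple-path enumeration of water bridges via networkx."""
    import networkx as nx

    wmap = {}
    for i in np.nonzero(topology.is_water)[0]:
        wmap[int(i)] = ("w", str(topology.chain[i]), int(topology.resnum[i]))
    g1, g2 = set(map(int, group1)), set(map(int, group2))
    G = nx.Graph()
    for hb in hbonds:
        u = wmap.get(hb.donor, ("p", hb.donor))
        v = wmap.get(hb.acceptor, ("p", hb.acceptor))
        if u != v:
            G.add_edge(u, v)
    found = set()
    for a1 in g1:
        if ("p", a1) not in G:
            continue
        for a2 in g2:
            if ("p", a2) not in G:
                continue
            for path in nx.all_simple_paths(G, ("p", a1), ("p", a2), cutoff=3):
                inner = path[1:-1]
                if 1 <= len(inner) <= 2 and all(n[0] == "w" for n in inner):
                    found.add((a1, a2, frozenset(n[1:] for n in inner)))
    return found


def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Horn's closed-form quaternion superposition; independent of Kabsch/SVD."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    sxx = x.T @ y
    a = np.empty((4, 4))
    a[0, 0] = sxx[0, 0] + sxx[1, 1] + sxx[2, 2]
    a[0, 1] = a[1, 0] = sxx[1, 2] - sxx[2, 1]
    a[0, 2] = a[2, 0] = sxx[2, 0] - sxx[0, 2]
    a[0, 3] = a[3, 0] = sxx[0, 1] - sxx[1, 0]
    a[1, 1] = sxx[0, 0] - sxx[1, 1] - sxx[2, 2]
    a[1, 2] = a[2, 1] = sxx[0, 1] + sxx[1, 0]
    a[1, 3] = a[3, 1] = sxx[0, 2] + sxx[2, 0]
    a[2, 2] = -sxx[0, 0] + sxx[1, 1] - sxx[2, 2]
    a[2, 3] = a[3, 2] = sxx[1, 2] + sxx[2, 1]
    a[3, 3] = -sxx[0, 0] - sxx[1, 1] + sxx[2, 2]
    evals, evecs = np.linalg.eigh(a)
    q = evecs[:, -1]  # eigenvector of the largest eigenvalue
    w, qx, qy, qz = q
    rot = np.array([
        [w*w + qx*qx - qy*qy - qz*qz, 2*(qx*qy - w*qz), 2*(qx*qz + w*qy)],
        [2*(qx*qy + w*qz), w*w - qx*qx + qy*qy - qz*qz, 2*(qy*qz - w*qx)],
        [2*(qx*qz - w*qy), 2*(qy*qz + w*qx), w*w - qx*qx - qy*qy + qz*qz],
    ])
    aligned = x @ rot.T
    return float(np.sqrt(np.mean(np.sum((aligned - y) ** 2, axis=1))))


def strip_hydrogens(topology: Topology, coords: np.ndarray) -> Tuple[Topology, np.ndarray]:
    """Heavy-atom-only copy of a structure (crystal-like, no hydrogens)."""
    keep = np.array([e != "H" for e in topology.element])
    idx = np.nonzero(keep)[0]
    topo = Topology(
        serial=topology.serial[idx].copy(),
        name=topology.name[idx].copy(),
        element=topology.element[idx].copy(),
        resname=topology.resname[idx].copy(),
        chain=topology.chain[idx].copy(),
        resnum=topology.resnum[idx].copy(),
        is_water=topology.is_water[idx].copy(),
    )
    return topo, np.asarray(coords, dtype=float)[idx]
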