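"""Per-frame geometric hydrogen-bond detection.

Criteria follow standard trajectory-analysis practice for water-mediated
interaction studies: a donor--acceptor heavy-atom distance cutoff of 3.0 A
and a D-H-A angle cutoff of 120 degrees, with the angle measured at the
hydrogen (180 degrees = linear).  Both cutoffs are inclusive.  A heavy-only
mode (distance-only, default 3.5 A) supports crystal structures without
hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from gluebridge.structio import Topology

__all__ = [
    "HBondCriteria",
    "HBond",
    "DonorTable",
    "assign_donors_acceptors",
    "detect_hbonds",
    "hbonds_to_rows",
]

#: heavy elements that can act as hydrogen-bond donors or acceptors
POLAR_ELEMENTS = ("N", "O", "S")

#: maximum heavy-atom covalent bond length used for neighbour counting (A)
_COVALENT_CUTOFF = 1.75


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    Parameters
    ----------
    da_cutoff : float
        Donor--acceptor heavy-atom distance cutoff in A (inclusive).
    dha_min_angle : float
        Minimum donor-hydrogen-acceptor angle in degrees, vertex at the
        hydrogen (inclusive; 180 = linear).
    heavy_only : bool
        Distance-only mode for structures without hydrogens.
    heavy_cutoff : float
        Distance cutoff in heavy-only mode (A).  Larger than ``da_cutoff``
        because the hydrogen position cannot tighten the geometry.
    heavy_min_dist : float
        Minimum distance in heavy-only mode, to exclude covalent and
        1-3 contacts that a distance-only criterion would otherwise admit.
    """

    da_cutoff: float = 3.0
    dha_min_angle: float = 120.0
    heavy_only: bool = False
    heavy_cutoff: float = 3.5
    heavy_min_dist: float = 2.0

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0:
            raise ValueError("da_cutoff must be positive")
        if not (0 < self.dha_min_angle <= 180):
            raise ValueError("dha_min_angle must be in (0, 180]")
        if self.heavy_cutoff <= 0:
            raise ValueError("heavy_cutoff must be positive")


@dataclass(frozen=True)
class HBond:
    """A single detected hydrogen bond in one frame.

    ``hydrogen`` is ``None`` in heavy-only mode; ``angle`` is then NaN.
    Atom identities are 0-based topology indices of heavy atoms.
    """

    donor: int
    hydrogen: Optional[int]
    acceptor: int
    frame: int
    distance: float
    angle: float


@dataclass
class DonorTable:
    """Donor entries (one per attached hydrogen) and acceptor indices."""

    donor_heavy: np.ndarray      # (n_donors,) heavy-atom index
    donor_hydrogen: np.ndarray   # (n_donors,) hydrogen index (-1 in heavy-only mode)
    acceptors: np.ndarray        # (n_acceptors,) heavy-atom index


def _heavy_neighbor_counts(topology: Topology, coords: np.ndarray) -> np.ndarray:
    """Number of covalently bonded heavy neighbours per atom (distance rule)."""
    heavy = np.nonzero(np.asarray([e != "H" for e in topology.element]))[0]
    counts = np.zeros(topology.n_atoms, dtype=int)
    if len(heavy) < 2:
        return counts
    tree = cKDTree(coords[heavy])
    for i, j in tree.query_pairs(_COVALENT_CUTOFF):
        counts[heavy[i]] += 1
        counts[heavy[j]] += 1
    return counts


def assign_donors_acceptors(topology: Topology, coords: Optional[np.ndarray] = None,
                            criteria: HBondCriteria = HBondCriteria()) -> DonorTable:
    """Build donor and acceptor tables from element rules.

    Donors are N/O/S heavy atoms with at least one attached hydrogen, one
    donor entry per hydrogen.  Acceptors are all O and S, plus any N that is
    not quaternary (fewer than four bonded partners counting heavy neighbours
    and hydrogens).  Water oxygen is therefore both a double donor and an
    acceptor.  In heavy-only mode every polar heavy atom appears once as a
    donor candidate and once as an acceptor.

    ``coords`` (a reference frame) is needed to count heavy neighbours for
    the quaternary-nitrogen rule; without it every N is accepted.
    """
    polar = np.nonzero(np.asarray([e in POLAR_ELEMENTS for e in topology.element]))[0]

    if criteria.heavy_only:
        return DonorTable(
            donor_heavy=polar.copy(),
            donor_hydrogen=np.full(len(polar), -1, dtype=int),
            acceptors=polar.copy(),
        )

    dh: List[int] = []
    dhyd: List[int] = []
    for i in polar:
        for h in topology.h_attach.get(int(i), []):
            dh.append(int(i))
            dhyd.append(int(h))

    heavy_nb = None
    if coords is not None:
        heavy_nb = _heavy_neighbor_counts(topology, np.asarray(coords, dtype=float))
    acc: List[int] = []
    for i in polar:
        e = topology.element[i]
        if e in ("O", "S"):
            acc.append(int(i))
        elif e == "N":
            n_h = len(topology.h_attach.get(int(i), []))
            n_heavy = int(heavy_nb[i]) if heavy_nb is not None else 0
            if n_heavy + n_h < 4:  # quaternary N has no lone pair
                acc.append(int(i))
    return DonorTable(
        donor_heavy=np.asarray(dh, dtype=int),
        donor_hydrogen=np.asarray(dhyd, dtype=int),
        acceptors=np.asarray(acc, dtype=int),
    )


def _minimum_image(delta: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


def detect_hbonds(coords: np.ndarray, table: DonorTable,
                  criteria: HBondCriteria = HBondCriteria(),
                  frame: int = 0,
                  box: Optional[np.ndarray] = None,
                  topology: Optional[Topology] = None) -> List[HBond]:
    """Detect all hydrogen bonds in one frame.

    Returns exactly the donor entry / acceptor pairs with D-A distance <=
    cutoff and D-H-A angle >= the minimum angle (both inclusive); the
    neighbour-list acceleration cannot change the result set.  Minimum-image
    distances are used when an orthorhombic ``box`` is given.

    In heavy-only mode the angle test is skipped, pairs closer than
    ``heavy_min_dist`` are rejected, and pairs within one residue are
    excluded (requires ``topology``); only the (donor < acceptor) orientation
    of each symmetric pair is emitted.
    """
    coords = np.asarray(coords, dtype=float)
    out: List[HBond] = []
    if len(table.acceptors) == 0 or len(table.donor_heavy) == 0:
        return out

    cutoff = criteria.heavy_cutoff if criteria.heavy_only else criteria.da_cutoff
    acc_pos = coords[table.acceptors]
    if box is not None:
        box = np.asarray(box, dtype=float)
        tree = cKDTree(np.mod(acc_pos, box), boxsize=box)
        don_query = np.mod(coords[table.donor_heavy], box)
    else:
        tree = cKDTree(acc_pos)
        don_query = coords[table.donor_heavy]

    neighbors = tree.query_ball_point(don_query, cutoff)
    cos_min = np.cos(np.deg2rad(criteria.dha_min_angle))

    for k in range(len(table.donor_heavy)):
        d_idx = int(table.donor_heavy[k])
        h_idx = int(table.donor_hydrogen[k])
        for a_k in neighbors[k]:
            a_idx = int(table.acceptors[a_k])
            if a_idx == d_idx:
                continue
            delta = _minimum_image(coords[a_idx] - coords[d_idx], box)
            dist = float(np.linalg.norm(delta))
            if dist > cutoff:  # KD-tree padding guard
                continue
            if criteria.heavy_only:
                if a_idx < d_idx:
                    continue  # symmetric pair: emit once
                if dist < criteria.heavy_min_dist:
                    continue
                if topology is not None and topology.residue_key(d_idx) == topology.residue_key(a_idx):
                    continue
                out.append(HBond(d_idx, None, a_idx, frame, dist, float("nan")))
            else:
                v_d = _minimum_image(coords[d_idx] - coords[h_idx], box)
                v_a = _minimum_image(coords[a_idx] - coords[h_idx], box)
                nd = np.linalg.norm(v_d)
                na = np.linalg.norm(v_a)
                if nd == 0 or na == 0:
                    continue
                cos_angle = float(np.dot(v_d, v_a) / (nd * na))
                # angle >= threshold <=> cos(angle) <= cos(threshold)
                if cos_angle <= cos_min + 1e-12:
                    angle = float(np.degrees(np.arccos(np.clip(cos_angle, -1.0, 1.0))))
                    out.append(HBond(d_idx, h_idx, a_idx, frame, dist, angle))
    return out


def hbonds_to_rows(hbonds: Sequence[HBond], topology: Topology) -> List[dict]:
    """Flatten hydrogen bonds into TSV-ready dict rows with residue labels."""
    rows = []
    for hb in hbonds:
        rows.append({
            "frame": hb.frame,
            "donor_serial": int(topology.serial[hb.donor]),
            "donor": f"{topology.chain[hb.donor]}/{topology.resname[hb.donor]}"
                     f"{topology.resnum[hb.donor]}/{topology.name[hb.donor]}",
            "hydrogen_serial": int(topology.serial[hb.hydrogen]) if hb.hydrogen is not None else -1,
            "acceptor_serial": int(topology.serial[hb.acceptor]),
            "acceptor": f"{topology.chain[hb.acceptor]}/{topology.resname[hb.acceptor]}"
                        f"{topology.resnum[hb.acceptor]}/{topology.name[hb.acceptor]}",
            "distance": round(hb.distance, 3),
            "angle": round(hb.angle, 2) if hb.hydrogen is not None else float("nan"),
        })
    return rows
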