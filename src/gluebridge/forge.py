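"""Synthetic interface trajectories with planted water bridges.

The forge emulates the geometry of a molecular-glue ternary-complex
interface at toy scale: two short protein-like chains (A and B) face each
other across a solvated gap, polar side-chain sites point into the gap, and
water-mediated hydrogen-bond bridges of order 1 or 2 are *planted* between
chosen site pairs with a known per-frame on/off schedule.  The realized
schedule is recorded in a :class:`TruthManifest`, which is sufficient to
recompute every planted interface statistic without the trajectory -- the
ground truth for testing the detection pipeline.

Geometry guarantees
-------------------
When a bridge is "on", every hydrogen-bond link along its water path is
placed with a donor-acceptor distance of 2.7-2.8 A and a near-linear D-H-A
angle, i.e. safely inside the 3.0 A / 120 degree detection criteria (margin
>= 0.1 A and >= 10 degrees even for multiplexed bridges sharing a residue
pair).  When "off", the dedicated water is parked far outside the interface
(every link >= 2 A beyond the cutoff).  Isotropic Gaussian noise of scale
``noise_sigma`` is added to all atoms, and an optional random rigid-body
wobble is applied to chain B *before* water placement, so planted bridges
survive the wobble.  A build-time self-check detects the all-on noiseless
frame and verifies that the detected bridge inventory equals the planted
one exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from gluebridge.bridges import PairKey, enumerate_water_bridges, count_direct_interface_hbonds
from gluebridge.hbond import HBondCriteria, assign_donors_acceptors, detect_hbonds
from gluebridge.structio import Topology, Trajectory, select_atoms, infer_hydrogen_attachment, write_multimodel_pdb

__all__ = [
    "InterfaceSpec",
    "PlantedBridge",
    "TruthManifest",
    "InterfaceModel",
    "GeometryError",
    "build_interface_topology",
    "simulate_bridge_schedule",
    "render_trajectory",
    "manifest_pair_statistics",
    "random_scenario",
    "paper_like_scenario",
]

# residue geometry constants (A)
_RES_SPACING = 3.8          # along-chain spacing
_SITE_PROTRUSION = 1.8      # side-chain O sticks this far into the gap
_SITE_Y = (0.5, 5.0)        # lateral planes of the two site oxygens per residue
_OH_BOND = 0.96             # O-H bond length
_NH_BOND = 1.01             # N-H bond length
_LINK_ORDER2 = 2.8          # link length of order-2 paths
_MIN_LINK = 2.0             # shortest physically sensible link
_MAX_LINK = 2.9             # longest link (0.1 A inside the 3.0 A cutoff)


class GeometryError(ValueError):
    """Raised when a requested bridge cannot be realised geometrically."""


@dataclass(frozen=True)
class PlantedBridge:
    """A water-mediated bridge to plant between chain-A and chain-B sites.

    ``res1``/``res2`` are 1-based residue numbers on chain A / chain B whose
    interface site atoms (side-chain O) are the endpoints.  ``schedule_kind``
    is ``"bernoulli"`` (independent per-frame draws, the default -- no
    kinetics are implied by the model) or ``"markov"`` (two-state chain with
    transition probabilities ``p_on`` = P(off->on), ``p_off`` = P(on->off),
    whose stationary occupancy must equal ``occupancy_target``).
    """

    res1: int
    res2: int
    order: int = 1
    occupancy_target: float = 0.5
    schedule_kind: str = "bernoulli"
    p_on: Optional[float] = None
    p_off: Optional[float] = None

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError("bridge order must be 1 or 2")
        if not (0.0 <= self.occupancy_target <= 1.0):
            raise ValueError("occupancy_target must be in [0, 1]")
        if self.schedule_kind not in ("bernoulli", "markov"):
            raise ValueError(f"unknown schedule_kind {self.schedule_kind!r}")
        if self.schedule_kind == "markov":
            if self.p_on is None or self.p_off is None:
                raise ValueError("markov schedule requires p_on and p_off")
            if not (0 < self.p_on <= 1 and 0 < self.p_off <= 1):
                raise ValueError("markov transition probabilities must be in (0, 1]")
            stat = self.p_on / (self.p_on + self.p_off)
            if abs(stat - self.occupancy_target) > 1e-9:
                raise ValueError(
                    f"markov stationary occupancy {stat:.12f} does not equal "
                    f"occupancy_target {self.occupancy_target}"
                )

    @classmethod
    def markov(cls, res1: int, res2: int, occupancy: float, mean_on_frames: float,
               order: int = 1) -> "PlantedBridge":
        """Markov bridge from target occupancy and mean on-dwell length."""
        if not (0 < occupancy < 1):
            raise ValueError("markov occupancy must be in (0, 1)")
        p_off = 1.0 / mean_on_frames
        p_on = p_off * occupancy / (1.0 - occupancy)
        if p_on > 1.0:
            raise ValueError("mean_on_frames too short for this occupancy")
        return cls(res1, res2, order=order, occupancy_target=occupancy,
                   schedule_kind="markov", p_on=p_on, p_off=p_off)


@dataclass(frozen=True)
class InterfaceSpec:
    """Parameters of the synthetic two-chain solvated interface.

    ``donor_sites``/``acceptor_sites`` list, per chain ("A"/"B"), the 1-based
    residues whose interface site is a donor (side-chain O-H) or a plain
    acceptor (side-chain O).  ``chain_separation`` must exceed twice the
    3 A hydrogen-bond cutoff so that no direct inter-protein contacts occur
    unless engineered.  ``noise_sigma`` is the isotropic thermal jitter per
    coordinate; ``rigid_body_amplitude`` the SD of the random per-frame
    rigid translation of chain B.
    """

    n_residues_per_chain: int = 6
    donor_sites: Mapping[str, Tuple[int, ...]] = field(default_factory=dict)
    acceptor_sites: Mapping[str, Tuple[int, ...]] = field(default_factory=dict)
    n_bulk_waters: int = 10
    chain_separation: float = 9.0
    noise_sigma: float = 0.05
    rigid_body_amplitude: float = 0.0
    bridges: Tuple[PlantedBridge, ...] = ()

    def __post_init__(self) -> None:
        if self.n_residues_per_chain < 1:
            raise ValueError("invariant violated: n_residues_per_chain >= 1")
        if self.chain_separation <= 6.0:
            raise ValueError(
                "invariant violated: chain_separation must exceed 6 A "
                "(twice the 3 A H-bond cutoff) to rule out accidental direct contacts"
            )
        if self.noise_sigma < 0:
            raise ValueError("invariant violated: noise_sigma >= 0")
        if self.rigid_body_amplitude < 0:
            raise ValueError("invariant violated: rigid_body_amplitude >= 0")
        if self.n_bulk_waters < 0:
            raise ValueError("invariant violated: n_bulk_waters >= 0")
        for chain, sites in list(self.donor_sites.items()) + list(self.acceptor_sites.items()):
            if chain not in ("A", "B"):
                raise ValueError(f"invariant violated: unknown chain {chain!r}")
            for r in sites:
                if not (1 <= r <= self.n_residues_per_chain):
                    raise ValueError(f"invariant violated: site residue {r} outside chain")
        for chain in ("A", "B"):
            overlap = set(self.donor_sites.get(chain, ())) & set(self.acceptor_sites.get(chain, ()))
            if overlap:
                raise ValueError(f"invariant violated: residues {sorted(overlap)} of chain "
                                 f"{chain} are both donor and acceptor sites")
        for b in self.bridges:
            for chain, res in (("A", b.res1), ("B", b.res2)):
                if res not in self.donor_sites.get(chain, ()) and \
                   res not in self.acceptor_sites.get(chain, ()):
                    raise ValueError(
                        f"invariant violated: bridge endpoint residue {res} on chain {chain} "
                        "is not declared as a donor or acceptor site"
                    )


@dataclass
class TruthManifest:
    """Realized per-frame schedule of every planted bridge.

    Sufficient to recompute every planted interface statistic without the
    trajectory: each record carries the residue pair, order, dedicated water
    ids and the realized on/off record.
    """

    seed: int
    n_frames: int
    pairs: List[Tuple[int, int]]                 # (res1, res2) per bridge
    orders: List[int]
    water_ids: List[Tuple[Tuple[str, int], ...]]  # (chain, resnum) of dedicated waters
    on: List[np.ndarray]                          # boolean arrays, one per bridge
    trajectory_path: Optional[str] = None

    @property
    def realized_occupancy(self) -> List[float]:
        return [float(o.mean()) for o in self.on]

    def save(self, path) -> None:
        lines = [f"seed = {self.seed}", f"n_frames = {self.n_frames}",
                 f"n_bridges = {len(self.on)}"]
        if self.trajectory_path:
            lines.append(f"trajectory = {self.trajectory_path}")
        for i, on in enumerate(self.on):
            if i < len(self.water_ids) and self.water_ids[i]:
                waters = ";".join(f"{c}:{r}" for c, r in self.water_ids[i])
            else:
                waters = "-"
            bits = "".join("1" if x else "0" for x in on)
            lines.append(
                f"bridge {i}: res1={self.pairs[i][0]} res2={self.pairs[i][1]} "
                f"order={self.orders[i]} waters={waters} "
                f"realized={on.mean():.6f} on={bits}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "TruthManifest":
        seed = n_frames = 0
        traj: Optional[str] = None
        pairs: List[Tuple[int, int]] = []
        orders: List[int] = []
        water_ids: List[Tuple[Tuple[str, int], ...]] = []
        on: List[np.ndarray] = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("seed"):
                seed = int(line.split("=")[1])
            elif line.startswith("n_frames"):
                n_frames = int(line.split("=")[1])
            elif line.startswith("trajectory"):
                traj = line.split("=", 1)[1].strip()
            elif line.startswith("bridge "):
                fields = dict(tok.split("=", 1) for tok in line.split(": ", 1)[1].split())
                pairs.append((int(fields["res1"]), int(fields["res2"])))
                orders.append(int(fields["order"]))
                if fields["waters"] == "-":
                    water_ids.append(())
                else:
                    water_ids.append(tuple(
                        (c, int(r)) for c, r in
                        (w.split(":") for w in fields["waters"].split(";"))
                    ))
                on.append(np.array([ch == "1" for ch in fields["on"]], dtype=bool))
        m = cls(seed=seed, n_frames=n_frames, pairs=pairs, orders=orders,
                water_ids=water_ids, on=on, trajectory_path=traj)
        for o in m.on:
            if len(o) != n_frames:
                raise ValueError("manifest on-record length does not match n_frames")
        return m


@dataclass
class InterfaceModel:
    """Topology + base geometry of a forged interface system."""

    spec: InterfaceSpec
    topology: Topology
    base_coords: np.ndarray
    site_atom: Dict[Tuple[str, int, int], int]     # (chain, res, slot) -> site O index
    site_hydrogen: Dict[Tuple[str, int, int], int]  # (chain, res, slot) -> site H (donor sites)
    bridge_waters: List[Tuple[Tuple[str, int], ...]]   # per bridge: water (chain, resnum) ids
    water_oxygen: Dict[Tuple[str, int], int]      # water id -> O index
    water_hydrogens: Dict[Tuple[str, int], Tuple[int, int]]
    park_positions: Dict[Tuple[str, int], np.ndarray]
    chain_b_atoms: np.ndarray
    multiplex_index: List[int]                    # azimuth slot of each bridge within its pair


def _site_role(spec: InterfaceSpec, chain: str, res: int) -> str:
    if res in spec.donor_sites.get(chain, ()):
        return "donor"
    return "acceptor"


def build_interface_topology(spec: InterfaceSpec) -> InterfaceModel:
    """Construct the deterministic base topology and coordinates.

    Chains A and B each consist of ``n_residues_per_chain`` minimal polar
    residues (backbone N/H/CA/C/O plus a side-chain O site, donors carrying
    an additional hydroxyl H) facing each other across ``chain_separation``.
    Dedicated bridging waters (one or two per planted bridge) and bulk
    waters are appended as 3-atom O/H/H groups on chain W.  Atom ordering is
    deterministic; residues are numbered 1-based per chain.

    Raises :class:`GeometryError` if a planted bridge's endpoints are too
    far apart (or too close) for its order.
    """
    sep = spec.chain_separation
    serial = 1
    rows: List[Tuple[int, str, str, str, str, int, bool]] = []
    coords: List[np.ndarray] = []
    site_atom: Dict[Tuple[str, int, int], int] = {}
    site_hydrogen: Dict[Tuple[str, int, int], int] = {}

    def add(name: str, element: str, resname: str, chain: str, resnum: int,
            pos: Sequence[float], water: bool = False) -> int:
        nonlocal serial
        rows.append((serial, name, element, resname, chain, resnum, water))
        coords.append(np.asarray(pos, dtype=float))
        serial += 1
        return len(rows) - 1

    for chain, z0, zdir in (("A", 0.0, +1.0), ("B", sep, -1.0)):
        for r in range(1, spec.n_residues_per_chain + 1):
            x0 = (r - 1) * _RES_SPACING
            has_site = (r in spec.donor_sites.get(chain, ())
                        or r in spec.acceptor_sites.get(chain, ()))
            resname = "GLX" if has_site else "GLY"
            add("N", "N", resname, chain, r, (x0, 0.0, z0))
            add("H", "H", resname, chain, r, (x0, -_NH_BOND, z0))
            add("CA", "C", resname, chain, r, (x0 + 1.46, 0.5, z0))
            add("C", "C", resname, chain, r, (x0 + 2.2, -0.8, z0))
            add("O", "O", resname, chain, r, (x0 + 2.2, -2.03, z0))
            if has_site:
                # two well-separated interface oxygens per site residue:
                # a second bridge on the same residue pair gets its own
                # endpoint atoms (residue-level statistics merge them)
                for slot, y in enumerate(_SITE_Y):
                    iog = add(f"OG{slot + 1}", "O", resname, chain, r,
                              (x0 + 1.46, y, z0 + zdir * _SITE_PROTRUSION))
                    site_atom[(chain, r, slot)] = iog
                    if r in spec.donor_sites.get(chain, ()):
                        ihg = add(f"HG{slot + 1}", "H", resname, chain, r,
                                  (x0 + 1.46, y, z0 + zdir * (_SITE_PROTRUSION + _OH_BOND)))
                        site_hydrogen[(chain, r, slot)] = ihg

    # dedicated bridge waters + feasibility/multiplexing bookkeeping
    water_oxygen: Dict[Tuple[str, int], int] = {}
    water_hydrogens: Dict[Tuple[str, int], Tuple[int, int]] = {}
    park_positions: Dict[Tuple[str, int], np.ndarray] = {}
    bridge_waters: List[Tuple[Tuple[str, int], ...]] = []
    multiplex_index: List[int] = []
    slot_counter: Dict[Tuple[int, int], int] = {}
    wnum = 0

    base_arr = np.asarray(coords)

    for b in spec.bridges:
        k = slot_counter.get((b.res1, b.res2), 0)
        slot_counter[(b.res1, b.res2)] = k + 1
        if k >= len(_SITE_Y):
            raise GeometryError(
                f"more than {len(_SITE_Y)} bridges requested on pair {b.res1}-{b.res2}"
            )
        multiplex_index.append(k)
        p1 = base_arr[site_atom[("A", b.res1, k)]]
        p2 = base_arr[site_atom[("B", b.res2, k)]]
        gap = float(np.linalg.norm(p2 - p1))
        if b.order == 1:
            link = gap / 2.0
            if not (_MIN_LINK <= link <= _MAX_LINK):
                raise GeometryError(
                    f"order-1 bridge {b.res1}-{b.res2}: endpoint gap {gap:.2f} A needs a "
                    f"link of {link:.2f} A, outside [{_MIN_LINK}, {_MAX_LINK}] A"
                )
        else:
            a = (gap - _LINK_ORDER2) / 2.0
            if gap < 2.0 * _MIN_LINK or a > _LINK_ORDER2 - 0.05:
                raise GeometryError(
                    f"order-2 bridge {b.res1}-{b.res2}: endpoint gap {gap:.2f} A is "
                    "outside the feasible range for three 2.8 A links"
                )
        ids = []
        for _ in range(b.order):
            wnum += 1
            wid = ("W", wnum)
            ids.append(wid)
            io = add("OW", "O", "HOH", "W", wnum, (0.0, 0.0, 0.0), water=True)
            ih1 = add("HW1", "H", "HOH", "W", wnum, (_OH_BOND, 0.0, 0.0), water=True)
            ih2 = add("HW2", "H", "HOH", "W", wnum, (-_OH_BOND, 0.0, 0.0), water=True)
            water_oxygen[wid] = io
            water_hydrogens[wid] = (ih1, ih2)
            park_positions[wid] = np.array([-12.0 - 4.0 * wnum, 0.0, sep / 2.0])
        bridge_waters.append(tuple(ids))

    # bulk waters: lattice displaced well beyond the chains, never bonded
    x_far = spec.n_residues_per_chain * _RES_SPACING + 8.0
    for i in range(spec.n_bulk_waters):
        wnum += 1
        wid = ("W", wnum)
        pos = np.array([x_far + 4.0 * (i % 5), 4.0 * (i // 5), sep / 2.0])
        io = add("OW", "O", "HOH", "W", wnum, pos, water=True)
        add("HW1", "H", "HOH", "W", wnum, pos + (0.76, 0.59, 0.0), water=True)
        add("HW2", "H", "HOH", "W", wnum, pos + (-0.76, 0.59, 0.0), water=True)
        water_oxygen[wid] = io
        water_hydrogens[wid] = (io + 1, io + 2)

    base = np.asarray(coords)
    # park dedicated waters by default (base state = all bridges off)
    for wid, park in park_positions.items():
        io = water_oxygen[wid]
        ih1, ih2 = water_hydrogens[wid]
        base[io] = park
        base[ih1] = park + (0.76, 0.59, 0.0)
        base[ih2] = park + (-0.76, 0.59, 0.0)

    topo = Topology(
        serial=np.array([r[0] for r in rows], dtype=int),
        name=np.array([r[1] for r in rows], dtype=object),
        element=np.array([r[2] for r in rows], dtype=object),
        resname=np.array([r[3] for r in rows], dtype=object),
        chain=np.array([r[4] for r in rows], dtype=object),
        resnum=np.array([r[5] for r in rows], dtype=int),
        is_water=np.array([r[6] for r in rows], dtype=bool),
    )
    topo.h_attach = infer_hydrogen_attachment(topo, base)
    topo.validate()

    model = InterfaceModel(
        spec=spec, topology=topo, base_coords=base,
        site_atom=site_atom, site_hydrogen=site_hydrogen,
        bridge_waters=bridge_waters, water_oxygen=water_oxygen,
        water_hydrogens=water_hydrogens, park_positions=park_positions,
        chain_b_atoms=np.nonzero(topo.chain.astype(str) == "B")[0],
        multiplex_index=multiplex_index,
    )
    if spec.bridges:
        _verify_planted_geometry(model)
    return model


def simulate_bridge_schedule(bridges: Sequence[PlantedBridge], n_frames: int,
                             seed: int) -> TruthManifest:
    """Draw the per-frame on/off record of every bridge; reproducible by seed."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    on: List[np.ndarray] = []
    for b in bridges:
        if b.schedule_kind == "bernoulli":
            rec = rng.random(n_frames) < b.occupancy_target
        else:
            rec = np.empty(n_frames, dtype=bool)
            state = rng.random() < b.occupancy_target  # stationary start
            for f in range(n_frames):
                u = rng.random()
                if state:
                    state = not (u < b.p_off)
                else:
                    state = u < b.p_on
                rec[f] = state
        on.append(rec)
    return TruthManifest(
        seed=seed, n_frames=n_frames,
        pairs=[(b.res1, b.res2) for b in bridges],
        orders=[b.order for b in bridges],
        water_ids=[], on=on,
    )


def _orthonormal_frame(u: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n1 = ref - np.dot(ref, u) * u
    n1 /= np.linalg.norm(n1)
    return n1, np.cross(u, n1)


def _place_bridge(coords: np.ndarray, model: InterfaceModel, bi: int,
                  donor_targets: Dict[int, List[np.ndarray]]) -> None:
    """Place the waters (and their hydrogens) of on-bridge ``bi``."""
    spec = model.spec
    b = spec.bridges[bi]
    k = model.multiplex_index[bi]
    a1_idx = model.site_atom[("A", b.res1, k)]
    a2_idx = model.site_atom[("B", b.res2, k)]
    p1 = coords[a1_idx]
    p2 = coords[a2_idx]
    gap = float(np.linalg.norm(p2 - p1))
    u = (p2 - p1) / gap
    n1, n2 = _orthonormal_frame(u)
    role1 = _site_role(spec, "A", b.res1)
    role2 = _site_role(spec, "B", b.res2)
    wids = model.bridge_waters[bi]

    def set_water(wid, opos, h_dirs):
        io = model.water_oxygen[wid]
        ih1, ih2 = model.water_hydrogens[wid]
        coords[io] = opos
        coords[ih1] = opos + _OH_BOND * h_dirs[0]
        coords[ih2] = opos + _OH_BOND * h_dirs[1]

    if b.order == 1:
        # the water sits on the site-pair axis; spare hydrogens point along
        # +-n2 (the along-chain direction), which can never reach another
        # pair's waters at the residue spacing
        w = p1 + (gap / 2.0) * u
        h_dirs = []
        if role2 == "acceptor":
            h_dirs.append((p2 - w) / np.linalg.norm(p2 - w))
        if role1 == "acceptor":
            h_dirs.append((p1 - w) / np.linalg.norm(p1 - w))
        spares = [n2, -n2]
        while len(h_dirs) < 2:
            h_dirs.append(spares.pop(0))
        set_water(wids[0], w, h_dirs)
        if role1 == "donor":
            donor_targets.setdefault(a1_idx, []).append(w)
        if role2 == "donor":
            donor_targets.setdefault(a2_idx, []).append(w)
    else:
        a = (gap - _LINK_ORDER2) / 2.0
        h = math.sqrt(max(_LINK_ORDER2 ** 2 - a * a, 0.04))
        # slot-0 paths bow toward the backbone side (-n1), slot-1 paths away
        # (+n1): each stays clear of the other site plane
        nhat = -n1 if k == 0 else n1
        w1 = p1 + a * u + h * nhat
        w2 = p2 - a * u + h * nhat
        # w1 donates to w2; endpoint links donate toward whichever side accepts
        d12 = (w2 - w1) / np.linalg.norm(w2 - w1)
        h1_dirs = [d12]
        if role1 == "acceptor":
            h1_dirs.append((p1 - w1) / np.linalg.norm(p1 - w1))
        else:
            h1_dirs.append(nhat)
            donor_targets.setdefault(a1_idx, []).append(w1)
        h2_dirs = []
        if role2 == "acceptor":
            h2_dirs.append((p2 - w2) / np.linalg.norm(p2 - w2))
        else:
            donor_targets.setdefault(a2_idx, []).append(w2)
        h2_dirs.append(nhat)
        if len(h2_dirs) < 2:
            h2_dirs.append(np.cross(u, nhat))
        set_water(wids[0], w1, h1_dirs[:2])
        set_water(wids[1], w2, h2_dirs[:2])


def _render_frame(model: InterfaceModel, on_flags: Sequence[bool],
                  wobble: Optional[np.ndarray] = None) -> np.ndarray:
    """Noise-free coordinates of one frame given bridge on/off flags."""
    coords = model.base_coords.copy()
    if wobble is not None:
        coords[model.chain_b_atoms] += wobble
    donor_targets: Dict[int, List[np.ndarray]] = {}
    for bi, on in enumerate(on_flags):
        if on:
            _place_bridge(coords, model, bi, donor_targets)
        # off bridges stay parked (base state)
    for site_idx, targets in donor_targets.items():
        site = coords[site_idx]
        dirs = np.array([(t - site) / np.linalg.norm(t - site) for t in targets])
        mean_dir = dirs.mean(axis=0)
        mean_dir /= np.linalg.norm(mean_dir)
        h_idx = None
        for key, idx in model.site_atom.items():
            if idx == site_idx:
                h_idx = model.site_hydrogen.get(key)
        if h_idx is not None:
            coords[h_idx] = site + _OH_BOND * mean_dir
    return coords


def _verify_planted_geometry(model: InterfaceModel) -> None:
    """Self-check: the all-on noiseless frame yields exactly the planted bridges."""
    coords = _render_frame(model, [True] * len(model.spec.bridges))
    topo = model.topology
    table = assign_donors_acceptors(topo, coords)
    hbonds = detect_hbonds(coords, table)
    g1 = select_atoms(topo, "chain A and not water")
    g2 = select_atoms(topo, "chain B and not water")
    found = enumerate_water_bridges(hbonds, topo, g1, g2)
    found_keys = {(topo.residue_key(br.atom1)[2], topo.residue_key(br.atom2)[2],
                   br.water_set) for br in found}
    planted_keys = {(b.res1, b.res2, frozenset(model.bridge_waters[bi]))
                    for bi, b in enumerate(model.spec.bridges)}
    if found_keys != planted_keys:
        raise GeometryError(
            "planted bridge self-check failed: detected inventory "
            f"{sorted(found_keys)} != planted {sorted(planted_keys)}; "
            "the requested site/bridge layout creates accidental or missing links"
        )
    if count_direct_interface_hbonds(hbonds, g1, g2) != 0:
        raise GeometryError("planted geometry creates direct inter-protein H-bonds")


def render_trajectory(model: InterfaceModel, manifest: TruthManifest,
                      out_path=None) -> Trajectory:
    """Render the trajectory dictated by a schedule manifest.

    Noise and wobble random streams are derived from ``manifest.seed``, so a
    given (model, manifest, seed) renders byte-identical files.  The
    manifest's ``water_ids`` and ``trajectory_path`` fields are filled in.
    """
    spec = model.spec
    if len(manifest.on) != len(spec.bridges):
        raise ValueError("manifest bridge count does not match the interface spec")
    for (r1, r2), b in zip(manifest.pairs, spec.bridges):
        if (r1, r2) != (b.res1, b.res2):
            raise ValueError("manifest bridge pairs do not match the interface spec")
    manifest.water_ids = list(model.bridge_waters)

    noise_rng = np.random.default_rng([manifest.seed, 101])
    wobble_rng = np.random.default_rng([manifest.seed, 202])
    n_frames = manifest.n_frames
    frames = np.empty((n_frames, model.topology.n_atoms, 3))
    for f in range(n_frames):
        wobble = None
        if spec.rigid_body_amplitude > 0:
            wobble = spec.rigid_body_amplitude * wobble_rng.standard_normal(3)
        frames[f] = _render_frame(model, [on[f] for on in manifest.on], wobble)
    if spec.noise_sigma > 0:
        frames += spec.noise_sigma * noise_rng.standard_normal(frames.shape)

    traj = Trajectory(coords=frames)
    if out_path is not None:
        write_multimodel_pdb(out_path, model.topology, traj)
        manifest.trajectory_path = str(out_path)
    return traj


def manifest_pair_statistics(manifest: TruthManifest, model: InterfaceModel
                             ) -> Dict[str, Tuple[float, float]]:
    """Planted per-pair (occupancy, frequency) recomputed from the manifest alone.

    Distinct planted bridges of the same residue pair use disjoint dedicated
    waters, so each on-bridge contributes one distinct water path per frame.
    """
    topo = model.topology
    per_pair: Dict[str, List[np.ndarray]] = {}
    for bi, (r1, r2) in enumerate(manifest.pairs):
        a1 = model.site_atom[("A", r1, 0)]
        a2 = model.site_atom[("B", r2, 0)]
        pk = PairKey.from_residues(topo.residue_key(a1), topo.residue_key(a2))
        per_pair.setdefault(pk.label, []).append(manifest.on[bi])
    out: Dict[str, Tuple[float, float]] = {}
    for label, recs in per_pair.items():
        counts = np.sum(recs, axis=0)
        out[label] = (float(np.count_nonzero(counts) / manifest.n_frames),
                      float(counts.sum() / (1.0 * manifest.n_frames)))
    return out


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------

def random_scenario(rng: np.random.Generator, n_frames: int = 2000,
                    noise_sigma: float = 0.05) -> Tuple[InterfaceSpec, TruthManifest, InterfaceModel]:
    """A random but geometrically safe planted configuration.

    2-4 bridges on distinct residue pairs (one pair may carry a second,
    multiplexed bridge), random orders, occupancy targets uniform in
    [0.05, 0.95], mostly Bernoulli schedules with occasional Markov ones.
    """
    n_res = 6
    n_bridges = int(rng.integers(2, 5))
    residues = rng.permutation(np.arange(1, n_res + 1))[:n_bridges]
    bridges: List[PlantedBridge] = []
    donor_a: Set[int] = set()
    acceptor_a: Set[int] = set()
    donor_b: Set[int] = set()
    acceptor_b: Set[int] = set()
    for r in residues:
        r = int(r)
        order = int(rng.integers(1, 3))
        occ = float(rng.uniform(0.05, 0.95))
        if rng.random() < 0.25 and 0.1 < occ < 0.85:
            b = PlantedBridge.markov(r, r, occ, mean_on_frames=float(rng.uniform(8, 25)),
                                     order=order)
        else:
            b = PlantedBridge(r, r, order=order, occupancy_target=occ)
        bridges.append(b)
        (donor_a if rng.random() < 0.5 else acceptor_a).add(r)
        (donor_b if rng.random() < 0.5 else acceptor_b).add(r)
    if n_bridges >= 2 and rng.random() < 0.5:
        # a second water path over the first pair -> frequency can exceed 1
        r = int(residues[0])
        bridges.append(PlantedBridge(r, r, order=int(rng.integers(1, 3)),
                                     occupancy_target=float(rng.uniform(0.2, 0.8))))
    spec = InterfaceSpec(
        n_residues_per_chain=n_res,
        donor_sites={"A": tuple(sorted(donor_a)), "B": tuple(sorted(donor_b))},
        acceptor_sites={"A": tuple(sorted(acceptor_a)), "B": tuple(sorted(acceptor_b))},
        n_bulk_waters=int(rng.integers(4, 10)),
        noise_sigma=noise_sigma,
        bridges=tuple(bridges),
    )
    model = build_interface_topology(spec)
    manifest = simulate_bridge_schedule(spec.bridges, n_frames,
                                        seed=int(rng.integers(0, 2 ** 31 - 1)))
    return spec, manifest, model


#: planted occupancy targets of the default apo/holo study conditions.
#: The holo interface carries more bridges with higher occupancies than the
#: apo one (same qualitative pattern as a glue-stabilized interface); the
#: apo interface keeps a sparse, weakly occupied bridge set.
_CONDITION_BRIDGES = {
    "holo": (
        PlantedBridge(2, 2, order=1, occupancy_target=0.85),
        PlantedBridge(2, 2, order=2, occupancy_target=0.45),
        PlantedBridge(3, 3, order=2, occupancy_target=0.60),
        PlantedBridge(4, 4, order=1, occupancy_target=0.50),
        PlantedBridge(5, 5, order=2, occupancy_target=0.35),
        PlantedBridge(6, 6, order=1, occupancy_target=0.25),
    ),
    "apo": (
        PlantedBridge(2, 2, order=1, occupancy_target=0.30),
        PlantedBridge(4, 4, order=1, occupancy_target=0.15),
        PlantedBridge(6, 6, order=2, occupancy_target=0.08),
    ),
}


def paper_like_scenario(condition: str, noise_sigma: float = 0.05) -> InterfaceSpec:
    """Default apo/holo study conditions of the synthetic interface."""
    if condition not in _CONDITION_BRIDGES:
        raise ValueError("condition must be 'apo' or 'holo'")
    return InterfaceSpec(
        n_residues_per_chain=6,
        donor_sites={"A": (2, 4, 6), "B": (3, 5)},
        acceptor_sites={"A": (3, 5), "B": (2, 4, 6)},
        n_bulk_waters=8,
        noise_sigma=noise_sigma,
        bridges=_CONDITION_BRIDGES[condition],
    )
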