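"""Multi-model structure I/O, atom selection and covalent-hydrogen inference.

Conventions
-----------
* Coordinates are in Angstrom throughout.
* Frame indices are 0-based; residue numbers follow the authored PDB
  numbering (1-based for synthetic systems, arbitrary for deposited
  structures -- e.g. FRAP's kinase domain is numbered 2018-2112 and those
  numbers must survive untouched, because interface pairs are reported with
  author numbering such as Tyr2105).
* The natively tested trajectory format is multi-model PDB (one MODEL block
  per frame).  Binary formats (DCD/XTC/...) are mapped onto the same
  :class:`Trajectory` contract through MDAnalysis when it is installed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Topology",
    "Trajectory",
    "FormatError",
    "SelectionError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_binary_trajectory",
    "select_atoms",
    "infer_hydrogen_attachment",
]

#: residue names recognised as water
WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC", "H2O"})

#: backbone atom names (protein)
BACKBONE_NAMES = ("N", "CA", "C", "O")


class FormatError(ValueError):
    """Raised for malformed or internally inconsistent structure files."""


class SelectionError(ValueError):
    """Raised for malformed selection queries."""


@dataclass
class Topology:
    """Static atom table of a structure.

    Parallel arrays indexed by 0-based atom index.  ``serial`` keeps the
    authored atom serial numbers, ``resnum`` the authored residue numbers.
    ``h_attach`` maps a heavy-atom index to the indices of its covalently
    attached hydrogens.
    """

    serial: np.ndarray          # int
    name: np.ndarray            # str  (stripped atom names)
    element: np.ndarray         # str  (upper-case)
    resname: np.ndarray         # str
    resnum: np.ndarray          # int  (authored)
    chain: np.ndarray           # str
    is_water: np.ndarray        # bool
    h_attach: Dict[int, List[int]] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def residue_key(self, i: int) -> Tuple[str, str, int]:
        """(chain, resname, resnum) of atom ``i``."""
        return (str(self.chain[i]), str(self.resname[i]), int(self.resnum[i]))

    def water_molecules(self) -> Dict[Tuple[str, int], List[int]]:
        """Map (chain, resnum) of each water molecule to its atom indices."""
        out: Dict[Tuple[str, int], List[int]] = {}
        for i in np.nonzero(self.is_water)[0]:
            out.setdefault((str(self.chain[i]), int(self.resnum[i])), []).append(int(i))
        return out

    def validate(self) -> None:
        if len(np.unique(self.serial)) != self.n_atoms:
            raise FormatError("atom serial numbers are not unique")
        for heavy, hs in self.h_attach.items():
            for h in hs:
                if self.element[h] != "H":
                    raise FormatError(
                        f"atom {self.serial[h]} attached as hydrogen to {self.serial[heavy]} "
                        f"but has element {self.element[h]}"
                    )
        for key, idx in self.water_molecules().items():
            elems = sorted(self.element[i] for i in idx)
            if elems != ["H", "H", "O"]:
                raise FormatError(f"water {key} does not consist of exactly 1 O and 2 H (got {elems})")


@dataclass
class Trajectory:
    """Ordered frames of coordinates congruent with a :class:`Topology`.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``box`` is an
    optional (n_frames, 3) array of orthorhombic box edge lengths.
    """

    coords: np.ndarray
    box: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("trajectory coordinates must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE", "CA", "MN", "CU", "SE"}


def _element_from_name(name: str, resname: str) -> str:
    """Infer the element from a PDB atom name when the element field is absent.

    The first alphabetic character after stripping leading digits is used;
    calcium ions (resname CA) are the only two-letter case we disambiguate,
    since an atom *named* CA in a protein residue is an alpha carbon.
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise FormatError(f"cannot infer element from atom name {name!r}")
    if resname.strip() in _TWO_LETTER_ELEMENTS and stripped.upper() == resname.strip():
        return stripped.upper()
    return stripped[0].upper()


def read_multimodel_pdb(path) -> Tuple[Topology, Trajectory]:
    """Read a (multi-model) PDB file into a topology and trajectory.

    One frame per MODEL block; a file without MODEL records yields a single
    frame.  Alternate locations are resolved by keeping the highest-occupancy
    conformer.  Hydrogen attachment is inferred from frame 0 (see
    :func:`infer_hydrogen_attachment`).

    Raises
    ------
    FormatError
        If atom counts differ between models (the offending model is named)
        or an ATOM/HETATM line cannot be parsed (the line number is named).
    """
    path = Path(path)
    frames: List[List[Tuple[float, float, float]]] = []
    cur: List[Tuple[float, float, float]] = []
    meta: List[Tuple[int, str, str, str, str, int, bool, str, float]] = []
    first_model = True
    model_label = 1
    box = None
    in_model = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    box = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
                except ValueError:
                    raise FormatError(f"{path.name}: unparseable CRYST1 record at line {lineno}")
            elif rec == "MODEL ":
                if cur:
                    frames.append(cur)
                    cur = []
                    first_model = False
                in_model = True
                try:
                    model_label = int(line.split()[1])
                except (IndexError, ValueError):
                    model_label = len(frames) + 1
            elif rec == "ENDMDL":
                if frames and len(cur) != len(frames[0]):
                    raise FormatError(
                        f"{path.name}: MODEL {model_label} has {len(cur)} atoms, "
                        f"expected {len(frames[0])}"
                    )
                frames.append(cur)
                cur = []
                first_model = False
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    altloc = line[16].strip()
                    resname = line[17:20].strip()
                    chain = line[21].strip() or " "
                    resnum = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    occ_str = line[54:60].strip()
                    occupancy = float(occ_str) if occ_str else 1.0
                    element = line[76:78].strip().upper() if len(line) >= 78 else ""
                except (ValueError, IndexError):
                    raise FormatError(f"{path.name}: unparseable {rec.strip()} line {lineno}")
                if not element:
                    element = _element_from_name(name, resname)
                cur.append((x, y, z))
                if first_model:
                    meta.append((serial, name, element, resname, chain, resnum,
                                 resname in WATER_RESNAMES, altloc, occupancy))

    if cur:
        if frames and len(cur) != len(frames[0]):
            raise FormatError(
                f"{path.name}: MODEL {model_label} has {len(cur)} atoms, expected {len(frames[0])}"
            )
        frames.append(cur)
    if not frames:
        raise FormatError(f"{path.name}: no coordinates found")

    keep = _resolve_altlocs(meta)
    coords = np.asarray(frames, dtype=float)[:, keep, :]
    meta = [meta[i] for i in keep]

    topo = Topology(
        serial=np.array([m[0] for m in meta], dtype=int),
        name=np.array([m[1] for m in meta], dtype=object),
        element=np.array([m[2] for m in meta], dtype=object),
        resname=np.array([m[3] for m in meta], dtype=object),
        chain=np.array([m[4] for m in meta], dtype=object),
        resnum=np.array([m[5] for m in meta], dtype=int),
        is_water=np.array([m[6] for m in meta], dtype=bool),
    )
    topo.h_attach = infer_hydrogen_attachment(topo, coords[0])
    topo.validate()
    box_arr = None
    if box is not None:
        box_arr = np.tile(np.asarray(box, dtype=float), (coords.shape[0], 1))
    return topo, Trajectory(coords=coords, box=box_arr)


def _resolve_altlocs(meta) -> List[int]:
    """Indices to keep, resolving alternate locations by highest occupancy."""
    best: Dict[Tuple[str, int, str, str], Tuple[float, int]] = {}
    order: List[Tuple[str, int, str, str]] = []
    for i, m in enumerate(meta):
        key = (m[4], m[5], m[3], m[1])  # chain, resnum, resname, atom name
        if m[7] == "":  # no altloc: always keep (duplicates without altloc are legitimate serials)
            key = key + (i,)  # type: ignore[assignment]
        if key not in best:
            best[key] = (m[8], i)
            order.append(key)
        elif m[8] > best[key][0]:
            best[key] = (m[8], i)
    return sorted(best[k][1] for k in order)


def write_multimodel_pdb(path, topology: Topology, trajectory: Trajectory) -> None:
    """Write a trajectory as a fixed-column multi-model PDB file.

    Waters are written as HETATM, everything else as ATOM; coordinates are
    rounded to 3 decimals (PDB precision).
    """
    if trajectory.n_atoms != topology.n_atoms:
        raise FormatError("topology and trajectory atom counts differ")
    lines: List[str] = []
    if trajectory.box is not None:
        a, b, c = trajectory.box[0]
        lines.append(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}  90.00  90.00  90.00 P 1           1")
    multi = trajectory.n_frames > 1
    for f in range(trajectory.n_frames):
        if multi:
            lines.append(f"MODEL     {f + 1:4d}")
        for i in range(topology.n_atoms):
            rec = "HETATM" if topology.is_water[i] else "ATOM  "
            name = str(topology.name[i])
            # PDB name column alignment: 1/2-char element names start in col 14
            pname = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = trajectory.coords[f, i]
            elem = str(topology.element[i])
            lines.append(
                f"{rec}{int(topology.serial[i]) % 100000:5d} {pname:<4s}{'':1s}"
                f"{str(topology.resname[i]):<3s} {str(topology.chain[i]):1s}"
                f"{int(topology.resnum[i]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {elem:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_binary_trajectory(topology_path, trajectory_path) -> Tuple[Topology, Trajectory]:
    """Read a binary trajectory (DCD/XTC/TRR/...) through MDAnalysis.

    The topology is taken from a PDB file; the result satisfies the same
    :class:`Trajectory` contract as :func:`read_multimodel_pdb`.
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError("binary trajectory support requires MDAnalysis") from exc
    topo, _ = read_multimodel_pdb(topology_path)
    u = mda.Universe(str(topology_path), str(trajectory_path))
    if len(u.atoms) != topo.n_atoms:
        raise FormatError(
            f"trajectory has {len(u.atoms)} atoms, topology has {topo.n_atoms}"
        )
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = np.array([u.dimensions[:3].copy() for _ in u.trajectory], dtype=float)
    return topo, Trajectory(coords=coords, box=box)


# ---------------------------------------------------------------------------
# hydrogen attachment
# ---------------------------------------------------------------------------

def infer_hydrogen_attachment(topology: Topology, frame0: np.ndarray,
                              max_bond: float = 1.2) -> Dict[int, List[int]]:
    """Assign each hydrogen to its nearest heavy atom within ``max_bond`` A.

    Candidates are restricted to the hydrogen's own residue (name convention:
    hydrogens are authored inside the residue they belong to).  Hydrogens with
    no heavy atom within the cutoff are left unattached.
    """
    frame0 = np.asarray(frame0, dtype=float)
    attach: Dict[int, List[int]] = {}
    res_atoms: Dict[Tuple[str, int], List[int]] = {}
    for i in range(topology.n_atoms):
        res_atoms.setdefault((str(topology.chain[i]), int(topology.resnum[i])), []).append(i)
    for i in range(topology.n_atoms):
        if topology.element[i] != "H":
            continue
        sibs = [j for j in res_atoms[(str(topology.chain[i]), int(topology.resnum[i]))]
                if topology.element[j] != "H"]
        if not sibs:
            continue
        d = np.linalg.norm(frame0[sibs] - frame0[i], axis=1)
        k = int(np.argmin(d))
        if d[k] <= max_bond:
            attach.setdefault(sibs[k], []).append(i)
    return attach


# ---------------------------------------------------------------------------
# atom selection
# ---------------------------------------------------------------------------

def select_atoms(topology: Topology, query: str) -> np.ndarray:
    """Select atom indices with a small AND-combined query grammar.

    Clauses (joined with ``and``):

    * ``chain A [B ...]``   -- chain identifiers
    * ``resid 5`` / ``resid 5-20`` / ``resid 5 8 12-20``
    * ``name N CA C O``     -- atom-name list
    * ``water`` / ``not water``
    * ``backbone``          -- protein N, CA, C, O (excludes waters)
    * ``protein``           -- alias of ``not water``
    * ``all``

    Returns a sorted (order-preserving) integer index array.  Unknown chains
    or residue numbers yield an empty selection with a warning; a malformed
    query raises :class:`SelectionError`.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    query = query.strip()
    if not query:
        raise SelectionError("empty selection query")
    for clause in [c.strip() for c in query.split(" and ")]:
        toks = clause.split()
        if not toks:
            raise SelectionError(f"empty clause in query {query!r}")
        kw = toks[0].lower()
        if kw == "chain":
            if len(toks) < 2:
                raise SelectionError("'chain' requires at least one chain id")
            wanted = set(toks[1:])
            missing = wanted - set(str(c) for c in topology.chain)
            if missing:
                warnings.warn(f"unknown chain(s) {sorted(missing)}: selection may be empty")
            mask &= np.isin(topology.chain.astype(str), list(wanted))
        elif kw == "resid":
            if len(toks) < 2:
                raise SelectionError("'resid' requires residue numbers or ranges")
            wanted_res: set = set()
            for t in toks[1:]:
                if "-" in t[1:]:  # allow negative single numbers
                    lo, hi = t.rsplit("-", 1) if not t.startswith("-") else (t, None)
                    try:
                        lo_i, hi_i = int(lo), int(hi)
                    except (TypeError, ValueError):
                        raise SelectionError(f"bad residue range {t!r}")
                    if hi_i < lo_i:
                        raise SelectionError(f"bad residue range {t!r}")
                    wanted_res.update(range(lo_i, hi_i + 1))
                else:
                    try:
                        wanted_res.add(int(t))
                    except ValueError:
                        raise SelectionError(f"bad residue number {t!r}")
            present = set(int(r) for r in topology.resnum)
            if not (wanted_res & present):
                warnings.warn(f"no atoms with residue number in {sorted(wanted_res)[:5]}...")
            mask &= np.isin(topology.resnum, list(wanted_res))
        elif kw == "name":
            if len(toks) < 2:
                raise SelectionError("'name' requires at least one atom name")
            mask &= np.isin(topology.name.astype(str), toks[1:])
        elif kw == "water":
            mask &= topology.is_water
        elif kw == "not":
            if len(toks) == 2 and toks[1].lower() == "water":
                mask &= ~topology.is_water
            else:
                raise SelectionError(f"unsupported negation {clause!r}")
        elif kw == "protein":
            mask &= ~topology.is_water
        elif kw == "backbone":
            mask &= (~topology.is_water) & np.isin(topology.name.astype(str), BACKBONE_NAMES)
        elif kw == "all":
            pass
        else:
            raise SelectionError(f"unknown selection keyword {toks[0]!r}")
    return np.nonzero(mask)[0]
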