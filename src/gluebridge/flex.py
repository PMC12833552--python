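"""Superposition-based flexibility and proximity analysis.

RMSD/RMSF are computed after optimal least-squares rigid-body superposition
(Kabsch; proper rotation, det = +1, no reflection) of every frame onto a
reference over an alignment selection -- typically the backbone (N, CA, C,
O) of one protein, after which fluctuations of all chains are profiled.
No mass weighting is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from gluebridge.structio import Topology

__all__ = [
    "FlexProfile",
    "ProximityStat",
    "kabsch_rotation",
    "superpose_and_rmsd",
    "rmsf_profile",
    "min_interchain_distance",
]


@dataclass
class FlexProfile:
    """Per-residue RMSF profile plus the per-frame RMSD of the alignment."""

    selection: str
    reference_frame: int
    residue_keys: List[Tuple[str, str, int]]   # (chain, resname, resnum)
    rmsf_per_residue: np.ndarray               # (n_residues,)
    rmsf_per_atom: np.ndarray                  # (n_selected_atoms,)
    rmsd_per_frame: Optional[np.ndarray] = None


@dataclass
class ProximityStat:
    """Per-frame minimum inter-group atom distance with its mean +/- SD."""

    label: str
    per_frame_min: np.ndarray
    mean: float
    sd: float


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation + translation mapping ``mobile`` onto ``reference``.

    Returns (R, t, rmsd) with ``R @ (x - mobile_centroid) + t`` the aligned
    coordinates.  Uses the SVD form of the Kabsch solution with the
    determinant correction, so the rotation is always proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    a = mobile - mc
    b = reference - rc
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    aligned = a @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - b) ** 2, axis=1))))
    return rot, rc, rmsd


def _check_alignment_selection(ref_sel: np.ndarray) -> None:
    if ref_sel.shape[0] < 3:
        raise ValueError("alignment selection needs at least 3 atoms")
    centered = ref_sel - ref_sel.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("alignment selection atoms are collinear; superposition is degenerate")


def superpose_and_rmsd(coords: np.ndarray, align_idx: np.ndarray,
                       reference: int | np.ndarray = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Superpose every frame onto a reference over ``align_idx``.

    Parameters
    ----------
    coords : (n_frames, n_atoms, 3) trajectory coordinates (A)
    align_idx : atom indices used both for the fit and the RMSD
    reference : frame index (default 0) or explicit (n_atoms, 3) array

    Returns
    -------
    aligned : (n_frames, n_atoms, 3) aligned coordinates (all atoms moved by
        the fit transform)
    rmsd : (n_frames,) RMSD over ``align_idx`` after alignment
    """
    coords = np.asarray(coords, dtype=float)
    align_idx = np.asarray(align_idx, dtype=int)
    ref = coords[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference, dtype=float)
    ref_sel = ref[align_idx]
    _check_alignment_selection(ref_sel)
    ref_centroid = ref_sel.mean(axis=0)

    aligned = np.empty_like(coords)
    rmsd = np.empty(coords.shape[0])
    for f in range(coords.shape[0]):
        rot, _, r = kabsch_rotation(coords[f, align_idx], ref_sel)
        mc = coords[f, align_idx].mean(axis=0)
        aligned[f] = (coords[f] - mc) @ rot.T + ref_centroid
        rmsd[f] = r
    return aligned, rmsd


def rmsf_profile(aligned: np.ndarray, topology: Topology, sel_idx: np.ndarray,
                 selection: str = "", reference_frame: int = 0) -> FlexProfile:
    """Root-mean-square fluctuation about the time-average position.

    Per-atom RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|^2); the per-residue value
    is the mean over the residue's selected (typically backbone) atoms.  The
    trajectory must already be aligned.
    """
    aligned = np.asarray(aligned, dtype=float)
    sel_idx = np.asarray(sel_idx, dtype=int)
    if sel_idx.size == 0:
        raise ValueError("empty RMSF selection")
    if aligned.shape[0] < 2:
        warnings.warn("single-frame trajectory: RMSF is identically zero")
    sub = aligned[:, sel_idx, :]
    mean_pos = sub.mean(axis=0)
    rmsf_atom = np.sqrt(np.mean(np.sum((sub - mean_pos) ** 2, axis=2), axis=0))

    res_keys: List[Tuple[str, str, int]] = []
    res_index: Dict[Tuple[str, str, int], List[int]] = {}
    for k, i in enumerate(sel_idx):
        key = topology.residue_key(int(i))
        if key not in res_index:
            res_index[key] = []
            res_keys.append(key)
        res_index[key].append(k)
    rmsf_res = np.array([rmsf_atom[res_index[key]].mean() for key in res_keys])
    return FlexProfile(
        selection=selection,
        reference_frame=reference_frame,
        residue_keys=res_keys,
        rmsf_per_residue=rmsf_res,
        rmsf_per_atom=rmsf_atom,
    )


def min_interchain_distance(coords: np.ndarray, group1: np.ndarray, group2: np.ndarray,
                            label: str = "") -> ProximityStat:
    """Per-frame minimum distance between any atom of group1 and of group2."""
    group1 = np.asarray(group1, dtype=int)
    group2 = np.asarray(group2, dtype=int)
    if group1.size == 0 or group2.size == 0:
        raise ValueError("distance groups must be non-empty")
    if set(group1.tolist()) & set(group2.tolist()):
        raise ValueError("distance groups must be disjoint")
    coords = np.asarray(coords, dtype=float)
    mins = np.empty(coords.shape[0])
    for f in range(coords.shape[0]):
        mins[f] = cdist(coords[f, group1], coords[f, group2]).min()
    sd = float(mins.std(ddof=1)) if len(mins) > 1 else 0.0
    return ProximityStat(label=label, per_frame_min=mins, mean=float(mins.mean()), sd=sd)
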