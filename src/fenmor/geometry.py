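"""Geometric binding descriptors.

Implements the descriptor set used to characterize ligand pose in the
orthosteric pocket of a pre-oriented (membrane normal = lab z) receptor:

* FEN-D147 distance: minimum heavy-atom distance from the piperidine amine
  nitrogen to the Asp147 carboxylate oxygens;
* FEN-H297 distance: piperidine nitrogen to the *unprotonated* imidazole
  nitrogen of His297 (tautomer-dependent);
* dZ: z-separation of the ligand and receptor mass-weighted centers of mass,
  with the disordered terminal residue ranges excluded from the receptor;
* ligand RMSD after best-fit superposition on receptor C-alpha atoms;
* vertical angle between the ligand long axis and +z;
* chi2 sidechain dihedrals (His: CA-CB-CG-ND1, Trp: CA-CB-CG-CD1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from MDAnalysis.lib.distances import calc_dihedrals
from MDAnalysis.analysis.align import rotation_matrix

from .errors import DataError, SelectionError
from .structure import MolecularSystem, SelectionMap

log = logging.getLogger(__name__)

#: residue-specific 4th atom of the chi2 dihedral
CHI2_FOURTH_ATOM = {"HIS": "ND1", "HID": "ND1", "HIE": "ND1", "HIP": "ND1",
                    "TRP": "CD1"}


def min_heavy_distance(system: MolecularSystem, frame: int,
                       set_a, set_b) -> float:
    """Minimum pairwise Euclidean distance between two atom index sets (A)."""
    set_a = np.asarray(set_a, dtype=int)
    set_b = np.asarray(set_b, dtype=int)
    if set_a.size == 0 or set_b.size == 0:
        raise SelectionError("min_heavy_distance: empty atom set")
    pos = system.positions(frame)
    return float(cdist(pos[set_a], pos[set_b]).min())


def fen_d147_distance(system: MolecularSystem, frame: int,
                      selmap: SelectionMap) -> float:
    """Key-nitrogen to carboxylate-oxygen minimum distance (A)."""
    return min_heavy_distance(
        system, frame, [selmap.ligand_key_nitrogen],
        selmap.acidic_carboxylate_oxygens,
    )


_HIP_WARNED = False


def fen_h297_distance(system: MolecularSystem, frame: int,
                      selmap: SelectionMap, his_state: str = "HID") -> float:
    """Key-nitrogen to unprotonated imidazole nitrogen distance (A).

    HID leaves N-epsilon unprotonated, HIE leaves N-delta unprotonated.  HIP
    has no unprotonated nitrogen; by convention N-epsilon is used (logged).
    """
    global _HIP_WARNED
    state = his_state.upper()
    if state == "HID":
        n_idx = selmap.his_Nepsilon
    elif state == "HIE":
        n_idx = selmap.his_Ndelta
    elif state == "HIP":
        if not _HIP_WARNED:
            log.warning(
                "HIP has no unprotonated imidazole nitrogen; using N-epsilon "
                "by convention"
            )
            _HIP_WARNED = True
        n_idx = selmap.his_Nepsilon
    else:
        raise DataError(f"unknown histidine state: {his_state!r}")
    return min_heavy_distance(system, frame, [selmap.ligand_key_nitrogen], [n_idx])


def _com(pos: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return (pos * masses[:, None]).sum(axis=0) / masses.sum()


def delta_z(system: MolecularSystem, frame: int, selmap: SelectionMap) -> float:
    """(ligand COM z) - (receptor COM z), mass-weighted, terminal ranges
    excluded from the receptor set only."""
    pos = system.positions(frame)
    masses = system.atoms["mass"].to_numpy()
    lig = np.asarray(selmap.ligand_heavy)
    rec = selmap.receptor_com_retained(system)
    return float(_com(pos[lig], masses[lig])[2] - _com(pos[rec], masses[rec])[2])


def vertical_angle(system: MolecularSystem, frame: int,
                   selmap: SelectionMap) -> float:
    """Angle (deg, [0, 180]) between the ligand axis and +z.

    The axis runs from the key nitrogen to the centroid of the configured
    axis-head atoms (default: the phenethyl ring).
    """
    head = np.asarray(selmap.ligand_axis_head)
    if head is None or head.size == 0:
        raise SelectionError("ligand axis head atoms not configured")
    pos = system.positions(frame)
    v = pos[head].mean(axis=0) - pos[selmap.ligand_key_nitrogen]
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise DataError("zero-length ligand axis")
    return float(np.degrees(np.arccos(np.clip(v[2] / norm, -1.0, 1.0))))


def ligand_rmsd(system: MolecularSystem, frame: int, reference_frame: int,
                selmap: SelectionMap) -> float:
    """Ligand heavy-atom RMSD after best-fit superposition on receptor
    C-alpha atoms (terminal exclusions applied); no re-fit on the ligand."""
    a = system.atoms
    ca = np.flatnonzero(((a["name"] == "CA") & ~a["is_ligand"]).to_numpy())
    resids = a["resid"].to_numpy()[ca]
    keep = np.ones(ca.size, dtype=bool)
    for lo, hi in selmap.excluded_terminal_residues:
        keep &= ~((resids >= lo) & (resids <= hi))
    fit = ca[keep]
    if fit.size < 3:
        raise SelectionError(f"need >= 3 fitting atoms, have {fit.size}")
    lig = np.asarray(selmap.ligand_heavy)

    mob, ref = system.positions(frame), system.positions(reference_frame)
    com_mob, com_ref = mob[fit].mean(axis=0), ref[fit].mean(axis=0)
    R, _ = rotation_matrix(mob[fit] - com_mob, ref[fit] - com_ref)
    lig_fit = (mob[lig] - com_mob) @ R.T + com_ref
    return float(np.sqrt(((lig_fit - ref[lig]) ** 2).sum(axis=1).mean()))


def chi2(system: MolecularSystem, frame: int, resid: int) -> float:
    """chi2 sidechain dihedral (deg, (-180, 180], IUPAC sign convention)."""
    a = system.atoms
    res = a[(a["resid"] == resid) & ~a["is_ligand"]]
    if res.empty:
        raise SelectionError(f"no residue {resid}")
    resname = res["resname"].iloc[0]
    fourth = CHI2_FOURTH_ATOM.get(resname)
    if fourth is None:
        raise DataError(f"chi2 undefined for residue type {resname}")
    idx = []
    for name in ("CA", "CB", "CG", fourth):
        hit = res[res["name"] == name]
        if hit.empty:
            raise SelectionError(f"residue {resid} ({resname}) missing atom {name}")
        idx.append(hit.index[0])
    pos = system.positions(frame)
    ang = calc_dihedrals(
        pos[idx[0]][None, :], pos[idx[1]][None, :],
        pos[idx[2]][None, :], pos[idx[3]][None, :],
    )
    deg = float(np.degrees(ang[0]))
    if deg <= -180.0:
        deg += 360.0
    return deg


def unwrap_degrees(series) -> np.ndarray:
    """Unwrap a dihedral time series through the +/-180 deg boundary."""
    return np.degrees(np.unwrap(np.radians(np.asarray(series, dtype=float))))


def com_xy_positions(system: MolecularSystem, frames, selections: dict,
                     selmap: SelectionMap, reference_vector=(1.0, 0.0, 0.0),
                     stride: int = 1) -> pd.DataFrame:
    """Mass-weighted COM positions of named entities in a receptor-centered
    frame: origin = receptor COM; z = lab z (membrane normal); x = the
    reference vector projected into the xy-plane; y completes a right-handed
    frame.  ``reference_vector`` is either a 3-vector or a pair of atom
    indices (tail, head) evaluated per frame.
    """
    frames = list(frames)[::stride]
    masses = system.atoms["mass"].to_numpy()
    rec = selmap.receptor_com_retained(system)
    rows = []
    for f in frames:
        pos = system.positions(f)
        origin = _com(pos[rec], masses[rec])
        if isinstance(reference_vector, (tuple, list, np.ndarray)) and len(reference_vector) == 2:
            tail, head = (int(i) for i in reference_vector)
            ref = pos[head] - pos[tail]
        else:
            ref = np.asarray(reference_vector, dtype=float)
        proj = np.array([ref[0], ref[1], 0.0])
        norm = np.linalg.norm(proj)
        if norm < 1e-6:
            raise DataError("degenerate reference vector (xy projection ~ 0)")
        x_ax = proj / norm
        z_ax = np.array([0.0, 0.0, 1.0])
        y_ax = np.cross(z_ax, x_ax)
        for label, sel in selections.items():
            sel = np.asarray(sel, dtype=int)
            d = _com(pos[sel], masses[sel]) - origin
            rows.append({
                "entity": label, "frame": f, "time_ns": system.times[f],
                "x": float(d @ x_ax), "y": float(d @ y_ax), "z": float(d @ z_ax),
            })
    return pd.DataFrame(rows)


def compute_descriptors(system: MolecularSystem, selmap: SelectionMap,
                        his_state: str = "HID", reference_frame: int = 0,
                        chi2_residues=()) -> pd.DataFrame:
    """Per-frame descriptor table: ``frame, time_ns, fen_d147, fen_h297,
    delta_z, rmsd, vertical_angle[, chi2_<resid>...]``."""
    rows = []
    for f in range(system.n_frames):
        row = {
            "frame": f,
            "time_ns": system.times[f],
            "fen_d147": fen_d147_distance(system, f, selmap),
            "fen_h297": fen_h297_distance(system, f, selmap, his_state),
            "delta_z": delta_z(system, f, selmap),
            "rmsd": ligand_rmsd(system, f, reference_frame, selmap),
            "vertical_angle": vertical_angle(system, f, selmap),
        }
        for resid in chi2_residues:
            row[f"chi2_{resid}"] = chi2(system, f, resid)
        rows.append(row)
    return pd.DataFrame(rows)
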