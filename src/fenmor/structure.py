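"""Structure/trajectory I/O and named atom selections.

The analysis layer consumes a :class:`MolecularSystem`: an atoms table
(roles: ligand substituent labels, receptor residue/sidechain annotations)
plus an in-memory coordinate block, one row per frame.  MDAnalysis does the
actual PDB/XTC parsing and writing; this module only attaches the domain
roles the downstream modules need.

Conventions
-----------
* coordinates in Angstrom, times in ns;
* frames are 0-based internally, residue numbers are 1-based as in the PDB;
* "heavy atom" means element != H throughout;
* sidechain = all residue heavy atoms except backbone N, CA, C, O (and OXT).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import MDAnalysis as mda
from MDAnalysis.coordinates.memory import MemoryReader

from .errors import SelectionError, StructureError

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

#: standard atomic masses (u) for mass-weighted centers of mass
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
}

DEFAULT_LIGAND_RESNAMES = frozenset({"LIG", "FEN", "UNL", "BU72"})

#: fentanyl substituent groups: toy atom name -> group label.  The 4-axial
#: hydrogen position is carried by its bonded piperidine carbon (C4), since a
#: hydrogen cannot take part in heavy-atom contacts.
FENTANYL_SUBSTITUENTS = {
    "N1": "piperidine",
    "C2": "piperidine",
    "C6": "piperidine",
    "C4": "axial_h",
    "C7": "propanamide",
    "O1": "propanamide",
    "C8": "propanamide",
    "C9": "phenyl",
    "C10": "phenyl",
    "C11": "phenethyl",
    "C12": "phenethyl",
    "C13": "phenethyl",
    "C14": "phenethyl",
    "C15": "phenethyl",
}

#: atoms whose centroid defines the ligand long-axis head (phenethyl ring)
LIGAND_AXIS_HEAD_ATOMS = ("C13", "C14", "C15")
#: ligand key (piperidine amine) nitrogen
LIGAND_KEY_NITROGEN = "N1"


def element_from_name(name: str) -> str:
    """Guess an element symbol from a PDB atom name (first alpha character)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def mass_of(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), 12.011)


@dataclass
class MolecularSystem:
    """Atoms with roles plus per-frame coordinates.

    Parameters
    ----------
    atoms
        One row per atom with columns ``serial, name, element, resid,
        resname, chain, is_ligand, is_sidechain, substituent, mass``.
    coords
        ``(n_frames, n_atoms, 3)`` array, Angstrom.
    times
        ``(n_frames,)`` array of frame times in ns.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError(
                f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.shape[0] != self.times.shape[0]:
            raise StructureError("one time per frame required")
        if self.coords.shape[1] != len(self.atoms):
            raise StructureError(
                f"coordinate block has {self.coords.shape[1]} atoms but the "
                f"topology has {len(self.atoms)}"
            )
        if not np.isfinite(self.coords).all():
            raise StructureError("non-finite coordinates")
        if self.atoms["serial"].duplicated().any():
            raise StructureError("duplicate atom serials")
        lig_heavy = self.atoms[
            self.atoms["is_ligand"] & (self.atoms["element"] != "H")
        ]
        if lig_heavy["substituent"].isna().any():
            missing = lig_heavy.loc[lig_heavy["substituent"].isna(), "name"]
            raise StructureError(
                "ligand heavy atoms without a substituent label: "
                + ", ".join(missing)
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def positions(self, frame: int) -> np.ndarray:
        """Coordinates of one frame, ``(n_atoms, 3)`` Angstrom."""
        return self.coords[frame]

    def ligand_heavy_indices(self) -> np.ndarray:
        a = self.atoms
        return np.flatnonzero(a["is_ligand"].to_numpy() & (a["element"] != "H").to_numpy())

    def receptor_sidechain_heavy(self) -> pd.DataFrame:
        """Receptor sidechain heavy atoms (the contact-eligible set)."""
        a = self.atoms
        mask = (~a["is_ligand"]) & a["is_sidechain"] & (a["element"] != "H")
        return a[mask]


def _annotate(atoms: pd.DataFrame, ligand_resnames, substituent_map) -> pd.DataFrame:
    atoms = atoms.copy()
    atoms["is_ligand"] = atoms["resname"].isin(ligand_resnames)
    atoms["is_sidechain"] = (~atoms["is_ligand"]) & ~atoms["name"].isin(BACKBONE_NAMES)
    atoms["substituent"] = pd.Series(
        [
            substituent_map.get(n) if lig else None
            for n, lig in zip(atoms["name"], atoms["is_ligand"])
        ],
        index=atoms.index,
        dtype=object,
    )
    atoms["mass"] = atoms["element"].map(mass_of)
    return atoms


def _trajectory_n_atoms(path: Path) -> int | None:
    try:
        reader = mda.coordinates.core.reader(str(path))
        n = reader.n_atoms
        reader.close()
        return n
    except Exception:
        return None


def load_system(
    topology_path,
    trajectory_path=None,
    *,
    ligand_resnames=DEFAULT_LIGAND_RESNAMES,
    substituent_map=None,
) -> MolecularSystem:
    """Load a PDB topology and (optionally) a trajectory.

    With no trajectory the single frame comes from the topology coordinates.
    Substituent labels are assigned to ligand atoms by atom name from
    ``substituent_map`` (default: the fentanyl toy mapping).
    """
    topology_path = Path(topology_path)
    if substituent_map is None:
        substituent_map = FENTANYL_SUBSTITUENTS
    if not topology_path.exists():
        raise StructureError(f"topology not found: {topology_path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            if trajectory_path is None:
                u = mda.Universe(str(topology_path))
            else:
                trajectory_path = Path(trajectory_path)
                if not trajectory_path.exists():
                    raise StructureError(
                        f"trajectory not found: {trajectory_path}")
                u = mda.Universe(str(topology_path), str(trajectory_path))
    except StructureError:
        raise
    except Exception as exc:
        n_top = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                n_top = len(mda.Universe(str(topology_path)).atoms)
        except Exception:
            pass
        n_trj = _trajectory_n_atoms(trajectory_path) if trajectory_path else None
        if n_top is not None and n_trj is not None and n_top != n_trj:
            raise StructureError(
                f"atom count mismatch: topology has {n_top} atoms, "
                f"trajectory has {n_trj}"
            ) from exc
        raise StructureError(f"failed to load system: {exc}") from exc

    names = [n.strip() for n in u.atoms.names]
    try:
        elements = [e.upper() if e else element_from_name(n)
                    for e, n in zip(u.atoms.elements, names)]
    except mda.exceptions.NoDataError:
        elements = [element_from_name(n) for n in names]
    try:
        chains = list(u.atoms.chainIDs)
    except mda.exceptions.NoDataError:
        chains = [""] * len(names)
    atoms = pd.DataFrame(
        {
            "serial": np.arange(1, len(names) + 1),
            "name": names,
            "element": elements,
            "resid": u.atoms.resids,
            "resname": [r.strip() for r in u.atoms.resnames],
            "chain": chains,
        }
    )
    atoms = _annotate(atoms, ligand_resnames, substituent_map)

    frames = []
    times = []
    with warnings.catch_warnings():
        # single-frame PDBs have no dt; placeholder CRYST1 records are fine
        warnings.simplefilter("ignore", UserWarning)
        for ts in u.trajectory:
            frames.append(ts.positions.astype(float).copy())
            # MDAnalysis times are ps; we keep ns
            times.append(float(ts.time) / 1000.0 if np.isfinite(ts.time) else 0.0)
    return MolecularSystem(atoms=atoms, coords=np.array(frames), times=np.array(times))


def system_from_arrays(
    atoms: pd.DataFrame,
    coords: np.ndarray,
    times=None,
    *,
    ligand_resnames=DEFAULT_LIGAND_RESNAMES,
    substituent_map=None,
) -> MolecularSystem:
    """Build a system from a raw atoms table (``serial, name, resid, resname,
    chain`` and optionally ``element``) plus coordinates; roles are derived."""
    atoms = atoms.copy()
    if "element" not in atoms:
        atoms["element"] = [element_from_name(n) for n in atoms["name"]]
    if substituent_map is None:
        substituent_map = FENTANYL_SUBSTITUENTS
    atoms = _annotate(atoms, ligand_resnames, substituent_map)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    if times is None:
        times = np.arange(coords.shape[0], dtype=float)
    return MolecularSystem(atoms=atoms, coords=coords, times=np.asarray(times, float))


def to_universe(system: MolecularSystem) -> mda.Universe:
    """Materialize an MDAnalysis Universe (MemoryReader) from a system."""
    a = system.atoms
    resid_codes, res_starts = pd.factorize(
        pd.Series(list(zip(a["resid"], a["resname"], a["chain"]))), sort=False
    )
    n_res = len(res_starts)
    u = mda.Universe.empty(
        n_atoms=len(a),
        n_residues=n_res,
        n_segments=1,
        atom_resindex=resid_codes,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=False,
    )
    u.add_TopologyAttr("names", list(a["name"]))
    u.add_TopologyAttr("elements", list(a["element"]))
    u.add_TopologyAttr("chainIDs", [c if c else "A" for c in a["chain"]])
    u.add_TopologyAttr("resids", [r for r, _, _ in res_starts])
    u.add_TopologyAttr("resnames", [rn for _, rn, _ in res_starts])
    u.add_TopologyAttr("masses", list(a["mass"]))
    u.load_new(
        system.coords.astype(np.float32),
        format=MemoryReader,
        dt=float(np.diff(system.times).mean() * 1000.0) if system.n_frames > 1 else 1.0,
    )
    return u


def write_pdb(system: MolecularSystem, path, frame: int = 0) -> None:
    """Write one frame as a single-MODEL PDB (topology file)."""
    u = to_universe(system)
    u.trajectory[frame]
    with warnings.catch_warnings():
        # the toy topologies legitimately lack altLocs/occupancies/...
        warnings.simplefilter("ignore", UserWarning)
        with mda.Writer(str(path), n_atoms=system.n_atoms) as w:
            w.write(u.atoms)


def write_xtc(system: MolecularSystem, path) -> None:
    """Write all frames as an XTC trajectory (coordinates only)."""
    u = to_universe(system)
    with mda.Writer(str(path), n_atoms=system.n_atoms) as w:
        for i, ts in enumerate(u.trajectory):
            ts.time = system.times[i] * 1000.0  # ns -> ps
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def resolve_selection(system: MolecularSystem, spec) -> np.ndarray:
    """Resolve a selection into a sorted, de-duplicated 0-based index array.

    ``spec`` is either an explicit index list (passed through, sorted, unique)
    or a textual selection: whitespace-separated clauses combined with AND.
    Supported clauses: ``ligand``, ``receptor``/``protein``, ``sidechain``,
    ``heavy``, ``calpha``, ``residue A`` / ``residue A-B``, ``name X[,Y...]``,
    ``substituent LABEL``.
    """
    if not isinstance(spec, str):
        idx = np.unique(np.asarray(list(spec), dtype=int))
        if idx.size and (idx.min() < 0 or idx.max() >= system.n_atoms):
            raise SelectionError(f"atom index out of range in {idx}")
        return idx

    a = system.atoms
    mask = np.ones(len(a), dtype=bool)
    tokens = spec.split()
    i = 0
    while i < len(tokens):
        tok = tokens[i].lower()
        if tok == "ligand":
            mask &= a["is_ligand"].to_numpy()
        elif tok in ("receptor", "protein"):
            mask &= ~a["is_ligand"].to_numpy()
        elif tok == "sidechain":
            mask &= a["is_sidechain"].to_numpy()
        elif tok == "heavy":
            mask &= (a["element"] != "H").to_numpy()
        elif tok == "calpha":
            mask &= (a["name"] == "CA").to_numpy() & ~a["is_ligand"].to_numpy()
        elif tok in ("residue", "resid"):
            i += 1
            if i >= len(tokens):
                raise SelectionError("'residue' needs a number or range")
            part = tokens[i]
            if "-" in part:
                lo, hi = (int(x) for x in part.split("-", 1))
            else:
                lo = hi = int(part)
            if not a["resid"].isin(range(lo, hi + 1)).any():
                raise SelectionError(f"no such residue(s): {part}")
            mask &= a["resid"].between(lo, hi).to_numpy()
        elif tok == "name":
            i += 1
            if i >= len(tokens):
                raise SelectionError("'name' needs at least one atom name")
            wanted = {n.upper() for n in tokens[i].split(",")}
            mask &= a["name"].str.upper().isin(wanted).to_numpy()
        elif tok == "substituent":
            i += 1
            if i >= len(tokens):
                raise SelectionError("'substituent' needs a label")
            mask &= (a["substituent"] == tokens[i]).to_numpy()
        else:
            raise SelectionError(f"unknown selection token: {tok!r}")
        i += 1
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    return idx


@dataclass
class SelectionMap:
    """Named atom selections the descriptors need.

    ``excluded_terminal_residues`` are two (first, last) residue-number
    ranges dropped from the receptor center-of-mass and RMSD-fitting sets,
    mirroring the exclusion of disordered N-/C-terminal tails.
    """

    ligand_heavy: np.ndarray
    ligand_key_nitrogen: int
    acidic_carboxylate_oxygens: np.ndarray
    his_Ndelta: int
    his_Nepsilon: int
    receptor_com_atoms: np.ndarray
    excluded_terminal_residues: tuple = ((52, 65), (336, 347))
    ligand_axis_head: np.ndarray = field(default=None)

    def validate(self, system: MolecularSystem) -> None:
        for attr in ("ligand_heavy", "acidic_carboxylate_oxygens",
                     "receptor_com_atoms"):
            idx = np.asarray(getattr(self, attr))
            if idx.size == 0:
                raise SelectionError(f"selection {attr!r} is empty")
            if idx.min() < 0 or idx.max() >= system.n_atoms:
                raise SelectionError(f"selection {attr!r} has out-of-range indices")
        for attr in ("ligand_key_nitrogen", "his_Ndelta", "his_Nepsilon"):
            i = getattr(self, attr)
            if not 0 <= i < system.n_atoms:
                raise SelectionError(f"{attr} index {i} out of range")

    def receptor_com_retained(self, system: MolecularSystem) -> np.ndarray:
        """receptor_com_atoms minus atoms in the excluded terminal ranges."""
        idx = np.asarray(self.receptor_com_atoms)
        resids = system.atoms["resid"].to_numpy()[idx]
        keep = np.ones(idx.size, dtype=bool)
        for lo, hi in self.excluded_terminal_residues:
            keep &= ~((resids >= lo) & (resids <= hi))
        retained = idx[keep]
        if retained.size == 0:
            raise SelectionError(
                "receptor COM selection is empty after terminal exclusions"
            )
        return retained


def default_selection_map(system: MolecularSystem,
                          excluded_terminal_residues=None) -> SelectionMap:
    """Build the standard selection map by role: the ligand's key nitrogen,
    the acidic anchor's carboxylate oxygens (ASP OD1/OD2), the histidine
    imidazole nitrogens (ND1/NE2), and all receptor heavy atoms for the COM.
    """
    a = system.atoms
    lig_heavy = system.ligand_heavy_indices()
    if lig_heavy.size == 0:
        raise SelectionError("no ligand heavy atoms found")

    def _one(mask, what):
        idx = np.flatnonzero(mask)
        if idx.size != 1:
            raise SelectionError(f"expected exactly one {what}, found {idx.size}")
        return int(idx[0])

    key_n = _one(
        a["is_ligand"].to_numpy() & (a["name"] == LIGAND_KEY_NITROGEN).to_numpy(),
        "ligand key nitrogen (N1)",
    )
    asp_mask = (~a["is_ligand"]) & (a["resname"] == "ASP") & a["name"].isin(["OD1", "OD2"])
    od = np.flatnonzero(asp_mask.to_numpy())
    if od.size == 0:
        raise SelectionError("no ASP carboxylate oxygens found")
    his = (~a["is_ligand"]) & (a["resname"].isin(["HIS", "HID", "HIE", "HIP"]))
    nd1 = _one((his & (a["name"] == "ND1")).to_numpy(), "His ND1")
    ne2 = _one((his & (a["name"] == "NE2")).to_numpy(), "His NE2")
    rec_heavy = np.flatnonzero((~a["is_ligand"]).to_numpy() & (a["element"] != "H").to_numpy())
    head = np.flatnonzero(
        a["is_ligand"].to_numpy() & a["name"].isin(LIGAND_AXIS_HEAD_ATOMS).to_numpy()
    )
    if excluded_terminal_residues is None:
        # default: the first two and last two receptor residues play the
        # role of the excluded N-/C-terminal tails on toy systems
        resids = np.sort(a.loc[~a["is_ligand"], "resid"].unique())
        excluded_terminal_residues = (
            (int(resids[0]), int(resids[min(1, resids.size - 1)])),
            (int(resids[max(-2, -resids.size)]), int(resids[-1])),
        )
    return SelectionMap(
        ligand_heavy=lig_heavy,
        ligand_key_nitrogen=key_n,
        acidic_carboxylate_oxygens=od,
        his_Ndelta=nd1,
        his_Nepsilon=ne2,
        receptor_com_atoms=rec_heavy,
        excluded_terminal_residues=tuple(excluded_terminal_residues),
        ligand_axis_head=head,
    )


# ---------------------------------------------------------------------------
# tabular results
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path, format: str = "csv",
                  header_comment: str | None = None) -> None:
    """Write a results table as CSV or JSON with lossless numeric round-trip.

    CSV uses pandas' shortest-repr float formatting; JSON uses the records
    orientation via the stdlib encoder (also shortest-repr).  An optional
    comment line (e.g. seed/config hash) is prepended to CSV as ``# ...``.
    """
    path = Path(path)
    if format == "csv":
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            table.to_csv(fh, index=False)
    elif format == "json":
        payload = {
            "columns": list(table.columns),
            "data": [list(row) for row in table.itertuples(index=False)],
        }
        if header_comment:
            payload["comment"] = header_comment
        with open(path, "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format: {format}")


def read_results(path, format: str = "csv") -> pd.DataFrame:
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path, comment="#", float_precision="round_trip")
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["data"], columns=payload["columns"])
    raise ValueError(f"unknown format: {format}")
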