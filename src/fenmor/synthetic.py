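"""Synthetic receptor-ligand systems and titration records.

This module generates toy data with the statistical structure the analysis
layer assumes, so every downstream stage is testable without external
trajectories:

* a rigid helical receptor scaffold with a pseudo-Asp (carboxylate oxygens
  at a configurable "D-site" anchor) and a pseudo-His (imidazole nitrogens
  at an "H-site" anchor), plus a mobile multi-substituent ligand whose
  hidden binding mode follows a two-state Markov chain.  In the D-site mode
  the ligand key nitrogen sits at a truncated-normal distance from the
  D-site anchor and far (>= anchor separation) from the H-site anchor, and
  symmetrically for the H-site mode;
* per-pH tautomer-state records drawn from the closed-form equilibrium
  populations of a microscopic two-site histidine model, optionally coupled
  to a ligand distance (short distances lock the HID state).

The geometry is deliberately schematic (a stated non-goal is realism): the
receptor is rigid, only the ligand moves, and distances are what carry the
signal.  Ground truth (hidden mode per frame) is written as a CSV sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm
from scipy.spatial.distance import cdist

from .errors import ConfigError, DataError
from .structure import (
    FENTANYL_SUBSTITUENTS,
    MolecularSystem,
    system_from_arrays,
    write_pdb,
    write_xtc,
)

MODE_NAMES = ("D147", "H297")

# ligand internal geometry (Angstrom): columns name, element, local coords.
# Local frame: key nitrogen at the origin, long axis along -x (phenethyl),
# anilide branch along +x.  One or more heavy atoms per substituent group;
# C4 carries the 4-axial hydrogen's substituent label.
_LIGAND_TEMPLATE = [
    ("N1", "N", (0.0, 0.0, 0.0)),
    ("C2", "C", (1.2, 1.0, 0.0)),
    ("C6", "C", (1.2, -1.0, 0.0)),
    ("C4", "C", (2.5, 0.0, 0.2)),
    ("C7", "C", (3.8, 0.9, 0.0)),
    ("O1", "O", (4.3, 1.9, 0.4)),
    ("C8", "C", (4.9, 0.0, -0.3)),
    ("C9", "C", (3.1, -1.7, 0.5)),
    ("C10", "C", (4.0, -2.6, 0.9)),
    ("C11", "C", (-1.3, 0.7, 0.0)),
    ("C12", "C", (-2.6, 0.0, 0.0)),
    ("C13", "C", (-3.9, 0.7, 0.2)),
    ("C14", "C", (-5.1, 0.0, 0.2)),
    ("C15", "C", (-4.0, 2.1, 0.2)),
]


@dataclass
class ToyComplexParams:
    """Parameters of the two-state toy complex.

    The Markov chain switches the hidden binding mode once per frame step;
    ``mode_distance_means``/``sd`` set the truncated-normal (at zero)
    key-nitrogen-to-anchor distance of each mode.
    """

    n_receptor_residues: int = 24
    anchor_positions: tuple = ((0.0, 0.0, 9.0), (0.0, 0.0, 0.0))
    mode_distance_means: tuple = (2.8, 3.0)
    mode_distance_sd: tuple = (0.3, 0.3)
    mode_transition_matrix: tuple = ((0.95, 0.05), (0.05, 0.95))
    n_frames: int = 500
    frame_spacing: float = 0.1  # ns per frame
    seed: int = 0
    start_mode: int = 0
    jitter_sd: float = 0.05  # per-atom positional noise, Angstrom

    def validate(self) -> None:
        T = np.asarray(self.mode_transition_matrix, dtype=float)
        if T.shape != (2, 2) or (T < 0).any() or \
                not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigError("transition matrix must be 2x2 row-stochastic")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if any(s <= 0 for s in self.mode_distance_sd):
            raise ConfigError("distance sds must be > 0")
        if self.n_receptor_residues < 8:
            raise ConfigError("need >= 8 receptor residues")
        if self.start_mode not in (0, 1):
            raise ConfigError("start_mode must be 0 or 1")


def _simulate_modes(params: ToyComplexParams, rng: np.random.Generator) -> np.ndarray:
    T = np.asarray(params.mode_transition_matrix, dtype=float)
    modes = np.empty(params.n_frames, dtype=int)
    modes[0] = params.start_mode
    for t in range(1, params.n_frames):
        modes[t] = rng.choice(2, p=T[modes[t - 1]])
    return modes


def _truncnorm_draw(mean, sd, rng, size=None):
    """Normal(mean, sd) truncated at zero."""
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                         random_state=rng, size=size)


def _receptor_atoms(params: ToyComplexParams):
    """Rigid helical scaffold: Ala-like residues (backbone + inward CB),
    with a pseudo-Asp and a pseudo-His whose sidechain tips reach the
    anchors.  Returns (records, coords)."""
    n = params.n_receptor_residues
    a1 = np.asarray(params.anchor_positions[0], dtype=float)
    a2 = np.asarray(params.anchor_positions[1], dtype=float)
    i_asp = n // 3
    i_his = (2 * n) // 3
    radius = 11.0
    zs = np.linspace(-8.0, 8.0, n)
    records, coords = [], []
    serial = 1
    for i in range(n):
        resid = i + 1
        theta = np.radians(100.0 * i)
        ca = np.array([radius * np.cos(theta), radius * np.sin(theta), zs[i]])
        inward = -np.array([np.cos(theta), np.sin(theta), 0.0])
        if i == i_asp:
            resname = "ASP"
        elif i == i_his:
            resname = "HIS"
        else:
            resname = "ALA"
        backbone = [
            ("N", "N", ca + np.array([-0.9, 0.8, -0.6])),
            ("CA", "C", ca),
            ("C", "C", ca + np.array([1.0, 0.6, 0.6])),
            ("O", "O", ca + np.array([1.5, 1.6, 0.4])),
        ]
        side = []
        if resname == "ALA":
            side = [("CB", "C", ca + 2.5 * inward)]
        elif resname == "ASP":
            # sidechain reaches anchor 1; OD1 exactly at the anchor
            cb = ca + 0.33 * (a1 - ca)
            cg = ca + 0.66 * (a1 - ca)
            side = [("CB", "C", cb), ("CG", "C", cg),
                    ("OD1", "O", a1),
                    ("OD2", "O", a1 + np.array([0.0, 1.1, -0.6]))]
        elif resname == "HIS":
            # imidazole: NE2 exactly at anchor 2, ND1 ~2.2 A away
            cb = ca + 0.33 * (a2 - ca)
            cg = ca + 0.66 * (a2 - ca)
            nd1 = a2 + np.array([1.3, 1.1, 1.2])
            side = [("CB", "C", cb), ("CG", "C", cg),
                    ("ND1", "N", nd1),
                    ("CD2", "C", a2 + np.array([-1.2, 0.6, 0.9])),
                    ("CE1", "C", a2 + np.array([0.4, 1.9, 1.6])),
                    ("NE2", "N", a2)]
        for name, element, pos in backbone + side:
            records.append({"serial": serial, "name": name, "element": element,
                            "resid": resid, "resname": resname, "chain": "A"})
            coords.append(pos)
            serial += 1
    return records, np.array(coords)


def _ligand_frame_coords(n1_pos, u, phi, jitter):
    """Rigid-body placement: key nitrogen at n1_pos, internal z mapped onto
    the approach direction u, internal xy rotated by azimuth phi about u."""
    u = u / np.linalg.norm(u)
    # orthonormal basis perpendicular to u
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v0 = np.cross(u, helper)
    v0 /= np.linalg.norm(v0)
    w0 = np.cross(u, v0)
    ex = np.cos(phi) * v0 + np.sin(phi) * w0
    ey = np.cross(u, ex)
    R = np.column_stack([ex, ey, u])  # maps internal (x,y,z) -> lab
    local = np.array([c for _, _, c in _LIGAND_TEMPLATE])
    return n1_pos + local @ R.T + jitter


def generate_toy_complex(params: ToyComplexParams, out_dir=None):
    """Generate the two-state toy complex.

    Returns ``(system, hidden_modes, paths)``.  When ``out_dir`` is given,
    writes ``topology.pdb`` (single MODEL), ``trajectory.xtc`` and the
    ground-truth sidecar ``modes.csv`` (columns ``frame,mode``); otherwise
    ``paths`` is empty.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    modes = _simulate_modes(params, rng)
    rec_records, rec_coords = _receptor_atoms(params)

    anchors = np.asarray(params.anchor_positions, dtype=float)
    n_lig = len(_LIGAND_TEMPLATE)
    lig_resid = params.n_receptor_residues + 1
    lig_records = [
        {"serial": len(rec_records) + i + 1, "name": name, "element": el,
         "resid": lig_resid, "resname": "LIG", "chain": "L"}
        for i, (name, el, _) in enumerate(_LIGAND_TEMPLATE)
    ]

    n_atoms = len(rec_records) + n_lig
    coords = np.empty((params.n_frames, n_atoms, 3))
    coords[:, : len(rec_records)] = rec_coords  # rigid receptor
    for f in range(params.n_frames):
        m = modes[f]
        other = 1 - m
        d = _truncnorm_draw(params.mode_distance_means[m],
                            params.mode_distance_sd[m], rng)
        u = anchors[m] - anchors[other]
        u = u / np.linalg.norm(u)
        n1 = anchors[m] + d * u
        phi = rng.uniform(0.0, 2.0 * np.pi)
        jitter = rng.normal(0.0, params.jitter_sd, size=(n_lig, 3))
        coords[f, len(rec_records):] = _ligand_frame_coords(n1, u, phi, jitter)

    atoms = pd.DataFrame(rec_records + lig_records)
    times = np.arange(params.n_frames) * params.frame_spacing
    system = system_from_arrays(atoms, coords, times,
                                substituent_map=FENTANYL_SUBSTITUENTS)
    paths = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "topology": out_dir / "topology.pdb",
            "trajectory": out_dir / "trajectory.xtc",
            "modes": out_dir / "modes.csv",
        }
        write_pdb(system, paths["topology"])
        write_xtc(system, paths["trajectory"])
        pd.DataFrame({"frame": np.arange(params.n_frames),
                      "mode": [MODE_NAMES[m] for m in modes]}
                     ).to_csv(paths["modes"], index=False)
    return system, modes, paths


# ---------------------------------------------------------------------------
# titration records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingRule:
    """Distance-protonation coupling for the pseudo-His site.

    Below ``cutoff_free`` only the HID tautomer is permitted (the ligand
    amine hydrogen-bonds to N-epsilon, which therefore cannot protonate);
    at or above it all three states are available.  ``cutoff_lock`` marks
    the strictly-locked regime the exclusivity statistic reports on.
    ``distance_distributions`` maps each state to a (mean, sd) of its
    truncated-normal ligand-distance distribution.
    """

    cutoff_lock: float = 4.0
    cutoff_free: float = 7.0
    distance_distributions: dict = field(default_factory=lambda: {
        "HID": (3.0, 0.5), "HIE": (8.5, 0.8), "HIP": (8.0, 0.8)})

    def __post_init__(self):
        if not self.cutoff_lock < self.cutoff_free:
            raise ConfigError("cutoff_lock must be < cutoff_free")


def generate_titration_records(model, ph_grid, n_frames: int,
                               coupling: CouplingRule | None = None,
                               seed: int = 0,
                               with_distances: bool | None = None) -> pd.DataFrame:
    """Draw per-pH tautomer-state records from the microscopic equilibrium.

    Uncoupled: states are multinomial draws from the closed-form
    populations; if distances are requested they are drawn from the
    population-weighted mixture of per-state distributions *independently*
    of the recorded state.  Coupled: a provisional state picks the distance
    distribution, then the state is redrawn from the populations restricted
    by the coupling rule at that distance.

    Returns a DataFrame (ph, frame, state[, distance]).
    """
    from .titration import STATES, micro_populations

    ph_grid = list(ph_grid)
    if not ph_grid:
        raise ConfigError("pH grid is empty")
    if n_frames < 1:
        raise ConfigError("n_frames must be >= 1")
    if coupling is not None:
        with_distances = True
    elif with_distances is None:
        with_distances = False
    rule = coupling if coupling is not None else CouplingRule()
    rng = np.random.default_rng(seed)
    rows = []
    state_order = ("HIP", "HID", "HIE")
    for ph in ph_grid:
        f_hip, f_hid, f_hie = micro_populations(model, ph)
        p = np.array([f_hip, f_hid, f_hie])
        states_idx = rng.choice(3, size=n_frames, p=p)
        if with_distances:
            mix_idx = rng.choice(3, size=n_frames, p=p)
            dists = np.empty(n_frames)
            for k, s in enumerate(state_order):
                sel = mix_idx == k
                if sel.any():
                    mean, sd = rule.distance_distributions[s]
                    dists[sel] = _truncnorm_draw(mean, sd, rng, size=int(sel.sum()))
        if coupling is not None:
            # below cutoff_free the allowed set is {HID}; restricting and
            # renormalizing a single-state space is deterministic
            states_idx[dists < rule.cutoff_free] = 1
        for i in range(n_frames):
            row = {"ph": float(ph), "frame": i,
                   "state": state_order[states_idx[i]]}
            if with_distances:
                row["distance"] = float(dists[i])
            rows.append(row)
    return pd.DataFrame(rows)


def write_titration_csv(records: pd.DataFrame, path) -> None:
    cols = ["ph", "frame", "state"] + (
        ["distance"] if "distance" in records else [])
    records[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# static complexes for single-structure contact profiles
# ---------------------------------------------------------------------------

def generate_static_complex(contact_spec, seed: int = 0, out_path=None,
                            cutoff: float = 4.5, max_retries: int = 200):
    """Build a single-model complex whose contact set equals ``contact_spec``.

    ``contact_spec`` is an iterable of (residue_number, substituent_label)
    pairs.  Each listed residue receives one sidechain atom placed exactly
    4.0 A from an atom of the named substituent and > ``cutoff`` from every
    other substituent; all other residues sit >= 8 A from the ligand.
    Returns the system (and writes a PDB when ``out_path`` is given).
    """
    contact_spec = sorted(set((int(r), str(s)) for r, s in contact_spec))
    valid_subs = set(FENTANYL_SUBSTITUENTS.values())
    for _, s in contact_spec:
        if s not in valid_subs:
            raise ConfigError(f"unknown substituent: {s}")
    rng = np.random.default_rng(seed)

    # the template is expanded so each substituent has room for a contact
    # atom at 4.0 A that clears every other substituent by > cutoff
    lig_local = 1.8 * np.array([c for _, _, c in _LIGAND_TEMPLATE])
    lig_names = [n for n, _, _ in _LIGAND_TEMPLATE]
    lig_elems = [e for _, e, _ in _LIGAND_TEMPLATE]
    sub_of = [FENTANYL_SUBSTITUENTS[n] for n in lig_names]

    by_res: dict[int, list[str]] = {}
    for r, s in contact_spec:
        by_res.setdefault(r, []).append(s)
    listed = sorted(by_res)
    n_res = max(10, (max(listed) if listed else 9) + 1)

    records, coords = [], []
    serial = 1
    for i in range(n_res):
        resid = i + 1
        theta = 2.0 * np.pi * i / n_res
        # far ring: whole residue >= 8 A from any ligand atom
        ca = np.array([21.0 * np.cos(theta), 21.0 * np.sin(theta),
                       3.0 * np.sin(3 * theta)])
        entries = [("N", "N", ca + np.array([-0.9, 0.8, -0.6])),
                   ("CA", "C", ca),
                   ("C", "C", ca + np.array([1.0, 0.6, 0.6])),
                   ("O", "O", ca + np.array([1.5, 1.6, 0.4]))]
        sc_names = ["CB", "CG", "CD", "CE", "CZ"]
        for k, sub in enumerate(by_res.get(resid, [])):
            sub_atoms = lig_local[[j for j, s in enumerate(sub_of) if s == sub]]
            other_atoms = lig_local[[j for j, s in enumerate(sub_of) if s != sub]]
            placed = None
            for _ in range(max_retries):
                target = sub_atoms[rng.integers(len(sub_atoms))]
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                cand = target + 4.0 * v
                if cdist(cand[None], other_atoms).min() > cutoff and \
                        cdist(cand[None], sub_atoms).min() >= 3.0:
                    placed = cand
                    break
            if placed is None:
                raise DataError(
                    f"could not place contact atom for residue {resid} / "
                    f"substituent {sub} after {max_retries} retries"
                )
            entries.append((sc_names[k], "C", placed))
        for name, element, pos in entries:
            records.append({"serial": serial, "name": name, "element": element,
                            "resid": resid, "resname": "ALA", "chain": "A"})
            coords.append(pos)
            serial += 1
    for i, (name, el, pos) in enumerate(zip(lig_names, lig_elems, lig_local)):
        records.append({"serial": serial + i, "name": name, "element": el,
                        "resid": n_res + 1, "resname": "LIG", "chain": "L"})
        coords.append(pos)

    system = system_from_arrays(pd.DataFrame(records), np.array(coords),
                                times=[0.0])
    # construction check: the realized contact set must equal the spec
    from .contacts import frame_contact_set
    realized = frame_contact_set(system, 0, cutoff=cutoff)
    if realized != set(contact_spec):
        raise DataError(
            f"static complex construction failed: wanted {set(contact_spec)}, "
            f"got {realized}"
        )
    if out_path is not None:
        write_pdb(system, out_path)
    return system
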