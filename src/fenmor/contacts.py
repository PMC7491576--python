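"""Contact-fraction profiles, substituent fingerprints and Tanimoto similarity.

A receptor residue is "in contact" with a ligand substituent in a frame when
any sidechain heavy atom of the residue lies within ``cutoff`` (default
4.5 A, boundary inclusive) of any heavy atom of that substituent.  Residue-
level profiles record, per residue, the fraction of frames with a contact to
*any* substituent; the fingerprint matrix binarizes the per-(substituent,
residue) fractions at ``binarize_threshold``.

Tanimoto similarity between two simulations is computed on the residue-level
binary contact sets: Tc = |A n B| / |A u B|.  The residue-level profile (not
a row-collapse of the fingerprint) is the authority for Tc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DataError
from .structure import MolecularSystem, load_system

DEFAULT_CUTOFF = 4.5
DEFAULT_BINARIZE = 0.25
DEFAULT_DISPLAY = 0.25
DEFAULT_SIGNIFICANCE = 0.5


@dataclass
class ContactProfile:
    """Per-residue contact fractions for one simulation."""

    label: str
    table: pd.DataFrame  # columns: residue, resname, fraction
    n_frames: int

    def fractions(self) -> pd.Series:
        return self.table.set_index("residue")["fraction"]

    def binary_set(self, threshold: float = DEFAULT_BINARIZE) -> frozenset:
        t = self.table
        return frozenset(t.loc[t["fraction"] >= threshold, "residue"])


@dataclass
class FingerprintMatrix:
    """Binary substituent x residue contact matrix (rows: substituents)."""

    matrix: pd.DataFrame

    def n_contacts(self) -> int:
        return int(self.matrix.to_numpy().sum())


def _contact_atoms(system: MolecularSystem):
    """(receptor sidechain heavy indices, their resids/resnames,
    ligand heavy indices, their substituent labels)."""
    sc = system.receptor_sidechain_heavy()
    rec_idx = sc.index.to_numpy()
    lig = system.atoms.loc[system.ligand_heavy_indices()]
    return (rec_idx, sc["resid"].to_numpy(), sc["resname"].to_numpy(),
            lig.index.to_numpy(), lig["substituent"].to_numpy())


def frame_contact_set(system: MolecularSystem, frame: int,
                      cutoff: float = DEFAULT_CUTOFF) -> set:
    """Set of (residue, substituent) pairs in contact in one frame."""
    rec_idx, resids, _, lig_idx, subs = _contact_atoms(system)
    if rec_idx.size == 0 or lig_idx.size == 0:
        return set()
    pos = system.positions(frame)
    close = cdist(pos[rec_idx], pos[lig_idx]) <= cutoff
    pairs = set()
    for i, j in zip(*np.nonzero(close)):
        pairs.add((int(resids[i]), str(subs[j])))
    return pairs


def _pair_fraction_table(system: MolecularSystem, frames,
                         cutoff: float) -> pd.DataFrame:
    """(residue, substituent) -> fraction of frames in contact, plus the
    residue-level any-substituent fraction; vectorized over atoms."""
    frames = list(frames)
    if not frames:
        raise DataError("no frames to analyse")
    rec_idx, resids, resnames, lig_idx, subs = _contact_atoms(system)
    uniq_res, res_codes = np.unique(resids, return_inverse=True)
    uniq_sub, sub_codes = np.unique(subs, return_inverse=True)
    pair_counts = np.zeros((uniq_res.size, uniq_sub.size))
    res_counts = np.zeros(uniq_res.size)
    for f in frames:
        pos = system.positions(f)
        close = cdist(pos[rec_idx], pos[lig_idx]) <= cutoff
        pair_hit = np.zeros((uniq_res.size, uniq_sub.size), dtype=bool)
        ii, jj = np.nonzero(close)
        pair_hit[res_codes[ii], sub_codes[jj]] = True
        pair_counts += pair_hit
        res_counts += pair_hit.any(axis=1)
    resname_of = dict(zip(resids, resnames))
    return pd.DataFrame({
        "residue": np.repeat(uniq_res, uniq_sub.size),
        "resname": [resname_of[r] for r in np.repeat(uniq_res, uniq_sub.size)],
        "substituent": np.tile(uniq_sub, uniq_res.size),
        "pair_fraction": (pair_counts / len(frames)).ravel(),
        "residue_fraction": np.repeat(res_counts / len(frames), uniq_sub.size),
    })


def contact_fractions(system: MolecularSystem, frames=None,
                      cutoff: float = DEFAULT_CUTOFF,
                      label: str = "") -> ContactProfile:
    """Per-residue fraction of frames with any ligand contact."""
    if frames is None:
        frames = range(system.n_frames)
    tab = _pair_fraction_table(system, frames, cutoff)
    res = (tab.drop_duplicates("residue")
              [["residue", "resname", "residue_fraction"]]
              .rename(columns={"residue_fraction": "fraction"})
              .reset_index(drop=True))
    return ContactProfile(label=label, table=res, n_frames=len(list(frames)))


def fingerprint(system: MolecularSystem, frames=None,
                cutoff: float = DEFAULT_CUTOFF,
                binarize_threshold: float = DEFAULT_BINARIZE) -> FingerprintMatrix:
    """Binary substituent x residue matrix: 1 iff the pair's contact
    fraction is >= ``binarize_threshold``."""
    if frames is None:
        frames = range(system.n_frames)
    tab = _pair_fraction_table(system, frames, cutoff)
    mat = (tab.pivot(index="substituent", columns="residue",
                     values="pair_fraction") >= binarize_threshold).astype(int)
    # rows must cover every configured substituent, even all-zero ones
    all_subs = sorted(
        s for s in system.atoms["substituent"].dropna().unique()
    )
    mat = mat.reindex(all_subs, fill_value=0)
    return FingerprintMatrix(matrix=mat)


def filter_profiles(profiles, display_threshold: float = DEFAULT_DISPLAY,
                    significance_threshold: float = DEFAULT_SIGNIFICANCE):
    """Display/significance residue filters across profiles.

    Display set (inclusive >=): residues reaching ``display_threshold`` in at
    least one profile.  Significant set (strict >): per profile, residues
    whose fraction exceeds ``significance_threshold``.
    """
    profiles = list(profiles)
    if not profiles:
        raise DataError("no profiles")
    display = set()
    significant = {}
    for p in profiles:
        t = p.table
        display |= set(t.loc[t["fraction"] >= display_threshold, "residue"])
        significant[p.label] = frozenset(
            t.loc[t["fraction"] > significance_threshold, "residue"]
        )
    return frozenset(display), significant


def tanimoto(profile_a: ContactProfile, profile_b: ContactProfile,
             binarize_threshold: float = DEFAULT_BINARIZE) -> float:
    """Tanimoto coefficient of the binarized residue contact sets."""
    a = profile_a.binary_set(binarize_threshold)
    b = profile_b.binary_set(binarize_threshold)
    return tanimoto_sets(a, b)


def tanimoto_sets(a, b) -> float:
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise DataError("Tanimoto undefined for two empty contact sets")
    return len(a & b) / len(union)


def tanimoto_matrix(profiles, binarize_threshold: float = DEFAULT_BINARIZE) -> pd.DataFrame:
    """Symmetric profile x profile Tc matrix."""
    labels = [p.label for p in profiles]
    n = len(profiles)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = tanimoto(profiles[i], profiles[j],
                                             binarize_threshold)
    return pd.DataFrame(out, index=labels, columns=labels)


def crystal_contact_profile(pdb_path, cutoff: float = DEFAULT_CUTOFF,
                            label: str = "crystal",
                            **load_kwargs) -> ContactProfile:
    """Single-structure contact profile (fractions in {0, 1}) from a
    one-MODEL PDB, e.g. a crystal complex."""
    system = load_system(pdb_path, **load_kwargs)
    if system.ligand_heavy_indices().size == 0:
        raise DataError(f"no ligand found in {pdb_path}")
    return contact_fractions(system, frames=[0], cutoff=cutoff, label=label)
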