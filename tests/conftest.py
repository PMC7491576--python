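import numpy as np
import pandas as pd
import pytest

from fenmor.structure import SelectionMap, system_from_arrays
from fenmor.synthetic import ToyComplexParams, generate_toy_complex


def build_system(atom_rows, coords, times=None, substituent_map=None):
    """Hand-built system: atom_rows = [(name, resid, resname, chain), ...]."""
    atoms = pd.DataFrame(
        [{"serial": i + 1, "name": n, "resid": r, "resname": rn, "chain": c}
         for i, (n, r, rn, c) in enumerate(atom_rows)]
    )
    return system_from_arrays(atoms, np.asarray(coords, dtype=float),
                              times=times, substituent_map=substituent_map)


@pytest.fixture(scope="session")
def toy():
    """Small default toy complex with its hidden modes and selection map."""
    from fenmor.structure import default_selection_map

    params = ToyComplexParams(n_frames=120, seed=123)
    system, modes, _ = generate_toy_complex(params)
    return system, modes, default_selection_map(system)


@pytest.fixture(scope="session")
def toy_on_disk(tmp_path_factory):
    """The same toy complex written out (PDB + XTC + ground truth)."""
    out = tmp_path_factory.mktemp("toy")
    params = ToyComplexParams(n_frames=100, seed=321)
    system, modes, paths = generate_toy_complex(params, out_dir=out)
    return system, modes, paths


def make_selmap(**kw):
    """SelectionMap with explicit indices for hand-built micro-systems."""
    defaults = dict(
        ligand_heavy=np.array([0]),
        ligand_key_nitrogen=0,
        acidic_carboxylate_oxygens=np.array([1]),
        his_Ndelta=1,
        his_Nepsilon=1,
        receptor_com_atoms=np.array([1]),
        excluded_terminal_residues=((10**6, 10**6), (10**6 + 1, 10**6 + 1)),
        ligand_axis_head=np.array([0]),
    )
    defaults.update(kw)
    return SelectionMap(**defaults)
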