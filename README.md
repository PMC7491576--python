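# fenmor

Analysis toolkit for molecular-dynamics studies of fentanyl binding to the
μ-opioid receptor (mOR), a class A GPCR. Fentanyl anchors in the orthosteric
pocket through a salt bridge between its charged piperidine amine and Asp147,
but can also reach a deeper pose hydrogen-bonded to His297 — a pose that is
only compatible with one histidine tautomer (HID, Nδ-protonated). Untangling
these binding modes therefore requires analysing trajectories *and*
constant-pH titration data together. `fenmor` implements that analysis layer:

* **Geometric descriptors** — FEN–D147 distance (piperidine N to the Asp147
  carboxylate oxygens, minimum heavy-atom distance), FEN–H297 distance
  (piperidine N to the *unprotonated* imidazole nitrogen, tautomer-aware),
  ligand depth ΔZ (z-separation of ligand and receptor centres of mass with
  terminal residues excluded), receptor-frame ligand RMSD, vertical angle of
  the ligand long axis, and χ₂ sidechain dihedrals.
* **Binding-mode classification** — per-frame labels from a 3.5 Å distance
  threshold (D147 / H297 / BOTH / NEITHER), weighted-ensemble-style group
  schemes, occupancy and cumulative-time bookkeeping, hierarchical clustering
  with medoid representatives.
* **Contact fingerprints** — per-residue contact fractions (any sidechain
  heavy atom within 4.5 Å of any ligand heavy atom), binary
  substituent × residue fingerprint matrices (piperidine, phenethyl, phenyl,
  propanamide, 4-axial position), display (≥ 0.25) and significance (> 0.5)
  filters, and Tanimoto similarity T_c = |A∩B| / |A∪B| between binary contact
  sets.
* **Titration analysis** — tautomer occupancies (HID/HIE/HIP) vs pH,
  macroscopic pKa from a generalized Hill fit
  S(pH) = 1 / (1 + 10^{n(pKa − pH)}) of the neutral fraction
  S = f_HID + f_HIE, the microscopic↔macroscopic closed form
  pKa_macro = −log₁₀(10^{−pKaδ} + 10^{−pKaε}), distance–protonation coupling
  statistics, and convergence diagnostics.
* **Synthetic systems** — a generator for toy receptor–ligand complexes whose
  hidden binding mode follows a two-state Markov chain, titration records
  drawn from the microscopic tautomer equilibrium (optionally
  distance-coupled), and static complexes with exactly specified contact
  sets. Every downstream stage is testable without external trajectories.

## Worked example

```python
import numpy as np
import fenmor as fm

# a 2000-frame toy complex: hidden mode switches between D147- and
# H297-bound with the default Markov chain
params = fm.ToyComplexParams(n_frames=2000, seed=42)
system, hidden, _ = fm.generate_toy_complex(params)
selmap = fm.default_selection_map(system)

desc = fm.compute_descriptors(system, selmap, his_state="HID")
series = fm.classify_series(desc)
print(fm.occupancy(series["label"]))
# {'H297': 0.536, 'D147': 0.427, 'NEITHER': 0.036}

gt = np.array([fm.synthetic.MODE_NAMES[m] for m in hidden])
print((series["label"].to_numpy() == gt).mean())   # 0.964

# titration: microscopic model -> sampled records -> Hill fit
model = fm.MicroTautomerModel(pka_delta=6.8, pka_epsilon=7.4)
print(fm.macro_pka(model))                          # 6.703
recs = fm.generate_titration_records(model, np.linspace(2.5, 9.5, 16),
                                     2000, seed=42)
fit = fm.fit_hill(fm.occupancies(recs))
print(fit.pka, fit.hill_n)                          # 6.687  0.996
```

The mode occupancies track the hidden Markov chain (96% per-frame agreement
at the default ~2σ separation of the distance distributions from the 3.5 Å
threshold; > 99% for well-separated distributions), and the fitted
macroscopic pKa recovers the closed-form value of the generating model to
within sampling error.

The same pipeline is available from the shell:

```bash
fenmor simulate --out-dir run --seed 42 --coupled
fenmor analyze  --out-dir run
fenmor titrate  --out-dir run
fenmor report   --out-dir run   # single JSON summary
```

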