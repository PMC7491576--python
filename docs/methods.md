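# Methods

This note records the models, conventions and numerical choices behind
`fenmor`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is computed, under which assumptions, and
where a genuinely open design choice was settled.

## Geometric descriptors

All coordinates are in Å, times in ns, frames 0-based, residue numbers
1-based as in the PDB. "Heavy atom" means element ≠ H throughout; the
sidechain of a residue is every heavy atom except backbone N, CA, C, O and
OXT, which PDB naming makes unambiguous.

* **FEN–D147 distance**: minimum Euclidean distance from the ligand's key
  (piperidine amine) nitrogen to the Asp147 carboxylate oxygens OD1/OD2.
* **FEN–H297 distance**: key nitrogen to the *unprotonated* imidazole
  nitrogen of His297. The mapping is tautomer-dependent: HID (Nδ-H) leaves
  Nε unprotonated, HIE (Nε-H) leaves Nδ unprotonated. HIP has no
  unprotonated nitrogen; the package uses Nε by convention and logs a
  warning, since the distance definition only covers neutral states.
* **ΔZ**: (ligand COM z) − (receptor COM z), mass-weighted with standard
  atomic masses (a "centre of mass" is taken literally, not as a geometric
  centre). Two terminal residue-number ranges — disordered N-/C-terminal
  tails — are excluded from the receptor set only. The z axis is the lab
  frame's third axis, assuming a pre-oriented membrane system; no membrane
  normal is estimated from lipids.
* **Ligand RMSD**: best-fit superposition (Kabsch, via MDAnalysis) on
  receptor Cα atoms within the retained residue range, then heavy-atom
  ligand RMSD without re-fitting on the ligand. The fitting set is the
  standard receptor-frame choice for a ligand progress coordinate.
* **Vertical angle**: angle between the ligand long axis and +z, in
  [0°, 180°]. The axis is not uniquely defined by the underlying science;
  the package default runs from the key nitrogen to the centroid of the
  phenethyl ring, and the head selection is configurable.
* **χ₂ dihedral**: CA–CB–CG–ND1 for histidine, CA–CB–CG–CD1 for
  tryptophan; signed IUPAC convention, degrees in (−180°, 180°], with an
  unwrapping helper for time series crossing the boundary.
* **Receptor-centred COM plots**: origin at the receptor COM, z = lab z,
  x = a configurable reference vector projected into the xy plane (the
  published convention, "the N2–H vector", is ambiguous about which
  hydrogen; hence a free parameter), y completing a right-handed frame.

## Contacts, fingerprints, Tanimoto

A residue contacts a substituent in a frame when any sidechain heavy atom
is within 4.5 Å (inclusive: "within" is read as ≤, and the boundary is
configurable) of any heavy atom of the substituent. Per-residue profiles
report the fraction of frames with a contact to any substituent. The
fingerprint matrix binarizes per-(substituent, residue) fractions at 0.25;
the binarization threshold is not dictated by the science and defaults to
the display threshold so that one notion of "in contact" is used
throughout. Display filtering is inclusive (fraction ≥ 0.25 in at least
one profile); significance is strict (fraction > 0.5).

The 4-axial hydrogen of the piperidine ring is tracked as a fingerprint
row by mapping its substituent label onto the bonded carbon, because a
hydrogen cannot participate in heavy-atom contacts. This is a package
decision, flagged rather than asserted as the only possible reading.

Tanimoto similarity is computed on residue-level binary contact sets,
T_c = |A∩B| / |A∪B|, over the union of residues contacting in either
profile; it is undefined (an error) when both sets are empty. A row-wise
collapse of the fingerprint can differ from residue-level binarization;
the residue-level profile is the authority for T_c.

## Binding modes and clustering

A frame is D147-bound when FEN–D147 ≤ 3.5 Å, H297-bound when
FEN–H297 ≤ 3.5 Å; BOTH and NEITHER complete the partition. BOTH is added
for totality — the standard thresholds make it geometrically
near-impossible but not provably so. Group schemes reproduce the interval
predicates used to select cluster input from each weighted-ensemble run
(first-matching-group semantics; unmatched frames stay unassigned).
Weighted-ensemble statistical weights are deliberately ignored: frames are
treated as plain unweighted samples, matching how the cluster input data
were taken.

Clustering is agglomerative (scikit-learn) on z-scored
(fen_d147, fen_h297, ΔZ) features with Euclidean metric and average
linkage; linkage, features and k are configurable since no single choice
is canonical. The representative of a cluster is its medoid — the member
minimizing summed in-cluster distance, ties broken by lowest frame index —
and "most populated cluster" means largest member count.

## Titration model

The doubly protonated imidazolium (HIP) loses its Nδ proton with
microscopic constant pKaδ (giving HIE) or its Nε proton with pKaε (giving
HID). Equilibrium populations are proportional to ([H⁺], Ka_ε, Ka_δ) for
(HIP, HID, HIE) — note HID, which retains the Nδ proton, carries the
constant for losing the *other* proton. The implementation factors out the
dominant exponent so that an infinite pKa degrades gracefully to the
one-site (carboxylic-acid-like) model.

The macroscopic constant for the +1 → 0 transition is
pKa_macro = −log₁₀(Ka_δ + Ka_ε). The neutral fraction S = f_HID + f_HIE
of the two-site model is exactly a Hill curve with n = 1 in Ka_δ + Ka_ε,
which the fitting tests exploit as a closed-form oracle.

Hill fits use S(pH) = 1 / (1 + 10^{n(pKa − pH)}) with free n by default
(n can be fixed to 1), deterministic initialization (pKa₀ = pH of the
sample nearest S = 0.5, n₀ = 1), scipy least squares. A fit is flagged
extrapolated when the estimate falls outside the sampled pH range ±2 units
or S never brackets 0.5. Convergence diagnostics refit on growing prefixes
(default 5 chunks) and declare convergence when the last two estimates
differ by < 0.1 pKa units.

Distance–protonation coupling is summarized by the exclusivity statistic:
the fraction of records with distance below the lock cutoff (default
4.0 Å) that are in the HID state; 1.0 means the short-distance regime is
exclusively HID. With no records below the cutoff the statistic is
reported as missing rather than defaulted.

## Synthetic systems

The generator produces the study conditions the analysis assumes, not
realistic biophysics (explicitly a non-goal: rigid receptor, schematic
geometry, no solvent or membrane).

* **Toy complex**: a helical scaffold of Ala-like residues (backbone plus
  an inward CB) around the z axis, with a pseudo-Asp whose OD1 sits at the
  D-site anchor (default (0, 0, 9) Å) and a pseudo-His whose NE2 sits at
  the H-site anchor (default origin). The ligand carries ≥ 1 heavy atom
  per substituent group. Its hidden mode follows a two-state Markov chain
  (default persistence 0.95 per frame step); in each frame the key
  nitrogen is placed at a truncated-normal distance (defaults 2.8 ± 0.3 Å
  for the D-site mode, 3.0 ± 0.3 Å for the H-site mode, truncation at zero
  for positivity) from the active anchor along the direction away from the
  other anchor, so the inactive-anchor distance is at least the 9 Å anchor
  separation. A random azimuthal rotation and small positional jitter
  (0.05 Å) vary the contact pattern between frames. Topology is written as
  a single-MODEL PDB and the trajectory as XTC (timestamp-free, hence
  byte-reproducible for a fixed seed); the hidden mode sequence is written
  as a `frame,mode` CSV sidecar, titration records as
  `ph,frame,state,distance` CSV.
* **Titration records**: multinomial draws from the closed-form
  populations at each pH (default grid: 16 points spanning 2.5–9.5,
  mirroring a 16-replica titration design). The published coupling
  behaviour specifies exclusive HID below 4 Å and HIE/HIP available at
  ≥ 7 Å, leaving 4–7 Å open; the generator restricts the state space to
  {HID} below the free cutoff (7 Å) and leaves it unrestricted above,
  which reproduces both stated regimes. Coupled draws pick a provisional
  state, draw a distance from that state's distribution, then redraw the
  state from the restricted, renormalized populations. Uncoupled draws
  with distances sample the distance from the population-weighted mixture
  *independently* of the recorded state, so that P(HID | short distance)
  equals the overall HID fraction — the null the exclusivity statistic is
  compared against.
* **Static complexes**: each requested (residue, substituent) contact is
  realized by a sidechain atom placed exactly 4.0 Å from an atom of the
  substituent and > 4.5 Å from every other substituent (rejection sampling
  over directions, bounded retries); all other residues sit ≥ 8 Å away.
  The construction is verified against the requested spec before the file
  is written.

What the generator does **not** emulate: receptor flexibility, solvent and
membrane, force-field energetics, weighted-ensemble weights and bin
structure, and replica-exchange mixing. Tests passing on these toys
therefore validate the *analysis* layer — definitions, conventions,
estimators, determinism — not the ability to reproduce published
trajectory-derived numbers, which require the original μs-scale
simulations.

## Problem sizes and tolerances

The test suite and the acceptance script choose sizes that make the
statistical checks sharp while keeping runs quick: 10,000 frames for
mode-recovery checks (binomial 3σ bands, with the occupancy variance
inflated by the chain's lag-1 autocorrelation factor (1+ρ)/(1−ρ)), 100
frames for exhaustive contact-oracle comparisons, 20 seeds × 16 pH ×
2,000 frames for pKa-recovery statistics (median error < 0.05, 95% within
0.15), and 50 random specifications for static round trips. Numeric
round-trips through CSV use shortest-repr floats and round-trip parsing.
MDAnalysis's dihedral kernel runs in single precision; dihedral agreement
is asserted at 10⁻⁴ degrees, far below any physically meaningful
difference.

## Known limitations

* The toy H-site pose sits *below* the receptor COM, so its ΔZ is negative
  rather than small-positive as in a real receptor pocket; only the
  separation between mode distributions matters to the analysis.
* The vertical-angle axis and the x-axis reference vector of the
  COM-projection frame are conventions, not derived quantities; comparing
  absolute angles across packages requires matching these choices.
* `fen_h297_distance` for HIP is a documented convention, not a physical
  definition.
* Tanimoto values depend on the binarization threshold; report it
  alongside any T_c.
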