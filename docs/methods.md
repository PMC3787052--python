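# Methods

`ncsmd` implements the post-processing pipeline used to characterise the
native state of neuronal calcium sensor-1 (NCS-1) from molecular-dynamics
ensembles: segment-resolved RMSD, center-of-mass (COM) distance series,
conformational clustering, NOE back-calculation, and time-averaged
inter-residue energy maps. This note records the models, conventions and
numerical choices; it states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structures, numbering and segments

Structures are read from PDB files (via gemmi); author residue numbering is
taken at face value with no renumbering. HETATM records (waters, ions,
glycols) are dropped on read by default; hydrogens are kept when present.
Alternate locations keep the highest-occupancy conformer, ties resolved
toward altloc `A`; insertion codes are rejected (the NCS-1 entries contain
none). mmCIF, PSF topologies and hydrogen addition are out of scope.

The built-in segment registry covers helices H1 (11–18) through H9
(166–174), strands β1–β6, loops L1 (56–61), L2 (133–145) and L3 (175–187),
the protein core PC = residues 11–174 and the hinge loop HL = 93–98. The
literature defines the C-terminal tail both as 175–187 and as D176–D190;
both are exposed (`L3` and `L3_METHODS`) and neither is silently preferred.

"Backbone" defaults to {N, CA, C, O}. Whether a given published backbone
RMSD included the carbonyl O is usually unstated; the set is therefore
configurable to {N, CA, C} and {CA}, and downstream tolerances (±0.3–0.4 Å
on structure-comparison values) absorb the convention difference.

## Superposition and partial RMSD

Superposition is determinant-corrected Kabsch (SVD of the covariance
matrix, reflections rejected), requiring ≥ 3 non-collinear points. Partial
RMSD fits the rigid transform on one atom set (PC backbone in the standard
protocol) and measures the deviation over another set *without refitting*,
so a segment's RMSD is its displacement in the core frame. Atom
correspondence between two different structures is established by
(residue id, atom name) intersection — plus chain when both structures are
multi-chain — never by file order; order-based pairing applies only within
a trajectory, whose frames share one topology by construction.

Kabsch is cross-checked in the tests against two independent oracles: a
multi-start minimisation over rotation space and Horn's quaternion
eigenvalue method (agreement ≤ 1e-6 Å on random instances).

Series smoothing is a centered moving average with truncated edge windows
(default width 51 frames). It is cosmetic, for plotting; statistics are
always computed on the raw series.

COM is mass-weighted by default (element masses from gemmi), with a
geometric-centroid flag; zero total mass is an error rather than a silent
fallback.

## Sampling protocol

Trajectory analyses (energy maps, NOE time averages, RMSD matrices) sample
frames every `stride` ps over the final `window` ns, the standard protocol
being 50 ps over the last 100 ns. The stride must be a multiple of the
frame spacing `dt`; a 2000-frame, dt = 50 ps trajectory is used in full.
Averages are plain arithmetic means over sampled frames (no block
averaging).

## Inter-residue energy maps

The atom-pair potential is Coulomb plus Lennard-Jones under the CHARMM
cubic switching function, smoothly tapering between r_on = 10 Å and
r_off = 12 Å:

E(r) = S(r)·[ C·qᵢqⱼ/r + εᵢⱼ((Rmin/r)¹² − 2(Rmin/r)⁶) ]

with C = 332.0636 kcal·Å/(mol·e²), εᵢⱼ = √(εᵢεⱼ) and
Rmin = Rmin/2ᵢ + Rmin/2ⱼ (CHARMM combining rules, matching the force-field
family the parameters come from). The dielectric is vacuum: the operator
defines a map of direct interactions over explicit-solvent frames, not a
solvation model. Long-range electrostatics are deliberately neglected — a
residue pair contributes only when its minimum inter-atomic distance is
within r_off, and S(r) drives each atom pair continuously to zero at the
cutoff (continuity at 10 and 12 Å is property-tested to ~1e-6).

A residue-pair energy sums all inter-residue atom pairs except those within
three covalent bonds (the 1-2/1-3/1-4 pairs across the peptide bond of
sequence-adjacent residues). Excluding them prevents bonded geometry from
appearing as huge spurious adjacent-residue energies; whether the original
analyses did so is unstated, so the exclusion is configurable
(`exclude_bonded`, `n_excluded_bonds`). Bonds are inferred by distance
(< 1.9 Å heavy–heavy, < 1.3 Å with hydrogen) on the topology coordinates,
which covers backbone chemistry and the synthetic pseudo-atoms; no 1-4
scaling is applied. Hydrogens are included whenever present and
parameterized. The parameter table is a bespoke three-column-per-atom
format (charge, ε, Rmin/2) because those are the only quantities the map
needs; full force-field parsing is out of scope.

The map is symmetric with a zero diagonal (excluded from classification
and filtering). Entries are binned at boundaries 0, −2, −15, −30 kcal/mol
(edges belong to the more-negative class): repulsive, weak
dispersion/hydrophobic, hydrogen-bond-like, strong polar/weak ionic, ionic.
Salt bridges are entries strictly below −30 kcal/mol; a bridge is
*conserved* between two maps when it is below threshold in both (reported
energy: the mean of the two entries).

## NOE back-calculation

Equivalent protons are combined by **summing** r⁻⁶ over the cross-product
of the two proton groups, r_eff = (Σ r⁻⁶)^(−1/6); a mean-combination flag
exists only for cross-checking other software conventions. Ensembles use
sixth-power time averaging: the per-frame Σ r⁻⁶ is averaged over sampled
frames before the −1/6 power.

The violation rule is implemented literally as specified by the protocol it
reproduces, and the asymmetry deserves emphasis: a restraint is **flagged**
when r_eff exceeds upper + 0.6 Å, but the violation magnitude is
**measured from the raw upper bound**, V = r_eff − upper. Consequently
every reported violation is ≥ 0.6 Å. The summary ⟨V⟩ averages V over the
violated restraints only (denominator n_violated) and is reported as
absent, not 0, when nothing is violated. Restraints referencing protons
absent from the model are a hard error by default (`skip_missing` lists
them separately instead), since silently dropping restraints against a
heavy-atom model would inflate satisfaction rates.

## Clustering

Frames are compared by superpose-then-RMSD over a fit set; the dense
pairwise matrix (≤ ~2000 frames at the standard sampling, well within
memory) is clustered hierarchically. The linkage is **complete** by design:
it is the one standard linkage whose cut at height h certifies that every
intra-cluster pairwise RMSD is ≤ h, which is exactly the property a 2 Å
"same conformational state" cutoff relies on; the certificate is asserted
in the tests. Cluster ids are ordered by population (ties: smallest member
frame index). The representative structure is the medoid — the member
minimizing summed RMSD to its cluster, ties to the smallest frame index —
the common "most representative structure" convention, stated here because
it is rarely defined where used.

## Synthetic data

The generator provides planted-truth systems, not physics:

- `build_helix` places an ideal α-helix backbone (φ = −57°, ψ = −47°,
  ω = 180°, standard bond lengths/angles) by internal-coordinate chaining;
  the i→i+4 O···N partners land at 3.09 Å and dihedrals are exact, both
  verified by recomputation. Amide hydrogens are optional.
- `plant_salt_bridge` attaches one ±1e pseudo-atom to each of two residues
  at a requested separation (default 3 Å), displaced 5 Å outward from the
  molecular body so the sites cannot clash with intervening backbone, and
  emits a parameter table in which everything else is neutral with a small
  ε (0.05 kcal/mol, Rmin/2 = 1.8 Å). The planted contact is then provably
  the only entry that can cross the ionic threshold.
- `make_trajectory` adds seeded isotropic Gaussian displacements
  (per-coordinate σ = amplitude) around a base conformation, optionally
  with a linear rigid drift of a named segment. Frames are uncorrelated in
  time — adequate because every operator under test is agnostic to the
  generating dynamics, but it means passing tests say nothing about
  time-correlation-sensitive analyses on real trajectories.
- `make_restraints` plants an exactly known violated subset:
  round(n·fraction) restraints get upper = r_eff − depth − 0.6 (violated by
  construction, V = depth + 0.6), the rest upper = r_eff + 1.0.
- Preset systems used by the tests and the acceptance script: a 20-residue
  helix with a bridge planted at residues 5/12 over 25 frames (amplitude
  0.05 Å); a 30-residue protonated helix with 200 restraints at 20%
  violations of depth 0.3 Å over 30 frames (amplitude 0.06 Å); and a
  two-state trajectory of 2 × 20 frames (amplitude 0.1 Å) whose second
  conformer is a 100° hinge bend giving ~5 Å inter-state RMSD against
  ~0.3 Å intra-state spread. These sizes keep the whole pipeline — map,
  NOE report, 40×40 RMSD matrix, clustering — in seconds while leaving
  order-of-magnitude separation between planted signal and noise.

All randomness flows through numpy's seeded PCG64 generator; identical
seeds give bitwise-identical output.

## Validation against the deposited structures

The comparison of the NCS-1 crystal form (1G8I, chain B) with the solution
form (2LCP, model 1) — core backbone RMSD near 4.4 Å, with segment values
such as H1 ≈ 6.4 Å, H9 ≈ 4.0 Å, L1 ≈ 3.2 Å — is wired into
`tests/test_acceptance.py` via `geometry.compare_structures`. The PDB
entries themselves are not redistributed with the package; place `1G8I.pdb`
and `2LCP.pdb` under `data/` to run those two checks. Everything else runs
offline on the synthetic systems.

## Known limitations

- Energetics assume residue ids unique across the structure (single-chain
  proteins); multi-chain energy maps would need chain-qualified residue
  keys.
- The bond-inference exclusion is geometric; exotic covalent links
  (disulfides between sequence-distant residues) are not excluded.
- Quantities that depend on the original hundreds-of-ns trajectories
  (plateau RMSD levels, cluster counts of the real simulations, the real
  NOE satisfaction rate) are outside what synthetic data can reproduce;
  the pipeline reproduces the operators and their planted-truth behavior,
  not those trajectory-specific numbers.
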