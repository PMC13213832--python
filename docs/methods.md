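# Methods

## Scope and model

`mdpharm` derives pharmacophore models of a protein–protein interface pocket
from an MD trajectory of the ligand-free, solvated complex, and screens and
filters ligand libraries for dual-binding stabilizer candidates. Running the
MD itself, computing MMGBSA energies, and building large screening databases
are out of scope: trajectories come in as multi-model PDB (or GRO), MMGBSA
results come in as tables, and the external screening engine is optional
behind an adapter (the built-in reference matcher is the default).

The underlying assumption is that the solvent reports on interaction
propensity: pocket atoms that persistently hydrogen-bond water would bond a
ligand's donor/acceptor groups; residues whose desolvation is favorable
(positive ΔG_sol) would accept hydrophobic or aromatic contacts; sites that
accumulate ions would hold charged groups. The trajectory supplies the
statistics, a single representative frame supplies the geometry.

## Pipeline parameters (defaults and provenance)

| Parameter | Default | Notes |
|---|---|---|
| Pocket cutoff around reference/probes | 5.0 Å | heavy-atom min distance |
| H-bond distance / angle | 3.0 Å / 150° | angle at the hydrogen |
| Covalent X–H inference | ≤ 1.25 Å | donors need a bound H |
| Ion contact cutoff | 4.0 Å | any pocket heavy atom |
| ΔG_sol threshold | 0.2 kJ/mol | hydrophobic/aromatic sites |
| Normed H-bond threshold | 30 | occupancy% / mean SASA (nm²) |
| Ion difference threshold | 25% | \|cation% − anion%\| |
| SASA floor for normalization | 0.01 nm² | excluded atoms are reported |
| Probe radius / sphere points | 1.4 Å / 960 | Shrake–Rupley |
| Clustering RMSD cutoff | 1.5 Å | pocket heavy atoms |
| Feature & exclusion radius | 1.0 Å | engine requires radii |
| Water placement | 4.0 Å, 150°→100° in 10° steps | |
| Ion placement scan | 2.0→5.0 Å in 0.5 Å steps | |
| Hydrophobic / aromatic shift | 4.0 Å / 3.0 Å | toward center / along normal |
| Subset sweep | k = min(N, 10) … 4 | subsets < 3 are never screened |
| Per-k cap / hit budget | 50 000 / 10 000 | budget checked after each k |
| Matcher position tolerance | 1.0 Å | equals the feature radius |
| MMGBSA balance threshold | 0.5 | min(\|ΔG_AL\|,\|ΔG_BL\|)/max |

Angle-relaxation step (10°), ion-scan step (0.5 Å), feature/exclusion radii
and the matcher tolerance are this package's own choices where the procedure
is otherwise silent; all are configurable.

### Statistics definitions

H-bond statistics use *occupancy* (fraction of frames with ≥ 1 event per
atom) rather than raw event counts before SASA normalization. Occupancy is
bounded, which makes the threshold of 30 transferable across systems; the
normed frequency is occupancy-% divided by the atom's time-averaged SASA in
nm², computed on solvent-stripped heavy atoms with the same frame stride as
the counts. Donor candidates are pocket N/O atoms with an inferred covalent
hydrogen; all pocket N/O atoms are acceptor candidates.

### Solvation free energies

ΔG_sol per residue is Σ σ(atom)·SASA(atom) per frame (waters/ions stripped),
reported as mean ± sd over frames. The shipped atomic solvation parameter
table (`asp_eisenberg.txt`, id `eisenberg-mclachlan-1986-kj`) uses
Eisenberg–McLachlan-style per-class coefficients converted to kJ mol⁻¹ Å⁻²:
C +0.0669, N/O −0.0251, charged carboxylate/terminal O −0.1004, charged
amine N −0.2092, S +0.0879. Atom classes are element-based with
charged-group overrides (ASP/GLU carboxylate oxygens, LYS NZ, ARG NE/NH*,
OXT). The table is user-overridable and its id is recorded in every
`SolvationProfile`, because the absolute per-residue scale (and hence the
0.2 kJ/mol threshold) depends on the chosen table.

### Scoring

Feature raw scores are kind-specific (ΔG_sol; normed H-bond frequency;
ion-percentage difference). Normalization divides each raw score by the
maximum of the *same kind* over the **master** model (aromatic and
hydrophobic normalize separately even though both derive from ΔG_sol);
master-level maxima keep scores comparable across subsets. The subset score
is the normalized sum times the symmetry factor min(N_A,N_B)/max(N_A,N_B)
(0/0 → 0). Ranking breaks score ties lexicographically on feature ids so
runs are deterministic; the hit budget is checked after each subset size
completes, making the sequential semantics exact regardless of execution
strategy.

### Geometry conventions

Kabsch superposition (via scipy's rotation alignment) always returns a
proper rotation. The representative frame is the GROMOS-style cluster
centre: most neighbours within the RMSD cutoff, ties broken by smallest
total RMSD, then lowest frame index. Aromatic ring normals come from the
smallest principal component of the ring atoms (PHE/TYR six-ring, TRP
indole); of the two opposite normals, the one whose 3 Å translation lands
nearer the pocket centre is used for the position, and both are exported as
directions. H-bond feature directions follow the donor→acceptor vector.
When no water or ion satisfies the placement criteria, the feature falls
back to the hydrophobic rule applied to the source atom position.

### Buried surface area

BSA_XL = SASA(X) + SASA(L) − SASA(X∪L), each term computed with only that
group present, on heavy atoms, and *not* halved: the harmonic-mean ranking
is scale-invariant, and the unhalved value is the definition's most direct
reading. Poses with any ligand–protein heavy-atom distance < 1 Å are
flagged as clashing but kept and reported.

### Reference matcher

The built-in matcher searches injective, kind-respecting assignments of
model features to ligand features, pruned by pairwise-distance compatibility
(|d_model − d_ligand| ≤ 2·tolerance), Kabsch-aligns the candidate
assignment, and accepts a pose when every aligned feature is within the
tolerance and no ligand heavy atom penetrates an exclusion sphere; the
lowest-RMSD pose wins. It is exact (verified against exhaustive assignment
enumeration) and intended for library sizes where an external engine is not
warranted; the engine adapter isolates a Pharmer-style binary behind the
same interface and raises a capability error when the binary is absent.

## Synthetic fixtures: what they emulate, and what they don't

The generator builds a two-chain complex whose residues line an interface
cleft (idealized templates, side chains pointing inward), with explicit
3-site waters and Na⁺/Cl⁻ ions placed in exact H-bond/contact geometry in a
seed-chosen set of frames (occupancy is therefore exact by construction,
`round(p·n_frames)` frames) and parked in a bulk region otherwise; Gaussian
jitter (default 0.05 Å) plays the role of thermal noise. Polar-role
residues carry charged groups so their ΔG_sol is unambiguously negative
under the shipped ASP table, and the generator *verifies at build time*
that each planted water/ion satisfies only its own site's criterion
(angle-aware for H-bonds, distance-margin for ions), raising rather than
emitting an ambiguous fixture. Ligand libraries copy rigid-motion-plus-
jitter subsets of a model's exclusion-clear features (true ligands) or are
made unmatchable by construction (kind swapped to an absent kind, or a
feature displaced until the exact matcher rejects it).

Passing tests on these fixtures demonstrate that the statistics, thresholds,
placement rules, scoring, matching and filtering are implemented correctly —
they do not demonstrate that the thresholds are well-chosen for real
proteins, that real water/ion statistics converge in 50 frames, or that the
idealized geometry resembles real pocket shapes. No physical realism is
claimed for the fixtures.

## Problem sizes

Default test fixtures use 2 × 20 residues (~350 atoms plus solvent), 10–50
frames, 960 sphere points, and libraries of ~10 ligands; the recovery suite
runs five seeds at 50 frames. These sizes were chosen so the full pipeline
exercises every stage while each stage's statistic is far from its
threshold (planted margins are ≥ 10× the noise scale).

## Known limitations

- PDB/GRO only; XTC/DCD readers are not bundled (convert upstream).
- The SASA implementation is point-sampling (no analytic areas or
  gradients); molecular-surface (SES) definitions are not supported.
- Ligand feature perception from bare conformers is minimal (formal
  charges, ring detection, N/O chemistry) — annotated feature records or an
  external engine are the intended inputs.
- Table-style screened-model counts from large-database runs are
  environment-dependent (parallel race conditions, database contents) and
  are not reproduced, only the deterministic sequential semantics.
- The MMGBSA stage imports and ranks tables; it computes no energies.
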