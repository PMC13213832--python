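# mdpharm

Interface pharmacophores from molecular-dynamics trajectories of
protein–protein (PP) complexes, for screening **dual-binding stabilizers** —
small molecules that sit in a pocket at the PP interface and interact with
*both* partners, strengthening the complex rather than disrupting it.

## Who this is for

Computational chemists and structural bioinformaticians who have an MD
trajectory of a solvated two-chain complex (no ligand required) and want
screening-ready pharmacophore models of an interface pocket, plus principled
filters that favor the dual-binding mode.

## The method

From the ligand-free trajectory, the interaction propensity of each pocket
site is measured against the solvent itself:

- **Hydrophobic / aromatic sites** — per-residue solvation free energy
  ΔG_sol = Σ_atoms σ(atom) · SASA(atom) (Shrake–Rupley areas, atomic
  solvation parameters σ), averaged over frames; residues with
  ΔG_sol > 0.2 kJ/mol qualify, PHE/TYR/TRP are classed aromatic.
- **H-bond donors / acceptors** — water hydrogen bonds to pocket N/O atoms
  (3 Å / 150° at the hydrogen), occupancy normalized by the atom's mean SASA
  (in nm²); sites above 30 qualify.
- **Charged sites** — percentage of frames with a Na⁺/Cl⁻ contact within
  4 Å; sites where |cation% − anion%| > 25 qualify.

Features are placed in a representative frame (GROMOS-style RMSD clustering
of the pocket residues): H-bond features at bonded water-oxygen positions
(4 Å / 150°, relaxed to 100°), charged features at bound-ion positions
(2–5 Å scan), hydrophobic features at the residue center of mass shifted
4 Å toward the pocket center, aromatic features 3 Å along the ring normal.
Every protein heavy atom becomes an exclusion sphere.

All k-feature subsets of this *master pharmacophore* (k from min(N, 10)
down to 4) are scored

    score = min(N_A, N_B)/max(N_A, N_B) × Σ normalized feature scores

where N_A, N_B count features contributed by each partner — a subset drawn
from one partner alone scores 0, enforcing dual binding. Ranked subsets
(top 50 000 per k) are screened until hits exceed 10 000; hits are re-ranked
by the harmonic mean HM(BSA_AL, BSA_BL) of the ligand's buried surface area
with each partner, and optionally by imported MMGBSA tables
(ΔG_AL, ΔG_BL, ΔG_(AB)L).

If the pocket is unknown, Fpocket output over many frames can be scanned:
each pocket's probes are treated as a pseudo-ligand and the (frame, pocket)
with the largest HM(BSA_AL, BSA_BL) is selected.

## Worked example

Everything runs on a self-contained synthetic complex (no downloads): two
idealized chains forming an interface cleft, explicit waters and ions with
planted interaction occupancies, and a ligand library planted to match.

```bash
mdpharm fixtures --out fx --plan minimal --residues-per-chain 10 \
        --n-frames 10 --occupancy 1.0 --seed 11
mdpharm extract  --trajectory fx/complex.pdb --out extract \
        --reference fx/ground_truth.json --seed 11
mdpharm models   --extract-dir extract --out models --seed 11
mdpharm screen   --models-dir models --library synthetic \
        --complex extract/representative_frame.pdb --out screen --seed 11
```

prints

```
fixture written to fx
extract: representative frame 5, 20 pocket residues
models: 8 features (N_A=4, N_B=4)
screen: 4 hits, 4 ranked
```

`extract/` holds the per-atom site statistics and per-residue ΔG_sol tables
(e.g. the first pocket residue, an aspartate, has
ΔG_sol = −5.87 ± 0.16 kJ/mol: polar, as built), the representative frame and
the pocket definition. `models/master.json` is the screening-engine-ready
pharmacophore (8 features, 4 per chain, so the master's symmetry factor is
1) with one exclusion sphere per protein heavy atom; `models_k*.csv` are the
ranked subset manifests. `screen/hits_ranked.csv` ranks the matched library
ligands by harmonic-mean buried surface area — the top hit buries
252/256 Å² against the two chains (HM = 254 Å²), a balanced dual binder,
and `screen/screen_report.csv` gives the per-k subset/hit accounting.

An MMGBSA table (columns `ligand_id, dG_AL, dG_BL, dG_ABL`, replicate
columns `dG_AL_1..` supported) can be re-ranked with
`mdpharm rank-mmgbsa --table scores.csv --out ranked.csv`, which sorts by
ΔG_(AB)L and flags ligands whose |ΔG_AL|/|ΔG_BL| balance falls below 0.5.

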