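# ncres — noncanonical amino-acid residue templates for structure prediction

Structure predictors in the AlphaFold3 family understand modified peptides
through the Chemical Component Dictionary (CCD): every residue, canonical or
not, must resolve to a component entry with named atoms, a bond table and
reference coordinates. Many therapeutically relevant noncanonical amino
acids have no such entry, which blocks prediction of the peptides that
contain them. `ncres` closes that gap for peptide-embeddable monomers: it
decides whether a small molecule can act as a single residue in a peptide
chain, finds the closest existing component, builds a named 3D residue
topology when none exists, exports it in AlphaFold3-style CSV + JSON form,
and validates predicted structures with backbone-geometry, ω-dihedral, RMSD
and chirality metrics.

## What it computes

**Residue scope.** A molecule qualifies as a residue monomer when it has a
free (non-amide, non-nitro/nitrile) amine nitrogen with at least one
hydrogen and a free carboxyl group (acid or carboxylate). The bond-count
shortest path between the amino nitrogen N and the carboxyl carbon C<sub>carb</sub>
fixes the class: 2 bonds → α, 3 → β, 4 → γ; δ and longer are rejected.
Robustness filters (molecular weight, ring/heavy-atom/heteroatom counts,
multiple acids, masked acids, oligomers, metal centres) emit nonexclusive
machine-readable exclusion flags.

**Component mapping and similarity search.** Queries are mapped onto a
component library in two passes: an exact match on the full 27-character
InChIKey, then a relaxed match on its first 14 characters (the connectivity
layer, which tolerates protonation and tautomer differences). Ranking uses
2048-bit Morgan fingerprints (radius 2) under Tanimoto (default), Dice,
cosine or Kulczynski coefficients; a Tanimoto score of 1.0 is treated as an
exact structural match. Top-k (default 10) hits carry all four scores.

**Topology building.** Accepted residues get one ETKDG distance-geometry
conformer (seeded, MMFF-relaxed by default) and CCD-convention atom names:
backbone N/CA/C/O/OXT (CB, CG label the extra backbone carbons of β/γ
residues), side chains walked breadth-first from the terminal backbone
carbon with Greek position letters (CB, CG, CD, CE, CZ, …), hydrogens named
after their parent heavy atom (HA, HB2/HB3, HXT).

**Export.** Custom residues receive three-letter component IDs from the
sequence ZCA, ZCB, … (skipping standard codes) and are written as
three-section CSVs (metadata / atoms / bonds, with polymer leaving-atom
flags) referenced from an AlphaFold3-style JSON job. A helper emits the
five-residue GGXGG probe peptide with the custom residue at position 3.

**Validation.** Five geometric metrics with closed reference bands
(mean ± 4σ where the mean and σ are known):

| metric | band | (mean, σ) |
|---|---|---|
| d(N–C1) | 1.382–1.534 Å | — |
| d(C<sub>k</sub>–C<sub>carb</sub>) | 1.441–1.609 Å | 1.525 ± 0.021 |
| mean d(C<sub>carb</sub>–O) | 1.151–1.311 Å | 1.231 ± 0.020 |
| mean ∠(C<sub>k</sub>–C<sub>carb</sub>–O) | 114.0–127.6° | 120.8 ± 1.7 |
| ∠(O–C<sub>carb</sub>–O) | 110–130° | — |

plus ω-dihedral banding for peptides (good: every |ω| ≥ 150° or ≤ 30°;
borderline: any 120° ≤ |ω| < 150° and none bad; bad: any 30° < |ω| < 120°
or missing), RMSD √(1/N ΣᵢΣⱼ (xᵢⱼ<sup>native</sup> − xᵢⱼ<sup>model</sup>)²) over
all/backbone/Cα selections with optional Kabsch superposition, and R/S
chirality agreement between the input stereo-SMILES and the modelled 3D
coordinates.

## Worked example

```bash
ncres fixtures --out fx
printf 'NCC(=O)O\nNC(Cc1ccccc1)C(=O)O\nNCCCC(=O)O\nNCC(=O)NCC(=O)O\n' > mols.smi
ncres classify --in mols.smi --out decisions.csv
```

prints

```
labels: {'alpha': 2, 'gamma': 1, 'rejected': 1}
flags (nonexclusive): {'delta_or_longer': 1, 'oligomer': 1}
```

Glycine and phenylglycine-like inputs are α residues (2-bond N→C<sub>carb</sub>
path), GABA is γ (4 bonds), and the Gly-Gly dipeptide is rejected: its only
free amine sits 5 bonds from the free acid and the backbone crosses an amide
bond (`delta_or_longer;oligomer`).

```bash
ncres search --library fx/mini_ccd_synthetic.sdf --smiles 'NC(Cc1ccccc1)C(=O)O' --k 3
```

returns the top hit `PHE` with `"tanimoto": 1.0` flagged `"exact": true`
(graph-identical to the stored phenylalanine; fingerprints carry no
chirality bits), followed by `SER` (0.423) and `ASP` (0.407).

```bash
ncres build --smiles 'NC(Cc1ccccc1)C(=O)O' --out residue/
ncres export --residue residue/ZCA.csv --motif GGXGG --out job/
```

writes `residue/ZCA.csv` — component `ZCA`, 23 atoms / 23 bonds, backbone
map `{N: N, C1: CA, Ccarb: C, O1: O, O2: OXT}`, leaving atoms
`[H2, HXT, OXT]` — and `job/ncres_job.json`, a validated job spec whose
`GGXGG` chain carries one modification `{ptmPosition: 3, ptmType: "ZCA"}`
and references the component CSV.

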