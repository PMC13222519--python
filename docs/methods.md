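# Methods

## Residue-scope model

A *peptide-embeddable residue monomer* is a molecule that can be written as
a single residue definition and joined into a chain by standard amide
bonds. Operationally this requires (i) a free amine — a nitrogen that is
not part of a nitro or nitrile group, is not an amide nitrogen, has at most
three heavy-atom neighbours and carries at least one hydrogen — and (ii) a
free carboxyl group: an sp² carbon bound to one doubly bonded oxygen and
one singly bonded oxygen that is protonated or anionic. Esters and
carbonates deliberately do not count; when they appear in place of a free
acid the molecule is flagged `masked_acid`.

Classification is purely topological: the bond-count shortest path over all
(amine N, carboxyl C) pairs. Two bonds → alpha, three → beta, four → gamma,
five or more → rejected (`delta_or_longer`). Ties among minimal pairs are
broken by the lexicographically smallest (N index, C index) so the stored
backbone path is reproducible. Salts are stripped before analysis by
keeping the largest fragment (heavy-atom count, then molecular weight);
screening `X.Cl` therefore equals screening `X`.

Amide nitrogens are defined at the SMARTS level: a nitrogen bonded to a
carbon that bears a double bond to oxygen, excluding the candidate's own
free-carboxyl carbons (so carbamic-acid-like nitrogens are not misflagged).

### Exclusion flags and limits

Flags are nonexclusive; acceptance requires zero flags and an
alpha/beta/gamma label. The complexity limits are artifact defaults chosen
to keep conformer generation robust, all overridable in `ScopeLimits`:
MW ≤ 600 Da, rings ≤ 4, heavy atoms ≤ 40, heteroatoms ≤ 12, free acids ≤ 2.
They are design choices of this package, not published thresholds, and the
package makes no claim that they reproduce any published screen counts.

The oligomer rule needs care: a strict "≥ 2 amide bonds" rule misses
dipeptides with a free N-terminus (Gly-Gly has exactly one amide bond),
while "≥ 1 amide bond" would wrongly flag side-chain primary amides
(asparagine, glutamine). `ncres` flags `oligomer` when the molecule has two
or more amide bonds anywhere **or** when an amide bond lies on the chosen
N→C<sub>carb</sub> backbone path. This keeps asparagine accepted and rejects
dipeptides. Metal/coordination detection is an element whitelist
(H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I); anything else flags
`metal_or_coordination`.

## Component mapping

InChIKeys are generated with the standard InChI backend after salt
stripping; optional standardization (valence cleanup, canonical tautomer)
makes keys robust to drawn tautomers. Mapping is two-pass: exact full-key
lookup, then the 14-character connectivity layer, which matches molecular
skeletons across protonation states (acetic acid …-N vs acetate …-M share
the prefix). Confidence is `high` only under identity — full-key equality
or a Morgan-Tanimoto-1.0 graph match — otherwise `ambiguous`, and all
candidates are returned sorted by component id so users can inspect them.
Stored SDF key properties are trusted when they match the 14-10-1 pattern,
else recomputed after light sanitization (kekulization repair and valence
normalization; metal disconnection off so organometallic records keep
their stored graph). Unparseable records are logged and skipped, never
fatal.

## Similarity search

Fingerprints are hashed circular (Morgan) environments, radius 2, 2048
bits, without chirality bits — the standard configuration — so enantiomers
score 1.0, consistent with treating Tanimoto 1.0 as graph-level (not
stereo-level) equivalence. The four coefficients are computed from on-bit
counts |A|, |B| and the intersection c:

- Tanimoto c/(|A|+|B|−c)
- Dice 2c/(|A|+|B|)
- cosine c/√(|A||B|)
- Kulczynski (c/|A| + c/|B|)/2 — the arithmetic-mean ("Kulczynski II")
  variant, the form common in fingerprint toolkits.

Two empty fingerprints score 0 by convention. Hits are sorted by the
ranking coefficient descending with ties broken by ascending component id;
k defaults to 10 and results truncate to the library size.

## Topology building

Coordinates come exclusively from ETKDGv3 distance-geometry embedding
(hydrogens added first; heavy-atom indices preserved), deterministic for a
fixed (molecule, seed, optimize) triple. The default seed is 42 and MMFF94
relaxation is on (UFF fallback when MMFF lacks parameters); both are
recorded in the output metadata. Embedding retries three times with
incremented seeds before failing. A mapped component template, when
supplied and graph-identical, contributes *atom names only* for matched
atoms — never coordinates.

Naming follows component-dictionary conventions. Alpha backbones are
N/CA/C/O with the second carboxyl oxygen OXT (hydrogen HXT). For beta and
gamma residues the carbonyl-adjacent carbon is CA and the
nitrogen-adjacent carbon CB (beta) or CG with CB between (gamma),
following the standard beta-alanine/GABA component entries. Side chains
are walked breadth-first from the terminal backbone carbon; depth maps to
the Greek letters B, G, D, E, Z, H, the name being element symbol +
letter, with numeric suffixes when several same-element atoms share a
depth (CG1/CG2 style) and canonical-rank tie-breaking for reproducibility.
Atoms beyond depth six or attached elsewhere get generic element+counter
names, kept unique and ≤ 4 characters. Hydrogen names derive from the
parent heavy atom in the modern PDB dialect: single hydrogens drop the
number (HA, HXT, H), a CH₂ numbers from 2 (HB2/HB3), a CH₃ from 1
(HB1–HB3), heteroatom hydrogens from the bare name (H, H2).

Topology validation enforces name uniqueness, an index↔name bijection,
no self/duplicate bonds, full backbone-role coverage matching the residue
class, and connectivity of the whole bonded graph.

## Export formats

Residue CSVs have three sections. `[metadata]` holds key/value rows with
JSON-encoded values (component id, class, backbone map, source SMILES,
InChIKey, seed, optimize flag, template id); `[atoms]` holds
index/name/element/charge/x/y/z/is_backbone/parent_heavy/leaving rows with
full-precision (`repr`) coordinates so the write→read round trip is the
identity; `[bonds]` holds name-space bond rows with kekulized orders and
an aromatic flag. Files are UTF-8 with RFC-4180 quoting and
byte-deterministic. Leaving atoms follow polymer conventions: OXT, HXT and
the highest-numbered amine hydrogen.

Component IDs are assigned from the sequence ZCA, ZCB, …, ZCZ, ZDA, …,
skipping a packaged curated list of standard codes (20 canonical residues
plus common modified residues); assignment is injective within a session.

The JSON job spec (dialect `ncres-af3`, version 1) follows the public
AlphaFold3 input field names where they are public (`name`, `modelSeeds`,
`sequences`, `protein.modifications` with `ptmPosition`/`ptmType`); the
`customComponents` block is a namespaced extension referencing residue
CSVs per file or as a folder. A shipped JSON schema documents the layout;
validation is programmatic (`validate_af3_job`) and checks structure,
1-based modification positions against sequence length, and that every
non-standard `ptmType` resolves to a readable component CSV. "Acceptance"
in this package means schema plus referential validity — running an
external predictor is out of scope, and byte-level interoperability with
any particular patched predictor build is not guaranteed.

## Geometric validation

The five metrics use closed intervals; the three bands with known
underlying statistics are exactly mean ± 4σ (1.525 ± 0.021 Å,
1.231 ± 0.020 Å, 120.8 ± 1.7°) and `reference_band` reconstructs them.
Angles are in degrees; ω is normalized to (−180°, 180°] and banded on
|ω| with the printed inequalities: endpoints 30 and 150 belong to *good*,
120 to *borderline*; a missing ω is *bad*. For beta/gamma residues the
dihedral substitutes the backbone carbon adjacent to the amide bond for
Cα (the `c1_name` argument overrides this).

RMSD implements √(1/N Σ‖Δx‖²) over name-matched atoms for the all-atom,
backbone and Cα selections. The equation itself has no alignment step;
the default applies Kabsch least-squares superposition first, with
`superpose=False` for the raw evaluation, since structure-comparison
tables conventionally superpose — an interpretation, recorded here.

Chirality agreement perceives expected R/S labels from the definition's
source SMILES and observed labels from the model coordinates via 3D
stereo perception on the same atom graph; centres with undefined expected
stereo are skipped with a note. Achiral residues report accuracy "n/a"
(`None`), treated as vacuously agreeing in aggregates.

## Synthetic fixtures — what they do and do not show

The mini component library is a 12-record synthetic stand-in for the
public components file: familiar ids (GLY, ALA, LYS, SER, PHE, ASP, BAL,
GAB, ACY/ACT, BNZ, EOH), stored InChIKeys, CCD-convention atom names on
the two records used for naming comparisons, and an acid/conjugate-base
pair exercising connectivity-layer matching. It is generated by code at
run time (deterministic bytes) and is *not* an excerpt of the real
dictionary; passing tests demonstrate the mapping/search machinery, not
coverage of the real dictionary's 40k+ components, its nonstandard
valences, or its legacy records. Similarly, the toy molecule panel (25
hand-analysed SMILES) exercises every classifier branch but cannot stand
in for the chemical diversity of a registered-compound database, and the
ideal-geometry generator produces exact internal coordinates rather than
force-field or predictor output. Headline pass rates of external
predictors are therefore out of scope here and are not claimed by any
test.

Problem sizes were chosen for fast, deterministic runs: a 12-component
library, a 25-molecule panel, a 20-fingerprint decoy set for top-k
checks, and single-conformer embeddings.

## Known limitations

- Conformer generation is single-engine (RDKit ETKDG) and single-conformer;
  no ensembles, no quantum-chemistry refinement, no ring-conformation
  sampling.
- Charge/tautomer handling is limited to salt stripping plus optional
  standardization; no enumeration.
- Generic names for atoms without standard analogues (element + position
  letter, then element + counter) are a documented package choice; other
  tools may choose differently.
- The CSV dialect is fully documented but package-specific; a consumer
  must read it with `read_residue_csv` or implement the three-section
  layout.
- Substructure and 3D-shape similarity are not provided; search is
  fingerprint-based only.
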