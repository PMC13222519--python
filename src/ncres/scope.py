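"""Decide whether a molecule is a peptide-embeddable alpha/beta/gamma residue.

A residue monomer, in the sense used throughout this package, is a molecule
carrying a free (non-amide) amine nitrogen and a terminal carboxyl group whose
shortest connecting path is two (alpha), three (beta) or four (gamma) bonds.
Anything longer (delta or beyond), or any molecule tripping a robustness
filter (oligomer, masked acid, metal centre, size limits, ...), is rejected
with machine-readable exclusion flags.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdmolops
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

# Free carboxylic acid or carboxylate anion: sp2 carbon with one double-bonded
# oxygen and one single-bonded oxygen that is protonated or anionic (esters,
# where the single oxygen continues to carbon, deliberately do not match).
CARBOXYL_SMARTS = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1,OX1-]")
# Masked acid: the single-bonded oxygen continues to a carbon (ester/carbonate).
MASKED_ACID_SMARTS = Chem.MolFromSmarts("[CX3](=[OX1])[OX2][#6]")
NITRO_N_SMARTS = Chem.MolFromSmarts("[$([NX3](=O)=O),$([NX3+](=O)[O-])]")
NITRILE_N_SMARTS = Chem.MolFromSmarts("[NX1]#[CX2]")
AMIDE_BOND_SMARTS = Chem.MolFromSmarts("[CX3](=[OX1])[NX3]")

ORGANIC_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)


class ParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized."""

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


@dataclass(frozen=True)
class CarboxylSite:
    carbon_index: int
    o_double_index: int
    o_single_index: int


@dataclass(frozen=True)
class AmineSite:
    nitrogen_index: int
    h_count: int
    is_amide: bool
    heavy_degree: int


@dataclass(frozen=True)
class BackboneClassification:
    """Alpha/beta/gamma verdict together with the realizing N→Ccarb path."""

    label: str  # alpha | beta | gamma | rejected
    path_length_bonds: int | None
    n_index: int | None
    ccarb_index: int | None
    path_atoms: tuple[int, ...]

    LABELS = {2: "alpha", 3: "beta", 4: "gamma"}


@dataclass(frozen=True)
class ScopeLimits:
    """Complexity/robustness limits. Defaults are artifact choices, all
    overridable; they are not derived from any published screen."""

    max_mw: float = 600.0
    max_rings: int = 4
    max_heavy_atoms: int = 40
    max_hetero_atoms: int = 12
    max_acids: int = 2
    allow_amide: bool = False
    allow_quaternary: bool = False


@dataclass(frozen=True)
class ScopeDecision:
    accepted: bool
    classification: BackboneClassification
    exclusion_flags: frozenset[str]


class QueryMolecule:
    """A sanitized query molecule with salts stripped.

    Salt stripping keeps the largest fragment by heavy-atom count, ties broken
    by molecular weight; the retained fragment is re-sanitized. The original
    SMILES is preserved in ``source_smiles``.
    """

    def __init__(self, smiles: str):
        self.source_smiles = smiles
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ParseError(smiles)
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        if len(frags) > 1:
            mol = max(
                frags,
                key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.MolWt(f)),
            )
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # pragma: no cover - sanitize after parse rarely fails
            raise ParseError(smiles, f"sanitization failed ({exc})") from exc
        self.mol = mol

    @property
    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    def __repr__(self) -> str:
        return f"QueryMolecule({self.canonical_smiles!r})"


def _as_mol(mol: QueryMolecule | Chem.Mol) -> Chem.Mol:
    return mol.mol if isinstance(mol, QueryMolecule) else mol


def find_carboxyl_sites(mol: QueryMolecule | Chem.Mol) -> list[CarboxylSite]:
    """Locate every free carboxylic-acid / carboxylate carbon.

    Returns one :class:`CarboxylSite` per matching carbon, with the doubly and
    singly bonded oxygens identified. Esters and carbonates do not match.
    """
    m = _as_mol(mol)
    sites = []
    seen = set()
    for c_idx, o_dbl, o_sgl in m.GetSubstructMatches(CARBOXYL_SMARTS):
        if c_idx in seen:
            continue
        seen.add(c_idx)
        sites.append(CarboxylSite(c_idx, o_dbl, o_sgl))
    return sites


def _is_amide_nitrogen(atom: Chem.Atom, carboxyl_carbons: set[int]) -> bool:
    """N bonded to a carbon that bears a double bond to O, excluding the
    candidate's own free-carboxyl carbons."""
    for nbr in atom.GetNeighbors():
        if nbr.GetAtomicNum() != 6 or nbr.GetIdx() in carboxyl_carbons:
            continue
        for bond in nbr.GetBonds():
            other = bond.GetOtherAtom(nbr)
            if (
                other.GetAtomicNum() == 8
                and bond.GetBondType() == Chem.BondType.DOUBLE
            ):
                return True
    return False


def find_amine_sites(
    mol: QueryMolecule | Chem.Mol,
    allow_amide: bool = False,
    allow_quaternary: bool = False,
) -> list[AmineSite]:
    """Collect candidate amino nitrogens.

    All nitrogens are considered except those in nitro and nitrile groups.
    Under the defaults, amide nitrogens and nitrogens with more than three
    heavy-atom neighbours are discarded, and a free amine must carry at least
    one hydrogen.
    """
    m = _as_mol(mol)
    excluded = {match[0] for match in m.GetSubstructMatches(NITRO_N_SMARTS)}
    excluded |= {match[0] for match in m.GetSubstructMatches(NITRILE_N_SMARTS)}
    carboxyl_carbons = {s.carbon_index for s in find_carboxyl_sites(m)}

    sites = []
    for atom in m.GetAtoms():
        if atom.GetAtomicNum() != 7 or atom.GetIdx() in excluded:
            continue
        h_count = atom.GetTotalNumHs()
        heavy_degree = atom.GetDegree()
        is_amide = _is_amide_nitrogen(atom, carboxyl_carbons)
        if not allow_amide and is_amide:
            continue
        if not allow_quaternary and heavy_degree > 3:
            continue
        if not allow_amide and h_count < 1:
            # free amine must have at least one H for peptide-bond formation
            continue
        sites.append(AmineSite(atom.GetIdx(), h_count, is_amide, heavy_degree))
    return sites


def classify_backbone(
    mol: QueryMolecule | Chem.Mol,
    carboxyls: list[CarboxylSite],
    amines: list[AmineSite],
) -> BackboneClassification:
    """Classify by the bond-count shortest path over all (Ccarb, N) pairs.

    The minimum path length determines the label (2 → alpha, 3 → beta,
    4 → gamma, ≥5 → rejected). Ties among minimal pairs are broken by the
    lexicographically smallest (n_index, ccarb_index) for reproducibility.
    """
    m = _as_mol(mol)
    if not carboxyls or not amines:
        return BackboneClassification("rejected", None, None, None, ())

    best: tuple[int, int, int, tuple[int, ...]] | None = None
    for am in sorted(amines, key=lambda a: a.nitrogen_index):
        for cx in sorted(carboxyls, key=lambda c: c.carbon_index):
            path = rdmolops.GetShortestPath(m, am.nitrogen_index, cx.carbon_index)
            if not path:  # disconnected after salt strip
                continue
            nbonds = len(path) - 1
            key = (nbonds, am.nitrogen_index, cx.carbon_index)
            if best is None or key < best[:3]:
                best = (nbonds, am.nitrogen_index, cx.carbon_index, tuple(path))

    if best is None:
        return BackboneClassification("rejected", None, None, None, ())
    nbonds, n_idx, c_idx, path = best
    label = BackboneClassification.LABELS.get(nbonds, "rejected")
    return BackboneClassification(label, nbonds, n_idx, c_idx, path)


def _amide_bond_matches(m: Chem.Mol) -> list[tuple[int, int]]:
    """(carbonyl C, N) index pairs of amide bonds."""
    return [(c, n) for (c, _o, n) in m.GetSubstructMatches(AMIDE_BOND_SMARTS)]


def apply_scope_filters(
    mol: QueryMolecule | Chem.Mol,
    cls: BackboneClassification,
    limits: ScopeLimits = ScopeLimits(),
) -> ScopeDecision:
    """Evaluate exclusion flags and produce the final accept/reject decision.

    Flags are nonexclusive; a molecule is accepted iff it carries no flags and
    the backbone label is alpha, beta or gamma. The oligomer rule fires when
    the molecule contains two or more amide bonds anywhere, or when an amide
    bond lies on the chosen N→Ccarb backbone path (so dipeptides are flagged
    while side-chain primary amides such as asparagine's are not).
    """
    m = _as_mol(mol)
    flags: set[str] = set()

    carboxyls = find_carboxyl_sites(m)
    amines = find_amine_sites(m, limits.allow_amide, limits.allow_quaternary)

    if not carboxyls:
        flags.add("no_carboxyl")
        if m.HasSubstructMatch(MASKED_ACID_SMARTS):
            flags.add("masked_acid")
    if not amines:
        flags.add("no_amine")

    if Descriptors.MolWt(m) > limits.max_mw:
        flags.add("mw_above_threshold")
    if m.GetRingInfo().NumRings() > limits.max_rings:
        flags.add("ring_count_above_threshold")
    if m.GetNumHeavyAtoms() > limits.max_heavy_atoms:
        flags.add("heavy_atom_count_above_threshold")
    n_hetero = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    if n_hetero > limits.max_hetero_atoms:
        flags.add("hetero_atom_count_above_threshold")
    if len(carboxyls) > limits.max_acids:
        flags.add("multi_acid_above_limit")

    if any(a.GetSymbol() not in ORGANIC_ELEMENTS for a in m.GetAtoms()):
        flags.add("metal_or_coordination")

    amide_pairs = _amide_bond_matches(m)
    path_set = set(cls.path_atoms)
    on_path = any(c in path_set and n in path_set for c, n in amide_pairs)
    if len(amide_pairs) >= 2 or on_path:
        flags.add("oligomer")

    if cls.label == "rejected" and carboxyls and amines:
        flags.add("delta_or_longer")

    accepted = not flags and cls.label in ("alpha", "beta", "gamma")
    return ScopeDecision(accepted, cls, frozenset(flags))


def screen_molecule(
    smiles: str, limits: ScopeLimits = ScopeLimits()
) -> ScopeDecision:
    """Classify and filter a single SMILES; raises :class:`ParseError` on
    unparseable input."""
    qm = QueryMolecule(smiles)
    carboxyls = find_carboxyl_sites(qm)
    amines = find_amine_sites(qm, limits.allow_amide, limits.allow_quaternary)
    cls = classify_backbone(qm, carboxyls, amines)
    return apply_scope_filters(qm, cls, limits)


def screen_batch(
    smiles_input, limits: ScopeLimits = ScopeLimits()
) -> pd.DataFrame:
    """Screen a batch of SMILES (iterable of strings, file path, or open file).

    Blank lines are skipped; unparseable records yield a row flagged
    ``parse_error`` and processing continues. Returns a DataFrame with columns
    id, smiles, label, path_length, accepted, flags (semicolon-joined). Summary
    counts are attached as ``df.attrs['label_counts']`` and
    ``df.attrs['flag_counts']`` (flags nonexclusive).
    """
    if isinstance(smiles_input, (str,)):
        with open(smiles_input) as fh:
            lines = fh.readlines()
    elif isinstance(smiles_input, io.IOBase):
        lines = smiles_input.readlines()
    else:
        lines = list(smiles_input)

    rows = []
    idx = 0
    for line in lines:
        smiles = line.strip().split()[0] if line.strip() else ""
        if not smiles:
            continue
        idx += 1
        try:
            dec = screen_molecule(smiles, limits)
            rows.append(
                {
                    "id": idx,
                    "smiles": smiles,
                    "label": dec.classification.label,
                    "path_length": dec.classification.path_length_bonds,
                    "accepted": dec.accepted,
                    "flags": ";".join(sorted(dec.exclusion_flags)),
                }
            )
        except ParseError:
            rows.append(
                {
                    "id": idx,
                    "smiles": smiles,
                    "label": "rejected",
                    "path_length": None,
                    "accepted": False,
                    "flags": "parse_error",
                }
            )

    df = pd.DataFrame(
        rows,
        columns=["id", "smiles", "label", "path_length", "accepted", "flags"],
    )
    label_counts = df["label"].value_counts().to_dict() if len(df) else {}
    flag_counts: dict[str, int] = {}
    for fl in df["flags"] if len(df) else []:
        for f in filter(None, fl.split(";")):
            flag_counts[f] = flag_counts.get(f, 0) + 1
    df.attrs["label_counts"] = label_counts
    df.attrs["flag_counts"] = flag_counts
    return df
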