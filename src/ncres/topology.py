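"""3D conformer embedding and CCD-style residue atom naming.

Numeric RDKit atom indices are converted to residue-style atom names: the
backbone gets the conventional labels (N, CA, C, O, OXT; with CB/CG used for
the extra backbone carbons of beta and gamma residues), side chains are
walked breadth-first from the terminal backbone carbon and named with Greek
position letters (B, G, D, E, Z, H) plus numeric suffixes on ties, and every
hydrogen is named after its heavy-atom parent. Coordinates always come from
distance-geometry embedding; a mapped CCD template, when supplied, only
contributes atom names for graph-matched atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from rdkit import Chem
from rdkit.Chem import AllChem

from ncres.scope import (
    BackboneClassification,
    QueryMolecule,
    classify_backbone,
    find_amine_sites,
    find_carboxyl_sites,
)

logger = logging.getLogger(__name__)

GREEK_LETTERS = "BGDEZH"  # side-chain position letters by bond depth
MAX_NAME_LEN = 4

# Backbone-carbon labels, nitrogen-adjacent first, following the standard
# beta-alanine / GABA component conventions (carbonyl-adjacent carbon is CA).
_BACKBONE_CARBON_LABELS = {
    "alpha": ["CA"],
    "beta": ["CB", "CA"],
    "gamma": ["CG", "CB", "CA"],
}


class EmbeddingError(RuntimeError):
    """Distance-geometry embedding failed after retries."""


class TopologyError(ValueError):
    """A residue-topology invariant is violated."""


@dataclass(frozen=True)
class NamedAtom:
    index: int
    element: str
    name: str
    formal_charge: int
    xyz: tuple[float, float, float]
    is_backbone: bool
    parent_heavy: str | None = None  # heavy-atom name, hydrogens only


@dataclass(frozen=True)
class BondRecord:
    atom1_name: str
    atom2_name: str
    order: str  # single | double | triple
    aromatic: bool


@dataclass(frozen=True)
class ResidueTopology:
    residue_class: str  # alpha | beta | gamma
    atoms: tuple[NamedAtom, ...]
    bonds: tuple[BondRecord, ...]
    backbone_map: dict  # role (N, C1..Ck, Ccarb, O1, O2) -> atom name
    metadata: dict = field(default_factory=dict)

    def atom(self, name: str) -> NamedAtom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.atoms]


def embed_conformer(
    mol: QueryMolecule | Chem.Mol,
    seed: int = 42,
    optimize: bool = True,
    max_attempts: int = 3,
) -> Chem.Mol:
    """Embed one 3D conformer with ETKDG distance geometry.

    Hydrogens are added before embedding (heavy-atom indices are preserved).
    Deterministic for fixed (input, seed, optimize). On failure, retries with
    incremented seeds up to ``max_attempts`` times, then raises
    :class:`EmbeddingError`. With ``optimize=True`` the conformer is relaxed
    with MMFF94 (UFF fallback for atom types MMFF cannot handle).
    """
    m = mol.mol if isinstance(mol, QueryMolecule) else mol
    molh = Chem.AddHs(Chem.Mol(m))
    conf_id = -1
    for attempt in range(max_attempts):
        params = AllChem.ETKDGv3()
        params.randomSeed = seed + attempt
        conf_id = AllChem.EmbedMolecule(molh, params)
        if conf_id >= 0:
            break
    if conf_id < 0:
        raise EmbeddingError(
            f"embedding failed after {max_attempts} attempts for "
            f"{Chem.MolToSmiles(m)!r}"
        )
    if optimize:
        try:
            if AllChem.MMFFHasAllMoleculeParams(molh):
                AllChem.MMFFOptimizeMolecule(molh)
            else:
                AllChem.UFFOptimizeMolecule(molh)
        except Exception:
            logger.warning("force-field optimization failed; keeping raw embed")
    return molh


def recognize_backbone(
    mol: QueryMolecule | Chem.Mol, cls: BackboneClassification
) -> dict:
    """Assign backbone roles N, C1..Ck, Ccarb, O1, O2 to atom indices.

    Roles come from the stored classification path; the carboxyl oxygens are
    the doubly bonded (O1) and singly bonded (O2) oxygens on Ccarb.
    """
    m = mol.mol if isinstance(mol, QueryMolecule) else mol
    if cls.label not in ("alpha", "beta", "gamma"):
        raise TopologyError(f"cannot build backbone for label {cls.label!r}")
    path = list(cls.path_atoms)
    if len(path) != cls.path_length_bonds + 1:
        raise TopologyError("classification path inconsistent with bond count")

    roles = {"N": path[0], "Ccarb": path[-1]}
    for i, idx in enumerate(path[1:-1], start=1):
        roles[f"C{i}"] = idx

    ccarb = m.GetAtomWithIdx(path[-1])
    o_double = o_single = None
    for bond in ccarb.GetBonds():
        other = bond.GetOtherAtom(ccarb)
        if other.GetAtomicNum() != 8:
            continue
        if bond.GetBondType() == Chem.BondType.DOUBLE:
            o_double = other.GetIdx()
        elif bond.GetBondType() == Chem.BondType.SINGLE:
            o_single = other.GetIdx()
    if o_double is None or o_single is None:
        raise TopologyError("carboxyl oxygens not resolvable on Ccarb")
    roles["O1"] = o_double
    roles["O2"] = o_single
    return roles


def _hydrogen_names(parent_name: str, parent_element: str, count: int) -> list[str]:
    """Hydrogen names for ``count`` hydrogens on one heavy atom.

    Modern PDB dialect: a single hydrogen drops the number (HA, HXT, H); a
    carbon CH2 numbers from 2 (HB2, HB3); a CH3 numbers from 1 (HB1..HB3);
    heteroatoms number from the bare name (H, H2, H3).
    """
    suffix = parent_name[len(parent_element):] if parent_name.startswith(
        parent_element
    ) else parent_name
    base = "H" + suffix
    if count == 1:
        return [base]
    if parent_element == "C":
        start = 2 if count == 2 else 1
        return [f"{base}{start + i}" for i in range(count)]
    return [base] + [f"{base}{i}" for i in range(2, count + 1)]


def _uniquify(name: str, used: set[str], element: str) -> str:
    if name not in used and len(name) <= MAX_NAME_LEN:
        return name
    i = 1
    while True:
        cand = f"{name}{i}" if len(f"{name}{i}") <= MAX_NAME_LEN else f"{element}{i}"
        if cand not in used:
            if len(name) > MAX_NAME_LEN or name != cand:
                pass
            return cand
        i += 1


def _template_names(molh: Chem.Mol, template_mol: Chem.Mol) -> dict | None:
    """Adopt heavy-atom names from a graph-identical template component.

    The template must carry an ``atom_names`` property (space-separated names
    in atom order). Returns a heavy-atom index->name map, or None when the
    graphs do not match exactly.
    """
    if not template_mol.HasProp("atom_names"):
        return None
    t = Chem.RemoveHs(Chem.Mol(template_mol))
    names = template_mol.GetProp("atom_names").split()
    heavy_names = [
        names[a.GetIdx()]
        for a in template_mol.GetAtoms()
        if a.GetAtomicNum() != 1
    ] if len(names) == template_mol.GetNumAtoms() else names
    if len(heavy_names) != t.GetNumAtoms():
        return None
    q = Chem.RemoveHs(Chem.Mol(molh))
    if q.GetNumAtoms() != t.GetNumAtoms():
        return None
    match = q.GetSubstructMatch(t)
    if len(match) != t.GetNumAtoms():
        return None
    return {match[ti]: heavy_names[ti] for ti in range(t.GetNumAtoms())}


def assign_atom_names(
    molh: Chem.Mol,
    backbone_map: dict,
    residue_class: str,
    template_mol: Chem.Mol | None = None,
) -> list[NamedAtom]:
    """Name every atom (heavy and hydrogen) of an embedded residue molecule.

    Returns NamedAtom records carrying the full index<->name bijection, the
    conformer coordinates, backbone membership and, for hydrogens, the parent
    heavy-atom name.
    """
    conf = molh.GetConformer()
    ranks = list(Chem.CanonicalRankAtoms(molh, breakTies=True))
    used: set[str] = set()
    names: dict[int, str] = {}

    backbone_idx = set(backbone_map.values())
    n_idx = backbone_map["N"]
    ccarb_idx = backbone_map["Ccarb"]
    carbon_roles = [r for r in backbone_map if r.startswith("C") and r != "Ccarb"]
    carbon_roles.sort(key=lambda r: int(r[1:]))
    ck_idx = backbone_map[carbon_roles[-1]] if carbon_roles else None

    adopted = _template_names(molh, template_mol) if template_mol is not None else None
    if adopted:
        for idx, nm in adopted.items():
            if nm in used or len(nm) > MAX_NAME_LEN:
                adopted = None
                break
            names[idx] = nm
            used.add(nm)
    if not adopted:
        names.clear()
        used.clear()
        # backbone first
        def put(idx: int, name: str):
            elem = molh.GetAtomWithIdx(idx).GetSymbol()
            nm = _uniquify(name, used, elem)
            names[idx] = nm
            used.add(nm)

        put(n_idx, "N" if molh.GetAtomWithIdx(n_idx).GetAtomicNum() == 7 else
            molh.GetAtomWithIdx(n_idx).GetSymbol())
        labels = _BACKBONE_CARBON_LABELS[residue_class]
        for role, label in zip(carbon_roles, labels):
            idx = backbone_map[role]
            atom = molh.GetAtomWithIdx(idx)
            if atom.GetAtomicNum() == 6:
                put(idx, label)
            else:  # unusual hetero backbone member: element + position letter
                put(idx, atom.GetSymbol() + label[-1])
        put(ccarb_idx, "C")
        put(backbone_map["O1"], "O")
        put(backbone_map["O2"], "OXT")

        # side chain: BFS from the terminal backbone carbon (Ck)
        visited = set(backbone_idx)
        frontier = [ck_idx] if ck_idx is not None else [ccarb_idx]
        depth = 0
        while frontier:
            nxt = []
            for idx in frontier:
                for nbr in molh.GetAtomWithIdx(idx).GetNeighbors():
                    j = nbr.GetIdx()
                    if nbr.GetAtomicNum() == 1 or j in visited:
                        continue
                    visited.add(j)
                    nxt.append(j)
            depth += 1
            if not nxt:
                break
            # group same-element atoms at this depth; tie-break by canonical rank
            nxt.sort(key=lambda j: (molh.GetAtomWithIdx(j).GetSymbol(), ranks[j]))
            if depth <= len(GREEK_LETTERS):
                letter = GREEK_LETTERS[depth - 1]
                groups: dict[str, list[int]] = {}
                for j in nxt:
                    groups.setdefault(molh.GetAtomWithIdx(j).GetSymbol(), []).append(j)
                for elem, members in groups.items():
                    if len(members) == 1:
                        put(members[0], f"{elem}{letter}")
                    else:
                        for i, j in enumerate(members, start=1):
                            put(j, f"{elem}{letter}{i}")
            else:
                for j in nxt:
                    put(j, molh.GetAtomWithIdx(j).GetSymbol())
            frontier = nxt

        # anything left (substituents on N or mid-backbone atoms): generic names
        for atom in molh.GetAtoms():
            idx = atom.GetIdx()
            if atom.GetAtomicNum() == 1 or idx in names:
                continue
            put(idx, atom.GetSymbol())

    # hydrogens, named after their heavy-atom parent
    parent_of: dict[int, int] = {}
    h_by_parent: dict[int, list[int]] = {}
    for atom in molh.GetAtoms():
        if atom.GetAtomicNum() != 1:
            continue
        nbrs = atom.GetNeighbors()
        if not nbrs:
            raise TopologyError(f"isolated hydrogen at index {atom.GetIdx()}")
        p = nbrs[0].GetIdx()
        parent_of[atom.GetIdx()] = p
        h_by_parent.setdefault(p, []).append(atom.GetIdx())

    for p, hs in sorted(h_by_parent.items()):
        hs.sort(key=lambda j: ranks[j])
        pname = names[p]
        pelem = molh.GetAtomWithIdx(p).GetSymbol()
        for h_idx, h_name in zip(hs, _hydrogen_names(pname, pelem, len(hs))):
            nm = _uniquify(h_name, used, "H")
            names[h_idx] = nm
            used.add(nm)

    atoms = []
    for atom in molh.GetAtoms():
        idx = atom.GetIdx()
        pos = conf.GetAtomPosition(idx)
        is_h = atom.GetAtomicNum() == 1
        atoms.append(
            NamedAtom(
                index=idx,
                element=atom.GetSymbol(),
                name=names[idx],
                formal_charge=atom.GetFormalCharge(),
                xyz=(pos.x, pos.y, pos.z),
                is_backbone=(idx in backbone_idx),
                parent_heavy=names[parent_of[idx]] if is_h else None,
            )
        )
    return atoms


_ORDER_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
}


def build_topology(
    molh: Chem.Mol,
    named_atoms: list[NamedAtom],
    residue_class: str,
    backbone_map: dict,
    metadata: dict | None = None,
) -> ResidueTopology:
    """Assemble and validate the named bond table into a ResidueTopology.

    Aromatic bonds are kekulized to single/double orders and flagged
    aromatic. Raises :class:`TopologyError` listing the offending atoms or
    bonds when an invariant (name uniqueness, connectivity, role coverage)
    fails.
    """
    by_index = {a.index: a for a in named_atoms}
    kek = Chem.Mol(molh)
    Chem.Kekulize(kek, clearAromaticFlags=False)

    bonds = []
    seen_pairs = set()
    for bond in kek.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        pair = (min(i, j), max(i, j))
        if pair in seen_pairs:
            raise TopologyError(f"duplicate bond {pair}")
        seen_pairs.add(pair)
        order = _ORDER_NAMES.get(bond.GetBondType())
        if order is None:
            raise TopologyError(f"unsupported bond order on bond {pair}")
        bonds.append(
            BondRecord(
                by_index[i].name,
                by_index[j].name,
                order,
                bond.GetIsAromatic(),
            )
        )

    name_map = {role: by_index[idx].name for role, idx in backbone_map.items()}
    topo = ResidueTopology(
        residue_class=residue_class,
        atoms=tuple(named_atoms),
        bonds=tuple(bonds),
        backbone_map=name_map,
        metadata=dict(metadata or {}),
    )
    validate_topology(topo)
    return topo


def validate_topology(topo: ResidueTopology) -> None:
    """Check ResidueTopology invariants, raising TopologyError on violation."""
    names = [a.name for a in topo.atoms]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise TopologyError(f"duplicate atom names: {sorted(dupes)}")
    name_set = set(names)
    for b in topo.bonds:
        if b.atom1_name == b.atom2_name:
            raise TopologyError(f"self-bond on {b.atom1_name}")
        if b.atom1_name not in name_set or b.atom2_name not in name_set:
            raise TopologyError(f"bond references unknown atom: {b}")
    pairs = [(min(b.atom1_name, b.atom2_name), max(b.atom1_name, b.atom2_name))
             for b in topo.bonds]
    if len(pairs) != len(set(pairs)):
        raise TopologyError("duplicate bond pairs in name space")

    n_carbons = {"alpha": 1, "beta": 2, "gamma": 3}[topo.residue_class]
    required = ["N", "Ccarb", "O1", "O2"] + [f"C{i}" for i in range(1, n_carbons + 1)]
    missing = [r for r in required if r not in topo.backbone_map]
    if missing:
        raise TopologyError(f"backbone roles missing: {missing}")
    for role, nm in topo.backbone_map.items():
        if nm not in name_set:
            raise TopologyError(f"backbone role {role} -> unknown atom {nm}")

    # connectivity over the name graph
    if len(topo.atoms) > 1:
        adj: dict[str, set[str]] = {n: set() for n in names}
        for b in topo.bonds:
            adj[b.atom1_name].add(b.atom2_name)
            adj[b.atom2_name].add(b.atom1_name)
        stack = [names[0]]
        seen = set()
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(adj[cur] - seen)
        if seen != name_set:
            raise TopologyError(
                f"topology disconnected; unreachable atoms: {sorted(name_set - seen)}"
            )


def build_residue_topology(
    smiles: str,
    seed: int = 42,
    optimize: bool = True,
    template_mol: Chem.Mol | None = None,
) -> ResidueTopology:
    """End-to-end convenience: classify, embed, name and assemble a residue.

    Raises :class:`TopologyError` if the molecule is not an accepted
    alpha/beta/gamma residue.
    """
    qm = QueryMolecule(smiles)
    carboxyls = find_carboxyl_sites(qm)
    amines = find_amine_sites(qm)
    cls = classify_backbone(qm, carboxyls, amines)
    if cls.label not in ("alpha", "beta", "gamma"):
        raise TopologyError(f"not an alpha/beta/gamma residue: {smiles!r}")
    backbone = recognize_backbone(qm, cls)
    molh = embed_conformer(qm, seed=seed, optimize=optimize)
    atoms = assign_atom_names(molh, backbone, cls.label, template_mol=template_mol)
    meta = {"source_smiles": smiles, "seed": seed, "optimize": optimize}
    return build_topology(molh, atoms, cls.label, backbone, metadata=meta)
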