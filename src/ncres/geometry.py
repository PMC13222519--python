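"""Geometric validation of residue and peptide structures.

Implements five backbone-geometry metrics with fixed reference bands
(mean ± 4σ where the underlying mean and σ are known), peptide-bond
omega-dihedral banding (good / borderline / bad), RMSD with optional
least-squares rigid-body superposition, and chirality agreement between an
input definition and a modelled 3D structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

# (mean, sigma) pairs behind the ± 4σ reference bands, in Å / degrees.
REFERENCE_STATS = {
    "d_Ck_Ccarb": (1.525, 0.021),
    "d_Ccarb_O_mean": (1.231, 0.020),
    "ang_Ck_Ccarb_O_mean": (120.8, 1.7),
}

# Closed reference intervals for the five metrics. d_N_C1 and the O-C-O
# sanity band are printed directly without (mean, sigma).
GEOMETRY_BANDS = {
    "d_N_C1": (1.382, 1.534),
    "d_Ck_Ccarb": (1.441, 1.609),
    "d_Ccarb_O_mean": (1.151, 1.311),
    "ang_Ck_Ccarb_O_mean": (114.0, 127.6),
    "ang_O1_Ccarb_O2": (110.0, 130.0),
}

METRIC_NAMES = tuple(GEOMETRY_BANDS)

OMEGA_GOOD_MIN = 150.0
OMEGA_GOOD_MAX = 30.0
OMEGA_BORDERLINE_MIN = 120.0


def reference_band(mean: float, sigma: float, n_sigma: float = 4.0) -> tuple[float, float]:
    """Closed interval mean ± n_sigma·sigma."""
    return (mean - n_sigma * sigma, mean + n_sigma * sigma)


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class CoordinateSet:
    """Named atomic coordinates with backbone/CA selection tags."""

    atoms: tuple  # of (name, element, (x, y, z))
    backbone_names: frozenset[str] = frozenset({"N", "CA", "C", "O"})
    calpha_names: frozenset[str] = frozenset({"CA"})

    def __post_init__(self):
        names = [a[0] for a in self.atoms]
        if len(names) != len(set(names)):
            raise GeometryError("atom names must be unique in a CoordinateSet")
        for name, _el, xyz in self.atoms:
            if not all(math.isfinite(v) for v in xyz):
                raise GeometryError(f"non-finite coordinates on atom {name}")

    @classmethod
    def from_topology(cls, topo) -> "CoordinateSet":
        bb = frozenset(a.name for a in topo.atoms if a.is_backbone)
        ca = frozenset({topo.backbone_map.get("C1", "CA")}) & {
            a.name for a in topo.atoms
        }
        return cls(
            tuple((a.name, a.element, a.xyz) for a in topo.atoms),
            backbone_names=bb,
            calpha_names=ca or frozenset({"CA"}),
        )

    def position(self, name: str) -> np.ndarray | None:
        for n, _el, xyz in self.atoms:
            if n == name:
                return np.asarray(xyz, dtype=float)
        return None

    def names(self, selection: str = "all") -> list[str]:
        if selection == "all":
            return [a[0] for a in self.atoms]
        if selection == "backbone":
            return [a[0] for a in self.atoms if a[0] in self.backbone_names]
        if selection == "calpha":
            return [a[0] for a in self.atoms if a[0] in self.calpha_names]
        raise GeometryError(f"unknown selection {selection!r}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CoordinateSet":
        atoms = tuple(
            (n, el, tuple(rotation @ np.asarray(xyz) + translation))
            for n, el, xyz in self.atoms
        )
        return CoordinateSet(atoms, self.backbone_names, self.calpha_names)


@dataclass(frozen=True)
class GeometryReport:
    values: dict  # metric -> float or None when unresolvable
    in_range: dict  # metric -> bool
    all_pass: bool

    def __getattr__(self, item):
        if item in GEOMETRY_BANDS:
            return self.values[item]
        raise AttributeError(item)


@dataclass(frozen=True)
class OmegaReport:
    omega_prev: float | None
    omega_next: float | None
    category: str  # good | borderline | bad


@dataclass(frozen=True)
class RMSDResult:
    value: float
    selection: str
    superposed: bool
    n_atoms: int


@dataclass(frozen=True)
class ChiralityReport:
    centers: tuple  # of (atom_name, expected, observed, agree)
    accuracy: float | None  # None when no stereocenters (n/a)
    notes: tuple = ()

    @property
    def effective_accuracy(self) -> float:
        """Accuracy with achiral molecules treated as vacuously agreeing."""
        return 1.0 if self.accuracy is None else self.accuracy


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, normalized to (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def geometry_metrics(coords: CoordinateSet, backbone_map: dict) -> GeometryReport:
    """Evaluate the five reference metrics on a residue.

    ``backbone_map`` maps roles (N, C1..Ck, Ccarb, O1, O2) to atom names in
    ``coords``. A missing role atom yields a None value and a failed flag for
    every metric that needs it.
    """
    carbon_roles = sorted(
        (r for r in backbone_map if r.startswith("C") and r != "Ccarb"),
        key=lambda r: int(r[1:]),
    )
    ck_role = carbon_roles[-1] if carbon_roles else None

    def pos(role):
        name = backbone_map.get(role)
        return coords.position(name) if name else None

    n, c1 = pos("N"), pos("C1")
    ck = pos(ck_role) if ck_role else None
    ccarb, o1, o2 = pos("Ccarb"), pos("O1"), pos("O2")

    values: dict = {}
    values["d_N_C1"] = _dist(n, c1) if n is not None and c1 is not None else None
    values["d_Ck_Ccarb"] = (
        _dist(ck, ccarb) if ck is not None and ccarb is not None else None
    )
    if ccarb is not None and o1 is not None and o2 is not None:
        values["d_Ccarb_O_mean"] = (_dist(ccarb, o1) + _dist(ccarb, o2)) / 2
        values["ang_O1_Ccarb_O2"] = _angle(o1, ccarb, o2)
    else:
        values["d_Ccarb_O_mean"] = None
        values["ang_O1_Ccarb_O2"] = None
    if all(p is not None for p in (ck, ccarb, o1, o2)):
        values["ang_Ck_Ccarb_O_mean"] = (
            _angle(ck, ccarb, o1) + _angle(ck, ccarb, o2)
        ) / 2
    else:
        values["ang_Ck_Ccarb_O_mean"] = None

    in_range = {
        m: (v is not None and GEOMETRY_BANDS[m][0] <= v <= GEOMETRY_BANDS[m][1])
        for m, v in values.items()
    }
    return GeometryReport(values, in_range, all(in_range.values()))


def _norm_omega(omega: float) -> float:
    omega = math.fmod(omega, 360.0)
    if omega > 180.0:
        omega -= 360.0
    elif omega <= -180.0:
        omega += 360.0
    return omega


def categorize_omegas(omega_prev: float | None, omega_next: float | None) -> str:
    """Band an (ω_prev, ω_next) pair.

    good: every present ω has |ω| ≥ 150° or |ω| ≤ 30°; borderline: at least
    one ω with 120° ≤ |ω| < 150° and none in the bad zone; bad: any ω with
    30° < |ω| < 120°, or a missing value.
    """
    omegas = [omega_prev, omega_next]
    if any(o is None for o in omegas):
        return "bad"
    mags = [abs(_norm_omega(o)) for o in omegas]
    if any(OMEGA_GOOD_MAX < m < OMEGA_BORDERLINE_MIN for m in mags):
        return "bad"
    if any(OMEGA_BORDERLINE_MIN <= m < OMEGA_GOOD_MIN for m in mags):
        return "borderline"
    return "good"


class PeptideStructure:
    """An ordered list of residues, each a dict of atom name -> xyz.

    Thin container used for omega-dihedral checks over a peptide chain; can
    be built synthetically or loaded from a PDB/mmCIF file.
    """

    def __init__(self, residues: list[dict]):
        self.residues = [
            {k: np.asarray(v, dtype=float) for k, v in r.items()} for r in residues
        ]

    def __len__(self):
        return len(self.residues)

    @classmethod
    def from_file(cls, path, chain: str | None = None) -> "PeptideStructure":
        """Load the first (or named) chain of a PDB/mmCIF structure."""
        import gemmi

        st = gemmi.read_structure(str(path))
        st.setup_entities()
        model = st[0]
        residues = []
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            for res in ch:
                residues.append(
                    {atom.name: (atom.pos.x, atom.pos.y, atom.pos.z) for atom in res}
                )
            break  # first matching (or first overall) chain only
        return cls(residues)


def classify_omega(
    structure: PeptideStructure,
    residue_index: int,
    c1_name: str = "CA",
) -> OmegaReport:
    """Compute and band ω_prev and ω_next for residue ``residue_index``
    (0-based) of a peptide.

    ω_prev is the torsion C1(i-1)–Ccarb(i-1)–N(i)–C1(i) and ω_next the same
    over the i → i+1 peptide bond, with C1 generalizing Cα (for beta/gamma
    residues the backbone carbon adjacent to the amide bond is used; pass
    ``c1_name`` to override). Unresolvable atoms make the ω missing, which
    bands as bad.
    """
    res = structure.residues

    def omega_between(a: int, b: int) -> float | None:
        if not (0 <= a < len(res) and 0 <= b < len(res)):
            return None
        ra, rb = res[a], res[b]
        needed = [ra.get(c1_name), ra.get("C"), rb.get("N"), rb.get(c1_name)]
        if any(p is None for p in needed):
            return None
        return dihedral(*needed)

    omega_prev = omega_between(residue_index - 1, residue_index)
    omega_next = omega_between(residue_index, residue_index + 1)
    return OmegaReport(omega_prev, omega_next, categorize_omegas(omega_prev, omega_next))


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rotation R and centroids aligning q onto p (both (N,3))."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (q - qc).T @ (p - pc)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    return r, pc, qc


def rmsd(
    native: CoordinateSet,
    model: CoordinateSet,
    selection: str = "all",
    superpose: bool = True,
) -> RMSDResult:
    """Root-mean-square deviation over name-matched atoms.

    Computes sqrt(1/N Σ_i Σ_j (x_ij^native − x_ij^model)²) over the selected
    correspondence; with ``superpose=True`` an optimal least-squares
    rigid-body superposition (Kabsch) is applied to the model first.
    """
    names_native = set(native.names(selection))
    names_model = set(model.names(selection))
    common = sorted(names_native & names_model)
    if not common:
        missing = sorted(names_native ^ names_model)
        raise GeometryError(
            f"no matched atoms for selection {selection!r}; unmatched: {missing}"
        )
    p = np.array([native.position(n) for n in common])
    q = np.array([model.position(n) for n in common])
    if superpose and len(common) >= 1:
        r, pc, qc = kabsch_rotation(p, q)
        q = (q - qc) @ r.T + pc
    value = float(np.sqrt(np.sum((p - q) ** 2) / len(common)))
    return RMSDResult(value, selection, superpose, len(common))


def chirality_agreement(defn, model: CoordinateSet) -> ChiralityReport:
    """Compare expected (input-SMILES) and observed (3D) stereocentre labels.

    Expected R/S labels are perceived from the definition's source SMILES;
    observed labels come from the model coordinates via 3D stereo
    perception. Centers with undefined expected stereo are skipped with a
    note. Achiral molecules report accuracy None (n/a), treated as vacuously
    agreeing in aggregates.
    """
    smiles = defn.metadata.get("source_smiles") or defn.topology.metadata.get(
        "source_smiles"
    )
    if not smiles:
        raise GeometryError("definition lacks source_smiles metadata")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GeometryError(f"cannot parse source SMILES {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        from rdkit.Chem import Descriptors

        mol = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.MolWt(f)))
        Chem.SanitizeMol(mol)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)

    index_to_name = {a.index: a.name for a in defn.topology.atoms}
    notes = []
    expected: dict[int, str] = {}
    for idx, label in Chem.FindMolChiralCenters(mol, includeUnassigned=True):
        if label in ("R", "S"):
            expected[idx] = label
        else:
            notes.append(
                f"center {index_to_name.get(idx, idx)} skipped: expected "
                f"stereo undefined"
            )
    if not expected:
        return ChiralityReport((), None, tuple(notes))

    # rebuild the hydrogenated molecule in the same atom order as the
    # topology, install model coordinates by name, and perceive 3D stereo
    molh = Chem.AddHs(mol)
    conf = Chem.Conformer(molh.GetNumAtoms())
    for atom in molh.GetAtoms():
        idx = atom.GetIdx()
        name = index_to_name.get(idx)
        pos = model.position(name) if name else None
        if pos is None:
            notes.append(f"model missing atom {name!r}; centers may be skipped")
            pos = np.zeros(3)
        conf.SetAtomPosition(idx, [float(v) for v in pos])
    molh.RemoveAllConformers()
    molh.AddConformer(conf, assignId=True)
    Chem.AssignStereochemistryFrom3D(molh)

    observed: dict[int, str] = {}
    for idx, label in Chem.FindMolChiralCenters(molh, includeUnassigned=True):
        observed[idx] = label

    centers = []
    agree_count = 0
    for idx in sorted(expected):
        exp = expected[idx]
        obs = observed.get(idx, "?")
        agree = exp == obs
        agree_count += agree
        centers.append((index_to_name.get(idx, str(idx)), exp, obs, agree))
    accuracy = agree_count / len(centers)
    return ChiralityReport(tuple(centers), accuracy, tuple(notes))
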