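"""Synthetic fixtures: toy molecule panels, a mini component library, and
ideal/perturbed coordinate sets.

Everything here is generated programmatically so the whole package builds
and tests offline. The mini component library is a small synthetic stand-in
for the public chemical-component dictionary export: records reuse familiar
component ids (GLY, ALA, ACY, ...) and CCD naming conventions, but are
built from SMILES with RDKit rather than copied from the dictionary.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, inchi

from ncres.geometry import CoordinateSet, GeometryError, dihedral

ALPHA_BACKBONE_MAP = {"N": "N", "C1": "CA", "Ccarb": "C", "O1": "O", "O2": "OXT"}


@dataclass(frozen=True)
class ToyMolecule:
    smiles: str
    label: str  # alpha | beta | gamma | rejected
    expected_flags: frozenset[str]
    note: str = ""

    @property
    def accepted(self) -> bool:
        return not self.expected_flags and self.label in ("alpha", "beta", "gamma")


def toy_molecule_set() -> list[ToyMolecule]:
    """Labelled SMILES panel with ground-truth classifications and flags.

    Labels and flags were fixed from independent hand analysis of each
    structure (bond-count shortest paths, substructure inspection), not from
    running the production classifier.
    """
    t = ToyMolecule
    f = frozenset
    return [
        # --- accepted residues ---
        t("NCC(=O)O", "alpha", f(), "glycine"),
        t("C[C@H](N)C(=O)O", "alpha", f(), "L-alanine"),
        t("C[C@@H](N)C(=O)O", "alpha", f(), "D-alanine"),
        t("NC(c1ccccc1)C(=O)O", "alpha", f(), "phenylglycine"),
        t("N[C@@H](CO)C(=O)O", "alpha", f(), "serine"),
        t("N[C@@H](CCCCN)C(=O)O", "alpha", f(), "lysine"),
        t("N[C@@H](CC(N)=O)C(=O)O", "alpha", f(), "asparagine: side-chain amide"),
        t("N[C@@H](CC(=O)O)C(=O)O", "alpha", f(), "aspartate: two acids allowed"),
        t("OC(=O)C1CCCN1", "alpha", f(), "proline: secondary amine"),
        t("NCC(=O)O.Cl", "alpha", f(), "glycine hydrochloride salt"),
        t("NCCC(=O)O", "beta", f(), "beta-alanine"),
        t("CC(N)CC(=O)O", "beta", f(), "3-aminobutanoic acid"),
        t("NCCCC(=O)O", "gamma", f(), "GABA"),
        # --- decoys ---
        t("NCCCCC(=O)O", "rejected", f({"delta_or_longer"}), "delta amino acid"),
        t("NCCCCCC(=O)O", "rejected", f({"delta_or_longer"}), "epsilon amino acid"),
        t("NCC(=O)NCC(=O)O", "rejected", f({"oligomer", "delta_or_longer"}),
          "Gly-Gly dipeptide"),
        t("CC(=O)NCC(=O)O", "rejected", f({"no_amine"}), "N-acetylglycine"),
        t("COC(=O)CN", "rejected", f({"no_carboxyl", "masked_acid"}),
          "glycine methyl ester"),
        t("O=[N+]([O-])c1ccc(C(=O)O)cc1", "rejected", f({"no_amine"}),
          "4-nitrobenzoic acid: nitro N excluded"),
        t("N#CCC(=O)O", "rejected", f({"no_amine"}), "cyanoacetic: nitrile N"),
        t("C[N+](C)(C)CC(=O)O", "rejected", f({"no_amine"}), "betaine: quaternary N"),
        # flagged molecules keep their backbone label but are not accepted
        t("NC(C[Li])C(=O)O", "alpha", f({"metal_or_coordination"}),
          "organolithium adduct"),
        t("NC(CC(=O)O)(CC(=O)O)C(=O)O", "alpha", f({"multi_acid_above_limit"}),
          "three free acids"),
        t("NC(Cc1c(I)c(I)c(I)c(I)c1I)C(=O)O", "alpha", f({"mw_above_threshold"}),
          "pentaiodophenylalanine: heavy halogens"),
        t("NC(C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F)C(=O)O", "alpha",
          f({"hetero_atom_count_above_threshold"}), "perfluoro chain"),
        t("CCO", "rejected", f({"no_carboxyl", "no_amine"}), "ethanol"),
    ]


# component_id -> (SMILES, optional heavy-atom names in SMILES atom order)
_LIBRARY_SPECS: list[tuple[str, str, str | None]] = [
    ("GLY", "NCC(=O)O", "N CA C O OXT"),
    ("ALA", "C[C@H](N)C(=O)O", "CB CA N C O OXT"),  # L-alanine (S at CA)
    ("LYS", "N[C@@H](CCCCN)C(=O)O", None),
    ("SER", "N[C@@H](CO)C(=O)O", None),
    ("PHE", "N[C@@H](Cc1ccccc1)C(=O)O", None),
    ("ASP", "N[C@@H](CC(=O)O)C(=O)O", None),
    ("BAL", "NCCC(=O)O", None),        # beta-alanine
    ("GAB", "NCCCC(=O)O", None),       # gamma-aminobutyric acid
    ("ACY", "CC(=O)O", None),          # acetic acid  \ protonation pair sharing
    ("ACT", "CC(=O)[O-]", None),       # acetate      / the connectivity layer
    ("BNZ", "c1ccccc1", None),         # decoy
    ("EOH", "CCO", None),              # decoy
]


def mini_component_library_text() -> str:
    """Deterministic SDF text of the synthetic 12-component mini library.

    Each record carries component_id, three_letter_code and a precomputed
    stored InChIKey; the two residue records used for naming comparisons
    additionally carry CCD-convention atom names.
    """
    sio = io.StringIO()
    writer = Chem.SDWriter(sio)
    try:
        for comp_id, smiles, atom_names in _LIBRARY_SPECS:
            mol = Chem.MolFromSmiles(smiles)
            AllChem.Compute2DCoords(mol)
            mol.SetProp("_Name", comp_id)
            mol.SetProp("component_id", comp_id)
            mol.SetProp("three_letter_code", comp_id)
            mol.SetProp("InChIKey", inchi.MolToInchiKey(mol))
            if atom_names:
                mol.SetProp("atom_names", atom_names)
            writer.write(mol)
    finally:
        writer.close()
    return sio.getvalue()


def mini_component_library(out_path) -> Path:
    """Materialize the synthetic mini library SDF at ``out_path`` (gzipped
    when the suffix is .gz). Bytes are deterministic."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    text = mini_component_library_text()
    if out_path.suffix == ".gz":
        import gzip

        with gzip.open(out_path, "wb") as fh:
            fh.write(text.encode())
    else:
        out_path.write_text(text)
    return out_path


def library_component_ids() -> list[str]:
    return [c for c, _s, _n in _LIBRARY_SPECS]


@dataclass(frozen=True)
class IdealGeometrySpec:
    """Internal coordinates of an idealized alpha-residue backbone.

    Defaults place the carboxyl-adjacent bond lengths and angles at the
    reference means (Cα–C 1.525 Å, C–O 1.231 Å, ∠Cα–C–O 120.8°); the N–Cα
    bond and the carboxyl O–C–O angle are free choices inside their bands
    (O–C–O defaults to the planar value 360° − 2·120.8° = 118.4°).
    """

    d_n_c1: float = 1.46
    d_ck_ccarb: float = 1.525
    d_ccarb_o1: float = 1.231
    d_ccarb_o2: float = 1.231
    ang_ck_ccarb_o1: float = 120.8
    ang_ck_ccarb_o2: float = 120.8
    ang_o1_ccarb_o2: float | None = None  # None -> planar sp2 value
    ang_n_c1_ccarb: float = 110.0

    @property
    def oco_angle(self) -> float:
        if self.ang_o1_ccarb_o2 is not None:
            return self.ang_o1_ccarb_o2
        return 360.0 - self.ang_ck_ccarb_o1 - self.ang_ck_ccarb_o2


def ideal_alpha_coordinates(
    spec: IdealGeometrySpec = IdealGeometrySpec(),
    perturb: float | None = None,
    seed: int = 0,
) -> CoordinateSet:
    """Backbone coordinates (N, CA, C, O, OXT) realizing ``spec`` exactly.

    With ``perturb`` set, i.i.d. Gaussian coordinate noise of that σ (Å) is
    added using the given seed. Raises :class:`GeometryError` when the three
    carboxyl angles are not simultaneously realizable.
    """
    a1 = math.radians(spec.ang_ck_ccarb_o1)
    a2 = math.radians(spec.ang_ck_ccarb_o2)
    theta = math.radians(spec.oco_angle)

    c = np.zeros(3)
    ca = np.array([spec.d_ck_ccarb, 0.0, 0.0])
    o1 = spec.d_ccarb_o1 * np.array([math.cos(a1), math.sin(a1), 0.0])
    # azimuth of O2 about the C->CA axis so that angle(O1, C, O2) = theta
    cos_phi_num = math.cos(theta) - math.cos(a1) * math.cos(a2)
    cos_phi_den = math.sin(a1) * math.sin(a2)
    cos_phi = cos_phi_num / cos_phi_den
    if abs(cos_phi) > 1.0 + 1e-9:
        raise GeometryError(
            f"carboxyl angles infeasible: cos(azimuth) = {cos_phi:.6f}"
        )
    cos_phi = max(-1.0, min(1.0, cos_phi))
    sin_phi = math.sqrt(max(0.0, 1.0 - cos_phi * cos_phi))
    o2 = spec.d_ccarb_o2 * np.array(
        [math.cos(a2), math.sin(a2) * cos_phi, math.sin(a2) * sin_phi]
    )
    # N in the xy-plane at the chosen N-CA-C angle
    an = math.radians(180.0 - spec.ang_n_c1_ccarb)
    n = ca + spec.d_n_c1 * np.array([math.cos(an), math.sin(an), 0.0])

    coords = {"N": n, "CA": ca, "C": c, "O": o1, "OXT": o2}
    _verify_ideal(coords, spec)
    if perturb is not None:
        rng = np.random.default_rng(seed)
        coords = {k: v + rng.normal(0.0, perturb, 3) for k, v in coords.items()}
    atoms = tuple(
        (name, name[0], tuple(float(x) for x in coords[name]))
        for name in ("N", "CA", "C", "O", "OXT")
    )
    return CoordinateSet(atoms)


def _verify_ideal(coords: dict, spec: IdealGeometrySpec, tol: float = 1e-6) -> None:
    def d(a, b):
        return float(np.linalg.norm(coords[a] - coords[b]))

    def ang(a, b, c_):
        v1, v2 = coords[a] - coords[b], coords[c_] - coords[b]
        cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))

    checks = [
        (d("N", "CA"), spec.d_n_c1),
        (d("CA", "C"), spec.d_ck_ccarb),
        (d("C", "O"), spec.d_ccarb_o1),
        (d("C", "OXT"), spec.d_ccarb_o2),
        (ang("CA", "C", "O"), spec.ang_ck_ccarb_o1),
        (ang("CA", "C", "OXT"), spec.ang_ck_ccarb_o2),
        (ang("O", "C", "OXT"), spec.oco_angle),
        (ang("N", "CA", "C"), spec.ang_n_c1_ccarb),
    ]
    for got, want in checks:
        if abs(got - want) > tol:
            raise GeometryError(
                f"ideal geometry infeasible: wanted {want}, realized {got}"
            )


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D so that |CD| = bond, ∠(B,C,D) = angle and the torsion
    A-B-C-D equals ``torsion_deg`` (natural-extension / NeRF construction)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    # v spans the half-plane containing A: torsion 0 (cis) puts D on A's side
    v = ab - np.dot(ab, bc) * bc
    v /= np.linalg.norm(v)
    w = np.cross(bc, v)
    for phi_try in (phi, -phi):
        d = c + bond * (
            -math.cos(theta) * bc
            + math.sin(theta) * (math.cos(phi_try) * v + math.sin(phi_try) * w)
        )
        if abs(_wrap(dihedral(a, b, c, d) - torsion_deg)) < 1e-6:
            return d
    raise GeometryError("torsion construction failed")  # pragma: no cover


def _wrap(delta: float) -> float:
    while delta > 180.0:
        delta -= 360.0
    while delta <= -180.0:
        delta += 360.0
    return delta


def peptide_with_omegas(omega_prev: float, omega_next: float):
    """Three-residue synthetic peptide whose central residue realizes the
    requested ω_prev and ω_next torsions (other torsions arbitrary).

    Returns a :class:`~ncres.geometry.PeptideStructure`; the central residue
    has index 1.
    """
    from ncres.geometry import PeptideStructure

    ca1 = np.array([0.0, 0.0, 0.0])
    c1 = np.array([1.52, 0.0, 0.0])
    n2 = c1 + 1.33 * np.array(
        [math.cos(math.radians(180 - 116)), math.sin(math.radians(180 - 116)), 0.0]
    )
    ca2 = place_atom(ca1, c1, n2, 1.46, 121.0, omega_prev)
    c2 = place_atom(c1, n2, ca2, 1.52, 110.0, -60.0)
    n3 = place_atom(n2, ca2, c2, 1.33, 116.0, -45.0)
    ca3 = place_atom(ca2, c2, n3, 1.46, 121.0, omega_next)
    return PeptideStructure([
        {"CA": ca1, "C": c1},
        {"N": n2, "CA": ca2, "C": c2},
        {"N": n3, "CA": ca3},
    ])
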