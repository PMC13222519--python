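"""Geometric validation: reference bands, omega banding, RMSD, chirality."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ncres.ccd import standard_inchikey
from ncres.export import ResidueDefinition
from ncres.fixtures import (
    ALPHA_BACKBONE_MAP,
    IdealGeometrySpec,
    ideal_alpha_coordinates,
    peptide_with_omegas,
)
from ncres.geometry import (
    GEOMETRY_BANDS,
    REFERENCE_STATS,
    CoordinateSet,
    GeometryError,
    PeptideStructure,
    categorize_omegas,
    chirality_agreement,
    classify_omega,
    geometry_metrics,
    reference_band,
    rmsd,
)
from ncres.topology import build_residue_topology


def test_reference_bands_reconstruct_from_mean_sigma():
    for metric, (mean, sigma) in REFERENCE_STATS.items():
        lo, hi = reference_band(mean, sigma, 4.0)
        want_lo, want_hi = GEOMETRY_BANDS[metric]
        assert lo == pytest.approx(want_lo, abs=1e-9)
        assert hi == pytest.approx(want_hi, abs=1e-9)


def test_ideal_alpha_fixture_passes_all_five():
    report = geometry_metrics(ideal_alpha_coordinates(), ALPHA_BACKBONE_MAP)
    assert report.all_pass
    assert sum(report.in_range.values()) == 5
    assert report.values["d_Ck_Ccarb"] == pytest.approx(1.525, abs=1e-9)
    assert report.values["ang_Ck_Ccarb_O_mean"] == pytest.approx(120.8, abs=1e-9)


def test_short_n_c1_bond_fails_its_flag():
    coords = ideal_alpha_coordinates(IdealGeometrySpec(d_n_c1=1.30))
    report = geometry_metrics(coords, ALPHA_BACKBONE_MAP)
    assert not report.in_range["d_N_C1"]
    assert not report.all_pass
    others = {m: ok for m, ok in report.in_range.items() if m != "d_N_C1"}
    assert all(others.values())


def test_carboxyl_angle_mean_is_arithmetic():
    coords = ideal_alpha_coordinates(
        IdealGeometrySpec(ang_ck_ccarb_o1=118.0, ang_ck_ccarb_o2=123.0)
    )
    report = geometry_metrics(coords, ALPHA_BACKBONE_MAP)
    assert report.values["ang_Ck_Ccarb_O_mean"] == pytest.approx(120.5, abs=1e-9)
    assert report.in_range["ang_Ck_Ccarb_O_mean"]


def test_missing_role_atom_marks_metric_missing():
    coords = ideal_alpha_coordinates()
    bad_map = {**ALPHA_BACKBONE_MAP, "N": "NX"}
    report = geometry_metrics(coords, bad_map)
    assert report.values["d_N_C1"] is None
    assert not report.in_range["d_N_C1"]
    assert not report.all_pass


def test_perturbed_fixture_breaks_geometry():
    coords = ideal_alpha_coordinates(perturb=0.5, seed=7)
    report = geometry_metrics(coords, ALPHA_BACKBONE_MAP)
    assert not report.all_pass


def test_metrics_invariant_under_rigid_motion():
    coords = ideal_alpha_coordinates()
    base = geometry_metrics(coords, ALPHA_BACKBONE_MAP)
    rot = Rotation.from_euler("xyz", [31.0, -59.0, 123.0], degrees=True).as_matrix()
    moved = coords.transformed(rot, np.array([5.0, -3.0, 11.0]))
    report = geometry_metrics(moved, ALPHA_BACKBONE_MAP)
    for metric in GEOMETRY_BANDS:
        assert report.values[metric] == pytest.approx(
            base.values[metric], abs=1e-6
        )


@pytest.mark.parametrize(
    "omegas,category",
    [
        ((179.2, -178.0), "good"),
        ((0.0, 10.0), "good"),        # cis is geometrically well-formed
        ((30.0, 150.0), "good"),      # band endpoints belong to good
        ((140.0, 165.0), "borderline"),
        ((120.0, -178.0), "borderline"),
        ((90.0, 179.0), "bad"),
        ((31.0, 119.0), "bad"),
    ],
)
def test_omega_banding_examples(omegas, category):
    ps = peptide_with_omegas(*omegas)
    report = classify_omega(ps, 1)
    assert report.omega_prev == pytest.approx(omegas[0], abs=1e-6)
    assert report.omega_next == pytest.approx(omegas[1], abs=1e-6)
    assert report.category == category


def test_missing_omega_is_bad():
    ps = peptide_with_omegas(179.0, 179.0)
    del ps.residues[2]["CA"]  # omega_next loses an atom
    report = classify_omega(ps, 1)
    assert report.omega_next is None
    assert report.category == "bad"
    assert categorize_omegas(170.0, None) == "bad"


def test_omega_banding_matches_brute_force_grid():
    def oracle(mag):
        if mag <= 30.0 or mag >= 150.0:
            return "good"
        if 120.0 <= mag < 150.0:
            return "borderline"
        return "bad"

    for deg in range(0, 181):
        mag = float(deg)
        for signed in (mag, -mag):
            assert categorize_omegas(signed, signed) == oracle(mag), deg


def test_omega_invariant_under_rigid_motion():
    ps = peptide_with_omegas(140.0, 165.0)
    rot = Rotation.from_euler("zyx", [17.0, 77.0, -41.0], degrees=True).as_matrix()
    shift = np.array([-4.0, 9.0, 2.0])
    moved = PeptideStructure(
        [{k: rot @ v + shift for k, v in res.items()} for res in ps.residues]
    )
    a, b = classify_omega(ps, 1), classify_omega(moved, 1)
    assert b.omega_prev == pytest.approx(a.omega_prev, abs=1e-6)
    assert b.omega_next == pytest.approx(a.omega_next, abs=1e-6)
    assert b.category == a.category


def test_rmsd_identity_translation_and_toy_case():
    coords = ideal_alpha_coordinates()
    assert rmsd(coords, coords, superpose=False).value == 0.0
    assert rmsd(coords, coords, superpose=True).value == pytest.approx(0.0, abs=1e-9)

    shifted = coords.transformed(np.eye(3), np.array([1.0, 0.0, 0.0]))
    assert rmsd(coords, shifted, superpose=False).value == pytest.approx(1.0)

    native = CoordinateSet((("A1", "C", (0.0, 0.0, 0.0)), ("A2", "C", (1.0, 0.0, 0.0))))
    model = CoordinateSet((("A1", "C", (0.0, 0.0, 0.0)), ("A2", "C", (2.0, 0.0, 0.0))))
    assert rmsd(native, model, superpose=False).value == pytest.approx(
        math.sqrt(0.5)
    )


def test_superposed_rmsd_bounded_by_raw():
    rng = np.random.default_rng(11)
    coords = ideal_alpha_coordinates()
    for trial in range(5):
        rot = Rotation.random(random_state=trial).as_matrix()
        noisy_atoms = tuple(
            (n, el, tuple(rot @ np.asarray(xyz) + rng.normal(0, 0.3, 3) + [2, 1, 0]))
            for n, el, xyz in coords.atoms
        )
        model = CoordinateSet(noisy_atoms)
        sup = rmsd(coords, model, superpose=True).value
        raw = rmsd(coords, model, superpose=False).value
        assert sup <= raw + 1e-9


def test_rmsd_selections(toy_panel):
    topo = build_residue_topology("N[C@@H](CO)C(=O)O", seed=42)
    cs = CoordinateSet.from_topology(topo)
    all_atoms = rmsd(cs, cs, selection="all")
    backbone = rmsd(cs, cs, selection="backbone")
    calpha = rmsd(cs, cs, selection="calpha")
    assert all_atoms.n_atoms > backbone.n_atoms > calpha.n_atoms == 1


def test_rmsd_empty_correspondence_raises():
    a = CoordinateSet((("A1", "C", (0.0, 0.0, 0.0)),))
    b = CoordinateSet((("B1", "C", (0.0, 0.0, 0.0)),))
    with pytest.raises(GeometryError, match="A1|B1"):
        rmsd(a, b)


def _definition(smiles, code="ZCA"):
    topo = build_residue_topology(smiles, seed=42)
    return ResidueDefinition(
        code, topo,
        {"source_smiles": smiles, "inchikey": standard_inchikey(smiles),
         "seed": 42, "optimize": True, "template_id": None},
    )


def test_chirality_self_agreement():
    defn = _definition("C[C@H](N)C(=O)O")
    model = CoordinateSet.from_topology(defn.topology)
    report = chirality_agreement(defn, model)
    assert report.accuracy == 1.0
    assert len(report.centers) == 1
    assert report.centers[0][0] == "CA"


def test_chirality_mirror_flips_all_centers():
    defn = _definition("C[C@@H](O)[C@@H](N)C(=O)O")  # two stereocentres
    model = CoordinateSet.from_topology(defn.topology)
    assert chirality_agreement(defn, model).accuracy == 1.0
    mirror = CoordinateSet(
        tuple((n, el, (-x, y, z)) for n, el, (x, y, z) in model.atoms)
    )
    assert chirality_agreement(defn, mirror).accuracy == 0.0


def test_chirality_single_center_inversion_scores_half():
    defn = _definition("C[C@@H](O)[C@@H](N)C(=O)O")
    model = CoordinateSet.from_topology(defn.topology)
    report = chirality_agreement(defn, model)
    assert len(report.centers) == 2
    # invert the CB centre by swapping two of its substituent positions
    swap_a, swap_b = "OG", "HB"
    pos = {n: xyz for n, _el, xyz in model.atoms}
    assert swap_a in pos and swap_b in pos
    swapped = CoordinateSet(tuple(
        (n, el, pos[swap_b] if n == swap_a else pos[swap_a] if n == swap_b else xyz)
        for n, el, xyz in model.atoms
    ))
    report = chirality_agreement(defn, swapped)
    assert report.accuracy == 0.5


def test_achiral_reports_na():
    defn = _definition("NCC(=O)O")
    model = CoordinateSet.from_topology(defn.topology)
    report = chirality_agreement(defn, model)
    assert report.accuracy is None
    assert report.centers == ()
    assert report.effective_accuracy == 1.0


def test_peptide_structure_from_pdb(tmp_path):
    pdb = tmp_path / "two_res.pdb"
    lines = []
    ps = peptide_with_omegas(175.0, -170.0)
    serial = 1
    for i, res in enumerate(ps.residues, start=1):
        for name, xyz in res.items():
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} GLY A{i:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {name[0]:>2s}"
            )
            serial += 1
    pdb.write_text("\n".join(lines) + "\nEND\n")
    loaded = PeptideStructure.from_file(pdb)
    assert len(loaded) == 3
    report = classify_omega(loaded, 1)
    assert report.category == "good"
    assert report.omega_prev == pytest.approx(175.0, abs=1e-2)
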