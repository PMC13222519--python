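"""Component-ID assignment, residue CSV dialect and AF3-style job specs."""

import json

import pytest

from ncres.ccd import standard_inchikey
from ncres.export import (
    ExportError,
    JobValidationError,
    ResidueDefinition,
    assign_component_id,
    build_af3_json,
    build_ggxgg_json,
    load_standard_codes,
    read_residue_csv,
    validate_af3_job,
    write_residue_csv,
)
from ncres.topology import ResidueTopology, build_residue_topology


def _definition(smiles="NCC(=O)O", code="ZCA", **extra):
    topo = build_residue_topology(smiles, seed=42)
    meta = {
        "source_smiles": smiles,
        "inchikey": standard_inchikey(smiles),
        "seed": 42,
        "optimize": True,
        "template_id": None,
        **extra,
    }
    return ResidueDefinition(code, topo, meta)


def test_component_id_sequence():
    assert assign_component_id(set()) == "ZCA"
    assert assign_component_id({"ZCA"}) == "ZCB"
    prior = {f"ZC{c}" for c in "ABCDEFGHIJKLMNO"}  # 15 prior assignments
    assert assign_component_id(prior) == "ZCP"


def test_component_id_rolls_to_next_letter_block():
    prior = {f"ZC{c}" for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"}
    assert assign_component_id(prior) == "ZDA"


def test_component_ids_injective_and_collision_free():
    codes = load_standard_codes()
    session: set[str] = set()
    for _ in range(60):
        new = assign_component_id(session)
        assert new not in session
        assert new not in codes
        session.add(new)


def test_invalid_component_id_rejected():
    with pytest.raises(ExportError):
        _definition(code="zca")
    with pytest.raises(ExportError):
        _definition(code="ZCAA")


def test_csv_round_trip_identity(tmp_path):
    for smiles in ("NCC(=O)O", "C[C@H](N)C(=O)O", "NCCC(=O)O", "NCCCC(=O)O"):
        defn = _definition(smiles)
        path = tmp_path / f"{defn.component_id}_{smiles.count('C')}.csv"
        write_residue_csv(defn, path)
        assert read_residue_csv(path) == defn


def test_csv_byte_deterministic(tmp_path):
    defn = _definition()
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_residue_csv(defn, p1)
    write_residue_csv(defn, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_glycine_csv_row_counts(tmp_path):
    defn = _definition("NCC(=O)O")
    path = tmp_path / "gly.csv"
    write_residue_csv(defn, path)
    lines = path.read_text().splitlines()
    atoms_at = lines.index("[atoms]")
    bonds_at = lines.index("[bonds]")
    atom_rows = lines[atoms_at + 2 : bonds_at]
    bond_rows = lines[bonds_at + 2 :]
    assert len(atom_rows) == 10
    assert len(bond_rows) == 9
    # leaving atoms: OXT, HXT and one amine hydrogen
    leaving = {r.split(",")[1] for r in atom_rows if r.endswith("true")}
    assert leaving == {"OXT", "HXT", "H2"}


def test_duplicate_atom_name_refused(tmp_path):
    defn = _definition()
    atoms = list(defn.topology.atoms)
    atoms[1] = atoms[1].__class__(**{**atoms[1].__dict__, "name": atoms[0].name})
    bad_topo = ResidueTopology(
        defn.topology.residue_class, tuple(atoms), defn.topology.bonds,
        defn.topology.backbone_map, defn.topology.metadata,
    )
    bad = ResidueDefinition("ZCB", bad_topo, defn.metadata)
    with pytest.raises(ExportError, match="duplicate"):
        write_residue_csv(bad, tmp_path / "bad.csv")


def test_missing_section_reported(tmp_path):
    defn = _definition()
    path = tmp_path / "gly.csv"
    write_residue_csv(defn, path)
    text = path.read_text()
    truncated = text[: text.index("[bonds]")]
    broken = tmp_path / "broken.csv"
    broken.write_text(truncated)
    with pytest.raises(ExportError, match="bonds"):
        read_residue_csv(broken)


def test_unknown_bond_atom_reported_with_row(tmp_path):
    defn = _definition()
    path = tmp_path / "gly.csv"
    write_residue_csv(defn, path)
    lines = path.read_text().splitlines()
    last_bond_row = len(lines)
    lines.append("NOPE,CA,single,false")
    bad = tmp_path / "badbond.csv"
    bad.write_text("\n".join(lines) + "\n")
    with pytest.raises(ExportError, match=str(last_bond_row + 1)):
        read_residue_csv(bad)


def test_ggxgg_job(tmp_path):
    defn = _definition()
    job_path = build_ggxgg_json(defn, tmp_path / "job")
    job = json.loads(job_path.read_text())
    protein = job["sequences"][0]["protein"]
    assert protein["sequence"] == "GGXGG"
    assert protein["modifications"] == [{"ptmPosition": 3, "ptmType": "ZCA"}]
    assert job["customComponents"]["files"] == ["components/ZCA.csv"]
    assert validate_af3_job(job_path)


def test_job_with_two_custom_residues(tmp_path):
    zca = _definition("NCC(=O)O", "ZCA")
    zcb = _definition("NCCC(=O)O", "ZCB")
    job_path = build_af3_json(
        chains=["GXGGX"],
        modifications=[[(2, "ZCA"), (5, "ZCB")]],
        definitions={"ZCA": zca, "ZCB": zcb},
        out_dir=tmp_path / "job2",
    )
    job = json.loads(job_path.read_text())
    assert sorted(job["customComponents"]["files"]) == [
        "components/ZCA.csv", "components/ZCB.csv",
    ]
    assert validate_af3_job(job_path)


def test_directory_reference_mode(tmp_path):
    defn = _definition()
    job_path = build_af3_json(
        ["GGXGG"], [[(3, "ZCA")]], {"ZCA": defn}, tmp_path / "jobdir",
        as_directory=True,
    )
    job = json.loads(job_path.read_text())
    assert job["customComponents"] == {"directory": "components"}
    assert validate_af3_job(job_path)


def test_standard_code_modification_needs_no_component(tmp_path):
    job_path = build_af3_json(
        ["GGGGG"], [[(2, "SEP")]], {}, tmp_path / "jobsep",
    )
    assert validate_af3_job(job_path)


def test_undefined_component_rejected(tmp_path):
    with pytest.raises(JobValidationError, match="ZZZ"):
        build_af3_json(["GGXGG"], [[(3, "ZZZ")]], {}, tmp_path / "bad")


def test_position_out_of_range_rejected(tmp_path):
    defn = _definition()
    with pytest.raises(JobValidationError, match="position"):
        build_af3_json(["GGXGG"], [[(9, "ZCA")]], {"ZCA": defn}, tmp_path / "bad2")


def test_tampered_job_fails_validation(tmp_path):
    defn = _definition()
    job_path = build_ggxgg_json(defn, tmp_path / "job3")
    job = json.loads(job_path.read_text())
    job["sequences"][0]["protein"]["modifications"][0]["ptmType"] = "ZZZ"
    job_path.write_text(json.dumps(job))
    with pytest.raises(JobValidationError):
        validate_af3_job(job_path)
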