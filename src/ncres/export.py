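"""Component-ID assignment and CSV/JSON export of residue definitions.

A :class:`ResidueDefinition` bundles a three-letter component ID with a named
residue topology and provenance metadata. Definitions are serialized to a
three-section CSV (metadata, atoms, bonds) and referenced from an
AlphaFold3-style JSON job specification in which modified sequence positions
point at custom component IDs.
"""

from __future__ import annotations

import csv
import io
import json
import re
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from ncres.topology import (
    BondRecord,
    NamedAtom,
    ResidueTopology,
    TopologyError,
    validate_topology,
)

COMPONENT_ID_RE = re.compile(r"^[A-Z0-9]{3}$")
CSV_SECTIONS = ("metadata", "atoms", "bonds")
ATOM_COLUMNS = (
    "index", "name", "element", "charge", "x", "y", "z",
    "is_backbone", "parent_heavy", "leaving",
)
BOND_COLUMNS = ("atom1", "atom2", "order", "aromatic")


class ExportError(ValueError):
    """Raised when a definition violates an invariant or a file is malformed."""


def load_standard_codes() -> frozenset[str]:
    """Packaged list of standard three-letter codes used for collision checks
    (the 20 canonical residues plus common modified residues; a curated
    subset, not the full dictionary)."""
    text = resources.files("ncres").joinpath("data/standard_codes.txt").read_text()
    return frozenset(
        line.strip().upper()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class ResidueDefinition:
    component_id: str
    topology: ResidueTopology
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not COMPONENT_ID_RE.match(self.component_id):
            raise ExportError(
                f"component_id must be 3 uppercase alphanumerics, got "
                f"{self.component_id!r}"
            )

    def leaving_atoms(self) -> frozenset[str]:
        """Atoms departing on peptide-bond formation: the OXT-role oxygen,
        its hydrogen, and one amine hydrogen on the backbone nitrogen
        (polymer conventions)."""
        topo = self.topology
        leaving = set()
        oxt = topo.backbone_map.get("O2")
        n_name = topo.backbone_map.get("N")
        if oxt:
            leaving.add(oxt)
            leaving.update(
                a.name for a in topo.atoms
                if a.element == "H" and a.parent_heavy == oxt
            )
        n_hs = sorted(
            a.name for a in topo.atoms
            if a.element == "H" and a.parent_heavy == n_name
        )
        if n_hs:
            leaving.add(n_hs[-1])  # highest-numbered amine hydrogen
        return frozenset(leaving)


def assign_component_id(existing: set[str] | frozenset[str] | None = None) -> str:
    """First unused code in the sequence ZCA, ZCB, ... ZCZ, ZDA, ...

    Codes present in the packaged standard-code list or in ``existing`` are
    skipped, so assignment is injective within a session and never collides
    with a standard residue code.
    """
    taken = {c.upper() for c in (existing or set())} | load_standard_codes()
    for second in string.ascii_uppercase[string.ascii_uppercase.index("C"):]:
        for third in string.ascii_uppercase:
            code = f"Z{second}{third}"
            if code not in taken:
                return code
    raise ExportError("component-ID sequence exhausted")


def _fmt(value: float) -> str:
    return repr(float(value))


def write_residue_csv(defn: ResidueDefinition, path) -> None:
    """Write a residue definition as a three-section CSV.

    Sections are ``[metadata]`` (key,value rows with JSON-encoded values),
    ``[atoms]`` and ``[bonds]``. UTF-8, RFC-4180 quoting, byte-deterministic
    for a fixed definition. Refuses to write a definition whose topology
    violates an invariant.
    """
    try:
        validate_topology(defn.topology)
    except TopologyError as exc:
        raise ExportError(f"refusing to write invalid definition: {exc}") from exc

    leaving = defn.leaving_atoms()
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n", quoting=csv.QUOTE_MINIMAL)

    buf.write("[metadata]\n")
    w.writerow(["key", "value"])
    meta = {
        "component_id": defn.component_id,
        "residue_class": defn.topology.residue_class,
        "backbone_map": defn.topology.backbone_map,
        "topology_metadata": defn.topology.metadata,
        **defn.metadata,
    }
    for key in meta:
        w.writerow([key, json.dumps(meta[key], sort_keys=True)])

    buf.write("[atoms]\n")
    w.writerow(ATOM_COLUMNS)
    for a in defn.topology.atoms:
        w.writerow([
            a.index, a.name, a.element, a.formal_charge,
            _fmt(a.xyz[0]), _fmt(a.xyz[1]), _fmt(a.xyz[2]),
            str(a.is_backbone).lower(),
            a.parent_heavy or "",
            str(a.name in leaving).lower(),
        ])

    buf.write("[bonds]\n")
    w.writerow(BOND_COLUMNS)
    for b in defn.topology.bonds:
        w.writerow([b.atom1_name, b.atom2_name, b.order, str(b.aromatic).lower()])

    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_residue_csv(path) -> ResidueDefinition:
    """Read back a three-section residue CSV, reconstructing the definition.

    Schema violations are reported with the offending row number; a missing
    section raises an error naming it.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    sections: dict[str, list[tuple[int, list[str]]]] = {}
    current = None
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            if current not in CSV_SECTIONS:
                raise ExportError(f"row {lineno}: unknown section {current!r}")
            sections[current] = []
            continue
        if current is None:
            raise ExportError(f"row {lineno}: content before any section header")
        if line.strip():
            row = next(csv.reader([line]))
            sections[current].append((lineno, row))

    for sec in CSV_SECTIONS:
        if sec not in sections:
            raise ExportError(f"missing section: {sec}")

    meta: dict = {}
    for lineno, row in sections["metadata"][1:]:  # skip header
        if len(row) != 2:
            raise ExportError(f"row {lineno}: metadata rows need key,value")
        try:
            meta[row[0]] = json.loads(row[1])
        except json.JSONDecodeError as exc:
            raise ExportError(f"row {lineno}: bad metadata value ({exc})") from exc
    for req in ("component_id", "residue_class", "backbone_map"):
        if req not in meta:
            raise ExportError(f"metadata missing required key {req!r}")

    header_row = sections["atoms"][0][1]
    if tuple(header_row) != ATOM_COLUMNS:
        raise ExportError(
            f"row {sections['atoms'][0][0]}: unknown atom columns {header_row}"
        )
    atoms = []
    names = set()
    for lineno, row in sections["atoms"][1:]:
        if len(row) != len(ATOM_COLUMNS):
            raise ExportError(f"row {lineno}: atom row has {len(row)} fields")
        try:
            atoms.append(NamedAtom(
                index=int(row[0]),
                name=row[1],
                element=row[2],
                formal_charge=int(row[3]),
                xyz=(float(row[4]), float(row[5]), float(row[6])),
                is_backbone=row[7] == "true",
                parent_heavy=row[8] or None,
            ))
        except ValueError as exc:
            raise ExportError(f"row {lineno}: bad atom field ({exc})") from exc
        names.add(row[1])

    header_row = sections["bonds"][0][1]
    if tuple(header_row) != BOND_COLUMNS:
        raise ExportError(
            f"row {sections['bonds'][0][0]}: unknown bond columns {header_row}"
        )
    bonds = []
    for lineno, row in sections["bonds"][1:]:
        if len(row) != len(BOND_COLUMNS):
            raise ExportError(f"row {lineno}: bond row has {len(row)} fields")
        if row[0] not in names or row[1] not in names:
            raise ExportError(f"row {lineno}: bond references unknown atom name")
        bonds.append(BondRecord(row[0], row[1], row[2], row[3] == "true"))

    extra_meta = {
        k: v for k, v in meta.items()
        if k not in ("component_id", "residue_class", "backbone_map",
                     "topology_metadata")
    }
    topo = ResidueTopology(
        residue_class=meta["residue_class"],
        atoms=tuple(atoms),
        bonds=tuple(bonds),
        backbone_map=dict(meta["backbone_map"]),
        metadata=dict(meta.get("topology_metadata") or {}),
    )
    validate_topology(topo)
    return ResidueDefinition(meta["component_id"], topo, extra_meta)


# ---------------------------------------------------------------------------
# AlphaFold3-style JSON job specification
# ---------------------------------------------------------------------------

JOB_DIALECT = "ncres-af3"
JOB_VERSION = 1


class JobValidationError(ExportError):
    """A job specification fails schema or referential validity."""


def build_af3_json(
    chains: list[str],
    modifications: list[list[tuple[int, str]]],
    definitions: dict[str, ResidueDefinition],
    out_dir,
    name: str = "ncres_job",
    model_seeds: tuple[int, ...] = (1,),
    as_directory: bool = False,
) -> Path:
    """Write a JSON job spec plus one component CSV per custom residue.

    ``chains`` are one-letter sequences (``X`` is allowed as a placeholder at
    modified positions); ``modifications[c]`` lists (1-based position,
    component_id) entries for chain ``c``. Custom components are written
    under ``out_dir/components/`` and referenced either per file or as a
    folder (``as_directory=True``). Returns the job-file path.
    """
    out_dir = Path(out_dir)
    comp_dir = out_dir / "components"
    comp_dir.mkdir(parents=True, exist_ok=True)
    standard = load_standard_codes()

    referenced: list[str] = []
    sequences = []
    chain_ids = [string.ascii_uppercase[i % 26] for i in range(len(chains))]
    if len(modifications) != len(chains):
        raise JobValidationError("modifications must list one entry per chain")
    for chain, mods, cid in zip(chains, modifications, chain_ids):
        entries = []
        for pos, code in mods:
            if not 1 <= pos <= len(chain):
                raise JobValidationError(
                    f"modification position {pos} outside chain of length "
                    f"{len(chain)}"
                )
            if code not in standard:
                if code not in definitions:
                    raise JobValidationError(
                        f"unresolved component_id {code!r}"
                    )
                if code not in referenced:
                    referenced.append(code)
            entries.append({"ptmPosition": pos, "ptmType": code})
        protein = {"id": cid, "sequence": chain}
        if entries:
            protein["modifications"] = entries
        sequences.append({"protein": protein})

    for code in referenced:
        write_residue_csv(definitions[code], comp_dir / f"{code}.csv")

    if as_directory:
        custom = {"directory": "components"}
    else:
        custom = {"files": [f"components/{code}.csv" for code in referenced]}

    job = {
        "dialect": JOB_DIALECT,
        "version": JOB_VERSION,
        "name": name,
        "modelSeeds": list(model_seeds),
        "sequences": sequences,
        "customComponents": custom,
    }
    job_path = out_dir / f"{name}.json"
    job_path.write_text(json.dumps(job, indent=2, sort_keys=True) + "\n")
    validate_af3_job(job_path)
    return job_path


def build_ggxgg_json(defn: ResidueDefinition, out_dir, name: str = "ggxgg") -> Path:
    """Emit the five-residue GGXGG probe job with the custom residue at
    position 3, flanked by glycines."""
    return build_af3_json(
        chains=["GGXGG"],
        modifications=[[(3, defn.component_id)]],
        definitions={defn.component_id: defn},
        out_dir=out_dir,
        name=name,
    )


def validate_af3_job(job_path) -> dict:
    """Validate a job file against the shipped schema and check referential
    integrity (every custom component resolves to a readable CSV whose
    component_id matches; modification positions are in range).

    Returns the parsed job on success; raises :class:`JobValidationError`.
    """
    job_path = Path(job_path)
    base = job_path.parent
    try:
        job = json.loads(job_path.read_text())
    except json.JSONDecodeError as exc:
        raise JobValidationError(f"job file is not valid JSON: {exc}") from exc

    for field_name, typ in (
        ("dialect", str), ("version", int), ("name", str),
        ("modelSeeds", list), ("sequences", list), ("customComponents", dict),
    ):
        if field_name not in job:
            raise JobValidationError(f"missing field {field_name!r}")
        if not isinstance(job[field_name], typ):
            raise JobValidationError(f"field {field_name!r} has wrong type")
    if not all(isinstance(s, int) for s in job["modelSeeds"]):
        raise JobValidationError("modelSeeds must be integers")

    custom = job["customComponents"]
    available: dict[str, ResidueDefinition] = {}
    if "directory" in custom:
        comp_dir = base / custom["directory"]
        if not comp_dir.is_dir():
            raise JobValidationError(f"component directory missing: {comp_dir}")
        paths = sorted(comp_dir.glob("*.csv"))
    elif "files" in custom:
        paths = [base / f for f in custom["files"]]
    else:
        raise JobValidationError("customComponents needs 'files' or 'directory'")
    for p in paths:
        if not p.is_file():
            raise JobValidationError(f"referenced component file missing: {p}")
        defn = read_residue_csv(p)
        available[defn.component_id] = defn

    standard = load_standard_codes()
    for entry in job["sequences"]:
        if "protein" not in entry:
            raise JobValidationError("each sequence entry must contain 'protein'")
        protein = entry["protein"]
        for req in ("id", "sequence"):
            if req not in protein:
                raise JobValidationError(f"protein entry missing {req!r}")
        seq = protein["sequence"]
        for mod in protein.get("modifications", []):
            pos, code = mod.get("ptmPosition"), mod.get("ptmType")
            if not isinstance(pos, int) or not 1 <= pos <= len(seq):
                raise JobValidationError(
                    f"modification position {pos} out of range for chain "
                    f"{protein['id']}"
                )
            if code not in standard and code not in available:
                raise JobValidationError(f"unresolved component_id {code!r}")
    return job
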