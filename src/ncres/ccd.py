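"""Chemical-component reference library and InChIKey-based mapping.

Components are read from an SDF file (optionally gzipped) in the dialect of
the public CCD export: each record carries an identifier and, optionally, a
stored InChIKey property. Queries are mapped in two passes: an exact match on
the full 27-character InChIKey, then a relaxed match on the 14-character
connectivity layer, which tolerates protonation-state and tautomer
differences while preserving the molecular skeleton.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import inchi
from rdkit.Chem.MolStandardize import rdMolStandardize

from ncres.scope import ParseError, QueryMolecule

logger = logging.getLogger(__name__)

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")
CONNECTIVITY_PREFIX_LEN = 14

# SDF data-field names that may hold a stored InChIKey; configurable because
# public component exports are not consistent about the property name.
DEFAULT_KEY_FIELDS = ("InChIKey", "InChI_Key", "INCHIKEY", "InChI Key", "inchikey")
DEFAULT_ID_FIELDS = ("component_id", "ID", "id", "ChemCompId", "pdbx_component_id")


class EmptyLibraryError(ValueError):
    """Raised when an SDF yields zero parseable component records."""


class InChIError(ValueError):
    """InChI generation failed for a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"InChI generation failed for {smiles!r}")


@dataclass(frozen=True)
class CCDComponent:
    component_id: str
    three_letter_code: str
    mol: Chem.Mol = field(compare=False, repr=False)
    inchikey: str
    key_source: str  # stored_property | recomputed

    @property
    def connectivity_key(self) -> str:
        return self.inchikey[:CONNECTIVITY_PREFIX_LEN]


@dataclass(frozen=True)
class MappingResult:
    mode: str  # full_key | connectivity_layer | none
    candidates: tuple[CCDComponent, ...]
    confidence: str  # high | ambiguous | none


def _light_sanitize(mol: Chem.Mol) -> Chem.Mol:
    """Kekulization repair and valence normalization; metal disconnection is
    deliberately left off so stored organometallic records keep their graph."""
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        mol.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
        )
    return mol


def _strip_salts(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        from rdkit.Chem import Descriptors

        mol = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.MolWt(f)))
        Chem.SanitizeMol(mol)
    return mol


def standard_inchikey(
    mol: QueryMolecule | Chem.Mol | str, standardize: bool = False
) -> str:
    """Standard 27-character InChIKey of a molecule, salts stripped first.

    With ``standardize=True``, valence cleanup and tautomer canonicalization
    are applied before key generation, making the key robust to drawn
    tautomers. Deterministic for a fixed input.
    """
    if isinstance(mol, str):
        mol = QueryMolecule(mol)
    m = mol.mol if isinstance(mol, QueryMolecule) else Chem.Mol(mol)
    m = _strip_salts(m)
    if standardize:
        m = rdMolStandardize.Cleanup(m)
        m = rdMolStandardize.CanonicalTautomer(m)
    key = inchi.MolToInchiKey(m)
    if not key or not INCHIKEY_RE.match(key):
        raise InChIError(Chem.MolToSmiles(m))
    return key


class ComponentLibrary:
    """In-memory index of CCD components keyed by full InChIKey and by the
    14-character connectivity prefix."""

    def __init__(self, components: list[CCDComponent]):
        if not components:
            raise EmptyLibraryError("no parseable component records")
        self.components: dict[str, CCDComponent] = {}
        self.by_full_key: dict[str, list[CCDComponent]] = {}
        self.by_prefix: dict[str, list[CCDComponent]] = {}
        for comp in sorted(components, key=lambda c: c.component_id):
            if comp.component_id in self.components:
                logger.warning("duplicate component_id %s skipped", comp.component_id)
                continue
            self.components[comp.component_id] = comp
            self.by_full_key.setdefault(comp.inchikey, []).append(comp)
            self.by_prefix.setdefault(comp.connectivity_key, []).append(comp)

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components.values())

    def __getitem__(self, component_id: str) -> CCDComponent:
        return self.components[component_id]


def _record_id(mol: Chem.Mol, id_fields=DEFAULT_ID_FIELDS) -> str | None:
    for f in id_fields:
        if mol.HasProp(f):
            val = mol.GetProp(f).strip()
            if val:
                return val
    name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
    return name or None


def load_component_library(
    sdf_path,
    key_fields=DEFAULT_KEY_FIELDS,
    id_fields=DEFAULT_ID_FIELDS,
) -> ComponentLibrary:
    """Load an SDF (optionally ``.gz``) of components into a searchable index.

    Stored InChIKey properties are trusted when syntactically valid, else the
    key is recomputed after light sanitization. Unparseable records are logged
    and skipped; an SDF with zero parseable records raises
    :class:`EmptyLibraryError`.
    """
    sdf_path = str(sdf_path)
    opener = gzip.open if sdf_path.endswith(".gz") else open
    components: list[CCDComponent] = []
    with opener(sdf_path, "rb") as fh:
        supplier = Chem.ForwardSDMolSupplier(fh, sanitize=False, removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("skipping unparseable SDF record %d", i)
                continue
            try:
                mol = _light_sanitize(mol)
            except Exception:
                logger.warning("skipping unsanitizable SDF record %d", i)
                continue
            comp_id = _record_id(mol, id_fields)
            if not comp_id:
                logger.warning("skipping SDF record %d without identifier", i)
                continue
            key, source = None, "recomputed"
            for f in key_fields:
                if mol.HasProp(f):
                    stored = mol.GetProp(f).strip()
                    if INCHIKEY_RE.match(stored):
                        key, source = stored, "stored_property"
                        break
            if key is None:
                try:
                    key = inchi.MolToInchiKey(mol)
                except Exception:
                    key = ""
                if not key or not INCHIKEY_RE.match(key):
                    logger.warning("skipping record %s: no InChIKey", comp_id)
                    continue
            code = comp_id.upper()[:3]
            components.append(CCDComponent(comp_id, code, mol, key, source))
    return ComponentLibrary(components)


def _graph_identical(query_mol: Chem.Mol, comp_mol: Chem.Mol) -> bool:
    """Tanimoto 1.0 cross-check on Morgan fingerprints (graph-level identity,
    insensitive to stereo and protonation-independent bits)."""
    from ncres.similarity import compute_fingerprint, similarity_score

    try:
        fa = compute_fingerprint(query_mol)
        fb = compute_fingerprint(comp_mol)
    except Exception:
        return False
    return similarity_score(fa.bits, fb.bits, "tanimoto") == 1.0


def map_query_to_ccd(
    mol: QueryMolecule | Chem.Mol | str,
    library: ComponentLibrary,
    retain_all: bool = True,
    standardize: bool = False,
) -> MappingResult:
    """Two-pass mapping of a query molecule onto the component library.

    Pass 1 is an exact lookup on the full InChIKey; on failure, pass 2 matches
    the first fourteen characters (the connectivity layer). Candidates sharing
    a key are returned sorted by component_id; with ``retain_all=False`` only
    the first is kept. Confidence is ``high`` only for a full-key match or a
    graph-identical (Tanimoto 1.0) candidate, else ``ambiguous``.
    """
    if isinstance(mol, str):
        mol = QueryMolecule(mol)
    query_mol = mol.mol if isinstance(mol, QueryMolecule) else mol
    key = standard_inchikey(mol, standardize=standardize)

    candidates = sorted(
        library.by_full_key.get(key, []), key=lambda c: c.component_id
    )
    if candidates:
        if not retain_all:
            candidates = candidates[:1]
        return MappingResult("full_key", tuple(candidates), "high")

    prefix = key[:CONNECTIVITY_PREFIX_LEN]
    candidates = sorted(
        library.by_prefix.get(prefix, []), key=lambda c: c.component_id
    )
    if candidates:
        if not retain_all:
            candidates = candidates[:1]
        confidence = (
            "high"
            if any(_graph_identical(query_mol, c.mol) for c in candidates)
            else "ambiguous"
        )
        return MappingResult("connectivity_layer", tuple(candidates), confidence)

    return MappingResult("none", (), "none")
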