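"""Fingerprint similarity search over a component library.

Components and queries are hashed to 2048-bit circular (Morgan) fingerprints
with radius 2; ranking supports four set-overlap coefficients (Tanimoto,
Dice, cosine, Kulczynski). A hit scoring Tanimoto 1.0 is treated as an exact
structural match (graph-level equivalence; fingerprints carry no chirality
bits, so enantiomers also score 1.0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from ncres.scope import QueryMolecule

logger = logging.getLogger(__name__)

FP_RADIUS = 2
FP_NBITS = 2048
COEFFICIENTS = ("tanimoto", "dice", "cosine", "kulczynski")

_GENERATOR = rdFingerprintGenerator.GetMorganGenerator(
    radius=FP_RADIUS, fpSize=FP_NBITS
)


@dataclass(frozen=True)
class FingerprintRecord:
    component_id: str
    bits: np.ndarray  # uint8 0/1 vector of length 2048

    def __post_init__(self):
        if self.bits.shape != (FP_NBITS,):
            raise ValueError(f"fingerprint must have length {FP_NBITS}")


@dataclass(frozen=True)
class SearchConfig:
    coefficient: str = "tanimoto"
    k: int = 10
    exact_match_threshold: float = 1.0  # fixed by convention

    def __post_init__(self):
        if self.coefficient not in COEFFICIENTS:
            raise ValueError(f"unknown coefficient {self.coefficient!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class SimilarityHit:
    component_id: str
    scores: dict  # coefficient -> value in [0, 1]
    rank: int  # 1-based under the ranking coefficient
    exact: bool = False


@dataclass(frozen=True)
class SearchResult:
    hits: tuple[SimilarityHit, ...]
    exact_match: bool
    config: SearchConfig


def compute_fingerprint(
    mol: QueryMolecule | Chem.Mol | str, component_id: str = ""
) -> FingerprintRecord:
    """Morgan radius-2, 2048-bit fingerprint of a sanitized molecule."""
    if isinstance(mol, str):
        mol = QueryMolecule(mol)
    m = mol.mol if isinstance(mol, QueryMolecule) else mol
    if m.GetNumAtoms() == 0:
        raise ValueError("cannot fingerprint an empty molecule")
    fp = _GENERATOR.GetFingerprint(m)
    bits = np.zeros(FP_NBITS, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return FingerprintRecord(component_id, bits)


def similarity_score(a: np.ndarray, b: np.ndarray, coefficient: str = "tanimoto") -> float:
    """Set-overlap similarity of two equal-length binary vectors.

    With on-bit counts ``|A|``, ``|B|`` and intersection ``c``:
    tanimoto = c/(|A|+|B|-c); dice = 2c/(|A|+|B|); cosine = c/sqrt(|A||B|);
    kulczynski = (c/|A| + c/|B|)/2 (the arithmetic-mean variant). Two empty
    fingerprints score 0 by convention.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na = int(np.count_nonzero(a))
    nb = int(np.count_nonzero(b))
    c = int(np.count_nonzero(np.logical_and(a, b)))
    if na == 0 or nb == 0:
        return 0.0
    if coefficient == "tanimoto":
        return c / (na + nb - c)
    if coefficient == "dice":
        return 2 * c / (na + nb)
    if coefficient == "cosine":
        return c / math.sqrt(na * nb)
    if coefficient == "kulczynski":
        return (c / na + c / nb) / 2
    raise ValueError(f"unknown coefficient {coefficient!r}")


def library_fingerprints(library) -> list[FingerprintRecord]:
    """Precompute fingerprints for every component in a ComponentLibrary."""
    return [compute_fingerprint(c.mol, c.component_id) for c in library]


def search(
    query: QueryMolecule | Chem.Mol | str,
    library_fps: list[FingerprintRecord],
    cfg: SearchConfig = SearchConfig(),
) -> SearchResult:
    """Rank library components against a query.

    Hits are sorted by the ranking coefficient (descending), ties broken by
    ascending component_id; every hit carries all four coefficient scores.
    A Tanimoto score of 1.0 marks an exact structural match. Result length is
    ``min(k, library size)``.
    """
    if not library_fps:
        logger.warning("similarity search over an empty library")
        return SearchResult((), False, cfg)
    qfp = compute_fingerprint(query)

    scored = []
    for rec in library_fps:
        scores = {
            coef: similarity_score(qfp.bits, rec.bits, coef)
            for coef in COEFFICIENTS
        }
        scored.append((rec.component_id, scores))
    scored.sort(key=lambda t: (-t[1][cfg.coefficient], t[0]))

    hits = tuple(
        SimilarityHit(
            cid,
            scores,
            rank=i + 1,
            exact=scores["tanimoto"] >= cfg.exact_match_threshold,
        )
        for i, (cid, scores) in enumerate(scored[: cfg.k])
    )
    return SearchResult(hits, any(h.exact for h in hits), cfg)
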