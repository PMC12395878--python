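"""Counted substructure-key fingerprints, atom coverage, and dataset statistics.

A fingerprint is a length-39 vector (for the default registry) of
non-negative integers: entry *i* is the number of *distinct atom sets* in
the molecule matching key *i*'s relaxed pattern.  Distinct-atom-set counting
deduplicates pattern automorphisms (a benzene ring matched by a six-carbon
ring pattern counts once, not twelve times), while different placements of
the same key — and matches of different keys — may share atoms freely:
detections overlap by design, mirroring how biosynthetic building blocks
overlap in real scaffolds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .keyset import KeyRegistry, SubstructureKey
from .structio import MoleculeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CountFingerprint",
    "CoverageResult",
    "count_matches",
    "fingerprint_molecule",
    "binarise",
    "atom_coverage",
    "batch_fingerprint",
    "occurrence_stats",
    "cooccurrence_pmi",
]

# Generous cap so large molecules never silently truncate their match lists.
_MAX_MATCHES = 1_000_000


@dataclass(frozen=True)
class CountFingerprint:
    """Per-key match counts for one molecule, in registry index order."""

    counts: np.ndarray
    registry_version: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class CoverageResult:
    """Heavy atoms touched by at least one key match, as a fraction."""

    covered_heavy_atoms: int
    total_heavy_atoms: int

    @property
    def coverage(self) -> float:
        return self.covered_heavy_atoms / self.total_heavy_atoms


def _matches(mol: Chem.Mol, key: SubstructureKey) -> tuple[tuple[int, ...], ...]:
    return mol.GetSubstructMatches(key.pattern, uniquify=True, maxMatches=_MAX_MATCHES)


def count_matches(record: MoleculeRecord | Chem.Mol, key: SubstructureKey) -> int:
    """Number of distinct atom-index sets matching the key's relaxed pattern."""
    mol = record.mol if isinstance(record, MoleculeRecord) else record
    return len(_matches(mol, key))


def fingerprint_molecule(
    record: MoleculeRecord | Chem.Mol, registry: KeyRegistry
) -> CountFingerprint:
    """Counted fingerprint of one molecule over every registry key."""
    mol = record.mol if isinstance(record, MoleculeRecord) else record
    counts = np.fromiter(
        (count_matches(mol, key) for key in registry), dtype=np.int64, count=len(registry)
    )
    return CountFingerprint(counts=counts, registry_version=registry.version)


def binarise(fp: CountFingerprint | np.ndarray) -> np.ndarray:
    """Element-wise presence indicator (count > 0) as a 0/1 integer vector."""
    counts = fp.counts if isinstance(fp, CountFingerprint) else np.asarray(fp)
    return (counts > 0).astype(np.int64)


def atom_coverage(
    record: MoleculeRecord | Chem.Mol, registry: KeyRegistry
) -> CoverageResult:
    """Fraction of heavy atoms appearing in at least one match of any key.

    Hydrogens are excluded from both numerator and denominator; the key
    patterns only ever map heavy atoms.
    """
    mol = record.mol if isinstance(record, MoleculeRecord) else record
    total = mol.GetNumHeavyAtoms()
    if total == 0:
        raise ValueError("molecule has no heavy atoms")
    covered: set[int] = set()
    for key in registry:
        for match in _matches(mol, key):
            covered.update(match)
    return CoverageResult(covered_heavy_atoms=len(covered), total_heavy_atoms=total)


def batch_fingerprint(
    records: list[MoleculeRecord],
    registry: KeyRegistry,
    with_coverage: bool = True,
) -> pd.DataFrame:
    """Fingerprint a list of records into a table (one row per molecule).

    Columns are the registry key names (integer counts) plus, optionally, a
    final ``coverage`` column.  Row order follows input order; records that
    fail to fingerprint are logged and omitted.  Raises if every row fails
    or the input is empty.
    """
    if not records:
        raise ValueError("no records to fingerprint")
    rows: list[list] = []
    ids: list[str] = []
    for rec in records:
        try:
            fp = fingerprint_molecule(rec, registry)
            row = list(fp.counts)
            if with_coverage:
                row.append(atom_coverage(rec, registry).coverage)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("record %r dropped: %s", rec.id, exc)
            continue
        ids.append(rec.id)
        rows.append(row)
    if not rows:
        raise ValueError("all records failed to fingerprint")
    columns = list(registry.names) + (["coverage"] if with_coverage else [])
    frame = pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=columns)
    frame[registry.names] = frame[registry.names].astype(np.int64)
    return frame


def _count_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Drop a trailing coverage column if present; keep key-count columns."""
    if "coverage" in table.columns:
        return table.drop(columns="coverage")
    return table


def occurrence_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Per-key count distribution summary over a fingerprint table.

    Returns a frame indexed by key name with columns mean, q25, median,
    q75 and max.
    """
    counts = _count_matrix(table)
    if counts.empty:
        raise ValueError("empty fingerprint table")
    return pd.DataFrame(
        {
            "mean": counts.mean(),
            "q25": counts.quantile(0.25),
            "median": counts.median(),
            "q75": counts.quantile(0.75),
            "max": counts.max(),
        }
    )


def cooccurrence_pmi(table: pd.DataFrame) -> pd.DataFrame:
    """Pointwise mutual information of key co-occurrence across molecules.

    Occurrence is binarised (count > 0) and probabilities are molecule
    fractions; ``PMI(i, j) = log2(p(i and j) / (p(i) p(j)))``.  Pairs with a
    zero marginal are undefined and reported as NaN; pairs that never
    co-occur despite nonzero marginals get ``-inf``.  The diagonal is
    ``-log2 p(i)``.
    """
    counts = _count_matrix(table)
    if len(counts) < 2:
        raise ValueError("PMI needs at least two molecules")
    present = (counts.to_numpy() > 0).astype(float)
    n = present.shape[0]
    p_single = present.mean(axis=0)
    p_joint = (present.T @ present) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log2(p_joint) - np.log2(p_single[:, None] * p_single[None, :])
    undefined = (p_single[:, None] == 0) | (p_single[None, :] == 0)
    pmi[undefined] = np.nan
    return pd.DataFrame(pmi, index=counts.columns, columns=counts.columns)
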