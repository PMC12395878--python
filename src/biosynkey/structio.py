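"""Reading molecular structures and constitution-level (InChI-skeleton) matching.

Natural-product identification here follows the connectivity criterion: two
compounds are "the same" when the formula, connectivity (``/c``) and
hydrogen (``/h``) layers of their standard InChI agree — i.e. identical
constitution, stereochemistry ignored.  That criterion is deliberately
blind to the stereo, charge and isotope layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import inchi

logger = logging.getLogger(__name__)

# RDKit is chatty about unparseable records; skips are reported explicitly.
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "SkeletonKey",
    "SkipReport",
    "StructureReadError",
    "read_structures",
    "record_from_smiles",
    "write_smiles",
    "skeleton_key",
    "match_by_skeleton",
]


class StructureReadError(IOError):
    """Raised when a structure file is missing or yields no parseable records."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed molecule plus its provenance."""

    id: str
    mol: Chem.Mol
    source: str = ""

    @property
    def heavy_atom_count(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


@dataclass(frozen=True)
class SkeletonKey:
    """Layers 1-3 of a standard InChI: formula, connectivity, hydrogens."""

    formula_layer: str
    connectivity_layer: str
    h_layer: str


@dataclass
class SkipReport:
    """Bookkeeping for records a reader could not parse."""

    n_read: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)

    def log(self, position: int, reason: str) -> None:
        self.skipped.append((position, reason))
        logger.warning("skipping record %d: %s", position, reason)


def record_from_smiles(smiles: str, id: str = "", source: str = "") -> MoleculeRecord:
    """Parse a single SMILES into a record; raises on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureReadError(f"unparseable SMILES {smiles!r}")
    return MoleculeRecord(id=id or smiles, mol=mol, source=source)


def _read_smiles_file(path: Path, report: SkipReport) -> list[MoleculeRecord]:
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"{path.name}:{lineno}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                report.log(lineno, f"unparseable SMILES {smiles!r}")
                continue
            records.append(
                MoleculeRecord(id=mol_id, mol=mol, source=f"{path}:{lineno}")
            )
            report.n_read += 1
    return records


def _read_sdf_file(path: Path, report: SkipReport) -> list[MoleculeRecord]:
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for idx, mol in enumerate(supplier):
        if mol is None:
            report.log(idx + 1, "unparseable SDF record")
            continue
        mol_id = (
            mol.GetProp("_Name")
            if mol.HasProp("_Name") and mol.GetProp("_Name").strip()
            else f"{path.name}:{idx + 1}"
        )
        records.append(MoleculeRecord(id=mol_id, mol=mol, source=f"{path}:{idx + 1}"))
        report.n_read += 1
    return records


def read_structures(
    path, format: str | None = None
) -> tuple[list[MoleculeRecord], SkipReport]:
    """Read molecules from a SMILES or SDF file.

    Parseable records are returned in file order; unparseable ones are
    skipped, counted, and logged with their line/record number.  SMILES
    lines are whitespace-separated ``SMILES [id]``; a missing id is
    synthesised as ``<file>:<line>``.

    Raises
    ------
    StructureReadError
        If the file is missing or contains zero parseable records.
    """
    path = Path(path)
    if not path.exists():
        raise StructureReadError(f"no such file: {path}")
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "smiles"
    if format not in ("smiles", "sdf"):
        raise ValueError(f"format must be 'smiles' or 'sdf', got {format!r}")
    report = SkipReport()
    reader = _read_sdf_file if format == "sdf" else _read_smiles_file
    records = reader(path, report)
    if not records:
        raise StructureReadError(
            f"{path}: no parseable records ({report.n_skipped} skipped)"
        )
    return records, report


def write_smiles(records: Iterable[MoleculeRecord], path) -> None:
    """Write records as a two-column ``SMILES id`` file."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f"{rec.smiles}\t{rec.id}\n")


def skeleton_key(record: MoleculeRecord) -> SkeletonKey:
    """Constitution key from InChI layers 1-3 (formula, ``/c``, ``/h``).

    Stereo (``/b /t /m /s``), charge and isotope layers are discarded, so
    any two stereoisomers of the same constitution share a key.
    """
    text = inchi.MolToInchi(record.mol)
    if not text:
        raise StructureReadError(f"InChI generation failed for record {record.id!r}")
    # "InChI=1S/<formula>/c.../h.../..." — split on layer prefixes.
    body = text.split("=", 1)[1]
    layers = body.split("/")
    formula = layers[1] if len(layers) > 1 else ""
    c_layer = ""
    h_layer = ""
    for layer in layers[2:]:
        if layer.startswith("c"):
            c_layer = layer[1:]
        elif layer.startswith("h"):
            h_layer = layer[1:]
        elif layer[:1] in ("b", "t", "m", "s", "i", "p", "q"):
            break  # stereo/isotope/charge block starts; layers 1-3 are done
    return SkeletonKey(formula_layer=formula, connectivity_layer=c_layer, h_layer=h_layer)


def match_by_skeleton(
    query: Sequence[MoleculeRecord], reference: Sequence[MoleculeRecord]
) -> dict[str, list[str]]:
    """Map each query id to the reference ids with an identical skeleton.

    Records whose InChI cannot be generated are skipped with a log message.
    Queries with no match map to an empty list.
    """
    if not query or not reference:
        raise ValueError("query and reference must both be non-empty")
    index: dict[SkeletonKey, list[str]] = {}
    for rec in reference:
        try:
            index.setdefault(skeleton_key(rec), []).append(rec.id)
        except StructureReadError as exc:
            logger.warning("reference record dropped: %s", exc)
    out: dict[str, list[str]] = {}
    for rec in query:
        try:
            out[rec.id] = list(index.get(skeleton_key(rec), []))
        except StructureReadError as exc:
            logger.warning("query record dropped: %s", exc)
    return out
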