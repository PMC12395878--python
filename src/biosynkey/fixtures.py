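"""Synthetic molecules, reaction chains and labelled sets with known truth.

Real benchmark inputs (natural-product databases, curated pathways,
ontology labels) are licensed and large; this module builds structurally
honest stand-ins from the registry's own building blocks, so every other
module can be exercised end-to-end with known expected outcomes.

Molecules are assembled by joining block fragments (isoprene units, acetate
units, sugar rings, ...) with single bonds — a crude but biosynthetically
shaped analogue of how natural scaffolds grow.  Reaction chains apply one
block addition per step, so chain position is a true biosynthetic-distance
analogue: compounds further apart along a chain genuinely share less
structure.  Labelled sets give each class a distinct dominant block profile
(terpenoid-like, polyketide-like, glycoside-like), which makes them
separable by construction.

All randomness flows through one ``numpy`` generator created from the seed
argument; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .biodistance import PathwayGraph, ReactionChain
from .classify import LabelledSet
from .fingerprint import batch_fingerprint
from .keyset import KeyRegistry, load_default_registry
from .structio import MoleculeRecord

__all__ = [
    "BlockRecipe",
    "SyntheticChain",
    "BLOCK_FRAGMENTS",
    "assemble",
    "make_chain",
    "make_chain_set",
    "chains_to_pathway_graphs",
    "make_labelled_set",
    "small_molecule_records",
]

# fragment SMILES, head atom (bond to previous block), tail atom (bond to next)
BLOCK_FRAGMENTS: dict[str, tuple[str, int, int]] = {
    "isoprene_c5": ("CC(C)CC", 0, 4),
    "acetyl_c2": ("CC=O", 0, 1),
    "malonyl_c3": ("O=CCC=O", 1, 3),
    "benzyl_c6c1": ("c1ccccc1C", 6, 6),
    "phenylpropanoid_c6c3": ("c1ccccc1CCC", 6, 8),
    "pyranose": ("C1OC(O)C(O)C(O)C1O", 0, 0),
    "furanose": ("C1OC(O)C(O)C1O", 0, 0),
    "alpha_amino_acid": ("NCC(=O)O", 1, 1),
    "hydroxyl": ("O", 0, 0),
    "primary_amine": ("N", 0, 0),
    "methyl_c1": ("C", 0, 0),
}


@dataclass(frozen=True)
class BlockRecipe:
    """Ordered list of registry building-block names to join with single bonds."""

    blocks: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [b for b in self.blocks if b not in BLOCK_FRAGMENTS]
        if unknown:
            raise ValueError(f"unknown building blocks: {unknown}")

    def multiplicities(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.blocks:
            out[b] = out.get(b, 0) + 1
        return out


@dataclass(frozen=True)
class SyntheticChain:
    """A seed molecule plus the ordered block edits that grew it."""

    seed_smiles: str
    edits: tuple[str, ...]
    chain: ReactionChain


def _join(base: Chem.RWMol, base_atom: int, fragment_name: str) -> tuple[Chem.RWMol, int]:
    """Attach a block fragment to ``base`` by a single bond; returns the new
    molecule and the index of the fragment's tail atom in it."""
    smiles, head, tail = BLOCK_FRAGMENTS[fragment_name]
    frag = Chem.MolFromSmiles(smiles)
    offset = base.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(base, frag))
    combined.AddBond(base_atom, offset + head, Chem.BondType.SINGLE)
    return combined, offset + tail


# single-heteroatom decorations hang off a backbone carbon instead of
# extending the chain (three hydroxyls must give three C-OH groups, not a
# peroxide chain)
_DECORATION_BLOCKS = frozenset({"hydroxyl", "primary_amine"})


def assemble(
    recipe: BlockRecipe | Sequence[str], seed: int = 0, mol_id: str = ""
) -> tuple[MoleculeRecord, dict[str, int]]:
    """Join the recipe's blocks into one molecule.

    Chain blocks are joined head-to-tail with single bonds; decoration
    blocks (hydroxyl, primary amine) attach to the first still-undecorated
    backbone carbon with a free valence and do not advance the chain.
    Returns the record together with the expected *minimum* count of each
    block's substructure key: by construction the assembled molecule
    contains at least ``multiplicity`` placements of every named block
    (overlapping placements may push the observed count higher).

    Raises on an empty recipe or a valence-illegal assembly, naming the
    recipe position that failed.
    """
    if not isinstance(recipe, BlockRecipe):
        recipe = BlockRecipe(blocks=tuple(recipe))
    if not recipe.blocks:
        raise ValueError("empty recipe")
    smiles0, _, tail0 = BLOCK_FRAGMENTS[recipe.blocks[0]]
    mol = Chem.RWMol(Chem.MolFromSmiles(smiles0))
    tail = tail0
    decorated: set[int] = set()
    for pos, name in enumerate(recipe.blocks[1:], start=1):
        try:
            if name in _DECORATION_BLOCKS:
                free = [
                    a.GetIdx()
                    for a in mol.GetAtoms()
                    if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
                ]
                if not free:
                    raise ValueError("no carbon with free valence")
                site = next((c for c in free if c not in decorated), free[0])
                decorated.add(site)
                mol, _ = _join(mol, site, name)
            else:
                mol, tail = _join(mol, tail, name)
            Chem.SanitizeMol(mol)
        except Exception as exc:
            raise ValueError(f"recipe position {pos} ({name!r}): {exc}") from exc
    final = mol.GetMol()
    Chem.SanitizeMol(final)
    record = MoleculeRecord(
        id=mol_id or "blocks:" + "+".join(recipe.blocks),
        mol=final,
        source="fixtures.assemble",
    )
    return record, recipe.multiplicities()


# Edits applied by synthetic "reactions": one block addition per step.
DEFAULT_EDIT_PALETTE = (
    "isoprene_c5",
    "acetyl_c2",
    "hydroxyl",
    "pyranose",
    "methyl_c1",
)

_SEED_SCAFFOLDS = (
    "CC(C)CCO",  # prenol-like
    "CC(=O)CC(=O)O",  # polyketide starter
    "c1ccccc1CCO",  # phenylpropanoid-like
    "OCC1OC(O)C(O)C(O)C1O",  # hexose
)

_MAX_EDIT_RETRIES = 20


def _free_carbons(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
    ]


def _apply_edit(mol: Chem.Mol, edit: str, rng: np.random.Generator) -> Chem.Mol:
    for _ in range(_MAX_EDIT_RETRIES):
        sites = _free_carbons(mol)
        if not sites:
            break
        site = int(rng.choice(sites))
        try:
            grown, _ = _join(Chem.RWMol(mol), site, edit)
            out = grown.GetMol()
            Chem.SanitizeMol(out)
            return out
        except Exception:
            continue
    raise ValueError(f"edit {edit!r} inapplicable: no free valence found")


def make_chain(
    n_steps: int,
    seed: int = 0,
    edit_palette: Sequence[str] = DEFAULT_EDIT_PALETTE,
    chain_id: str = "",
) -> SyntheticChain:
    """Grow a synthetic reaction chain of ``n_steps`` single-block edits.

    Deterministic for a fixed seed; every intermediate is sanitised, and
    chain length equals the number of edits.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    seed_smiles = _SEED_SCAFFOLDS[int(rng.integers(len(_SEED_SCAFFOLDS)))]
    mol = Chem.MolFromSmiles(seed_smiles)
    chain_id = chain_id or f"synchain{seed}"
    records = [MoleculeRecord(id=f"{chain_id}:c0", mol=mol, source="fixtures.make_chain")]
    edits = []
    for step in range(1, n_steps + 1):
        edit = str(rng.choice(edit_palette))
        mol = _apply_edit(mol, edit, rng)
        edits.append(edit)
        records.append(
            MoleculeRecord(id=f"{chain_id}:c{step}", mol=mol, source="fixtures.make_chain")
        )
    chain = ReactionChain(pathway_id=chain_id, compounds=tuple(records))
    return SyntheticChain(seed_smiles=seed_smiles, edits=tuple(edits), chain=chain)


def make_chain_set(
    n_chains: int, n_steps: int = 6, seed: int = 0
) -> list[SyntheticChain]:
    """A reproducible family of chains; chain *i* derives its seed from ``seed``."""
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_chains)
    return [
        make_chain(n_steps, seed=int(s), chain_id=f"synchain{seed}.{i}")
        for i, s in enumerate(sub_seeds)
    ]


def chains_to_pathway_graphs(chains: Sequence[SyntheticChain]) -> list[PathwayGraph]:
    """Linear pathway graphs (one edge per edit) from synthetic chains."""
    graphs = []
    for sc in chains:
        compounds = sc.chain.compounds
        graphs.append(
            PathwayGraph(
                pathway_id=sc.chain.pathway_id,
                nodes={r.id: r for r in compounds},
                edges=tuple(
                    (compounds[i].id, compounds[i + 1].id)
                    for i in range(len(compounds) - 1)
                ),
            )
        )
    return graphs


# Class profiles: dominant block and how many copies a member carries.
DEFAULT_CLASS_PROFILES: dict[str, tuple[str, tuple[int, int]]] = {
    "terpenoid_like": ("isoprene_c5", (3, 5)),
    "polyketide_like": ("acetyl_c2", (4, 7)),
    "glycoside_like": ("pyranose", (2, 3)),
}


def make_labelled_set(
    n_per_class: int = 50,
    class_profiles: dict[str, tuple[str, tuple[int, int]]] | None = None,
    multilabel_fraction: float = 0.0,
    noise_edits: int = 1,
    seed: int = 0,
    registry: KeyRegistry | None = None,
) -> LabelledSet:
    """Build a separable multilabel classification fixture.

    Each class is defined by a dominant building block repeated a
    class-specific number of times (drawn per molecule from the profile's
    inclusive range), plus ``noise_edits`` random decorations.  A
    ``multilabel_fraction`` of each class's molecules (rounded down)
    additionally carries a second class's profile and both labels.
    Deterministic per seed.
    """
    if class_profiles is None:
        class_profiles = DEFAULT_CLASS_PROFILES
    class_names = sorted(class_profiles)
    if len(class_names) < 2:
        raise ValueError("need at least two classes")
    if registry is None:
        registry = load_default_registry()
    rng = np.random.default_rng(seed)
    n_multi = int(multilabel_fraction * n_per_class)
    records: list[MoleculeRecord] = []
    labels: dict[str, frozenset[str]] = {}
    for cls_idx, cls in enumerate(class_names):
        block, (lo, hi) = class_profiles[cls]
        for i in range(n_per_class):
            blocks = [block] * int(rng.integers(lo, hi + 1))
            label = {cls}
            if i < n_multi:
                other = class_names[(cls_idx + 1) % len(class_names)]
                o_block, (o_lo, o_hi) = class_profiles[other]
                blocks += [o_block] * int(rng.integers(o_lo, o_hi + 1))
                label.add(other)
            blocks += [
                str(rng.choice(["hydroxyl", "methyl_c1"])) for _ in range(noise_edits)
            ]
            mol_id = f"{cls}:{i}"
            record, _ = assemble(BlockRecipe(tuple(blocks)), mol_id=mol_id)
            records.append(record)
            labels[mol_id] = frozenset(label)
    table = batch_fingerprint(records, registry, with_coverage=False)
    return LabelledSet(fingerprints=table, labels=labels)


def make_isoprene_driven_set(
    n_per_class: int = 50, seed: int = 0, registry: KeyRegistry | None = None
) -> LabelledSet:
    """Two-class fixture where isoprene count is the only clean signal.

    Both classes are oligo-isoprenoids; the rich class carries 4-6 isoprene
    units, the poor class 1-3.  Because every isoprene unit also brings a
    methyl branch, the methyl channel would separate the classes too; to
    keep the discriminative signal on the isoprene key alone, a random
    number (0-4) of each molecule's methyl groups is hydroxylated
    (CH3 → CH2OH), which blurs the methyl and oxygen channels across the
    class boundary without touching isoprene placements.
    """
    if registry is None:
        registry = load_default_registry()
    rng = np.random.default_rng(seed)
    records: list[MoleculeRecord] = []
    labels: dict[str, frozenset[str]] = {}
    for cls, (lo, hi) in (("terpene_rich", (4, 6)), ("terpene_poor", (1, 3))):
        for i in range(n_per_class):
            k = int(rng.integers(lo, hi + 1))
            record, _ = assemble(BlockRecipe(("isoprene_c5",) * k))
            mol = record.mol
            n_oh = int(rng.integers(0, 5))
            for _ in range(n_oh):
                methyls = [
                    a.GetIdx()
                    for a in mol.GetAtoms()
                    if a.GetAtomicNum() == 6
                    and a.GetTotalNumHs() == 3
                    and a.GetDegree() == 1
                ]
                if not methyls:
                    break
                site = int(rng.choice(methyls))
                grown, _ = _join(Chem.RWMol(mol), site, "hydroxyl")
                mol = grown.GetMol()
                Chem.SanitizeMol(mol)
            mol_id = f"{cls}:{i}"
            records.append(MoleculeRecord(id=mol_id, mol=mol, source="fixtures"))
            labels[mol_id] = frozenset({cls})
    table = batch_fingerprint(records, registry, with_coverage=False)
    return LabelledSet(fingerprints=table, labels=labels)


# Small named molecules used for oracle-equivalence and coverage checks.
SMALL_MOLECULES: tuple[tuple[str, str], ...] = (
    ("methane", "C"),
    ("ethanol", "CCO"),
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("fluorobenzene", "Fc1ccccc1"),
    ("acetone", "CC(C)=O"),
    ("acetic_acid", "CC(=O)O"),
    ("pyruvic_acid", "CC(=O)C(=O)O"),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
    ("ribose", "OCC1OC(O)C(O)C1O"),
    ("glycine", "NCC(=O)O"),
    ("alanine", "CC(N)C(=O)O"),
    ("serine", "OCC(N)C(=O)O"),
    ("cysteine", "SCC(N)C(=O)O"),
    ("isoprene", "CC(=C)C=C"),
    ("prenol", "CC(C)=CCO"),
    ("cyclopropane", "C1CC1"),
    ("cyclobutanone", "O=C1CCC1"),
    ("cyclopentane", "C1CCCC1"),
    ("cyclohexanol", "OC1CCCCC1"),
    ("phenol", "Oc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("benzaldehyde", "O=Cc1ccccc1"),
    ("chloroethane", "CCCl"),
    ("bromobenzene", "Brc1ccccc1"),
    ("iodomethane", "CI"),
    ("dimethyl_phosphate", "COP(=O)(O)OC"),
    ("glycerol", "OCC(O)CO"),
    ("malonic_acid", "OC(=O)CC(=O)O"),
    ("butanedione", "CC(=O)C(=O)C"),
)


def small_molecule_records() -> list[MoleculeRecord]:
    """Parse the built-in small-molecule roster (all ≤ 12 heavy atoms)."""
    return [
        MoleculeRecord(id=name, mol=Chem.MolFromSmiles(smiles), source="fixtures")
        for name, smiles in SMALL_MOLECULES
    ]
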