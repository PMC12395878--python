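"""Registry of biosynthetic substructure keys.

The fingerprint is built from a fixed, ordered set of 39 substructure keys
drawn from the logic of natural-product biosynthesis: the eight fundamental
building blocks (C5 isoprene, C2 acetate, C1 methyl, C6C3 phenylpropanoid,
C6C2N, C6C1, indole-C2N and the C3 pyruvate unit), amino acids, sugar
moieties, small decorations (hydroxyl, carbonyl, halogens, carbocycles, ...)
and coenzyme/helper motifs.  Each key carries the metabolic pathway it is
most associated with (shikimate, acetate, terpenoid, carbohydrate,
amino-acid, or none for decorations), which downstream modules use to
aggregate feature importances and colour visualisations.

Patterns are authored as SMARTS and then *bond-order relaxed*: atom identity
(the element) stays strict while every bond is rewritten to match any bond
order.  The rationale is biosynthetic: an atom's element records where it
came from, whereas bond orders change freely as enzymes oxidise, reduce and
aromatise scaffolds.  Atoms authored in ``[#n...]`` bracket form are treated
as deliberately strict and pass through relaxation verbatim, which is how a
few keys (methyl, hydroxyl, carbonyl) keep H-count or degree constraints
that an element-only pattern could not express.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Sequence

from rdkit import Chem

__all__ = [
    "PATHWAYS",
    "SubstructureKey",
    "KeyRegistry",
    "RegistryError",
    "SmartsParseError",
    "relax_bond_orders",
    "load_default_registry",
    "customise_registry",
]

#: Closed set of pathway annotations; "none" marks decorations and helpers.
PATHWAYS = frozenset(
    {"shikimate", "acetate", "terpenoid", "carbohydrate", "amino-acid", "none"}
)

_PERIODIC = Chem.GetPeriodicTable()
_TWO_LETTER = ("Cl", "Br")
_ORGANIC_SUBSET = set("BCNOPSFI") | set("bcnops")
_BOND_CHARS = set("-=#:/\\~@")
_ELEMENT_RE = re.compile(r"([A-Z][a-z]?|[bcnops])")


class RegistryError(ValueError):
    """Raised for invalid registries or invalid customisation requests."""


class SmartsParseError(ValueError):
    """Raised when a SMARTS pattern cannot be tokenised or compiled."""


def _atomic_number(symbol: str) -> int:
    sym = symbol if len(symbol) > 1 else symbol.upper()
    num = _PERIODIC.GetAtomicNumber(sym)
    if num == 0:
        raise SmartsParseError(f"unknown element symbol {symbol!r}")
    return num


def relax_bond_orders(smarts: str) -> str:
    """Rewrite a SMARTS pattern to element-strict, bond-order-flexible form.

    Every atom primitive becomes an element-only constraint ``[#n]`` and
    every bond (explicit or implicit, including ring closures) becomes the
    any-bond connector ``~``.  Bracket atoms whose body starts with ``#``
    are considered deliberately strict and are kept verbatim, so the
    function is idempotent: ``relax(relax(s)) == relax(s)``.

    Parameters
    ----------
    smarts:
        A valid SMARTS pattern.

    Returns
    -------
    str
        The relaxed pattern, guaranteed to compile.
    """
    out: list[str] = []
    i, n = 0, len(smarts)
    need_bond = False  # an atom was emitted; next atom needs an explicit '~'

    def emit_atom(token: str) -> None:
        nonlocal need_bond
        if need_bond:
            out.append("~")
        out.append(token)
        need_bond = True

    while i < n:
        ch = smarts[i]
        if ch == "[":
            j = smarts.find("]", i)
            if j < 0:
                raise SmartsParseError(f"unclosed bracket atom at position {i} in {smarts!r}")
            body = smarts[i + 1 : j]
            if body.startswith("#"):
                emit_atom(f"[{body}]")  # deliberately strict: verbatim
            else:
                stripped = body.lstrip("0123456789")  # drop isotope prefix
                match = _ELEMENT_RE.match(stripped)
                if match is None:
                    raise SmartsParseError(
                        f"cannot relax bracket atom [{body}] in {smarts!r}"
                    )
                emit_atom(f"[#{_atomic_number(match.group(1))}]")
            i = j + 1
        elif smarts[i : i + 2] in _TWO_LETTER:
            emit_atom(f"[#{_atomic_number(smarts[i:i + 2])}]")
            i += 2
        elif ch in _ORGANIC_SUBSET:
            emit_atom(f"[#{_atomic_number(ch)}]")
            i += 1
        elif ch in _BOND_CHARS:
            i += 1  # dropped; '~' is inserted lazily before the next atom
        elif ch.isdigit():
            out.append(f"~{ch}")  # ring closure: keep digit, any-bond it
            i += 1
        elif ch == "%":
            out.append(f"~{smarts[i:i + 3]}")
            i += 3
        elif ch == "(":
            out.append("(")  # need_bond persists: branch bond becomes '(~'
            i += 1
        elif ch == ")":
            out.append(")")
            need_bond = True
            i += 1
        elif ch == ".":
            out.append(".")
            need_bond = False
            i += 1
        else:
            raise SmartsParseError(f"unexpected token {ch!r} at position {i} in {smarts!r}")

    relaxed = "".join(out)
    if Chem.MolFromSmarts(relaxed) is None:
        raise SmartsParseError(f"relaxed pattern {relaxed!r} does not compile")
    return relaxed


@dataclass(frozen=True)
class SubstructureKey:
    """One biosynthetic substructure pattern.

    Attributes
    ----------
    index:
        0-based position in the fingerprint vector.
    name:
        Short unique identifier, e.g. ``"isoprene_c5"`` or ``"fluorine"``.
    group:
        Display group used to summarise related keys in figures.
    pathway:
        One of :data:`PATHWAYS`; ``"none"`` for decorations/helpers.
    smarts_raw:
        The pattern as authored.
    smarts_relaxed:
        The bond-order-relaxed pattern actually matched.
    is_dewick_block:
        Marks the eight fundamental biosynthetic building blocks.
    """

    index: int
    name: str
    group: str
    pathway: str
    smarts_raw: str
    smarts_relaxed: str
    is_dewick_block: bool = False

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise RegistryError(
                f"key {self.name!r}: pathway {self.pathway!r} not in {sorted(PATHWAYS)}"
            )
        if Chem.MolFromSmarts(self.smarts_relaxed) is None:
            raise SmartsParseError(
                f"key {self.name!r}: relaxed SMARTS {self.smarts_relaxed!r} does not compile"
            )

    @property
    def pattern(self) -> Chem.Mol:
        """Compiled RDKit query molecule for :attr:`smarts_relaxed` (cached)."""
        return _compiled(self.smarts_relaxed)

    @property
    def n_pattern_atoms(self) -> int:
        return _compiled(self.smarts_relaxed).GetNumAtoms()


_PATTERN_CACHE: dict[str, Chem.Mol] = {}


def _compiled(smarts: str) -> Chem.Mol:
    mol = _PATTERN_CACHE.get(smarts)
    if mol is None:
        mol = Chem.MolFromSmarts(smarts)
        if mol is None:
            raise SmartsParseError(f"SMARTS {smarts!r} does not compile")
        _PATTERN_CACHE[smarts] = mol
    return mol


@dataclass(frozen=True)
class KeyRegistry:
    """Ordered, versioned collection of :class:`SubstructureKey`."""

    keys: tuple[SubstructureKey, ...]
    version: str

    def __post_init__(self) -> None:
        names = [k.name for k in self.keys]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise RegistryError(f"duplicate key names: {dupes}")
        for pos, key in enumerate(self.keys):
            if key.index != pos:
                raise RegistryError(
                    f"key {key.name!r} has index {key.index}, expected {pos}"
                )

    def __len__(self) -> int:
        return len(self.keys)

    def __iter__(self) -> Iterator[SubstructureKey]:
        return iter(self.keys)

    def __getitem__(self, item: int | str) -> SubstructureKey:
        if isinstance(item, str):
            for key in self.keys:
                if key.name == item:
                    return key
            raise KeyError(item)
        return self.keys[item]

    def __contains__(self, name: object) -> bool:
        return any(k.name == name for k in self.keys)

    @property
    def names(self) -> list[str]:
        return [k.name for k in self.keys]

    @property
    def dewick_blocks(self) -> list[SubstructureKey]:
        return [k for k in self.keys if k.is_dewick_block]

    def pathway_of(self, name: str) -> str:
        return self[name].pathway

    def subset(self, names: Sequence[str]) -> "KeyRegistry":
        """New registry restricted to ``names`` (re-indexed, order kept)."""
        missing = [n for n in names if n not in self]
        if missing:
            raise RegistryError(f"unknown key names: {missing}")
        kept = [k for k in self.keys if k.name in set(names)]
        return KeyRegistry(
            keys=tuple(replace(k, index=i) for i, k in enumerate(kept)),
            version=f"{self.version}+subset{len(kept)}",
        )

    def to_records(self) -> list[dict]:
        return [
            {
                "index": k.index,
                "name": k.name,
                "group": k.group,
                "pathway": k.pathway,
                "smarts_raw": k.smarts_raw,
                "is_dewick_block": k.is_dewick_block,
            }
            for k in self.keys
        ]

    def save(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(
                {"version": self.version, "keys": self.to_records()}, handle, indent=1
            )


def _registry_from_payload(payload: dict, *, expect_default: bool = False) -> KeyRegistry:
    try:
        version = payload["version"]
        raw_keys = payload["keys"]
    except (KeyError, TypeError) as exc:
        raise RegistryError(f"registry payload malformed: {exc}") from exc
    keys = []
    for pos, rec in enumerate(raw_keys):
        raw = rec["smarts_raw"]
        keys.append(
            SubstructureKey(
                index=pos,
                name=rec["name"],
                group=rec["group"],
                pathway=rec["pathway"],
                smarts_raw=raw,
                smarts_relaxed=relax_bond_orders(raw),
                is_dewick_block=bool(rec.get("is_dewick_block", False)),
            )
        )
    registry = KeyRegistry(keys=tuple(keys), version=version)
    if expect_default and len(registry) != 39:
        raise RegistryError(
            f"default registry must define 39 keys, found {len(registry)}"
        )
    return registry


_DEFAULT_REGISTRY: KeyRegistry | None = None


def load_default_registry() -> KeyRegistry:
    """Load the built-in 39-key registry (cached after the first call)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        text = resources.files("biosynkey.data").joinpath("registry.json").read_text()
        _DEFAULT_REGISTRY = _registry_from_payload(json.loads(text), expect_default=True)
    return _DEFAULT_REGISTRY


def load_registry(path) -> KeyRegistry:
    """Load a registry from a JSON file produced by :meth:`KeyRegistry.save`."""
    with open(path) as handle:
        return _registry_from_payload(json.load(handle))


def customise_registry(
    registry: KeyRegistry,
    add: Iterable[SubstructureKey] = (),
    remove: Iterable[str] = (),
) -> KeyRegistry:
    """Return a new registry with keys added and/or removed.

    Indices are re-assigned contiguously (removed keys close the gap, added
    keys are appended in the order given) and the version string records the
    edit.  The input registry is not modified.  All validation problems are
    collected and reported together.
    """
    add = list(add)
    remove = list(remove)
    problems: list[str] = []
    existing = set(registry.names)
    for name in remove:
        if name not in existing:
            problems.append(f"cannot remove unknown key {name!r}")
    seen_new = set()
    for key in add:
        if key.name in existing and key.name not in remove:
            problems.append(f"cannot add duplicate key {key.name!r}")
        if key.name in seen_new:
            problems.append(f"key {key.name!r} added twice")
        seen_new.add(key.name)
        try:
            relax_bond_orders(key.smarts_raw)
        except SmartsParseError as exc:
            problems.append(f"key {key.name!r}: {exc}")
    if problems:
        raise RegistryError("; ".join(problems))

    removed = set(remove)
    kept = [k for k in registry.keys if k.name not in removed]
    merged = kept + [
        replace(k, smarts_relaxed=relax_bond_orders(k.smarts_raw)) for k in add
    ]
    reindexed = tuple(replace(k, index=i) for i, k in enumerate(merged))
    suffix = f"+{len(add)}-{len(remove)}" if (add or remove) else ""
    return KeyRegistry(keys=reindexed, version=f"{registry.version}{suffix}")
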