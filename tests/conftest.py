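"""Shared fixtures, including an independent subgraph-match oracle.

The oracle counts distinct atom sets matching a relaxed pattern by naive
backtracking (networkx monomorphism search over the molecular graph),
parsing the pattern text itself — it shares no matching code with the
production path.
"""

from __future__ import annotations

import re

import networkx as nx
import pytest
from networkx.algorithms import isomorphism
from rdkit import Chem

from biosynkey import fixtures, keyset

_ATOM_BODY = re.compile(r"#(?P<elem>\d+)(?P<rest>.*)$")
_H_CONSTRAINT = re.compile(r"H(\d?)")
_D_CONSTRAINT = re.compile(r"D(\d+)")


def _parse_pattern(relaxed: str) -> nx.Graph:
    """Pattern graph from relaxed SMARTS (bracket atoms, '~' bonds only)."""
    graph = nx.Graph()
    stack: list[int] = []
    ring_open: dict[str, int] = {}
    prev: int | None = None
    idx = 0
    i = 0
    while i < len(relaxed):
        ch = relaxed[i]
        if ch == "[":
            j = relaxed.index("]", i)
            body = relaxed[i + 1 : j]
            m = _ATOM_BODY.match(body)
            assert m, f"oracle cannot parse atom [{body}]"
            elem = int(m.group("elem"))
            rest = m.group("rest")
            h = _H_CONSTRAINT.search(rest)
            d = _D_CONSTRAINT.search(rest)
            graph.add_node(
                idx,
                elem=elem,
                h=int(h.group(1) or 1) if h else None,
                degree=int(d.group(1)) if d else None,
            )
            if prev is not None:
                graph.add_edge(prev, idx)
            prev = idx
            idx += 1
            i = j + 1
        elif ch == "~":
            i += 1  # bond itself carries no constraint
        elif ch.isdigit() or ch == "%":
            label = relaxed[i : i + 3] if ch == "%" else ch
            if label in ring_open:
                graph.add_edge(ring_open.pop(label), prev)
            else:
                ring_open[label] = prev
            i += len(label)
        elif ch == "(":
            stack.append(prev)
            i += 1
        elif ch == ")":
            prev = stack.pop()
            i += 1
        elif ch == ".":
            prev = None
            i += 1
        else:
            raise AssertionError(f"oracle cannot parse {ch!r} in {relaxed!r}")
    return graph


def _mol_graph(mol: Chem.Mol) -> nx.Graph:
    graph = nx.Graph()
    for atom in mol.GetAtoms():
        graph.add_node(
            atom.GetIdx(),
            elem=atom.GetAtomicNum(),
            h=atom.GetTotalNumHs(),
            degree=atom.GetDegree(),
        )
    for bond in mol.GetBonds():
        graph.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    return graph


def oracle_count(mol: Chem.Mol, relaxed_smarts: str) -> int:
    """Distinct atom sets of `mol` matching the pattern, by brute force."""
    pattern = _parse_pattern(relaxed_smarts)
    if pattern.number_of_nodes() == 0:
        return 0

    def node_match(mol_attrs, pat_attrs):
        if mol_attrs["elem"] != pat_attrs["elem"]:
            return False
        if pat_attrs["h"] is not None and mol_attrs["h"] != pat_attrs["h"]:
            return False
        if pat_attrs["degree"] is not None and mol_attrs["degree"] != pat_attrs["degree"]:
            return False
        return True

    matcher = isomorphism.GraphMatcher(_mol_graph(mol), pattern, node_match=node_match)
    return len({frozenset(m) for m in matcher.subgraph_monomorphisms_iter()})


@pytest.fixture(scope="session")
def oracle():
    return oracle_count


@pytest.fixture(scope="session")
def registry():
    return keyset.load_default_registry()


@pytest.fixture(scope="session")
def small_records():
    return fixtures.small_molecule_records()
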