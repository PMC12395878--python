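"""Biosynthetic-distance benchmark built from reaction chains.

A pathway is a directed graph of substrate → product reaction edges.  The
benchmark keeps pathways that are at least six reactions long and contain
at least one known natural product (matched by InChI skeleton), extracts
the longest simple reaction chain per pathway, and enumerates compound
pairs (x, x+n) separated by n = 1..6 reactions.  Fingerprint similarity is
then summarised per n; a shuffled-pair control provides each method's
baseline similarity.  A fingerprint that tracks biosynthesis should show
similarity decaying smoothly with n and a control well below the n = 1
distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import DataStructs, MACCSkeys, rdFingerprintGenerator

from .fingerprint import fingerprint_molecule
from .keyset import KeyRegistry
from .similarity import multiset_tanimoto
from .structio import MoleculeRecord, SkeletonKey, skeleton_key

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayGraph",
    "ReactionChain",
    "DistancePair",
    "DecayCurve",
    "filter_pathways",
    "longest_chain",
    "generate_pairs",
    "shuffle_control",
    "decay_curve",
    "read_pathways",
    "DEFAULT_METHODS",
]

N_MAX = 6  # benchmark horizon: pairs up to six reactions apart
MIN_REACTIONS = 6  # pathway filter: at least six reactions long


@dataclass(frozen=True)
class PathwayGraph:
    """One pathway: compounds (with structures) and substrate→product edges."""

    pathway_id: str
    nodes: dict[str, MoleculeRecord]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for sub, prod in self.edges:
            if sub not in self.nodes or prod not in self.nodes:
                raise ValueError(
                    f"pathway {self.pathway_id!r}: edge ({sub!r}, {prod!r}) "
                    "references a missing node"
                )

    @property
    def reaction_count(self) -> int:
        return len(self.edges)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class ReactionChain:
    """Ordered compounds c0..cL joined by single reactions; length L."""

    pathway_id: str
    compounds: tuple[MoleculeRecord, ...]

    @property
    def length(self) -> int:
        return len(self.compounds) - 1


@dataclass(frozen=True)
class DistancePair:
    """Two compounds separated by ``n_reactions`` enzymatic steps."""

    compound_a: MoleculeRecord
    compound_b: MoleculeRecord
    n_reactions: int
    is_control: bool = False


def read_pathways(edge_table: pd.DataFrame, structures: dict[str, MoleculeRecord]) -> list[PathwayGraph]:
    """Assemble pathway graphs from an edge list table.

    ``edge_table`` needs columns pathway_id, substrate_id, product_id;
    ``structures`` maps compound ids to parsed records.  Edges whose
    compounds lack a structure are dropped with a warning.
    """
    required = {"pathway_id", "substrate_id", "product_id"}
    if not required.issubset(edge_table.columns):
        raise ValueError(f"edge table must have columns {sorted(required)}")
    graphs = []
    for pid, sub_table in edge_table.groupby("pathway_id", sort=True):
        edges = []
        nodes: dict[str, MoleculeRecord] = {}
        for _, row in sub_table.iterrows():
            a, b = str(row["substrate_id"]), str(row["product_id"])
            if a not in structures or b not in structures:
                logger.warning("pathway %s: dropping edge (%s, %s) without structures", pid, a, b)
                continue
            nodes[a] = structures[a]
            nodes[b] = structures[b]
            edges.append((a, b))
        if edges:
            graphs.append(PathwayGraph(pathway_id=str(pid), nodes=nodes, edges=tuple(edges)))
    return graphs


def filter_pathways(
    graphs: Iterable[PathwayGraph],
    natural_product_refs: Sequence[MoleculeRecord],
    min_reactions: int = MIN_REACTIONS,
) -> list[PathwayGraph]:
    """Keep pathways ≥ ``min_reactions`` long containing ≥ 1 natural product.

    Natural-product membership is decided by InChI-skeleton identity
    against the reference records (constitution match, stereo ignored).
    """
    ref_keys: set[SkeletonKey] = set()
    for rec in natural_product_refs:
        try:
            ref_keys.add(skeleton_key(rec))
        except Exception as exc:
            logger.warning("reference record %r dropped: %s", rec.id, exc)
    kept = []
    for graph in graphs:
        if graph.reaction_count < min_reactions:
            continue
        has_np = any(
            _safe_skeleton(rec) in ref_keys for rec in graph.nodes.values()
        )
        if has_np:
            kept.append(graph)
    if not kept:
        logger.warning("no pathways passed the filter")
    return kept


def _safe_skeleton(rec: MoleculeRecord) -> SkeletonKey | None:
    try:
        return skeleton_key(rec)
    except Exception:
        return None


def longest_chain(graph: PathwayGraph) -> ReactionChain:
    """Maximum-length simple directed path through the pathway.

    Ties are broken by the lexicographically smallest compound-id sequence.
    Cycles are handled by the simple-path constraint (no node revisited).
    """
    if not graph.edges:
        raise ValueError(f"pathway {graph.pathway_id!r} has no edges")
    g = graph.to_digraph()
    best: list[str] | None = None

    def extend(path: list[str], seen: set[str]) -> None:
        nonlocal best
        extended = False
        for nxt in sorted(g.successors(path[-1])):
            if nxt not in seen:
                extended = True
                path.append(nxt)
                seen.add(nxt)
                extend(path, seen)
                seen.remove(nxt)
                path.pop()
        if not extended:  # maximal path; compare against the incumbent
            if (
                best is None
                or len(path) > len(best)
                or (len(path) == len(best) and path < best)
            ):
                best = list(path)

    for start in sorted(g.nodes):
        extend([start], {start})
    assert best is not None
    return ReactionChain(
        pathway_id=graph.pathway_id,
        compounds=tuple(graph.nodes[n] for n in best),
    )


def generate_pairs(chain: ReactionChain, n_max: int = N_MAX) -> list[DistancePair]:
    """All (c_x, c_{x+n}) pairs with 1 ≤ n ≤ min(n_max, L − x).

    Every position serves as a start, so a chain of L reactions yields
    L − n + 1 pairs at distance n.
    """
    if chain.length < 1:
        raise ValueError("chain must contain at least one reaction")
    pairs = []
    compounds = chain.compounds
    length = chain.length
    for n in range(1, min(n_max, length) + 1):
        for x in range(length - n + 1):
            pairs.append(
                DistancePair(
                    compound_a=compounds[x],
                    compound_b=compounds[x + n],
                    n_reactions=n,
                )
            )
    return pairs


def shuffle_control(pairs: Sequence[DistancePair], seed: int) -> list[DistancePair]:
    """Control pairs: second partners permuted uniformly at random.

    The multiset of partner molecules is preserved; permutations that pair
    a compound with itself (identical InChI skeleton) are re-drawn.  Fails
    if no self-free permutation exists (e.g. all molecules identical).
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs to shuffle")
    rng = np.random.default_rng(seed)
    firsts = [p.compound_a for p in pairs]
    seconds = [p.compound_b for p in pairs]
    first_keys = [_safe_skeleton(r) for r in firsts]
    second_keys = [_safe_skeleton(r) for r in seconds]
    if all(
        fk is not None and fk == sk for fk in first_keys for sk in second_keys
    ):
        raise ValueError("impossible derangement: all molecules are identical")
    for _ in range(1000):
        perm = rng.permutation(len(pairs))
        if all(first_keys[i] != second_keys[perm[i]] for i in range(len(pairs))):
            return [
                DistancePair(
                    compound_a=firsts[i],
                    compound_b=seconds[perm[i]],
                    n_reactions=pairs[i].n_reactions,
                    is_control=True,
                )
                for i in range(len(pairs))
            ]
    raise ValueError("could not find a self-free shuffle in 1000 attempts")


# ---------------------------------------------------------------------------
# Similarity decay summary
# ---------------------------------------------------------------------------

_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
_RDKIT_GEN = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)


def _binary_sim(method: str) -> Callable[[Chem.Mol, Chem.Mol], float]:
    def generator(mol: Chem.Mol):
        if method == "morgan":
            return _MORGAN_GEN.GetFingerprint(mol)
        if method == "rdkit":
            return _RDKIT_GEN.GetFingerprint(mol)
        if method == "maccs":
            return MACCSkeys.GenMACCSKeys(mol)
        raise ValueError(f"unknown baseline method {method!r}")

    cache: dict[int, object] = {}

    def sim(a: Chem.Mol, b: Chem.Mol) -> float:
        fa = cache.get(id(a))
        if fa is None:
            fa = cache[id(a)] = generator(a)
        fb = cache.get(id(b))
        if fb is None:
            fb = cache[id(b)] = generator(b)
        return DataStructs.TanimotoSimilarity(fa, fb)

    return sim


DEFAULT_METHODS = ("biosynfoni", "morgan", "rdkit", "maccs")


@dataclass
class DecayCurve:
    """Similarity distributions per reaction distance and per method."""

    per_n: dict[str, dict[int, list[float]]]  # method -> n -> similarities
    control: dict[str, list[float]]  # method -> similarities
    n_max: int = N_MAX

    def medians(self) -> pd.DataFrame:
        """Median similarity per method (rows) and distance n (columns)."""
        data = {}
        for method, by_n in self.per_n.items():
            data[method] = {n: float(np.median(v)) for n, v in by_n.items() if v}
        frame = pd.DataFrame(data).T
        frame = frame.reindex(sorted(frame.columns), axis=1)
        return frame

    def control_medians(self) -> pd.Series:
        return pd.Series(
            {m: float(np.median(v)) for m, v in self.control.items() if v}
        )

    def to_frame(self) -> pd.DataFrame:
        """Long format: method, n (0 for control), similarity, is_control."""
        rows = []
        for method, by_n in self.per_n.items():
            for n, sims in by_n.items():
                rows.extend(
                    {"method": method, "n": n, "similarity": s, "is_control": False}
                    for s in sims
                )
        for method, sims in self.control.items():
            rows.extend(
                {"method": method, "n": 0, "similarity": s, "is_control": True}
                for s in sims
            )
        return pd.DataFrame(rows, columns=["method", "n", "similarity", "is_control"])


def decay_curve(
    pairs: Sequence[DistancePair],
    control: Sequence[DistancePair],
    registry: KeyRegistry,
    methods: Sequence[str] = DEFAULT_METHODS,
) -> DecayCurve:
    """Similarity of every pair (and control pair) under each fingerprint.

    The counted biosynthetic fingerprint is compared with the multiset
    Tanimoto coefficient; baseline fingerprints (Morgan radius-2 2048-bit,
    Daylight-style path 2048-bit, 167-key MACCS) with the binary one.
    """
    if not pairs:
        raise ValueError("no pairs to evaluate")

    def make_scorer(method: str) -> Callable[[Chem.Mol, Chem.Mol], float]:
        if method == "biosynfoni":
            fp_cache: dict[int, np.ndarray] = {}

            def scorer(a: Chem.Mol, b: Chem.Mol) -> float:
                ca = fp_cache.get(id(a))
                if ca is None:
                    ca = fp_cache[id(a)] = fingerprint_molecule(a, registry).counts
                cb = fp_cache.get(id(b))
                if cb is None:
                    cb = fp_cache[id(b)] = fingerprint_molecule(b, registry).counts
                return multiset_tanimoto(ca, cb)

            return scorer
        return _binary_sim(method)

    per_n: dict[str, dict[int, list[float]]] = {}
    control_sims: dict[str, list[float]] = {}
    for method in methods:
        scorer = make_scorer(method)
        by_n: dict[int, list[float]] = {}
        ok = True
        try:
            for pair in pairs:
                by_n.setdefault(pair.n_reactions, []).append(
                    scorer(pair.compound_a.mol, pair.compound_b.mol)
                )
            csims = [
                scorer(p.compound_a.mol, p.compound_b.mol) for p in control
            ]
        except Exception as exc:
            logger.warning("method %r omitted: %s", method, exc)
            ok = False
        if ok:
            per_n[method] = by_n
            control_sims[method] = csims
    if not per_n:
        raise ValueError("no method produced any similarities")
    return DecayCurve(per_n=per_n, control=control_sims)
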