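"""Structural analysis: interaction matrix, connectivity census, dependencies.

The dependency classification works on the signed species digraph induced by
the hypergraph (one edge per tail literal, signed by the literal): an ordered
pair (a, b) is an *activator* relation when every signed walk from a to b has
positive parity (even number of inhibiting edges), an *inhibitor* when all
walks are negative, *ambivalent* when both parities are reachable and *none*
without any walk.  Parity reachability is computed by breadth-first search on
the parity-doubled graph.  A relation is *complete* when a walk of the
deciding sign exists that uses only cofactor-free edges (single-literal
interactions); otherwise the influence needs co-factors and is *incomplete*.
Structure is cutoff-independent by default; a cutoff filter is available.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .logic import LogicalNetwork

__all__ = [
    "InteractionMatrix",
    "DependencyMatrix",
    "interaction_matrix",
    "sources_and_sinks",
    "dependency_matrix",
    "signed_edges",
]

PRODUCT = "product"
ACTIVATOR = "activating-participant"
INHIBITOR = "inhibiting-participant"
NONE = ""

RELATIONS = (
    "complete-activator",
    "incomplete-activator",
    "complete-inhibitor",
    "incomplete-inhibitor",
    "ambivalent",
    "none",
)


@dataclass(frozen=True)
class InteractionMatrix:
    """Species x interaction participation grid with per-species connectivity."""

    frame: pd.DataFrame  # rows: species, columns: arc ids
    connectivity: pd.Series

    def cell(self, species: str, arc_id: int) -> str:
        return self.frame.at[species, arc_id]

    def to_tsv(self, path=None):
        out = self.frame.copy()
        out["connectivity"] = self.connectivity
        text = out.to_csv(sep="\t")
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(text)


def interaction_matrix(net: LogicalNetwork) -> InteractionMatrix:
    """Participation of every species in every interaction.

    Logic and stimulus arcs have exactly one ``product`` cell (the target);
    the declared-output row has only its participant cell.  Connectivity is
    the number of interactions a species appears in, matching the published
    per-species connection counts.
    """
    species = list(net.species_order())
    arc_ids = [a.id for a in net.arcs]
    frame = pd.DataFrame(NONE, index=pd.Index(species, name="Species"),
                         columns=arc_ids)
    for arc in net.arcs:
        for lit in arc.tail:
            frame.at[lit.species, arc.id] = INHIBITOR if lit.negated else ACTIVATOR
        if arc.target is not None:
            frame.at[arc.target, arc.id] = PRODUCT
    connectivity = (frame != NONE).sum(axis=1)
    connectivity.name = "connectivity"
    return InteractionMatrix(frame, connectivity)


def sources_and_sinks(net: LogicalNetwork):
    """Species without predecessors (sources) / successors (sinks).

    Sinks never appear as a tail literal; sources are never the target of any
    interaction (the stimulus switches count as producing their input species,
    so declared inputs are excluded automatically).  Both lists carry the
    species' connectivity count.  Species touching no interaction at all are
    reported in neither list.
    """
    in_tail: set[str] = set()
    targeted: set[str] = set()
    involved: dict[str, int] = {}
    for arc in net.arcs:
        for name in arc.species_involved():
            involved[name] = involved.get(name, 0) + 1
        for lit in arc.tail:
            in_tail.add(lit.species)
        if arc.target is not None:
            targeted.add(arc.target)
    sources = [
        (name, involved[name])
        for name in net.species_order()
        if name in involved and name not in targeted
    ]
    sinks = [
        (name, involved[name])
        for name in net.species_order()
        if name in involved and name not in in_tail
    ]
    return sources, sinks


def signed_edges(net: LogicalNetwork, cutoff: Optional[int] = None):
    """Signed influence edges (source, target, negated, cofactor_free)."""
    edges = []
    for arc in net.arcs:
        if arc.kind != "logic":
            continue
        if cutoff is not None and arc.timescale > cutoff:
            continue
        single = len(arc.tail) == 1
        for lit in arc.tail:
            edges.append((lit.species, arc.target, lit.negated, single))
    return edges


def _parity_reachable(adjacency, start):
    """BFS on the parity-doubled graph; returns {(node, parity), ...} reachable
    from ``start`` by walks of length >= 1."""
    seen = set()
    queue = deque()
    for (target, negated) in adjacency.get(start, ()):
        key = (target, 1 if negated else 0)
        if key not in seen:
            seen.add(key)
            queue.append(key)
    while queue:
        node, parity = queue.popleft()
        for (target, negated) in adjacency.get(node, ()):
            key = (target, parity ^ (1 if negated else 0))
            if key not in seen:
                seen.add(key)
                queue.append(key)
    return seen


@dataclass(frozen=True)
class DependencyMatrix:
    """Pairwise influence classification; ``frame.at[a, b]`` is the relation
    of affecting species a (row) on affected species b (column).  The matrix
    is generally non-symmetric."""

    frame: pd.DataFrame

    def relation(self, affecting: str, affected: str) -> str:
        return self.frame.at[affecting, affected]

    def to_tsv(self, path=None):
        text = self.frame.to_csv(sep="\t")
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(text)


def dependency_matrix(net: LogicalNetwork, cutoff: Optional[int] = None) -> DependencyMatrix:
    species = list(net.species_order())
    full: dict[str, list] = {}
    free: dict[str, list] = {}
    for src, dst, negated, single in signed_edges(net, cutoff):
        full.setdefault(src, []).append((dst, negated))
        if single:
            free.setdefault(src, []).append((dst, negated))

    frame = pd.DataFrame("none", index=pd.Index(species, name="affecting"),
                         columns=species)
    for a in species:
        reach = _parity_reachable(full, a)
        reach_free = _parity_reachable(free, a)
        for b in species:
            pos = (b, 0) in reach
            neg = (b, 1) in reach
            if pos and neg:
                rel = "ambivalent"
            elif pos:
                rel = ("complete-" if (b, 0) in reach_free else "incomplete-") + "activator"
            elif neg:
                rel = ("complete-" if (b, 1) in reach_free else "incomplete-") + "inhibitor"
            else:
                rel = "none"
            frame.at[a, b] = rel
    return DependencyMatrix(frame)
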