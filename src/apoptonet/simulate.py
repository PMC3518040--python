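"""Logical steady states, timescale snapshot tables, synchronous dynamics.

The central readout is the three-valued logical steady state (LSS): starting
from the clamped boundary (inputs, housekeeping constant, explicit clamps)
with every other species *undetermined*, species are fixed to 1 as soon as one
active interaction fires and to 0 once every active interaction is off (or
none exists).  The iteration is monotone in the Kleene information order and
converges to the least fixed point; species still undetermined at convergence
take cycle-dependent values (e.g. the Hog1/Ptp3 negative feedback without
osmotic stress) and are reported as such rather than given an order-dependent
binary value.

Every value determined by the LSS is provably constant across *all*
synchronous attractors of the same scenario, which is what the brute-force
:func:`enumerate_attractors` oracle checks on small networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .logic import (
    UNDETERMINED,
    HyperArc,
    LogicalNetwork,
    NetworkIntegrityError,
    evaluate_arc,
    kleene_or,
    update_value,
)

__all__ = [
    "Scenario",
    "ScenarioError",
    "StateTableError",
    "StateSpaceSizeError",
    "StateTable",
    "Attractor",
    "compute_lss",
    "snapshot_table",
    "synchronous_step",
    "synchronous_trajectory",
    "enumerate_attractors",
    "knockout_scan",
]


class ScenarioError(ValueError):
    """Inconsistent scenario configuration (e.g. contradictory clamps)."""


class StateTableError(ValueError):
    pass


class StateSpaceSizeError(ValueError):
    """Raised when exhaustive enumeration would exceed the state-space bound."""


@dataclass(frozen=True)
class Scenario:
    """An in-silico experiment: stimulus pattern plus perturbations.

    ``input_assignment``
        values for input species; unlisted inputs are 0.
    ``clamps``
        species held at a fixed value throughout (overexpression = clamp 1;
        value-knockdown = clamp 0).  Literals referencing a clamped species
        evaluate against the clamped value.
    ``deletions``
        gene deletions: the species is fixed at 0 *and* every hyperarc it
        participates in is disabled (a deleted protein cannot mediate its
        reactions).
    ``cutoffs``
        timescale snapshots for :func:`snapshot_table`.
    """

    input_assignment: Mapping[str, int] = field(default_factory=dict)
    clamps: Mapping[str, int] = field(default_factory=dict)
    deletions: tuple[str, ...] = ()
    cutoffs: tuple[int, ...] = (0, 4, 5, 6)

    def resolved(self, net: LogicalNetwork) -> "Scenario":
        """Canonicalize species names against ``net`` and validate."""
        inputs = {}
        for name, value in self.input_assignment.items():
            resolved = net.resolve(name)
            if net.species[resolved].role != "input":
                raise ScenarioError(f"{resolved!r} is not an input species")
            if value not in (0, 1):
                raise ScenarioError(f"input value for {resolved!r} must be 0 or 1")
            inputs[resolved] = value
        clamps = {}
        for name, value in self.clamps.items():
            resolved = net.resolve(name)
            if value not in (0, 1):
                raise ScenarioError(f"clamp value for {resolved!r} must be 0 or 1")
            if resolved in clamps and clamps[resolved] != value:
                raise ScenarioError(f"{resolved!r} clamped both 0 and 1")
            clamps[resolved] = value
        for name, value in clamps.items():
            if name in inputs and inputs[name] != value:
                raise ScenarioError(
                    f"{name!r} clamped to {value} but assigned input value {inputs[name]}"
                )
        deletions = tuple(dict.fromkeys(net.resolve(d) for d in self.deletions))
        for name in deletions:
            if clamps.get(name) == 1:
                raise ScenarioError(f"{name!r} both deleted and clamped to 1")
        cutoffs = tuple(self.cutoffs)
        if any(not 0 <= c <= 6 for c in cutoffs):
            raise ScenarioError(f"cutoffs {cutoffs} outside 0..6")
        if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
            raise ScenarioError(f"cutoffs {cutoffs} not strictly increasing")
        return Scenario(inputs, clamps, deletions, cutoffs)

    def fixed_values(self, net: LogicalNetwork) -> dict[str, int]:
        """Species whose value the scenario pins, with that value."""
        fixed = {}
        for name in net.inputs:
            fixed[name] = self.input_assignment.get(name, 0)
        for name in net.constants:
            fixed[name] = 1
        fixed.update(self.clamps)
        for name in self.deletions:
            fixed[name] = 0
        return fixed

    def effective_network(self, net: LogicalNetwork) -> LogicalNetwork:
        return net.with_deletions(self.deletions) if self.deletions else net


def compute_lss(net: LogicalNetwork, scen: Scenario, cutoff: int) -> dict:
    """Three-valued least-fixed-point logical steady state at ``cutoff``.

    Returns a mapping over every species; values are 0, 1 or
    :data:`~apoptonet.logic.UNDETERMINED` (``None``) for cycle-dependent
    species.
    """
    scen = scen.resolved(net)
    work = scen.effective_network(net)
    fixed = scen.fixed_values(net)
    state = {name: UNDETERMINED for name in net.species_order()}
    state.update(fixed)
    pending = [n for n in net.species_order() if n not in fixed]
    changed = True
    while changed:
        changed = False
        still = []
        for name in pending:
            value = update_value(name, work, state, cutoff)
            if value is UNDETERMINED:
                still.append(name)
            else:
                state[name] = value
                changed = True
        pending = still
    return state


@dataclass(frozen=True)
class StateTable:
    """Species x timescale-snapshot matrix of {0, 1, undetermined}."""

    species: tuple[str, ...]
    cutoffs: tuple[int, ...]
    cells: Mapping[tuple[str, int], Optional[int]]

    def value(self, species: str, cutoff: int):
        return self.cells[(species, cutoff)]

    def row(self, species: str) -> tuple:
        return tuple(self.cells[(species, c)] for c in self.cutoffs)

    def subset(self, species: Sequence[str]) -> "StateTable":
        names = tuple(species)
        missing = [s for s in names if s not in self.species]
        if missing:
            raise StateTableError(f"species not in table: {missing}")
        cells = {
            (s, c): self.cells[(s, c)] for s in names for c in self.cutoffs
        }
        return StateTable(names, self.cutoffs, cells)

    def to_frame(self) -> pd.DataFrame:
        data = {
            f"t={c}": [_render(self.cells[(s, c)]) for s in self.species]
            for c in self.cutoffs
        }
        return pd.DataFrame(data, index=pd.Index(self.species, name="Species"))

    def to_tsv(self, path=None) -> str | None:
        text = self.to_frame().to_csv(sep="\t")
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(text)
        return None

    @classmethod
    def from_tsv(cls, source) -> "StateTable":
        frame = pd.read_csv(source, sep="\t", index_col=0, dtype=str)
        cutoffs = tuple(int(col.split("=", 1)[1]) for col in frame.columns)
        species = tuple(frame.index)
        cells = {}
        for s in species:
            for col, c in zip(frame.columns, cutoffs):
                cells[(s, c)] = _unrender(frame.at[s, col])
        return cls(species, cutoffs, cells)


def _render(value) -> str:
    return "?" if value is UNDETERMINED else str(int(value))


def _unrender(text: str):
    return UNDETERMINED if text.strip() == "?" else int(text)


def snapshot_table(net: LogicalNetwork, scen: Scenario) -> StateTable:
    """One LSS column per scenario cutoff; each column is computed afresh with
    that cutoff's interaction set (snapshots are independent, not carried over)."""
    scen = scen.resolved(net)
    cells = {}
    for cutoff in scen.cutoffs:
        state = compute_lss(net, scen, cutoff)
        for name, value in state.items():
            cells[(name, cutoff)] = value
    return StateTable(net.species_order(), scen.cutoffs, cells)


def synchronous_step(
    net: LogicalNetwork, scen: Scenario, state: Mapping[str, int], cutoff: int
) -> dict:
    """One simultaneous update of every free species; fixed species held."""
    work = scen.effective_network(net)
    fixed = scen.fixed_values(net)
    new = {}
    for name in net.species_order():
        if name in fixed:
            new[name] = fixed[name]
        else:
            new[name] = update_value(name, work, state, cutoff)
    return new


def synchronous_trajectory(
    net: LogicalNetwork,
    scen: Scenario,
    initial: Mapping[str, int],
    cutoff: int,
    n_steps: int,
) -> list[dict]:
    """Synchronous state sequence of length ``n_steps + 1`` from ``initial``.

    ``initial`` must cover every species with binary values; scenario-fixed
    species are overridden by their scenario values from step 0 on.
    """
    scen = scen.resolved(net)
    missing = [n for n in net.species_order() if n not in initial]
    if missing:
        raise ScenarioError(f"initial state misses species {missing[:3]}...")
    if any(initial[n] not in (0, 1) for n in net.species_order()):
        raise ScenarioError("initial state must be binary (no undetermined)")
    state = {n: initial[n] for n in net.species_order()}
    state.update(scen.fixed_values(net))
    out = [state]
    for _ in range(n_steps):
        state = synchronous_step(net, scen, state, cutoff)
        out.append(state)
    return out


@dataclass(frozen=True)
class Attractor:
    """A synchronous attractor: one state (point) or a cycle of states."""

    states: tuple
    basin_size: int = 0

    def __len__(self) -> int:
        return len(self.states)

    @property
    def is_point(self) -> bool:
        return len(self.states) == 1


def _compile_successor(net, scen, cutoff):
    """Bitmask transition function over the free species of a scenario."""
    work = scen.effective_network(net)
    fixed = scen.fixed_values(net)
    order = net.species_order()
    free = [n for n in order if n not in fixed]
    index = {n: i for i, n in enumerate(free)}

    # Per free species: list of (pos_mask, neg_mask) over free bits for each
    # active arc, with fixed-species literals pre-resolved.
    compiled: list[list[tuple[int, int]] | None] = []
    for name in free:
        arcs = []
        for arc in work.arcs_targeting(name, cutoff):
            if arc.dose_gated:
                continue
            pos = neg = 0
            dead = False
            for lit in arc.tail:
                if lit.species in fixed:
                    value = fixed[lit.species]
                    if (value == 0) != lit.negated:  # literal is false
                        dead = True
                        break
                    continue  # literal always true: drop
                bit = 1 << index[lit.species]
                if lit.negated:
                    neg |= bit
                else:
                    pos |= bit
            if not dead:
                arcs.append((pos, neg))
        compiled.append(arcs)

    def successor(x: int) -> int:
        y = 0
        for i, arcs in enumerate(compiled):
            for pos, neg in arcs:
                if (x & pos) == pos and (x & neg) == 0:
                    y |= 1 << i
                    break
        return y

    return free, fixed, successor


def enumerate_attractors(
    net: LogicalNetwork, scen: Scenario, cutoff: int, bound: int = 22
) -> list[Attractor]:
    """All synchronous attractors with exact basin sizes, by exhaustive
    transition-graph traversal over the free (unclamped, non-input) species.

    Deterministic ordering: attractors sorted by their lexicographically
    smallest state (species-table order); cycles are rotated to start there.
    """
    scen = scen.resolved(net)
    free, fixed, successor = _compile_successor(net, scen, cutoff)
    if len(free) > bound:
        raise StateSpaceSizeError(
            f"{len(free)} free species exceed the enumeration bound {bound}; "
            "clamp or subset the network"
        )
    size = 1 << len(free)
    # color: 0 unvisited, else 1+attractor id once resolved
    attractor_of = [-1] * size
    attractors: list[list[int]] = []
    for start in range(size):
        if attractor_of[start] >= 0:
            continue
        path = []
        seen_at = {}
        x = start
        while attractor_of[x] < 0 and x not in seen_at:
            seen_at[x] = len(path)
            path.append(x)
            x = successor(x)
        if attractor_of[x] >= 0:
            aid = attractor_of[x]
        else:  # new cycle discovered within path
            aid = len(attractors)
            attractors.append(path[seen_at[x]:])
        for state in path:
            attractor_of[state] = aid

    basins = [0] * len(attractors)
    for aid in attractor_of:
        basins[aid] += 1

    order = net.species_order()

    def decode(x: int) -> dict:
        state = dict(fixed)
        for i, name in enumerate(free):
            state[name] = (x >> i) & 1
        return {n: state[n] for n in order}

    def state_key(x: int) -> tuple:
        state = decode(x)
        return tuple(state[n] for n in order)

    results = []
    for aid, cycle in enumerate(attractors):
        pivot = min(range(len(cycle)), key=lambda i: state_key(cycle[i]))
        rotated = cycle[pivot:] + cycle[:pivot]
        results.append(
            Attractor(tuple(decode(x) for x in rotated), basins[aid])
        )
    results.sort(key=lambda a: tuple(a.states[0][n] for n in order))
    return results


def knockout_scan(
    net: LogicalNetwork,
    base: Scenario,
    targets: Iterable[str],
    readout: str,
    cutoff: int,
    mode: str = "clamp",
) -> dict:
    """Readout LSS value under single perturbation of each target.

    ``mode="clamp"`` fixes the target at 0 (value knockdown); ``mode="delete"``
    removes the gene entirely (value 0 and all mediated interactions gone).
    """
    if mode not in ("clamp", "delete"):
        raise ValueError(f"unknown knockout mode {mode!r}")
    readout = net.resolve(readout)
    results = {}
    for target in targets:
        target = net.resolve(target)
        if mode == "clamp":
            scen = replace(base, clamps={**dict(base.clamps), target: 0})
        else:
            scen = replace(base, deletions=tuple(base.deletions) + (target,))
        results[target] = compute_lss(net, scen, cutoff)[readout]
    return results
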