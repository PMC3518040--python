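"""Shared helpers: tiny hand-built networks and brute-force oracles."""

import itertools

from apoptonet.logic import HyperArc, Literal, LogicalNetwork, SpeciesNode
from apoptonet.simulate import synchronous_step


def toy(species, arcs, inputs=()):
    nodes = [
        SpeciesNode(n, "input" if n in inputs else "other",
                    "input" if n in inputs else "internal")
        for n in species
    ]
    return LogicalNetwork(nodes, arcs)


def arc(i, expr_tail, target, ts=4):
    tail = tuple(
        Literal(name.lstrip("!"), name.startswith("!")) for name in expr_tail
    )
    return HyperArc(i, tail, target, ts)


def all_binary_states(net, fixed):
    free = [n for n in net.species_order() if n not in fixed]
    for bits in itertools.product((0, 1), repeat=len(free)):
        state = dict(fixed)
        state.update(zip(free, bits))
        yield state


def naive_attractors(net, scen, cutoff):
    """Independent orbit tracer: follow the synchronous map from every state
    using the dict-based step function until a state repeats."""
    scen = scen.resolved(net)
    fixed = scen.fixed_values(net)
    order = net.species_order()
    found = {}
    for state in all_binary_states(net, fixed):
        seen = []
        keys = {}
        current = dict(state, **fixed)
        while True:
            key = tuple(current[n] for n in order)
            if key in keys:
                cycle = seen[keys[key]:]
                pivot = min(range(len(cycle)), key=lambda i: cycle[i])
                rotated = tuple(cycle[pivot:] + cycle[:pivot])
                found.setdefault(rotated, 0)
                found[rotated] += 1
                break
            keys[key] = len(seen)
            seen.append(key)
            current = synchronous_step(net, scen, current, cutoff)
    return found
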