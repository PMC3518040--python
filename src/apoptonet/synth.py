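"""Seeded random signed logical hypergraphs for property testing.

The generator emulates the structural statistics of the encoded apoptosis
network — predominantly single-literal interactions (mean tail size around
1.16) with roughly 17% negated literals — at configurable size, so the
steady-state engine can be checked against brute-force oracles on thousands
of small instances without any external data.

Sampling uses a single explicitly threaded :class:`random.Random` source and
integer-only draws, so a seed reproduces the same network on any platform.
Tail-size and sign proportions are allocated by deterministic quota rather
than independent coin flips: a requested fraction is hit exactly (up to
rounding) for every seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .logic import Literal, HyperArc, LogicalNetwork, SpeciesNode, TIMESCALES

__all__ = ["GeneratorConfig", "GeneratorError", "random_network",
           "yeast_like_suite", "arc_statistics"]


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the random-network generator.

    ``p_negated`` and ``p_multi`` are target fractions (of negated literals
    and of arcs with tail size > 1) allocated by quota; defaults mirror the
    yeast model's histogram.
    """

    n_species: int
    n_arcs: int
    max_tail: int = 2
    p_negated: float = 0.17
    n_inputs: int = 1
    seed: int = 0
    p_multi: float = 0.16

    def validate(self) -> None:
        if self.n_species < 2:
            raise GeneratorError("need at least two species")
        if not 0 <= self.n_inputs < self.n_species:
            raise GeneratorError("n_inputs must be < n_species")
        if not 1 <= self.max_tail < self.n_species:
            raise GeneratorError("max_tail must be in [1, n_species)")
        if not 0 <= self.p_negated <= 1 or not 0 <= self.p_multi <= 1:
            raise GeneratorError("fractions must lie in [0, 1]")
        n_targets = self.n_species - self.n_inputs
        if self.n_arcs > n_targets * (self.n_species - 1):
            raise GeneratorError(
                f"{self.n_arcs} arcs infeasible for {self.n_species} species "
                f"with {self.n_inputs} inputs"
            )


def random_network(cfg: GeneratorConfig) -> LogicalNetwork:
    """Deterministic-for-a-seed random network satisfying every invariant:
    arcs never target inputs, tails have no duplicates, no self-loops."""
    cfg.validate()
    rng = random.Random(cfg.seed)
    inputs = [f"IN{i + 1}" for i in range(cfg.n_inputs)]
    internal = [f"S{i + 1}" for i in range(cfg.n_species - cfg.n_inputs)]
    species = [SpeciesNode(n, "input", "input") for n in inputs] + [
        SpeciesNode(n, "other", "internal") for n in internal
    ]
    names = inputs + internal

    n_multi = round(cfg.p_multi * cfg.n_arcs) if cfg.max_tail > 1 else 0
    sizes = [rng.randint(2, cfg.max_tail) for _ in range(n_multi)]
    sizes += [1] * (cfg.n_arcs - n_multi)
    rng.shuffle(sizes)

    seen: set[tuple] = set()
    tails: list[tuple[str, ...]] = []
    targets: list[str] = []
    attempts = 0
    for size in sizes:
        while True:
            attempts += 1
            if attempts > 200 * cfg.n_arcs:
                raise GeneratorError(
                    "could not place all arcs without duplicates; "
                    "lower n_arcs or raise n_species"
                )
            target = internal[rng.randrange(len(internal))]
            pool = [n for n in names if n != target]
            tail = tuple(sorted(rng.sample(pool, size)))
            key = (target, tail)
            if key not in seen:
                seen.add(key)
                tails.append(tail)
                targets.append(target)
                break

    slots = [(i, j) for i, tail in enumerate(tails) for j in range(len(tail))]
    n_negated = round(cfg.p_negated * len(slots))
    negated = set(rng.sample(slots, n_negated))

    arcs = []
    for i, (tail, target) in enumerate(zip(tails, targets)):
        literals = tuple(
            Literal(sp, (i, j) in negated) for j, sp in enumerate(tail)
        )
        arcs.append(
            HyperArc(
                id=i + 1, tail=literals, target=target,
                timescale=TIMESCALES[rng.randrange(len(TIMESCALES))],
            )
        )
    return LogicalNetwork(species, arcs, name=f"random-{cfg.seed}")


def yeast_like_suite(
    n_networks: int, seed: int, max_species: int = 12
) -> list[LogicalNetwork]:
    """Reproducible battery of small networks for oracle-equivalence tests."""
    master = random.Random(seed)
    suite = []
    for _ in range(n_networks):
        n = master.randint(5, max_species)
        cfg = GeneratorConfig(
            n_species=n,
            n_arcs=master.randint(n, 2 * n),
            max_tail=2,
            p_negated=0.17,
            n_inputs=master.randint(1, max(1, n // 4)),
            seed=master.randrange(2 ** 31),
        )
        suite.append(random_network(cfg))
    return suite


def arc_statistics(net: LogicalNetwork) -> dict:
    """Tail-size histogram and negated-literal fraction of the logic arcs."""
    sizes: dict[int, int] = {}
    literals = 0
    negated = 0
    for arc in net.arcs:
        if arc.kind != "logic":
            continue
        sizes[len(arc.tail)] = sizes.get(len(arc.tail), 0) + 1
        for lit in arc.tail:
            literals += 1
            negated += lit.negated
    return {
        "tail_sizes": dict(sorted(sizes.items())),
        "mean_tail": sum(k * v for k, v in sizes.items()) / max(sum(sizes.values()), 1),
        "negated_fraction": negated / literals if literals else 0.0,
    }
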