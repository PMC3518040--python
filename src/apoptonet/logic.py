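"""Domain types for timed signed logical hypergraphs and three-valued evaluation.

A network is a collection of species (nodes) and hyperarcs.  Each hyperarc is an
AND-conjunction of signed literals producing one target species, annotated with a
discrete *timescale* label: simulating the network at cutoff ``t = x`` uses every
interaction whose timescale is ``<= x``.  Several arcs onto the same target are
OR-combined.  Values are Kleene three-valued: 0 (off), 1 (on) and *undetermined*
(represented as ``None``), the latter signalling a cycle-dependent value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

__all__ = [
    "UNDETERMINED",
    "TIMESCALES",
    "COMPARTMENTS",
    "ROLES",
    "SpeciesNode",
    "Literal",
    "HyperArc",
    "LogicalNetwork",
    "NetworkIntegrityError",
    "canonical_key",
    "evaluate_literal",
    "evaluate_arc",
    "update_value",
    "kleene_not",
    "kleene_and",
    "kleene_or",
]

#: Three-valued "unknown"; kept as ``None`` so states read naturally in Python.
UNDETERMINED = None

#: Timescales used by the encoded model. 1 and 3 are reserved (accepted by the
#: type, unused by the yeast network).
TIMESCALES = (0, 2, 4, 5, 6)
_VALID_TIMESCALES = frozenset(range(7))

COMPARTMENTS = ("cytosol", "nucleus", "mitochondria", "input", "other")
ROLES = ("input", "output", "internal", "constant")


class NetworkIntegrityError(ValueError):
    """Raised when a network or one of its components violates an invariant."""


def canonical_key(name: str) -> str:
    """Normalization key for species lookup (case/space/underscore-insensitive)."""
    return name.upper().replace(" ", "").replace("_", "")


@dataclass(frozen=True)
class SpeciesNode:
    """One named network node.

    ``role`` distinguishes the nine stimulus inputs, the single output
    (Apoptosis in the yeast model), the housekeeping constant and ordinary
    internal species.
    """

    name: str
    compartment: str = "other"
    role: str = "internal"
    description: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise NetworkIntegrityError(
                f"unknown compartment {self.compartment!r} for species {self.name!r}"
            )
        if self.role not in ROLES:
            raise NetworkIntegrityError(
                f"unknown role {self.role!r} for species {self.name!r}"
            )


@dataclass(frozen=True)
class Literal:
    """A species reference with a sign; ``!X`` in rule notation is ``negated=True``."""

    species: str
    negated: bool = False

    def __str__(self) -> str:
        return ("!" if self.negated else "") + self.species


@dataclass(frozen=True)
class HyperArc:
    """One interaction: AND over ``tail`` literals produces ``target``.

    ``kind`` separates ordinary logic rules from the two bookkeeping row types
    of the encoded model: stimulus rows (``kind="input"``, empty tail, target is
    an input species) and the output row (``kind="output"``, no target).  Both
    count toward the arc census but are inert during value updates.

    ``dose_gated`` marks interactions that require an overexpression dose of
    their (single) tail species; at ordinary Boolean levels they never fire.
    """

    id: int
    tail: tuple[Literal, ...]
    target: Optional[str]
    timescale: int
    reference: str = ""
    kind: str = "logic"
    dose_gated: bool = False

    def __post_init__(self) -> None:
        if self.timescale not in _VALID_TIMESCALES:
            raise NetworkIntegrityError(
                f"arc {self.id}: timescale {self.timescale} outside 0..6"
            )
        if self.kind not in ("logic", "input", "output"):
            raise NetworkIntegrityError(f"arc {self.id}: unknown kind {self.kind!r}")
        if self.kind == "logic":
            if not self.tail:
                raise NetworkIntegrityError(f"arc {self.id}: empty tail")
            if self.target is None:
                raise NetworkIntegrityError(f"arc {self.id}: logic arc without target")
            names = [lit.species for lit in self.tail]
            if len(set(names)) != len(names):
                raise NetworkIntegrityError(
                    f"arc {self.id}: duplicate species in tail"
                )
            if self.target in names:
                raise NetworkIntegrityError(
                    f"arc {self.id}: self-loop on {self.target!r}"
                )
        elif self.kind == "input":
            if self.tail:
                raise NetworkIntegrityError(f"arc {self.id}: input arc with a tail")
            if self.target is None:
                raise NetworkIntegrityError(f"arc {self.id}: input arc needs a target")
        else:  # output
            if self.target is not None:
                raise NetworkIntegrityError(f"arc {self.id}: output arc with a target")
            if len(self.tail) != 1:
                raise NetworkIntegrityError(
                    f"arc {self.id}: output arc must name exactly one species"
                )

    def species_involved(self) -> tuple[str, ...]:
        names = [lit.species for lit in self.tail]
        if self.target is not None:
            names.append(self.target)
        return tuple(names)

    def __str__(self) -> str:
        lhs = " + ".join(
            ("2 " if self.dose_gated else "") + str(lit) for lit in self.tail
        )
        rhs = self.target or ""
        return f"{lhs} = {rhs}".strip()


class LogicalNetwork:
    """Species, hyperarcs and declared inputs/outputs of one logical model.

    Species order is preserved as given (the encoded yeast model keeps the
    published species-table order) and used for every deterministic tie-break.
    """

    def __init__(
        self,
        species: Iterable[SpeciesNode],
        arcs: Iterable[HyperArc],
        name: str = "network",
        aliases: Optional[Mapping[str, str]] = None,
    ) -> None:
        self.name = name
        #: alternative spellings accepted by :meth:`resolve`, keyed by
        #: canonical_key(alias) -> declared species name
        self.aliases: dict[str, str] = dict(aliases or {})
        self.species: dict[str, SpeciesNode] = {}
        self._keys: dict[str, str] = {}  # canonical key -> name
        for node in species:
            if node.name in self.species:
                raise NetworkIntegrityError(f"duplicate species {node.name!r}")
            key = canonical_key(node.name)
            if key in self._keys:
                raise NetworkIntegrityError(
                    f"species {node.name!r} collides with {self._keys[key]!r}"
                )
            self.species[node.name] = node
            self._keys[key] = node.name
        self.arcs: list[HyperArc] = list(arcs)
        self._validate()
        self._index_arcs()

    # -- integrity ---------------------------------------------------------
    def _validate(self) -> None:
        seen_ids: set[int] = set()
        for arc in self.arcs:
            if arc.id in seen_ids:
                raise NetworkIntegrityError(f"duplicate arc id {arc.id}")
            seen_ids.add(arc.id)
            for name in arc.species_involved():
                if name not in self.species:
                    raise NetworkIntegrityError(
                        f"arc {arc.id} references unknown species {name!r}"
                    )
            if (
                arc.kind == "logic"
                and self.species[arc.target].role == "input"
            ):
                raise NetworkIntegrityError(
                    f"arc {arc.id} targets input species {arc.target!r}"
                )

    def _index_arcs(self) -> None:
        self._producers: dict[str, list[HyperArc]] = {n: [] for n in self.species}
        for arc in self.arcs:
            if arc.kind == "logic":
                self._producers[arc.target].append(arc)

    # -- accessors ---------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(n for n, s in self.species.items() if s.role == "input")

    @property
    def outputs(self) -> tuple[str, ...]:
        return tuple(n for n, s in self.species.items() if s.role == "output")

    @property
    def constants(self) -> tuple[str, ...]:
        return tuple(n for n, s in self.species.items() if s.role == "constant")

    def species_order(self) -> tuple[str, ...]:
        return tuple(self.species)

    def resolve(self, name: str) -> str:
        """Canonical species name for ``name`` (alias/case-insensitive)."""
        if name in self.species:
            return name
        key = canonical_key(name)
        if key in self._keys:
            return self._keys[key]
        alias = self.aliases.get(key)
        if alias is not None and canonical_key(alias) in self._keys:
            return self._keys[canonical_key(alias)]
        raise KeyError(f"unknown species {name!r} in network {self.name!r}")

    def arcs_targeting(self, species: str, cutoff: int | None = None) -> list[HyperArc]:
        """Logic arcs producing ``species``; optionally only those active at ``cutoff``."""
        arcs = self._producers[self.resolve(species)]
        if cutoff is None:
            return list(arcs)
        return [a for a in arcs if a.timescale <= cutoff]

    def active_arcs(self, cutoff: int) -> list[HyperArc]:
        """All arcs (any kind) with timescale <= cutoff."""
        return [a for a in self.arcs if a.timescale <= cutoff]

    def timescale_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for arc in self.arcs:
            hist[arc.timescale] = hist.get(arc.timescale, 0) + 1
        return dict(sorted(hist.items()))

    def arc_by_id(self, arc_id: int) -> HyperArc:
        for arc in self.arcs:
            if arc.id == arc_id:
                return arc
        raise KeyError(f"no arc with id {arc_id}")

    def with_deletions(self, deleted: Iterable[str]) -> "LogicalNetwork":
        """Copy of the network with every hyperarc referencing a deleted species removed.

        Gene-deletion semantics: a deleted species cannot mediate the
        interactions it appears in, whether as producer target or tail literal
        (either sign).  The species node itself stays in the network so states
        keep a fixed shape; callers clamp its value to 0.
        """
        gone = {self.resolve(d) for d in deleted}
        kept = [
            a
            for a in self.arcs
            if not (set(a.species_involved()) & gone)
        ]
        return LogicalNetwork(self.species.values(), kept, name=self.name,
                              aliases=self.aliases)

    def __repr__(self) -> str:
        return (
            f"<LogicalNetwork {self.name!r}: {self.n_species} species, "
            f"{self.n_arcs} arcs>"
        )


# -- three-valued (Kleene) connectives ------------------------------------

def kleene_not(value):
    if value is UNDETERMINED:
        return UNDETERMINED
    return 1 - value


def kleene_and(values) -> int | None:
    """Kleene conjunction: 0 dominates, else undetermined dominates, else 1."""
    result = 1
    for v in values:
        if v == 0:
            return 0
        if v is UNDETERMINED:
            result = UNDETERMINED
    return result


def kleene_or(values) -> int | None:
    """Kleene disjunction: 1 dominates, else undetermined dominates, else 0."""
    result = 0
    for v in values:
        if v == 1:
            return 1
        if v is UNDETERMINED:
            result = UNDETERMINED
    return result


def evaluate_literal(lit: Literal, state: Mapping[str, int | None]):
    """Value of one signed literal under ``state`` (Kleene negation)."""
    try:
        value = state[lit.species]
    except KeyError:
        raise KeyError(f"state does not cover species {lit.species!r}") from None
    return kleene_not(value) if lit.negated else value


def evaluate_arc(arc: HyperArc, state: Mapping[str, int | None]):
    """Kleene AND over the arc's tail literals.

    Dose-gated arcs require an overexpression dose never reached by plain
    Boolean levels and therefore evaluate to 0; input/output bookkeeping arcs
    likewise contribute nothing.
    """
    if arc.kind != "logic" or arc.dose_gated:
        return 0
    return kleene_and(evaluate_literal(lit, state) for lit in arc.tail)


def update_value(species: str, net: LogicalNetwork, state, cutoff: int):
    """OR over all arcs producing ``species`` active at ``cutoff``.

    Species without an active producing arc default to 0 — matching the
    all-zero non-input, non-housekeeping column of the model at t = 0.  Inputs
    and clamped species are the caller's responsibility.
    """
    arcs = net.arcs_targeting(species, cutoff)
    if not arcs:
        return 0
    return kleene_or(evaluate_arc(a, state) for a in arcs)
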