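"""Plain-text rule files for logical networks, plus JSON and .bnet export.

The canonical grammar, one interaction per line::

    @network yeast-apoptosis
    @species STM1-CYT | cytosol | internal | Translation initiation factor
    113: YCA1 + !BIR1 = APOPTOSIS @ 6  # Walter et al. 2006
    17: = ACETIC-ACID @ 2              # stimulus switch
    59: APOPTOSIS = @ 4                # declared output
    35: 2 CDC48 = ROS-CYT @ 4          # overexpression-gated

``!`` negates a literal, ``+`` is conjunction (AND), ``@`` carries the
timescale, ``#`` starts a reference comment.  A leading ``2`` marks an
overexpression-dose-gated interaction.  Parsing and serialization round-trip
losslessly up to whitespace.
"""

from __future__ import annotations

import json
import re
from typing import Mapping, Optional

from .logic import (
    HyperArc,
    Literal,
    LogicalNetwork,
    NetworkIntegrityError,
    SpeciesNode,
    canonical_key,
)

__all__ = [
    "RuleParseError",
    "parse_rules",
    "load_rules",
    "serialize_rules",
    "save_rules",
    "parse_interaction",
    "format_interaction",
    "network_to_json",
    "network_from_json",
    "export_bnet",
]


class RuleParseError(ValueError):
    """Malformed rule text; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


_ARC_RE = re.compile(
    r"^(?:(?P<id>\d+)\s*:\s*)?(?P<lhs>[^=]*)=(?P<rhs>[^@]*)(?:@\s*(?P<ts>\S+))?$"
)


def _resolve(name: str, known: dict[str, str], aliases: Mapping[str, str] | None):
    key = canonical_key(name)
    if key in known:
        return known[key]
    if aliases:
        target = aliases.get(key)
        if target is not None and canonical_key(target) in known:
            return known[canonical_key(target)]
    raise KeyError(name)


def parse_interaction(
    text: str,
    known: dict[str, str],
    aliases: Mapping[str, str] | None = None,
    arc_id: int | None = None,
    timescale: int | None = None,
    reference: str = "",
) -> HyperArc:
    """Parse one interaction line into a :class:`HyperArc`.

    ``known`` maps canonical keys to declared species names.  The id and
    timescale may be embedded (``"113: ... @ 6"``) or passed explicitly.
    """
    body = text
    if "#" in body:
        body, comment = body.split("#", 1)
        if not reference:
            reference = comment.strip()
    m = _ARC_RE.match(body.strip())
    if m is None:
        raise RuleParseError(f"cannot parse interaction {text!r}")
    if m.group("id") is not None:
        arc_id = int(m.group("id"))
    if arc_id is None:
        raise RuleParseError(f"interaction {text!r} has no id")
    if m.group("ts") is not None:
        ts_text = m.group("ts").strip()
        if not ts_text.isdigit():
            raise RuleParseError(f"malformed timescale {ts_text!r}")
        timescale = int(ts_text)
    if timescale is None:
        raise RuleParseError(f"interaction {text!r} has no timescale")
    if not 0 <= timescale <= 6:
        raise RuleParseError(f"timescale {timescale} outside 0..6")

    lhs = m.group("lhs").strip()
    rhs = m.group("rhs").strip()

    def resolve(name: str) -> str:
        try:
            return _resolve(name, known, aliases)
        except KeyError:
            raise RuleParseError(f"unknown species {name!r}") from None

    if not lhs:  # "= TARGET": stimulus switch for an input species
        if not rhs:
            raise RuleParseError(f"interaction {text!r} has neither tail nor target")
        return HyperArc(
            id=arc_id, tail=(), target=resolve(rhs), timescale=timescale,
            reference=reference, kind="input",
        )
    if not rhs:  # "SPECIES =": declared output
        return HyperArc(
            id=arc_id, tail=(Literal(resolve(lhs)),), target=None,
            timescale=timescale, reference=reference, kind="output",
        )

    dose_gated = False
    if lhs.startswith("2 "):
        dose_gated = True
        lhs = lhs[2:].strip()
    literals = []
    for token in lhs.split("+"):
        token = token.strip()
        if not token:
            raise RuleParseError(f"empty literal in {text!r}")
        negated = token.startswith("!")
        if negated:
            token = token[1:].strip()
        literals.append(Literal(resolve(token), negated))
    if dose_gated and (len(literals) != 1 or literals[0].negated):
        raise RuleParseError(
            "dose-gated interactions take a single positive literal"
        )
    return HyperArc(
        id=arc_id, tail=tuple(literals), target=resolve(rhs),
        timescale=timescale, reference=reference, dose_gated=dose_gated,
    )


def format_interaction(arc: HyperArc, with_id: bool = True) -> str:
    if arc.kind == "input":
        expr = f"= {arc.target}"
    elif arc.kind == "output":
        expr = f"{arc.tail[0].species} ="
    else:
        lhs = " + ".join(str(lit) for lit in arc.tail)
        if arc.dose_gated:
            lhs = "2 " + lhs
        expr = f"{lhs} = {arc.target}"
    line = f"{expr} @ {arc.timescale}"
    if with_id:
        line = f"{arc.id}: {line}"
    if arc.reference:
        line += f"  # {arc.reference}"
    return line


def parse_rules(
    text: str, aliases: Mapping[str, str] | None = None, name: str = "network"
) -> LogicalNetwork:
    species: list[SpeciesNode] = []
    known: dict[str, str] = {}
    arcs: list[HyperArc] = []
    seen_ids: set[int] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            if line.startswith("@network"):
                name = line[len("@network"):].strip() or name
            elif line.startswith("@species"):
                fields = [f.strip() for f in line[len("@species"):].split("|")]
                if not fields or not fields[0]:
                    raise RuleParseError("@species line without a name")
                node = SpeciesNode(
                    name=fields[0],
                    compartment=fields[1] if len(fields) > 1 and fields[1] else "other",
                    role=fields[2] if len(fields) > 2 and fields[2] else "internal",
                    description=fields[3] if len(fields) > 3 else "",
                )
                key = canonical_key(node.name)
                if key in known:
                    raise RuleParseError(f"duplicate species {node.name!r}")
                species.append(node)
                known[key] = node.name
            else:
                arc = parse_interaction(line, known, aliases)
                if arc.id in seen_ids:
                    raise RuleParseError(f"duplicate arc id {arc.id}")
                seen_ids.add(arc.id)
                arcs.append(arc)
        except RuleParseError as exc:
            if exc.line is None:
                raise RuleParseError(str(exc), lineno) from None
            raise
        except NetworkIntegrityError as exc:
            raise RuleParseError(str(exc), lineno) from None
    return LogicalNetwork(species, arcs, name=name)


def load_rules(path, aliases: Mapping[str, str] | None = None) -> LogicalNetwork:
    with open(path, "r", encoding="utf-8") as handle:
        return parse_rules(handle.read(), aliases)


def serialize_rules(net: LogicalNetwork) -> str:
    lines = [f"@network {net.name}"]
    for node in net.species.values():
        lines.append(
            f"@species {node.name} | {node.compartment} | {node.role}"
            + (f" | {node.description}" if node.description else "")
        )
    for arc in net.arcs:
        lines.append(format_interaction(arc))
    return "\n".join(lines) + "\n"


def save_rules(net: LogicalNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(serialize_rules(net))


# -- JSON ------------------------------------------------------------------

def network_to_json(net: LogicalNetwork) -> str:
    payload = {
        "name": net.name,
        "species": [
            {
                "name": s.name,
                "compartment": s.compartment,
                "role": s.role,
                "description": s.description,
            }
            for s in net.species.values()
        ],
        "arcs": [
            {
                "id": a.id,
                "tail": [{"species": l.species, "negated": l.negated} for l in a.tail],
                "target": a.target,
                "timescale": a.timescale,
                "reference": a.reference,
                "kind": a.kind,
                "dose_gated": a.dose_gated,
            }
            for a in net.arcs
        ],
    }
    return json.dumps(payload, indent=2)


def network_from_json(text: str) -> LogicalNetwork:
    payload = json.loads(text)
    species = [SpeciesNode(**s) for s in payload["species"]]
    arcs = [
        HyperArc(
            id=a["id"],
            tail=tuple(Literal(l["species"], l["negated"]) for l in a["tail"]),
            target=a["target"],
            timescale=a["timescale"],
            reference=a.get("reference", ""),
            kind=a.get("kind", "logic"),
            dose_gated=a.get("dose_gated", False),
        )
        for a in payload["arcs"]
    ]
    return LogicalNetwork(species, arcs, name=payload.get("name", "network"))


# -- .bnet export ----------------------------------------------------------

def export_bnet(net: LogicalNetwork) -> str:
    """Boolean rule dialect: ``target, factor`` with ``&``, ``|`` and ``!``.

    Inputs copy themselves, the housekeeping constant is 1, species without
    producers are 0.  Dose-gated and bookkeeping arcs are omitted (they never
    fire at plain Boolean levels).  Names are mangled to bnet identifiers.
    """
    def ident(name: str) -> str:
        return re.sub(r"[^0-9A-Za-z_]", "_", name)

    lines = ["targets, factors"]
    for name, node in net.species.items():
        if node.role == "input":
            factor = ident(name)
        elif node.role == "constant":
            factor = "1"
        else:
            terms = []
            for arc in net.arcs_targeting(name):
                if arc.dose_gated:
                    continue
                conj = " & ".join(
                    ("!" if lit.negated else "") + ident(lit.species)
                    for lit in arc.tail
                )
                terms.append(f"({conj})" if len(arc.tail) > 1 else conj)
            factor = " | ".join(terms) if terms else "0"
        lines.append(f"{ident(name)}, {factor}")
    return "\n".join(lines) + "\n"
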