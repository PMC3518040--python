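"""Interaction matrix, connectivity census and signed-path dependencies."""

import random

import pytest

from apoptonet.simulate import Scenario, compute_lss
from apoptonet.structure import (
    ACTIVATOR,
    INHIBITOR,
    NONE,
    PRODUCT,
    dependency_matrix,
    interaction_matrix,
    signed_edges,
    sources_and_sinks,
)
from apoptonet.synth import yeast_like_suite
from _toynets import arc, toy


def test_interaction_matrix_caspase_column(yeast):
    im = interaction_matrix(yeast)
    assert im.cell("YCA1", 113) == ACTIVATOR
    assert im.cell("BIR1", 113) == INHIBITOR
    assert im.cell("APOPTOSIS", 113) == PRODUCT
    assert im.cell("HOG1", 113) == NONE


def test_connectivity_census(yeast):
    im = interaction_matrix(yeast)
    expected = {"H2B": 5, "CAMP": 2, "RedActinDyn": 3, "ROS-MT": 1,
                "MCD1-NUC": 1}
    for name, count in expected.items():
        assert int(im.connectivity[name]) == count
    # encoded housekeeping supply: 16 interactions (published census says 18)
    assert int(im.connectivity["HK"]) == 16


def test_column_sums(yeast):
    """Every interaction contributes |tail| participant cells plus one
    product cell (the declared-output row has no product)."""
    im = interaction_matrix(yeast)
    for a in yeast.arcs:
        column = im.frame[a.id]
        participants = int((column == ACTIVATOR).sum() + (column == INHIBITOR).sum())
        products = int((column == PRODUCT).sum())
        assert participants == len(a.tail)
        assert products == (1 if a.target is not None else 0)


def test_sources_and_sinks_census(yeast):
    sources, sinks = sources_and_sinks(yeast)
    assert dict(sinks) == {"ROS-MT": 1, "MCD1-NUC": 1, "H2B": 5, "CAMP": 2}
    as_dict = dict(sources)
    assert as_dict["RedActinDyn"] == 3
    assert as_dict["ABNORMALTELOMER"] == 1
    assert as_dict["HK"] == 16
    # declared inputs never show up as sources (their stimulus rows target them)
    assert not set(as_dict) & set(yeast.inputs)


def test_fully_connected_triangle_has_no_sources_or_sinks():
    net = toy("ABC", [arc(1, ["A"], "B"), arc(2, ["B"], "C"),
                      arc(3, ["C"], "A")])
    sources, sinks = sources_and_sinks(net)
    assert sources == [] and sinks == []


def test_dependency_examples(yeast):
    dm = dependency_matrix(yeast)
    assert dm.relation("NMA111-NUC", "BIR1") == "complete-inhibitor"
    assert dm.relation("BIR1", "APOPTOSIS") == "incomplete-inhibitor"
    assert dm.relation("MATING", "H2B") == "complete-activator"
    assert dm.relation("H2B", "MATING") == "none"  # sink, no outgoing path


def test_dependency_matrix_non_symmetric(yeast):
    dm = dependency_matrix(yeast)
    assert dm.relation("MATING", "MAPK") != dm.relation("MAPK", "MATING")


def _closure(edges):
    """Sign-semiring transitive closure: walk reachability by parity."""
    pos = {(u, v) for u, v, neg in edges if not neg}
    neg = {(u, v) for u, v, neg in edges if neg}
    changed = True
    while changed:
        changed = False
        for first, second, bucket in (
            (pos, pos, pos), (neg, neg, pos), (pos, neg, neg), (neg, pos, neg)
        ):
            fresh = {
                (a, d)
                for (a, b) in first
                for (c, d) in second
                if b == c
            } - bucket
            if fresh:
                bucket |= fresh
                changed = True
    return pos, neg


def _oracle_relation(edges, single_edges, a, b):
    pos, neg = _closure(edges)
    p, n = (a, b) in pos, (a, b) in neg
    if p and n:
        return "ambivalent"
    if not p and not n:
        return "none"
    spos, sneg = _closure(single_edges)
    if p:
        return ("complete-" if (a, b) in spos else "incomplete-") + "activator"
    return ("complete-" if (a, b) in sneg else "incomplete-") + "inhibitor"


def test_dependency_agrees_with_signed_closure_oracle():
    """Parity-doubled BFS vs an independent algebraic closure over the sign
    semiring, for every ordered pair of a battery of random networks."""
    for net in yeast_like_suite(25, seed=41, max_species=10):
        dm = dependency_matrix(net)
        edges = [(u, v, neg) for u, v, neg, _ in signed_edges(net)]
        singles = [(u, v, neg) for u, v, neg, s in signed_edges(net) if s]
        for a in net.species_order():
            for b in net.species_order():
                assert dm.relation(a, b) == _oracle_relation(
                    edges, singles, a, b
                ), (net.name, a, b)


def test_no_dependency_means_knockout_has_no_effect():
    """If the matrix reports no path from a to the readout, clamping a can
    never move the readout's steady-state value."""
    rng = random.Random(19)
    checked = 0
    for net in yeast_like_suite(20, seed=83, max_species=9):
        dm = dependency_matrix(net)
        scen = Scenario(
            input_assignment={i: rng.randint(0, 1) for i in net.inputs}
        )
        readouts = [n for n in net.species_order()
                    if net.species[n].role != "input"]
        baseline = compute_lss(net, scen, 6)
        for a in net.species_order():
            if net.species[a].role == "input":
                continue
            for readout in readouts:
                if a == readout or dm.relation(a, readout) != "none":
                    continue
                for value in (0, 1):
                    perturbed = compute_lss(
                        net,
                        Scenario(input_assignment=scen.input_assignment,
                                 clamps={a: value}),
                        6,
                    )
                    assert perturbed[readout] == baseline[readout]
                    checked += 1
    assert checked > 100


def test_cutoff_filtered_dependencies(yeast):
    """Heat reaches nuclear Nma111 only once the t=4 propagation arcs exist;
    within the t=5 feedback block Hog1's influence on Ptp3 is ambivalent
    (the direct activating chain plus the odd-signed loop walk)."""
    early = dependency_matrix(yeast, cutoff=2)
    late = dependency_matrix(yeast, cutoff=4)
    assert early.relation("HEAT", "NMA111-NUC") == "none"
    assert late.relation("HEAT", "NMA111-NUC") == "complete-activator"
    assert dependency_matrix(yeast, cutoff=6).relation("HOG1", "PTP3") == "ambivalent"
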