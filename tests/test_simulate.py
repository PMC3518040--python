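"""Logical steady states, snapshot tables, synchronous dynamics, attractors."""

import random

import pytest

from apoptonet.logic import UNDETERMINED, evaluate_arc, update_value
from apoptonet.simulate import (
    Scenario,
    ScenarioError,
    StateSpaceSizeError,
    StateTable,
    compute_lss,
    enumerate_attractors,
    knockout_scan,
    snapshot_table,
    synchronous_step,
    synchronous_trajectory,
)
from apoptonet.synth import GeneratorConfig, random_network, yeast_like_suite
from _toynets import arc, naive_attractors, toy


# -- logical steady states -------------------------------------------------

def test_linear_chain_propagates():
    net = toy("ABC", [arc(1, ["A"], "B"), arc(2, ["B"], "C")], inputs="A")
    state = compute_lss(net, Scenario(input_assignment={"A": 1}), 6)
    assert (state["B"], state["C"]) == (1, 1)
    off = compute_lss(net, Scenario(), 6)
    assert (off["B"], off["C"]) == (0, 0)


def test_all_inputs_off_everything_dark(yeast):
    """Without stimuli only housekeeping-fed species (and their consequences)
    can be on at t = 0."""
    state = compute_lss(yeast, Scenario(), 0)
    on = {n for n, v in state.items() if v == 1}
    expected = {"HK"} | {
        a.target for a in yeast.arcs if a.kind == "logic" and a.timescale == 0
    }
    assert on == expected


def test_lss_is_consistent_fixpoint(yeast):
    scen = Scenario(input_assignment={i: 1 for i in yeast.inputs})
    for cutoff in (0, 4, 5, 6):
        state = compute_lss(yeast, scen, cutoff)
        fixed = scen.resolved(yeast).fixed_values(yeast)
        for name, value in state.items():
            if name in fixed or value is UNDETERMINED:
                continue
            assert update_value(name, yeast, state, cutoff) == value, name


def test_lss_idempotent(yeast):
    """Re-running the fixed-point computation cannot change determined values:
    one synchronous sweep over the LSS reproduces it."""
    scen = Scenario(input_assignment={i: 1 for i in yeast.inputs})
    state = compute_lss(yeast, scen, 6)
    assert all(v is not UNDETERMINED for v in state.values())
    again = synchronous_step(yeast, scen, state, 6)
    assert again == state


def test_hog1_loop_undetermined_without_osmotic_stress(yeast):
    """Heat alone leaves the Hog1/Ptp3 negative feedback without a classical
    point value; the three-valued LSS reports it honestly."""
    state = compute_lss(yeast, Scenario(input_assignment={"HEAT": 1}), 5)
    assert state["HOG1"] is UNDETERMINED
    assert state["PTP3"] is UNDETERMINED
    assert state["SLT2"] == 1  # determined despite feeding the loop


def test_snapshot_monotone_for_pure_activation_networks():
    for seed in range(5):
        cfg = GeneratorConfig(n_species=9, n_arcs=14, p_negated=0.0,
                              n_inputs=2, seed=seed)
        net = random_network(cfg)
        scen = Scenario(input_assignment={i: 1 for i in net.inputs},
                        cutoffs=(0, 2, 4, 5, 6))
        table = snapshot_table(net, scen)
        for sp in net.species_order():
            row = table.row(sp)
            for earlier, later in zip(row, row[1:]):
                if earlier == 1:
                    assert later == 1


def test_state_table_tsv_round_trip(yeast):
    scen = Scenario(input_assignment={"HEAT": 1})
    table = snapshot_table(yeast, scen)
    again = StateTable.from_tsv(__import__("io").StringIO(table.to_tsv()))
    assert again.species == table.species
    assert again.cutoffs == table.cutoffs
    assert dict(again.cells) == dict(table.cells)


def test_inconsistent_scenarios_rejected(yeast):
    with pytest.raises(ScenarioError):
        Scenario(input_assignment={"HEAT": 1}, clamps={"HEAT": 0}).resolved(yeast)
    with pytest.raises(ScenarioError):
        Scenario(clamps={"BIR1": 2}).resolved(yeast)
    with pytest.raises(ScenarioError):
        Scenario(cutoffs=(4, 4)).resolved(yeast)
    with pytest.raises(ScenarioError):
        Scenario(clamps={"BIR1": 1}, deletions=("BIR1",)).resolved(yeast)


# -- synchronous dynamics --------------------------------------------------

def test_fixpoint_gives_constant_trajectory(yeast):
    scen = Scenario(input_assignment={i: 1 for i in yeast.inputs})
    lss = compute_lss(yeast, scen, 6)
    traj = synchronous_trajectory(yeast, scen, lss, 6, 5)
    assert all(state == lss for state in traj)


def test_two_node_negative_loop_period_four():
    net = toy("AB", [arc(1, ["!B"], "A"), arc(2, ["A"], "B")])
    scen = Scenario()
    start = {"A": 0, "B": 0}
    traj = synchronous_trajectory(net, scen, start, 6, 8)
    states = [(s["A"], s["B"]) for s in traj]
    # hand-enumerated orbit: 00 -> 10 -> 11 -> 01 -> 00 ...
    assert states[:5] == [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]
    assert states[4] == states[0]


def test_heat_only_hog1_column_oscillates(yeast):
    scen = Scenario(input_assignment={"HEAT": 1})
    start = {n: 0 for n in yeast.species_order()}
    traj = synchronous_trajectory(yeast, scen, start, 5, 40)
    tail = [s["HOG1"] for s in traj[-12:]]
    assert len(set(tail)) > 1  # never settles


def test_trajectory_rejects_undetermined_initial(yeast):
    scen = Scenario()
    bad = {n: 0 for n in yeast.species_order()}
    bad["YCA1"] = UNDETERMINED
    with pytest.raises(ScenarioError):
        synchronous_trajectory(yeast, scen, bad, 6, 1)


# -- attractors ------------------------------------------------------------

def test_acyclic_cascade_single_point_attractor():
    net = toy(
        "ABCDE",
        [arc(1, ["A"], "B"), arc(2, ["B"], "C"), arc(3, ["C"], "D"),
         arc(4, ["!D"], "E")],
        inputs="A",
    )
    found = enumerate_attractors(net, Scenario(input_assignment={"A": 1}), 6)
    assert len(found) == 1
    assert found[0].is_point
    assert found[0].basin_size == 2 ** 4
    assert found[0].states[0] == {"A": 1, "B": 1, "C": 1, "D": 1, "E": 0}


def test_two_node_positive_loop_attractor_set():
    net = toy("AB", [arc(1, ["B"], "A"), arc(2, ["A"], "B")])
    found = enumerate_attractors(net, Scenario(), 6)
    kinds = sorted((len(a), tuple(sorted((s["A"], s["B"]) for s in a.states)))
                   for a in found)
    assert kinds == [
        (1, ((0, 0),)),
        (1, ((1, 1),)),
        (2, ((0, 1), (1, 0))),
    ]
    assert sum(a.basin_size for a in found) == 4


def test_attractor_cycle_invariant(yeast):
    """Applying one synchronous step to states[i] yields states[(i+1) % len]."""
    net = toy("AB", [arc(1, ["!B"], "A"), arc(2, ["A"], "B")])
    scen = Scenario()
    for attractor in enumerate_attractors(net, scen, 6):
        n = len(attractor)
        for i, state in enumerate(attractor.states):
            nxt = synchronous_step(net, scen, state, 6)
            assert nxt == attractor.states[(i + 1) % n]


def test_enumeration_matches_naive_orbit_tracing():
    """Bitmask transition-graph traversal vs an independent dict-based orbit
    tracer, on a battery of random networks."""
    rng = random.Random(7)
    for net in yeast_like_suite(30, seed=11, max_species=9):
        scen = Scenario(
            input_assignment={i: rng.randint(0, 1) for i in net.inputs}
        )
        fast = enumerate_attractors(net, scen, 6)
        slow = naive_attractors(net, scen, 6)
        order = net.species_order()
        fast_keys = {
            tuple(tuple(s[n] for n in order) for s in a.states): a.basin_size
            for a in fast
        }
        assert fast_keys == slow


def test_lss_determined_values_hold_in_every_attractor():
    rng = random.Random(5)
    for net in yeast_like_suite(40, seed=23, max_species=10):
        scen = Scenario(
            input_assignment={i: rng.randint(0, 1) for i in net.inputs}
        )
        lss = compute_lss(net, scen, 6)
        for attractor in enumerate_attractors(net, scen, 6):
            for state in attractor.states:
                for name, value in lss.items():
                    if value is not UNDETERMINED:
                        assert state[name] == value


def test_state_space_bound_enforced(yeast):
    with pytest.raises(StateSpaceSizeError):
        enumerate_attractors(yeast, Scenario(), 6, bound=22)


# -- perturbation scans ----------------------------------------------------

def test_bir1_overexpression_blocks_caspase_arc(yeast):
    scen = Scenario(input_assignment={"HEAT": 1})
    free = compute_lss(yeast, scen, 6)
    assert evaluate_arc(yeast.arc_by_id(113), free) == 1
    clamped = compute_lss(
        yeast, Scenario(input_assignment={"HEAT": 1}, clamps={"BIR1": 1}), 6
    )
    assert evaluate_arc(yeast.arc_by_id(113), clamped) == 0


def test_knockout_of_downstream_sink_leaves_readout(yeast):
    base = Scenario(input_assignment={i: 1 for i in yeast.inputs})
    result = knockout_scan(yeast, base, ["H2B", "CAMP", "ROS-MT"],
                           "APOPTOSIS", 6)
    baseline = compute_lss(yeast, base, 6)["APOPTOSIS"]
    assert all(v == baseline for v in result.values())


def test_stm1_deletion_switches_off_fragmentation_route(yeast):
    base = Scenario(input_assignment={"H2O2": 1})
    result = knockout_scan(yeast, base, ["STM1-NUC"], "DNA-FRAG", 6,
                           mode="delete")
    assert result["STM1-NUC"] == 0


def test_single_deletions_never_leave_apoptosis_undetermined(yeast):
    """Robustness sweep: deleting any one non-input species may change the
    outcome but never makes the death readout cycle-dependent."""
    base = Scenario(input_assignment={i: 1 for i in yeast.inputs})
    targets = [
        n for n, s in yeast.species.items()
        if s.role not in ("input", "output")
    ]
    values = knockout_scan(yeast, base, targets, "APOPTOSIS", 6, mode="delete")
    assert all(v is not UNDETERMINED for v in values.values())
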