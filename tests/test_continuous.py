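"""Hill functions, BooleCube interpolation and ODE simulation."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from apoptonet.continuous import (
    HillParameters,
    ParameterError,
    boolecube,
    build_continuous,
    constant_drive,
    hill,
    normalized_hill,
    pulse_drive,
    simulate,
)
from apoptonet.logic import UNDETERMINED
from apoptonet.models import build_yeast_network
from apoptonet.simulate import Scenario, compute_lss


# -- closed-form pieces ----------------------------------------------------

@pytest.mark.parametrize("n", [1.0, 2.0, 3.0, 8.0])
def test_hill_half_activation_at_threshold(n):
    assert hill(0.5, n, 0.5) == pytest.approx(0.5)
    assert hill(0.2, n, 0.2) == pytest.approx(0.5)


def test_hill_closed_form_values():
    assert hill(0.0, 3, 0.5) == 0.0
    assert hill(1.0, 3, 0.5) == pytest.approx(8 / 9)
    assert normalized_hill(1.0, 3, 0.5) == pytest.approx(1.0)
    assert normalized_hill(0.0, 3, 0.5) == 0.0
    assert normalized_hill(0.5, 3, 0.5) == pytest.approx(9 / 16)


def test_hill_monotone_increasing():
    xs = np.linspace(0, 1, 50)
    ys = hill(xs, 4, 0.3)
    assert np.all(np.diff(ys) > 0)


def test_hill_parameter_validation():
    with pytest.raises(ParameterError):
        hill(0.5, 0, 0.5)
    with pytest.raises(ParameterError):
        hill(0.5, 3, -1)
    with pytest.raises(ParameterError):
        normalized_hill(0.5, 3, 1.2)
    with pytest.raises(ParameterError):
        HillParameters(k=1.0)
    with pytest.raises(ParameterError):
        HillParameters(tau=-1)


def test_pulse_drive():
    assert pulse_drive(1.0, 0.0)(17.3) == 1.0
    assert pulse_drive(1.0, 2.0)(0.0) == 1.0
    assert pulse_drive(1.0, np.log(2))(1.0) == pytest.approx(0.5)
    with pytest.raises(ParameterError):
        pulse_drive(0.0, 1.0)
    with pytest.raises(ParameterError):
        pulse_drive(1.0, -0.1)


# -- BooleCube -------------------------------------------------------------

def test_boolecube_or_midpoint():
    assert boolecube(lambda a, b: a or b, [0.5, 0.5]) == pytest.approx(0.75)


def test_boolecube_and_corners():
    for a, b in itertools.product((0, 1), repeat=2):
        assert boolecube(lambda x, y: x and y, [a, b]) == int(bool(a and b))


def test_boolecube_arity_mismatch():
    with pytest.raises(ParameterError):
        boolecube([0, 1, 1], [0.5, 0.5])


def _naive_boolecube(table, point):
    m = len(point)
    total = 0.0
    for c in range(1 << m):
        weight = 1.0
        for i in range(m):
            bit = (c >> i) & 1
            weight *= point[i] if bit else 1 - point[i]
        total += table[c] * weight
    return total


@given(
    st.integers(min_value=1, max_value=4).flatmap(
        lambda m: st.tuples(
            st.lists(st.integers(0, 1), min_size=1 << m, max_size=1 << m),
            st.lists(
                st.floats(0, 1, allow_nan=False), min_size=m, max_size=m
            ),
        )
    )
)
def test_boolecube_matches_naive_sum_and_stays_bounded(table_point):
    table, point = table_point
    value = boolecube(table, point)
    assert value == pytest.approx(_naive_boolecube(table, point), abs=1e-12)
    assert -1e-12 <= value <= 1 + 1e-12


def test_apoptosis_rule_interpolation_matches_reference(yeast):
    """The 11-regulator apoptosis update, interpolated at an arbitrary
    interior point, equals the direct sum over all 2^11 corners."""
    model = build_continuous(yeast, mode="boolecube", cutoff=6)
    regs, table = model.boolean_update_table("APOPTOSIS")
    assert len(regs) == 11
    rng = np.random.default_rng(2)
    for _ in range(5):
        point = rng.uniform(0, 1, len(regs))
        assert boolecube(table, point) == pytest.approx(
            _naive_boolecube(table, point), abs=1e-9
        )


def test_boolecube_reproduces_boolean_update_on_all_corners(yeast):
    model = build_continuous(yeast, mode="boolecube", cutoff=6)
    for name in model.dynamic:
        regs, table = model.boolean_update_table(name)
        for c in range(1 << len(regs)):
            point = [(c >> i) & 1 for i in range(len(regs))]
            assert boolecube(table, point) == table[c]


# -- ODE simulation --------------------------------------------------------

def test_boolean_fixpoint_is_ode_equilibrium(yeast):
    scen = Scenario(input_assignment={i: 1 for i in yeast.inputs})
    lss = compute_lss(yeast, scen, 6)
    model = build_continuous(yeast, mode="boolecube", cutoff=6,
                             input_drives={i: 1.0 for i in yeast.inputs})
    init = {s: float(lss[s]) for s in model.dynamic}
    traj = simulate(model, init, t_end=8.0)
    assert traj.equilibrium
    drift = max(abs(traj.final[s] - init[s]) for s in model.dynamic)
    assert drift < 1e-6


def test_trajectories_stay_in_unit_interval(yeast):
    model = build_continuous(
        yeast, cutoff=6,
        input_drives={"HEAT": pulse_drive(1.0, 0.1), "H2O2": 1.0},
    )
    traj = simulate(model, None, t_end=25.0)
    values = traj.frame.to_numpy()
    assert values.min() >= -1e-3
    assert values.max() <= 1.001


def test_steep_hill_equilibria_recover_boolean_lss(yeast):
    """With a steep normalized Hill transform (n = 20) and binary-consistent
    start, continuous equilibria land within 0.05 of the logical steady
    state (all-inputs scenario)."""
    scen = Scenario(input_assignment={i: 1 for i in yeast.inputs})
    lss = compute_lss(yeast, scen, 6)
    assert all(v is not UNDETERMINED for v in lss.values())
    model = build_continuous(
        yeast, mode="normalized-hillcube", params=HillParameters(n=20.0),
        cutoff=6, input_drives={i: 1.0 for i in yeast.inputs},
    )
    init = {s: float(lss[s]) for s in model.dynamic}
    traj = simulate(model, init, t_end=50.0)
    deviation = max(
        abs(traj.final[s] - lss[s]) for s in model.dynamic
    )
    assert deviation < 0.05


def test_clamped_and_deleted_species_follow_their_levels(yeast):
    model = build_continuous(
        yeast, cutoff=6, clamps={"BIR1": 1.0}, deletions=("YCA1",),
        input_drives={"ACETIC-ACID": 1.0},
    )
    traj = simulate(model, None, t_end=5.0)
    assert np.all(traj.frame["BIR1"].to_numpy() == 1.0)
    assert np.all(traj.frame["YCA1"].to_numpy() == 0.0)


def test_input_drive_validation(yeast):
    with pytest.raises(ParameterError):
        build_continuous(yeast, input_drives={"BIR1": 1.0})
    with pytest.raises(ParameterError):
        build_continuous(yeast, clamps={"BIR1": 1.5})
    with pytest.raises(ParameterError):
        constant_drive(2.0)


def test_mode_selection_changes_dynamics(yeast):
    drives = {"H2O2": 1.0}
    finals = {}
    for mode in ("boolecube", "hillcube", "normalized-hillcube"):
        model = build_continuous(yeast, mode=mode, cutoff=6,
                                 input_drives=drives)
        finals[mode] = simulate(model, None, t_end=15.0).final["ROS-CYT"]
    # hillcube saturates below 1 (f(1) = 8/9 per stage), normalized reaches 1
    assert finals["hillcube"] < finals["normalized-hillcube"]
    assert finals["normalized-hillcube"] == pytest.approx(1.0, abs=1e-3)
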