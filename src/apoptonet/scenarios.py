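"""Named in-silico experiments on the yeast apoptosis model.

Each case study packages a scenario configuration, runs the discrete or
continuous engine and returns a :class:`CaseStudyResult` whose summary
metrics are recomputed from the stored table/trajectory.

Continuous case studies start from the *resting state*: the no-stimulus
logical steady state (housekeeping proteins present, stress machinery off),
with cycle-dependent species resolved to 0.  They default to the
normalized-Hill-cube conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .continuous import (
    HillParameters,
    Trajectory,
    build_continuous,
    pulse_drive,
    simulate,
)
from .logic import UNDETERMINED, LogicalNetwork
from .models import build_bcl2_extension, build_vcp_extension, build_yeast_network
from .simulate import Scenario, StateTable, compute_lss, snapshot_table

__all__ = [
    "TABLE_SPECIES_YEAST",
    "CaseStudyResult",
    "resting_state",
    "run_all_inputs_table",
    "run_hog1_heat_study",
    "run_bir1_acetic_study",
    "run_stm1_study",
    "run_humanized",
]

#: The 15 species displayed in the additive-mode steady-state table.
TABLE_SPECIES_YEAST = (
    "ACETIC-ACID", "ADOZELESIN", "AIF1-MT", "AIF1-NUC", "APOPTOSIS", "BIR1",
    "DNA-FRAG", "H2O2", "HEAT", "NMA111-NUC", "ROS-CYT", "STE20-CYT",
    "STM1-CYT", "STM1-NUC", "YCA1",
)

_BCL2_SPECIES = ("UV", "AKT-SIGNALING", "BCL-XL", "P53", "BAD", "BAX",
                 "BCL-2", "APOPTOSIS")
_VCP_SPECIES = ("AKT-SIGNALING", "GP130-STAT3", "NFKB-CYT", "NFKB-NUC",
                "NFKB/IKBA", "VCP", "C-3-6-7", "C-9-12", "IKBA", "IAP",
                "SURVIVAL", "APOPTOSIS")


@dataclass
class CaseStudyResult:
    """Outcome of one named scenario run."""

    name: str
    table: Optional[StateTable] = None
    trajectory: Optional[Trajectory] = None
    metrics: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)


def resting_state(net: LogicalNetwork, cutoff: int = 6) -> dict[str, float]:
    """Pre-treatment activation levels: the no-stimulus LSS as floats, with
    cycle-dependent (undetermined) species resolved to 0."""
    lss = compute_lss(net, Scenario(), cutoff)
    return {
        name: 0.0 if value is UNDETERMINED else float(value)
        for name, value in lss.items()
    }


def run_all_inputs_table(full: bool = False) -> CaseStudyResult:
    """Additive mode: all nine stimuli switched on simultaneously; one LSS
    snapshot per timescale cutoff 0/4/5/6."""
    net = build_yeast_network()
    scen = Scenario(input_assignment={name: 1 for name in net.inputs})
    table = snapshot_table(net, scen)
    shown = table if full else table.subset(TABLE_SPECIES_YEAST)
    metrics = {
        "apoptosis_final": table.value("APOPTOSIS", 6),
        "bir1_final": table.value("BIR1", 6),
        "yca1_final": table.value("YCA1", 6),
    }
    return CaseStudyResult("all-inputs", table=shown, metrics=metrics,
                           config={"inputs": "all nine = 1",
                                   "cutoffs": list(scen.cutoffs)})


def run_hog1_heat_study(
    mode: str = "normalized-hillcube",
    params: Optional[HillParameters] = None,
    amplitude: float = 1.0,
    decay_rate: float = 0.05,
    t_end: float = 80.0,
) -> CaseStudyResult:
    """Heat-only stimulation of the Hog1/phosphatase feedback subsystem.

    Hog1 rises as the Ptp2/Ptp3 phosphatases are still absent, overshoots,
    and is pulled back by the Hog1 -> Hog1-dependent genes -> Ptp3 negative
    feedback to an interior plateau: peak < 1, plateau strictly between 0
    and the peak.
    """
    net = build_yeast_network()
    model = build_continuous(
        net, mode=mode, params=params, cutoff=6,
        input_drives={"HEAT": pulse_drive(amplitude, decay_rate)}
        if amplitude > 0 else {},
    )
    traj = simulate(model, resting_state(net), t_end=t_end,
                    n_points=int(10 * t_end) + 1)
    hog1 = traj.series("HOG1")
    peak_time = float(hog1.idxmax())
    tail = hog1[hog1.index >= 0.8 * t_end]
    metrics = {
        "hog1_peak": float(hog1.max()),
        "hog1_peak_time": peak_time,
        "hog1_plateau": float(tail.mean()),
        "hog1_final": float(hog1.iloc[-1]),
    }
    return CaseStudyResult(
        "hog1-heat", trajectory=traj, metrics=metrics,
        config={"mode": mode, "amplitude": amplitude,
                "decay_rate": decay_rate, "t_end": t_end},
    )


def run_bir1_acetic_study(
    overexpress: bool = False,
    reversal: bool = False,
    mode: str = "normalized-hillcube",
    params: Optional[HillParameters] = None,
    pulse_decay: float = 0.15,
    bir1_decay: float = 0.25,
    t_stress: float = 25.0,
    t_recovery: float = 40.0,
) -> CaseStudyResult:
    """Acetic-acid pulse stimulation with Bir1 as the apoptosis gatekeeper.

    Default: the acid pulse decays while Bir1 is degraded (Nma111-mediated,
    imposed as a decaying time course since the rule set carries no
    acid-responsive route to Nma111); cytosolic cytochrome c is high and
    apoptosis climbs to its maximum through the metacaspase route.

    ``overexpress=True``: Bir1 clamped at 1 throughout — apoptosis stays at 0.

    ``reversal=True``: after the stress phase Bir1 is released to its own
    dynamics, accumulates (nothing degrades it any more) and pushes the
    already-reached apoptosis level back to zero — the deliberately
    biologically implausible "revived cell" control.
    """
    net = build_yeast_network()
    acid = pulse_drive(1.0, pulse_decay)
    common = dict(mode=mode, params=params, cutoff=6,
                  input_drives={"ACETIC-ACID": acid})
    init = resting_state(net)

    if overexpress:
        model = build_continuous(net, clamps={"BIR1": 1.0}, **common)
        traj = simulate(model, init, t_end=t_stress,
                        n_points=int(10 * t_stress) + 1)
    else:
        stressed = build_continuous(
            net, drives={"BIR1": pulse_drive(1.0, bir1_decay)}, **common
        )
        traj = simulate(stressed, init, t_end=t_stress,
                        n_points=int(10 * t_stress) + 1)
        if reversal:
            # release Bir1; the acid pulse continues decaying from t_stress
            def acid_tail(t, offset=t_stress):
                return acid(t + offset)

            recovery = build_continuous(
                net, mode=mode, params=params, cutoff=6,
                input_drives={"ACETIC-ACID": acid_tail},
            )
            init2 = dict(traj.final)
            traj2 = simulate(recovery, init2, t_end=t_recovery,
                             n_points=int(10 * t_recovery) + 1)
            traj = Trajectory.concat(traj, traj2)

    apoptosis = traj.series("APOPTOSIS")
    metrics = {
        "apoptosis_max": float(apoptosis.max()),
        "apoptosis_final": float(apoptosis.iloc[-1]),
        "cytc_cyt_max": float(traj.series("CYTC-CYT").max()),
        "bir1_final": float(traj.series("BIR1").iloc[-1]),
    }
    variant = "overexpress" if overexpress else ("reversal" if reversal else "pulse")
    return CaseStudyResult(
        f"bir1-acetic-{variant}", trajectory=traj, metrics=metrics,
        config={"mode": mode, "pulse_decay": pulse_decay,
                "variant": variant},
    )


def run_stm1_study(knockout: bool = False) -> CaseStudyResult:
    """H2O2 stimulation with or without deletion of both Stm1 compartment
    nodes.  The deletion removes the Stm1-mediated DNA-fragmentation
    interaction entirely, so that route stays off in the knockout."""
    net = build_yeast_network()
    deletions = ("STM1-CYT", "STM1-NUC") if knockout else ()
    scen = Scenario(input_assignment={"H2O2": 1}, deletions=deletions)
    table = snapshot_table(net, scen)
    lss = compute_lss(net, scen, 6)
    effective = scen.resolved(net).effective_network(net)
    try:
        arc105 = effective.arc_by_id(105)
        route_active = (
            all(
                (lss[lit.species] == 0) == lit.negated
                for lit in arc105.tail
                if lss[lit.species] is not UNDETERMINED
            )
            and not any(lss[lit.species] is UNDETERMINED for lit in arc105.tail)
        )
    except KeyError:
        route_active = False
    metrics = {
        "apoptosis_final": table.value("APOPTOSIS", 6),
        "dna_frag_final": table.value("DNA-FRAG", 6),
        "stm1_route_active": route_active,
    }
    return CaseStudyResult(
        "stm1-knockout" if knockout else "stm1-h2o2",
        table=table.subset(("H2O2", "STM1-CYT", "STM1-NUC", "DNA-FRAG",
                            "ROS-CYT", "YCA1", "APOPTOSIS")),
        metrics=metrics,
        config={"H2O2": 1, "deletions": list(deletions)},
    )


def run_humanized(model: str) -> CaseStudyResult:
    """Akt-signalling-only scenario on a humanized extension ('bcl2' or 'vcp')."""
    if model == "bcl2":
        net = build_bcl2_extension()
        shown = _BCL2_SPECIES
    elif model == "vcp":
        net = build_vcp_extension()
        shown = _VCP_SPECIES
    else:
        raise ValueError(f"unknown humanized model {model!r}; use 'bcl2' or 'vcp'")
    scen = Scenario(input_assignment={"AKT-SIGNALING": 1})
    table = snapshot_table(net, scen)
    metrics = {"apoptosis_final": table.value("APOPTOSIS", 6)}
    if model == "vcp":
        metrics.update(
            survival_final=table.value("SURVIVAL", 6),
            caspases_ever_on=any(
                table.value(sp, c) == 1
                for sp in ("C-3-6-7", "C-9-12")
                for c in scen.cutoffs
            ),
        )
    else:
        metrics.update(
            bcl2_t4=table.value("BCL-2", 4),
            bclxl_t4=table.value("BCL-XL", 4),
        )
    return CaseStudyResult(
        f"humanized-{model}", table=table.subset(shown), metrics=metrics,
        config={"AKT-SIGNALING": 1},
    )
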