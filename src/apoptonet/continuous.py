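"""Discrete-to-continuous conversion: BooleCube and Hill-cube ODE models.

Each non-input species i obtains one ODE

    dx_i/dt = (1/tau_i) * (B_i(x~) - x_i),       x_i in [0, 1],

where B_i is the multilinear (BooleCube) interpolation of the species'
Boolean update rule — OR over its producing interactions, AND with sign over
each tail — evaluated on transformed regulator activations x~.  The
transform selects the mode: raw coordinates (``boolecube``), per-edge Hill
sigmoids f(x) = x^n / (x^n + k^n) (``hillcube``), or Hill sigmoids rescaled
so f(1) = 1 (``normalized-hillcube``, the default for case studies).  At
binary corners B_i reproduces the Boolean update exactly, so every Boolean
fixed point is an ODE equilibrium in boolecube mode, and for steep
normalized Hill transforms equilibria approach the logical steady state.

Inputs follow caller-supplied drive functions (e.g. exponentially decaying
pulses), clamped species follow constants, and deleted genes sit at zero
with their mediated interactions removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .logic import LogicalNetwork

__all__ = [
    "MODES",
    "ParameterError",
    "SimulationError",
    "HillParameters",
    "ContinuousModel",
    "Trajectory",
    "hill",
    "normalized_hill",
    "boolecube",
    "build_continuous",
    "pulse_drive",
    "constant_drive",
    "simulate",
]

MODES = ("boolecube", "hillcube", "normalized-hillcube")


class ParameterError(ValueError):
    pass


class SimulationError(RuntimeError):
    def __init__(self, message: str, last_time: float | None = None):
        self.last_time = last_time
        super().__init__(message)


def hill(x, n: float, k: float):
    """Hill sigmoid x^n / (x^n + k^n); hill(k, n, k) = 1/2 for any n."""
    if n <= 0 or k <= 0:
        raise ParameterError(f"Hill parameters must be positive (n={n}, k={k})")
    x = np.asarray(x, dtype=float)
    xn = x ** n
    out = xn / (xn + k ** n)
    return out if out.ndim else float(out)


def normalized_hill(x, n: float, k: float):
    """Hill sigmoid rescaled to reach exactly 1 at x = 1 (requires k < 1)."""
    if not 0 < k < 1:
        raise ParameterError(f"normalization needs k in (0,1), got {k}")
    return hill(x, n, k) / hill(1.0, n, k)


def pulse_drive(amplitude: float, decay_rate: float) -> Callable[[float], float]:
    """Exponentially decaying stimulus u(t) = A exp(-lambda t); lambda = 0
    gives a constant drive."""
    if not 0 < amplitude <= 1:
        raise ParameterError(f"pulse amplitude must be in (0,1], got {amplitude}")
    if decay_rate < 0:
        raise ParameterError(f"decay rate must be >= 0, got {decay_rate}")

    def drive(t):
        return amplitude * math.exp(-decay_rate * t)

    drive.amplitude = amplitude
    drive.decay_rate = decay_rate
    return drive


def constant_drive(level: float) -> Callable[[float], float]:
    if not 0 <= level <= 1:
        raise ParameterError(f"drive level must be in [0,1], got {level}")
    return lambda t: level


def boolecube(f, point: Sequence[float]) -> float:
    """Multilinear interpolation of an m-ary Boolean function at ``point``.

    ``f`` is either a callable of m binary arguments or a corner table of
    length 2^m indexed so bit i of the corner index is argument i.  Exactly
    reproduces f on binary corners.
    """
    point = np.asarray(point, dtype=float)
    m = point.size
    if callable(f):
        table = np.array(
            [float(f(*(((c >> i) & 1) for i in range(m)))) for c in range(1 << m)]
        )
    else:
        table = np.asarray(f, dtype=float)
        if table.size != 1 << m:
            raise ParameterError(
                f"corner table of size {table.size} does not match arity {m}"
            )
    return float(_interpolate(table, point))


def _interpolate(table: np.ndarray, point: np.ndarray) -> float:
    # Bit i of the corner index is argument i, so after reshaping to (2,)*m
    # axis j carries argument (m-1-j); contract trailing axes first.
    m = point.size
    values = table.reshape((2,) * m)  # shape () when m == 0
    for j in range(m - 1, -1, -1):
        p = point[m - 1 - j]
        lo = np.take(values, 0, axis=j)
        hi = np.take(values, 1, axis=j)
        values = lo * (1.0 - p) + hi * p
    return values


@dataclass(frozen=True)
class HillParameters:
    """Per-edge Hill coefficients/thresholds and per-species time constants.

    Defaults n = 3, k = 0.5, tau = 1 for every edge and species; individual
    overrides are keyed by (regulator, target) for n/k and species for tau.
    """

    n: float = 3.0
    k: float = 0.5
    tau: float = 1.0
    edge_n: Mapping[tuple[str, str], float] = field(default_factory=dict)
    edge_k: Mapping[tuple[str, str], float] = field(default_factory=dict)
    species_tau: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for value in (self.n, self.tau, *self.edge_n.values(),
                      *self.species_tau.values()):
            if value <= 0:
                raise ParameterError(f"parameter must be positive, got {value}")
        for value in (self.k, *self.edge_k.values()):
            if not 0 < value < 1:
                raise ParameterError(f"threshold k must be in (0,1), got {value}")

    def n_for(self, regulator: str, target: str) -> float:
        return self.edge_n.get((regulator, target), self.n)

    def k_for(self, regulator: str, target: str) -> float:
        return self.edge_k.get((regulator, target), self.k)

    def tau_for(self, species: str) -> float:
        return self.species_tau.get(species, self.tau)


class ContinuousModel:
    """Compiled ODE system for one network / scenario / mode combination."""

    def __init__(self, net, mode, params, cutoff, input_drives, clamps,
                 deletions, drives):
        if mode not in MODES:
            raise ParameterError(f"unknown mode {mode!r}; choose from {MODES}")
        self.network = net
        self.mode = mode
        self.params = params
        self.cutoff = cutoff
        self.input_drives = input_drives  # input species -> time function
        self.drives = drives              # any species -> time function
        self.clamps = clamps              # species -> constant level
        self.deletions = deletions

        work = net.with_deletions(deletions) if deletions else net
        order = net.species_order()
        driven = set(input_drives) | set(drives)
        fixed_levels = dict(clamps)
        for name in net.constants:
            fixed_levels.setdefault(name, 1.0)
        for name in deletions:
            fixed_levels[name] = 0.0
        for name in net.inputs:
            if name not in driven and name not in fixed_levels:
                fixed_levels[name] = 0.0
        self.fixed_levels = fixed_levels
        self.dynamic: list[str] = [
            n for n in order
            if n not in fixed_levels and n not in driven
            and net.species[n].role != "input"
        ]
        self._dyn_index = {n: i for i, n in enumerate(self.dynamic)}
        self._full_index = {n: i for i, n in enumerate(order)}
        self.order = order

        # Compile per-dynamic-species: regulators, corner table, edge params.
        self._compiled = []
        for name in self.dynamic:
            arcs = [a for a in work.arcs_targeting(name, cutoff)
                    if not a.dose_gated]
            regs: list[str] = []
            for arc in arcs:
                for lit in arc.tail:
                    if lit.species not in regs:
                        regs.append(lit.species)
            regs.sort(key=self._full_index.__getitem__)
            m = len(regs)
            pos = np.zeros(m, dtype=np.int64)
            table = np.zeros(1 << m)
            for c in range(1 << m):
                bits = {r: (c >> i) & 1 for i, r in enumerate(regs)}
                value = 0
                for arc in arcs:
                    if all((bits[l.species] == 0) == l.negated for l in arc.tail):
                        value = 1
                        break
                table[c] = value
            ns = np.array([params.n_for(r, name) for r in regs])
            ks = np.array([params.k_for(r, name) for r in regs])
            self._compiled.append(
                (name, regs, table, ns, ks, params.tau_for(name))
            )

    # -- evaluation --------------------------------------------------------
    def _transform(self, x: np.ndarray, ns: np.ndarray, ks: np.ndarray):
        if self.mode == "boolecube" or x.size == 0:
            return x
        xn = np.clip(x, 0.0, None) ** ns
        h = xn / (xn + ks ** ns)
        if self.mode == "hillcube":
            return h
        return h * (1.0 + ks ** ns)  # divide by hill(1, n, k)

    def full_levels(self, t: float, y: np.ndarray) -> np.ndarray:
        """Assemble activation levels for every species at time t."""
        levels = np.empty(len(self.order))
        for name, level in self.fixed_levels.items():
            levels[self._full_index[name]] = level
        for name, fn in self.input_drives.items():
            levels[self._full_index[name]] = fn(t)
        for name, fn in self.drives.items():
            levels[self._full_index[name]] = fn(t)
        for name, i in self._dyn_index.items():
            levels[self._full_index[name]] = y[i]
        return levels

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        levels = self.full_levels(t, y)
        out = np.empty(len(self.dynamic))
        for i, (name, regs, table, ns, ks, tau) in enumerate(self._compiled):
            if regs:
                x = np.array([levels[self._full_index[r]] for r in regs])
                b = _interpolate(table, self._transform(x, ns, ks))
            else:
                b = 0.0
            out[i] = (b - y[i]) / tau
        return out

    def boolean_update_table(self, species: str):
        """(regulators, corner table) of the compiled Boolean rule."""
        for name, regs, table, *_ in self._compiled:
            if name == species:
                return tuple(regs), table.copy()
        raise KeyError(f"{species!r} is not a dynamic species of this model")

    def initial_vector(self, initial) -> np.ndarray:
        if initial is None:
            initial = {}
        y0 = np.zeros(len(self.dynamic))
        for i, name in enumerate(self.dynamic):
            y0[i] = float(initial.get(name, 0.0))
        if np.any((y0 < 0) | (y0 > 1)):
            raise ParameterError("initial state must lie in the unit hypercube")
        return y0


def build_continuous(
    net: LogicalNetwork,
    mode: str = "normalized-hillcube",
    params: Optional[HillParameters] = None,
    cutoff: int = 6,
    input_drives: Optional[Mapping[str, Callable]] = None,
    clamps: Optional[Mapping[str, float]] = None,
    deletions: Sequence[str] = (),
    drives: Optional[Mapping[str, Callable]] = None,
) -> ContinuousModel:
    """Compile the logical network into an ODE model.

    ``input_drives`` maps input species to time functions (numbers are
    wrapped as constants).  ``drives`` may override any species with a time
    course (used e.g. to impose a degradation time course on a protein).
    ``clamps`` hold species at constant levels in [0, 1].
    """
    params = params or HillParameters()

    def normalize_drives(mapping):
        out = {}
        for name, fn in (mapping or {}).items():
            resolved = net.resolve(name)
            out[resolved] = fn if callable(fn) else constant_drive(float(fn))
        return out

    input_drives = normalize_drives(input_drives)
    for name in input_drives:
        if net.species[name].role != "input":
            raise ParameterError(f"{name!r} is not an input; use drives= instead")
    drives = normalize_drives(drives)
    clamps = {net.resolve(k): float(v) for k, v in (clamps or {}).items()}
    for name, level in clamps.items():
        if not 0 <= level <= 1:
            raise ParameterError(f"clamp level for {name!r} outside [0,1]")
    deletions = tuple(net.resolve(d) for d in deletions)
    return ContinuousModel(net, mode, params, cutoff, input_drives, clamps,
                           deletions, drives)


@dataclass(frozen=True)
class Trajectory:
    """Time grid and per-species activation levels of one simulation."""

    times: np.ndarray
    frame: pd.DataFrame  # index: time, columns: species
    equilibrium: bool

    @property
    def final(self) -> pd.Series:
        return self.frame.iloc[-1]

    def series(self, species: str) -> pd.Series:
        return self.frame[species]

    def to_tsv(self, path=None):
        text = self.frame.to_csv(sep="\t", index_label="time")
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(text)

    @staticmethod
    def concat(first: "Trajectory", second: "Trajectory") -> "Trajectory":
        """Join two consecutive legs; the second leg's clock restarts at the
        first leg's end."""
        shifted = second.frame.copy()
        shifted.index = second.times + first.times[-1]
        frame = pd.concat([first.frame.iloc[:-1], shifted])
        times = np.concatenate([first.times[:-1], second.times + first.times[-1]])
        return Trajectory(times, frame, second.equilibrium)


def simulate(
    model: ContinuousModel,
    initial: Optional[Mapping[str, float]] = None,
    t_end: float = 30.0,
    n_points: int = 301,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "LSODA",
    equilibrium_tol: float = 1e-6,
) -> Trajectory:
    """Integrate the ODE system and return the trajectory on a uniform grid.

    The equilibrium flag is set when the right-hand side stays below
    ``equilibrium_tol`` (sup-norm) over the final time-constant of the run.
    """
    y0 = model.initial_vector(initial)
    times = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(model.rhs, (0.0, t_end), y0, method=method, t_eval=times,
                    rtol=rtol, atol=atol)
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else None
        raise SimulationError(f"ODE solver failed: {sol.message}", last)

    data = np.empty((times.size, len(model.order)))
    for j, t in enumerate(times):
        data[j] = model.full_levels(t, sol.y[:, j])
    frame = pd.DataFrame(data, index=pd.Index(times, name="time"),
                         columns=model.order)

    tau_max = max(
        (model.params.tau_for(s) for s in model.dynamic), default=1.0
    )
    window = times >= times[-1] - tau_max
    eq = all(
        np.max(np.abs(model.rhs(t, sol.y[:, j]))) < equilibrium_tol
        for j, t in enumerate(times)
        if window[j]
    ) if model.dynamic else True
    return Trajectory(times, frame, bool(eq))
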