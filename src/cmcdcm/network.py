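"""Source networks, numerical integration and the sensor-level forward model.

A :class:`NetworkModel` assembles canonical microcircuits into a cortical
hierarchy (by default the six-source auditory network: bilateral primary
auditory cortex A1, bilateral superior temporal gyrus STG, right inferior
frontal gyrus and right intraparietal sulcus).  Forward extrinsic
connections run up the hierarchy from superficial pyramidal outputs;
backward connections run down from deep pyramidal outputs and are
inhibitory at their targets.  A Gaussian thalamic volley (prior latency
20 ms) drives the spiny stellate populations of bilateral A1.

Source dynamics are integrated with fixed-step RK4 and projected to sensors
through a linear lead field applied to a weighted mixture of population
potentials (pyramidal-dominated by default, reflecting the dendritic origin
of MEG/EEG signals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import _core
from .microcircuit import (
    GAMMA_KEYS,
    EffectiveConnectivity,
    ExtrinsicTarget,
    IntrinsicTarget,
    MicrocircuitParams,
    ModulationSpec,
    apply_modulation,
)

__all__ = [
    "Source",
    "NetworkModel",
    "InputSpec",
    "SimulationGrid",
    "LeadField",
    "ERFDataset",
    "Trajectories",
    "ContributionAnalysis",
    "IntegrationDivergence",
    "CONDITIONS",
    "CONDITION_DESIGN",
    "exogenous_input",
    "integrate",
    "observe",
    "simulate_conditions",
    "solver_convergence_error",
    "contribution_analysis",
    "default_sources",
    "default_network",
    "default_grid",
]

#: The 2x2 condition cells, in storage order.
CONDITIONS: tuple[str, ...] = (
    "attended_deviant",
    "attended_standard",
    "unattended_deviant",
    "unattended_standard",
)

#: Factor indicators per condition; expectation = 1 marks deviants
#: (expectation violation), so the unattended standard is the baseline.
CONDITION_DESIGN: dict[str, dict[str, int]] = {
    "attended_deviant": {"attention": 1, "expectation": 1},
    "attended_standard": {"attention": 1, "expectation": 0},
    "unattended_deviant": {"attention": 0, "expectation": 1},
    "unattended_standard": {"attention": 0, "expectation": 0},
}


class IntegrationDivergence(RuntimeError):
    """Raised when the network state leaves the finite range during integration."""


@dataclass(frozen=True)
class Source:
    name: str
    mni: tuple[float, float, float]
    level: int


def default_sources() -> list[Source]:
    """The six-source auditory hierarchy with its prior MNI coordinates."""
    return [
        Source("lA1", (-42, -22, 7), 1),
        Source("rA1", (46, -14, 8), 1),
        Source("lSTG", (-60, -48, 20), 2),
        Source("rSTG", (56, -40, 18), 2),
        Source("rIPS", (34, -66, 46), 3),
        Source("rIFG", (52, 24, 0), 4),
    ]


@dataclass
class NetworkModel:
    """A hierarchy of canonical-microcircuit sources with extrinsic coupling.

    ``af[i, j]`` (resp. ``ab[i, j]``) is the forward (backward) strength of
    the connection j -> i; forward entries may only point up-level and
    backward entries only down-level.  ``c`` holds exogenous input weights,
    nonzero only at the declared input sources.  ``params`` may be shared or
    given per source.
    """

    sources: list[Source]
    af: np.ndarray
    ab: np.ndarray
    c: np.ndarray
    params: MicrocircuitParams | list[MicrocircuitParams] = field(
        default_factory=MicrocircuitParams
    )
    modulations: list[ModulationSpec] = field(default_factory=list)
    name: str = "model"

    def __post_init__(self) -> None:
        n = len(self.sources)
        self.af = np.asarray(self.af, float)
        self.ab = np.asarray(self.ab, float)
        self.c = np.asarray(self.c, float)
        if self.af.shape != (n, n) or self.ab.shape != (n, n) or self.c.shape != (n,):
            raise ValueError("connectivity shapes inconsistent with source count")
        if np.any(self.af < 0) or np.any(self.ab < 0):
            raise ValueError("extrinsic strengths must be nonnegative")
        levels = np.array([s.level for s in self.sources])
        up = levels[:, None] > levels[None, :]  # target strictly above origin
        if np.any(self.af[~up] != 0):
            raise ValueError("forward connections must run up the hierarchy")
        if np.any(self.ab[~up.T] != 0):
            raise ValueError("backward connections must run down the hierarchy")
        if isinstance(self.params, list) and len(self.params) != n:
            raise ValueError("per-source parameter list length mismatch")
        # every modulation target must resolve against this model
        self.effective({m.factor: 0 for m in self.modulations})

    # -- helpers -----------------------------------------------------------
    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def source_names(self) -> list[str]:
        return [s.name for s in self.sources]

    @property
    def index_of(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.sources)}

    def params_of(self, i: int) -> MicrocircuitParams:
        return self.params[i] if isinstance(self.params, list) else self.params

    # parameter stacks are cached: model instances are treated as immutable
    # (use dataclasses.replace / with_modulations to derive variants)
    def kappa_stack(self) -> np.ndarray:
        if "_kappa_stack" not in self.__dict__:
            self.__dict__["_kappa_stack"] = np.stack(
                [self.params_of(i).kappa_vector() for i in range(self.n_sources)]
            )
        return self.__dict__["_kappa_stack"]

    def gamma_stack(self) -> np.ndarray:
        if "_gamma_stack" not in self.__dict__:
            self.__dict__["_gamma_stack"] = np.stack(
                [self.params_of(i).gamma_vector() for i in range(self.n_sources)]
            )
        return self.__dict__["_gamma_stack"]

    def slope_vector(self) -> np.ndarray:
        if "_slope_vector" not in self.__dict__:
            self.__dict__["_slope_vector"] = np.array(
                [self.params_of(i).sigmoid_slope for i in range(self.n_sources)]
            )
        return self.__dict__["_slope_vector"]

    def effective(self, x: Mapping[str, float]) -> EffectiveConnectivity:
        """Condition-specific connectivity (see :func:`apply_modulation`)."""
        return apply_modulation(
            self.af, self.ab, self.gamma_stack(), self.modulations, x, self.index_of
        )

    def with_modulations(self, modulations: list[ModulationSpec], name: str | None = None):
        return replace(self, modulations=modulations, name=name or self.name)

    def scaled(self, log_af: float = 0.0, log_ab: float = 0.0) -> "NetworkModel":
        """Globally rescale extrinsic strengths on the log scale."""
        return replace(
            self, af=self.af * math.exp(log_af), ab=self.ab * math.exp(log_ab)
        )


def default_network(
    params: MicrocircuitParams | None = None,
    forward_strength: float = 2.0,
    backward_strength: float = 0.5,
    modulations: list[ModulationSpec] | None = None,
    name: str = "arch_IFG+IPS_interconnected_bilateral",
) -> NetworkModel:
    """The selected architecture: both fronto-parietal sources, interconnected,
    bilaterally coupled to STG, with thalamic input to bilateral A1."""
    sources = default_sources()
    idx = {s.name: i for i, s in enumerate(sources)}
    n = len(sources)
    af = np.zeros((n, n))
    ab = np.zeros((n, n))
    forward_pairs = [
        ("lA1", "lSTG"),
        ("rA1", "rSTG"),
        ("lSTG", "rIPS"),
        ("rSTG", "rIPS"),
        ("lSTG", "rIFG"),
        ("rSTG", "rIFG"),
        ("rIPS", "rIFG"),
    ]
    for lo, hi in forward_pairs:
        af[idx[hi], idx[lo]] = forward_strength
        ab[idx[lo], idx[hi]] = backward_strength
    c = np.zeros(n)
    c[idx["lA1"]] = c[idx["rA1"]] = 1.0
    return NetworkModel(
        sources=sources,
        af=af,
        ab=ab,
        c=c,
        params=params or MicrocircuitParams(),
        modulations=modulations or [],
        name=name,
    )


# ---------------------------------------------------------------------------
# Input, grid, lead field, dataset containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputSpec:
    """Gaussian thalamic input: peak ``amplitude`` at ``latency`` ms."""

    latency: float = 20.0
    dispersion: float = 8.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("input dispersion must be > 0")
        if self.amplitude < 0:
            raise ValueError("input amplitude must be >= 0")


def exogenous_input(spec: InputSpec, t):
    """Evaluate the Gaussian input drive at time(s) ``t`` (ms)."""
    t = np.asarray(t, float)
    out = spec.amplitude * np.exp(-((t - spec.latency) ** 2) / (2 * spec.dispersion**2))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SimulationGrid:
    """Output sampling grid: ``t_start`` to ``t_end`` ms in steps of ``dt``."""

    t_start: float = 1.0
    t_end: float = 1.0 + 89 * (1000.0 / 300.0)
    dt: float = 1000.0 / 300.0

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        count = (self.t_end - self.t_start) / self.dt
        if abs(count - round(count)) > 1e-6:
            raise ValueError("(t_end - t_start) / dt must be an integer sample count")

    @property
    def n_times(self) -> int:
        return int(round((self.t_end - self.t_start) / self.dt)) + 1

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_times) * self.dt

    @property
    def sfreq(self) -> float:
        return 1000.0 / self.dt


def default_grid() -> SimulationGrid:
    """The 1-300 ms peristimulus window sampled at 300 Hz (90 samples)."""
    return SimulationGrid()


@dataclass
class LeadField:
    """Linear map from source activity to sensors.

    ``gain`` is (n_sensors, n_sources); ``contribution`` weights the
    population potentials into each source's scalar dipole activity and is
    held fixed during inversion.
    """

    gain: np.ndarray
    contribution: Mapping[str, float] = field(
        default_factory=lambda: {"SS": 0.0, "SP": 0.8, "II": 0.0, "DP": 0.2}
    )

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, float)
        if self.gain.ndim != 2:
            raise ValueError("lead field gain must be sensors x sources")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field gain must be finite")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    def contribution_vector(self) -> np.ndarray:
        order = ("SS", "SP", "II", "DP")
        return np.array([self.contribution.get(p, 0.0) for p in order], float)


@dataclass
class ERFDataset:
    """Condition-labelled trial-averaged sensor responses.

    ``data`` has shape (n_conditions, n_sensors, n_times).
    """

    data: np.ndarray
    conditions: tuple[str, ...]
    times: np.ndarray
    sfreq: float
    subject_id: str | None = None
    units: str = "a.u."
    leadfield: LeadField | None = None
    seed: int | None = None
    truth: dict | None = None  # ground-truth parameters when synthetic

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.times = np.asarray(self.times, float)
        self.conditions = tuple(self.conditions)
        if self.data.ndim != 3:
            raise ValueError("data must be condition x sensor x time")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if self.data.shape[0] != len(self.conditions):
            raise ValueError("condition axis length mismatch")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("dataset contains non-finite values")

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    def condition(self, label: str) -> np.ndarray:
        return self.data[self.conditions.index(label)]


@dataclass
class Trajectories:
    """Per-source population state trajectories on a sampling grid.

    ``states`` has shape (n_times, n_sources, 8): potentials V(SS, SP, II,
    DP) in columns 0-3 and currents in columns 4-7.
    """

    times: np.ndarray
    states: np.ndarray
    source_names: list[str]

    def potentials(self) -> np.ndarray:
        return self.states[:, :, :4]

    def source_activity(self, contribution: np.ndarray) -> np.ndarray:
        """(n_sources, n_times) scalar dipole activity."""
        return np.einsum("tsp,p->st", self.potentials(), contribution)


# ---------------------------------------------------------------------------
# Integration and observation
# ---------------------------------------------------------------------------

DEFAULT_SOLVER_DT = 0.5  # ms


def _run_kernel(model, eff, input_spec, y0, t0, n_steps, dt, bnorm):
    traj = _core.integrate_rk4(
        y0,
        float(t0),
        int(n_steps),
        float(dt),
        np.ascontiguousarray(eff.af),
        np.ascontiguousarray(eff.ab),
        np.ascontiguousarray(model.c),
        np.ascontiguousarray(model.kappa_stack()),
        np.ascontiguousarray(eff.gammas),
        np.ascontiguousarray(model.slope_vector()),
        float(input_spec.latency),
        float(input_spec.dispersion),
        float(input_spec.amplitude),
        np.ascontiguousarray(eff.g_dyn_sp),
        np.ascontiguousarray(eff.g_dyn_ii),
        np.ascontiguousarray(bnorm),
        bool(eff.dynamic),
    )
    if not np.all(np.isfinite(traj)):
        bad = np.argwhere(~np.isfinite(traj))
        k, i = int(bad[0, 0]), int(bad[0, 1])
        raise IntegrationDivergence(
            f"state of source {model.sources[i].name!r} became non-finite "
            f"at t = {t0 + k * dt:.2f} ms"
        )
    return traj


def integrate(
    model: NetworkModel,
    x: Mapping[str, float],
    input_spec: InputSpec,
    grid: SimulationGrid,
    solver_dt: float = DEFAULT_SOLVER_DT,
) -> Trajectories:
    """Integrate the network ODEs for condition ``x`` from the zero state.

    Integration starts at t = 0 (stimulus onset) with fixed-step classical
    RK4.  Step sizes are chosen as the largest values <= ``solver_dt`` that
    land exactly on every output sample, so the returned trajectories
    involve no interpolation.  Raises :class:`IntegrationDivergence` when a
    state becomes non-finite.
    """
    eff = model.effective(x)
    row = eff.ab.sum(axis=1, keepdims=True)
    bnorm = np.where(row > 0, eff.ab / np.where(row == 0, 1.0, row), 0.0)
    n = model.n_sources
    y0 = np.zeros((n, 8))
    # phase A: stimulus onset (t=0) up to the first output sample
    if grid.t_start > 0:
        m = max(1, int(math.ceil(grid.t_start / solver_dt - 1e-9)))
        trajA = _run_kernel(model, eff, input_spec, y0, 0.0, m, grid.t_start / m, bnorm)
        y0 = trajA[-1]
    # phase B: sub-stepped so every grid time is an integration point
    n_sub = max(1, int(math.ceil(grid.dt / solver_dt - 1e-9)))
    n_steps = n_sub * (grid.n_times - 1)
    trajB = _run_kernel(
        model, eff, input_spec, y0, grid.t_start, n_steps, grid.dt / n_sub, bnorm
    )
    return Trajectories(
        times=grid.times, states=trajB[::n_sub], source_names=model.source_names
    )


def observe(trajectories: Trajectories, leadfield: LeadField) -> np.ndarray:
    """Project source trajectories to sensors: (n_sensors, n_times)."""
    activity = trajectories.source_activity(leadfield.contribution_vector())
    if leadfield.gain.shape[1] != activity.shape[0]:
        raise ValueError(
            f"lead field maps {leadfield.gain.shape[1]} sources, "
            f"trajectories have {activity.shape[0]}"
        )
    return leadfield.gain @ activity


def simulate_conditions(
    model: NetworkModel,
    input_spec: InputSpec,
    grid: SimulationGrid,
    leadfield: LeadField,
    solver_dt: float = DEFAULT_SOLVER_DT,
    subject_id: str | None = None,
) -> ERFDataset:
    """Simulate the sensor ERF of every cell of the 2x2 design."""
    data = np.empty((len(CONDITIONS), leadfield.n_sensors, grid.n_times))
    for k, cond in enumerate(CONDITIONS):
        traj = integrate(model, CONDITION_DESIGN[cond], input_spec, grid, solver_dt)
        data[k] = observe(traj, leadfield)
    return ERFDataset(
        data=data,
        conditions=CONDITIONS,
        times=grid.times,
        sfreq=grid.sfreq,
        subject_id=subject_id,
        leadfield=leadfield,
    )


def solver_convergence_error(
    model: NetworkModel,
    x: Mapping[str, float],
    input_spec: InputSpec,
    grid: SimulationGrid,
    solver_dt: float = DEFAULT_SOLVER_DT,
    refine: int = 10,
) -> float:
    """Max deviation of the dt solution from a dt/refine reference,
    normalized per state channel by the reference peak absolute value."""
    coarse = integrate(model, x, input_spec, grid, solver_dt).states
    fine = integrate(model, x, input_spec, grid, solver_dt / refine).states
    peak = np.abs(fine).max(axis=0)
    peak = np.where(peak > 0, peak, 1.0)
    return float((np.abs(coarse - fine) / peak[None]).max())


# ---------------------------------------------------------------------------
# Contribution analysis (gain sweeps)
# ---------------------------------------------------------------------------


@dataclass
class ContributionAnalysis:
    """A1 source-activity curves under a sweep of intrinsic gain scalings.

    ``curves[k]`` is the hemisphere-averaged activity with log-gain
    ``offsets[k]`` applied to the targeted population; ``baseline`` is the
    unmodulated curve; ``onset_ms[k]`` is the first latency at which the
    modulated and baseline curves diverge beyond the threshold fraction of
    the baseline peak (NaN if they never do).
    """

    offsets: np.ndarray
    times: np.ndarray
    curves: np.ndarray
    baseline: np.ndarray
    differences: np.ndarray
    onset_ms: np.ndarray
    peaks: np.ndarray
    target_sources: tuple[str, ...]
    population: str


def contribution_analysis(
    model: NetworkModel,
    target_sources: Sequence[str] = ("lA1", "rA1"),
    population: str = "II",
    sweep: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8),
    input_spec: InputSpec | None = None,
    grid: SimulationGrid | None = None,
    readout_sources: Sequence[str] | None = None,
    contribution: np.ndarray | None = None,
    threshold: float = 0.05,
    solver_dt: float = DEFAULT_SOLVER_DT,
    activity_dependent: bool = False,
) -> ContributionAnalysis:
    """Sweep the gain (log-scaling of self-inhibition) of one population.

    For each sweep value g the targeted population's self-inhibition is
    scaled by ``exp(-g)`` (positive g = disinhibition) and the
    hemisphere-averaged A1 activity is recorded, together with its
    difference from the unmodulated baseline and the latency at which that
    difference first exceeds ``threshold`` x the baseline peak — the
    modulated condition standing in for 'attended' and the baseline for
    'unattended'.
    """
    input_spec = input_spec or InputSpec()
    grid = grid or default_grid()
    readout_sources = tuple(readout_sources or target_sources)
    if contribution is None:
        contribution = LeadField(np.zeros((1, model.n_sources))).contribution_vector()
    idx = model.index_of
    missing = [s for s in tuple(target_sources) + readout_sources if s not in idx]
    if missing:
        raise KeyError(f"unknown sources in contribution analysis: {missing}")
    offsets = np.asarray(list(sweep), float)
    if offsets.size == 0 or not np.all(np.isfinite(offsets)):
        raise ValueError("sweep must be a finite, non-empty list of gain offsets")

    read_idx = [idx[s] for s in readout_sources]

    def a1_curve(g: float) -> np.ndarray:
        spec = ModulationSpec(
            factor="sweep",
            intrinsic=[IntrinsicTarget(s, population, g=g) for s in target_sources],
            activity_dependent=activity_dependent,
        )
        swept = model.with_modulations([spec])
        traj = integrate(swept, {"sweep": 1}, input_spec, grid, solver_dt)
        return traj.source_activity(np.asarray(contribution, float))[read_idx].mean(axis=0)

    baseline = a1_curve(0.0)
    curves = np.stack([baseline if g == 0.0 else a1_curve(g) for g in offsets])
    diffs = curves - baseline[None]
    peak = np.abs(baseline).max()
    onset = np.full(offsets.size, np.nan)
    for k in range(offsets.size):
        above = np.abs(diffs[k]) > threshold * peak
        if above.any():
            onset[k] = grid.times[int(np.argmax(above))]
    return ContributionAnalysis(
        offsets=offsets,
        times=grid.times,
        curves=curves,
        baseline=baseline,
        differences=diffs,
        onset_ms=onset,
        peaks=np.abs(curves).max(axis=1),
        target_sources=tuple(target_sources),
        population=population,
    )
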