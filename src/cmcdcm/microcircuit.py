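"""Canonical-microcircuit neural mass model: populations, parameters, modulation.

Each cortical source is modeled with four neuronal populations — spiny
stellate cells (SS, layer 4), superficial pyramidal cells (SP, layers 2/3),
inhibitory interneurons (II) and deep pyramidal cells (DP, layers 5/6) —
each carrying a membrane potential V (mV) and a current I (mV/ms).  The
populations are coupled by signed intrinsic connections ``gamma`` and, across
sources, by excitatory forward (SP -> SS/DP of the higher source) and
inhibitory backward (DP -> SP/II of the lower source) extrinsic connections.

Experimental context (here: attention and expectation in a 2x2 design)
enters as log-scale modulation of extrinsic strengths and of the inhibitory
self-connections ("gain") of SP or II populations.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PopulationLabel",
    "GAMMA_KEYS",
    "MicrocircuitParams",
    "SourceState",
    "ExtrinsicTarget",
    "IntrinsicTarget",
    "ModulationSpec",
    "EffectiveConnectivity",
    "firing_rate",
    "state_derivative",
    "apply_modulation",
]


class PopulationLabel(enum.IntEnum):
    """The four populations of the canonical microcircuit."""

    SS = 0  # spiny stellate, L4
    SP = 1  # superficial pyramidal, L2/3
    II = 2  # inhibitory interneurons
    DP = 3  # deep pyramidal, L5/6


#: Order of the ten intrinsic couplings gamma_{m->n}; fixed storage order for
#: all (n_sources, 10) coupling arrays used by the integrator.
GAMMA_KEYS: tuple[str, ...] = (
    "SS->SS",
    "SP->SS",
    "II->SS",
    "SS->II",
    "DP->II",
    "II->II",
    "SS->SP",
    "SP->SP",
    "DP->DP",
    "II->DP",
)

_DEFAULT_KAPPA = {"SS": 1 / 4, "SP": 1 / 8, "II": 1 / 16, "DP": 1 / 28}
_DEFAULT_GAMMA = {
    "SS->SS": 4.0,
    "SP->SS": 4.0,
    "II->SS": 4.0,
    "SS->II": 4.0,
    "DP->II": 2.0,
    "II->II": 4.0,
    "SS->SP": 2.0,
    "SP->SP": 8.0,
    "DP->DP": 2.0,
    "II->DP": 2.0,
}


@dataclass(frozen=True)
class MicrocircuitParams:
    """Rate constants, intrinsic couplings and sigmoid slope of one source.

    Parameters
    ----------
    kappa
        Synaptic rate constants (1/ms) per population; the membrane time
        constant of population ``m`` is ``1/kappa[m]`` ms.
    gamma
        The ten intrinsic coupling strengths (dimensionless, >= 0), keyed as
        in :data:`GAMMA_KEYS`.  The self-couplings ``SP->SP`` and ``II->II``
        are the inhibitory self-connections whose attenuation implements an
        increase in population gain (precision).
    sigmoid_slope
        Slope ``r`` of the centered logistic potential-to-rate transform.
    """

    kappa: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_KAPPA))
    gamma: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_GAMMA))
    sigmoid_slope: float = 2 / 3

    def __post_init__(self) -> None:
        missing = set(p.name for p in PopulationLabel) - set(self.kappa)
        if missing:
            raise ValueError(f"kappa missing populations: {sorted(missing)}")
        missing = set(GAMMA_KEYS) - set(self.gamma)
        if missing:
            raise ValueError(f"gamma missing couplings: {sorted(missing)}")
        if any(k <= 0 for k in self.kappa.values()):
            raise ValueError("all synaptic rate constants kappa must be > 0")
        if any(g < 0 for g in self.gamma.values()):
            raise ValueError("intrinsic couplings gamma must be >= 0")
        if self.sigmoid_slope <= 0:
            raise ValueError("sigmoid slope must be > 0")

    def kappa_vector(self) -> np.ndarray:
        """Rate constants as a (4,) array in SS, SP, II, DP order."""
        return np.array([self.kappa[p.name] for p in PopulationLabel], float)

    def gamma_vector(self) -> np.ndarray:
        """Intrinsic couplings as a (10,) array in :data:`GAMMA_KEYS` order."""
        return np.array([self.gamma[k] for k in GAMMA_KEYS], float)

    def with_gamma(self, **updates: float) -> "MicrocircuitParams":
        gamma = dict(self.gamma)
        for key, value in updates.items():
            key = key.replace("_", "->") if "->" not in key else key
            if key not in GAMMA_KEYS:
                raise KeyError(key)
            gamma[key] = value
        return replace(self, gamma=gamma)


@dataclass
class SourceState:
    """Membrane potentials and currents of one source (8 states).

    ``v`` and ``i`` are (4,) arrays in SS, SP, II, DP order.
    """

    v: np.ndarray = field(default_factory=lambda: np.zeros(4))
    i: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, float)
        self.i = np.asarray(self.i, float)
        if self.v.shape != (4,) or self.i.shape != (4,):
            raise ValueError("SourceState holds 4 potentials and 4 currents")


def firing_rate(v, r: float):
    """Centered logistic transform from postsynaptic potential to firing rate.

    ``sigma(v) = 1/(1 + exp(-r v)) - 1/2`` — an odd, strictly increasing
    function of ``v`` saturating at +/- 1/2, so the zero state maps to zero
    output and the all-zero network state is a fixed point.
    """
    if r <= 0:
        raise ValueError("sigmoid slope r must be > 0")
    v = np.asarray(v, float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite membrane potential")
    out = 1.0 / (1.0 + np.exp(-r * v)) - 0.5
    return float(out) if out.ndim == 0 else out


def state_derivative(
    state: SourceState,
    params: MicrocircuitParams,
    forward_drive: float = 0.0,
    backward_drive: float = 0.0,
    u: float = 0.0,
    input_weight: float = 0.0,
) -> SourceState:
    """Time derivative of one source's eight states.

    ``forward_drive`` is the summed extrinsic excitatory input
    ``A^F sigma(V_SP)`` from hierarchically lower sources (it enters the SS
    and DP current equations with positive sign); ``backward_drive`` is the
    extrinsic inhibitory input ``A^B sigma(V_DP)`` from higher sources (it
    enters the SP and II equations with negative sign).  Exogenous
    (thalamic) drive ``u``, scaled by ``input_weight`` (the C vector entry),
    excites the spiny stellate population only.  Every current equation
    carries the damping terms ``-2 kappa I - kappa^2 V`` of the critically
    damped second-order synaptic (alpha) kernel, giving each population an
    impulse response ``t exp(-kappa t)``.
    """
    for name, val in (("forward", forward_drive), ("backward", backward_drive), ("u", u)):
        if not math.isfinite(val):
            raise ValueError(f"non-finite {name} drive")
    kap = params.kappa_vector()
    g = params.gamma_vector()
    r = params.sigmoid_slope
    sig = firing_rate(state.v, r)
    s_ss, s_sp, s_ii, s_dp = sig

    di = np.empty(4)
    # spiny stellate: ascending extrinsic + thalamic input
    di[0] = kap[0] * (
        forward_drive - g[0] * s_ss - g[1] * s_sp - g[2] * s_ii + input_weight * u
    )
    # superficial pyramidal: descending extrinsic (inhibitory)
    di[1] = kap[1] * (-backward_drive + g[6] * s_ss - g[7] * s_sp)
    # inhibitory interneurons: descending extrinsic (inhibitory)
    di[2] = kap[2] * (-backward_drive + g[3] * s_ss + g[4] * s_dp - g[5] * s_ii)
    # deep pyramidal: ascending extrinsic
    di[3] = kap[3] * (forward_drive - g[8] * s_dp - g[9] * s_ii)
    di -= 2.0 * kap * state.i + kap**2 * state.v  # alpha-kernel damping
    return SourceState(v=state.i.copy(), i=di)


# ---------------------------------------------------------------------------
# Condition-dependent modulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtrinsicTarget:
    """A (connection, direction) modulation target with log-scaling b.

    ``tie`` names the free-parameter group the target belongs to during
    inversion; targets sharing a tie share one estimated value.
    """

    src: str
    dst: str
    direction: str  # "forward" | "backward"
    b: float = 0.0
    tie: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"direction must be forward/backward, got {self.direction!r}")


@dataclass(frozen=True)
class IntrinsicTarget:
    """A (source, population) gain target with log-scaling g.

    Positive ``g`` scales the population's inhibitory self-connection by
    ``exp(-g)`` under the active condition — disinhibition, i.e. increased
    gain.
    """

    source: str
    population: str  # "SP" | "II"
    g: float = 0.0
    tie: str | None = None

    def __post_init__(self) -> None:
        if self.population not in ("SP", "II"):
            raise ValueError("gain targets apply to SP or II self-connections")


@dataclass
class ModulationSpec:
    """All modulation targets of one experimental factor.

    When ``activity_dependent`` is set, intrinsic gain scaling is not static:
    the log-scaling of a source is multiplied at each instant by
    ``(1 + sigma(V_DP))`` of its backward-afferent source(s), so descending
    activity gates the gain change.
    """

    factor: str
    extrinsic: list[ExtrinsicTarget] = field(default_factory=list)
    intrinsic: list[IntrinsicTarget] = field(default_factory=list)
    activity_dependent: bool = False


_SELF_GAMMA_INDEX = {"SP": GAMMA_KEYS.index("SP->SP"), "II": GAMMA_KEYS.index("II->II")}


@dataclass
class EffectiveConnectivity:
    """Connectivity after condition-specific modulation.

    ``gammas`` has shape (n_sources, 10) in :data:`GAMMA_KEYS` order.
    ``g_dyn_sp`` / ``g_dyn_ii`` hold per-source log-gain scalings that must be
    applied dynamically (activity-dependent mode); they are zero otherwise.
    """

    af: np.ndarray
    ab: np.ndarray
    gammas: np.ndarray
    g_dyn_sp: np.ndarray
    g_dyn_ii: np.ndarray

    @property
    def dynamic(self) -> bool:
        return bool(np.any(self.g_dyn_sp) or np.any(self.g_dyn_ii))


def apply_modulation(
    af: np.ndarray,
    ab: np.ndarray,
    gammas: np.ndarray,
    specs: Iterable[ModulationSpec],
    x: Mapping[str, float],
    index_of: Mapping[str, int],
) -> EffectiveConnectivity:
    """Scale connectivity by the factor-specific log modulations for condition x.

    Every targeted extrinsic strength theta becomes ``theta * exp(sum_k b_k x_k)``
    over the factors k targeting it; intrinsic gain targets scale the
    population's self-inhibition by ``exp(-sum_k g_k x_k)``.  With all
    indicators zero the base connectivity is returned bit-identically.

    ``x`` maps factor id -> condition indicator in {0, 1}; ``index_of`` maps
    source name -> row/column index of ``af``/``ab``/``gammas``.
    """
    af = np.array(af, float)
    ab = np.array(ab, float)
    gammas = np.array(gammas, float)
    n = gammas.shape[0]
    log_af = np.zeros_like(af)
    log_ab = np.zeros_like(ab)
    log_gain = np.zeros((n, 10))
    g_dyn_sp = np.zeros(n)
    g_dyn_ii = np.zeros(n)

    for spec in specs:
        xk = float(x.get(spec.factor, 0.0))
        if xk not in (0.0, 1.0):
            raise ValueError(f"condition indicator for {spec.factor!r} must be 0 or 1")
        for t in spec.extrinsic:
            if t.src not in index_of or t.dst not in index_of:
                raise KeyError(f"modulation target references unknown source {t.src}->{t.dst}")
            i, j = index_of[t.dst], index_of[t.src]
            mat = af if t.direction == "forward" else ab
            if mat[i, j] == 0:
                raise ValueError(
                    f"no {t.direction} connection {t.src}->{t.dst} to modulate"
                )
            (log_af if t.direction == "forward" else log_ab)[i, j] += t.b * xk
        for t in spec.intrinsic:
            if t.source not in index_of:
                raise KeyError(f"gain target references unknown source {t.source!r}")
            i = index_of[t.source]
            if spec.activity_dependent:
                if t.population == "SP":
                    g_dyn_sp[i] += t.g * xk
                else:
                    g_dyn_ii[i] += t.g * xk
            else:
                log_gain[i, _SELF_GAMMA_INDEX[t.population]] -= t.g * xk

    if np.any(log_af):
        af = af * np.exp(log_af)
    if np.any(log_ab):
        ab = ab * np.exp(log_ab)
    if np.any(log_gain):
        gammas = gammas * np.exp(log_gain)
    return EffectiveConnectivity(af=af, ab=ab, gammas=gammas, g_dyn_sp=g_dyn_sp, g_dyn_ii=g_dyn_ii)
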