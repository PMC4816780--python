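"""Model spaces, fixed-effects Bayesian model selection, and parameter averaging.

The analysis proceeds in three stages, each a family of
:class:`~cmcdcm.network.NetworkModel` variants with deterministic ids:

1. *architecture* — nine networks differing in the presence of the right
   inferior frontal (rIFG) and intraparietal (rIPS) sources and in their
   coupling with the superior temporal gyri;
2. *extrinsic* — sixteen models crossing, per experimental factor
   (attention, expectation), which extrinsic connections its log-scaling
   parameters may modulate: forward only (F), backward only (B), both (R)
   or none (N);
3. *intrinsic* — eighty-one models crossing nine per-factor options for
   gain (self-inhibition) modulation of superficial pyramidal or inhibitory
   interneuron populations at the A1, STG or fronto-parietal level, all
   levels (Full), or nowhere (Null).

Fixed-effects selection sums subject-level free energies (the assumption
being that one model generated every subject's data) and turns them into
posterior model probabilities under a uniform model prior.  Bayesian
parameter averaging (BPA) pools subject posteriors by precision weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import log_softmax, ndtr

from .microcircuit import ExtrinsicTarget, IntrinsicTarget, ModulationSpec
from .network import NetworkModel, Source, default_network, default_sources
from .inversion import Posterior, PriorSpec

__all__ = [
    "ModelSpace",
    "EvidenceTable",
    "BMSResult",
    "BPAResult",
    "build_architecture_space",
    "build_extrinsic_space",
    "build_intrinsic_space",
    "ffx_bms",
    "bpa",
    "WINNING_ARCHITECTURE_ID",
    "WINNING_EXTRINSIC_ID",
    "WINNING_INTRINSIC_ID",
]

WINNING_ARCHITECTURE_ID = "arch_IFG+IPS_interconnected_bilateral"
WINNING_EXTRINSIC_ID = "ext_att-B_exp-R"
WINNING_INTRINSIC_ID = "int_att-A1_II_exp-Null"


@dataclass
class ModelSpace:
    """An enumerable family of models for one selection stage."""

    stage: str  # architecture | extrinsic | intrinsic
    models: list[tuple[str, NetworkModel]]

    def __post_init__(self) -> None:
        ids = [mid for mid, _ in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("model ids must be unique")

    @property
    def ids(self) -> list[str]:
        return [mid for mid, _ in self.models]

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, model_id: str) -> NetworkModel:
        for mid, m in self.models:
            if mid == model_id:
                return m
        raise KeyError(model_id)

    def subset(self, ids: Sequence[str], stage: str | None = None) -> "ModelSpace":
        return ModelSpace(stage or self.stage, [(i, self[i]) for i in ids])


# ---------------------------------------------------------------------------
# Stage 1: architectures
# ---------------------------------------------------------------------------

_REQUIRED = ("lA1", "rA1", "lSTG", "rSTG", "rIPS", "rIFG")


def _architecture(
    sources: dict[str, Source],
    name: str,
    with_ifg: bool,
    with_ips: bool,
    bilateral: bool,
    interconnected: bool,
    forward_strength: float,
    backward_strength: float,
    params,
) -> NetworkModel:
    roster = ["lA1", "rA1", "lSTG", "rSTG"]
    if with_ips:
        roster.append("rIPS")
    if with_ifg:
        roster.append("rIFG")
    srcs = [sources[n] for n in roster]
    idx = {n: i for i, n in enumerate(roster)}
    n = len(srcs)
    af = np.zeros((n, n))
    ab = np.zeros((n, n))
    pairs = [("lA1", "lSTG"), ("rA1", "rSTG")]
    stg = ["lSTG", "rSTG"] if bilateral else ["rSTG"]
    for fp in ("rIPS", "rIFG"):
        if fp in idx:
            pairs += [(s, fp) for s in stg]
    if interconnected and with_ifg and with_ips:
        pairs.append(("rIPS", "rIFG"))
    for lo, hi in pairs:
        af[idx[hi], idx[lo]] = forward_strength
        ab[idx[lo], idx[hi]] = backward_strength
    c = np.zeros(n)
    c[idx["lA1"]] = c[idx["rA1"]] = 1.0
    return NetworkModel(sources=srcs, af=af, ab=ab, c=c, params=params, name=name)


def build_architecture_space(
    sources: Sequence[Source] | None = None,
    forward_strength: float = 2.0,
    backward_strength: float = 0.5,
    params=None,
) -> ModelSpace:
    """The nine candidate architectures of the first selection stage.

    All variants keep thalamic input to bilateral A1 and reciprocal
    A1 <-> STG coupling, and differ in which fronto-parietal sources are
    present (rIFG, rIPS), whether they couple to the STG bilaterally or to
    the right STG only, and whether they are interconnected.  The selected
    architecture (both sources, interconnected, bilateral STG coupling) is
    ``arch_IFG+IPS_interconnected_bilateral``.
    """
    from .microcircuit import MicrocircuitParams

    src_list = list(sources) if sources is not None else default_sources()
    by_name = {s.name: s for s in src_list}
    missing = [n for n in _REQUIRED if n not in by_name]
    if missing:
        raise ValueError(f"architecture space requires sources {missing}")
    params = params or MicrocircuitParams()
    variants = [
        ("arch_STG-only", False, False, True, False),
        ("arch_IFG_ipsi", True, False, False, False),
        ("arch_IFG_bilateral", True, False, True, False),
        ("arch_IPS_ipsi", False, True, False, False),
        ("arch_IPS_bilateral", False, True, True, False),
        ("arch_IFG+IPS_ipsi", True, True, False, False),
        ("arch_IFG+IPS_bilateral", True, True, True, False),
        ("arch_IFG+IPS_interconnected_ipsi", True, True, False, True),
        ("arch_IFG+IPS_interconnected_bilateral", True, True, True, True),
    ]
    models = [
        (
            name,
            _architecture(
                by_name, name, ifg, ips, bilat, inter,
                forward_strength, backward_strength, params,
            ),
        )
        for name, ifg, ips, bilat, inter in variants
    ]
    return ModelSpace("architecture", models)


# ---------------------------------------------------------------------------
# Stage 2: extrinsic modulation
# ---------------------------------------------------------------------------

EXTRINSIC_OPTIONS = ("F", "B", "R", "N")
_FACTORS = ("attention", "expectation")
_FACTOR_SHORT = {"attention": "att", "expectation": "exp"}


def _modulatable_connections(model: NetworkModel) -> list[tuple[str, str]]:
    """Forward connections (lo, hi) between A1<->STG and STG<->fronto-parietal;
    the interconnection among fronto-parietal sources is not modulated."""
    names = model.source_names
    out = []
    for i, hi in enumerate(names):
        for j, lo in enumerate(names):
            if model.af[i, j] > 0 and ("A1" in lo or "STG" in lo):
                out.append((lo, hi))
    return out


def _extrinsic_targets(model: NetworkModel, factor: str, option: str) -> list[ExtrinsicTarget]:
    short = _FACTOR_SHORT[factor]
    conns = _modulatable_connections(model)
    targets: list[ExtrinsicTarget] = []
    if option in ("F", "R"):
        targets += [
            ExtrinsicTarget(lo, hi, "forward", tie=f"{short}_fwd") for lo, hi in conns
        ]
    if option in ("B", "R"):
        targets += [
            ExtrinsicTarget(hi, lo, "backward", tie=f"{short}_back") for lo, hi in conns
        ]
    return targets


def build_extrinsic_space(base: NetworkModel) -> ModelSpace:
    """The 4 x 4 extrinsic-modulation family over attention x expectation.

    Per factor: F = forward connections only, B = backward only, R = both
    (reciprocal), N = none.  The member reported as winning lets expectation
    modulate both directions and attention the backward connections only
    (``ext_att-B_exp-R``).
    """
    models = []
    for att_opt in EXTRINSIC_OPTIONS:
        for exp_opt in EXTRINSIC_OPTIONS:
            mods = [
                ModulationSpec("attention", extrinsic=_extrinsic_targets(base, "attention", att_opt)),
                ModulationSpec("expectation", extrinsic=_extrinsic_targets(base, "expectation", exp_opt)),
            ]
            mid = f"ext_att-{att_opt}_exp-{exp_opt}"
            models.append((mid, base.with_modulations(mods, name=mid)))
    return ModelSpace("extrinsic", models)


# ---------------------------------------------------------------------------
# Stage 3: intrinsic gain modulation
# ---------------------------------------------------------------------------

INTRINSIC_OPTIONS = (
    "Null",
    "A1_SP",
    "A1_II",
    "STG_SP",
    "STG_II",
    "FP_SP",
    "FP_II",
    "Full_SP",
    "Full_II",
)

_LEVEL_SOURCES = {
    "A1": lambda names: [n for n in names if "A1" in n],
    "STG": lambda names: [n for n in names if "STG" in n],
    "FP": lambda names: [n for n in names if n in ("rIPS", "rIFG")],
}


def _intrinsic_targets(
    model: NetworkModel, factor: str, option: str
) -> list[IntrinsicTarget]:
    if option == "Null":
        return []
    level, pop = option.rsplit("_", 1)
    short = _FACTOR_SHORT[factor]
    names = model.source_names
    if level == "Full":
        srcs = sum((_LEVEL_SOURCES[lv](names) for lv in ("A1", "STG", "FP")), [])
        return [
            IntrinsicTarget(s, pop, tie=f"{short}_gain_{_src_level(s)}_{pop}") for s in srcs
        ]
    srcs = _LEVEL_SOURCES[level](names)
    return [IntrinsicTarget(s, pop, tie=f"{short}_gain_{level}_{pop}") for s in srcs]


def _src_level(name: str) -> str:
    if "A1" in name:
        return "A1"
    if "STG" in name:
        return "STG"
    return "FP"


def build_intrinsic_space(
    winner: NetworkModel, activity_dependent: bool = False
) -> ModelSpace:
    """The 9 x 9 intrinsic-gain family built on the stage-2 winner.

    Each non-Null option adds gain log-scaling parameters on the SP or II
    self-inhibition at the named hierarchical level (bilaterally where the
    level has two sources); stage-2 extrinsic modulation is retained by all
    members, and ``int_att-Null_exp-Null`` is the stage-2 winner itself.
    """
    base_ext = {spec.factor: list(spec.extrinsic) for spec in winner.modulations}
    models = []
    for att_opt in INTRINSIC_OPTIONS:
        for exp_opt in INTRINSIC_OPTIONS:
            mods = []
            for factor, opt in (("attention", att_opt), ("expectation", exp_opt)):
                mods.append(
                    ModulationSpec(
                        factor,
                        extrinsic=base_ext.get(factor, []),
                        intrinsic=_intrinsic_targets(winner, factor, opt),
                        activity_dependent=activity_dependent and opt != "Null",
                    )
                )
            mid = f"int_att-{att_opt}_exp-{exp_opt}"
            models.append((mid, winner.with_modulations(mods, name=mid)))
    return ModelSpace("intrinsic", models)


# ---------------------------------------------------------------------------
# Fixed-effects BMS
# ---------------------------------------------------------------------------


@dataclass
class EvidenceTable:
    """Subjects x models table of free energies (nats)."""

    values: np.ndarray
    subjects: list[str]
    model_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.subjects), len(self.model_ids)):
            raise ValueError("evidence table shape mismatch")

    @classmethod
    def from_posteriors(cls, posteriors: dict[str, dict[str, Posterior]]) -> "EvidenceTable":
        """``posteriors[subject][model_id]`` -> table (missing cells NaN)."""
        subjects = list(posteriors)
        model_ids = sorted({m for subj in posteriors.values() for m in subj})
        vals = np.full((len(subjects), len(model_ids)), np.nan)
        for i, s in enumerate(subjects):
            for j, m in enumerate(model_ids):
                if m in posteriors[s]:
                    vals[i, j] = posteriors[s][m].free_energy
        return cls(vals, subjects, model_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.model_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EvidenceTable":
        return cls(df.to_numpy(float), [str(i) for i in df.index], [str(c) for c in df.columns])


@dataclass
class BMSResult:
    """Fixed-effects group evidences and posterior model probabilities."""

    group_evidence: dict[str, float]
    probabilities: dict[str, float]
    best: str
    runner_up: str | None
    log_bf_runner_up: float | None

    def to_dict(self) -> dict:
        return {
            "group_evidence": self.group_evidence,
            "probabilities": self.probabilities,
            "best": self.best,
            "runner_up": self.runner_up,
            "log_bf_runner_up": self.log_bf_runner_up,
        }


def ffx_bms(table: EvidenceTable) -> BMSResult:
    """Fixed-effects Bayesian model selection over an evidence table.

    Group log evidence per model is the sum of subject free energies;
    posterior probabilities are the softmax of group evidences under a
    uniform model prior (computed by log-sum-exp, so adding a constant to
    every column leaves them unchanged).
    """
    if not np.all(np.isfinite(table.values)):
        raise ValueError("fixed-effects BMS requires a complete evidence table")
    group = table.values.sum(axis=0)
    logp = log_softmax(group)
    order = np.argsort(-group)
    best = int(order[0])
    runner = int(order[1]) if len(table.model_ids) > 1 else None
    return BMSResult(
        group_evidence={m: float(g) for m, g in zip(table.model_ids, group)},
        probabilities={m: float(np.exp(lp)) for m, lp in zip(table.model_ids, logp)},
        best=table.model_ids[best],
        runner_up=None if runner is None else table.model_ids[runner],
        log_bf_runner_up=None if runner is None else float(group[best] - group[runner]),
    )


# ---------------------------------------------------------------------------
# Bayesian parameter averaging
# ---------------------------------------------------------------------------


@dataclass
class BPAResult:
    """Precision-weighted group posterior with directional probabilities.

    ``p_positive[k]`` (``p_negative[k]``) is the Gaussian posterior
    probability that parameter k exceeds (falls below) zero.
    """

    mean: np.ndarray
    cov: np.ndarray
    param_names: list[str]
    p_positive: np.ndarray
    p_negative: np.ndarray
    n_subjects: int
    prior_corrected: bool

    def __getitem__(self, name: str) -> tuple[float, float]:
        k = self.param_names.index(name)
        return float(self.mean[k]), float(self.cov[k, k])


def bpa(
    posteriors: Sequence[Posterior],
    prior: PriorSpec | None = None,
    correct_prior: bool = True,
) -> BPAResult:
    """Bayesian parameter averaging of subject-level Gaussian posteriors.

    Pools by adding posterior precisions and precision-weighted means.  With
    ``correct_prior`` (requires ``prior``), the prior is counted once rather
    than n times: ``(n - 1)`` prior precisions (and precision-weighted prior
    means) are subtracted, so n copies of the prior average back to the
    prior itself.
    """
    if not posteriors:
        raise ValueError("no posteriors to average")
    names = posteriors[0].param_names
    p = len(names)
    for post in posteriors:
        if post.param_names != names:
            raise ValueError("posteriors disagree in parameter dimension or ordering")
    if correct_prior and prior is None:
        raise ValueError("prior correction requires the PriorSpec")

    prec = np.zeros((p, p))
    pm = np.zeros(p)
    for post in posteriors:
        lam_i = np.linalg.inv(post.cov)
        prec += lam_i
        pm += lam_i @ post.mean
    n = len(posteriors)
    if correct_prior and n > 1:
        free = [q for q in prior.params if q.var > 0]
        if [q.name for q in free] != names:
            raise ValueError("prior does not match the posteriors' parameters")
        prec0 = np.diag([1.0 / q.var for q in free])
        mu0 = np.array([q.mean for q in free])
        prec -= (n - 1) * prec0
        pm -= (n - 1) * (prec0 @ mu0)
    eig = np.linalg.eigvalsh(0.5 * (prec + prec.T))
    if eig.min() <= 0:
        raise np.linalg.LinAlgError(
            f"pooled precision not positive definite (min eigenvalue {eig.min():.3e})"
        )
    cov = np.linalg.inv(prec)
    cov = 0.5 * (cov + cov.T)
    mean = cov @ pm
    sd = np.sqrt(np.diag(cov))
    z = np.divide(mean, sd, out=np.zeros_like(mean), where=sd > 0)
    return BPAResult(
        mean=mean,
        cov=cov,
        param_names=list(names),
        p_positive=ndtr(z),
        p_negative=ndtr(-z),
        n_subjects=n,
        prior_corrected=bool(correct_prior and n > 1),
    )
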