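# Methods

`cmcdcm` implements dynamic causal modeling (DCM) of evoked
magnetoencephalographic responses with a canonical-microcircuit neural mass
model, for the study design in which temporal attention and sensory
expectation (a roving-oddball standard/deviant manipulation) are crossed in
a 2×2 factorial design. This note documents the generative model, the
inversion and selection machinery, the synthetic-study generator, and the
numerical and design choices a maintainer would want to know.

## The generative model

### Microcircuit dynamics

Each cortical source contains four populations — spiny stellate cells (SS,
layer 4), superficial pyramidal cells (SP, layers 2/3), inhibitory
interneurons (II), and deep pyramidal cells (DP, layers 5/6) — each with a
membrane potential `V_m` (mV) and current `I_m = dV_m/dt`. Synaptic
dynamics follow the critically damped second-order (alpha) kernel: each
current equation carries the damping terms `−2κ_m I_m − κ_m² V_m`, giving
population `m` the impulse response `t·exp(−κ_m t)` with time constant
`1/κ_m` ms. Presynaptic influence enters through the centered logistic
rate function

```
σ(v) = 1/(1 + exp(−r v)) − 1/2 ,
```

an odd, saturating function with σ(0) = 0, so the all-zero state is an
exact fixed point of the network. The intrinsic couplings are the ten
signed connections

```
İ_SS = κ_SS ( A^F σ(V_SP,lower) − γ_SS→SS σ(V_SS) − γ_SP→SS σ(V_SP) − γ_II→SS σ(V_II) + C·u )  − 2κ_SS I_SS − κ_SS² V_SS
İ_SP = κ_SP ( −A^B σ(V_DP,higher) + γ_SS→SP σ(V_SS) − γ_SP→SP σ(V_SP) )                        − 2κ_SP I_SP − κ_SP² V_SP
İ_II = κ_II ( −A^B σ(V_DP,higher) + γ_SS→II σ(V_SS) + γ_DP→II σ(V_DP) − γ_II→II σ(V_II) )      − 2κ_II I_II − κ_II² V_II
İ_DP = κ_DP ( A^F σ(V_SP,lower) − γ_DP→DP σ(V_DP) − γ_II→DP σ(V_II) )                          − 2κ_DP I_DP − κ_DP² V_DP
```

Ascending (forward) extrinsic connections `A^F` carry superficial pyramidal
output of lower sources into the SS and DP populations of higher sources
and are excitatory; descending (backward) connections `A^B` carry deep
pyramidal output downward into SP and II and enter with negative
(inhibitory) sign. Interneurons inhibit every population they touch — a
property the test suite audits directly. There is no intrinsic SP→DP
coupling; the four-population circuit is implemented exactly as listed
above. Conduction delays are omitted (pure ODE coupling).

The damping-term form is a deliberate package choice: the alpha-kernel
`−2κI − κ²V` is the only dimensionally consistent second-order synaptic
kernel in these units (both terms are mV/ms²), and it is what makes the
default circuit satisfy the stability requirement below.

### Default parameters

All defaults are configuration values, not constants; they were selected
by linearized eigenvalue analysis so that the baseline network *and* every
condition of the 2×2 design under the default effect sizes are
asymptotically stable, with the impulse response decaying below 1% of its
peak within the 300 ms analysis window.

| parameter | default | units | note |
|---|---|---|---|
| κ (SS, SP, II, DP) | 1/4, 1/8, 1/16, 1/28 | 1/ms | membrane/synaptic time constants 4–28 ms |
| γ (intrinsic) | 4, 4, 4, 4, 2, 4, 2, 8, 2, 2 | – | order as the ten couplings above; SP→SP = 8 and SS→SP = 2 damp the SS↔SP loop |
| r (sigmoid slope) | 2/3 | – | standard convention for evoked-response neural mass models |
| forward / backward strength | 2.0 / 0.5 | – | keeps the cortico-cortical loop gain below its oscillatory margin under the strongest modulated condition |
| input latency / dispersion / amplitude | 20 / 8 / 1 | ms, ms, a.u. | Gaussian thalamic volley to bilateral A1 |

### Network, input and observation

The default network is the six-source auditory hierarchy — bilateral
primary auditory cortex (lA1, rA1), bilateral superior temporal gyrus
(lSTG, rSTG), right intraparietal sulcus (rIPS) and right inferior frontal
gyrus (rIFG) — with thalamic input to bilateral A1 only. Hierarchy levels
are A1 (1) < STG (2) < rIPS (3) < rIFG (4); forward connections may only
point up-level and backward connections down-level. Placing rIFG above
rIPS is a convention that realizes the "fronto-parietal sources
interconnected" architecture within a strict hierarchy; nothing downstream
depends on which of the two sits higher.

Sensors see a fixed linear mixture: each source contributes a scalar
dipole activity `0.8·V_SP + 0.2·V_DP` (pyramidal-dominated, reflecting the
dendritic origin of MEG/EEG signals; SS and II contribute 0 by default),
projected through a sensors × sources lead-field matrix. Which populations
are visible to sensors is not identifiable from data of this kind; the
SP-dominant mixture is a declared convention.

### Condition-specific modulation

Experimental factors enter as log-scaling parameters. An extrinsic target
with parameter `b` scales its connection by `exp(b·x)` under condition
indicator `x ∈ {0, 1}`; an intrinsic gain target with parameter `g` scales
the self-inhibition `γ_SP→SP` or `γ_II→II` by `exp(−g·x)`, so positive `g`
means disinhibition — an increase of the population's gain, the circuit
quantity interpreted as precision. Multiplicative log-scale modulation
keeps strengths positive, and a zero parameter is exactly neutral: with
all indicators or parameters zero the four condition responses are
bit-identical.

Deviants carry the expectation indicator (expectation violation), attended
trials the attention indicator; the unattended standard is the baseline.

An optional activity-dependent mode makes gain modulation state-dependent:
the log-scaling of a source is multiplied at each instant by
`(1 + σ(V_DP))` of its backward-afferent sources (weighted by the backward
adjacency), so descending drive gates the gain change. No canonical
equation exists for this mechanism; the implemented form is a declared
choice and the mode is OFF by default — all shipped model spaces and the
synthetic generator use static gain scaling.

## Numerical integration

Fixed-step classical Runge–Kutta 4, default step 0.5 ms, starting from the
zero state at stimulus onset (t = 0). Output sampling is exact: the
integrator subdivides each output interval into equal steps no longer than
the solver step, so grid samples are integration points and no
interpolation is involved. Instability raises an explicit divergence error
naming the source and time. A step-halving utility measures the deviation
from a 10× finer reference; for the default model and the 1–300 ms window
at 300 Hz the maximum channel-normalized deviation is ~7×10⁻⁵, well inside
the 10⁻³ contract. The inner loops are numba-compiled, which is what makes
finite-difference Jacobians and replicate studies tractable on one CPU.

## Inversion (variational Laplace)

The observation model is Gaussian with a single isotropic sensor-noise
precision `exp(λ)` (one hyperparameter; a deliberate simplification of
multi-component noise models, identifiable at this problem size). Free
parameters carry Gaussian priors on log-scaling coordinates:

- extrinsic global log-scales (forward, backward): N(0, 1/16)
- modulation parameters b, g (one per tie group): N(0, 1/4)
- input latency: N(20 ms, 16 ms²); log input amplitude: N(0, 1/16)
- noise log-precision hyperprior: N(4, 16)

Modulation targets that share a *tie* label share one estimated parameter
(e.g. all backward connections modulated by attention form one group).
This tying is the package's desk-scale identifiability choice; per-target
parameters are available by giving targets distinct ties. Zero prior
variance fixes a parameter and removes its Jacobian column.

The fit loop is EM-style Gauss–Newton: sensitivities come from central
finite differences (step `10⁻³ × max(1, prior SD)` per parameter), the
posterior covariance is `Σ = (e^λ JᵀJ + Σ₀⁻¹)⁻¹`, and the mean update is
halved until the proposed step increases the free energy, else rejected —
so the accepted-F trace is non-decreasing by construction. Several
Gauss–Newton steps reuse one Jacobian before it is refreshed (default 8),
which roughly halves inversion cost without changing fixed points. The
noise log-precision is updated by clipped Newton steps from its
maximum-likelihood value (the objective is concave in λ, so this converges
globally; naive Newton from a distant start can overshoot catastrophically).
Convergence is declared after 4 consecutive outer sweeps improving F by
less than 10⁻² nats, with a cap of 64 sweeps.

The free energy is reported with exact bookkeeping,
`F = accuracy − complexity`, where accuracy is the expected Gaussian
log-likelihood of the residuals (including the `tr(JΣJᵀ)` uncertainty
correction) and complexity is `KL(q‖p)` for the parameter posterior plus
the KL term of the Gaussian belief over λ. Data and predictions are
mean-centered per sensor before residual computation, and only samples
inside the analysis window enter the residuals.

## Model comparison and parameter averaging

Fixed-effects Bayesian model selection sums subject-level free energies
per model (the assumption that one model generated every subject's data)
and applies a softmax under a uniform model prior, computed by
log-sum-exp; probabilities are exactly shift-invariant and normalized. The
report includes the log Bayes factor of the best model against the
runner-up. A lead of 3 nats corresponds to ≈95% posterior probability, 32
nats to >99.99%.

The three model-space factories reproduce the staged search:
architecture (9 members varying the presence and STG coupling of the
fronto-parietal sources; the non-winning members are documented
reconstructions, since only the winner's structure is fully specified),
extrinsic modulation (4 options {forward, backward, reciprocal, none} per
factor = 16; the A1↔STG and STG↔fronto-parietal connections are
modulatable, the rIPS↔rIFG interconnection is not), and intrinsic gain (9
options {Null, A1/STG/FP/Full × SP/II} per factor = 81, applied
bilaterally where a level has two sources, with stage-2 extrinsic
modulation retained by every member).

Bayesian parameter averaging pools subject posteriors by precision
weighting. With prior correction (default ON, the standard multi-subject
derivation), the prior is counted once rather than n times, so n copies of
the prior pool back to the prior exactly; the uncorrected rule is
available by flag. Directional statements ("the gain increase is positive
with posterior probability > 99%") are one-sided Gaussian tail
probabilities at zero of the pooled posterior.

## Synthetic studies

The generator emulates the study structure: 2×2 condition design, 1–300 ms
window at 300 Hz (90 samples), 6 subjects, 32 sensors (desk-scale stand-ins
for the original 275-sensor arrays), 8 dB sensor SNR, Gaussian
between-subject variability (SD 0.1 on the log scale) around group effect
sizes of 0.5 (attention, backward), 0.7 (attention, A1-II gain), 0.5 / 0.4
(expectation, forward / backward). These defaults yield condition
contrasts of roughly 10–30% of the peak sensor response. Lead fields are
smooth unit-norm random topographies on a circular sensor array,
deterministic per seed. Noise is white in time and sensors — real MEG
noise is colored and spatially correlated, so recovery rates measured here
are optimistic in that specific respect. The generating process is exactly
the simulator under test: recovery failures therefore localize to
inversion or selection, not to a generator mismatch.

What passing recovery tests shows: that the pipeline identifies the
generating modulation site (II vs SP gain) and effect signs under the
stated noise and between-subject variability. What it does not show:
robustness to lead-field misspecification, colored noise, source
mislocalization, or model classes outside the enumerated spaces.

## Numerical choices and degenerate inputs

- Softmax via log-sum-exp with max subtraction; no overflow for any finite
  evidence table.
- Posterior covariances are symmetrized; pooled BPA precision is checked
  for positive definiteness and rejected with the offending eigenvalue.
- Singular prior/posterior covariances raise errors carrying the condition
  number.
- A zero-amplitude input yields exactly zero trajectories, predictions and
  sensor data (fixed-point property, asserted in tests).
- Unstable subject draws in the generator are re-drawn (recorded count, at
  most 10) before erroring.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; fits contain no stochastic steps, so the whole
  pipeline is bit-reproducible given seeds.

## Problem sizes

The shipped tests and the acceptance script use the generator's default
study (6 subjects × 32 sensors × 90 samples × 4 conditions) with ten
replicates for recovery rates, a three-model candidate space
{A1-II winner, A1-SP rival, extrinsic-only Null}, and small two-source
networks for unit-level inversion properties. These sizes were chosen so a
full run completes comfortably on a single CPU while leaving every
selection margin (thousands of nats) far from its decision threshold.

## Known limitations

- The spatial forward model is a generic parameterized lead field; no
  realistic head model, dipole orientation fitting, or spatial parameter
  estimation (the lead field is fixed and known during inversion).
- One isotropic noise component; no per-sensor or temporally correlated
  noise estimation.
- Trial-level variability, artifacts, and tone-by-tone roving sequences
  are out of scope; the unit of data is the trial-averaged ERF.
- Fixed-effects selection only; no random-effects BMS or Bayesian model
  averaging.
- The relative divergence latencies of II- vs SP-gain sweeps in the
  contribution analysis depend on the fitted parameter regime; the
  package asserts the structural property (disinhibition monotonically
  raises the A1 peak) rather than any particular latency ordering.
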