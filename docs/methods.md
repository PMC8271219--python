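# Methods

## Regulatory-network model

Each node of a signed topology follows a shifted-Hill ODE:

    dX_i/dt = g_i * prod_j H^s(X_j; X0_ji, n_ji, lambda_ji) - k_i * X_i
    H^s(X)  = lambda + (1 - lambda) / (1 + (X / X0)^n)

The product runs over the regulators j of node i; an empty product is 1.
`H^s` equals 1 with no regulator input and approaches the fold change
`lambda` at saturation — `lambda > 1` for activation, `0 < lambda < 1` for
inhibition. The model deliberately abstracts transcription, translation and
post-transcriptional control (e.g. miR-200 acting on ZEB1 mRNA) into a
single regulation layer; there are no delays, no explicit estrogen-ligand
pharmacology and no spatial effects.

### The default network

The bundled topology (`emt_er.topo`, 5 nodes / 13 edges) couples the
estrogen-receptor module — ERa66 self-activation, ERa66 ⊣ ERa36,
ERa66 ⊣ SLUG, SLUG ⊣ ERa66, ZEB1 ⊣ ERa66, ERa36 → ZEB1 — to the EMT core:
the mutually inhibitory, self-activatory ZEB1/miR-200 loop together with
SLUG (SLUG ⊣ miR-200, miR-200 ⊣ SLUG, SLUG → ZEB1, SLUG self-activation).
The exact SLUG edge set is the one point where the literature permits
variants; the bundled default is the full mutual-inhibition version, which
reproduces the reference multistability census (~65% bistable / ~20%
tristable / ~9% monostable), while a minimal 10-edge variant
(`emt_er_minimal.topo`, SLUG ⊣ miR-200 only) ships alongside for
comparison — it is markedly less multistable (~54% bistable / 23%
monostable). Topologies are data: any edge list in the whitespace
"SOURCE TARGET TYPE" dialect (1 = activation, 2 = inhibition) is a drop-in
replacement.

### Kinetic-parameter ensembles

One "cell line" is one random draw of all kinetic parameters; the ensemble
is the population of possible realizations of the circuit. Defaults:

| parameter | range | units |
|---|---|---|
| production g | U[1, 100] | conc/time |
| degradation k | U[0.1, 1] | 1/time |
| Hill coefficient n | integer U{1..6} | – |
| activation fold lambda | U[1, 100] | – |
| inhibition fold | 1 / U[1, 100] | – |
| threshold X0 (edge j→i) | U[0.02 M_j, 1.98 M_j] | conc |

The threshold rule is the *half-functional* rule: each regulator should
have roughly even odds of sitting above its threshold across the ensemble.
`M_j` is the median level of regulator j estimated by a one-pass Monte
Carlo that multiplies the unregulated g/k draw by a shifted-Hill factor
for each of j's own incoming edges (regulator at a random unregulated
level, threshold from the unregulated rule). This regulation awareness
matters: anchoring every threshold at the bare median g/k (available as
`threshold_rule="half_functional_unregulated"`) leaves strongly inhibited
nodes orders of magnitude below their regulators' thresholds, switches the
feedback loops off, and collapses the census to ~55% monostable. A fully
recursive (self-consistent) estimate moves the census by < 0.5 percentage
points, so the one-pass estimate is the default. The realized
P(regulator > threshold) is 0.43–0.53 on every edge of the default
network. Both median estimates use fixed internal seeds: the rule is a
deterministic property of the ranges, not part of a run's random stream.

In-silico over-/down-expression multiplies/divides one node's production
rate by a configurable fold (default 10×), leaving everything else fixed.

### Steady-state enumeration

Per parameter set, 100 initial conditions are drawn log-uniformly between
each node's extreme achievable levels ((g/k) × the product of the extreme
incoming Hill multipliers). Each trajectory is relaxed by an adaptive
embedded Runge–Kutta pair (Bogacki–Shampine 3(2), FSAL, error control with
rtol 1e-4 / step-size clamps), compiled with numba; when the relative
residual max|dX/dt|/max(X, 1) falls below 1e-3 a damped Newton iteration
with the analytic Jacobian polishes the point to residual 1e-10.
Trajectories that fail to settle within t_max = 1000 time units are
reported non-converged (sustained oscillations fall in this bucket; none
occur in the default ensemble at n = 5000). Newton is only ever started
from a settled point, so it cannot jump basins, and every polished state
is certified stable by the Jacobian's eigenvalues (max real part < 1e-6);
the rare saddle hit is dropped and counted. States are deduplicated at
Euclidean distance 0.1 in log2 concentration space — far above the
post-Newton jitter (~1e-10) and well below the separation of genuine
attractors. 100 initial conditions saturate state discovery for this
network: quadrupling them changes < 2% of the per-set counts. scipy's
LSODA serves as an independent cross-check oracle in the test suite (the
compiled path agrees to < 1e-3 in log2 norm); it is not the production
integrator because the ensemble stage runs ~500k relaxations.

### Scoring and classification

All steady states are pooled (each state weighted equally), log2
transformed and z-normalized per node. Scores: EM = z(ZEB1) − z(miR200),
resistance = z(ERa36) − z(ERa66). The EM scores are fitted with a
3-component and the resistance scores with a 2-component univariate
Gaussian mixture (EM algorithm, 20 restarts, fixed seed); cutpoints are
the equal-posterior boundaries between adjacent components ordered by
mean. A degenerate fit — vanishing weight, unseparated components (mean
gap below half the pooled component SD) or disordered boundaries — falls
back to quantile cutpoints with a warning. Classification is a partition
into ES/ER/HS/HR/MS/MR; exact ties go to the lower (less mesenchymal, more
sensitive) class. Perturbed ensembles are scored with the *control* run's
normalization statistics and thresholds so frequency shifts are
comparable; the perturbed run reuses the control's initial-condition
stream, making the fold = 1 perturbation an exact no-op.

The randomized-topology control rewires the network by directed
double-edge swaps that keep each edge's sign, every node's in/out degree
and the global activation/inhibition counts; self-loops are left in place
and swaps creating duplicates or new self-loops are rejected. Each
randomized network is simulated, normalized and scored independently; the
wild-type Spearman correlation is reported with its percentile in the
randomized distribution.

### Stochastic dynamics and landscapes

Euler–Maruyama: X(t+dt) = X + f(X) dt + eta*sqrt(dt)*N(0,1) per node, with
clipping at 0 and a 1e9 divergence guard. The noise amplitude is not fixed
by the reference formulation (a unit-variance increment is negligible
against concentrations of order 10–10^4), so eta defaults to 5% of each
node's g/k scale and is exposed as a knob; landscape reproductions are
therefore qualitative (basin count and arrangement), not quantitative.
Defaults: dt = 0.01, horizons of 10^3–10^4 time units, recording every 10
steps. Occupancy histograms over the (EM, resistance) plane give P and the
pseudo-potential −log P; empty bins stay empty (+inf) unless an optional
Gaussian smoothing is requested. Transition detection classifies the score
series and commits a switch only after the new label persists ≥ dwell_min
samples (default 50), debouncing threshold chatter.

## Population model

Agent-based, discrete time. Each cell carries two scores fixed at birth —
sensitive-state score ~ N(−2, SD²), resistant-state score ~ N(+2, SD²),
clamped to [−6, 6] — and a state index selecting the active one. SD is the
non-genetic heterogeneity. Per step, in order:

1. **death** — basal (p = 0.1) and, under drug, an independent draw
   escaped with probability e^x/(e^x + c), c = 0.6, of the active score x
   (per-step drug mortality ≈ 0.82 for a typical sensitive cell, ≈ 0.075
   for a typical resistant one);
2. **drug-induced plasticity** — drug-surviving sensitive cells flip to R
   with probability `drug_induced_psr`;
3. **stochastic switching** — simultaneous draws S→R with p_sr and R→S
   with p_rs, plus an independent MET-induced R→S draw;
4. **proliferation** — division with probability 0.91 × (1 − N/K),
   K = 10^5, evaluated at the post-death population size; daughters
   inherit the state and resample both scores from the population
   Gaussians (the mother keeps hers).

The sigmoid is implemented as *survival* against drug-induced death:
the alternative (death growing with resistance score) contradicts every
qualitative behavior of the system. Initial populations are 100 cells by
default; initially sensitive cells have their sensitive score
rejection-sampled below 0 (and initially resistant cells above 0),
matching the "all-sensitive start" protocol. Extinction probability is
the fraction of seeded replicates (default 100) at zero cells by the
horizon (default 100 steps), reported with its binomial standard error and
the final sizes of surviving replicates.

### Calibration caveat

The qualitative regimes are robust and tested: P_SR = 1 rescues an
all-sensitive population into a near-capacity resistant colony; P_SR = 0
guarantees extinction under drug; heterogeneity delays but does not by
itself prevent elimination; MET induction (forced R→S) collapses an
otherwise surviving population and never increases final size. The
*quantitative* extinction probabilities in the intermediate regime
(P_SR = 0.5 / P_RS = 1.0 across SD = 0.65–0.75, and P_SR = P_RS = 0.2 at
SD = 0.8) are a different matter: there the per-step population growth
factor sits within ~1% of 1, so they are exquisitely sensitive to
implementation details that the published description leaves open — the
within-step ordering of switching and death, whether the two switching
draws chain, the initial population size, and the daughter-state rule. A
systematic scan of the textually defensible variants shows none matches
all reported anchor values simultaneously under the stated constants; the
implementation therefore follows the documented semantics above, and the
intermediate-regime probabilities it produces (extinction ≈ 1 in the
flushing regime, ≈ 0 in the persistent regime at these settings) should be
read as one consistent realization of an under-determined protocol rather
than a reproduction of the reference panel.

## Synthetic fixtures

Testing needs no external data. The fixtures module provides (a) the
degree/sign-preserving topology randomizer above; (b) toy circuits with
oracle-verified attractors — a symmetric two-node toggle switch (two
stable states located by dense grid-seeded root finding with
finite-difference stability checks, fully independent of the production
pipeline), a provably monostable auto-repressor, and a feed-forward
cascade with a closed-form fixed point; and (c) score ensembles drawn from
known Gaussian mixtures, returned with their generating parameters so
threshold recovery can be checked against analytic equal-posterior
boundaries. These fixtures exercise the machinery, not the biology: a
passing toggle test validates the solver contract, and only the ensemble
runs of the full network test the scientific claims.

## Reproducibility

Every random stage takes a `numpy.random.Generator` or integer seed;
workflows fan a single master seed into per-stage children via
`SeedSequence.spawn` and write manifests with SHA-256 checksums of every
output, so reruns are byte-identical. Problem sizes used by the bundled
reproduction script: 5000 parameter sets × 100 initial conditions for the
census and correlation; 100 replicates × 100 steps per extinction
estimate.

## Known limitations

- The regulation layer is coarse-grained; parameter ranges are generic
  rather than gene-specific, so all ensemble statements are statistical,
  not cell-line predictions.
- Limit cycles are reported as non-converged, not analyzed.
- Landscapes depend on the (configurable) noise scale; only their basin
  structure is meaningful.
- The population model has no cell–cell interactions, spatial structure,
  pharmacokinetics or genetic mutation; its intermediate-regime
  calibration is under-determined (see above).
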