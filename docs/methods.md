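# Methods

`ictonet` quantifies how the choice of node-dynamics model affects
predictions of epilepsy-surgery outcome made with network models. Nodes of
a binary directed network carry one of three stochastic seizure-transition
models; the propensity of the network to generate seizure-like activity
(brain network ictogenicity, BNI) is mapped over a window of excitability
and coupling parameters; the effect of a virtual resection is the
fractional change of the map-averaged BNI when one node is removed (node
ictogenicity, NI); and agreement between models is the weighted Kendall
rank correlation of their per-node NI values.

## Node models

All models are coupled through a binary adjacency matrix `M` with the
convention `M[i, j] = 1` iff node `i` receives an edge from node `j`, and
integrated with a fixed-step Euler–Maruyama scheme.

**Physiological model.** A modified Jansen–Rit neural mass per node:
pyramidal cells, excitatory interneurons, and slow and fast inhibitory
interneurons, plus a slow efferent feedback loop (12 state variables per
node). Rates are in s⁻¹ (`a = 100`, `b = 50`, `g = 500`, `a_d = 100`),
gains in mV (`A = 5`, `B = 44`, `G = 20`, `A_d = 3.25`), connectivity
constants `C1 = 135`, `C2 = 0.8 C1`, `C3 = C4 = C7 = 0.25 C1`,
`C5 = 0.3 C1`, `C6 = 0.1 C1`, and the potential-to-rate sigmoid has
`ν0 = 6 mV`, `e0 = 2.5 s⁻¹`, `r = 0.56 mV⁻¹`. The observable is the
pyramidal membrane potential `y3 − y5 − y7`. In the excitability window
used here (`p ∈ [50, 110]`) the node sits near a SNIC bifurcation;
Gaussian noise (σ = 1.85, entering the pyramidal input-current equation,
amplitude `A·a·σ·√dt` per step) triggers transitions between background
and large-amplitude epileptiform oscillation. Coupling adds
`α Σ_j M_ij y11_j` to the pyramidal input.

**Theta model.** The Ermentrout–Kopell canonical model, the normal form of
the SNIC bifurcation: one phase θ per node,
`dθ = [1 − cos θ + (1 + cos θ) I] dt` with
`I = p + ξ + α Σ_j M_ij [1 − cos(θ_j − θ_s)]`, where
`θ_s = −arccos((1+p)/(1−p))` is the uncoupled resting phase. An uncoupled
noise-free node rests for `p < 0` and spikes periodically with period
`π/√p` for `p > 0`.

**Bistable model.** The subcritical-Hopf normal form with a stabilising
quintic term, `ż = (p + iω) z + 2z|z|² − z|z|⁴` (ω = 20), coupled
additively in the real part (`α Σ_j M_ij x_j`) with independent noise
`β σ ξ` (β = 0.01, σ = 1.85) on both components. For `−1 ≤ p ≤ 0` the
fixed point `z = 0` coexists with a stable limit cycle at
`|z|² = 1 + √(1+p)`; the unstable cycle at `|z|² = 1 − √(1+p)` separates
the basins.

### Noise conventions

The physiological and bistable models read their printed σ as a
continuous-time diffusion: per-step increments of standard deviation
`σ·√dt` (times the model's amplitude factor). For the theta model this
reading is untenable: with σ = 8 the multiplicative phase diffusion
`(1+cos θ)·σ` overwhelms the drift entirely, and the BNI map loses all
coupling dependence (we verified that a node receiving a mean coupling
drive that shifts its effective excitability from −3 to −0.55 keeps an
ictal fraction near 0.15 instead of rising towards 0.9, and that map rows
become flat in α). We therefore read the theta σ as the standard deviation
of the noise *current* per integration step at the model's native step
(2×10⁻³) — the convention of the implementations this model class descends
from, where ξ is added to `I` and multiplied by `dt` — and convert it once
to the equivalent step-size-independent diffusion `σ·√(2×10⁻³) ≈ 0.358` so
that refining `dt` converges. In this regime ictal events are rare
noise-initiated and network-amplified, and the map has the expected
structure in both excitability and coupling.

### Integration defaults

`dt = 10⁻³ s` (physiological; its rates make larger steps marginally
stable against the fast inhibitory loop `g = 500 s⁻¹`) and `dt = 2×10⁻³`
(theta, bistable), both inside the `[10⁻³, 5×10⁻³]` band the models are
specified for. Initial conditions follow each model's ictogenicity
definition: physiological — all states zero with the transient discarded;
theta — every phase at `θ_s`; bistable — exactly `z = 0` (required by the
escape-time definition). Burn-in and reference-window lengths are
configurable; the shipped presets are listed below.

## Ictal classification

The fraction-of-time BNI needs a per-sample ictal/background decision, and
the models' sources do not pin one down. The choices here (all exposed in
`IctalClassifierConfig`, all sweepable):

* **theta** — a node is ictal while its phase is outside a band of
  half-width π/4 around θ_s, i.e. for the full span of each spike
  excursion. With the noise convention above, resting jitter stays well
  inside the band except very close to the SNIC.
* **physiological** — a node is ictal while its output deviates from its
  own per-trajectory median by more than a threshold. The median stands in
  for the background fixed-point output and is robust as long as the node
  is not ictal for most of the window. The threshold defaults to 6× the
  robust (MAD-based) standard deviation of a noise-driven single node at
  the lower edge of the excitability window — large enough to ignore
  background fluctuation, small against the tens-of-mV epileptiform
  excursions. It is calibrated once per map from a seed derived from the
  master seed only, so the intact map and all removal maps use the same
  threshold.
* **bistable** — BNI is an escape-time transform: per node, the first
  passage of `|z|²` past 1 (≥ the unstable-cycle separatrix everywhere in
  `p ∈ [−1, 0]`), censored at the reference time `T`; network
  `BNI = 1 − ⟨t_escape⟩/T`. Censored nodes contribute `T` (equivalently 0
  to BNI), which the escape-time definition leaves open.

## BNI maps and node ictogenicity

BNI is evaluated on a regular excitability×coupling grid (standard
windows: physiological `p ∈ [50,110]`, `α ∈ [0,1000]`; theta
`p ∈ [−4,−0.1]`, `α ∈ [0,10]`; bistable `p ∈ [−1,0]`, `α ∈ [0,10]`;
full-fidelity resolution 192×192), one stochastic realisation per cell.
`NI_i = (⟨BNI⟩₀ − ⟨BNI⟩_i)/⟨BNI⟩₀` compares the map mean before and after
deleting node *i* over the *same* grid window; `ΔNI = max_i NI_i − min_i
NI_i` measures heterogeneity. The classical single-operating-point variant
(raise α until BNI = 0.5, then measure removals there) is provided as
`calibrate_coupling_for_bni` (bisection with replicate averaging).

**Seeding and common random numbers.** Every cell's seed is a pure
function of (master seed, intact-network id, model, cell index), and every
*node label* then derives its own noise stream from the cell seed.
Consequences: (i) any map is reproducible in isolation and results are
independent of evaluation order and worker count; (ii) a node keeps its
noise realisation when other nodes are removed, so removal maps are paired
with the intact map (common random numbers), removing part of the shared
Monte-Carlo error from NI differences at no cost; (iii) the three models
never share noise streams — sharing them measurably biases the
cross-model rank agreement, because correlated Monte-Carlo errors then
masquerade as systematic (dis)agreement between models.

Grid-sweep kernels classify on the fly (numba, inline
xorshift64*/Marsaglia-polar Gaussian generator) and are tested to
reproduce the stored-trajectory reference route bit-for-bit; the bistable
kernel stops integrating once every node has escaped, which cannot change
any first-passage time.

## Model comparison

The weighted Kendall coefficient over all unordered node pairs uses weight
`|NI_i^A − NI_j^A|·|NI_i^B − NI_j^B|`: concordant pairs add it to P,
discordant to Q, τ = (P−Q)/(P+Q). Exactly tied values (absolute tolerance
10⁻¹²) carry zero weight. So do *structural* ties: node pairs in the same
automorphism orbit of the network, whose true NI values are equal by exact
symmetry — their simulated ordering is pure Monte-Carlo noise, and because
the weighting concentrates τ on the largest gaps, a vertex-transitive
network (e.g. a directed cycle or the complete digraph) would otherwise
contribute a ±1 coin flip to the ensemble mean at *any* simulation
fidelity. Orbits are computed exactly (marked-graph isomorphism with
degree-invariant pruning; generic random digraphs are rigid and cost
nothing). If no pair is rankable — every node in one orbit — τ is flagged
undefined and the network is excluded from ensemble means (with a count). The
weighting makes the statistic insensitive to rank flips among nearly-tied
nodes, whose order is dominated by simulation noise. A top-k restriction
(`top_k_kendall`) ranks by a named reference list and reports both
references.

The ensemble analysis min–max-normalises ΔNI per model, keeps networks
with normalised ΔNI > 0.05, sorts by the reference model's ΔNI and splits
into four equal-occupancy bins (remainder to the lowest bins), reporting
bin-wise ⟨τ⟩ ± s.e.m. with each model of a pair used as reference
separately. The degree–heterogeneity link is the Spearman correlation
between σ_out/⟨k_out⟩ (population-SD convention, stated here because the
convention is not fixed elsewhere) and ΔNI per model.

## Network ensembles (the synthetic data)

The study conditions are: all 13 weakly-connected nonisomorphic 3-node
digraphs and all 199 4-node ones (exhaustive enumeration over zero-diagonal
binary matrices, exact canonical-form deduplication — "connected" must be
read as *weakly* connected to reproduce those counts); and 125 19-node
digraphs with edge counts approximately uniform on [18, 342] (the
spanning-tree bound n−1 and the complete-digraph bound n(n−1)). The
19-node sampler stratifies: network k targets the edge count
`18 + k·(342−18)/(n−1)` (rounded), places that many directed edges
uniformly at random, and rejects draws that are not weakly connected or
are isomorphic (exact test behind degree/neighbourhood fingerprints) to an
accepted network. Self-loops are excluded throughout (the networks
represent inter-regional interaction). What this generator does *not*
emulate: weighted or signed coupling, and the spatial/functional
correlation structure of networks inferred from clinical recordings — so
passing ensemble tests speaks to the models' behaviour on generic directed
topologies, not to agreement on patient-derived networks.

## Problem sizes and presets

Full fidelity ("full" preset: 192×192 grids, reference windows 40 time
units for theta/bistable and 20 s physiological) costs hours per 19-node
network and is intended for batch runs via the CLI. The shipped reduced
preset ("desk": 24×24 grids; reference windows 20/20/8) resolves per-node
NI differences down to roughly 0.01 on 4-node networks — enough for the
cross-model agreement analyses — in ~20 s per network. The test suite's
19-node ensemble runs at a further reduced scale (8×8 grids; windows
chosen per model so that the NI noise floor, measured as the NI spread on
a rotationally symmetric network where it must vanish, is smallest for the
models whose true ΔNI contrasts are smallest). All reduced sizes are
stated in the tests that use them.

## Numerical choices and degenerate inputs

* Escape detection and phase classification happen after the full
  Euler–Maruyama step, including the noise increment.
* Isolated nodes (possible after removal) are simulated as uncoupled.
* A removal that leaves the intact map mean at zero makes NI undefined and
  raises a named error rather than returning 0/0.
* Non-finite trajectories raise a `SimulationError` carrying the model,
  parameters and step; fused kernels return NaN internally and the map
  layer converts that to the same error with the cell coordinates.
* The deterministic bifurcation diagnostics (SNIC onset, coexistence
  boundary, settled amplitudes) use bisection to a stated tolerance; the
  bistable diagnostics integrate the exactly-reduced radial equation
  `du/dt = 2u(p + 2u − u²)` with an adaptive solver at rtol 10⁻¹⁰, since a
  fixed-step integration of the rotating system at ω = 20 biases the
  settled radius by more than the tolerance.

## Known limitations

* The ictal classifiers are package choices; published work leaves them
  unspecified. Conclusions that depend on absolute BNI levels (rather than
  map averages and rankings) should sweep the classifier thresholds.
* The theta noise convention is a documented interpretation (see above);
  the alternative literal-diffusion reading destroys coupling dependence
  and is demonstrably unusable for this analysis.
* One stochastic realisation per grid cell (the study's design) makes
  per-cell BNI noisy; all conclusions are drawn from map averages and
  ensemble statistics. At strongly reduced grids the NI noise floor can
  mask the true ΔNI of dense, homogeneous networks. Concretely, at the
  reduced scale used by the 19-node ensemble tests (8×8 grids, windows
  4/24/12 time units) the measured floors are ≈0.03 (physiological),
  ≈0.1 (theta) and ≈0.002 (bistable) against true dense-network ΔNI of
  ≈0.005 — so at that scale the ensemble-level heterogeneity relations
  are resolved only for the bistable model, and recovering them for all
  models needs grids and windows hundreds of times larger (the
  full-fidelity 192×192 setting). The corresponding tests assert the
  full-fidelity expectations at the reduced scale and fail where the
  noise floor dominates; they document the resolution requirements rather
  than hide them.
* The escape-time (bistable) coupling window `α ∈ [0, 10]` combined with
  up to 18 inputs per node on 19-node networks linearly destabilises the
  background state over most of the map, pushing the map mean near its
  ceiling (≈0.87) and compressing that model's ΔNI dynamic range on dense
  networks.
* Multi-node (set) resections and parameter-window optimisation are out of
  scope.
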