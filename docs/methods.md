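# Methods

## Model

`liftwalk` simulates the spread of a binary opinion ("the idea") over a
small network of agents with a discrete-time quantum walk.  Each agent
holds one qubit: `|0>` means the idea has not been adopted, `|1>` that it
has.  The network state is the tensor product of the agent qubits with
agent 1 on the least significant slot, so the basis state `b_n…b_1` sits at
1-based index `int(b,2)+1` (for three agents, `|101>` is basis state 6).

A unitary on the network alone cannot express *asymmetric* influence — if
`U` moves amplitude from `|01>` to `|11>`, `U†U = I` forces a matching
reverse flow.  The model therefore lifts the state: the walk lives on the
network **twice**, original ⊗ mirror.  The original acts as the controller
of a block-diagonal operator

    U = diag(U_1, …, U_{2^n}),

where block `U_i` is applied to the mirror exactly when the controller
occupies basis state `|i>`.  Each block is a short "discussion script"
compiled from two gate primitives:

* **lecture** — a controlled rotation `R(θ)` on an uninfected agent's
  mirror qubit, conditioned on the lecturer's mirror qubit being `|1>`;
* **feedback** — a controlled rotation `R(φ)` (usually `φ < 0`,
  disinfection) on the lecturer, conditioned on the listener's mirror qubit
  being `|0>`.

`R(θ)` is the real rotation `[[cos θ, −sin θ], [sin θ, cos θ]]`.  The
lecture precedes the feedback in every pair interaction, which is what
gives the initiator of a conversation their edge: after the lecture the
listener's `|0>` amplitude — the very component that powers the feedback —
has already shrunk.

### Angle units

The linear-algebra layer (`qlinalg`) takes plain radians.  The model-level
angle tables (`Line3Angles`, `Ring3Angles`, `RingAngles`) are expressed in
**half-turns**: a table entry `x` compiles to `R(πx)`, so `0.5` is a full
`|0> → |1>` flip.  This is the unit in which the published scenario tables
(0.05, 0.01, …) are written: with it the package reproduces the published
line-graph stopping times (1139 and 5762 steps) exactly and the published
final-state distribution to all four printed digits; with plain radians the
same runs are an order of magnitude slower and match nothing.

## The walk iteration

One step maps the reduced network state σ (a `2^n × 2^n` density operator)
to the next one:

1. **lift** — form `ρ = σ ⊗ σ` (controller ⊗ mirror);
2. **evolve** — apply the block unitary, `ρ → U ρ U†`;
3. **reduce** — trace out the controller: `ρ_T = Tr_C(U ρ U†)`;
4. **measure** — with the diagonal stop projector `M_s` (all-infected state
   for propagation; both consensus states for group decisions), split
   `p_s = Tr(M_s ρ_T M_s)`, `p_c = 1 − p_s`;
5. **project** — the continuing state `σ' = M_c ρ_T M_c / p_c` starts the
   next step (it is renormalized to unit trace explicitly, because runs of
   several thousand steps would otherwise accumulate drift).

Because `U` is block diagonal, step 1–3 collapse algebraically to the Kraus
form `ρ_T = Σ_i σ_ii · U_i σ U_i†`, which is how the engine actually
computes it — `2^n` products of `2^n × 2^n` matrices instead of one
`4^n × 4^n` product.  A test asserts equality with the dense lifted product
to 1e-12.

Unconditional bookkeeping follows `P_c(t) = P_c(t−1)·p_c(t)`,
`P_s(t) = P_c(t−1)·p_s(t)`; the walk halts at the first step where the
cumulative stop probability reaches `1 − ε`.  The telescoping identity
`Σ_{τ≤t} P_s(τ) = 1 − Π_{τ≤t} p_c(τ)` guarantees termination whenever
`p_c` stays boundedly below 1, and is asserted at 1e-9 on every run in the
test suite.  Defaults: `ε = 0.01`, `max_steps = 20000`.  If `p_c` ever
falls below 1e-14 the remaining mass is booked as stopped in that step.

The mean number of infected agents is read from the projected state ρ_c as
the popcount-weighted diagonal sum — for three agents the weight vector is
`[0,1,1,2,1,2,2,3]`.

## Gate factories

* **Line of three agents** (`line3`): the eight blocks are fixed scripts —
  block 1 rotates all three mirrors unconditionally (idea initialization),
  blocks 2–7 are the pair/triple discussion scripts of the line topology,
  block 8 (everyone infected) is the identity.  The per-block named angles
  (`theta_x`, `theta_yx`, …) let the published tables be transcribed
  verbatim.
* **Ring of three agents** (`ring3`): the ring adds the A1–A3 edge; four
  blocks change.  The replaced scripts are transcribed literally from
  their printed tensor expressions, including the one block in which a
  feedback precedes the corresponding lecture — we preserve that ordering
  rather than "correcting" it.
* **Ring of n > 3 agents** (`build_ring_n`): generated from rules rather
  than a printed recipe, because the generating procedure exists in the
  source material only as a textual description.  Per block: read the
  infected set from the controller bit string; for each infected agent in
  increasing index order, emit one joint lecture of all its uninfected
  neighbors, then one feedback per neighbor in increasing index order.
  The all-one block is the identity; the all-zero block is either the
  tensor initialization rotation (propagation mode) or the identity
  (group-decision mode, where opinions pre-exist).

Two conventions in the n-agent generator are genuinely underdetermined and
are exposed as switches:

* `include_wrap` (default `False`): whether the A1–A_n edge participates in
  the interaction bookkeeping.  The description of the topology includes
  the edge, but the only worked interaction example omits it; the default
  follows the worked example.
* neighbor infection status is evaluated **statically** against the
  controller bit string, not re-evaluated as the script is being built.

### Known divergence

With this reconstruction (and with every variant of it we tried — wrap
included/excluded, static vs cascading status, joint vs sequential
lectures, alternative gate conditionings and orderings, unprojected
absorbing evolution), the five-member-ring group decision converges to a
consensus split of ≈ 0.50 at the stopping time, not the previously
reported 0.7488, and the mid-walk-measurement probabilities differ
correspondingly.  The engine itself is validated exactly on the line-graph
experiments, so the discrepancy is attributable to unprinted details of
the original n-agent gate-generation procedure.  The acceptance script
reports what this implementation actually computes.

## Group decisions and interference

In group-decision mode every member starts with an opinion qubit
`c|0> + d|1>` and the walk stops on either consensus state.  Opinion pairs
can be interpreted as probabilities (`probabilities_sqrt`, the default:
`(0.2, 0.8)` means an 80 % chance of favoring option 1, amplitudes are the
square roots) or as literal amplitudes renormalized
(`amplitudes_normalized`).

At any step the *decision probability* is read from the stopped component:
apply `M_s` to `ρ_T`, renormalize, and trace against the single-state
projectors — `P_1 = Tr(M_1 M_s ρ_T M_s M_1)/p_s`.  `run_decision` evaluates
this at the stopping step; the interference experiment evaluates the same
functional at a fixed horizon.  The raw corner entry of `ρ_T` would instead
be the one-step inflow (order 1e-3 per step) and is not a decision
probability; defining every option-probability readout through the same
stopped-state formula keeps the stopping-time, horizon, and per-branch
quantities on one scale.

The interference experiment runs the walk to `measure_step`, applies the
four joint projectors of one member pair to `ρ_T` (branch probabilities
`u`), then continues each renormalized, continue-projected branch
separately to `horizon`, where the option-1 decision probability `v_i` is
read.  The classical law of total probability predicts the undisturbed
walk's outcome to equal `u · v`; the measured gap between `u · v` and the
undisturbed value is the interference effect.  With the default generator
the gap for the five-ring scenario is ≈ 0.056; a walk with all angles zero
shows a gap of exactly zero (asserted in the tests).

## Numerical choices

* Tolerances: unitarity 1e-10 (max-norm of `U†U − I`), Hermiticity and
  trace 1e-9, PSD eigenvalue floor −1e-9 — comfortable for double
  precision at ≤ 10 qubits.
* The continuing state is renormalized to exact unit trace every step.
* Branches with measurement probability below 1e-12 are kept at weight 0
  rather than evolved.
* All agent and basis indices in the public API are 1-based; angles are
  never wrapped or normalized.

## Scenario library and fixtures

`runner.SCENARIOS` bundles the published settings: three line-graph
propagation scenarios (no disinfection; stubborn middle agent; compliant
middle agent), ring propagation at sizes 3–5 (θ = 0.05, φ = −0.01, with
initialization), the five-member ring group decision (θ = 0.05,
φ = −0.05, identity initialization, a 3-vs-2 opinion split), and the
interference experiment (three members 80 % sure of option 1, two members
10 % sure; pair (A1, A2) measured at step 25, horizon 50).

`generate_fixture(seed)` draws random small scenarios — line-3 or ring
3/4/5, all angles uniform in [−0.1, 0.1] half-turns, random product
opinions — used by the property suites (unitarity, telescoping,
density-operator invariants).  Fixtures are reproducible from the seed;
the model itself has no randomness anywhere.

## What the synthetic scenarios do and do not show

The generator draws homogeneous-magnitude angles and product-state initial
opinions on graphs of 3–5 agents.  Passing tests therefore demonstrate the
algebraic invariants of the walk and exact reproduction of the desk-scale
line-graph experiments; they say nothing about large networks (the dense
block representation scales as `8^n` memory), heterogeneous per-pair
angle calibration against behavioral data, or topologies beyond lines and
rings.  Ergodicity of the five-ring decision walk — trajectories from
different initial opinion arrangements merging onto a common path — is
measured to hold within 1e-3 from roughly step 165 onward with the default
generator (the test suite asserts the window from step 200; the stricter
150-step window misses by a factor of ~2 on the mean-infected curve).

## Problem sizes

All experiments run at their native sizes: 3-agent walks are 8-dimensional
reduced states over 1139–14,000 steps; the 5-agent decision runs are
32-dimensional over ~1100 steps.  The full suite completes in well under a
minute on one CPU.
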