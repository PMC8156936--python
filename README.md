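# liftwalk

Lifted quantum walks for asymmetric idea propagation and group decision
making on small agent networks.

## The problem

How long does a new idea take to conquer a small social network, and which
way does a group's discussion tip its final decision?  Classical random
walks on networks force *symmetric* transitions — if influence flows from
agent 1 to agent 2, the reverse flow is equally easy — while real social
influence is asymmetric: a confident speaker sways an open-minded listener
far more than the reverse.  Quantum-cognition models also need genuinely
quantum bookkeeping, because measured groups behave differently from
unmeasured ones (interference).

`liftwalk` implements a discrete-time quantum walk that gets asymmetry and
interference from one construction: the network state σ is *lifted* to
σ ⊗ σ — an original copy acting as controller, a mirror copy as target —
and evolved by a block-diagonal controlled unitary

    U = diag(U₁, …, U_{2ⁿ}),   ρ_T(t) = Tr_C( U (σ⊗σ) U† ),

where block `Uᵢ` is a short discussion script (controlled rotations
`R(θ) = [[cos θ, −sin θ], [sin θ, cos θ]]`: infected agents lecture
uninfected neighbors by angle θ, who push back by angle φ) applied to the
mirror only when the controller occupies basis state `|i⟩`.  Global
evolution stays unitary; local influence is asymmetric.  Each step lifts,
evolves, traces out the controller, measures against a stopping projector
`M_s`, and renormalizes the continuing component; the walk halts when the
cumulative stopping probability reaches `1 − ε`.

The package is aimed at quantum-cognition and opinion-dynamics researchers
who want a small, fully tested reference implementation of this model for
line and ring networks, including consensus formation with two stopping
states and mid-walk measurement (interference) experiments.

## Worked example

The bundled `no_disinfection` scenario is a 3-agent line A1—A2—A3 where
only positive (infecting) rotations occur, idea initialization favors A1
(θₓ = 0.05 half-turns, i.e. `R(0.05π)`), and every first speaker out-rotates
the reply:

```bash
liftwalk propagate --scenario no_disinfection --out out/
```

prints

```json
{"cum_Ps": 0.990007206652, "epsilon": 0.01, "mean_infected_final": 1.272899516337,
 "name": "no_disinfection", "t_f": 1139, "truncated": false}
```

— the walk needs **1139** steps for the cumulative probability of reaching
the all-infected state `|111⟩` to pass `1 − ε = 0.99`, and the mean number
of infected agents settles at **1.27**.  The per-step trajectory lands in
`out/trajectory.csv`:

```
step,ps,pc,Ps,Pc,cum_Ps,mean_infected
1,2.382202136e-08,0.9999999762,2.382202136e-08,0.9999999762,2.382202136e-08,0.02644494259
2,1.12415868e-06,0.9999988758,1.124158653e-06,0.999998852,1.147980675e-06,0.1016292548
...
```

`Ps(t)` peaks near step 24 and never exceeds 0.012: the idea spreads fast
early, then the network argues back and forth for a long tail.

As a library, the five-member ring group decision (all θᵢⱼ = 0.05,
φᵢⱼ = −0.05, no initialization block, three members for option 1):

```python
from liftwalk import OpinionState, run_decision
from liftwalk.ring import RingAngles, build_ring_n

blocks = build_ring_n(5, RingAngles(theta=0.05, phi=-0.05), initializing=False)
result = run_decision(blocks, OpinionState.from_bits("00111"))
print(f"t_f={result.t_f}  P0={result.P0:.4f}  P1={result.P1:.4f}")
# t_f=1091  P0=0.4990  P1=0.5010
```

The stopped state is supported on `|00000⟩` and `|11111⟩` only; `P1` is
the probability the agreement reached is option 1.  Under this package's
reconstruction of the n-agent ring generator the long-run split is close
to even — see `docs/methods.md` for the reconstruction, its switches, and
its known divergence from previously reported decision probabilities.

CLI subcommands: `propagate`, `decide`, `interfere`, `fixtures`; scenario
files are JSON or YAML (`--config`), bundled settings by name
(`--scenario`).  Exit codes: 0 success, 2 truncated at the step cap,
3 configuration error.

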