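# Methods

## The paradigm

The multi-arm trust game couples one Sender to three scripted Receivers
(confederates).  Every round the Sender splits an endowment of E = 40
points between itself and the Receivers.  An available Receiver is given
`m × allocation` points (multiplier m = 4) and returns some share; points
allocated to an unavailable Receiver are refunded.  Availability is an
independent Bernoulli draw per round with probability 1/period, one
confederate per schedule (periods 1, 3, 6), so availability is
unpredictable round to round but converges to the scheduled rate.  Returns
follow a two-phase trustworthiness script: rounds 1–70 (the switch round
itself included in phase 1) return a deterministic 75% of the multiplied
amount, i.e. three times the allocation; rounds 71–120 return a draw from
Binomial(given, 0.25) — bounded in [0, given], with mean exactly 25% of
the multiplied amount, so the Sender breaks even in expectation.  The
binomial was chosen over, e.g., a truncated Gaussian because it is the
simplest integer-valued law with the required support and mean.  All
monetary quantities are integers; fractional returns round half-up.
Rounds are 1-based everywhere, including logs.

## The sender model

The model is organized as four interacting mechanisms.

**Episodic memory and blending.**  Each interaction is stored as an
instance chunk: counterpart, a discretized one-step sequence context
(previous observed return bin ∈ {none, <0.4, 0.4–0.6, >0.6}; rounds since
last interaction ∈ {1, 2–3, ≥4}), and the observed return fraction
(quantized to 0.05-wide bins; an identical observation re-encodes the
existing chunk rather than creating a new one).  Retrieval strength is the
base-level activation `A = ln Σ_j (now − t_j)^(−d)` with decay d = 0.5,
the canonical recency-and-frequency law.  The predicted return fraction is
the blended value of the context-matching chunks (fallback: all chunks for
the counterpart), weighted by `exp(A/τ)` with τ = 0.25.  Before any
experience the prediction is a 0.5 prior, shifted by 0.1 per unit of
initial (dispositional) trust.  Transient activation noise is omitted;
stochasticity enters through action selection instead.

**Trust accumulators.**  Each counterpart has a trust and a trust-invest
accumulator (both start at `initial_trust` resp. 0).  Trust updates on
interactions in one of two modes:

* repair (trust ≤ threshold): `trust += η (returned − allocated)/E` —
  profitable reciprocation rebuilds trust toward and past the threshold;
* maintenance (trust > threshold): `trust += η (returned − expected)/E`,
  where `expected` is the blended prediction × amount given — anticipated
  generosity no longer inflates trust, while an unanticipated shortfall
  pulls it down immediately.

On every round without an interaction (counterpart unavailable, or
nothing allocated), trust is discounted by a fixed δ.  Discounting applies
to every non-interacting round, not only failed attempts, because reduced
opportunity alone should erode behavioral trust in this paradigm.

The two-mode form was adopted after the single-mode net-outcome
integrator proved structurally unable to produce the post-switch
phenomena: integrating `(returned − allocated)/E` for 70 generous rounds
drives trust to ≈ +60, a level no discounting can undo within the game,
freezing the counterpart in the trust regime forever (the trust-regime
reward is the joint payoff, which is split-invariant and therefore blind
to the strategy switch).  With maintenance-mode prediction errors, the
switch produces a few large negative surprises before memory adapts
(about three rounds, since the sequence context changes as soon as a
neutral return is observed), and trust crosses the threshold almost
immediately — consistent with the observed near-immediate behavioral
change-point after the switch.

**Trust-invest dynamics.**  The invest accumulator indexes unmet need to
interact.  It rises by `κ × allocation/E` when an allocation is refunded
because the counterpart was unavailable, gated on trust ≤ threshold (no
investment need toward a counterpart one already trusts).  A served
attempt relieves the need: a profitable interaction decays it by
(1 − κ); an unprofitable one resets it to zero — the necessity-driven
investment was tried and failed, and the regime falls back to distrust.
Geometric decay can never reach the strict `> 0` threshold, so values
below 1e-3 snap to zero; without this floor trust necessity is an
absorbing state.  This asymmetry — only intermittently available
counterparts can accumulate investment need — is what dissociates the
post-switch fates of the counterparts: the always-available one falls
from trust into plain distrust (sharp, sustained allocation drop), while
the intermittent ones cycle through trust necessity (transient
reallocation bump).

**Regimes and reward.**  Exactly one regime holds per counterpart: trust
(trust > threshold), trust necessity (trust ≤ threshold < invest), else
distrust.  Thresholds default to 0; only differences matter under the
linear updates.  The per-counterpart reward is: joint payoff
(own + other) under trust, −allocation under distrust (charged whether or
not the counterpart turned out to be available), the counterpart's gain
under trust necessity.  Own payoff is the Sender's net from the
interaction (returned − allocated), other payoff the counterpart's
(given − returned).  The round total adds the endowment kept and any
refunds, and is divided by E before utility updates so the selection
temperature is dimensionless.

**Procedural learning.**  Allocation policy is incremental: per
counterpart, increase / decrease / hold the previous allocation by a
fixed step (4 points = 10% of the endowment), clipped to the remaining
endowment, processed in an order sampled by Boltzmann over cumulative
payoffs (uniform at round 1; the ordering temperature shares the
selection noise s, saving a free parameter).  Rule utilities live on
(regime, predicted-return-bin) contexts shared across counterparts —
the only channel of cross-counterpart coupling — and update by
`U += α (R − U)` with the round's total reward, once per fired rule,
before the next round's decisions.  Actions are sampled by Boltzmann with
temperature s; unseen contexts start at zero utility.

### Parameter defaults

| parameter | default | role |
|---|---|---|
| d | 0.5 | memory decay (dimensionless) |
| τ | 0.25 | blending temperature |
| η | 1.0 | trust gain per normalized outcome |
| δ | 0.1 | trust discount per non-interacting round |
| κ | 0.5 | invest gain / decay factor |
| α | 0.2 | utility learning rate |
| s | 0.5 | selection noise (Boltzmann temperature) |
| step | 4 points | allocation adjustment per action |
| initial_trust | 0 | dispositional trust offset |

δ, α, s and the accumulator parameters are the quantities varied by
`grid_fit`; the rest are architectural constants exposed in config.

## Lesioned variants

`trust_only` freezes the invest accumulator (trust necessity becomes
unreachable); `no_trust` freezes both and reduces the reward to the
Sender's own net payoff plus endowment kept.  Measured at defaults
(200–2000 runs): the full model shows the phase-1 ordering (≈ +17-point
margin for the always-available counterpart over rounds 40–70), a
post-switch drop (≈ 1 point over rounds 71–90, deepening through the
rest of the game), and a medium/low bump of ≈ +0.3 points (rounds 71–85
vs 56–70); `no_trust` shows neither drop nor bump, and fits
bump-bearing cohort curves systematically worse in the neutral phase
(phase-2 RMSD ≈ 5.8–6.7 for the full model vs ≈ 6.9–7.5 across seeds).

## Fitting and inference

Fit quality is Pearson r and RMSD between mean allocation curves,
flattened over (round × counterpart) pairs, on three windows: full game,
rounds 1–70, rounds 71–120 (per-counterpart metrics are reported
alongside; r is signalled as undefined on constant series).  `grid_fit`
does exhaustive search — appropriate for a ≤5-dimensional stochastic
objective — scoring each point by full-window RMSD over n independent
seeded runs, ties broken by higher r then grid order.  Parameter recovery
at the suite's scale (targets from 200 runs, fits from 100 runs per grid
point, grids {0.1, 0.2, 0.4} × {0.1, 0.2, 0.4}) returns δ and α within
one grid step of the generating values on all tested seeds.

`infer_accumulators` is yoked inference: the logged decisions and payoffs
are fed through the model's memory and trust updates in place of its own,
yielding the latent trust/invest trajectories implied by observed
behavior.  It is a pure function of (log, parameters) and reproduces a
forward run's trace exactly when given that run's log.  One consequence of
the maintenance-mode update: with a constant generous return, inferred
trust rises early and then plateaus (the return becomes fully
anticipated) rather than growing without bound.

## Synthetic cohorts

No public dataset exists for this paradigm, so the generator produces
cohorts whose mean curves carry the qualitative structure reported for
human senders, as fitting targets that are deliberately *not* draws from
the model (model-misspecified targets, as with real participants).  Each
participant is a piecewise-linear template per counterpart — rise (high
schedule, ≈ 8 → 24 points) or drift down (medium/low, ≈ 8 → 2) to round
70; then an 18-point drop over 5 rounds for the high-schedule counterpart
and a 5-point bump decaying over 15 rounds for the others — plus
integer-rounded Gaussian noise (sd 2), clipped and renormalized to the
endowment, with returns produced by the real game engine so every log
satisfies every ledger invariant.  Default cohort size is 38.  The
generator emulates group-mean dynamics only: it has no
individual-difference covariates, no erratic-responder clusters, and its
participants are exchangeable — so tests passing against it show the
pipeline's correctness on data with the target structure, not robustness
to real human heterogeneity.

## Numerical and scale choices

Monte-Carlo sizes were chosen for statistical resolution of the smallest
effect under test (the ≈ +0.3-point reallocation bump, per-run sd ≈ 3):
the qualitative-reproduction check uses 2000 runs (standard error
≈ 0.07), the lesion fit comparison 80 runs per grid point over a
12-point grid, parameter recovery 3 seeds × (200-run targets, 100-run
fits).  A single 120-round game simulates in ≈ 15 ms.  All randomness
flows from numpy `SeedSequence` spawning, so every result is reproducible
from one integer seed.

## Known limitations

* The accumulator update laws are the package's own design (the
  literature describes the mechanisms qualitatively); they are
  config-exposed and swappable, and all module-level guarantees about
  them are property-based.
* The model's post-switch drop is more gradual than the human
  change-point (utility re-learning takes ≈ 15 rounds at α = 0.2),
  and its reallocation bump is smaller than the human one — the model
  lacks the explicit cross-counterpart trust coupling that would let the
  high-schedule counterpart's betrayal instantly update trust necessity
  toward the others; coupling enters only through shared rule utilities.
* The Receiver side is scripted, not modeled; the Receivers'
  outside-option draw is irrelevant to Sender-side computation and
  omitted.
* The animacy/inanimacy framing of counterparts is carried as a config
  label only, with no behavioral consequence.
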