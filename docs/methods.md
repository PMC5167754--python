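# Methods

## Model definition

### Single-unit dynamics

Each unit is a discrete-time stochastic state machine with three modes.

*Subthreshold.* `V` gains `Isyn + 1` with probability `p` per step and
`Isyn` otherwise.  `p` ("transit probability of the internal state") is
the only source of spontaneous drive; with no input, the first-passage
time from `V = 0` to the threshold `TH` is a sum of `TH` geometric
waits with mean `TH / p` (1000 steps at the defaults `p = 0.05`,
`TH = 50`).

*Burst.* Crossing `TH` at step `t` freezes a firing sequence — the
cumulative offsets of `[0] + S.isis + P.isis`, where `S` is the unit's
signature and `P` its current preferred pattern — and schedules the
first spike for `t + 1`.  Spikes are single steps at `V = AP`; between
spikes `V` sits at `TH + 1` (with the same `p`-drift applied on
plateau steps); one step after the final spike `V` resets to 0.  A
burst therefore contains exactly `1 + |S| + |P|` spikes and lasts
`(last offset + 1)` steps.  Synaptic input is ignored while bursting.

*Refractory.* `V` is clamped to 0 for `RP` steps and synaptic input is
discarded; then subthreshold integration restarts from 0.

The per-unit consequences are pinned by tests: the interburst onset
interval of an isolated unit is a renewal process with mean
`TH/p + (burst duration) + RP` (about 1087 steps at the defaults),
verified to 2% over >10^4 bursts.

### Synaptic exchange

Units occupy an `R x C` torus with Moore (8-neighbour) connectivity and
a uniform integer weight `g` (default 1; integer weights keep `V`
integer-valued).  A spike at cell `j` at step `t - 1` contributes `g`
to every neighbour's input at step `t` — a strict one-step delivery
delay, so a unit crossing threshold at `t` spikes at `t + 1` and its
neighbours' potentials react at `t + 2`.  External tonic stimuli enter
through a ninth channel with weight `g_e`; the default `g_e = TH = 50`
makes the stimulated unit follow the stimulus one burst per pulse
whenever it is not refractory (the choice is otherwise immaterial: any
`g_e >= TH` behaves identically for an unloaded cell).

### Intra-unit plasticity

The local informational context stores `(channel, arrival time)` pairs
for the last `M` steps (closed window: an event aged exactly `M` is
retained).  Recording is passive — arrivals during the unit's own
burst or refractory period are stored — but rule evaluation is
deferred to subthreshold steps, and an ongoing burst's frozen sequence
never changes.

A channel's windowed spike train is segmented into bursts at ISIs
larger than `gap` (default `2 x max signature ISI = 24`, safely below
the >= `RP` interburst silences).  Fingerprints have a fixed length of
`pattern_len = signature_spikes - 1` ISIs.  The candidate raised by an
arriving spike is the trailing `pattern_len` ISIs of the run ending at
that spike; an occurrence of a pattern is a segmented run whose
trailing ISIs equal it.  Trailing-window matching is what lets a
fingerprint travel: a re-emitting unit concatenates its own signature
in front of the propagated pattern, so the pattern always sits at the
tail of the received burst, and candidates never grow into unbounded
signature chains.

Occurrences are counted across the whole context (summed over
channels), for recognition and forgetting alike.  Pooling matters
asymmetrically, and deliberately so: a propagating fingerprint is
re-emitted by many neighbours and accumulates across channels, while
each neighbour's own cell-specific signature arrives through a single
channel only — so spontaneous recognition of neighbour signatures
stays rare while a stimulated unit's fingerprint can recruit cells
that hear it from several sides.  When several channels yield a
recognition in the same step, the channels are processed in a fresh
seeded random order and the last processed wins.

## Randomness and determinism

Every stochastic decision — subthreshold and in-burst drift, initial
potentials, signature ISIs, stimulated-cell placement, channel
processing order — is a pure function of `(seed, unit, time, purpose)`
through a splitmix64 finalizer.  There is no sequential RNG state, so
trajectories are bit-reproducible, independent of iteration order and
chunking, and identical between the two engines.  The compiled kernel
(numba) and the pure-Python reference loop are asserted bit-identical
on small driven grids in the test suite; the kernel's only structural
shortcut is evaluating the forgetting rule event-wise (on arrivals, on
context-window expiries, and on return to subthreshold) rather than
every step, which is exact because occurrence counts are pure functions
of the windowed context and can only change at those events.

## Analysis pipelines

*Wavelet complexity.* Each potential frame is zero-padded to the
smallest power-of-two square (64 x 64 for the 50 x 50 grid) and fully
decomposed with the non-standard (level-alternating) 2D Haar transform;
`C(t)` counts coefficients with magnitude above `eps`.  The default
`eps = 1e-6 x AP` makes `C` an effectively-nonzero count on integer
frames while absorbing float round-off; because `C(t)`'s oscillation is
driven by large synchronized patches (constant regions have zero detail
coefficients), its spectral content is insensitive to `eps` over many
orders of magnitude.  `C` is bounded by the padded coefficient count
(4096), not by the neuron count; only relative changes and rhythms of
`C(t)` are interpreted.  Spectra are mean-removed Welch periodograms
(default segment 2^16 samples; scaled runs use 2^15) with the dominant
frequency taken over nonzero bins.

*Fingerprint activity.* The per-step number of units whose preferred
pattern equals each tracked fingerprint ("recognize and emit" — the
emission follows automatically at the unit's next burst).  Memory
characterization takes the stimulation-window mean as baseline and
reports the reverberation period: the delay after stimulus offset until
the counts stay below 5% of baseline for a sustained run (default 1000
steps); if that never happens within the horizon the network is
classified long-term.  Competition classification marks winner-take-all
when one fingerprint holds the maximal count on more than 90% of active
steps and its mean exceeds 10x the runner-up's; these two thresholds
are reporting conventions, exposed as arguments.  Cluster statistics
(mean local clustering coefficient and mean shortest path of
same-fingerprint cells under Moore adjacency, per connected component)
use networkx.

## Experiment presets and scales

Presets encode the canonical conditions: 50 x 50 torus, `p = 0.05`,
`TH = 50`, `RP = 50`, `AP = 200`, `g = 1`, six-spike signatures with
ISIs uniform on 2..12, initial `V` uniform on 0..40, tonic period-100
stimuli with `g_e = 50`.  The memory presets stimulate for the first
half of the run at `(M, L)` = (500, 5), (400, 4), (350, 4); the
competition presets inject ten simultaneous tonic inputs.  Ten distinct
stimulus periods (60, 70, ..., 150) are used for the ten-input presets;
the sources' rates are otherwise unspecified, and this spread keeps the
evoked rhythms distinguishable.  Tonic single spikes never form
candidate fingerprints (a candidate needs `pattern_len + 1` spikes
within `gap`), so recognition is driven purely by neighbour bursts.

Reported quantities use 100,000-step runs for rhythm spectra and
ensembles of 60,000-step runs (3-5 seeds) for the memory and
competition statistics; these lengths put the spectral resolution
(~3e-5 cycles/step) and the regime statistics well past their mixing
transients while keeping a full reproduction in the minutes range on
one CPU.

## What the synthetic conditions do and do not show

The generator reproduces the study conditions exactly (parameter
values, signature statistics, stimulus protocols); it does not emulate
biological heterogeneity (per-neuron parameter spread), conduction
delays beyond one step, synaptic plasticity (weights are constant by
design), or noisy/jittered signatures — fingerprint matching is exact,
so robustness of recognition to timing jitter is untested here.

## Known limitations

The strict input-exclusion rule — synaptic input discarded during both
the burst and the refractory period — bounds how fast the collective
dynamics can cycle.  A unit's eight neighbours can contribute at most
`8 x (spikes per burst) x g = 48` a.u. per full neighbourhood cycle
with plain six-spike bursts, just below `TH = 50`, and in coherent
waves much of that arrives while the unit itself is bursting or
refractory and is discarded.  Consequently the autonomous 50 x 50
network settles into an asynchronous state whose dominant `C(t)`
frequency is ~1.5e-3 cycles/step (per-cell interburst period ~550),
and a period-100 stimulus imprints only a weak spectral line at 1e-2
rather than dominating the spectrum.  Fingerprint recognition is
correspondingly carried by the stimulated unit's neighbourhood (the
steady count scales with `M / stimulus period` against `L`) instead of
sweeping the whole lattice: the (M, L) presets still order and
classify as expected for short-term memory, but the long-term memory
and winner-take-all regimes, which require the faster self-sustained
collective rhythms, appear only marginally (occasional seeds) at these
parameters.  Crediting busy-period input instead (tested during
development) overshoots into saturated, always-long-term dynamics, so
the strict rule is retained as the model definition.
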