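"""Intra-unit plasticity: local informational context and fingerprint
recognition.

Each neuron keeps a *local informational context* — a sliding-window
memory of (input channel, spike time) pairs spanning the last ``M`` time
steps.  The window is closed: an event aged exactly M is retained.

Recognition works per channel.  The channel's windowed spike train is
segmented into *runs* (bursts) wherever an interspike interval exceeds
the segmentation ``gap``.  Fingerprints have a fixed length of
``pattern_len`` ISIs (pattern_len + 1 spikes), set by the network's
signature spike count; the *candidate* raised by an arriving spike is the
trailing ``pattern_len`` ISIs of the run ending at that spike, and an
*occurrence* of a pattern is a run whose trailing ISIs equal it.  Because
a bursting emitter concatenates its own signature with its preferred
pattern, the fingerprint being propagated always sits at the tail of the
received burst; trailing-window matching is what lets a fingerprint
travel through such combined bursts without spawning ever-growing
composite patterns.  If the candidate occurs at least ``L`` times in the
whole context (occurrences pooled over input channels), it overwrites
the neuron's preferred output pattern.  The preferred pattern is
*forgotten* once its context-wide count falls below L (the memory is
transient: occurrences expire with the window).

Neither rule applies while the neuron is generating a burst; events that
arrive during a burst or the refractory period are still recorded
(the memory is passive) and the checks are deferred to the first
subthreshold step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

from .core_model import Mode, NeuronState, PreferredPattern

__all__ = [
    "EXTERNAL",
    "SpikeEvent",
    "LocalContext",
    "ISIPattern",
    "PlasticityParams",
    "record_spike",
    "prune_context",
    "segment_channel_bursts",
    "count_pattern_occurrences",
    "context_pattern_count",
    "current_candidate",
    "apply_recognition_rule",
    "apply_forgetting_rule",
]

#: Channel identifier of the external stimulation channel.
EXTERNAL = "EXTERNAL"


@dataclass(frozen=True)
class SpikeEvent:
    channel: Hashable
    time: int


@dataclass(frozen=True)
class ISIPattern:
    """An ordered list of positive integer ISIs (a candidate fingerprint)."""

    isis: Tuple[int, ...]

    def __init__(self, isis: Sequence[int]):
        isis = tuple(int(x) for x in isis)
        if any(x < 1 for x in isis):
            raise ValueError(f"pattern ISIs must be >= 1, got {isis}")
        object.__setattr__(self, "isis", isis)

    def __len__(self) -> int:
        return len(self.isis)


@dataclass(frozen=True)
class PlasticityParams:
    """Knobs of the intra-unit contextualization mechanism.

    M
        Context window (time steps of transient memory).
    L
        Learning threshold: occurrences needed for recognition.
    gap
        Burst segmentation gap (time steps): ISIs larger than this split
        runs.  Safe default for the grid experiments is twice the largest
        admissible intraburst ISI (2 x 12 = 24), well below the >= 50-step
        interburst silences enforced by the refractory period.
    pattern_len
        Fingerprint length in ISIs (spikes - 1); 5 for six-spike
        signatures, matching the network's signature spec.
    """

    M: int = 400
    L: int = 4
    gap: int = 24
    pattern_len: int = 5

    def __post_init__(self) -> None:
        errors = []
        if self.M <= 0:
            errors.append(f"M must be > 0, got {self.M}")
        if self.L < 1:
            errors.append(f"L must be >= 1, got {self.L}")
        if self.gap <= 0:
            errors.append(f"gap must be > 0, got {self.gap}")
        if self.pattern_len < 1:
            errors.append(f"pattern_len must be >= 1, got {self.pattern_len}")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class LocalContext:
    """Sliding-window memory of per-channel spike arrival times."""

    M: int
    events: Dict[Hashable, List[int]] = field(default_factory=dict)

    def channel_times(self, channel: Hashable) -> List[int]:
        return self.events.get(channel, [])

    def all_events(self) -> List[SpikeEvent]:
        out = [
            SpikeEvent(ch, t)
            for ch, times in self.events.items()
            for t in times
        ]
        out.sort(key=lambda e: (e.time, str(e.channel)))
        return out


def record_spike(ctx: LocalContext, channel: Hashable, t: int) -> LocalContext:
    """Append an arrival; per-channel times must be non-decreasing."""
    times = ctx.events.setdefault(channel, [])
    if times and t < times[-1]:
        raise ValueError(
            f"out-of-order spike on channel {channel!r}: {t} < {times[-1]}"
        )
    times.append(int(t))
    return ctx


def prune_context(ctx: LocalContext, t_now: int) -> LocalContext:
    """Drop events older than the window (closed: age == M is kept)."""
    cutoff = t_now - ctx.M
    for ch in list(ctx.events):
        times = ctx.events[ch]
        i = 0
        while i < len(times) and times[i] < cutoff:
            i += 1
        if i:
            del times[:i]
        if not times:
            del ctx.events[ch]
    return ctx


def _runs(times: Sequence[int], gap: int) -> List[List[int]]:
    """Split a sorted spike train into maximal runs with ISIs <= gap."""
    runs: List[List[int]] = []
    for t in times:
        if runs and t - runs[-1][-1] <= gap:
            runs[-1].append(t)
        else:
            runs.append([t])
    return runs


def _windowed(ctx: LocalContext, channel: Hashable, t_now: Optional[int]):
    times = ctx.channel_times(channel)
    if t_now is None:
        return times
    cutoff = t_now - ctx.M
    return [t for t in times if t >= cutoff]


def segment_channel_bursts(
    ctx: LocalContext,
    channel: Hashable,
    gap: int,
    min_pattern_len: int = 2,
    t_now: Optional[int] = None,
) -> List[ISIPattern]:
    """ISI patterns of the channel's windowed runs.

    Runs shorter than ``min_pattern_len + 1`` spikes (e.g. tonic single
    spikes) yield nothing.
    """
    if gap <= 0:
        raise ValueError(f"gap must be > 0, got {gap}")
    out = []
    for run in _runs(_windowed(ctx, channel, t_now), gap):
        if len(run) >= min_pattern_len + 1:
            out.append(
                ISIPattern([b - a for a, b in zip(run, run[1:])])
            )
    return out


def count_pattern_occurrences(
    ctx: LocalContext,
    channel: Hashable,
    pattern: ISIPattern,
    gap: int,
    t_now: Optional[int] = None,
) -> int:
    """Number of windowed runs whose trailing ISIs equal ``pattern``."""
    k = len(pattern)
    if k < 1:
        raise ValueError("pattern must have at least one ISI")
    count = 0
    for run in _runs(_windowed(ctx, channel, t_now), gap):
        if len(run) >= k + 1:
            tail = tuple(
                run[i + 1] - run[i] for i in range(len(run) - k - 1, len(run) - 1)
            )
            if tail == pattern.isis:
                count += 1
    return count


def context_pattern_count(
    ctx: LocalContext,
    pattern: ISIPattern,
    gap: int,
    t_now: Optional[int] = None,
) -> int:
    """Occurrences of ``pattern`` across the whole context (all channels).

    This is the count the recognition and forgetting rules compare with
    the learning threshold: the fingerprint must have been received L
    times *in the local informational context*, regardless of which
    channels carried it.  Because every neuron that recognizes a
    fingerprint re-emits it as the tail of its bursts, a propagating
    fingerprint pools occurrences across input channels, while each
    neighbour's own (cell-specific) signature arrives through a single
    channel only and so never pools.
    """
    return sum(
        count_pattern_occurrences(ctx, ch, pattern, gap, t_now)
        for ch in list(ctx.events)
    )


def current_candidate(
    ctx: LocalContext,
    channel: Hashable,
    t_now: int,
    params: PlasticityParams,
) -> Optional[ISIPattern]:
    """Candidate fingerprint raised by the newest spike on ``channel``.

    The trailing ``pattern_len`` ISIs of the run ending at the newest
    windowed event, or None if that run is shorter than
    ``pattern_len + 1`` spikes.
    """
    times = _windowed(ctx, channel, t_now)
    k = params.pattern_len
    if len(times) < k + 1:
        return None
    tail = times[-(k + 1):]
    isis = [b - a for a, b in zip(tail, tail[1:])]
    if any(isi > params.gap for isi in isis):
        return None
    return ISIPattern(isis)


def apply_recognition_rule(
    state: NeuronState,
    ctx: LocalContext,
    channel: Hashable,
    t: int,
    params: PlasticityParams,
) -> NeuronState:
    """Recognize the incoming fingerprint on ``channel`` if seen >= L times.

    Must be triggered by a spike arrival on the channel; never applies
    while the neuron is bursting (the frozen sequence cannot change).
    """
    if state.mode == Mode.BURSTING:
        return state
    candidate = current_candidate(ctx, channel, t, params)
    if candidate is None:
        return state
    n = context_pattern_count(ctx, candidate, params.gap, t)
    if n >= params.L:
        state.preferred = PreferredPattern(candidate.isis)
    return state


def apply_forgetting_rule(
    state: NeuronState, ctx: LocalContext, t: int, params: PlasticityParams
) -> NeuronState:
    """Clear the preferred pattern once no channel holds it >= L times."""
    if state.mode == Mode.BURSTING or not state.preferred:
        return state
    pattern = ISIPattern(state.preferred.isis)
    if context_pattern_count(ctx, pattern, params.gap, t) >= params.L:
        return state
    state.preferred = PreferredPattern()
    return state
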