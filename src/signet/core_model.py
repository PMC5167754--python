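"""Single-unit spiking-bursting dynamics.

The model neuron is a discrete-time stochastic state machine with three
modes.  During *subthreshold* activity the membrane potential ``V`` drifts
upward by one unit with probability ``p`` per step, on top of the synaptic
input.  When ``V`` reaches the firing threshold ``TH`` the neuron emits a
whole *burst*: a frozen firing sequence obtained by concatenating the
neuron's interspike-interval signature ``S`` with its current preferred
output pattern ``P``.  Spikes are represented by one-step excursions of
``V`` to the peak potential ``AP``; between spikes ``V`` sits just above
threshold.  After the last spike ``V`` resets to zero and the neuron is
*refractory* for ``RP`` steps, during which synaptic input is discarded.

The signature is fixed per neuron and identifies it to the rest of the
network; the preferred pattern is rewritten by the intra-unit recognition
rule (see :mod:`signet.plasticity`) and is the vehicle by which recognized
fingerprints are re-emitted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence, Tuple

__all__ = [
    "Mode",
    "NeuronParams",
    "NeuralSignature",
    "PreferredPattern",
    "FiringSequence",
    "NeuronState",
    "build_firing_sequence",
    "subthreshold_step",
    "burst_step",
    "refractory_step",
]


class Mode(IntEnum):
    """Operating mode of a unit (values shared with the compiled kernel)."""

    SUBTHRESHOLD = 0
    BURSTING = 1
    REFRACTORY = 2


def _check_isis(isis: Sequence[int], what: str) -> Tuple[int, ...]:
    isis = tuple(int(x) for x in isis)
    if any(x < 1 for x in isis):
        raise ValueError(f"{what}: all ISIs must be >= 1, got {isis}")
    return isis


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of the stochastic spiking-bursting unit.

    p
        Transit probability of the internal state per time step.
    TH
        Firing threshold (a.u.); crossing it triggers a full burst.
    RP
        Refractory period (time steps) with V clamped to 0 after a burst.
    AP
        Peak membrane potential marking a spike (a.u.); must exceed TH.
    """

    p: float = 0.05
    TH: int = 50
    RP: int = 50
    AP: int = 200

    def __post_init__(self) -> None:
        errors = []
        if not (0.0 <= self.p <= 1.0):
            errors.append(f"p must be in [0, 1], got {self.p}")
        if not (self.AP > self.TH > 0):
            errors.append(f"need AP > TH > 0, got AP={self.AP}, TH={self.TH}")
        if self.RP < 0:
            errors.append(f"RP must be >= 0, got {self.RP}")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass(frozen=True)
class NeuralSignature:
    """A cell-specific fingerprint: ordered intraburst ISIs (time steps).

    A signature with k ISIs signs a burst of k+1 spikes.  The six-spike
    signatures used in the grid experiments therefore carry 5 ISIs, each
    drawn uniformly from 2..12.
    """

    isis: Tuple[int, ...]

    def __init__(self, isis: Sequence[int] = ()):
        object.__setattr__(self, "isis", _check_isis(isis, "signature"))

    def __len__(self) -> int:
        return len(self.isis)


@dataclass(frozen=True)
class PreferredPattern:
    """The ISI pattern appended after the signature; empty = none recognized.

    Stored as ISIs: the first ISI is the gap between the last signature
    spike and the first appended spike, so a burst's full ISI list is
    simply ``S.isis + P.isis``.
    """

    isis: Tuple[int, ...]

    def __init__(self, isis: Sequence[int] = ()):
        object.__setattr__(self, "isis", _check_isis(isis, "preferred pattern"))

    def __bool__(self) -> bool:
        return bool(self.isis)

    def __len__(self) -> int:
        return len(self.isis)


@dataclass(frozen=True)
class FiringSequence:
    """Frozen spike-time offsets of one burst, measured from burst onset.

    ``offsets[0] == 0`` (the onset spike); offsets are the cumulative sums
    of the concatenated signature + preferred ISI list, and ``N`` (the
    spike count) is ``1 + |S| + |P|``.
    """

    offsets: Tuple[int, ...]

    @property
    def N(self) -> int:
        return len(self.offsets)

    @property
    def duration(self) -> int:
        """Steps from onset to the zero-reset (last offset + 1)."""
        return self.offsets[-1] + 1


def build_firing_sequence(
    S: NeuralSignature, P: PreferredPattern
) -> FiringSequence:
    """Concatenate signature and preferred pattern into spike offsets."""
    isis = S.isis + P.isis
    return FiringSequence(tuple(itertools.accumulate((0,) + isis)))


@dataclass
class NeuronState:
    """Mutable per-unit state.

    ``t1`` and ``frozen_sequence`` are only meaningful while BURSTING
    (``spike_index`` points at the next offset to emit); ``rp_remaining``
    while REFRACTORY.  V is integer-valued (all increments are
    non-negative integers).
    """

    signature: NeuralSignature
    preferred: PreferredPattern = field(default_factory=PreferredPattern)
    V: int = 0
    mode: Mode = Mode.SUBTHRESHOLD
    t1: int = -1
    frozen_sequence: Optional[FiringSequence] = None
    spike_index: int = 0
    rp_remaining: int = 0


def subthreshold_step(
    state: NeuronState, params: NeuronParams, isyn: int, t: int, u: float
) -> NeuronState:
    """One subthreshold update at time step ``t``.

    V gains ``isyn + 1`` with probability p (``u < p``), else ``isyn``.
    If the updated V reaches TH, the firing sequence is frozen from the
    current (signature, preferred) and the burst's first spike is
    scheduled for ``t1 = t + 1``; the mode switches to BURSTING so the
    next step runs :func:`burst_step` with offset 0.
    """
    if state.mode != Mode.SUBTHRESHOLD:
        raise RuntimeError("subthreshold_step called outside SUBTHRESHOLD")
    state.V += isyn + (1 if u < params.p else 0)
    if state.V >= params.TH:
        state.frozen_sequence = build_firing_sequence(
            state.signature, state.preferred
        )
        state.t1 = t + 1
        state.spike_index = 0
        state.mode = Mode.BURSTING
    return state


def burst_step(
    state: NeuronState, params: NeuronParams, t: int, u: float
) -> Tuple[NeuronState, bool]:
    """One in-burst update; returns ``(state, spike_emitted)``.

    Synaptic input is ignored while bursting.  V is AP exactly at the
    frozen offsets, TH+1 one step after each non-final spike, 0 one step
    after the final spike (entering the refractory period), and otherwise
    drifts by +1 with probability p.
    """
    if state.mode != Mode.BURSTING or state.frozen_sequence is None:
        raise RuntimeError("burst_step called outside BURSTING")
    seq = state.frozen_sequence.offsets
    dt = t - state.t1
    k = state.spike_index
    if k < len(seq) and dt == seq[k]:
        state.V = params.AP
        state.spike_index += 1
        return state, True
    if k == len(seq) and dt == seq[-1] + 1:
        # one step after the final spike: reset and become refractory
        state.V = 0
        state.frozen_sequence = None
        state.spike_index = 0
        if params.RP > 0:
            state.mode = Mode.REFRACTORY
            state.rp_remaining = params.RP
        else:
            state.mode = Mode.SUBTHRESHOLD
        return state, False
    if 0 < k and dt == seq[k - 1] + 1:
        state.V = params.TH + 1
        return state, False
    if u < params.p:
        state.V += 1
    return state, False


def refractory_step(state: NeuronState, params: NeuronParams) -> NeuronState:
    """One refractory update: V stays 0, synaptic input is discarded."""
    if state.mode != Mode.REFRACTORY:
        raise RuntimeError("refractory_step called outside REFRACTORY")
    state.V = 0
    state.rp_remaining -= 1
    if state.rp_remaining <= 0:
        state.mode = Mode.SUBTHRESHOLD
        state.rp_remaining = 0
    return state
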