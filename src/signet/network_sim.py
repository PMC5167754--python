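"""Torus network, synaptic exchange, stimulation, and the simulation loop.

Neurons sit on a 2D grid with periodic boundaries, each excitatorily
connected to its eight Moore neighbours.  Communication is synchronous
with a one-step delivery delay: a spike (V = AP) at cell j at step t-1
contributes ``g_ji`` to each neighbour's synaptic input at step t (and is
recorded in their local informational contexts).  External tonic stimuli
are injected into chosen cells through a ninth, external channel.

Two engines produce identical results (bit for bit, thanks to the
counter-based RNG in :mod:`signet.rng`):

* :class:`ReferenceSimulator` — a readable pure-Python loop over the
  per-unit state machines of :mod:`signet.core_model` and the context
  operations of :mod:`signet.plasticity`;
* the compiled array kernel in :mod:`signet._kernel`, used by
  :func:`run_simulation` for production-size runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import rng
from .core_model import (
    Mode,
    NeuralSignature,
    NeuronParams,
    NeuronState,
    PreferredPattern,
    burst_step,
    refractory_step,
    subthreshold_step,
)
from .plasticity import (
    LocalContext,
    PlasticityParams,
    apply_forgetting_rule,
    apply_recognition_rule,
    prune_context,
    record_spike,
)

__all__ = [
    "NEIGHBOR_OFFSETS",
    "EXTERNAL_CHANNEL",
    "GridTopology",
    "StimulusEntry",
    "SimulationConfig",
    "ActivityRecord",
    "build_torus_grid",
    "compute_synaptic_input",
    "generate_random_signatures",
    "resolve_stimuli",
    "ReferenceSimulator",
    "advance_one_step",
    "run_simulation",
]

#: Moore neighbourhood offsets, fixed channel order 0..7.  The channel a
#: receiver assigns to a sender at relative offset ``o`` is the index of
#: ``-o``, i.e. ``7 - k`` for the sender's k-th neighbour.
NEIGHBOR_OFFSETS: Tuple[Tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

#: Integer id of the external stimulation channel (after the 8 neighbours).
EXTERNAL_CHANNEL = 8


@dataclass(frozen=True)
class GridTopology:
    """2D torus with Moore (8-neighbour) connectivity and uniform weight."""

    rows: int
    cols: int
    g: int
    neighbor_array: np.ndarray  # (n, 8) int64, row i = cells of i's channels

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def cell_index(self, r: int, c: int) -> int:
        return (r % self.rows) * self.cols + (c % self.cols)

    def cell_coords(self, i: int) -> Tuple[int, int]:
        return divmod(i, self.cols)

    def neighbors(self, i: int) -> Tuple[int, ...]:
        return tuple(int(j) for j in self.neighbor_array[i])


def build_torus_grid(rows: int, cols: int, g: int = 1) -> GridTopology:
    """Build the periodic Moore-neighbourhood grid.

    Dimensions below 3 are rejected: wrap-around would make neighbour
    sets collide (a cell would be its own neighbour or see a neighbour
    twice).
    """
    if rows < 3 or cols < 3:
        raise ValueError(f"grid dimensions must be >= 3, got {rows}x{cols}")
    n = rows * cols
    nbr = np.empty((n, 8), dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
                nbr[i, k] = ((r + dr) % rows) * cols + ((c + dc) % cols)
    return GridTopology(rows=rows, cols=cols, g=int(g), neighbor_array=nbr)


@dataclass(frozen=True)
class StimulusEntry:
    """A tonic external input: one spike every ``period`` steps.

    ``cell`` may be None, in which case a cell is chosen by the seeded
    RNG when the configuration is resolved.  ``t_end`` of None means the
    stimulus lasts until the end of the run.
    """

    period: int
    cell: Optional[int] = None
    t_start: int = 1
    t_end: Optional[int] = None
    g_e: int = 50

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ValueError(f"stimulus period must be >= 1, got {self.period}")
        if self.t_end is not None and self.t_start > self.t_end:
            raise ValueError(
                f"stimulus t_start {self.t_start} > t_end {self.t_end}"
            )

    def fires_at(self, t: int, duration: int) -> bool:
        end = duration if self.t_end is None else self.t_end
        return self.t_start <= t <= end and (t - self.t_start) % self.period == 0


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one experiment.

    Defaults are the grid-experiment conditions: 50x50 torus, p=0.05,
    TH=50, RP=50, AP=200, g=1, six-spike signatures with ISIs uniform on
    2..12, M=400, L=4, initial potentials uniform on 0..40.
    """

    duration: int
    seed: int
    rows: int = 50
    cols: int = 50
    neuron: NeuronParams = field(default_factory=NeuronParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    g: int = 1
    signature_spikes: int = 6
    isi_range: Tuple[int, int] = (2, 12)
    v0_range: Tuple[int, int] = (0, 40)
    stimuli: Tuple[StimulusEntry, ...] = ()
    #: explicit initial potentials (n,) — overrides v0_range (for tests)
    initial_v: Optional[Tuple[int, ...]] = None
    #: explicit signatures — overrides random generation (for tests)
    signatures: Optional[Tuple[NeuralSignature, ...]] = None

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def validate(self) -> None:
        errors = []
        if self.duration < 0:
            errors.append(f"duration must be >= 0, got {self.duration}")
        if self.rows < 3 or self.cols < 3:
            errors.append(f"grid must be >= 3x3, got {self.rows}x{self.cols}")
        if self.g < 0:
            errors.append(f"g must be >= 0, got {self.g}")
        if self.signature_spikes < 2:
            errors.append(
                f"signature_spikes must be >= 2, got {self.signature_spikes}"
            )
        lo, hi = self.isi_range
        if not (1 <= lo <= hi):
            errors.append(f"isi_range must satisfy 1 <= lo <= hi, got {lo, hi}")
        if hi > self.plasticity.gap:
            errors.append(
                f"max signature ISI {hi} exceeds segmentation gap "
                f"{self.plasticity.gap}: receiver bursts would be split"
            )
        if self.plasticity.pattern_len != self.signature_spikes - 1:
            errors.append(
                f"plasticity.pattern_len ({self.plasticity.pattern_len}) must "
                f"equal signature_spikes - 1 ({self.signature_spikes - 1})"
            )
        v0_lo, v0_hi = self.v0_range
        if not (0 <= v0_lo <= v0_hi < self.neuron.TH):
            errors.append(
                f"v0_range must lie in [0, TH), got {self.v0_range}"
            )
        if self.initial_v is not None and len(self.initial_v) != self.n_cells:
            errors.append("initial_v length must equal rows*cols")
        if self.signatures is not None:
            if len(self.signatures) != self.n_cells:
                errors.append("signatures length must equal rows*cols")
            elif any(
                len(s) != self.signature_spikes - 1 for s in self.signatures
            ):
                errors.append(
                    "every explicit signature must have signature_spikes-1 ISIs"
                )
        for s in self.stimuli:
            if s.cell is not None and not (0 <= s.cell < self.n_cells):
                errors.append(f"stimulus cell {s.cell} out of range")
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))


def generate_random_signatures(
    n_cells: int,
    spike_count: int,
    isi_range: Tuple[int, int],
    seed: int,
) -> List[NeuralSignature]:
    """One random signature per cell: ISIs i.i.d. uniform on the range.

    Signatures are drawn from per-cell counter streams; duplicates across
    cells are possible (and harmless) but vanishingly rare for six-spike
    signatures on 2..12 (11^5 patterns).
    """
    lo, hi = isi_range
    span = hi - lo + 1
    out = []
    for i in range(n_cells):
        isis = [
            lo + rng.uniform_int(seed, i, j, rng.SALT_SIGNATURE, span)
            for j in range(spike_count - 1)
        ]
        out.append(NeuralSignature(isis))
    return out


def resolve_stimuli(config: SimulationConfig) -> Tuple[StimulusEntry, ...]:
    """Fill in seeded random cells for stimuli declared with cell=None.

    Placements are drawn without replacement so concurrent stimuli target
    distinct cells.
    """
    taken = {s.cell for s in config.stimuli if s.cell is not None}
    resolved = []
    for k, s in enumerate(config.stimuli):
        if s.cell is not None:
            resolved.append(s)
            continue
        for attempt in range(10_000):
            cell = rng.uniform_int(
                config.seed, k, attempt, rng.SALT_STIMULUS, config.n_cells
            )
            if cell not in taken:
                break
        taken.add(cell)
        resolved.append(replace(s, cell=cell))
    return tuple(resolved)


def initial_potentials(config: SimulationConfig) -> np.ndarray:
    """Initial V, uniform on v0_range (or the explicit override)."""
    if config.initial_v is not None:
        return np.asarray(config.initial_v, dtype=np.int64)
    lo, hi = config.v0_range
    return np.array(
        [
            lo + rng.uniform_int(config.seed, i, 0, rng.SALT_INIT_V, hi - lo + 1)
            for i in range(config.n_cells)
        ],
        dtype=np.int64,
    )


@dataclass
class ActivityRecord:
    """Everything a simulation run produced.

    Potentials and recognized-signature labels are stored as strided
    frame stacks; per-signature recognition counts and (optionally) the
    wavelet complexity C(t) are stored at every step.  Label code -1
    means "no fingerprint recognized", -2 a recognized pattern that is
    not in the tracked set, and k >= 0 the k-th tracked signature.
    """

    config: SimulationConfig
    stimuli: Tuple[StimulusEntry, ...]
    tracked_cells: Tuple[int, ...]
    tracked_signatures: Tuple[NeuralSignature, ...]
    #: (n_tracked, duration + 1): neurons whose preferred pattern equals
    #: each tracked signature, per step
    signature_counts: np.ndarray
    frame_stride: int = 0
    v_frames: Optional[np.ndarray] = None  # (T_f, rows, cols) int32
    frame_times: Optional[np.ndarray] = None
    label_stride: int = 0
    label_frames: Optional[np.ndarray] = None  # (T_l, rows, cols) int16
    label_times: Optional[np.ndarray] = None
    spike_times: Optional[np.ndarray] = None
    spike_cells: Optional[np.ndarray] = None
    complexity: Optional[np.ndarray] = None  # C(t), one value per step 0..T
    complexity_eps: Optional[float] = None

    @property
    def duration(self) -> int:
        return self.config.duration

    @property
    def seed(self) -> int:
        return self.config.seed

    def stimulus_log(self) -> List[Tuple[int, int]]:
        """(cell, t) pairs of delivered external pulses."""
        out = []
        for s in self.stimuli:
            end = self.duration if s.t_end is None else min(s.t_end, self.duration)
            out.extend(
                (s.cell, t) for t in range(s.t_start, end + 1, s.period)
            )
        out.sort(key=lambda ct: (ct[1], ct[0]))
        return out


def compute_synaptic_input(
    topology: GridTopology,
    cell: int,
    spiked_prev: np.ndarray,
    stimuli: Sequence[StimulusEntry],
    t: int,
    duration: int,
    subthreshold: bool = True,
) -> int:
    """Synaptic input Isyn = g_e*pulse_e + sum_j g_ji*pulse_j at step t.

    ``spiked_prev`` flags cells with V = AP at t-1.  Input is discarded
    (returns 0) for cells that are bursting or refractory.
    """
    if not subthreshold:
        return 0
    isyn = int(topology.g) * int(
        np.count_nonzero(spiked_prev[topology.neighbor_array[cell]])
    )
    for s in stimuli:
        if s.cell == cell and s.fires_at(t, duration):
            isyn += int(s.g_e)
    return isyn


class ReferenceSimulator:
    """Pure-Python synchronous simulation loop (the readable engine).

    Intended for small grids and short runs: unit tests, hand traces and
    cross-validation of the compiled kernel.  Use
    :func:`run_simulation` for production runs.
    """

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        self.topology = build_torus_grid(config.rows, config.cols, config.g)
        self.stimuli = resolve_stimuli(config)
        sigs = (
            list(config.signatures)
            if config.signatures is not None
            else generate_random_signatures(
                config.n_cells,
                config.signature_spikes,
                config.isi_range,
                config.seed,
            )
        )
        self.signatures = sigs
        v0 = initial_potentials(config)
        self.states = [
            NeuronState(signature=sigs[i], V=int(v0[i]))
            for i in range(config.n_cells)
        ]
        self.contexts = [
            LocalContext(M=config.plasticity.M) for _ in range(config.n_cells)
        ]
        self.pending: List[set] = [set() for _ in range(config.n_cells)]
        self.t = 0
        self.spiked_prev = np.zeros(config.n_cells, dtype=bool)
        # per-step logs
        self.v_log: List[np.ndarray] = [v0.copy()]
        self.spikes: List[Tuple[int, int]] = []  # (t, cell)
        self.preferred_log: List[List[Tuple[int, ...]]] = [
            [st.preferred.isis for st in self.states]
        ]

    def advance_one_step(self) -> None:
        """Advance the whole network by one synchronous step."""
        cfg = self.config
        n = cfg.n_cells
        t = self.t + 1
        nbr = self.topology.neighbor_array

        # (1) deliver last step's spikes into contexts and Isyn
        isyn = np.zeros(n, dtype=np.int64)
        for j in np.flatnonzero(self.spiked_prev):
            for k in range(8):
                i = int(nbr[j, k])
                ch = 7 - k
                record_spike(self.contexts[i], ch, t)
                self.pending[i].add(ch)
                isyn[i] += cfg.g
        for s in self.stimuli:
            if s.fires_at(t, cfg.duration):
                record_spike(self.contexts[s.cell], EXTERNAL_CHANNEL, t)
                self.pending[s.cell].add(EXTERNAL_CHANNEL)
                isyn[s.cell] += s.g_e

        # (2)+(3) plasticity then dynamics, per neuron
        spiked_now = np.zeros(n, dtype=bool)
        for i in range(n):
            st = self.states[i]
            if st.mode == Mode.SUBTHRESHOLD:
                ctx = prune_context(self.contexts[i], t)
                if self.pending[i]:
                    order = sorted(
                        self.pending[i],
                        key=lambda ch: (
                            rng.uniform(
                                cfg.seed, i * 16 + ch, t, rng.SALT_CHANNEL_ORDER
                            ),
                            ch,
                        ),
                    )
                    for ch in order:
                        apply_recognition_rule(st, ctx, ch, t, cfg.plasticity)
                    self.pending[i].clear()
                apply_forgetting_rule(st, ctx, t, cfg.plasticity)
                u = rng.uniform(cfg.seed, i, t, rng.SALT_DYNAMICS)
                subthreshold_step(st, cfg.neuron, int(isyn[i]), t, u)
            elif st.mode == Mode.BURSTING:
                u = rng.uniform(cfg.seed, i, t, rng.SALT_DYNAMICS)
                _, emitted = burst_step(st, cfg.neuron, t, u)
                if emitted:
                    spiked_now[i] = True
                    self.spikes.append((t, i))
            else:
                refractory_step(st, cfg.neuron)

        # (4) log
        self.t = t
        self.spiked_prev = spiked_now
        self.v_log.append(
            np.array([st.V for st in self.states], dtype=np.int64)
        )
        self.preferred_log.append([st.preferred.isis for st in self.states])

    def run(self) -> "ReferenceSimulator":
        while self.t < self.config.duration:
            self.advance_one_step()
        return self

    def to_record(self) -> ActivityRecord:
        cfg = self.config
        tracked_cells = tuple(dict.fromkeys(s.cell for s in self.stimuli))
        tracked_sigs = tuple(self.signatures[c] for c in tracked_cells)
        counts = np.zeros((len(tracked_cells), cfg.duration + 1), dtype=np.int64)
        labels = np.full(
            (cfg.duration + 1, cfg.n_cells), -1, dtype=np.int16
        )
        sig_code: Dict[Tuple[int, ...], int] = {}
        for k, s in enumerate(tracked_sigs):
            sig_code.setdefault(s.isis, k)
        for t, prefs in enumerate(self.preferred_log):
            for i, isis in enumerate(prefs):
                if not isis:
                    continue
                k = sig_code.get(isis, -2)
                labels[t, i] = k
                if k >= 0:
                    counts[k, t] += 1
        spikes = np.array(self.spikes, dtype=np.int64).reshape(-1, 2)
        return ActivityRecord(
            config=cfg,
            stimuli=self.stimuli,
            tracked_cells=tracked_cells,
            tracked_signatures=tracked_sigs,
            signature_counts=counts,
            frame_stride=1,
            v_frames=np.stack(self.v_log).reshape(
                -1, cfg.rows, cfg.cols
            ).astype(np.int32),
            frame_times=np.arange(cfg.duration + 1),
            label_stride=1,
            label_frames=labels.reshape(-1, cfg.rows, cfg.cols),
            label_times=np.arange(cfg.duration + 1),
            spike_times=spikes[:, 0],
            spike_cells=spikes[:, 1],
        )


def advance_one_step(sim: ReferenceSimulator) -> ReferenceSimulator:
    """Functional alias for :meth:`ReferenceSimulator.advance_one_step`."""
    sim.advance_one_step()
    return sim


def run_simulation(
    config: SimulationConfig,
    engine: str = "fast",
    **record_options,
) -> ActivityRecord:
    """Run a full experiment and return its :class:`ActivityRecord`.

    ``engine="fast"`` uses the compiled array kernel (recommended);
    ``engine="reference"`` uses the pure-Python loop and records
    everything at stride 1 (small runs only).  See
    :func:`signet._kernel.run_fast` for the recording options of the
    fast engine (frame/label strides, spike raster, inline wavelet
    complexity).
    """
    config.validate()
    if engine == "reference":
        if record_options:
            raise ValueError(
                "the reference engine records everything; options "
                f"{sorted(record_options)} only apply to the fast engine"
            )
        return ReferenceSimulator(config).run().to_record()
    if engine == "fast":
        from ._kernel import run_fast

        return run_fast(config, **record_options)
    raise ValueError(f"unknown engine {engine!r}")
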