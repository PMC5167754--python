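"""Torus topology, synaptic exchange, the synchronous loop, and the
equivalence of the two simulation engines."""

import numpy as np
import pytest

from signet import (
    NeuralSignature,
    SimulationConfig,
    StimulusEntry,
    build_torus_grid,
    generate_random_signatures,
    run_simulation,
)
from signet.network_sim import (
    ReferenceSimulator,
    compute_synaptic_input,
    resolve_stimuli,
)


def test_torus_every_cell_has_eight_neighbors():
    topo = build_torus_grid(50, 50, g=1)
    assert topo.neighbor_array.shape == (2500, 8)
    # neighbour lists contain no duplicates and never the cell itself
    for i in (0, 49, 1275, 2499):
        nbrs = topo.neighbors(i)
        assert len(set(nbrs)) == 8 and i not in nbrs


def test_torus_wraparound_at_corner():
    topo = build_torus_grid(50, 50, g=1)
    nbrs = set(topo.neighbors(0))
    assert {topo.cell_index(49, 49), topo.cell_index(0, 49),
            topo.cell_index(49, 0)} <= nbrs


def test_three_by_three_full_wrap():
    topo = build_torus_grid(3, 3, g=1)
    for i in range(9):
        assert set(topo.neighbors(i)) == set(range(9)) - {i}


def test_grid_too_small_rejected():
    with pytest.raises(ValueError):
        build_torus_grid(2, 5)


def test_synaptic_input_weighted_sum():
    topo = build_torus_grid(5, 5, g=1)
    spiked = np.zeros(25, dtype=bool)
    assert compute_synaptic_input(topo, 12, spiked, [], 10, 100) == 0
    for j in list(topo.neighbors(12))[:3]:
        spiked[j] = True
    assert compute_synaptic_input(topo, 12, spiked, [], 10, 100) == 3
    stim = [StimulusEntry(period=10, cell=12, t_start=0, g_e=50)]
    assert compute_synaptic_input(topo, 12, spiked, stim, 10, 100) == 53
    # input is discarded for non-subthreshold cells
    assert (
        compute_synaptic_input(topo, 12, spiked, stim, 10, 100, subthreshold=False)
        == 0
    )


def test_random_signatures_match_spec():
    sigs = generate_random_signatures(2500, 6, (2, 12), seed=5)
    assert len(sigs) == 2500
    assert all(len(s) == 5 for s in sigs)
    isis = np.array([s.isis for s in sigs])
    assert isis.min() >= 2 and isis.max() <= 12
    # fixed seed: identical assignment
    again = generate_random_signatures(2500, 6, (2, 12), seed=5)
    assert all(a.isis == b.isis for a, b in zip(sigs, again))
    # all 11 values occur (i.i.d. uniform on 2..12)
    assert set(np.unique(isis)) == set(range(2, 13))


def test_stimulus_placement_seeded_and_distinct(config_factory):
    cfg = config_factory(
        rows=10, cols=10,
        stimuli=[StimulusEntry(period=100)] * 5,
    )
    cells = [s.cell for s in resolve_stimuli(cfg)]
    assert len(set(cells)) == 5
    assert cells == [s.cell for s in resolve_stimuli(cfg)]


def test_invalid_config_lists_offending_fields(config_factory):
    cfg = config_factory(duration=-5, rows=2)
    with pytest.raises(ValueError) as exc:
        run_simulation(cfg)
    msg = str(exc.value)
    assert "duration" in msg and "grid" in msg


def test_two_step_spike_delivery_delay(config_factory, fixed_signatures):
    """A cell crossing TH at t emits its first spike at t+1 and the
    neighbours' potentials rise at t+2 (pulses read V(t-1) = AP)."""
    cfg = config_factory(
        rows=5, cols=5, duration=8, p=0.0, g=1,
        signatures=fixed_signatures(25),
        initial_v=tuple([50 if i == 12 else 10 for i in range(25)]),
    )
    rec = run_simulation(cfg, engine="reference")
    v = rec.v_frames.reshape(9, 25)
    # the crossing is detected at the first update (t=1), the first AP
    # follows at t=2, and the neighbours' potentials rise at t=3
    assert v[2, 12] == 200
    nbr = build_torus_grid(5, 5).neighbors(12)
    assert all(v[2, j] == 10 for j in nbr)
    assert all(v[3, j] == 11 for j in nbr)


def test_burst_recruits_quiescent_neighbor_when_strong(
    config_factory, fixed_signatures
):
    """With g x (spikes per burst) >= TH a single presynaptic burst drives
    a quiescent neighbour over threshold."""
    cfg = config_factory(
        rows=5, cols=5, duration=60, p=0.0, g=10,
        signatures=fixed_signatures(25, isis=(2, 2, 2, 2, 2)),
        initial_v=tuple([50 if i == 12 else 0 for i in range(25)]),
    )
    rec = run_simulation(cfg, engine="reference")
    spikes_by_cell = {}
    for t, c in zip(rec.spike_times, rec.spike_cells):
        spikes_by_cell.setdefault(int(c), []).append(int(t))
    nbr = build_torus_grid(5, 5).neighbors(12)
    # source spikes at t = 2,4,6,8,10,12; each delivers 10 a.u. one step
    # later, so neighbours cross at t=11 and burst from t=12
    for j in nbr:
        assert spikes_by_cell[j][0] == 12


def test_duration_zero_yields_initial_frame_only(config_factory):
    cfg = config_factory(duration=0)
    rec = run_simulation(cfg, frame_stride=1, label_stride=1)
    assert rec.v_frames.shape == (1, 6, 6)
    assert rec.signature_counts.shape[1] == 1


def test_same_seed_bit_identical_records(config_factory):
    cfg = config_factory(
        rows=8, cols=8, duration=3000, L=2,
        stimuli=[StimulusEntry(period=100, cell=20, g_e=50)],
    )
    a = run_simulation(cfg, frame_stride=1, label_stride=1, record_raster=True,
                       track_complexity=True)
    b = run_simulation(cfg, frame_stride=1, label_stride=1, record_raster=True,
                       track_complexity=True)
    assert np.array_equal(a.v_frames, b.v_frames)
    assert np.array_equal(a.spike_times, b.spike_times)
    assert np.array_equal(a.spike_cells, b.spike_cells)
    assert np.array_equal(a.label_frames, b.label_frames)
    assert np.array_equal(a.signature_counts, b.signature_counts)
    assert np.array_equal(a.complexity, b.complexity)


def test_frame_striding_subsamples_same_trajectory(config_factory):
    cfg = config_factory(rows=6, cols=6, duration=600)
    full = run_simulation(cfg, frame_stride=1)
    strided = run_simulation(cfg, frame_stride=3)
    assert np.array_equal(full.v_frames[::3], strided.v_frames)


def test_engines_bit_identical(config_factory):
    """The compiled kernel and the pure-Python reference loop produce the
    same potentials, spikes, recognition labels and counts."""
    cfg = config_factory(
        rows=6, cols=6, duration=3000, L=2, M=400,
        stimuli=[StimulusEntry(period=100, cell=14, g_e=50)],
    )
    ref = run_simulation(cfg, engine="reference")
    fast = run_simulation(
        cfg, frame_stride=1, label_stride=1, record_raster=True
    )
    assert np.array_equal(ref.v_frames, fast.v_frames)
    assert np.array_equal(ref.spike_times, fast.spike_times)
    assert np.array_equal(ref.spike_cells, fast.spike_cells)
    assert np.array_equal(ref.label_frames, fast.label_frames)
    assert np.array_equal(ref.signature_counts, fast.signature_counts)
    assert ref.signature_counts.max() > 0  # recognition actually exercised


def test_spike_conservation(config_factory, fixed_signatures):
    """With p=0, every subthreshold potential increment equals exactly the
    weighted sum of last-step neighbour spikes (plus external pulses)."""
    cfg = config_factory(
        rows=6, cols=6, duration=400, p=0.0, g=7,
        signatures=fixed_signatures(36, isis=(2, 3, 2, 3, 2)),
        initial_v=tuple([40] * 36),
        stimuli=[StimulusEntry(period=90, cell=0, g_e=50)],
    )
    rec = run_simulation(cfg, frame_stride=1, record_raster=True)
    v = rec.v_frames.reshape(-1, 36).astype(np.int64)
    topo = build_torus_grid(6, 6, g=7)
    spiked = np.zeros((cfg.duration + 1, 36), dtype=bool)
    for t, c in zip(rec.spike_times, rec.spike_cells):
        spiked[t, c] = True
    AP, TH = 200, 50
    for t in range(1, cfg.duration + 1):
        for i in range(36):
            # select cells subthreshold across the update t-1 -> t
            if v[t - 1, i] < TH and 0 < v[t, i] < TH or (
                v[t - 1, i] < TH and v[t, i] >= TH and v[t, i] != AP
            ):
                isyn = compute_synaptic_input(
                    topo, i, spiked[t - 1], rec.stimuli, t, cfg.duration
                )
                assert v[t, i] - v[t - 1, i] == isyn, (t, i)


def test_isolated_neurons_follow_renewal_process(config_factory):
    """With g=0 and no stimulus, interburst onset intervals of each cell
    average TH/p + burst duration + RP (2% tolerance)."""
    cfg = config_factory(rows=15, cols=15, duration=8000, g=0, seed=21)
    rec = run_simulation(cfg, record_raster=True)
    st, sc = rec.spike_times, rec.spike_cells
    order = np.lexsort((st, sc))
    st, sc = st[order], sc[order]
    sigs = generate_random_signatures(225, 6, (2, 12), cfg.seed)
    expected, observed, n_int = 0.0, 0.0, 0
    for cell in range(225):
        times = st[sc == cell]
        onsets = times[np.diff(times, prepend=-10**9) > 24]
        if len(onsets) < 2:
            continue
        ivals = np.diff(onsets)
        observed += ivals.sum()
        n_int += len(ivals)
        expected += (
            cfg.neuron.TH / cfg.neuron.p
            + sum(sigs[cell].isis) + 1
            + cfg.neuron.RP
        ) * len(ivals)
    assert n_int > 1000
    assert abs(observed / expected - 1) < 0.02


def test_stimulated_cell_follows_tonic_input(config_factory):
    """An external pulse of weight TH makes the target burst once per
    stimulus period (period exceeds burst + refractory time)."""
    cfg = config_factory(
        rows=8, cols=8, duration=3000,
        stimuli=[StimulusEntry(period=100, cell=30, g_e=50)],
    )
    rec = run_simulation(cfg, record_raster=True)
    times = rec.spike_times[rec.spike_cells == 30]
    onsets = times[np.diff(times, prepend=-10**9) > 24]
    periods = np.diff(onsets)
    assert np.median(periods) == 100


def test_reference_engine_rejects_fast_options(config_factory):
    with pytest.raises(ValueError):
        run_simulation(config_factory(), engine="reference", frame_stride=2)
    with pytest.raises(ValueError):
        run_simulation(config_factory(), engine="warp")
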