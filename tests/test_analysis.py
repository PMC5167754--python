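"""Wavelet complexity, rhythm spectra, signature activity, clusters,
memory and competition classification."""

import numpy as np
import pytest

from signet import build_torus_grid
from signet.analysis import (
    characterize_memory,
    classify_competition_regime,
    cluster_metrics,
    complexity_of_frames,
    complexity_series,
    count_significant_coefficients,
    default_eps,
    inverse_haar_dwt2,
    nonstandard_haar_dwt2,
    power_spectrum,
    signature_activity_series,
)


# ---------------------------------------------------------------- DWT --


def _haar_1d_basis(N):
    """Orthonormal 1D Haar functions on N=2^n points, grouped by level.

    Returns (phi_coarsest, {level: [psi_{level,k}]}) with level = block
    size; psi is +1/sqrt(b) on the first half of its block, -1/sqrt(b)
    on the second.
    """
    phi = np.full(N, 1 / np.sqrt(N))
    psis = {}
    b = N
    while b >= 2:
        fns = []
        for k in range(N // b):
            f = np.zeros(N)
            f[k * b : k * b + b // 2] = 1 / np.sqrt(b)
            f[k * b + b // 2 : (k + 1) * b] = -1 / np.sqrt(b)
            fns.append(f)
        psis[b] = fns
        b //= 2
    return phi, psis


def _nonstandard_2d_projections(frame):
    """Brute-force projections of a 2^n-square frame onto the explicitly
    constructed non-standard 2D Haar basis, grouped by (level, band)."""
    N = frame.shape[0]
    phiN, psis = _haar_1d_basis(N)
    out = {("approx", N): [float(frame.flatten() @ np.outer(phiN, phiN).flatten())]}
    for b, fns in psis.items():
        # scaling functions at the same block size b
        phis = []
        for k in range(N // b):
            f = np.zeros(N)
            f[k * b : (k + 1) * b] = 1 / np.sqrt(b)
            phis.append(f)
        for band, (rows, cols) in {
            "h": (phis, fns),
            "v": (fns, phis),
            "d": (fns, fns),
        }.items():
            vals = [
                float(frame.flatten() @ np.outer(r, c).flatten())
                for r in rows
                for c in cols
            ]
            out[(band, b)] = vals
    return out


def test_dwt_zero_frame_all_zero():
    coeffs = nonstandard_haar_dwt2(np.zeros((8, 8)))
    assert np.all(coeffs == 0)


def test_dwt_constant_frame_single_coefficient():
    coeffs = nonstandard_haar_dwt2(np.full((8, 8), 7.0))
    nz = np.abs(coeffs) > 1e-9
    assert nz.sum() == 1  # only the coarsest average survives


def test_dwt_empty_frame_rejected():
    with pytest.raises(ValueError):
        nonstandard_haar_dwt2(np.zeros((0, 0)))


def test_dwt_roundtrip_exact_on_integer_frames():
    rs = np.random.RandomState(4)
    for shape in [(8, 8), (16, 16), (50, 50), (5, 9)]:
        frame = rs.randint(0, 201, size=shape).astype(float)
        coeffs = nonstandard_haar_dwt2(frame)
        recon = inverse_haar_dwt2(coeffs)
        assert np.allclose(recon[: shape[0], : shape[1]], frame, atol=1e-9)
        # padding region reconstructs to zero
        assert np.allclose(recon[shape[0]:, :], 0, atol=1e-9)


def test_dwt_matches_basis_projection_oracle():
    """Coefficients equal brute-force projections onto the explicit
    non-standard 2D Haar basis (per level and orientation, compared as
    magnitude multisets: the detail sign convention is arbitrary)."""
    rs = np.random.RandomState(5)
    frame = rs.randint(0, 201, size=(8, 8)).astype(float)
    coeffs = nonstandard_haar_dwt2(frame)
    oracle = _nonstandard_2d_projections(frame)
    # Parseval: total energy matches exactly
    assert np.isclose(
        np.sum(coeffs**2),
        sum(np.sum(np.square(v)) for v in oracle.values()),
    )
    # flatten oracle magnitudes and compare with the transform's
    got = np.sort(np.abs(coeffs).ravel())
    want = np.sort(np.abs(np.concatenate([v for v in oracle.values()])))
    assert np.allclose(got, want, atol=1e-9)


def test_complexity_invariant_to_constant_offset_except_coarsest():
    rs = np.random.RandomState(6)
    frame = rs.randint(0, 50, size=(16, 16)).astype(float)
    a = nonstandard_haar_dwt2(frame)
    b = nonstandard_haar_dwt2(frame + 13)
    diff = np.abs(a - b) > 1e-9
    assert diff.sum() == 1 and diff[0, 0]


def test_count_significant_thresholding():
    coeffs = np.array([[0.0, 0.5], [-2.0, 1e-9]])
    assert count_significant_coefficients(coeffs, 0.4) == 2
    assert count_significant_coefficients(coeffs, np.inf) == 0
    with pytest.raises(ValueError):
        count_significant_coefficients(coeffs, -1)


def test_batched_complexity_matches_per_frame():
    rs = np.random.RandomState(7)
    frames = rs.randint(0, 201, size=(10, 12, 12)).astype(float)
    eps = default_eps(200)
    batch = complexity_of_frames(frames, eps)
    single = [
        count_significant_coefficients(nonstandard_haar_dwt2(f), eps)
        for f in frames
    ]
    assert batch.tolist() == single


def test_complexity_series_from_record(driven_small_record):
    ws = complexity_series(driven_small_record)
    assert len(ws.C) == driven_small_record.duration + 1
    assert ws.C.min() >= 0 and ws.C.max() <= 64  # 6x6 pads to 8x8
    # stride-2 subsampling equals stride-1 values at shared times
    sub = complexity_of_frames(driven_small_record.v_frames[::2], ws.eps)
    assert np.array_equal(ws.C[::2], sub)


# ----------------------------------------------------------- spectra --


def test_spectrum_recovers_sinusoid_period():
    t = np.arange(1 << 15)
    x = np.sin(2 * np.pi * t / 100.0)
    spec = power_spectrum(x, window_length=1 << 14)
    assert abs(spec.dominant_frequency - 0.01) < 1 / (1 << 14)
    assert spec.power.max() == 1.0


def test_spectrum_recovers_square_wave_period():
    t = np.arange(1 << 15)
    x = ((t // 50) % 2).astype(float)  # period 100 square wave
    spec = power_spectrum(x, window_length=1 << 13)
    assert abs(spec.dominant_frequency - 0.01) <= 1 / (1 << 13)


def test_spectrum_stride_scales_frequencies():
    t = np.arange(1 << 14)
    x = np.sin(2 * np.pi * t / 50.0)  # period 50 samples at stride 2
    spec = power_spectrum(x, window_length=1 << 13, stride=2)
    assert abs(spec.dominant_frequency - 0.01) < 1e-4


def test_spectrum_white_noise_has_no_dominant_line():
    """Monte-Carlo null: white noise rarely produces a bin above 5x the
    median power."""
    hits = 0
    for seed in range(100):
        x = np.random.RandomState(seed).normal(size=4096)
        spec = power_spectrum(x, window_length=1024)
        psd = spec.power[1:]
        if psd.max() <= 5 * np.median(psd):
            hits += 1
    assert hits >= 95


def test_spectrum_rejects_short_series():
    with pytest.raises(ValueError):
        power_spectrum(np.zeros(100), window_length=1024)


# ------------------------------------------------- signature activity --


def test_activity_series_matches_label_scan(driven_small_record):
    sas = signature_activity_series(driven_small_record)
    labels = driven_small_record.label_frames.reshape(
        driven_small_record.duration + 1, -1
    )
    for k in range(sas.counts.shape[0]):
        scan = (labels == k).sum(axis=1)
        assert np.array_equal(sas.counts[k], scan)
    assert sas.counts.sum(axis=0).max() <= sas.n_cells


# ----------------------------------------------------------- clusters --


def test_cluster_metrics_trivial_cases():
    topo = build_torus_grid(7, 7)
    frame = np.full(49, -1)
    frame[10] = 0
    stats = cluster_metrics(frame, topo)
    assert stats.clustering[0] == 0.0 and stats.mean_path[0] == 0.0
    frame[11] = 0  # two adjacent cells
    stats = cluster_metrics(frame, topo)
    assert stats.mean_path[0] == 1.0 and stats.sizes[0] == 2


def test_cluster_metrics_full_torus_analytic():
    """All cells one label: clustering and mean path equal the analytic
    values of the full Moore torus (computed by brute force over offsets
    and wrapped Chebyshev distances)."""
    n = 7
    topo = build_torus_grid(n, n)
    stats = cluster_metrics(np.zeros(n * n, dtype=int), topo)
    offs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)]
    # clustering: fraction of neighbour pairs that are themselves adjacent
    links = 0
    for i, a in enumerate(offs):
        for b in offs[i + 1:]:
            d = (abs(a[0] - b[0]), abs(a[1] - b[1]))
            if max(d) == 1:
                links += 1
    expect_clust = links / (8 * 7 / 2)
    assert np.isclose(stats.clustering[0], expect_clust)
    # mean shortest path: wrapped Chebyshev distance, averaged over pairs
    dists = []
    for dr in range(n):
        for dc in range(n):
            if dr == dc == 0:
                continue
            dists.append(max(min(dr, n - dr), min(dc, n - dc)))
    expect_path = np.mean(dists)
    assert np.isclose(stats.mean_path[0], expect_path)


def test_cluster_metrics_shape_mismatch():
    with pytest.raises(ValueError):
        cluster_metrics(np.zeros(10), build_torus_grid(5, 5))


# ------------------------------------------- memory and competition --


def test_memory_zero_after_stimulation_is_short_term():
    series = np.zeros(5000)
    series[1000:2000] = 100
    mem = characterize_memory(series, 1000, 2000, 4999)
    assert mem.kind == "short_term" and mem.reverberation_period == 0
    # decaying tail: reverberation equals the time the counts stay up
    series[2000:2600] = 100
    mem = characterize_memory(series, 1000, 2000, 4999)
    assert mem.kind == "short_term"
    assert 550 <= mem.reverberation_period <= 650


def test_memory_persistent_activity_is_long_term():
    series = np.zeros(5000)
    series[1000:] = 50
    mem = characterize_memory(series, 1000, 2000, 4999)
    assert mem.kind == "long_term" and mem.reverberation_period is None


def test_memory_rejects_horizon_before_stim_end():
    with pytest.raises(ValueError):
        characterize_memory(np.zeros(100), 0, 50, 40)


def test_competition_classification_on_synthetic_series():
    T = 10000
    rs = np.random.RandomState(8)
    # WTA: one signature dominates by far
    wta = np.vstack(
        [1000 + rs.randint(0, 50, (1, T)), 10 + rs.randint(0, 5, (9, T))]
    )
    reg = classify_competition_regime(wta, (0, T - 1))
    assert reg.kind == "WTA" and reg.shares[0] > 0.9
    # WLC: comparable fluctuating levels, alternating dominance
    wlc = 100 + rs.randint(0, 50, (10, T))
    reg = classify_competition_regime(wlc, (0, T - 1))
    assert reg.kind == "WLC" and reg.switches > 100
    with pytest.raises(ValueError):
        classify_competition_regime(wlc[:1], (0, T - 1))
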