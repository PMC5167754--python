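"""Characterization of the two encoding modalities.

Rhythmic modality
    Each membrane-potential frame is treated as an image and decomposed
    with the two-dimensional *non-standard* Haar wavelet transform (the
    level-by-level alternating row/column decomposition, i.e. the usual
    2D multiresolution pyramid).  The number of significant coefficients
    C(t) is a one-dimensional complexity signal: small for synchronized
    frames, near-maximal for independent random activity.  Rhythms of
    propagating bursting wave fronts appear as spectral peaks of C(t),
    estimated here with Welch periodograms.

Spike-timing modality
    The per-step number of neurons whose preferred output pattern equals
    each tracked fingerprint ("recognize and emit") measures the level
    of activity of every signature travelling through the network.  From
    these series the memory regime (short- vs. long-term reverberation
    after stimulation ends) and the competition regime (winnerless vs.
    winner-take-all) are classified; the spatial organisation of
    same-signature clusters is quantified with clustering coefficients
    and shortest paths on the Moore-adjacency subgraph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pywt
from scipy import signal as sp_signal

from .network_sim import ActivityRecord, GridTopology

__all__ = [
    "WaveletSeries",
    "SpectrumResult",
    "SignatureActivitySeries",
    "ClusterStats",
    "MemoryCharacterization",
    "CompetitionRegime",
    "default_eps",
    "pad_to_pow2",
    "nonstandard_haar_dwt2",
    "inverse_haar_dwt2",
    "count_significant_coefficients",
    "complexity_of_frames",
    "complexity_series",
    "power_spectrum",
    "signature_activity_series",
    "cluster_metrics",
    "characterize_memory",
    "classify_competition_regime",
]


def default_eps(AP: int) -> float:
    """Default significance threshold: 10^-6 of the spike peak potential.

    On integer-valued frames this is an effectively-nonzero count while
    remaining robust to float round-off from the padded transform.
    """
    return 1e-6 * AP


def pad_to_pow2(frame: np.ndarray) -> np.ndarray:
    """Zero-pad a 2D frame into the smallest enclosing power-of-two square."""
    r, c = frame.shape
    size = 1
    while size < max(r, c):
        size *= 2
    out = np.zeros((size, size), dtype=np.float64)
    out[:r, :c] = frame
    return out


def nonstandard_haar_dwt2(frame: np.ndarray) -> np.ndarray:
    """Full non-standard 2D Haar decomposition of a frame.

    The frame is zero-padded to a power-of-two square and decomposed to
    the coarsest level with the orthonormal Haar filter pair; returns the
    coefficients packed into a single square array (approximation in the
    top-left corner, detail bands around it).  The transform is
    orthogonal: :func:`inverse_haar_dwt2` reconstructs the padded frame
    exactly up to float round-off.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2D array")
    padded = pad_to_pow2(frame.astype(np.float64))
    coeffs = pywt.wavedec2(padded, "haar")
    arr, _ = pywt.coeffs_to_array(coeffs)
    return arr

def inverse_haar_dwt2(coeff_array: np.ndarray) -> np.ndarray:
    """Reconstruct the (padded) frame from a packed coefficient array."""
    size = coeff_array.shape[0]
    template = pywt.wavedec2(np.zeros((size, size)), "haar")
    _, slices = pywt.coeffs_to_array(template)
    coeffs = pywt.array_to_coeffs(coeff_array, slices, output_format="wavedec2")
    return pywt.waverec2(coeffs, "haar")


def count_significant_coefficients(coeffs: np.ndarray, eps: float) -> int:
    """Number of coefficients with magnitude above ``eps``."""
    if eps < 0:
        raise ValueError(f"eps must be >= 0, got {eps}")
    return int(np.count_nonzero(np.abs(coeffs) > eps))


def complexity_of_frames(frames: np.ndarray, eps: float) -> np.ndarray:
    """C(t) for a stack of frames (T, rows, cols), computed in one batch."""
    frames = np.asarray(frames, dtype=np.float64)
    T, r, c = frames.shape
    size = 1
    while size < max(r, c):
        size *= 2
    padded = np.zeros((T, size, size), dtype=np.float64)
    padded[:, :r, :c] = frames
    coeffs = pywt.wavedec2(padded, "haar", axes=(1, 2))
    out = np.zeros(T, dtype=np.int64)
    out += np.count_nonzero(np.abs(coeffs[0]) > eps, axis=(1, 2))
    for detail in coeffs[1:]:
        for band in detail:
            out += np.count_nonzero(np.abs(band) > eps, axis=(1, 2))
    return out


@dataclass
class WaveletSeries:
    """C(t): per-frame significant-coefficient counts of a run.

    ``max_coefficients`` is the padded coefficient count (the attainable
    upper bound of C, e.g. 64^2 for a 50x50 grid padded to 64x64).
    """

    C: np.ndarray
    eps: float
    stride: int = 1
    max_coefficients: Optional[int] = None


def complexity_series(
    record: ActivityRecord, eps: Optional[float] = None
) -> WaveletSeries:
    """C(t) for a recorded run.

    Uses the inline complexity computed during the run when available
    (every step); otherwise transforms the stored V frames at their
    stride.
    """
    if eps is None:
        eps = (
            record.complexity_eps
            if record.complexity_eps is not None
            else default_eps(record.config.neuron.AP)
        )
    size = 1
    while size < max(record.config.rows, record.config.cols):
        size *= 2
    if record.complexity is not None and record.complexity_eps == eps:
        return WaveletSeries(
            record.complexity, eps, stride=1, max_coefficients=size * size
        )
    if record.v_frames is None:
        raise ValueError(
            "record has neither inline complexity at this eps nor V frames"
        )
    C = complexity_of_frames(record.v_frames, eps)
    return WaveletSeries(
        C, eps, stride=record.frame_stride, max_coefficients=size * size
    )


@dataclass
class SpectrumResult:
    """Normalized power spectrum of a scalar series.

    Frequencies are in cycles per time step; power is scaled to a
    maximum of 1; the dominant frequency excludes the zero bin.
    """

    frequencies: np.ndarray
    power: np.ndarray
    dominant_frequency: float


def power_spectrum(
    series, window_length: int = 1 << 16, stride: Optional[int] = None
) -> SpectrumResult:
    """Welch spectrum of C(t) (or any scalar series), mean removed.

    ``window_length`` is the Welch segment length in samples; it is the
    spectral resolution knob (default 2^16 steps, enough to separate the
    milli-cycle-per-step network rhythms).
    """
    if isinstance(series, WaveletSeries):
        x = np.asarray(series.C, dtype=np.float64)
        if stride is None:
            stride = series.stride
    else:
        x = np.asarray(series, dtype=np.float64)
    if stride is None:
        stride = 1
    if x.size < window_length:
        raise ValueError(
            f"series of length {x.size} shorter than window_length "
            f"{window_length}"
        )
    x = x - x.mean()
    freqs, psd = sp_signal.welch(
        x, fs=1.0 / stride, nperseg=window_length, detrend="constant"
    )
    peak = psd.max()
    if peak > 0:
        psd = psd / peak
    dom = float(freqs[1:][np.argmax(psd[1:])])
    return SpectrumResult(frequencies=freqs, power=psd, dominant_frequency=dom)


@dataclass
class SignatureActivitySeries:
    """Per-step counts of neurons recognizing each tracked signature."""

    counts: np.ndarray  # (n_tracked, T + 1)
    tracked_cells: Tuple[int, ...]
    n_cells: int

    def series(self, k: int) -> np.ndarray:
        return self.counts[k]


def signature_activity_series(record: ActivityRecord) -> SignatureActivitySeries:
    """Evolution of the number of neurons that recognize and emit each
    tracked fingerprint (one row per tracked signature, one column per
    time step)."""
    if record.signature_counts is None:
        raise ValueError("record carries no signature counts")
    return SignatureActivitySeries(
        counts=record.signature_counts,
        tracked_cells=record.tracked_cells,
        n_cells=record.config.n_cells,
    )


@dataclass
class ClusterStats:
    """Spatial organisation of same-label cells on the grid.

    ``clustering`` / ``mean_path`` / ``sizes`` are keyed by label.  The
    clustering coefficient is the mean local clustering over the label's
    cells within the Moore-adjacency subgraph; the mean shortest path is
    averaged over connected components (isolated cells contribute 0).
    """

    clustering: Dict[int, float]
    mean_path: Dict[int, float]
    sizes: Dict[int, int]


def cluster_metrics(
    label_frame: np.ndarray,
    topology: GridTopology,
    labels: Optional[Sequence[int]] = None,
) -> ClusterStats:
    """Clustering coefficient and shortest paths per recognized label.

    For each label the subgraph induced on the same-label cells,
    restricted to grid-adjacent (Moore) edges, is analysed.  Negative
    codes ("none recognized" / untracked) are skipped unless requested
    explicitly.
    """
    flat = np.asarray(label_frame).reshape(-1)
    if flat.shape[0] != topology.n_cells:
        raise ValueError("label frame does not match topology size")
    if labels is None:
        labels = sorted(int(v) for v in np.unique(flat) if v >= 0)
    clustering: Dict[int, float] = {}
    mean_path: Dict[int, float] = {}
    sizes: Dict[int, int] = {}
    nbr = topology.neighbor_array
    for lab in labels:
        cells = np.flatnonzero(flat == lab)
        sizes[lab] = int(cells.size)
        if cells.size == 0:
            clustering[lab] = 0.0
            mean_path[lab] = 0.0
            continue
        in_label = np.zeros(topology.n_cells, dtype=bool)
        in_label[cells] = True
        G = nx.Graph()
        G.add_nodes_from(int(c) for c in cells)
        for c in cells:
            for j in nbr[c]:
                if in_label[j]:
                    G.add_edge(int(c), int(j))
        clustering[lab] = float(np.mean(list(nx.clustering(G).values())))
        comp_paths = []
        for comp in nx.connected_components(G):
            if len(comp) == 1:
                comp_paths.append(0.0)
            else:
                comp_paths.append(
                    nx.average_shortest_path_length(G.subgraph(comp))
                )
        mean_path[lab] = float(np.mean(comp_paths))
    return ClusterStats(clustering=clustering, mean_path=mean_path, sizes=sizes)


@dataclass
class MemoryCharacterization:
    """Outcome of the reverberation analysis after stimulation ends."""

    kind: str  # "short_term" | "long_term"
    reverberation_period: Optional[int]
    floor: float
    baseline: float


def characterize_memory(
    series: np.ndarray,
    stim_start: int,
    stim_end: int,
    horizon: int,
    floor_frac: float = 0.05,
    sustain: int = 1000,
) -> MemoryCharacterization:
    """Classify a single-signature activity series as short/long-term memory.

    The baseline is the mean count over the stimulation window; the
    activity is considered extinguished at the first step after
    ``stim_end`` from which the counts stay below ``floor_frac`` x
    baseline for ``sustain`` consecutive steps.  If that never happens
    before ``horizon`` the network holds the fingerprint as a long-term
    memory.
    """
    series = np.asarray(series, dtype=np.float64)
    if horizon <= stim_end:
        raise ValueError(
            f"horizon {horizon} must exceed stimulation end {stim_end}"
        )
    horizon = min(horizon, series.size - 1)
    baseline = float(series[stim_start : stim_end + 1].mean())
    floor = floor_frac * baseline
    tail = series[stim_end : horizon + 1]
    below = tail < floor
    if baseline == 0.0:
        # nothing was ever recognized during stimulation
        return MemoryCharacterization("short_term", 0, floor, baseline)
    run = 0
    for offset, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= sustain:
            return MemoryCharacterization(
                "short_term", offset - sustain + 1, floor, baseline
            )
    return MemoryCharacterization("long_term", None, floor, baseline)


@dataclass
class CompetitionRegime:
    """Outcome of the multi-signature competition analysis.

    ``shares`` is each signature's fraction of (active) time steps on
    which it held the maximal count; ``switches`` counts dominance
    changes.  WTA requires one signature to dominate more than
    ``share_threshold`` of the time with a mean count more than
    ``ratio_threshold`` times the runner-up's.
    """

    kind: str  # "WTA" | "WLC"
    shares: np.ndarray
    mean_counts: np.ndarray
    switches: int


def classify_competition_regime(
    series: np.ndarray,
    window: Tuple[int, int],
    share_threshold: float = 0.9,
    ratio_threshold: float = 10.0,
) -> CompetitionRegime:
    """Winner-take-all vs. winnerless competition among >= 2 signatures."""
    counts = np.asarray(series, dtype=np.float64)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need counts for at least 2 tracked signatures")
    a, b = window
    win = counts[:, a : b + 1]
    active = win.sum(axis=0) > 0
    mean_counts = win.mean(axis=1)
    order = np.argsort(mean_counts)[::-1]
    if not active.any():
        return CompetitionRegime(
            "WLC", np.zeros(counts.shape[0]), mean_counts, 0
        )
    dom = np.argmax(win[:, active], axis=0)
    shares = np.bincount(dom, minlength=counts.shape[0]) / dom.size
    switches = int(np.count_nonzero(np.diff(dom)))
    top, runner = order[0], order[1]
    is_wta = shares[top] > share_threshold and (
        mean_counts[top] > ratio_threshold * max(mean_counts[runner], 1e-12)
    )
    return CompetitionRegime(
        "WTA" if is_wta else "WLC", shares, mean_counts, switches
    )
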