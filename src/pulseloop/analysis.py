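"""Offline analysis stack.

Epoching of pre-shot windows, Morlet time-frequency decomposition, ROI
power, responder classification, a Hjorth finite-difference surface
Laplacian, debiased weighted phase lag index (dwPLI) connectivity,
proportional-threshold graph metrics, and two nonparametric cluster-based
permutation tests: one over channel x frequency x time power maps, and one
over connectivity edges aggregated by shared nodes.

Statistical conventions follow the sensor-space permutation framework:
one-sample t-statistics over subjects on within-subject condition
differences, a cluster-forming threshold at alpha_cluster (two-sided),
summed t as the cluster statistic, and a sign-flip Monte Carlo null of the
maximum cluster statistic, with corrected p = (1 + #{null >= obs}) /
(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import fft as sp_fft
from scipy import signal, stats

from .recording import EEGRecording, MASTOIDS, channel_adjacency, neighbor_lists


# ---------------------------------------------------------------------------
# Epoching


@dataclass
class Epochs:
    """trials x channels x samples with a common relative time axis."""

    data: np.ndarray
    times: np.ndarray
    rate: float
    labels: tuple[str, ...]
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.labels.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None


def collapse_duplicate_events(times: Sequence[float], min_sep: float = 1.0) -> list[float]:
    """Reduce duplicate trigger marks within ``min_sep`` of the same event to
    the first occurrence."""
    out: list[float] = []
    for t in times:
        if not out or t - out[-1] >= min_sep:
            out.append(float(t))
    return out


def epoch_preshot(rec: EEGRecording, window_s: float = 6.0, kind: str | None = "fire") -> Epochs:
    """Cut [-window_s, 0) epochs before each (deduplicated) firing trigger.

    Events too early for a full pre-window are dropped and counted in
    ``n_dropped``.
    """
    times = collapse_duplicate_events(sorted(rec.event_times(kind)))
    if not times:
        raise ValueError("recording has no usable events")
    w = int(round(window_s * rec.rate))
    segs, dropped = [], 0
    for t in times:
        i1 = int(round(t * rec.rate))
        i0 = i1 - w
        if i0 < 0 or i1 > rec.n_samples:
            dropped += 1
            continue
        segs.append(rec.data[:, i0:i1])
    if not segs:
        raise ValueError("no epoch has sufficient pre-event data")
    data = np.stack(segs)
    times_axis = (np.arange(w) - w) / rec.rate
    return Epochs(data=data, times=times_axis, rate=rec.rate, labels=rec.labels, n_dropped=dropped)


def epoch_rest(rec: EEGRecording, epoch_s: float = 2.0) -> Epochs:
    """Continuous non-overlapping epochs for resting-state segments."""
    w = int(round(epoch_s * rec.rate))
    n = rec.n_samples // w
    if n == 0:
        raise ValueError("recording shorter than one epoch")
    data = rec.data[:, : n * w].reshape(rec.n_channels, n, w).transpose(1, 0, 2)
    return Epochs(data=data.copy(), times=np.arange(w) / rec.rate, rate=rec.rate, labels=rec.labels)


# ---------------------------------------------------------------------------
# Morlet TFR


@dataclass
class TFR:
    """Trial-averaged channel x frequency x time power map in dB.

    ``valid`` flags time-frequency samples farther than half the wavelet
    support from the epoch edges; edge-contaminated samples are False.
    """

    data_db: np.ndarray            # (n_channels, n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray              # (n_freqs, n_times) bool
    labels: tuple[str, ...]
    cycles: float = 5.0


def _morlet_kernel(freq: float, cycles: float, rate: float) -> np.ndarray:
    """Complex Morlet wavelet, amplitude-calibrated.

    Normalized so convolution with cos(2*pi*f*t) of amplitude A returns a
    complex series of magnitude A: the Gaussian weight sums to 2 (analytic
    half).  Support is +/- 5 Gaussian SDs.
    """
    sigma_t = cycles / (2 * np.pi * freq)
    half = int(np.ceil(5 * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    gauss = np.exp(-(t**2) / (2 * sigma_t**2))
    w = gauss * np.exp(2j * np.pi * freq * t)
    return 2.0 * w / gauss.sum()


def morlet_support_s(freq: float, cycles: float = 5.0) -> float:
    """Half-support (s) used for edge flagging: 5 sigma_t."""
    return 5.0 * cycles / (2 * np.pi * freq)


def morlet_tfr(
    ep: Epochs,
    freqs: np.ndarray | None = None,
    cycles: float = 5.0,
    t_step: float = 0.05,
) -> TFR:
    """Morlet continuous wavelet transform, trial-averaged, in dB.

    Per trial and channel the signal is convolved with an
    amplitude-calibrated complex Morlet wavelet (``cycles`` cycles); the
    half magnitude-squared (so a stationary sinusoid of amplitude A maps
    to A**2/2, matching the mean-square convention of the real-time
    feature) is averaged over trials and converted to dB on a time grid of
    ``t_step`` seconds.
    """
    if freqs is None:
        freqs = np.arange(4.0, 46.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    n_samp = ep.data.shape[-1]
    if n_samp / ep.rate < 2 * morlet_support_s(freqs.min(), cycles):
        raise ValueError("epoch shorter than the lowest-frequency wavelet support")
    decim = max(1, int(round(t_step * ep.rate)))
    idx = np.arange(0, n_samp, decim)
    times = ep.times[idx]
    n_trials, n_ch = ep.data.shape[:2]
    flat = ep.data.reshape(n_trials * n_ch, n_samp)
    nfft = sp_fft.next_fast_len(2 * n_samp)
    F = sp_fft.fft(flat, nfft, axis=-1)
    power = np.empty((n_ch, freqs.size, idx.size))
    valid = np.empty((freqs.size, idx.size), dtype=bool)
    for i, f in enumerate(freqs):
        k = _morlet_kernel(f, cycles, ep.rate)
        K = sp_fft.fft(k, nfft)
        conv = sp_fft.ifft(F * K, axis=-1)
        start = (k.size - 1) // 2
        seg = conv[:, start : start + n_samp][:, idx]
        p = 0.5 * np.abs(seg) ** 2
        power[:, i, :] = p.reshape(n_trials, n_ch, idx.size).mean(axis=0)
        half_s = morlet_support_s(f, cycles)
        valid[i] = (times - ep.times[0] >= half_s) & (ep.times[-1] - times >= half_s)
    with np.errstate(divide="ignore"):
        data_db = 10.0 * np.log10(power)
    return TFR(data_db=data_db, freqs=freqs, times=times, valid=valid,
               labels=ep.labels, cycles=cycles)


# ---------------------------------------------------------------------------
# ROI power and responder classification


@dataclass(frozen=True)
class RoiSpec:
    name: str
    channels: tuple[str, ...]
    band: tuple[float, float]
    window: tuple[float, float]


#: Confirmatory ROIs over the sensorimotor and frontal territories.
SMR_KEY_AREA = RoiSpec("SMR_Key_Area", ("Cz", "C3", "C4", "CP1", "CP2"), (12.0, 15.0), (-5.0, -0.5))
THETA_FRONTAL = RoiSpec("Theta_Frontal", ("Fz", "F3", "F4", "FC1", "FC2"), (4.0, 7.0), (-5.0, -1.0))


def roi_log_power(tfr: TFR, roi: RoiSpec) -> float:
    """Mean log10 power (dB/10) over ROI channels x band bins x time window,
    excluding edge-flagged samples."""
    ch_idx = [tfr.labels.index(c) if c in tfr.labels else -1 for c in roi.channels]
    if any(i < 0 for i in ch_idx):
        missing = [c for c in roi.channels if c not in tfr.labels]
        raise KeyError(f"ROI channels not in montage: {missing}")
    f_sel = (tfr.freqs >= roi.band[0]) & (tfr.freqs <= roi.band[1])
    t_sel = (tfr.times >= roi.window[0]) & (tfr.times <= roi.window[1])
    mask = tfr.valid & f_sel[:, None] & t_sel[None, :]
    if not mask.any():
        raise ValueError("ROI selection is empty (band/window outside valid coverage)")
    sub = tfr.data_db[ch_idx][:, mask]
    return float(sub.mean() / 10.0)


@dataclass(frozen=True)
class ResponderLabel:
    subject: str
    smr_responder: bool | None
    theta_responder: bool | None
    delta_smr: float | None = None
    delta_theta: float | None = None


def classify_responders(
    smr_power: Mapping[str, tuple[float, float]] | None = None,
    theta_power: Mapping[str, tuple[float, float]] | None = None,
) -> list[ResponderLabel]:
    """Single-electrode responder rule on (feedback, baseline) log10 power.

    SMR responder: Cz 12-15 Hz power higher under SMR feedback than under
    the no-sound baseline.  Theta responder: Fz 4-7 Hz power lower under
    theta feedback than baseline.  Strict inequalities; equality counts as
    non-responder.  Power values are the [-3.0, -0.5] s pre-shot means.
    """
    subjects = sorted(set(smr_power or {}) | set(theta_power or {}))
    if not subjects:
        raise ValueError("no subjects provided")
    out = []
    for s in subjects:
        smr_flag = d_smr = None
        theta_flag = d_theta = None
        if smr_power is not None:
            if s not in smr_power:
                raise KeyError(f"missing SMR conditions for subject {s!r}")
            fb, base = smr_power[s]
            d_smr = fb - base
            smr_flag = fb > base
        if theta_power is not None:
            if s not in theta_power:
                raise KeyError(f"missing theta conditions for subject {s!r}")
            fb, base = theta_power[s]
            d_theta = fb - base
            theta_flag = fb < base
        out.append(ResponderLabel(s, smr_flag, theta_flag, d_smr, d_theta))
    return out


#: Time window for the responder power metric.
RESPONDER_WINDOW = (-3.0, -0.5)


# ---------------------------------------------------------------------------
# Surface Laplacian (Hjorth finite difference)


def laplacian_fd(data: np.ndarray, labels: Sequence[str], adjacency: np.ndarray | None = None) -> np.ndarray:
    """Hjorth scalp current density: each channel minus the mean of its
    spatial neighbors.

    Mastoids are excluded from the neighbor graph and passed through
    unchanged.  Accepts (channels, samples) or (trials, channels, samples).
    """
    labels = tuple(labels)
    if adjacency is None:
        adjacency = channel_adjacency(labels)
    nbrs = neighbor_lists(np.asarray(adjacency, dtype=bool))
    scalp = [i for i, lab in enumerate(labels) if lab not in MASTOIDS]
    mast = set(range(len(labels))) - set(scalp)
    src = np.asarray(data, dtype=float)
    src3 = src[None] if src.ndim == 2 else src
    res = src3.copy()
    for c in scalp:
        nb = [j for j in nbrs[c] if j not in mast]
        if len(nb) < 1:
            raise ValueError(f"channel {labels[c]!r} has no scalp neighbors")
        res[:, c] = src3[:, c] - src3[:, nb].mean(axis=1)
    return res[0] if src.ndim == 2 else res


# ---------------------------------------------------------------------------
# dwPLI connectivity


@dataclass
class ConnectivityMatrix:
    values: np.ndarray            # (n, n) symmetric, nan diagonal
    band: tuple[float, float]
    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _dpss_tapers(n: int, rate: float, smoothing_hz: float) -> np.ndarray:
    """DPSS tapers for +/- ``smoothing_hz`` multitaper smoothing; falls back
    to a single Hann taper when the time-bandwidth product is too small."""
    t_len = n / rate
    nw = t_len * smoothing_hz
    k = int(max(1, np.floor(2 * nw - 1)))
    if nw < 1.0:
        return signal.windows.hann(n)[None, :]
    return signal.windows.dpss(n, nw, Kmax=k)


def dwpli_matrix(
    ep: Epochs,
    band: tuple[float, float],
    smoothing_hz: float = 1.0,
) -> ConnectivityMatrix:
    """Debiased weighted phase lag index over all channel pairs.

    Complex spectra come from a multitaper FFT (DPSS tapers, +/- 1 Hz
    smoothing by default); observations are trial x taper.  Per frequency
    bin, with Z_j the cross-spectrum of observation j,

        dwPLI = sum_{j != k} Im(Z_j) Im(Z_k) / sum_{j != k} |Im(Z_j) Im(Z_k)|

    computed via the debiased square estimator and averaged over the
    band's bins.  Insensitive to zero-lag (volume-conducted) coupling.
    """
    n_trials, n_ch, n_samp = ep.data.shape
    tapers = _dpss_tapers(n_samp, ep.rate, smoothing_hz)
    n_obs = n_trials * tapers.shape[0]
    if n_obs < 2:
        raise ValueError("need at least 2 observations (trials x tapers)")
    freqs = np.fft.rfftfreq(n_samp, 1.0 / ep.rate)
    sel = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    if sel.size == 0:
        raise ValueError(f"band {band} outside spectral resolution")
    x = signal.detrend(ep.data, axis=-1)
    # (trials, tapers, channels, freq_bins) -> observations x channels x bins
    tapered = x[:, None, :, :] * tapers[None, :, None, :]
    X = np.fft.rfft(tapered, axis=-1)[..., sel]
    X = X.reshape(n_obs, n_ch, sel.size)

    num = np.zeros((n_ch, n_ch))
    den = np.zeros((n_ch, n_ch))
    for b in range(sel.size):
        M = X[:, :, b]
        # Im(Z_ij^o) = Im(M_oi * conj(M_oj)) for each observation o
        imz = np.einsum("oi,oj->oij", M, M.conj()).imag
        s1 = imz.sum(axis=0)
        s2 = (imz**2).sum(axis=0)
        sa = np.abs(imz).sum(axis=0)
        nb = s1**2 - s2
        db = sa**2 - s2
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(db > 0, nb / np.where(db > 0, db, 1.0), 0.0)
        num += v
        den += 1.0
    vals = num / den
    vals = 0.5 * (vals + vals.T)
    np.fill_diagonal(vals, np.nan)
    return ConnectivityMatrix(values=vals, band=tuple(band), labels=ep.labels)


def global_fc(m: ConnectivityMatrix) -> float:
    """Global connectivity strength: mean of strictly-upper-triangular values."""
    if m.n < 2:
        raise ValueError("need at least 2 channels")
    iu = np.triu_indices(m.n, k=1)
    return float(np.nanmean(m.values[iu]))


# ---------------------------------------------------------------------------
# Graph construction and metrics


def binarize_top_proportion(m: ConnectivityMatrix, p: float = 0.20) -> np.ndarray:
    """Keep the ceil(p * E) strongest undirected edges (E = n(n-1)/2).

    Ties at the cut are broken by lexicographic channel-pair order, so the
    retained set is deterministic.
    """
    if not 0 < p <= 1:
        raise ValueError("proportion must be in (0, 1]")
    n = m.n
    iu, ju = np.triu_indices(n, k=1)
    w = m.values[iu, ju]
    keep = int(np.ceil(p * iu.size))
    order = sorted(range(iu.size), key=lambda e: (-w[e], iu[e], ju[e]))
    adj = np.zeros((n, n), dtype=bool)
    for e in order[:keep]:
        adj[iu[e], ju[e]] = adj[ju[e], iu[e]] = True
    return adj


@dataclass(frozen=True)
class GraphMetrics:
    global_efficiency: float
    clustering_coefficient: float
    weighted_strength: float
    degree_heterogeneity: float


def graph_metrics(adj: np.ndarray, weights: ConnectivityMatrix) -> GraphMetrics:
    """Binary efficiency/clustering (via networkx), mean retained-edge
    weighted strength, and degree heterogeneity = SD(degree)/mean(degree)."""
    import networkx as nx

    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    G = nx.from_numpy_array(adj.astype(int))
    if G.number_of_edges() == 0:
        return GraphMetrics(0.0, 0.0, 0.0, 0.0)
    eff = nx.global_efficiency(G)
    clust = nx.average_clustering(G)
    wmat = np.where(adj, weights.values, 0.0)
    strength = float(np.nansum(wmat, axis=1).mean())
    deg = adj.sum(axis=1).astype(float)
    het = float(deg.std() / deg.mean()) if deg.mean() > 0 else 0.0
    return GraphMetrics(float(eff), float(clust), strength, het)


# ---------------------------------------------------------------------------
# Cluster permutation machinery


@dataclass(frozen=True)
class Cluster:
    members: tuple[int, ...]      # flat indices into the statistic map
    stat: float                   # summed t
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_max: np.ndarray
    n_permutations: int
    alpha: float
    shape: tuple[int, ...] = ()

    def significant(self, level: float | None = None) -> list[Cluster]:
        level = self.alpha if level is None else level
        return [c for c in self.clusters if c.p < level]


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _tfr_clusters(
    supra: np.ndarray,
    tmap: np.ndarray,
    ch_nbrs: list[np.ndarray],
) -> list[tuple[np.ndarray, float]]:
    """Connected components of same-sign supra-threshold (ch, f, t) points.

    Adjacency: 4-neighborhood on the freq-time grid within a channel, plus
    identical (f, t) across spatially neighboring channels.
    """
    n_ch, n_f, n_t = tmap.shape
    out: list[tuple[np.ndarray, float]] = []
    for sign in (1, -1):
        mask = supra & ((tmap > 0) if sign > 0 else (tmap < 0))
        pts = np.flatnonzero(mask.ravel())
        if pts.size == 0:
            continue
        pos = {int(p): k for k, p in enumerate(pts)}
        uf = _UnionFind(pts.size)
        ft = n_f * n_t
        for k, p in enumerate(pts):
            c, rem = divmod(int(p), ft)
            f, t = divmod(rem, n_t)
            if t + 1 < n_t and (q := p + 1) in pos and mask.flat[q]:
                uf.union(k, pos[q])
            if f + 1 < n_f and (q := p + n_t) in pos:
                uf.union(k, pos[q])
            for c2 in ch_nbrs[c]:
                if c2 > c and (q := int(p + (c2 - c) * ft)) in pos:
                    uf.union(k, pos[q])
        roots: dict[int, list[int]] = {}
        for k, p in enumerate(pts):
            roots.setdefault(uf.find(k), []).append(int(p))
        for members in roots.values():
            arr = np.asarray(members)
            out.append((arr, float(tmap.flat[arr].sum())))
    return out


def _sign_flip_tmaps(X: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps for all sign-flip permutations in one shot.

    X is (n_subjects, n_points); signs is (n_perm, n_subjects).  Squares
    are sign-invariant, so each permutation's t needs only the flipped sum.
    """
    n = X.shape[0]
    ssq = (X**2).sum(axis=0)
    means = signs @ X / n
    var = (ssq - n * means**2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return means / np.sqrt(var / n)


def cluster_perm_tfr(
    diffs: np.ndarray,
    adjacency: np.ndarray,
    alpha_cluster: float = 0.05,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    tail: float = 0.05,
) -> ClusterResult:
    """Channel-frequency-time cluster permutation test on per-subject
    difference maps.

    ``diffs`` is (n_subjects, n_channels, n_freqs, n_times).  Points with
    |t| above the two-sided alpha_cluster critical value form clusters
    (positive and negative separately); the null distribution collects the
    maximum |summed t| under random per-subject sign flips.  Two-tailed
    inference: a cluster is significant at tail/2 per side.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 4:
        raise ValueError("diffs must be (subjects, channels, freqs, times)")
    n_sub = diffs.shape[0]
    if n_sub < 2:
        raise ValueError("need >= 2 subjects")
    shape = diffs.shape[1:]
    if adjacency.shape != (shape[0], shape[0]):
        raise ValueError("adjacency must cover all channels")
    ch_nbrs = neighbor_lists(np.asarray(adjacency, dtype=bool))
    tcrit = stats.t.ppf(1 - alpha_cluster / 2, df=n_sub - 1)

    X = diffs.reshape(n_sub, -1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tobs = _sign_flip_tmaps(X, np.ones((1, n_sub)))[0].reshape(shape)
    obs_clusters = _tfr_clusters(np.abs(tobs) > tcrit, tobs, ch_nbrs)

    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    tperm = _sign_flip_tmaps(X, signs)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        tm = tperm[i].reshape(shape)
        cl = _tfr_clusters(np.abs(tm) > tcrit, tm, ch_nbrs)
        if cl:
            null_max[i] = max(abs(s) for _, s in cl)

    clusters = [
        Cluster(tuple(int(m) for m in members), s,
                float((1 + np.sum(null_max >= abs(s))) / (n_perm + 1)))
        for members, s in obs_clusters
    ]
    clusters.sort(key=lambda c: -abs(c.stat))
    return ClusterResult(clusters, null_max, n_perm, alpha=tail / 2, shape=shape)


def _edge_clusters(
    sig: np.ndarray,
    tvals: np.ndarray,
    iu: np.ndarray,
    ju: np.ndarray,
) -> list[tuple[np.ndarray, float]]:
    """Connected components of same-sign significant edges, where two edges
    are adjacent iff they share a node."""
    out: list[tuple[np.ndarray, float]] = []
    for sign in (1, -1):
        idx = np.flatnonzero(sig & ((tvals > 0) if sign > 0 else (tvals < 0)))
        if idx.size == 0:
            continue
        uf = _UnionFind(idx.size)
        node_owner: dict[int, int] = {}
        for k, e in enumerate(idx):
            for node in (int(iu[e]), int(ju[e])):
                if node in node_owner:
                    uf.union(node_owner[node], k)
                else:
                    node_owner[node] = k
        roots: dict[int, list[int]] = {}
        for k, e in enumerate(idx):
            roots.setdefault(uf.find(k), []).append(int(e))
        for members in roots.values():
            arr = np.asarray(members)
            out.append((arr, float(tvals[arr].sum())))
    return out


def cluster_perm_edges(
    diffs: np.ndarray,
    alpha_edge: float = 0.05,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> ClusterResult:
    """Node-sharing edge-cluster permutation test on per-subject FC
    difference matrices (n_subjects, n, n).

    Edge-wise one-sample t on within-subject differences; edges with
    p < alpha_edge form clusters via shared nodes (positive and negative
    separately); summed t is the cluster statistic; the null is the max
    |cluster statistic| over per-subject sign flips.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 3 or diffs.shape[1] != diffs.shape[2]:
        raise ValueError("diffs must be (subjects, n, n)")
    n_sub, n = diffs.shape[:2]
    if n_sub < 2:
        raise ValueError("need >= 2 subjects")
    iu, ju = np.triu_indices(n, k=1)
    X = diffs[:, iu, ju]
    tcrit = stats.t.ppf(1 - alpha_edge / 2, df=n_sub - 1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tobs = _sign_flip_tmaps(X, np.ones((1, n_sub)))[0]
    obs_clusters = _edge_clusters(np.abs(tobs) > tcrit, tobs, iu, ju)

    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    tperm = _sign_flip_tmaps(X, signs)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        cl = _edge_clusters(np.abs(tperm[i]) > tcrit, tperm[i], iu, ju)
        if cl:
            null_max[i] = max(abs(s) for _, s in cl)

    clusters = [
        Cluster(tuple(int(m) for m in members), s,
                float((1 + np.sum(null_max >= abs(s))) / (n_perm + 1)))
        for members, s in obs_clusters
    ]
    clusters.sort(key=lambda c: -abs(c.stat))
    return ClusterResult(clusters, null_max, n_perm, alpha=alpha, shape=(iu.size,))
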