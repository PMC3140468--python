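"""Density-ordered clustering of cropped events (OPTICS + band cutting).

Events sharing a leader electrode are masked (samples less negative than a
threshold are zeroed), upsampled and peak-aligned, and compared under a
normalized distance that divides by the number of active stixels and by a
local amplitude scale. OPTICS turns the pairwise distances into a linear
ordering with reachability values; clusters are cut as low-reachability bands,
then de-duplicated across leader batches and split if composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .data import CroppedEvent, ElectrodeGeometry
from .modes import find_valley, is_multimodal

__all__ = [
    "BarycenterFeatures",
    "OpticsResult",
    "ClusterLabels",
    "barycenter",
    "mask_event",
    "event_distance",
    "pairwise_distances",
    "upsample_and_align",
    "optics_order",
    "cut_bands",
    "merge_duplicates",
    "split_composite",
]

UPSAMPLE = 5
DISJOINT_DISTANCE = 1e6  # sentinel for pairs with no shared active stixels


@dataclass(frozen=True)
class BarycenterFeatures:
    """Amplitude-weighted centroid of an event plus its (negated) peak depth."""

    x: float
    y: float
    neg_peak: float


@dataclass
class OpticsResult:
    ordering: np.ndarray       # permutation of event indices
    reachability: np.ndarray   # per ordering position; first element inf
    core_distance: np.ndarray  # per event


@dataclass
class ClusterLabels:
    labels: np.ndarray  # per-event integer, -1 = unassigned
    n_clusters: int
    merged_pairs: list[tuple[int, int]] = field(default_factory=list)


def barycenter(event: CroppedEvent, geometry: ElectrodeGeometry) -> BarycenterFeatures:
    """Weighted average of electrode positions, weights = |per-channel minima|."""
    minima = event.voltages.min(axis=1)
    weights = np.where(event.valid, np.abs(np.minimum(minima, 0.0)), 0.0)
    total = weights.sum()
    if total == 0:
        raise ValueError("all-zero event has no barycenter")
    pos = np.zeros((9, 2))
    pos[event.valid] = geometry.positions[event.channel_indices[event.valid]]
    xy = (weights[:, None] * pos).sum(axis=0) / total
    return BarycenterFeatures(x=float(xy[0]), y=float(xy[1]), neg_peak=float(minima.min()))


def mask_event(voltages: np.ndarray, mask_threshold_uv: float) -> tuple[np.ndarray, int]:
    """Zero samples less negative than the threshold; returns (masked, n_nonzero)."""
    if mask_threshold_uv >= 0:
        raise ValueError("mask threshold must be negative")
    masked = np.where(voltages <= mask_threshold_uv, voltages, 0.0)
    return masked, int(np.count_nonzero(masked))


def event_distance(
    x: np.ndarray,
    y: np.ndarray,
    amp_floor: float = 1.0,
    compensate: bool = True,
) -> float:
    """Normalized squared distance between two masked events.

    d = [sum over active stixels of (x_i - y_i)^2 / s_i] / N, where the active
    set is stixels nonzero in either input, N its size, and s_i a local
    amplitude scale max(|x_i|, |y_i|, amp_floor) that discounts the higher
    variance of high-voltage traces (s_i = 1 when ``compensate`` is off).
    Disjoint masks get a large sentinel so such pairs never become neighbors.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("events must have the same shape")
    active = (x != 0) | (y != 0)
    n = int(active.sum())
    if n == 0:
        return DISJOINT_DISTANCE
    dx = x[active] - y[active]
    if compensate:
        s = np.maximum(np.maximum(np.abs(x[active]), np.abs(y[active])), amp_floor)
    else:
        s = 1.0
    return float(np.sum(dx * dx / s) / n)


def pairwise_distances(
    events: np.ndarray, amp_floor: float = 1.0, compensate: bool = True
) -> np.ndarray:
    """Full matrix of ``event_distance`` over (n, ...) masked events."""
    flat = np.asarray(events, dtype=float).reshape(len(events), -1)
    n = len(flat)
    D = np.zeros((n, n))
    absflat = np.abs(flat)
    for i in range(n):
        xi, ai = flat[i], absflat[i]
        active = (xi != 0) | (flat != 0)  # (n, d)
        counts = active.sum(axis=1)
        diff = np.where(active, flat - xi, 0.0)
        if compensate:
            s = np.maximum(np.maximum(absflat, ai), amp_floor)
            num = np.sum(diff * diff / s, axis=1)
        else:
            num = np.sum(diff * diff, axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(counts > 0, num / np.maximum(counts, 1), DISJOINT_DISTANCE)
        D[i] = row
    np.fill_diagonal(D, 0.0)
    return D


def upsample_and_align(
    events: np.ndarray,
    factor: int = UPSAMPLE,
    keep_upsampled: bool = False,
    align_channel: int | None = None,
    max_shift_samples: float = 2.0,
) -> np.ndarray:
    """Cubic-spline upsample each event and center its absolute peak.

    Events are (n, channels, W). Each is upsampled x``factor`` in time,
    shifted so the deepest sample sits at the central position (edge values
    clamp the shift, nothing wraps around), then downsampled back unless
    ``keep_upsampled``. With ``align_channel`` the peak is searched on that
    row only — for leader-cropped events this keeps a deeper spike from a
    neighboring unit inside the crop from hijacking the alignment. Shifts are
    clamped to ``max_shift_samples``: cropped events are already centered to
    the sample, so only sub-sample corrections are legitimate.
    """
    events = np.asarray(events, dtype=float)
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    n, n_ch, W = events.shape
    if W < 4:
        raise ValueError("events shorter than 4 samples cannot be spline-interpolated")
    Wu = W * factor
    grid = np.arange(W)
    out = np.empty((n, n_ch, Wu))
    fine = np.arange(Wu) / factor
    max_shift = max_shift_samples * factor
    for i in range(n):
        spl = CubicSpline(grid, events[i], axis=1)
        up = spl(fine)
        if align_channel is None:
            ch = int(np.argmin(up.min(axis=1)))  # deepest channel overall
        else:
            ch = align_channel
        peak = int(np.argmin(up[ch]))
        shift = float(np.clip(peak - Wu // 2, -max_shift, max_shift))
        shifted_positions = np.clip(fine + shift / factor, 0, W - 1)
        out[i] = spl(shifted_positions)
    return out if keep_upsampled else out[:, :, ::factor]


def optics_order(
    events: np.ndarray | None,
    min_pts: int = 10,
    distances: np.ndarray | None = None,
    amp_floor: float = 1.0,
) -> OpticsResult:
    """OPTICS ordering under the masked event distance.

    Expansion starts at index 0; the next point is always the unprocessed one
    with the smallest reachability (ties by event index), so the ordering is
    deterministic. ``distances`` may supply a precomputed matrix directly.
    """
    if distances is None:
        if events is None:
            raise ValueError("provide events or a distance matrix")
        distances = pairwise_distances(events, amp_floor=amp_floor)
    D = np.asarray(distances, dtype=float)
    n = len(D)
    if n < min_pts:
        raise ValueError(f"need at least min_pts={min_pts} events, got {n}")
    # core distance = distance to the min_pts-th nearest point (self included)
    core = np.partition(D, min_pts - 1, axis=1)[:, min_pts - 1]

    reach = np.full(n, np.inf)
    processed = np.zeros(n, dtype=bool)
    ordering = np.empty(n, dtype=int)
    reach_out = np.empty(n)
    for pos in range(n):
        candidates = np.flatnonzero(~processed)
        i = candidates[np.argmin(reach[candidates])]  # argmin takes lowest index on ties
        ordering[pos] = i
        reach_out[pos] = reach[i]
        processed[i] = True
        new = np.maximum(core[i], D[i, candidates])
        np.minimum.at(reach, candidates, new)
    reach_out[0] = np.inf
    return OpticsResult(ordering=ordering, reachability=reach_out, core_distance=core)


def cut_bands(
    result: OpticsResult,
    band_spec: list[tuple[int, int]] | None = None,
    min_pts: int = 10,
    xi: float = 3.0,
) -> ClusterLabels:
    """Cut the OPTICS ordering into cluster bands.

    With ``band_spec``, each (start, end) index range in the ordering (end
    exclusive) becomes one cluster; ranges must not overlap. In auto mode the
    ordering is split wherever reachability jumps to ``xi`` x the median
    reachability — each split position starts a new band — and bands shorter
    than ``min_pts`` stay unassigned.
    """
    n = len(result.ordering)
    labels = np.full(n, -1, dtype=int)
    if band_spec is not None:
        used = np.zeros(n, dtype=bool)
        for cid, (start, end) in enumerate(band_spec):
            if used[start:end].any():
                raise ValueError("overlapping bands")
            used[start:end] = True
            labels[result.ordering[start:end]] = cid
        return ClusterLabels(labels=labels, n_clusters=len(band_spec))

    finite = result.reachability[np.isfinite(result.reachability)]
    if finite.size == 0:
        # every event unreachable from every other: all noise
        return ClusterLabels(labels=labels, n_clusters=0)
    threshold = xi * np.median(finite)
    is_split = ~np.isfinite(result.reachability) | (result.reachability >= threshold)
    is_split[0] = True
    starts = list(np.flatnonzero(is_split)) + [n]
    cid = 0
    for s, e in zip(starts[:-1], starts[1:]):
        if e - s >= min_pts:
            labels[result.ordering[s:e]] = cid
            cid += 1
    return ClusterLabels(labels=labels, n_clusters=cid)


def _normalized_xcorr(a: np.ndarray, b: np.ndarray, max_shift: int) -> float:
    """Peak normalized cross-correlation of two multichannel waveforms."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    W = a.shape[1]
    best = -np.inf
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            c = np.sum(a[:, s:] * b[:, : W - s])
        else:
            c = np.sum(a[:, :s] * b[:, -s:])
        best = max(best, c / (na * nb))
    return float(best)


def duplicate_xcorr(a: np.ndarray, b: np.ndarray, max_shift: int | None = None) -> float:
    """Cross-correlation of two embedded waveforms restricted to common support.

    A unit heard on two neighboring leader electrodes produces two crops
    whose 3x3 windows only partially overlap; correlating over the full
    array punishes the disjoint channels and hides the duplicate. The
    comparison is therefore restricted to channels where both waveforms
    carry signal — but only when both deepest channels lie in that common
    set, so two distinct units that merely brush each other's tails are
    never compared peak-less.
    """
    act_a = np.abs(a).max(axis=1) > 0
    act_b = np.abs(b).max(axis=1) > 0
    common = act_a & act_b
    if not common.any():
        return 0.0
    peak_a = int(np.argmin(a.min(axis=1)))
    peak_b = int(np.argmin(b.min(axis=1)))
    if not (common[peak_a] and common[peak_b]):
        return 0.0
    ms = max_shift if max_shift is not None else a.shape[1] // 2
    return _normalized_xcorr(a[common], b[common], ms)


def merge_duplicates(
    medians: dict[int, np.ndarray],
    xcorr_threshold: float = 0.95,
    max_shift: int | None = None,
) -> tuple[dict[int, int], list[tuple[int, int]]]:
    """Merge clusters whose median waveforms are near-duplicates.

    ``medians`` maps cluster id -> (channels, W) median embedded in a common
    channel space. Pairs with peak normalized common-support
    cross-correlation over time shifts >= the threshold merge transitively
    (union-find); returns the cluster relabeling map and the merged pairs.
    """
    ids = sorted(medians)
    parent = {c: c for c in ids}

    def find(c: int) -> int:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    merged: list[tuple[int, int]] = []
    for idx, ci in enumerate(ids):
        for cj in ids[idx + 1 :]:
            a, b = medians[ci], medians[cj]
            if duplicate_xcorr(a, b, max_shift) >= xcorr_threshold:
                ra, rb = find(ci), find(cj)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
                    merged.append((ci, cj))
    roots = sorted({find(c) for c in ids})
    relabel = {root: k for k, root in enumerate(roots)}
    return {c: relabel[find(c)] for c in ids}, merged


def split_composite(
    events: np.ndarray,
    min_pts: int = 10,
    n_components: int = 3,
    _depth: int = 0,
) -> list[np.ndarray]:
    """Split a composite cluster at multimodal principal-component projections.

    Events are projected onto the first ``n_components`` principal components;
    if any projection is multimodal the cluster splits at the deepest valley
    of that projection's histogram, recursing once. Unimodal clusters return
    unchanged as a single index array.
    """
    from sklearn.decomposition import PCA

    from .modes import fit_two_modes

    events = np.asarray(events, dtype=float)
    n = len(events)
    idx = np.arange(n)
    if n < 2 * min_pts:
        return [idx]
    flat = events.reshape(n, -1)
    k = min(n_components, n - 1, flat.shape[1])
    proj = PCA(n_components=k, random_state=0).fit_transform(flat)
    for comp in range(k):
        scores = proj[:, comp]
        fit = fit_two_modes(scores)
        if fit is not None and fit["ashman_d"] > 2.0 and fit["weights"].min() > 0.03:
            # cut at the valley between the two fitted modes; an outlier-driven
            # fit leaves one side below min_pts and the split is rejected
            valley = find_valley(scores, between=tuple(fit["means"]))
            left, right = idx[scores <= valley], idx[scores > valley]
            if min(len(left), len(right)) < min_pts or _depth >= 1:
                return [idx]
            out = []
            for part in (left, right):
                for sub in split_composite(events[part], min_pts, n_components, _depth + 1):
                    out.append(part[sub])
            return out
    return [idx]
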