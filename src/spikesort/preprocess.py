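"""Step 1 of the pipeline: filtering, clip extraction, whitening, segmentation.

Raw recordings are zero-phase FIR high-pass filtered, cut into noise clips and
spike clips by a two-threshold rule, spatially whitened with the inverse
square root of the noise spatial covariance, and spike clips are segmented
into spatio-temporally connected cropped events classified by leader channel.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from .data import Clip, CroppedEvent, ElectrodeGeometry, Recording

__all__ = [
    "highpass_filter",
    "extract_clips",
    "estimate_spatial_covariance",
    "spatial_whiten",
    "segment_events",
    "pooled_noise_sd",
]

DEFAULT_CLIP_SAMPLES = 32


def highpass_filter(recording: Recording, cutoff_hz: float = 200.0) -> Recording:
    """Zero-phase FIR high-pass, removing baseline drift below ``cutoff_hz``.

    A windowed-sinc (Hamming) filter applied forward-backward per channel; the
    order is chosen so a single pass gives >= 20 dB attenuation at half the
    cutoff (>= 40 dB after the two passes).
    """
    nyquist = recording.sample_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    if recording.filtered:
        raise ValueError("recording is already high-pass filtered")
    # Hamming transition width ~= 3.3 * fs / numtaps; a transition band equal
    # to the cutoff places the stopband edge at 0.5 * cutoff with ~53 dB.
    numtaps = int(np.ceil(3.3 * recording.sample_rate / cutoff_hz))
    numtaps += (numtaps + 1) % 2  # odd length -> type I, exact zero at DC
    taps = signal.firwin(numtaps, cutoff_hz, pass_zero=False, fs=recording.sample_rate)
    out = signal.filtfilt(taps, [1.0], recording.voltages, axis=1)
    return recording.with_voltages(out, filtered=True)


def pooled_noise_sd(recording: Recording) -> float:
    """Robust pooled noise standard deviation (median absolute deviation)."""
    v = recording.voltages
    return float(np.median(np.abs(v - np.median(v))) / 0.6744897501960817)


def extract_clips(
    recording: Recording,
    spike_threshold_uv: float,
    noise_exclusion_uv: float,
    clip_len: int = DEFAULT_CLIP_SAMPLES,
) -> list[Clip]:
    """Cut the recording into spike clips and noise clips.

    Both thresholds are negative-going with ``spike_threshold_uv`` the deeper
    one. Spike clips are ``clip_len`` windows centered on threshold crossings
    (crossings within one window merge into a single clip). Noise clips are
    non-overlapping ``clip_len`` windows in which no channel ever goes below
    ``noise_exclusion_uv``. Windows whose deepest sample falls between the two
    thresholds are discarded: too noisy for noise, too shallow for spikes.
    """
    if not (spike_threshold_uv < noise_exclusion_uv < 0):
        raise ValueError("need spike_threshold < noise_exclusion < 0 (negative-going)")
    n = recording.n_samples
    if clip_len > n:
        raise ValueError(f"clip_len {clip_len} exceeds recording length {n}")
    v = recording.voltages
    depth = v.min(axis=0)  # deepest (most negative) value across channels per sample

    clips: list[Clip] = []
    spike_samples = np.flatnonzero(depth < spike_threshold_uv)
    covered = np.zeros(n, dtype=bool)
    i = 0
    while i < len(spike_samples):
        # merge all crossings within one clip_len window into one clip
        j = i
        while j + 1 < len(spike_samples) and spike_samples[j + 1] - spike_samples[i] < clip_len:
            j += 1
        run = spike_samples[i : j + 1]
        center = run[np.argmin(depth[run])]  # center the clip on the deepest crossing
        start = int(np.clip(center - clip_len // 2, 0, n - clip_len))
        clips.append(Clip(v[:, start : start + clip_len].copy(), start, "spike"))
        covered[max(start - clip_len + 1, 0) : start + clip_len] = True
        i = j + 1

    for start in range(0, n - clip_len + 1, clip_len):
        window = depth[start : start + clip_len]
        if covered[start : start + clip_len].any():
            continue
        if window.min() >= noise_exclusion_uv:
            clips.append(Clip(v[:, start : start + clip_len].copy(), start, "noise"))
    return clips


def estimate_spatial_covariance(noise_clips: list[Clip] | np.ndarray, min_clips: int = 100) -> np.ndarray:
    """Zero-lag channel covariance pooled over noise clips (symmetric PSD)."""
    if isinstance(noise_clips, np.ndarray):
        stacks = noise_clips
    else:
        stacks = np.stack([c.voltages for c in noise_clips]) if noise_clips else np.empty((0, 0, 0))
    if stacks.shape[0] < min_clips:
        raise ValueError(f"need at least {min_clips} noise clips, got {stacks.shape[0]}")
    n_clips, n_ch, W = stacks.shape
    x = np.transpose(stacks, (1, 0, 2)).reshape(n_ch, -1)
    x = x - x.mean(axis=1, keepdims=True)
    cov = x @ x.T / x.shape[1]
    return (cov + cov.T) / 2.0


def spatial_whiten(
    recording: Recording,
    spatial_cov: np.ndarray,
    regularization: float = 1e-6,
) -> Recording:
    """Apply the symmetric inverse square root of the spatial noise covariance.

    The transform is rescaled so that the pooled per-channel noise standard
    deviation is preserved — thresholds keep familiar µV-like units while
    off-diagonal spatial noise correlations are removed.
    """
    cov = np.asarray(spatial_cov, dtype=float)
    if cov.shape != (recording.n_channels, recording.n_channels):
        raise ValueError("spatial covariance shape does not match channel count")
    cov = cov + regularization * np.mean(np.diag(cov)) * np.eye(len(cov))
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals <= 0):
        raise np.linalg.LinAlgError("spatial covariance is singular even after regularization")
    inv_sqrt = (evecs * (1.0 / np.sqrt(evals))) @ evecs.T
    scale = float(np.sqrt(np.mean(np.diag(cov))))  # keep pooled noise sd
    out = scale * (inv_sqrt @ recording.voltages)
    return recording.with_voltages(out, whitened=True)


def segment_events(
    spike_clip: Clip,
    threshold_uv: float,
    geometry: ElectrodeGeometry,
    W: int = DEFAULT_CLIP_SAMPLES,
) -> list[CroppedEvent]:
    """Split a spike clip into connected components and crop each one.

    Stixels (channel, sample) below ``threshold_uv`` are grouped into
    connected components, where two stixels connect if they are nearest
    neighbors on the electrode grid (4-connectivity) or adjacent in time.
    Each component yields one cropped event: a W-sample, 3x3-channel region
    centered on the component's absolute peak, zero-padded at array edges.
    """
    v = spike_clip.voltages
    n_ch, T = v.shape
    cube = v.reshape(geometry.rows, geometry.cols, T)
    below = cube < threshold_uv
    if not below.any():
        return []
    # face-connectivity in (row, col, time) = grid 4-neighbors x +-1 sample
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n_comp = ndimage.label(below, structure=structure)

    events: list[CroppedEvent] = []
    for comp in range(1, n_comp + 1):
        rows, cols, times = np.nonzero(labels == comp)
        vals = cube[rows, cols, times]
        # peak = deepest stixel; ties: earliest time, then lowest channel index
        channels = rows * geometry.cols + cols
        order = np.lexsort((channels, times, vals))
        k = order[0]
        leader = int(channels[k])
        peak_t = int(times[k])
        nbr_idx, valid = geometry.neighborhood(leader)
        crop = np.zeros((9, W))
        t0 = peak_t - W // 2
        src_lo, src_hi = max(t0, 0), min(t0 + W, T)
        dst_lo = src_lo - t0
        for slot, ch in enumerate(nbr_idx):
            if ch >= 0:
                crop[slot, dst_lo : dst_lo + (src_hi - src_lo)] = v[ch, src_lo:src_hi]
        events.append(
            CroppedEvent(
                voltages=crop,
                leader_channel=leader,
                peak_sample=spike_clip.start_sample + peak_t,
                channel_indices=nbr_idx,
                valid=valid,
            )
        )
    events.sort(key=lambda e: (e.peak_sample, e.leader_channel))
    return events
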