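"""Consensus templates, amplitude priors, firing-rate priors, reading frames.

A template is the robust consensus waveform of one cluster, stored on the
x5-upsampled time grid of its 3x3 electrode neighborhood, together with a
Gaussian prior on the per-spike amplitude scale factor (mu_c, sigma_c) and a
Poisson firing-rate prior r_c. The five "reading frames" are the downsampled
versions of the template at each sub-sample shift; they let the fitter place
spikes at 1/5-sample resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "Template",
    "build_template",
    "amplitude_prior",
    "firing_rate_prior",
    "make_phases",
    "save_template_bank",
    "load_template_bank",
]

UPSAMPLE = 5
MIN_EVENTS = 20


@dataclass
class Template:
    """Per-unit consensus waveform with amplitude and rate priors."""

    waveform: np.ndarray              # (9, W * UPSAMPLE), peak at center
    leader_channel: int
    channel_indices: np.ndarray       # absolute channel of each 3x3 slot (-1 off-array)
    valid: np.ndarray
    phases: list[np.ndarray] = field(default_factory=list)  # 5 x (9, W)
    amp_mean: float = 1.0             # mu_c
    amp_sd: float = 0.1               # sigma_c
    rate_hz: float = 1.0              # r_c
    n_events: int = 0
    unit_id: int = -1

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        self.channel_indices = np.asarray(self.channel_indices, dtype=int)
        if self.amp_sd < 0:
            raise ValueError("amplitude prior sd must be non-negative")
        if self.rate_hz < 0:
            raise ValueError("firing rate must be non-negative")

    @property
    def n_samples(self) -> int:
        """Template length in (downsampled) recording samples."""
        return self.waveform.shape[1] // UPSAMPLE

    @property
    def peak_amplitude(self) -> float:
        return float(-self.waveform.min())


def make_phases(waveform: np.ndarray, factor: int = UPSAMPLE) -> list[np.ndarray]:
    """Split an upsampled waveform into its ``factor`` sub-sample reading frames.

    Phase k keeps upsampled samples {k, k+factor, k+2 factor, ...}; fitting
    phase k at integer sample m represents a spike at time m - k/factor samples.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.shape[-1] % factor != 0:
        raise ValueError(
            f"upsampled length {waveform.shape[-1]} not divisible by factor {factor}"
        )
    return [waveform[..., k::factor] for k in range(factor)]


def _xcorr_align(event: np.ndarray, draft: np.ndarray, max_shift: int) -> tuple[int, float]:
    """Best integer shift (upsampled steps) and its normalized cross-correlation."""
    flat_d = draft.ravel()
    nd = np.linalg.norm(flat_d)
    best_s, best_c = 0, -np.inf
    W = event.shape[1]
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            a, b = event[:, s:], draft[:, : W - s]
        else:
            a, b = event[:, :s], draft[:, -s:]
        na = np.linalg.norm(a)
        if na == 0 or nd == 0:
            continue
        c = np.sum(a * b) / (na * np.linalg.norm(b))
        if c > best_c:
            best_c, best_s = c, s
    return best_s, best_c


def _shift(event: np.ndarray, s: int) -> np.ndarray:
    """Shift left by s samples, zero-filling the exposed edge."""
    out = np.zeros_like(event)
    W = event.shape[1]
    if s >= 0:
        out[:, : W - s] = event[:, s:]
    else:
        out[:, -s:] = event[:, :s]
    return out


def build_template(
    events: np.ndarray,
    min_events: int = MIN_EVENTS,
    align_window_s: float = 1e-3,
    dt: float = 1e-4,
    outlier_xcorr: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Median -> align -> median consensus over upsampled, aligned events.

    ``events`` is (n, 9, W*UPSAMPLE). A draft template is the pointwise median
    over events; each event is then aligned to the draft by maximizing
    normalized cross-correlation over time shifts (up to +-``align_window_s``),
    and the final template is the pointwise median of the aligned events —
    medians suppress outliers such as overlapping spikes from other units.
    Events whose alignment correlation stays below ``outlier_xcorr`` are
    excluded; returns (waveform, kept_mask).
    """
    events = np.asarray(events, dtype=float)
    if events.ndim != 3:
        raise ValueError("events must be (n_events, 9, W*UPSAMPLE)")
    n = events.shape[0]
    if n < min_events:
        raise ValueError(f"cluster has {n} events; need >= {min_events} to build a template")
    max_shift = max(1, int(round(align_window_s / dt * UPSAMPLE)))

    draft = np.median(events, axis=0)
    kept = np.ones(n, dtype=bool)
    aligned = np.empty_like(events)
    for i, ev in enumerate(events):
        s, c = _xcorr_align(ev, draft, max_shift)
        if c < outlier_xcorr:
            kept[i] = False
            continue
        aligned[i] = _shift(ev, s)
    if kept.sum() < min_events:
        warnings.warn("too few events survive outlier rejection; cluster dropped", stacklevel=2)
        raise ValueError("cluster dropped: insufficient well-aligned events")
    wave = np.median(aligned[kept], axis=0)
    # re-center the absolute peak at the central upsampled position
    Wu = wave.shape[1]
    deepest_ch = int(np.argmin(wave.min(axis=1)))
    peak = int(np.argmin(wave[deepest_ch]))
    wave = _shift(wave, peak - Wu // 2)
    return wave, kept


def amplitude_prior(events: np.ndarray, waveform: np.ndarray) -> tuple[float, float]:
    """Mean and sd of the per-event least-squares scale factor.

    For each aligned event V, lambda-hat = <V, T> / <T, T> with the ordinary
    inner product — the rescaling that best overlaps the event with its
    template.
    """
    events = np.asarray(events, dtype=float)
    flat_t = np.asarray(waveform, dtype=float).ravel()
    tt = flat_t @ flat_t
    if tt == 0:
        raise ValueError("degenerate template with zero norm")
    lams = events.reshape(events.shape[0], -1) @ flat_t / tt
    sd = float(np.std(lams, ddof=1)) if len(lams) > 1 else 0.0
    return float(np.mean(lams)), sd


def firing_rate_prior(n_events: int, clustered_duration_s: float) -> float:
    """Events per second over the clustered subset; 0 events flags the unit."""
    if clustered_duration_s <= 0:
        raise ValueError("duration must be positive")
    if n_events == 0:
        warnings.warn("unit with zero events: rate prior unusable", stacklevel=2)
    return n_events / clustered_duration_s


# ---------------------------------------------------------------------------
# Template bank I/O

def save_template_bank(templates: list[Template], path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("templates")
        for t in templates:
            g = grp.create_group(str(t.unit_id))
            g.create_dataset("waveform", data=t.waveform)
            g.create_dataset("phases", data=np.stack(t.phases))
            g.create_dataset("channel_indices", data=t.channel_indices)
            g.create_dataset("valid", data=t.valid.astype(bool))
            g.attrs["mu"] = t.amp_mean
            g.attrs["sigma"] = t.amp_sd
            g.attrs["rate_hz"] = t.rate_hz
            g.attrs["leader_channel"] = t.leader_channel
            g.attrs["n_events"] = t.n_events


def load_template_bank(path) -> list[Template]:
    templates = []
    with h5py.File(path, "r") as f:
        for key in sorted(f["templates"], key=int):
            g = f["templates"][key]
            templates.append(
                Template(
                    waveform=g["waveform"][()],
                    leader_channel=int(g.attrs["leader_channel"]),
                    channel_indices=g["channel_indices"][()],
                    valid=g["valid"][()].astype(bool),
                    phases=list(g["phases"][()]),
                    amp_mean=float(g.attrs["mu"]),
                    amp_sd=float(g.attrs["sigma"]),
                    rate_hz=float(g.attrs["rate_hz"]),
                    n_events=int(g.attrs["n_events"]),
                    unit_id=int(key),
                )
            )
    return templates
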