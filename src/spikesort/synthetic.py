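"""Ground-truthed synthetic MEA recordings and sorting scorecards.

The generator emulates the data model the sorter assumes: a rectangular
electrode grid (default 5x6 = 30 channels at 10 kHz), biphasic spike
waveforms localized to a 3x3 electrode neighborhood with exponential spatial
falloff, per-spike Gaussian amplitude jitter (10% sd), and zero-mean Gaussian
noise that is AR(1) in time and exponentially correlated in space. Every
planted spike is logged, so sorter output can be scored for false negatives
and false positives at a configurable time tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ElectrodeGeometry, Recording
from .templates import Template, make_phases

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_templates",
    "simulate_noise",
    "simulate_recording",
    "score_sorting",
]

UPSAMPLE = 5


@dataclass
class SimConfig:
    """Study conditions for a synthetic recording.

    Amplitudes are in units of the noise standard deviation; the 10% amplitude
    jitter and the noise correlation scales mirror the recordings the sorter
    targets (tau ~ a fraction of a ms, spatial correlation below one pitch).
    """

    rows: int = 5
    cols: int = 6
    pitch_um: float = 100.0
    sample_rate_hz: float = 10_000.0
    n_units: int = 10
    peak_min_sigma: float = 5.0
    peak_max_sigma: float = 10.0
    amp_jitter: float = 0.10
    noise_sigma: float = 10.0          # µV-like units
    noise_tau_s: float = 0.3e-3
    noise_spatial_um: float = 40.0     # exponential spatial correlation length
    rate_hz: float = 5.0
    refractory_s: float = 2e-3
    duration_s: float = 60.0
    clip_samples: int = 32
    min_separation_sigma: float = 2.5  # min masked-metric template distance / noise sd
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pitch_um", "sample_rate_hz", "peak_min_sigma", "peak_max_sigma",
            "noise_sigma", "rate_hz", "duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")

    @property
    def geometry(self) -> ElectrodeGeometry:
        return ElectrodeGeometry(self.rows, self.cols, self.pitch_um)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_hz


@dataclass
class GroundTruth:
    """Planted spikes plus the true per-unit generative parameters."""

    spikes: pd.DataFrame  # columns: unit_id, time_s, lam
    templates: list[Template]
    amp_mean: float = 1.0
    amp_sd: float = 0.10
    rates_hz: np.ndarray = field(default_factory=lambda: np.empty(0))


def _biphasic_kernel(t_ms: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Negative lobe (~0.5 ms wide) followed by a slower positive rebound."""
    neg_w = 0.22 * rng.uniform(0.8, 1.25)
    reb_w = 0.45 * rng.uniform(0.8, 1.25)
    reb_delay = 0.9 * rng.uniform(0.8, 1.2)
    reb_amp = rng.uniform(0.2, 0.45)
    return -np.exp(-0.5 * (t_ms / neg_w) ** 2) + reb_amp * np.exp(
        -0.5 * ((t_ms - reb_delay) / reb_w) ** 2
    )


def _template_xcorr(a: Template, b: Template, n_channels: int) -> float:
    """Peak normalized cross-correlation of two templates over time shifts."""
    Wu = a.waveform.shape[1]
    A = np.zeros((n_channels, Wu))
    B = np.zeros((n_channels, Wu))
    for slot, ch in enumerate(a.channel_indices):
        if ch >= 0:
            A[ch] = a.waveform[slot]
    for slot, ch in enumerate(b.channel_indices):
        if ch >= 0:
            B[ch] = b.waveform[slot]
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0:
        return 0.0
    best = 0.0
    for shift in range(-Wu // 2, Wu // 2 + 1, UPSAMPLE):
        if shift >= 0:
            c = np.sum(A[:, shift:] * B[:, : Wu - shift])
        else:
            c = np.sum(A[:, :shift] * B[:, -shift:])
        best = max(best, abs(c) / (na * nb))
    return best


def make_templates(config: SimConfig, rng: np.random.Generator, max_tries: int = 200) -> list[Template]:
    """Draw spatially localized biphasic templates with distinct waveforms.

    Each unit sits near a random interior electrode; its amplitude falls off
    exponentially with distance from a continuous soma position (length scale
    <= one pitch). Pairs of accepted templates have normalized peak
    cross-correlation < 0.95, enforced by rejection sampling.
    """
    if config.n_units < 1:
        raise ValueError("n_units must be >= 1")
    geom = config.geometry
    W = config.clip_samples
    Wu = W * UPSAMPLE
    dt_ms = 1000.0 / config.sample_rate_hz
    t_ms = (np.arange(Wu) - Wu // 2) * dt_ms / UPSAMPLE
    positions = geom.positions

    interior = [
        ch for ch in range(geom.n_electrodes)
        if 0 < geom.grid_position(ch)[0] < geom.rows - 1
        and 0 < geom.grid_position(ch)[1] < geom.cols - 1
    ]
    if not interior:
        interior = list(range(geom.n_electrodes))

    templates: list[Template] = []
    tries = 0
    while len(templates) < config.n_units:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {config.n_units} distinct templates in {max_tries} tries"
            )
        leader = int(rng.choice(interior))
        soma = positions[leader] + rng.uniform(-0.4, 0.4, size=2) * config.pitch_um
        ell = rng.uniform(0.4, 1.0) * config.pitch_um
        kernel = _biphasic_kernel(t_ms, rng)
        nbr_idx, valid = geom.neighborhood(leader)
        wave = np.zeros((9, Wu))
        for slot, ch in enumerate(nbr_idx):
            if ch >= 0:
                d = np.linalg.norm(positions[ch] - soma)
                wave[slot] = kernel * np.exp(-d / ell)
        peak_sigma = rng.uniform(config.peak_min_sigma, config.peak_max_sigma)
        wave *= peak_sigma * config.noise_sigma / np.abs(wave.min())
        # peak must sit on the leader: re-anchor leader as the deepest channel
        deepest = int(np.argmin(wave.min(axis=1)))
        if nbr_idx[deepest] != leader:
            continue
        # center the absolute peak at the central upsampled position
        shift = Wu // 2 - int(np.argmin(wave[deepest]))
        wave = np.roll(wave, shift, axis=1)
        cand = Template(
            waveform=wave,
            leader_channel=leader,
            channel_indices=nbr_idx,
            valid=valid,
            phases=make_phases(wave, UPSAMPLE),
            amp_mean=1.0,
            amp_sd=config.amp_jitter,
            rate_hz=config.rate_hz,
            n_events=0,
            unit_id=len(templates),
        )
        if any(_template_xcorr(cand, t, geom.n_electrodes) >= 0.95 for t in templates):
            continue
        if any(
            not _separated(cand, t, geom.n_electrodes, config)
            for t in templates
        ):
            continue
        templates.append(cand)
    return templates


def _separated(a: Template, b: Template, n_channels: int, config: SimConfig) -> bool:
    """Units are well separated when they are statistically distinguishable.

    Two rules, both on shared support only (disjoint units are separated by
    geography alone): the masked-metric waveform distance must clear the
    noise floor, and highly correlated waveforms (xcorr >= 0.8) must differ
    in amplitude by at least 1.5x — a same-site pair matching in both shape
    and scale cannot be told apart spike-by-spike by any method.
    """
    from .clustering import event_distance

    sigma = config.noise_sigma

    def emb(t: Template) -> np.ndarray:
        out = np.zeros((n_channels, t.phases[0].shape[1]))
        for slot, ch in enumerate(t.channel_indices):
            if ch >= 0:
                out[ch] = t.phases[0][slot]
        return np.where(out <= -2 * sigma, out, 0.0)

    am, bm = emb(a), emb(b)
    if not ((am != 0) & (bm != 0)).any():
        return True
    if event_distance(am, bm, amp_floor=sigma) < config.min_separation_sigma * sigma:
        return False
    if _template_xcorr(a, b, n_channels) >= 0.8:
        ratio = max(a.peak_amplitude, b.peak_amplitude) / min(
            a.peak_amplitude, b.peak_amplitude
        )
        return ratio >= 1.5
    return True


def simulate_noise(
    config: SimConfig,
    duration_s: float | None = None,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Gaussian noise, AR(1) in time with spatial exponential correlation.

    Per channel: x_t = a x_{t-1} + sigma sqrt(1-a^2) eps_t with
    a = exp(-dt/tau); channels are then mixed by the symmetric square root of
    the exponential spatial correlation matrix, which leaves each channel's
    variance at sigma^2 while installing the configured falloff.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    duration = config.duration_s if duration_s is None else duration_s
    geom = config.geometry
    n = int(round(duration * config.sample_rate_hz))
    a = float(np.exp(-config.dt / config.noise_tau_s)) if config.noise_tau_s > 0 else 0.0

    eps = rng.standard_normal((geom.n_electrodes, n))
    if a > 0:
        from scipy.signal import lfilter

        x = lfilter([np.sqrt(1.0 - a**2)], [1.0, -a], eps, axis=1)
        # warm-started from stationarity: scale initial transient away
        x[:, 0] = eps[:, 0]
    else:
        x = eps
    x *= config.noise_sigma

    if config.noise_spatial_um > 0:
        pos = geom.positions
        dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        corr = np.exp(-dist / config.noise_spatial_um)
        evals, evecs = np.linalg.eigh(corr)
        mix = (evecs * np.sqrt(np.clip(evals, 0, None))) @ evecs.T
        x = mix @ x
    return Recording(x, config.dt, geom, whitened=False, filtered=True)


def _draw_train(
    rate_hz: float, duration_s: float, refractory_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson train with a dead time: exponential gaps + refractory offset."""
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_hz) + refractory_s
        if t >= duration_s:
            break
        times.append(t)
    return np.asarray(times)


def simulate_recording(
    config: SimConfig,
    templates: list[Template] | None = None,
    mode: str = "train",
    overlap_k: int = 3,
    n_clips: int = 100,
    noiseless: bool = False,
) -> tuple[Recording, GroundTruth]:
    """Plant spikes in simulated noise; return the recording and ground truth.

    ``mode="train"``: per-unit Poisson trains at ``config.rate_hz`` with a
    refractory dead time; amplitudes ~ N(1, amp_jitter^2) truncated at 0.
    ``mode="clip"``: a sequence of ``n_clips`` windows, each containing exactly
    ``overlap_k`` distinct units planted at random times with an edge margin —
    the planted-spike validation design.
    """
    # independent sub-streams so the spike realization is identical with and
    # without noise, and templates do not perturb the noise draw
    tpl_rng = np.random.default_rng([config.seed, 1])
    noise_rng = np.random.default_rng([config.seed, 2])
    rng = np.random.default_rng([config.seed, 3])
    if templates is None:
        templates = make_templates(config, tpl_rng)
    geom = config.geometry
    W = config.clip_samples
    margin = W // 2 + 2

    if mode == "clip":
        if overlap_k > len(templates):
            raise ValueError("overlap_k exceeds number of templates")
        clip_span = 3 * W
        n = n_clips * clip_span
        duration = n * config.dt
    elif mode == "train":
        duration = config.duration_s
        n = int(round(duration * config.sample_rate_hz))
        max_spikes = int(config.rate_hz * duration * len(templates) * 10) + 1000
        if config.rate_hz * duration > max_spikes:
            raise ValueError("rate x duration overflow")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if noiseless:
        rec = Recording(
            np.zeros((geom.n_electrodes, n)), config.dt, geom, whitened=True, filtered=True
        )
    else:
        rec = simulate_noise(config, duration, noise_rng)
    v = rec.voltages

    rows = []
    if mode == "clip":
        for ci in range(n_clips):
            base = ci * clip_span
            units = rng.choice(len(templates), size=overlap_k, replace=False)
            for u in units:
                # spike lands inside the central W window, clear of clip edges
                t_int = base + clip_span // 2 + int(rng.integers(-(W // 2 - margin // 2), W // 2 - margin // 2 + 1))
                phase = int(rng.integers(0, UPSAMPLE))
                lam = max(rng.normal(1.0, config.amp_jitter), 1e-6)
                _add_spike(v, templates[u], t_int, phase, lam)
                rows.append((int(u), (t_int - phase / UPSAMPLE) * config.dt, lam))
    else:
        rates = np.full(len(templates), config.rate_hz, dtype=float)
        for u, tpl in enumerate(templates):
            for t in _draw_train(rates[u], duration, config.refractory_s, rng):
                t_fine = int(round(t * config.sample_rate_hz * UPSAMPLE))
                t_int, rem = divmod(t_fine, UPSAMPLE)
                phase = rem
                if phase:
                    t_int += 1  # spike at t_int - phase/5 samples
                    phase = UPSAMPLE - rem
                if not (margin <= t_int < n - margin):
                    continue
                lam = max(rng.normal(1.0, config.amp_jitter), 1e-6)
                _add_spike(v, tpl, t_int, phase, lam)
                rows.append((u, (t_int - phase / UPSAMPLE) * config.dt, lam))

    spikes = pd.DataFrame(rows, columns=["unit_id", "time_s", "lam"]).sort_values(
        "time_s", kind="stable", ignore_index=True
    )
    truth = GroundTruth(
        spikes=spikes,
        templates=templates,
        amp_sd=config.amp_jitter,
        rates_hz=np.full(len(templates), config.rate_hz),
    )
    return rec, truth


def _add_spike(v: np.ndarray, tpl: Template, t_int: int, phase: int, lam: float) -> None:
    """Add ``lam`` x (phase-k reading frame of ``tpl``) peaking at sample t_int."""
    wave = tpl.phases[phase]  # (9, W)
    W = wave.shape[1]
    t0 = t_int - W // 2
    lo, hi = max(t0, 0), min(t0 + W, v.shape[1])
    for slot, ch in enumerate(tpl.channel_indices):
        if ch >= 0:
            v[ch, lo:hi] += lam * wave[slot, lo - t0 : hi - t0]


def score_sorting(
    truth: GroundTruth,
    assignments: pd.DataFrame,
    time_tol_s: float = 0.5e-3,
    unit_map: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Per-unit false-negative / false-positive rates by one-to-one matching.

    ``assignments`` needs columns ``unit_id`` and ``time_s`` (sorter output);
    ``unit_map`` maps fitted unit ids to true unit ids (identity by default).
    Within each true unit, fitted and true spikes are matched greedily by
    |Δt| <= time_tol_s, each spike used at most once. A false negative is an
    unmatched true spike; a false positive an unmatched fitted spike.
    """
    fitted = assignments.copy()
    if unit_map is not None:
        fitted = fitted[fitted["unit_id"].isin(unit_map)].copy()
        fitted["unit_id"] = fitted["unit_id"].map(unit_map)

    out = []
    unit_ids = sorted(set(truth.spikes["unit_id"]) | set(fitted["unit_id"]))
    for u in unit_ids:
        t_true = np.sort(truth.spikes.loc[truth.spikes["unit_id"] == u, "time_s"].to_numpy())
        rows_f = fitted.loc[fitted["unit_id"] == u]
        t_fit = np.sort(rows_f["time_s"].to_numpy())
        lam_fit = rows_f.sort_values("time_s")["lam"].to_numpy() if "lam" in rows_f else None

        pairs = [
            (abs(tt - tf), i, j)
            for i, tt in enumerate(t_true)
            for j, tf in enumerate(t_fit)
            if abs(tt - tf) <= time_tol_s
        ]
        pairs.sort()
        used_t: set[int] = set()
        used_f: set[int] = set()
        amp_errs = []
        for d, i, j in pairs:
            if i in used_t or j in used_f:
                continue
            used_t.add(i)
            used_f.add(j)
            if lam_fit is not None:
                t_row = truth.spikes[truth.spikes["unit_id"] == u].sort_values("time_s")
                amp_errs.append(abs(lam_fit[j] - t_row["lam"].to_numpy()[i]))
        n_true, n_fit = len(t_true), len(t_fit)
        out.append(
            {
                "unit_id": u,
                "n_true": n_true,
                "n_fit": n_fit,
                "fn_rate": (n_true - len(used_t)) / n_true if n_true else np.nan,
                "fp_rate": (n_fit - len(used_f)) / n_fit if n_fit else 0.0,
                "amp_mae": float(np.mean(amp_errs)) if amp_errs else np.nan,
            }
        )
    return pd.DataFrame(out)


def match_units(
    true_templates: list[Template], fitted_templates: list[Template], n_channels: int
) -> dict[int, int]:
    """Greedy fitted->true unit map by peak template cross-correlation."""
    scores = []
    for j, ft in enumerate(fitted_templates):
        for i, tt in enumerate(true_templates):
            scores.append((-_template_xcorr(ft, tt, n_channels), j, i))
    scores.sort()
    mapping: dict[int, int] = {}
    taken: set[int] = set()
    for neg, j, i in scores:
        if j in mapping or i in taken or -neg < 0.5:
            continue
        mapping[j] = i
        taken.add(i)
    return mapping
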