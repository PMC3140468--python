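"""Amplitude-marginalized Bayesian greedy template fitting.

Each spike clip V is explained as a sum of scaled, shifted templates plus
correlated Gaussian noise. For a candidate "template c at time t" the
amplitude scale is integrated out under the unit's Gaussian prior
N(mu_c, sigma_c^2), giving the log posterior ratio against "no spike":

    A = T' C^-1 T + 1/sigma_c^2
    b = T' C^-1 V + mu_c/sigma_c^2
    log R = log(r_c dt) + b^2/(2A) - mu_c^2/(2 sigma_c^2) - 0.5 log(sigma_c^2 A)

with C the AR(1) noise covariance. The greedy loop fits the best single
candidate at the current absolute peak, subtracts it (least-squares scale and
shift), and repeats until no template's ratio summed over candidate times
exceeds one. Events whose residual still crosses threshold are archived as
"incomplete fits" and recycled into new templates for a second pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data import Clip, Recording
from .noise_model import NoiseModel
from .templates import Template

__all__ = [
    "FitConfig",
    "deduplicate_assignments",
    "SpikeAssignment",
    "log_posterior_ratio",
    "best_single_fit",
    "subtract_fit",
    "greedy_fit",
    "detect_incomplete",
    "update_priors",
    "two_pass_sort",
    "assignments_frame",
]

UPSAMPLE = 5


@dataclass
class FitConfig:
    """Knobs of the greedy fitter.

    ``spatial_reach`` limits candidate templates to leaders within that many
    grid steps (Chebyshev) of the current peak; candidate times span
    +-``time_radius_s`` around the peak. ``incomplete_threshold`` is the
    negative-going residual level (same units as the data) that flags an
    incomplete fit.
    """

    spatial_reach: int = 1
    time_radius_s: float = 1e-3
    max_spikes_per_event: int = 20
    incomplete_threshold: float = -40.0
    stop_log_ratio: float = 0.0  # accept while max summed log ratio exceeds this
    subtract_shift_range: int = 2

    def __post_init__(self) -> None:
        if self.max_spikes_per_event < 1:
            raise ValueError("max_spikes_per_event must be >= 1")


@dataclass
class SpikeAssignment:
    unit_id: int
    time_s: float        # sub-sample resolution via the reading frame
    lam: float
    log_ratio: float     # summed (over times) log posterior ratio at acceptance
    fit_pass: int = 1
    clip_index: int = -1


def _support(template: Template, phase: int, t: int, n: int) -> tuple[slice, np.ndarray, np.ndarray]:
    """Clip-window slice and matching template columns for phase-k at peak t."""
    wave = template.phases[phase]
    W = wave.shape[1]
    t0 = t - W // 2
    lo, hi = max(t0, 0), min(t0 + W, n)
    return slice(lo, hi), wave[:, lo - t0 : hi - t0], wave


def _embed(template: Template, phase: int, t: int, n_channels: int, n: int) -> np.ndarray:
    """Template phase embedded in the full (channels, n) clip frame."""
    out = np.zeros((n_channels, n))
    sl, cols, _ = _support(template, phase, t, n)
    for slot, ch in enumerate(template.channel_indices):
        if ch >= 0:
            out[ch, sl] = cols[slot]
    return out


def log_posterior_ratio(
    event: np.ndarray,
    template: Template,
    phase: int,
    t: int,
    noise: NoiseModel,
) -> float:
    """Log of p(spike of ``template`` at sample ``t`` | V) / p(no spike | V).

    The amplitude scale is marginalized under the Gaussian prior
    (amp_mean, amp_sd); the rate prior contributes log(r_c dt). A zero
    amplitude-prior sd falls back to the plug-in value at lambda = mu_c.
    """
    event = np.atleast_2d(np.asarray(event, dtype=float))
    n_ch, n = event.shape
    Temb = _embed(template, phase, t, n_ch, n)
    qTT = noise.quadratic_form(Temb, Temb)
    qTV = noise.quadratic_form(Temb, event)
    return _ratio_from_forms(qTT, qTV, template, noise.dt)


def _ratio_from_forms(qTT: float, qTV: float, template: Template, dt: float) -> float:
    mu, sd, rate = template.amp_mean, template.amp_sd, template.rate_hz
    log_prior = np.log(max(rate, 1e-300) * dt)
    if sd == 0:
        warnings.warn("zero amplitude-prior sd: using plug-in lambda = mu", stacklevel=3)
        return float(log_prior + mu * qTV - 0.5 * mu**2 * qTT)
    A = qTT + 1.0 / sd**2
    b = qTV + mu / sd**2
    return float(log_prior + b**2 / (2 * A) - mu**2 / (2 * sd**2) - 0.5 * np.log(sd**2 * A))


@dataclass
class _CandidateTable:
    """All (template, phase, t) log ratios around one peak."""

    units: list[int]
    per_unit_sum: dict[int, float]          # logsumexp over (phase, t)
    best: tuple[int, int, int, float] | None  # (unit, phase, t, log_ratio)


def _scan_candidates(
    event: np.ndarray,
    bank: list[Template],
    noise: NoiseModel,
    config: FitConfig,
    geometry,
) -> _CandidateTable:
    n_ch, n = event.shape
    peak_ch, peak_t = np.unravel_index(np.argmin(event), event.shape)
    pr, pc = geometry.grid_position(int(peak_ch))
    radius = max(1, int(round(config.time_radius_s / noise.dt)))
    t_lo, t_hi = max(0, peak_t - radius), min(n - 1, peak_t + radius)

    U = noise.apply_inverse(event)  # C^-1 V, shared by every candidate
    per_unit_logs: dict[int, list[float]] = {}
    best: tuple[int, int, int, float] | None = None
    best_key: tuple[float, float, int] | None = None

    for tpl in bank:
        lr, lc = geometry.grid_position(tpl.leader_channel)
        if max(abs(lr - pr), abs(lc - pc)) > config.spatial_reach:
            continue
        logs = per_unit_logs.setdefault(tpl.unit_id, [])
        W = tpl.phases[0].shape[1]
        half = W // 2
        chs = tpl.channel_indices[tpl.valid]
        # pad so every candidate placement sees a full (zero-extended) window;
        # truncated template support contributes exactly the in-window terms
        pad = np.zeros((len(chs), n + 2 * W))
        pad[:, W : W + n] = U[chs]
        seg = np.lib.stride_tricks.sliding_window_view(pad, W, axis=1)
        ts = np.arange(t_lo, t_hi + 1)
        for phase in range(UPSAMPLE):
            wave = tpl.phases[phase][tpl.valid]
            # qTV(t) = sum_slot wave[slot] . U[ch, t-half : t-half+W]
            qTV = np.einsum("cw,ctw->t", wave, seg[:, ts - half + W, :])
            interior = noise.quadratic_form(wave, wave, interior=True)
            for k, t in enumerate(ts):
                t0 = t - half
                if t0 >= 1 and t0 + W <= n - 1:
                    qTT = interior
                else:
                    Temb = _embed(tpl, phase, int(t), n_ch, n)
                    qTT = noise.quadratic_form(Temb, Temb)
                if qTT <= 0:
                    continue
                lr_val = _ratio_from_forms(qTT, float(qTV[k]), tpl, noise.dt)
                logs.append(lr_val)
                # ties: higher amplitude-prior mean, then lower unit id
                key = (lr_val, tpl.amp_mean, -tpl.unit_id)
                if best_key is None or key > best_key:
                    best_key = key
                    best = (tpl.unit_id, phase, int(t), lr_val)
    sums = {u: float(logsumexp(v)) for u, v in per_unit_logs.items() if v}
    return _CandidateTable(units=sorted(per_unit_logs), per_unit_sum=sums, best=best)


def best_single_fit(
    event: np.ndarray,
    bank: list[Template],
    noise: NoiseModel,
    config: FitConfig,
    geometry,
) -> tuple[int, int, int, dict[int, float]]:
    """Best (unit, phase, t) over all candidates around the event's peak.

    Returns the argmax and the per-unit table of log ratios summed over times
    (the quantity the stopping rule thresholds).
    """
    if not bank:
        raise ValueError("empty template bank")
    table = _scan_candidates(np.atleast_2d(event), bank, noise, config, geometry)
    if table.best is None:
        raise ValueError("no candidate template near the event peak")
    u, phase, t, _ = table.best
    return u, phase, t, table.per_unit_sum


def subtract_fit(
    event: np.ndarray,
    template: Template,
    t_star: int,
    config: FitConfig | None = None,
) -> tuple[np.ndarray, float, int, int] | None:
    """Least-squares subtraction of ``template`` near ``t_star``.

    Searches all 5 reading frames and +-``subtract_shift_range`` samples for
    the placement minimizing the ordinary-norm residual, with
    lambda = <V, T>/<T, T>. Returns (residual, lambda, t_sub, phase_sub), or
    None when the best lambda is non-positive (candidate rejected). The
    reported spike time stays the posterior argmax t_star, not t_sub.
    """
    config = config or FitConfig()
    event = np.atleast_2d(np.asarray(event, dtype=float))
    n_ch, n = event.shape
    best = None  # (gain, lam, t, phase)
    for phase in range(UPSAMPLE):
        for dt_shift in range(-config.subtract_shift_range, config.subtract_shift_range + 1):
            t = t_star + dt_shift
            sl, cols, _ = _support(template, phase, t, n)
            if sl.stop - sl.start <= 0:
                continue
            vt = 0.0
            tt = 0.0
            for slot, ch in enumerate(template.channel_indices):
                if ch >= 0:
                    vt += float(cols[slot] @ event[ch, sl])
                    tt += float(cols[slot] @ cols[slot])
            if tt == 0 or vt <= 0:
                continue
            gain = vt * vt / tt  # explained ordinary-norm energy
            if best is None or gain > best[0]:
                best = (gain, vt / tt, t, phase)
    if best is None:
        return None
    _, lam, t_sub, phase_sub = best
    residual = event.copy()
    sl, cols, _ = _support(template, phase_sub, t_sub, n)
    for slot, ch in enumerate(template.channel_indices):
        if ch >= 0:
            residual[ch, sl] -= lam * cols[slot]
    return residual, float(lam), t_sub, phase_sub


def greedy_fit(
    clip: Clip | np.ndarray,
    bank: list[Template],
    noise: NoiseModel,
    config: FitConfig,
    geometry,
    fit_pass: int = 1,
    clip_index: int = -1,
) -> tuple[list[SpikeAssignment], np.ndarray]:
    """Matching-pursuit loop: fit at the peak, subtract, repeat until the
    likelihood-ratio stopping rule fails. Returns (assignments, residual).
    """
    if isinstance(clip, Clip):
        start, event = clip.start_sample, clip.voltages.copy()
    else:
        start, event = 0, np.atleast_2d(np.asarray(clip, dtype=float)).copy()
    by_id = {t.unit_id: t for t in bank}
    out: list[SpikeAssignment] = []
    for _ in range(config.max_spikes_per_event):
        if not bank or event.min() >= 0:
            break
        table = _scan_candidates(event, bank, noise, config, geometry)
        if table.best is None or not table.per_unit_sum:
            break
        if max(table.per_unit_sum.values()) <= config.stop_log_ratio:
            break
        u, phase, t, _single = table.best
        sub = subtract_fit(event, by_id[u], t, config)
        if sub is None:
            break  # non-positive scale: candidate rejected, fit stops
        event, lam, _t_sub, _ = sub
        out.append(
            SpikeAssignment(
                unit_id=u,
                time_s=(start + t - phase / UPSAMPLE) * noise.dt,
                lam=lam,
                log_ratio=table.per_unit_sum[u],
                fit_pass=fit_pass,
                clip_index=clip_index,
            )
        )
    else:
        warnings.warn("max_spikes_per_event reached; partial fit", stacklevel=2)
    return out, event


def detect_incomplete(residual: np.ndarray, threshold: float) -> bool:
    """True when any residual sample still crosses the negative threshold."""
    return bool(np.min(residual) < threshold)


def update_priors(
    assignments: pd.DataFrame,
    total_duration_s: float,
    bank: list[Template],
    min_lam_values: int = 100,
) -> list[Template]:
    """Refresh each unit's rate and amplitude prior from pass-1 fits.

    r_c becomes n_fits / duration; (mu_c, sigma_c) become the mean/sd of the
    accepted scale factors above the unit's amplitude cutoff. Units with no
    fits keep their priors (flagged by an unchanged n_events of 0).
    """
    from .validation import amplitude_cutoff

    if total_duration_s <= 0:
        raise ValueError("duration must be positive")
    updated = []
    for tpl in bank:
        lam = assignments.loc[assignments["unit_id"] == tpl.unit_id, "lam"].to_numpy()
        if lam.size == 0:
            updated.append(replace(tpl))
            continue
        cutoff = 0.0
        if lam.size >= min_lam_values:
            cutoff, _ = amplitude_cutoff(lam)
        kept = lam[lam > cutoff] if cutoff > 0 else lam
        if kept.size == 0:
            kept = lam
        updated.append(
            replace(
                tpl,
                rate_hz=lam.size / total_duration_s,
                amp_mean=float(np.mean(kept)),
                amp_sd=float(np.std(kept, ddof=1)) if kept.size > 1 else tpl.amp_sd,
                n_events=int(lam.size),
            )
        )
    return updated


def deduplicate_assignments(df: pd.DataFrame, tol_s: float = 2.5e-4) -> pd.DataFrame:
    """Drop repeated fits of one spike reported from overlapping clips.

    Spike clips may overlap when bursts outlast the clip window, so the same
    spike can be fitted in two clips. Within each unit, fits closer than
    ``tol_s`` collapse onto the one with the higher posterior ratio.
    """
    if df.empty:
        return df
    keep_rows = []
    for _, grp in df.groupby("unit_id"):
        grp = grp.sort_values("log_ratio", ascending=False)
        kept_times: list[float] = []
        for row in grp.itertuples():
            if all(abs(row.time_s - t) > tol_s for t in kept_times):
                kept_times.append(row.time_s)
                keep_rows.append(row.Index)
    return df.loc[sorted(keep_rows)].sort_values(
        "time_s", kind="stable", ignore_index=True
    )


def assignments_frame(assignments: list[SpikeAssignment]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "unit_id": a.unit_id,
                "time_s": a.time_s,
                "lam": a.lam,
                "log_ratio": a.log_ratio,
                "fit_pass": a.fit_pass,
                "clip_index": a.clip_index,
            }
            for a in assignments
        ],
        columns=["unit_id", "time_s", "lam", "log_ratio", "fit_pass", "clip_index"],
    )
    return df.sort_values("time_s", kind="stable", ignore_index=True)


def two_pass_sort(
    recording: Recording,
    bank: list[Template],
    noise: NoiseModel,
    config: FitConfig,
    spike_clips: list[Clip] | None = None,
    clustering_params: dict | None = None,
) -> tuple[pd.DataFrame, list[Template], list[Clip]]:
    """Full two-pass fit: greedy pass 1, recycle incomplete residuals into new
    templates, update priors, refit everything in pass 2.

    Returns (assignments sorted by time, final template bank, archived
    incomplete residual clips).
    """
    from .pipeline import recluster_residuals
    from .preprocess import extract_clips

    if spike_clips is None:
        sigma = noise.sigma
        spike_clips = [
            c
            for c in extract_clips(recording, -4.0 * sigma, -2.0 * sigma)
            if c.kind == "spike"
        ]

    pass1: list[SpikeAssignment] = []
    residual_clips: list[Clip] = []
    for ci, clip in enumerate(spike_clips):
        fits, residual = greedy_fit(clip, bank, noise, config, recording.geometry, 1, ci)
        pass1.extend(fits)
        if detect_incomplete(residual, config.incomplete_threshold):
            residual_clips.append(Clip(residual, clip.start_sample, "spike"))

    df1 = deduplicate_assignments(assignments_frame(pass1))
    bank2 = update_priors(df1, recording.duration, bank) if len(df1) else list(bank)
    new_templates = recluster_residuals(
        residual_clips, recording, noise, bank2, **(clustering_params or {})
    )
    bank2 = bank2 + new_templates

    pass2: list[SpikeAssignment] = []
    for ci, clip in enumerate(spike_clips):
        fits, _ = greedy_fit(clip, bank2, noise, config, recording.geometry, 2, ci)
        pass2.extend(fits)
    return deduplicate_assignments(assignments_frame(pass2)), bank2, residual_clips
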