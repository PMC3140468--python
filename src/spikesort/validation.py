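"""Post-hoc reliability checks on sorted units.

A unit is trusted only if (1) residuals of its single-spike events look like
noise, (2) its amplitude scale-factor histogram is unimodal (after removing a
well-separated noise-fit mode, if any), and (3) its inter-spike intervals show
a refractory hole while cross-correlograms with other units do not. Units
whose amplitude histogram reaches down to the detection floor are missing true
spikes and are also excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .modes import find_valley, fit_two_modes

__all__ = [
    "residual_stats",
    "amplitude_cutoff",
    "refractory_violations",
    "cross_correlogram",
    "assess_reliability",
    "UnitReport",
]


@dataclass
class UnitReport:
    unit_id: int
    residual_pooled_sd: float = np.nan
    residual_ok: bool = True
    amplitude_cutoff: float = 0.0
    bimodal_flag: bool = False
    refractory_violation_fraction: float = np.nan
    amp_floor_ok: bool = True
    reliable: bool = False
    notes: list[str] = field(default_factory=list)


def residual_stats(
    events: np.ndarray,
    lams: np.ndarray,
    template_phase_waves: list[np.ndarray],
    phases: np.ndarray,
    min_events: int = 50,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Residual moments over single-spike events of one unit.

    ``events`` is (n, 9, W) peak-aligned single-spike events; each is reduced
    by lam_i x (its fitted reading frame). Returns the pointwise mean, the
    pointwise sd, and the pooled residual sd — all of which should match pure
    noise if the template and the amplitude-only variability model hold.
    """
    events = np.asarray(events, dtype=float)
    if events.shape[0] < min_events:
        raise ValueError(f"need >= {min_events} single-spike events, got {events.shape[0]}")
    residuals = np.empty_like(events)
    for i, ev in enumerate(events):
        residuals[i] = ev - lams[i] * template_phase_waves[int(phases[i])]
    return (
        residuals.mean(axis=0),
        residuals.std(axis=0, ddof=1),
        float(residuals.std(ddof=1)),
    )


def amplitude_cutoff(lams: np.ndarray, min_values: int = 100) -> tuple[float, bool]:
    """Cutoff below the main amplitude mode, and an overlapping-modes flag.

    Noise fits show up as a secondary low-amplitude mode in the scale-factor
    histogram. When such a mode is detected and well separated (the valley
    between the modes dips below half the minor mode's height), the valley
    becomes the per-unit cutoff and spikes below it are discarded. When two
    modes are discernible but overlap heavily, the unit is flagged unreliable.
    A unimodal histogram returns (0, False).
    """
    lams = np.asarray(lams, dtype=float)
    if lams.size < min_values:
        raise ValueError(f"need >= {min_values} amplitude values, got {lams.size}")
    fit = fit_two_modes(lams)
    if fit is None or fit["weights"].min() <= 0.03 or fit["ashman_d"] <= 2.0:
        return 0.0, False
    lo_mean, hi_mean = fit["means"]
    valley = find_valley(lams, between=(lo_mean, hi_mean))
    counts, edges = np.histogram(lams, bins=32)
    centers = (edges[:-1] + edges[1:]) / 2.0
    valley_h = counts[np.argmin(np.abs(centers - valley))]
    near_minor = np.abs(centers - lo_mean) <= 2 * fit["sds"][0]
    minor_peak_h = counts[near_minor].max() if near_minor.any() else counts.max()
    if valley_h >= 0.5 * max(minor_peak_h, 1):
        return 0.0, True  # discernible but heavily overlapping modes
    return float(valley), False


def refractory_violations(spike_train_s: np.ndarray, t_ref_s: float = 2e-3) -> float:
    """Fraction of consecutive inter-spike intervals shorter than ``t_ref_s``."""
    t = np.asarray(spike_train_s, dtype=float)
    if t.size < 2:
        return np.nan
    if np.any(np.diff(t) < 0):
        raise ValueError("spike train must be sorted ascending")
    isi = np.diff(t)
    return float(np.mean(isi < t_ref_s))


def cross_correlogram(
    train_a: np.ndarray,
    train_b: np.ndarray,
    bin_ms: float = 0.5,
    window_ms: float = 25.0,
    hole_halfwidth_ms: float = 1.5,
    p_value: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Spike-time difference histogram over +-window, plus a hole flag.

    Distinct units need not respect a mutual refractory period, so a depleted
    center (central +-``hole_halfwidth_ms`` mass under 50% of the flanking-bin
    expectation, Poisson-tested at ``p_value``) is suspicious — it suggests
    the two trains come from one neuron. Returns (counts, bin_edges_ms, flag).
    """
    a = np.sort(np.asarray(train_a, dtype=float))
    b = np.sort(np.asarray(train_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both spike trains must be non-empty")
    w = window_ms * 1e-3
    diffs = []
    j0 = 0
    for t in a:
        j0 = np.searchsorted(b, t - w)
        j1 = np.searchsorted(b, t + w)
        diffs.append(b[j0:j1] - t)
    d_ms = np.concatenate(diffs) * 1e3 if diffs else np.empty(0)
    edges = np.arange(-window_ms, window_ms + bin_ms / 2, bin_ms)
    counts, edges = np.histogram(d_ms, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    central = np.abs(centers) <= hole_halfwidth_ms
    if central.sum() == 0 or (~central).sum() == 0:
        return counts, edges, False
    expected = counts[~central].mean() * central.sum()
    observed = counts[central].sum()
    if expected <= 0:
        return counts, edges, False
    hole = observed < 0.5 * expected and stats.poisson.cdf(observed, expected) < p_value
    return counts, edges, bool(hole)


def assess_reliability(
    unit_id: int,
    lams: np.ndarray,
    spike_train_s: np.ndarray,
    template_peak: float,
    detection_floor: float,
    noise_sigma: float,
    residual_pooled_sd: float | None = None,
    refractory_bound: float = 0.005,
    t_ref_s: float = 2e-3,
    residual_sd_tolerance: float = 0.25,
) -> UnitReport:
    """Combine the per-unit criteria into a single reliability verdict.

    The unit passes when its amplitude histogram is unimodal (after any noise
    cutoff), its refractory-violation fraction stays below the bound, its
    residual sd matches the noise sd, and its amplitude distribution stays
    clear of the detection floor (a histogram reaching the floor means true
    spikes were missed by the trigger).
    """
    report = UnitReport(unit_id=unit_id)
    lams = np.asarray(lams, dtype=float)

    try:
        cutoff, bimodal = amplitude_cutoff(lams)
    except ValueError:
        cutoff, bimodal = 0.0, False
        report.notes.append("too few amplitudes for cutoff analysis")
    report.amplitude_cutoff = cutoff
    report.bimodal_flag = bimodal
    kept = lams[lams > cutoff] if cutoff > 0 else lams

    frac = refractory_violations(np.sort(spike_train_s), t_ref_s)
    report.refractory_violation_fraction = frac

    if residual_pooled_sd is not None:
        report.residual_pooled_sd = residual_pooled_sd
        report.residual_ok = abs(residual_pooled_sd / noise_sigma - 1.0) <= residual_sd_tolerance

    # detection-floor rule: a unit whose amplitude histogram extends
    # materially below the trigger threshold is missing sub-threshold spikes
    if kept.size:
        below = float(np.mean(kept * template_peak < detection_floor))
        report.amp_floor_ok = below <= 0.05
    else:
        report.amp_floor_ok = False
        report.notes.append("no amplitudes above cutoff")

    report.reliable = (
        not report.bimodal_flag
        and report.residual_ok
        and report.amp_floor_ok
        and not np.isnan(frac)
        and frac <= refractory_bound
    )
    return report
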