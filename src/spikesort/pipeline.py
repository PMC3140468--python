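"""Pipeline orchestration: configuration, stage wiring, artifact I/O.

Stages run in the fixed order preprocess -> cluster -> build templates ->
two-pass fit -> validate. Clustering uses a configurable time-subset of the
recording; fitting uses all of it. All stage parameters live in one
``PipelineConfig`` that round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as cl
from . import preprocess as pp
from .data import Clip, CroppedEvent, Recording
from .fitting import FitConfig, two_pass_sort
from .noise_model import NoiseModel, fit_noise_model
from .templates import (
    MIN_EVENTS,
    Template,
    amplitude_prior,
    build_template,
    make_phases,
)
from .validation import assess_reliability

logger = logging.getLogger("spikesort")

__all__ = ["PipelineConfig", "run_pipeline", "cluster_events", "recluster_residuals"]

UPSAMPLE = 5


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with defaults matching the module docs."""

    # preprocess
    highpass_hz: float = 200.0
    spike_k: float = 4.0          # spike threshold, multiples of noise sd
    noise_k: float = 3.5          # noise-exclusion threshold, multiples of noise sd
    clip_samples: int = 32
    # clustering
    mask_k: float = 2.0           # mask threshold, multiples of noise sd
    min_pts: int = 10
    band_xi: float = 3.0
    cluster_subset_s: float = 120.0   # emulates four 30-second segments
    merge_xcorr: float = 0.95
    # templates
    min_template_events: int = MIN_EVENTS
    # fitting
    time_radius_ms: float = 1.0
    max_spikes_per_event: int = 20
    incomplete_k: float = 4.0     # incomplete-fit threshold, multiples of noise sd
    # validation
    t_ref_ms: float = 2.0
    refractory_bound: float = 0.005
    seed: int = 0

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _masked_aligned(
    events: list[CroppedEvent], mask_threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Upsample/peak-align events; return (masked downsampled, aligned upsampled)."""
    raw = np.stack([e.voltages for e in events])
    up = cl.upsample_and_align(raw, UPSAMPLE, keep_upsampled=True, align_channel=4)
    down = up[:, :, ::UPSAMPLE]
    masked = np.where(down <= mask_threshold, down, 0.0)
    return masked, up


def cluster_events(
    events: list[CroppedEvent],
    noise_sigma: float,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Cluster cropped events; returns per-event integer labels (-1 noise).

    Events are batched by leader electrode (only same-leader events are
    directly comparable), each batch is OPTICS-ordered under the masked
    normalized distance and cut into bands, composite bands are split on
    multimodal principal components, and near-duplicate clusters across
    batches are merged by template-median cross-correlation.
    """
    config = config or PipelineConfig()
    n = len(events)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    mask_thr = -config.mask_k * noise_sigma

    by_leader: dict[int, list[int]] = {}
    for i, ev in enumerate(events):
        by_leader.setdefault(ev.leader_channel, []).append(i)

    next_label = 0
    medians: dict[int, np.ndarray] = {}
    n_channels = 0
    for ev in events:
        n_channels = max(n_channels, int(ev.channel_indices.max()) + 1)

    for leader, idxs in sorted(by_leader.items()):
        if len(idxs) < config.min_pts:
            continue
        batch = [events[i] for i in idxs]
        masked, aligned_up = _masked_aligned(batch, mask_thr)
        result = cl.optics_order(masked, min_pts=config.min_pts, amp_floor=noise_sigma)
        bands = cl.cut_bands(result, min_pts=config.min_pts, xi=config.band_xi)
        down = aligned_up[:, :, ::UPSAMPLE]
        for cid in range(bands.n_clusters):
            members = np.flatnonzero(bands.labels == cid)
            # split on the raw aligned waveforms: masking quantizes events into
            # discrete stixel patterns that fake multimodal projections
            for part in cl.split_composite(down[members], min_pts=config.min_pts):
                sub = members[part]
                if len(sub) < config.min_pts:
                    continue
                for i in sub:
                    labels[idxs[i]] = next_label
                med = np.median(aligned_up[sub][:, :, ::UPSAMPLE], axis=0)
                emb = np.zeros((n_channels, med.shape[1]))
                for slot, ch in enumerate(batch[0].channel_indices):
                    if ch >= 0:
                        emb[ch] = med[slot]
                medians[next_label] = emb
                next_label += 1

    if medians:
        relabel, merged = cl.merge_duplicates(medians, xcorr_threshold=config.merge_xcorr)
        if merged:
            logger.info("merged duplicate cluster pairs: %s", merged)
        labels = np.array([relabel.get(l, -1) if l >= 0 else -1 for l in labels])
    return labels


def build_templates_from_clusters(
    events: list[CroppedEvent],
    labels: np.ndarray,
    clustered_duration_s: float,
    dt: float,
    config: PipelineConfig | None = None,
    unit_id_start: int = 0,
) -> list[Template]:
    """Median-align-median templates + amplitude/rate priors per cluster."""
    config = config or PipelineConfig()
    bank: list[Template] = []
    uid = unit_id_start
    for cid in sorted(set(labels[labels >= 0])):
        members = [events[i] for i in np.flatnonzero(labels == cid)]
        if len(members) < config.min_template_events:
            logger.warning("cluster %d dropped: only %d events", cid, len(members))
            continue
        raw = np.stack([e.voltages for e in members])
        up = cl.upsample_and_align(raw, UPSAMPLE, keep_upsampled=True, align_channel=4)
        try:
            wave, kept = build_template(up, config.min_template_events, dt=dt)
        except ValueError:
            continue
        mu, sd = amplitude_prior(up[kept], wave)
        if mu <= 0:
            continue
        # normalize so the prior mean scale is 1
        wave = wave * mu
        sd = sd / mu
        lead = members[0]
        bank.append(
            Template(
                waveform=wave,
                leader_channel=lead.leader_channel,
                channel_indices=lead.channel_indices,
                valid=lead.valid,
                phases=make_phases(wave, UPSAMPLE),
                amp_mean=1.0,
                amp_sd=max(sd, 1e-3),
                rate_hz=max(len(members) / clustered_duration_s, 1e-6),
                n_events=len(members),
                unit_id=uid,
            )
        )
        uid += 1
    return bank


def recluster_residuals(
    residual_clips: list[Clip],
    recording: Recording,
    noise: NoiseModel,
    existing_bank: list[Template],
    config: PipelineConfig | None = None,
    duplicate_xcorr: float = 0.95,
) -> list[Template]:
    """Turn incomplete-fit residuals into new templates (missed spike types).

    Residual clips are re-segmented and clustered exactly like first-pass
    events; clusters that duplicate an existing template (peak waveform
    cross-correlation >= ``duplicate_xcorr``) are discarded.
    """
    config = config or PipelineConfig()
    if not residual_clips:
        return []
    events: list[CroppedEvent] = []
    thr = -config.spike_k * noise.sigma
    for clip in residual_clips:
        events.extend(pp.segment_events(clip, thr, recording.geometry, config.clip_samples))
    if len(events) < config.min_template_events:
        return []
    labels = cluster_events(events, noise.sigma, config)
    duration = len(residual_clips) * residual_clips[0].n_samples * noise.dt
    start_id = max((t.unit_id for t in existing_bank), default=-1) + 1
    candidates = build_templates_from_clusters(
        events, labels, max(duration, recording.duration), noise.dt, config, start_id
    )
    n_channels = recording.n_channels
    fresh = []
    for cand in candidates:
        cand_emb = _embed_wave(cand, n_channels)
        dup = False
        for tpl in existing_bank + fresh:
            if cl.duplicate_xcorr(cand_emb, _embed_wave(tpl, n_channels)) >= duplicate_xcorr:
                dup = True
                break
        if not dup:
            # residual counts under-estimate the unit's rate; use the full
            # recording duration so the prior is at least order-correct
            cand = dataclasses.replace(cand, rate_hz=cand.n_events / recording.duration)
            fresh.append(cand)
    # re-number sequentially after duplicate removal
    return [dataclasses.replace(t, unit_id=start_id + k) for k, t in enumerate(fresh)]


def _embed_wave(tpl: Template, n_channels: int) -> np.ndarray:
    down = tpl.phases[0]
    out = np.zeros((n_channels, down.shape[1]))
    for slot, ch in enumerate(tpl.channel_indices):
        if ch >= 0:
            out[ch] = down[slot]
    return out


@dataclass
class PipelineResult:
    recording: Recording
    noise: NoiseModel
    bank: list[Template]
    assignments: pd.DataFrame
    reports: list
    incomplete_clips: list[Clip] = field(default_factory=list)


def run_pipeline(recording: Recording, config: PipelineConfig | None = None) -> PipelineResult:
    """Execute every stage on a raw (or pre-filtered) recording."""
    config = config or PipelineConfig()

    if not recording.filtered:
        recording = pp.highpass_filter(recording, config.highpass_hz)
    sd0 = pp.pooled_noise_sd(recording)
    clips = pp.extract_clips(
        recording, -config.spike_k * sd0, -config.noise_k * sd0, config.clip_samples
    )
    noise_clips = [c for c in clips if c.kind == "noise"]
    if len(noise_clips) < 100:
        raise RuntimeError("too few noise clips to characterize the noise")

    if not recording.whitened:
        cov = pp.estimate_spatial_covariance(noise_clips)
        recording = pp.spatial_whiten(recording, cov)
        clips = pp.extract_clips(
            recording, -config.spike_k * sd0, -config.noise_k * sd0, config.clip_samples
        )
        noise_clips = [c for c in clips if c.kind == "noise"]

    noise = fit_noise_model(
        np.stack([c.voltages for c in noise_clips]),
        recording.sample_interval,
        min_clips=min(500, len(noise_clips)),
    )
    spike_clips = [c for c in clips if c.kind == "spike"]
    logger.info("clips: %d spike, %d noise", len(spike_clips), len(noise_clips))

    # clustering subset
    subset_end = config.cluster_subset_s / recording.sample_interval
    subset_clips = [c for c in spike_clips if c.start_sample < subset_end]
    subset_duration = min(config.cluster_subset_s, recording.duration)
    events: list[CroppedEvent] = []
    for clip in subset_clips:
        events.extend(
            pp.segment_events(
                clip, -config.spike_k * noise.sigma, recording.geometry, config.clip_samples
            )
        )
    labels = cluster_events(events, noise.sigma, config)
    bank = build_templates_from_clusters(
        events, labels, subset_duration, recording.sample_interval, config
    )
    logger.info("clusters: %d events -> %d templates", len(events), len(bank))
    if not bank:
        raise RuntimeError("no usable templates were built from the clustered subset")

    fit_config = FitConfig(
        time_radius_s=config.time_radius_ms * 1e-3,
        max_spikes_per_event=config.max_spikes_per_event,
        incomplete_threshold=-config.incomplete_k * noise.sigma,
    )
    assignments, bank, incomplete = two_pass_sort(
        recording, bank, noise, fit_config, spike_clips, {"config": config}
    )
    logger.info("fitted %d spikes (%d incomplete clips)", len(assignments), len(incomplete))

    reports = []
    for tpl in bank:
        rows = assignments[assignments["unit_id"] == tpl.unit_id]
        if len(rows) < 2:
            continue
        reports.append(
            assess_reliability(
                unit_id=tpl.unit_id,
                lams=rows["lam"].to_numpy(),
                spike_train_s=np.sort(rows["time_s"].to_numpy()),
                template_peak=tpl.peak_amplitude,
                detection_floor=config.spike_k * noise.sigma,
                noise_sigma=noise.sigma,
                refractory_bound=config.refractory_bound,
                t_ref_s=config.t_ref_ms * 1e-3,
            )
        )
    return PipelineResult(recording, noise, bank, assignments, reports, incomplete)
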