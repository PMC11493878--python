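"""Offline conditioning of recordings before ERP/ERSP analysis.

Downsampling to the 200-Hz analysis rate, a simplified automatic artifact /
bad-channel pass (amplitude, sample-to-sample jumps, high-frequency power),
and sleep-stage gating: all event-locked analyses are restricted to
non-REM stage 2 and slow-wave sleep (N3).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage, signal

from plaslab.synth import EPOCH_S, Recording


@dataclass
class ArtifactThresholds:
    amp_uv: float = 250.0        # absolute amplitude limit
    jump_uv: float = 80.0        # per-sample step limit
    hf_z: float = 6.0            # z-score limit on high-frequency power
    hf_cutoff_hz: float = 25.0
    pad_s: float = 0.25          # mask padding around violations
    bad_fraction: float = 0.3    # channel bad if masked above this fraction
    flat_uv: float = 1e-6        # std below this = flatline channel


@dataclass
class CleanRecording(Recording):
    """A Recording plus bad-channel list and per-sample masks."""

    bad_channels: list = dataclasses.field(default_factory=list)
    artifact_mask: np.ndarray | None = None   # per-sample, True = contaminated
    analysis_mask: np.ndarray | None = None   # N2/N3 AND NOT artifact

    @property
    def good_channels(self) -> list:
        return [ch for ch in self.channel_names if ch not in self.bad_channels]

    def good_index(self) -> np.ndarray:
        bad = set(self.bad_channels)
        return np.array([i for i, ch in enumerate(self.channel_names)
                         if ch not in bad])


def downsample(rec: Recording, target_hz: float = 200.0) -> Recording:
    """Anti-alias filter and decimate to ``target_hz``.

    Event and hypnogram timestamps are in seconds and unchanged. Requesting
    the current rate is the identity; upsampling is an error.
    """
    if target_hz > rec.rate:
        raise ValueError(f"cannot upsample {rec.rate} Hz to {target_hz} Hz")
    if target_hz == rec.rate:
        return rec
    ratio = rec.rate / target_hz
    if abs(ratio - round(ratio)) < 1e-9:
        data = signal.decimate(np.asarray(rec.data, float), int(round(ratio)),
                               ftype="fir", zero_phase=True, axis=1)
    else:
        frac = Fraction(target_hz / rec.rate).limit_denominator(1000)
        data = signal.resample_poly(np.asarray(rec.data, float),
                                    frac.numerator, frac.denominator, axis=1)
    return dataclasses.replace(rec, data=data.astype(np.float32), rate=target_hz)


def gate_stages(rec: Recording, stages=("N2", "N3"),
                artifact_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-sample mask: True exactly on samples inside 30-s epochs scored in
    ``stages`` and (optionally) not artifact-masked."""
    if rec.hypnogram is None or len(rec.hypnogram) == 0:
        raise ValueError("recording has no hypnogram")
    mask = np.zeros(rec.n_samples, bool)
    spe = int(EPOCH_S * rec.rate)
    stages = set(stages)
    for i, st in enumerate(rec.hypnogram):
        if st in stages:
            mask[i * spe:(i + 1) * spe] = True
    if artifact_mask is not None:
        mask &= ~artifact_mask
    return mask


def reject_artifacts(rec: Recording,
                     thresholds: ArtifactThresholds | None = None,
                     stages=("N2", "N3")) -> CleanRecording:
    """Simplified automatic artifact rejection.

    Flatline channels are removed first; samples exceeding the amplitude,
    jump, or high-frequency-power limits on any remaining channel are masked
    with padding; channels masked beyond ``bad_fraction`` are marked bad and
    the sample mask recomputed from good channels only. Deterministic.
    """
    thr = thresholds or ArtifactThresholds()
    data = np.asarray(rec.data, float)
    n_ch, n_samp = data.shape

    ch_std = data.std(axis=1)
    bad = set(np.flatnonzero(ch_std < thr.flat_uv))

    viol = np.zeros((n_ch, n_samp), bool)
    if np.isfinite(thr.amp_uv):
        viol |= np.abs(data) > thr.amp_uv
    if np.isfinite(thr.jump_uv):
        viol[:, 1:] |= np.abs(np.diff(data, axis=1)) > thr.jump_uv
    if np.isfinite(thr.hf_z) and rec.rate > 2.5 * thr.hf_cutoff_hz:
        sos = signal.butter(4, thr.hf_cutoff_hz, btype="high",
                            fs=rec.rate, output="sos")
        hf = signal.sosfiltfilt(sos, data, axis=1)
        win = max(3, int(rec.rate))
        power = ndimage.uniform_filter1d(hf**2, size=win, axis=1)
        mu = power.mean(axis=1, keepdims=True)
        sd = power.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        viol |= (power - mu) / sd > thr.hf_z

    frac = np.array([viol[i].mean() for i in range(n_ch)])
    bad |= set(np.flatnonzero(frac > thr.bad_fraction))

    good = np.array([i for i in range(n_ch) if i not in bad], int)
    artifact = viol[good].any(axis=0) if len(good) else np.zeros(n_samp, bool)
    pad = int(round(thr.pad_s * rec.rate))
    if pad and artifact.any():
        artifact = ndimage.binary_dilation(artifact, structure=np.ones(2 * pad + 1, bool))

    clean = CleanRecording(
        data=rec.data, rate=rec.rate, channel_names=rec.channel_names,
        channel_positions=rec.channel_positions, hypnogram=rec.hypnogram,
        events=rec.events, night=rec.night,
        bad_channels=[rec.channel_names[i] for i in sorted(bad)],
        artifact_mask=artifact,
    )
    clean.analysis_mask = gate_stages(clean, stages, artifact_mask=artifact)
    return clean


def cleaning_report(clean: CleanRecording) -> dict:
    """JSON-ready summary of the cleaning pass."""
    return {
        "night": clean.night,
        "bad_channels": list(clean.bad_channels),
        "percent_masked": float(100.0 * clean.artifact_mask.mean()),
        "percent_analyzable": float(100.0 * clean.analysis_mask.mean()),
    }
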