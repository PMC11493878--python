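"""Synthetic sleep-EEG cohorts for closed-loop acoustic-stimulation studies.

The generator produces everything the downstream analysis consumes without
any recorded data: participant profiles for a healthy (HC) and a cognitively
impaired (CI) group, multichannel overnight recordings with ground-truth
slow-wave and spindle events on a 1/f background, stimulation-evoked
responses, memory trajectories over eight test sessions (t0–t7, 40 items),
and pre/post plasma Aβ42/Aβ40 ratios.

Group structure emulated by default:

* CI profiles have fewer and smaller slow waves than HC profiles.
* The evoked-response gain is constant (1, 1, 1) across the three
  stimulation nights for HC and ramps up across nights for CI, encoding the
  delayed electrophysiological response of the impaired group.
* Memory benefits of stimulation appear at the post/1-week sessions for HC
  but only at the 3-month follow-up for CI; the plasma Aβ42/40 change scales
  with the electrophysiological response in the CI group only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from plaslab import layout as _layout

NIGHTS = ("BL", "E1", "E2", "E3")
STAGES = ("W", "N1", "N2", "N3", "REM")
EPOCH_S = 30.0
MEMORY_ITEMS = 40

# evoked-response kernel support relative to the stimulation marker (s)
EVOKED_ONSET_S = 0.25
EVOKED_OFFSET_S = 1.75
EVOKED_PEAK_WINDOW = (1.0, 1.5)  # induced second SW peak
EVOKED_TROUGH_WINDOW = (0.5, 1.0)  # induced trough


@dataclass
class SynthConfig:
    """All tunable knobs of the generator. Units in field names/comments."""

    # recording
    rate: float = 200.0          # Hz; analysis rate (raw data in the field is
                                 # recorded faster and downsampled to 200 Hz)
    n_channels: int = 128
    noise_rms_uv: float = 15.0   # RMS of the 1/f background per channel
    noise_exponent: float = 1.0  # power ∝ 1/f**exponent (1 = pink)

    # slow waves
    sw_freq_hz: float = 0.9
    sw_amp_mean_hc: float = 75.0  # µV peak at Fz
    sw_amp_mean_ci: float = 50.0
    sw_amp_sd: float = 15.0
    sw_density_mean_hc: float = 8.0   # events / minute of N2+N3
    sw_density_sd_hc: float = 1.5
    sw_density_mean_ci: float = 5.0
    sw_density_sd_ci: float = 1.2
    sw_topo_sigma: float = 0.7

    # spindles
    spindle_rate_per_min: float = 3.0  # in N2 epochs
    spindle_freq_lo: float = 12.0
    spindle_freq_hi: float = 16.0
    spindle_amp_uv: float = 20.0
    spindle_dur_s: float = 0.8
    spindle_topo_sigma: float = 0.6

    # hypnogram: repeating (stage, minutes) blocks
    stage_blocks: tuple = (("W", 4.0), ("N1", 4.0), ("N2", 10.0),
                           ("N3", 6.0), ("N2", 4.0), ("REM", 4.0))

    # cohort demographics (Montreal Cognitive Assessment cut-off at 25)
    age_mean_hc: float = 68.3
    age_sd_hc: float = 5.1
    age_mean_ci: float = 71.9
    age_sd_ci: float = 4.0
    p_female_hc: float = 14.0 / 18.0
    p_female_ci: float = 6.0 / 16.0
    moca_mean_hc: float = 27.9
    moca_sd_hc: float = 1.4
    moca_mean_ci: float = 23.3
    moca_sd_ci: float = 1.6

    # latent evoked responsiveness
    responsiveness_mean: float = 1.0
    responsiveness_sd: float = 0.35
    ci_night_gain: tuple = (0.4, 0.7, 1.0)  # E1..E3 ramp for CI profiles
    evoked_peak_uv: float = 8.0  # mean Fz voltage over 1–1.5 s post-marker
                                 # per unit (responsiveness × night gain)
    evoked_topo_sigma: float = 0.7

    # behavior: 40-item cued-recall task, feedback through t1–t4
    memory_t0_mean_hc: float = 13.1
    memory_t0_mean_ci: float = 9.4
    memory_t0_sd: float = 4.5
    memory_asymptote_hc: float = 32.0
    memory_asymptote_ci: float = 22.0
    memory_learning_rate: float = 0.55  # per feedback session
    memory_forget: tuple = (1.0, 4.0, 14.0)  # items lost by t5, t6, t7
    memory_noise_sd: float = 2.0
    memory_slope_hc: float = 0.5  # items per µV of response score
    memory_slope_ci: float = 0.5

    # plasma Aβ42/40
    abeta_pre_mean: float = 0.070
    abeta_pre_sd: float = 0.008
    abeta_noise_sd: float = 0.003
    abeta_slope_hc: float = 0.0     # Δratio per µV of response score
    abeta_slope_ci: float = 0.0008


@dataclass
class ParticipantProfile:
    """Latent per-participant parameters behind all simulated observables."""

    id: str
    group: str                  # "HC" | "CI"
    age: float
    gender: str                 # "M" | "F"
    moca: float
    responsiveness: float       # unitless ≥ 0, scales the evoked response
    sw_density: float           # slow-wave events / minute of N2+N3
    night_gain: tuple           # evoked gain for E1..E3
    memory_slope: float         # items per µV of response score
    abeta_slope: float          # Δ(Aβ42/40) per µV of response score

    def __post_init__(self):
        if self.group not in ("HC", "CI"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.responsiveness < 0:
            raise ValueError("responsiveness must be >= 0")
        g = tuple(float(x) for x in self.night_gain)
        if len(g) != 3 or any(b < a for a, b in zip(g, g[1:])):
            raise ValueError("night_gain must be 3 non-decreasing values")
        self.night_gain = g


@dataclass
class Recording:
    """One participant-night of multichannel EEG with ground truth."""

    data: np.ndarray            # (n_channels, n_samples) µV
    rate: float
    channel_names: list
    channel_positions: np.ndarray
    hypnogram: np.ndarray       # stage label per 30-s epoch
    events: pd.DataFrame        # columns: kind, time, amplitude
    night: str

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def validate(self):
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("one data row per channel name required")
        if len(self.hypnogram) != int(self.duration // EPOCH_S):
            raise ValueError("hypnogram length must be floor(duration/30 s)")
        if len(self.events) and not (
            (self.events["time"] >= 0).all()
            and (self.events["time"] < self.duration).all()
        ):
            raise ValueError("event times must lie within [0, duration)")
        return self


@dataclass
class BehavioralRecord:
    participant_id: str
    scores: np.ndarray  # 8 ints, sessions t0..t7, each in [0, 40]

    @property
    def gains(self) -> np.ndarray:
        """Baseline-corrected gains t1..t7 (score minus t0)."""
        return self.scores[1:] - self.scores[0]


@dataclass
class AbetaRecord:
    participant_id: str
    pre_ratio: float
    post_ratio: float

    @property
    def diff(self) -> float:
        return self.post_ratio - self.pre_ratio


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(n_hc: int, n_ci: int, config: SynthConfig | None = None,
                    seed: int | None = None) -> list:
    """Draw ``n_hc`` healthy and ``n_ci`` cognitively impaired profiles."""
    if n_hc < 0 or n_ci < 0:
        raise ValueError("cohort counts must be non-negative")
    cfg = config or SynthConfig()
    rng = np.random.default_rng(seed)
    profiles = []
    for group, n in (("HC", n_hc), ("CI", n_ci)):
        for i in range(n):
            if group == "HC":
                age = rng.normal(cfg.age_mean_hc, cfg.age_sd_hc)
                p_f = cfg.p_female_hc
                moca = float(np.clip(rng.normal(cfg.moca_mean_hc, cfg.moca_sd_hc), 26, 30))
                dens = rng.normal(cfg.sw_density_mean_hc, cfg.sw_density_sd_hc)
                gain = (1.0, 1.0, 1.0)
                m_slope, a_slope = cfg.memory_slope_hc, cfg.abeta_slope_hc
            else:
                age = rng.normal(cfg.age_mean_ci, cfg.age_sd_ci)
                p_f = cfg.p_female_ci
                moca = float(np.clip(rng.normal(cfg.moca_mean_ci, cfg.moca_sd_ci), 10, 25))
                dens = rng.normal(cfg.sw_density_mean_ci, cfg.sw_density_sd_ci)
                gain = cfg.ci_night_gain
                m_slope, a_slope = cfg.memory_slope_ci, cfg.abeta_slope_ci
            profiles.append(ParticipantProfile(
                id=f"{group}{i + 1:02d}",
                group=group,
                age=float(np.clip(age, 60, 85)),
                gender="F" if rng.random() < p_f else "M",
                moca=moca,
                responsiveness=float(max(0.0, rng.normal(
                    cfg.responsiveness_mean, cfg.responsiveness_sd))),
                sw_density=float(max(0.5, dens)),
                night_gain=gain,
                memory_slope=m_slope,
                abeta_slope=a_slope,
            ))
    return profiles


# ---------------------------------------------------------------------------
# recordings


def make_hypnogram(duration_min: float, blocks=None) -> np.ndarray:
    """Stage label per 30-s epoch from repeating fixed-proportion blocks."""
    blocks = blocks if blocks is not None else SynthConfig().stage_blocks
    n_epochs = int(duration_min * 60.0 // EPOCH_S)
    seq = []
    for stage, minutes in blocks:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        seq.extend([stage] * int(round(minutes * 60.0 / EPOCH_S)))
    if not seq:
        raise ValueError("stage_blocks must cover at least one epoch")
    reps = int(np.ceil(n_epochs / len(seq)))
    return np.array((seq * reps)[:n_epochs])


def pink_noise(n_channels: int, n_samples: int, rate: float, rms: float,
               exponent: float, rng) -> np.ndarray:
    """1/f^exponent background noise, per-channel independent, scaled to RMS."""
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate)
    shaping = np.zeros(n_freq)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spectrum = (rng.standard_normal((n_channels, n_freq))
            + 1j * rng.standard_normal((n_channels, n_freq))) * shaping
    x = np.fft.irfft(spectrum, n=n_samples, axis=1)
    cur = x.std(axis=1, keepdims=True)
    cur[cur == 0] = 1.0
    return (x * (rms / cur)).astype(np.float32)


def _sw_kernel(rate: float, freq: float):
    """One biphasic slow-wave cycle built from raised-cosine segments:
    a slow descent into the down-state trough (45% of the cycle), the steep
    up-slope to the positive peak (25%), and the return to baseline (30%).
    The up-state rise is deliberately faster than the descent, as in real
    slow waves, which keeps the online detector's criterion-crossing→peak
    lead inside its calibration range.

    Returns (kernel normalized to trough −1 / peak +0.8, peak offset s).
    """
    T = 1.0 / freq
    n1, n2, n3 = (int(round(f * T * rate)) for f in (0.45, 0.25, 0.30))
    down = -(1 - np.cos(np.pi * np.arange(n1) / n1)) / 2.0
    up = -1.0 + 1.8 * (1 - np.cos(np.pi * np.arange(n2) / n2)) / 2.0
    back = 0.8 * (1 + np.cos(np.pi * np.arange(n3 + 1) / n3)) / 2.0
    k = np.concatenate([down, up, back])
    return k, float((n1 + n2) / rate)


def _spindle_kernel(rate: float, freq: float, dur: float):
    n = int(round(dur * rate)) + 1
    tau = np.arange(n) / rate - dur / 2.0
    env = np.exp(-(tau**2) / (2 * (dur / 6.0) ** 2))
    k = np.sin(2 * np.pi * freq * (tau + dur / 2.0)) * env
    return k / np.abs(k).max()


def generate_night(profile: ParticipantProfile, night: str, duration_min: float,
                   config: SynthConfig | None = None,
                   seed: int | None = None) -> Recording:
    """Simulate one night: 1/f background plus ground-truth slow waves in
    N2/N3 (Poisson at the profile's density) and spindles in N2."""
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    if night not in NIGHTS:
        raise ValueError(f"night must be one of {NIGHTS}")
    cfg = config or SynthConfig()
    rng = np.random.default_rng(seed)
    rate = cfg.rate
    n_samples = int(round(duration_min * 60.0 * rate))
    names, pos = _layout.spiral_layout(cfg.n_channels)
    hypno = make_hypnogram(duration_min, cfg.stage_blocks)

    data = pink_noise(cfg.n_channels, n_samples, rate, cfg.noise_rms_uv,
                      cfg.noise_exponent, rng)

    sw_topo = _layout.gaussian_topography(pos, _layout.FZ_DIR, cfg.sw_topo_sigma)
    sw_topo = sw_topo / sw_topo[_layout.channel_index(names, "Fz")]
    sp_topo = _layout.gaussian_topography(pos, _layout.CZ_DIR, cfg.spindle_topo_sigma)
    sp_topo = sp_topo / sp_topo[_layout.channel_index(names, "Cz")]

    amp_mean = cfg.sw_amp_mean_hc if profile.group == "HC" else cfg.sw_amp_mean_ci
    sw_k, sw_peak_off = _sw_kernel(rate, cfg.sw_freq_hz)
    kernel_len = len(sw_k)

    rows = []
    # slow waves: Poisson per deep-sleep epoch, uniform placement inside it
    deep = np.flatnonzero(np.isin(hypno, ("N2", "N3")))
    lam = profile.sw_density * (EPOCH_S / 60.0)
    for ep in deep:
        for _ in range(rng.poisson(lam)):
            start = int(ep * EPOCH_S * rate
                        + rng.integers(0, int(EPOCH_S * rate) - kernel_len))
            amp = max(5.0, rng.normal(amp_mean, cfg.sw_amp_sd))
            seg = amp * sw_k
            data[:, start:start + kernel_len] += np.outer(sw_topo, seg).astype(np.float32)
            rows.append(("sw_peak", start / rate + sw_peak_off, amp))

    # spindles in N2
    sp_lam = cfg.spindle_rate_per_min * (EPOCH_S / 60.0)
    n2 = np.flatnonzero(hypno == "N2")
    for ep in n2:
        for _ in range(rng.poisson(sp_lam)):
            f = rng.uniform(cfg.spindle_freq_lo, cfg.spindle_freq_hi)
            k = _spindle_kernel(rate, f, cfg.spindle_dur_s)
            start = int(ep * EPOCH_S * rate
                        + rng.integers(0, int(EPOCH_S * rate) - len(k)))
            seg = cfg.spindle_amp_uv * k
            data[:, start:start + len(k)] += np.outer(sp_topo, seg).astype(np.float32)
            rows.append(("spindle", (start + len(k) // 2) / rate, cfg.spindle_amp_uv))

    events = pd.DataFrame(rows, columns=["kind", "time", "amplitude"])
    events = events.sort_values("time", ignore_index=True)
    return Recording(data=data, rate=rate, channel_names=names,
                     channel_positions=pos, hypnogram=hypno, events=events,
                     night=night).validate()


def benchmark_recording(n_events: int = 40, spacing_s: float = 4.0,
                        rate: float = 200.0, n_channels: int = 32,
                        amplitude_uv: float = 75.0,
                        background_uv: float = 20.0, freq: float = 1.0,
                        rise_fraction: float = 0.25,
                        seed: int = 0) -> Recording:
    """Deterministic detector-benchmark night: template-matched slow-wave
    events on a static background map.

    The background map is orthogonalized against the event topography and
    carries zero mean over every channel, so the frontal voltage comes from
    the events alone while the topographic correlation sweeps smoothly and
    monotonically through each event's rise — a noise-free signal on which
    detection should be essentially perfect. Ground-truth ``sw_peak`` events
    mark the positive peaks.
    """
    names, pos = _layout.spiral_layout(n_channels)
    topo = _layout.gaussian_topography(pos, _layout.FZ_DIR, 0.7)
    topo = topo / topo[_layout.channel_index(names, "Fz")]

    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n_channels)
    g -= g.mean()
    for ref in (topo - topo.mean(),):
        g -= (g @ ref) / (ref @ ref) * ref
    g *= background_uv / np.abs(g).max()

    T = 1.0 / freq
    n1 = int(round((1.0 - rise_fraction - 0.30) * T * rate))
    n2 = int(round(rise_fraction * T * rate))
    n3 = int(round(0.30 * T * rate))
    down = -(1 - np.cos(np.pi * np.arange(n1) / n1)) / 2.0
    up = -1.0 + 1.8 * (1 - np.cos(np.pi * np.arange(n2) / n2)) / 2.0
    back = 0.8 * (1 + np.cos(np.pi * np.arange(n3 + 1) / n3)) / 2.0
    k = np.concatenate([down, up, back])
    peak_off = (n1 + n2) / rate

    duration = EPOCH_S * np.ceil(((n_events + 1) * spacing_s + 4.0) / EPOCH_S)
    n_samples = int(round(duration * rate))
    data = np.tile(g[:, None], (1, n_samples)).astype(np.float32)
    truth = []
    for i in range(n_events):
        s = int(round((1.0 + (i + 0.5) * spacing_s) * rate))
        data[:, s:s + len(k)] += (amplitude_uv * np.outer(topo, k)).astype(np.float32)
        truth.append(s / rate + peak_off)
    hypno = np.array(["N2"] * int(duration // EPOCH_S))
    events = pd.DataFrame({"kind": "sw_peak", "time": truth,
                           "amplitude": amplitude_uv})
    return Recording(data=data, rate=rate, channel_names=names,
                     channel_positions=pos, hypnogram=hypno, events=events,
                     night="E1").validate()


# ---------------------------------------------------------------------------
# evoked responses


def evoked_kernel(rate: float, peak_uv: float = 1.0):
    """Stimulation-evoked kernel sampled on the post-marker axis.

    A damped 1-Hz cosine windowed to 0.25–1.75 s after the marker: a negative
    deflection centered in the 0.5–1 s window followed by a positive peak in
    1–1.5 s. Normalized so that the mean over 1–1.5 s equals ``peak_uv`` on
    the reference (Fz) channel.

    Returns (kernel array, onset offset in samples).
    """
    on = int(round(EVOKED_ONSET_S * rate))
    off = int(round(EVOKED_OFFSET_S * rate))
    n = off - on + 1
    tau = np.arange(n) / rate + EVOKED_ONSET_S
    k = -np.sin(2 * np.pi * (tau - EVOKED_ONSET_S)) * np.hanning(n)
    sel = (tau >= EVOKED_PEAK_WINDOW[0]) & (tau <= EVOKED_PEAK_WINDOW[1])
    k = k * (peak_uv / k[sel].mean())
    return k, on


def night_gain(profile: ParticipantProfile, night: str) -> float:
    if night == "BL":
        return 0.0
    return profile.night_gain[("E1", "E2", "E3").index(night)]


def inject_evoked_response(rec: Recording, markers, profile: ParticipantProfile,
                           config: SynthConfig | None = None) -> Recording:
    """Additively inject the evoked response at each real stimulation marker.

    Amplitude = responsiveness × night gain × ``config.evoked_peak_uv``;
    sham markers contribute nothing. Returns a new Recording.
    """
    cfg = config or SynthConfig()
    real = [m for m in markers if m.condition == "real"]
    bad = [m for m in real if not 0 <= m.time_s < rec.duration]
    if bad:
        raise ValueError(
            "marker(s) outside recording bounds: "
            + ", ".join(f"{m.time_s:.2f}s" for m in bad))

    data = rec.data.copy()
    if real:
        amp = profile.responsiveness * night_gain(profile, rec.night) * cfg.evoked_peak_uv
        topo = _layout.gaussian_topography(rec.channel_positions, _layout.FZ_DIR,
                                           cfg.evoked_topo_sigma)
        topo = topo / topo[_layout.channel_index(rec.channel_names, "Fz")]
        k, on = evoked_kernel(rec.rate, amp)
        patch = np.outer(topo, k).astype(np.float32)
        for m in real:
            start = int(round(m.time_s * rec.rate)) + on
            stop = min(start + len(k), rec.n_samples)  # edge kernels truncate
            data[:, start:stop] += patch[:, :stop - start]
    return dataclasses.replace(rec, data=data)


# ---------------------------------------------------------------------------
# behavior & biomarker


def generate_behavior_and_biomarker(profile: ParticipantProfile,
                                    response_score: float,
                                    config: SynthConfig | None = None,
                                    seed: int | None = None):
    """Simulate the 40-item cued-recall trajectory (t0–t7) and the plasma
    Aβ42/40 pre/post ratios for one participant.

    Sessions t1–t4 follow a saturating feedback-driven learning curve; t5–t7
    decay without feedback. The stimulation-response effect on memory is
    expressed at t5/t6 for HC profiles but only at t7 for CI profiles; the
    Aβ42/40 change is ``abeta_slope × response_score`` plus noise.
    """
    if not np.isfinite(response_score):
        raise ValueError("response_score must be finite")
    cfg = config or SynthConfig()
    rng = np.random.default_rng(seed)
    hc = profile.group == "HC"

    s0 = cfg.memory_t0_mean_hc if hc else cfg.memory_t0_mean_ci
    s0 = s0 + rng.normal(0.0, cfg.memory_noise_sd) if cfg.memory_noise_sd else s0
    smax = cfg.memory_asymptote_hc if hc else cfg.memory_asymptote_ci
    r = cfg.memory_learning_rate

    scores = np.empty(8)
    scores[0] = s0
    for k in range(1, 5):  # feedback sessions t1..t4
        scores[k] = s0 + (smax - s0) * (1.0 - np.exp(-r * k))
    f5, f6, f7 = cfg.memory_forget
    scores[5] = scores[4] - f5
    scores[6] = scores[4] - f6
    scores[7] = scores[4] - f7

    effect = profile.memory_slope * response_score
    if hc:
        scores[5] += effect
        scores[6] += effect
    else:
        scores[7] += effect
    if cfg.memory_noise_sd:
        scores[1:] += rng.normal(0.0, cfg.memory_noise_sd, 7)
    scores = np.clip(np.rint(scores), 0, MEMORY_ITEMS).astype(int)
    behav = BehavioralRecord(participant_id=profile.id, scores=scores)

    pre = float(np.clip(rng.normal(cfg.abeta_pre_mean, cfg.abeta_pre_sd),
                        0.005, 0.995))
    diff = profile.abeta_slope * response_score
    if cfg.abeta_noise_sd:
        diff += rng.normal(0.0, cfg.abeta_noise_sd)
    post = float(np.clip(pre + diff, 0.001, 0.999))
    abeta = AbetaRecord(participant_id=profile.id, pre_ratio=pre, post_ratio=post)
    return behav, abeta
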