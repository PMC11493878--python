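"""Online slow-wave peak prediction and phase-locked marker placement.

The online algorithm watches the rising phase of frontal voltage together
with the topographic correlation between the instantaneous scalp map and a
canonical slow-wave-peak template. Over the most recent 120 ms of data it
takes the sign of the first derivative of both series; when the average sign
of EACH series exceeds the criterion (default 0.75) — i.e. both voltage and
template correlation are clearly rising — a peak prediction is scored and a
marker is emitted after a calibrated delay (default 50 ms) so that the
stimulus (a 50-ms pink-noise burst in the real condition) coincides with the
predicted peak. On the baseline night the identical algorithm runs but only
logs sham markers.

Processing is strictly causal: every quantity at sample *t* depends only on
samples in the trailing window (t − 120 ms, t].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from plaslab import layout as _layout
from plaslab.synth import Recording, EPOCH_S


class CalibrationError(RuntimeError):
    """Raised when the stimulus-delay calibration cannot be performed."""


@dataclass
class TemplateMap:
    """Unit-norm canonical topography of a slow-wave peak."""

    weights: np.ndarray          # one scalar per channel, L2 norm 1
    channel_names: list
    frontal_channels: list       # subset used for the voltage criterion

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        n = np.linalg.norm(self.weights)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("template weights must be unit-norm")
        if not self.frontal_channels:
            raise ValueError("frontal_channels must be non-empty")
        missing = set(self.frontal_channels) - set(self.channel_names)
        if missing:
            raise ValueError(f"frontal channels not in layout: {sorted(missing)}")


@dataclass
class DetectorParams:
    window_ms: float = 120.0     # trailing criterion window
    criterion: float = 0.75      # sign-average threshold
    smooth_ms: float = 40.0      # causal moving-average applied to the
                                 # voltage/correlation series before the sign
                                 # criterion (the acquisition chain of the
                                 # real system is bandlimited; raw synthetic
                                 # noise is not)
    delay_ms: float = 50.0       # marker delay after criterion crossing
    stimulus_ms: float = 50.0    # pink-noise burst duration (descriptor only)
    refractory_s: float = 2.5    # lockout so the induced second peak (1–1.5 s
                                 # post-stimulus) cannot retrigger
    gating: tuple = ("N2", "N3")

    def __post_init__(self):
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if not (0 < self.criterion <= 1):
            raise ValueError("criterion must be in (0, 1]")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")


@dataclass
class StimulationMarker:
    time_s: float
    condition: str               # "real" | "sham"
    night: str
    delay_ms: float = 50.0
    lead_series: dict | None = None  # 120-ms voltage/correlation audit traces


@dataclass
class DetectionMetrics:
    n_markers: int
    precision: float
    recall: float
    phase_error_ms: dict         # median / mean / sd of signed offsets
    n_matched: int
    precision_defined: bool = True


# ---------------------------------------------------------------------------


def build_template(channel_names, channel_positions,
                   n_frontal: int = 17) -> TemplateMap:
    """Frontal-positive, posterior-negative gradient map, unit-normalized.

    The published template values live in the original stimulation software;
    this construction (cosine of the angle to the Fz direction) is a
    configurable stand-in with the same qualitative topography.
    """
    pos = np.asarray(channel_positions, float)
    if pos.shape[0] != len(channel_names):
        raise ValueError("positions and channel names disagree")
    w = pos @ _layout.FZ_DIR
    w = w / np.linalg.norm(w)
    frontal = _layout.nearest_channels(channel_names, pos, "Fz", n_frontal)
    return TemplateMap(weights=w, channel_names=list(channel_names),
                       frontal_channels=frontal)


def _stage_sample_mask(hypnogram, stages, rate: float, n_samples: int) -> np.ndarray:
    mask = np.zeros(n_samples, bool)
    spe = int(EPOCH_S * rate)
    for i, st in enumerate(hypnogram):
        if st in stages:
            mask[i * spe:(i + 1) * spe] = True
    return mask


def _criterion_series(rec: Recording, template: TemplateMap, params: DetectorParams):
    """Vectorized trailing-window criterion; identical to the causal
    per-sample loop because every window is half-open (t − 120 ms, t]."""
    data = np.asarray(rec.data, float)
    idx = [ _layout.channel_index(rec.channel_names, ch)
            for ch in template.frontal_channels ]
    v = data[idx].mean(axis=0)

    # Pearson correlation over channels: instantaneous scalp map vs template
    w = template.weights - template.weights.mean()
    wn = np.linalg.norm(w)
    xc = data - data.mean(axis=0, keepdims=True)
    denom = wn * np.linalg.norm(xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (w @ xc) / denom
    c[~np.isfinite(c)] = 0.0

    n_s = int(round(params.smooth_ms / 1000.0 * rec.rate))
    if n_s > 1:
        # causal moving average: output at t uses samples (t − n_s, t]
        box = np.ones(n_s) / n_s
        v = np.convolve(v, box, mode="full")[:len(v)]
        c = np.convolve(c, box, mode="full")[:len(c)]

    n_w = int(round(params.window_ms / 1000.0 * rec.rate))
    if n_w < 3:
        raise ValueError("criterion window must span at least 3 samples")
    n_d = n_w - 1  # sign-of-derivative terms per window
    kern = np.ones(n_d)
    sv = np.convolve(np.sign(np.diff(v)), kern, mode="full")[:len(v) - 1] / n_d
    sc = np.convolve(np.sign(np.diff(c)), kern, mode="full")[:len(c) - 1] / n_d
    # sv[i] averages diffs ending at sample i+1; valid once the window is full
    crossing = np.zeros(len(v), bool)
    ok = (sv > params.criterion) & (sc > params.criterion)
    crossing[n_d:] = ok[n_d - 1:]
    crossing[:n_w] = False
    return crossing, v, c


def detect_stream(rec: Recording, template: TemplateMap,
                  params: DetectorParams | None = None,
                  condition: str = "real",
                  keep_lead_series: bool = False) -> list:
    """Run the online predictor over one recording and place markers.

    Markers are emitted at ``crossing time + delay_ms``, only within gated
    sleep stages, with a refractory lockout after each prediction. Real
    markers are only legal on stimulation nights E1–E3, sham markers only on
    the baseline night.
    """
    params = params or DetectorParams()
    if condition not in ("real", "sham"):
        raise ValueError("condition must be 'real' or 'sham'")
    if condition == "real" and rec.night == "BL":
        raise ValueError("real markers are only placed on nights E1–E3")
    if condition == "sham" and rec.night != "BL":
        raise ValueError("sham markers are only placed on the baseline night")

    gated = _stage_sample_mask(rec.hypnogram, params.gating, rec.rate, rec.n_samples)
    if not gated.any():
        warnings.warn("no samples in gated stages; returning no markers",
                      stacklevel=2)
        return []

    crossing, v, c = _criterion_series(rec, template, params)
    candidates = np.flatnonzero(crossing & gated)

    n_w = int(round(params.window_ms / 1000.0 * rec.rate))
    markers = []
    next_allowed = -np.inf
    for s in candidates:
        t = s / rec.rate
        if t < next_allowed:
            continue
        m_time = t + params.delay_ms / 1000.0
        if m_time >= rec.duration:
            continue
        lead = None
        if keep_lead_series:
            lead = {"voltage": v[s - n_w + 1:s + 1].copy(),
                    "correlation": c[s - n_w + 1:s + 1].copy()}
        markers.append(StimulationMarker(time_s=m_time, condition=condition,
                                         night=rec.night,
                                         delay_ms=params.delay_ms,
                                         lead_series=lead))
        next_allowed = t + params.refractory_s
    return markers


def calibrate_delay(rec: Recording, template: TemplateMap,
                    params: DetectorParams | None = None,
                    truth_events=None, max_lead_s: float = 0.4) -> float:
    """Median lead time (ms) from criterion crossing to the true slow-wave
    peak, clipped to [0, 200] ms — the per-setup stimulus delay.

    ``truth_events`` defaults to the recording's own ground-truth table.
    """
    params = params or DetectorParams()
    ev = truth_events if truth_events is not None else rec.events
    peaks = np.sort(np.asarray(ev[ev["kind"] == "sw_peak"]["time"], float))
    if len(peaks) < 10:
        raise CalibrationError(
            f"calibration needs >= 10 ground-truth peaks, got {len(peaks)}")

    zero_delay = DetectorParams(window_ms=params.window_ms,
                                criterion=params.criterion,
                                smooth_ms=params.smooth_ms, delay_ms=0.0,
                                stimulus_ms=params.stimulus_ms,
                                refractory_s=params.refractory_s,
                                gating=params.gating)
    condition = "sham" if rec.night == "BL" else "real"
    markers = detect_stream(rec, template, zero_delay, condition=condition)
    if not markers:
        raise CalibrationError("no detections on the calibration recording")

    leads = []
    for m in markers:
        i = np.searchsorted(peaks, m.time_s)
        if i < len(peaks) and peaks[i] - m.time_s <= max_lead_s:
            leads.append(peaks[i] - m.time_s)
    if not leads:
        raise CalibrationError("no detection preceded a true peak closely "
                               "enough to estimate the lead time")
    return float(np.clip(np.median(leads) * 1000.0, 0.0, 200.0))


def evaluate_detection(markers, truth_events, tolerance_ms: float) -> DetectionMetrics:
    """Greedy one-to-one matching of markers to the nearest true peaks within
    a tolerance; precision/recall and the signed phase-error distribution."""
    if tolerance_ms <= 0:
        raise ValueError("tolerance must be positive")
    times = np.asarray([m.time_s for m in markers], float)
    if hasattr(truth_events, "columns"):
        truth = np.asarray(
            truth_events[truth_events["kind"] == "sw_peak"]["time"], float)
    else:
        truth = np.asarray(truth_events, float)

    tol = tolerance_ms / 1000.0
    pairs = []
    for i, t in enumerate(times):
        for j, p in enumerate(truth):
            if abs(t - p) <= tol:
                pairs.append((abs(t - p), i, j))
    pairs.sort()
    used_m, used_t, errors = set(), set(), []
    for _, i, j in pairs:
        if i in used_m or j in used_t:
            continue
        used_m.add(i)
        used_t.add(j)
        errors.append((times[i] - truth[j]) * 1000.0)

    n_matched = len(errors)
    precision_defined = len(times) > 0
    precision = n_matched / len(times) if precision_defined else 0.0
    recall = n_matched / len(truth) if len(truth) else 0.0
    err = np.asarray(errors)
    summary = {
        "median": float(np.median(err)) if n_matched else float("nan"),
        "mean": float(err.mean()) if n_matched else float("nan"),
        "sd": float(err.std(ddof=1)) if n_matched > 1 else float("nan"),
        "values": err,
    }
    return DetectionMetrics(n_markers=len(times), precision=precision,
                            recall=recall, phase_error_ms=summary,
                            n_matched=n_matched,
                            precision_defined=precision_defined)
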