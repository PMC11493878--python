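"""Event-related potential analysis around stimulation markers.

Epochs span −1.5 to 3 s around each marker; baseline correction subtracts
each trial-channel's mean over the whole epoch. Experimental nights are
compared with the baseline (sham) night by cluster-based permutation tests,
and the participant's electrophysiological response score is the
stimulation-count-weighted mean, over the three experimental nights, of the
Fz voltage difference (experimental − baseline) averaged over 1–1.5 s
post-stimulus — the window of the induced second slow-wave peak.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from plaslab import layout as _layout
from plaslab.cluster import ClusterResult, cluster_permutation
from plaslab.preprocess import CleanRecording
from plaslab.synth import Recording

DEFAULT_WINDOW = (-1.5, 3.0)
RESPONSE_WINDOW = (1.0, 1.5)
EXPERIMENTAL_NIGHTS = ("E1", "E2", "E3")


class EpochingError(RuntimeError):
    def __init__(self, night, message):
        super().__init__(message)
        self.night = night


@dataclass
class EpochSet:
    epochs: np.ndarray           # (n_trials, n_channels, n_times) µV
    times: np.ndarray            # marker-relative seconds, inclusive ends
    rate: float
    channel_names: list
    night: str
    n_stimulations: int          # trials surviving rejection

    @property
    def window(self):
        return (float(self.times[0]), float(self.times[-1]))


@dataclass
class ErpResult:
    erp: np.ndarray              # (n_channels, n_times) mean voltage
    times: np.ndarray
    channel_names: list
    night: str
    n_stimulations: int


@dataclass
class ResponseScore:
    participant_id: str
    value: float                 # µV (or dB for spectral band scores)
    weights_used: dict           # stimulation counts per experimental night
    units: str = "uV"


def epoch(rec: Recording, markers, window=DEFAULT_WINDOW) -> EpochSet:
    """One trial per marker; both window endpoints are included.

    Markers whose window would be truncated by the recording edges are
    dropped. On a CleanRecording, trials overlapping artifact-masked samples
    are dropped and bad channels are excluded.
    """
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must be increasing")
    n_pre = int(round(-w0 * rec.rate))
    n_post = int(round(w1 * rec.rate))
    times = np.arange(-n_pre, n_post + 1) / rec.rate

    artifact = getattr(rec, "artifact_mask", None)
    if isinstance(rec, CleanRecording):
        ch_idx = rec.good_index()
        names = rec.good_channels
    else:
        ch_idx = np.arange(len(rec.channel_names))
        names = list(rec.channel_names)

    trials = []
    for m in markers:
        c = int(round(m.time_s * rec.rate))
        lo, hi = c - n_pre, c + n_post + 1
        if lo < 0 or hi > rec.n_samples:
            continue
        if artifact is not None and artifact[lo:hi].any():
            continue
        trials.append(rec.data[ch_idx, lo:hi])
    if not trials:
        raise EpochingError(rec.night, f"no surviving trials on night {rec.night}")
    return EpochSet(epochs=np.asarray(trials, float), times=times,
                    rate=rec.rate, channel_names=names, night=rec.night,
                    n_stimulations=len(trials))


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each trial-channel's mean over the full epoch window."""
    corrected = epochs.epochs - epochs.epochs.mean(axis=2, keepdims=True)
    return dataclasses.replace(epochs, epochs=corrected)


def compute_erp(epochs: EpochSet) -> ErpResult:
    """Baseline-corrected trial average."""
    bc = baseline_correct(epochs)
    return ErpResult(erp=bc.epochs.mean(axis=0), times=epochs.times,
                     channel_names=epochs.channel_names, night=epochs.night,
                     n_stimulations=epochs.n_stimulations)


def erp_cluster_test(a: EpochSet, b: EpochSet, *, alpha: float = 0.05,
                     cluster_alpha: float = 0.05, n_perm: int = 1000,
                     channel_adjacency=None, seed=None) -> ClusterResult:
    """Cluster permutation comparison of two epoch sets (trials exchanged),
    on baseline-corrected data, over the channels × time lattice."""
    if a.channel_names != b.channel_names:
        raise ValueError("epoch sets must share the channel set")
    xa = baseline_correct(a).epochs
    xb = baseline_correct(b).epochs
    return cluster_permutation(xa, xb, channel_adjacency=channel_adjacency,
                               alpha=alpha, cluster_alpha=cluster_alpha,
                               n_perm=n_perm, seed=seed)


def erp_response_score(erps: dict, participant_id: str = "",
                       window=RESPONSE_WINDOW, channel: str = "Fz") -> ResponseScore:
    """Weighted mean Fz voltage difference (experimental − baseline night)
    over the induced-second-peak window, weighted by stimulation counts.
    ``erps`` maps night labels BL, E1, E2, E3 to ErpResult."""
    missing = [n for n in ("BL",) + EXPERIMENTAL_NIGHTS if n not in erps]
    if missing:
        raise ValueError(f"missing night(s): {missing}")
    bl = erps["BL"]
    ci = _layout.channel_index(bl.channel_names, channel)
    sel = (bl.times >= window[0]) & (bl.times <= window[1])
    if not sel.any():
        raise ValueError("response window outside the epoch time axis")

    diffs, weights = {}, {}
    for night in EXPERIMENTAL_NIGHTS:
        e = erps[night]
        if e.channel_names != bl.channel_names:
            raise ValueError("nights must share the channel set")
        diffs[night] = float((e.erp[ci, sel] - bl.erp[ci, sel]).mean())
        weights[night] = e.n_stimulations
        if e.n_stimulations <= 0:
            raise ValueError(f"night {night} has no stimulations to weight by")
    total = sum(weights.values())
    value = sum(diffs[n] * weights[n] for n in EXPERIMENTAL_NIGHTS) / total
    return ResponseScore(participant_id=participant_id, value=float(value),
                         weights_used=weights, units="uV")
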