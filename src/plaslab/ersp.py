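"""Time–frequency analysis of stimulation-evoked spectral perturbations.

Morlet-wavelet power over 0.5–20 Hz on −1.5 to 2.5 s epochs, normalized in
dB against the 2–2.5 s window (the quietest part of the epoch), compared
across nights by cluster permutation at p < .01, and reduced to
participant-level scores: band-specific median-power response scores
(stimulation-count-weighted, like the ERP score) and the per-night summed
activity — the sum of absolute dB power ratios (experimental/baseline) over
group-level significant-cluster bins after 1.5-SD outlier exclusion —
whose night trend separates a constant (healthy) from a ramping (impaired)
electrophysiological response.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from mne.time_frequency import tfr_array_morlet

from plaslab import layout as _layout
from plaslab import stats as _stats
from plaslab.cluster import ClusterResult, cluster_permutation
from plaslab.erp import EpochSet, ResponseScore, EXPERIMENTAL_NIGHTS

TFR_TIMES = (-1.5, 2.5)
BASELINE_WINDOW = (2.0, 2.5)
DEFAULT_FREQS = np.arange(0.5, 20.0 + 1e-9, 0.5)
SUMMED_TIME = (0.0, 2.5)
SUMMED_FREQ = (0.0, 16.0)
# support (in seconds) of an mne Morlet wavelet: ±5 sigma_t
_WAVELET_SUPPORT = 10.0 / (2.0 * np.pi)


def default_cycles(freqs) -> np.ndarray:
    """Linearly increasing cycle counts, 1.25 at 0.5 Hz to 7 at 20 Hz —
    short enough that the slowest wavelet fits the −1.5…3 s epoch."""
    freqs = np.asarray(freqs, float)
    return 1.25 + 5.75 * (freqs - 0.5) / 19.5


@dataclass
class TimeFreqMap:
    power: np.ndarray            # (n_channels, n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray            # marker-relative seconds
    channel_names: list
    night: str
    n_stimulations: int
    units: str = "power"         # "power" (µV²) or "dB"
    edge_mask: np.ndarray | None = None   # (n_freqs, n_times) True = edge-contaminated


@dataclass
class BandSpec:
    """A named time–electrode–frequency band for response extraction."""

    name: str
    f_lo: float
    f_hi: float
    t_lo: float
    t_hi: float
    channel_set: list


@dataclass
class SummedActivity:
    participant_id: str
    night: str
    value: float                 # summed |dB| over masked, pruned bins
    n_bins_used: int
    n_bins_excluded: int


def standard_bands(channel_names, channel_positions,
                   peak_window=(0.75, 1.5), beta_window=(-1.5, 0.0)) -> dict:
    """The five canonical bands: sw 0.75–1.5, delta 1–4, theta 4–8,
    spindle 12–16, beta 16–20 Hz. Spindle uses the 13 centroparietal
    channels around Cz; all others the 17 frontal channels around Fz.
    Time windows default to the induced-peak window except beta, which is
    scored pre-stimulus."""
    frontal = _layout.nearest_channels(channel_names, channel_positions, "Fz", 17)
    centroparietal = _layout.nearest_channels(channel_names, channel_positions, "Cz", 13)
    t0, t1 = peak_window
    return {
        "sw": BandSpec("sw", 0.75, 1.5, t0, t1, frontal),
        "delta": BandSpec("delta", 1.0, 4.0, t0, t1, frontal),
        "theta": BandSpec("theta", 4.0, 8.0, t0, t1, frontal),
        "spindle": BandSpec("spindle", 12.0, 16.0, t0, t1, centroparietal),
        "beta": BandSpec("beta", 16.0, 20.0, beta_window[0], beta_window[1], frontal),
    }


def morlet_tfr(epochs: EpochSet, freqs=None, cycles=None,
               t_crop=TFR_TIMES, decim: int = 1) -> TimeFreqMap:
    """Trial-averaged Morlet-wavelet power, cropped to ``t_crop``; bins
    within half a wavelet of the epoch edges are flagged in ``edge_mask``."""
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, float)
    cycles = default_cycles(freqs) if cycles is None else np.asarray(cycles, float)
    epoch_len = epochs.times[-1] - epochs.times[0]
    support = _WAVELET_SUPPORT * cycles / freqs
    too_slow = support >= epoch_len
    if too_slow.any():
        raise ValueError(
            f"frequencies {freqs[too_slow]} are unresolvable: wavelet longer "
            f"than the {epoch_len:.2f}-s epoch")

    power = tfr_array_morlet(epochs.epochs, sfreq=epochs.rate, freqs=freqs,
                             n_cycles=cycles, output="avg_power",
                             zero_mean=True, verbose="error")
    times = epochs.times.copy()
    if decim > 1:
        power = power[..., ::decim]
        times = times[::decim]
    sel = (times >= t_crop[0] - 1e-9) & (times <= t_crop[1] + 1e-9)
    power = power[..., sel]
    times = times[sel]

    half = support[:, None] / 2.0
    edge = ((times[None, :] - epochs.times[0] < half)
            | (epochs.times[-1] - times[None, :] < half))
    return TimeFreqMap(power=power, freqs=freqs, times=times,
                       channel_names=list(epochs.channel_names),
                       night=epochs.night, n_stimulations=epochs.n_stimulations,
                       units="power", edge_mask=edge)


def baseline_db(tfr: TimeFreqMap, window=BASELINE_WINDOW) -> TimeFreqMap:
    """10·log10(power / mean power in the baseline window), per
    channel × frequency."""
    if tfr.units != "power":
        raise ValueError("baseline_db expects linear power input")
    sel = (tfr.times >= window[0] - 1e-9) & (tfr.times <= window[1] + 1e-9)
    if not sel.any():
        raise ValueError("baseline window outside the time axis")
    base = tfr.power[..., sel].mean(axis=-1, keepdims=True)
    if (base <= 0).any():
        raise ValueError("zero baseline power: degenerate input")
    return dataclasses.replace(
        tfr, power=10.0 * np.log10(tfr.power / base), units="dB")


def tfr_cluster(a, b, *, alpha: float = 0.01, cluster_alpha: float = 0.05,
                n_perm: int = 1000, channel_adjacency=None,
                seed=None) -> ClusterResult:
    """Cluster permutation over the channels × frequency × time lattice.
    ``a``/``b`` are stacks (n_obs, n_ch, n_freqs, n_times) or lists of
    TimeFreqMap (one observation each)."""
    def as_stack(x):
        if isinstance(x, np.ndarray):
            return x
        return np.stack([m.power for m in x])
    return cluster_permutation(as_stack(a), as_stack(b),
                               channel_adjacency=channel_adjacency,
                               alpha=alpha, cluster_alpha=cluster_alpha,
                               n_perm=n_perm, seed=seed)


def significant_channel_fraction(result: ClusterResult,
                                 n_good_channels: int | None = None) -> np.ndarray:
    """Per time–frequency bin, the fraction of channels belonging to any
    significant cluster."""
    mask = result.significant_mask()          # (n_ch, n_freqs, n_times)
    n_ch = n_good_channels or mask.shape[0]
    return mask.sum(axis=0) / float(n_ch)


def band_response_score(tfrs: dict, band: BandSpec,
                        participant_id: str = "") -> ResponseScore:
    """Stimulation-count-weighted mean, over experimental nights, of the
    band's median dB power minus the baseline night's median. ``tfrs`` maps
    night labels to dB-unit TimeFreqMap."""
    missing = [n for n in ("BL",) + EXPERIMENTAL_NIGHTS if n not in tfrs]
    if missing:
        raise ValueError(f"missing night(s): {missing}")

    def band_median(tfr: TimeFreqMap) -> float:
        if tfr.units != "dB":
            raise ValueError("band scores are computed on dB maps")
        ch = [i for i, c in enumerate(tfr.channel_names) if c in set(band.channel_set)]
        fs = (tfr.freqs >= band.f_lo - 1e-9) & (tfr.freqs <= band.f_hi + 1e-9)
        ts = (tfr.times >= band.t_lo - 1e-9) & (tfr.times <= band.t_hi + 1e-9)
        if not ch or not fs.any() or not ts.any():
            raise ValueError(f"band {band.name!r} selects no bins")
        return float(np.median(tfr.power[np.ix_(ch, np.flatnonzero(fs),
                                                np.flatnonzero(ts))]))

    bl = band_median(tfrs["BL"])
    diffs, weights = {}, {}
    for night in EXPERIMENTAL_NIGHTS:
        diffs[night] = band_median(tfrs[night]) - bl
        weights[night] = tfrs[night].n_stimulations
        if weights[night] <= 0:
            raise ValueError(f"night {night} has no stimulations to weight by")
    total = sum(weights.values())
    value = sum(diffs[n] * weights[n] for n in EXPERIMENTAL_NIGHTS) / total
    return ResponseScore(participant_id=participant_id, value=float(value),
                         weights_used=weights, units="dB")


def summed_activity(tfr_exp: TimeFreqMap, tfr_bl: TimeFreqMap, mask,
                    night: str, participant_id: str = "",
                    t_range=SUMMED_TIME, f_range=SUMMED_FREQ,
                    exclusion_sd: float = 1.5,
                    symmetric: bool = False) -> SummedActivity:
    """Summed |dB| power ratio (experimental / baseline) over the masked
    bins, after restricting the mask to the post-stimulation window and
    0–16 Hz and pruning outlier bins.

    Per masked bin v = |10·log10(P_exp / P_bl)|; bins with
    v > mean(v) + ``exclusion_sd``·SD(v) (computed over this
    participant-night's masked bins, sample SD) are excluded; with
    ``symmetric=True`` the lower tail is excluded too. The remaining bins
    are summed — capturing both the height and the extent of the induced
    spectral perturbation.
    """
    if tfr_exp.units != "power" or tfr_bl.units != "power":
        raise ValueError("summed_activity expects linear power maps")
    mask = np.asarray(mask, bool)
    if mask.shape != tfr_exp.power.shape:
        mask = np.broadcast_to(mask, tfr_exp.power.shape)
    ts = (tfr_exp.times >= t_range[0] - 1e-9) & (tfr_exp.times <= t_range[1] + 1e-9)
    fs = (tfr_exp.freqs >= f_range[0] - 1e-9) & (tfr_exp.freqs <= f_range[1] + 1e-9)
    restricted = mask & fs[None, :, None] & ts[None, None, :]
    n_mask = int(restricted.sum())
    if n_mask == 0:
        warnings.warn("empty restricted mask: summed activity is 0", stacklevel=2)
        return SummedActivity(participant_id, night, 0.0, 0, 0)

    with np.errstate(divide="ignore"):
        v = np.abs(10.0 * np.log10(tfr_exp.power[restricted]
                                   / tfr_bl.power[restricted]))
    if n_mask > 1:
        mu, sd = v.mean(), v.std(ddof=1)
        keep = v <= mu + exclusion_sd * sd
        if symmetric:
            keep &= v >= mu - exclusion_sd * sd
    else:
        keep = np.ones(1, bool)
    return SummedActivity(participant_id=participant_id, night=night,
                          value=float(v[keep].sum()),
                          n_bins_used=int(keep.sum()),
                          n_bins_excluded=int(n_mask - keep.sum()))


def night_trend_and_group_tests(table: pd.DataFrame) -> dict:
    """Night trends of summed activity per group, plus per-night group tests.

    ``table`` columns: participant_id, group (HC/CI), night (E1..E3), value.
    Per group: OLS of value on the night index (E1=1 … E3=3), pooling
    participants. Per night: pooled-variance two-sample t between groups.
    """
    night_code = {n: i + 1 for i, n in enumerate(EXPERIMENTAL_NIGHTS)}
    df = table.copy()
    df["night_idx"] = df["night"].map(night_code)
    if df["night_idx"].isna().any():
        raise ValueError("nights must be E1, E2 or E3")

    trends = {}
    for group, sub in df.groupby("group"):
        if sub["participant_id"].nunique() < 2:
            raise ValueError(f"group {group} has fewer than 2 participants")
        fit = _stats.ols_fit(sub["value"].to_numpy(),
                             {"night": sub["night_idx"].to_numpy()},
                             formula=f"value ~ night [{group}]")
        trends[group] = fit

    groups = sorted(df["group"].unique())
    per_night = {}
    if len(groups) == 2:
        g1, g2 = groups
        for night in EXPERIMENTAL_NIGHTS:
            x = df[(df["group"] == g1) & (df["night"] == night)]["value"].to_numpy()
            y = df[(df["group"] == g2) & (df["night"] == night)]["value"].to_numpy()
            try:
                per_night[night] = _stats.two_sample_t(x, y)
            except ValueError:
                # degenerate (zero-variance) values: no evidence either way
                per_night[night] = _stats.TTestResult(t=0.0,
                                                      df=len(x) + len(y) - 2,
                                                      p=1.0)
    return {"trends": trends, "group_tests": per_night,
            "group_order": tuple(groups)}
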