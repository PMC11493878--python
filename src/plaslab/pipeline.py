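"""End-to-end orchestration: simulate → detect → quantify → tabulate.

Two granularities are provided:

* the full EEG chain (``run_participant_eeg``): synthesize each night,
  run the online detector (sham on the baseline night, real on E1–E3),
  inject the evoked responses the real stimulations produce, preprocess,
  epoch and score — used for integration checks at desk-scale night
  durations;
* latent-level cohorts (``latent_cohort_table``,
  ``simulate_summed_activity_table``): draw the participant-level response
  scores and their downstream observables directly from the profiles'
  latent parameters — used for the calibration and power studies where
  hundreds of replicate cohorts are needed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from plaslab import detector as _det
from plaslab import erp as _erp
from plaslab import ersp as _ersp
from plaslab import preprocess as _pre
from plaslab import synth as _synth

NIGHTS = _synth.NIGHTS
E_NIGHTS = _erp.EXPERIMENTAL_NIGHTS


def simulate_participant_night(profile, night, duration_min, config=None,
                               seed=None, params=None):
    """One closed-loop night: synthesize, detect markers (sham on BL, real
    otherwise), inject the evoked response for real stimulations.

    Returns (recording with evoked responses, markers).
    """
    cfg = config or _synth.SynthConfig()
    rec = _synth.generate_night(profile, night, duration_min, cfg, seed)
    template = _det.build_template(rec.channel_names, rec.channel_positions)
    condition = "sham" if night == "BL" else "real"
    markers = _det.detect_stream(rec, template, params, condition=condition)
    if condition == "real":
        rec = _synth.inject_evoked_response(rec, markers, profile, cfg)
    return rec, markers


def run_participant_eeg(profile, duration_min=20.0, config=None, seed=0,
                        params=None, compute_tfr=False, tfr_freqs=None):
    """Full chain for one participant across the four nights.

    Returns a dict with per-night markers, epoch sets, ERPs, the ERP
    response score, and (optionally) dB time–frequency maps.
    """
    cfg = config or _synth.SynthConfig()
    ss = np.random.SeedSequence(seed)
    night_seeds = {n: int(s.generate_state(1)[0] % (2**31))
                   for n, s in zip(NIGHTS, ss.spawn(len(NIGHTS)))}

    out = {"markers": {}, "epochs": {}, "erps": {}, "tfrs": {}}
    for night in NIGHTS:
        rec, markers = simulate_participant_night(
            profile, night, duration_min, cfg, night_seeds[night], params)
        clean = _pre.reject_artifacts(rec)
        ep = _erp.epoch(clean, markers)
        out["markers"][night] = markers
        out["epochs"][night] = ep
        out["erps"][night] = _erp.compute_erp(ep)
        if compute_tfr:
            tfr = _ersp.morlet_tfr(ep, freqs=tfr_freqs)
            out["tfrs"][night] = tfr
    out["response_score"] = _erp.erp_response_score(out["erps"], profile.id)
    return out


# ---------------------------------------------------------------------------
# latent-level cohorts


def latent_response_scores(profiles, config=None, seed=None,
                           noise_sd: float = 0.8) -> np.ndarray:
    """Participant ERP response scores drawn at the latent level: the
    stimulation-weighted night-gain mean times responsiveness times the
    configured evoked amplitude, plus measurement noise (µV)."""
    cfg = config or _synth.SynthConfig()
    rng = np.random.default_rng(seed)
    scores = np.array([p.responsiveness * np.mean(p.night_gain)
                       * cfg.evoked_peak_uv for p in profiles])
    if noise_sd:
        scores = scores + rng.normal(0.0, noise_sd, len(profiles))
    return scores


def latent_cohort_table(profiles, config=None, seed=None,
                        noise_sd: float = 0.8) -> pd.DataFrame:
    """ParticipantTable built from latent response scores, behavioral
    trajectories, and biomarkers. One row per participant with the
    documented column set (see README)."""
    cfg = config or _synth.SynthConfig()
    ss = np.random.SeedSequence(seed)
    score_seed, *part_seeds = ss.spawn(len(profiles) + 1)
    scores = latent_response_scores(
        profiles, cfg, int(score_seed.generate_state(1)[0] % (2**31)), noise_sd)

    rows = []
    for p, score, s in zip(profiles, scores, part_seeds):
        behav, abeta = _synth.generate_behavior_and_biomarker(
            p, float(score), cfg, int(s.generate_state(1)[0] % (2**31)))
        row = {"participant_id": p.id, "group": p.group, "age": p.age,
               "gender": p.gender, "moca": p.moca,
               "response_score_erp": float(score),
               "abeta_pre": abeta.pre_ratio, "abeta_post": abeta.post_ratio,
               "abeta_diff": abeta.diff}
        for k, g in enumerate(behav.gains, start=1):
            row[f"gain_t{k}"] = int(g)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_summed_activity_table(profiles, config=None, seed=None,
                                   shape=(6, 8, 12), db_scale: float = 2.0,
                                   noise_db: float = 1.0) -> pd.DataFrame:
    """Per participant-night summed activity from compact time–frequency
    maps whose masked-bin power ratio reflects the profile's night gain.

    Each participant-night gets a baseline and an experimental power map on
    a small (channels × frequencies × times) grid inside the 0–16 Hz /
    0–2.5 s summed-activity region; masked bins of the experimental map are
    scaled by ``responsiveness × night_gain × db_scale`` dB plus noise, and
    the actual :func:`plaslab.ersp.summed_activity` statistic is computed.
    """
    cfg = config or _synth.SynthConfig()
    rng = np.random.default_rng(seed)
    n_ch, n_f, n_t = shape
    freqs = np.linspace(1.0, 15.0, n_f)
    times = np.linspace(0.1, 2.4, n_t)
    names = [f"E{i + 1:03d}" for i in range(n_ch)]
    mask = np.zeros(shape, bool)
    mask[: max(1, n_ch // 2), : max(1, n_f // 2), : max(1, n_t // 2)] = True

    def tfr(power, night, n_stim):
        return _ersp.TimeFreqMap(power=power, freqs=freqs, times=times,
                                 channel_names=names, night=night,
                                 n_stimulations=n_stim, units="power")

    rows = []
    for p in profiles:
        for night in E_NIGHTS:
            base = np.exp(rng.normal(0.0, 0.2, shape))
            db = rng.normal(0.0, noise_db, shape)
            db[mask] += (p.responsiveness * _synth.night_gain(p, night)
                         * db_scale)
            exp_power = base * 10.0 ** (db / 10.0)
            sa = _ersp.summed_activity(tfr(exp_power, night, 100),
                                       tfr(base, "BL", 100), mask, night,
                                       participant_id=p.id)
            rows.append({"participant_id": p.id, "group": p.group,
                         "night": night, "value": sa.value,
                         "n_bins_used": sa.n_bins_used})
    return pd.DataFrame(rows)
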