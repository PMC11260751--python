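"""End-to-end cohort analysis: simulate, preprocess, measure, model, infer.

One call to :func:`analyze_cohort` reproduces the full study design on a
synthetic cohort: two-channel click (ABR) and 100 Hz click-train (FFR)
recordings at five gaze positions, channel-subtraction PAM isolation,
amplitude/latency metrics, the convolution model scored at maximal gaze,
and the correlation / regression / mediation battery on the subject x
gaze metrics table.

For full-size runs (2 000 sweeps per condition) the ensemble averages are
synthesized directly (see :func:`pamffr.cohort.synth_average`); sweep
matrices with amplitude rejection are exercised by the unit tests and
available through :func:`pamffr.cohort.synth_sweeps`.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from . import stats as pstats
from .cohort import (
    DEFAULT_EFFECTS,
    GAZE_ANGLES,
    Cohort,
    EffectStructure,
    GazeCondition,
    sample_cohort,
    synth_average,
)
from .conv_model import cohort_model_fit
from .metrics import (
    FFR_ONSET_WINDOW,
    FFR_RMS_WINDOW,
    PAM_WINDOW,
    onset_latency,
    peak_to_peak,
    rms_amplitude,
    spectrum_amplitude,
)
from .preprocess import AveragedResponse, bandpass_notch, isolate_pam
from .stimgen import StimSpec

__all__ = ["cohort_recordings", "build_metrics", "analyze_cohort",
           "mastoid_rows", "aggregated_rows"]

RecordingKey = Tuple[str, str, int, str]  # (subject_id, stimulus, position, channel)


def cohort_recordings(cohort: Cohort, n_sweeps: int = 2000,
                      stimuli: Iterable = ("click", 100.0),
                      channels: Tuple[str, ...] = ("mastoid", "c7"),
                      positions: Optional[Iterable[int]] = None,
                      apply_filter: bool = True) -> Dict[RecordingKey, AveragedResponse]:
    """Simulate and average every condition of the recording protocol.

    ``stimuli`` mixes the literal ``"click"`` with click-train fundamentals
    in Hz.  Noise streams are derived deterministically from the cohort
    seed and the condition indices, so identical cohorts yield identical
    recordings.
    """
    if positions is None:
        positions = sorted(GAZE_ANGLES)
    out: Dict[RecordingKey, AveragedResponse] = {}
    for si, prof in enumerate(cohort.subjects):
        for sj, stim in enumerate(stimuli):
            stim_obj = stim if stim == "click" else StimSpec(f0=float(stim))
            stim_name = "click" if stim == "click" else f"ffr{int(stim)}"
            for pos in positions:
                for ci, chan in enumerate(channels):
                    rng = np.random.default_rng(
                        [cohort.seed & 0x7FFFFFFF, 101 + si, 7 + sj, pos, ci]
                    )
                    avg = synth_average(prof, stim_obj, GazeCondition(pos), chan,
                                        n_sweeps, rng, cohort.structure)
                    if apply_filter:
                        avg.waveform = bandpass_notch(avg.waveform)
                    out[(prof.subject_id, stim_name, pos, chan)] = avg
    return out


def build_metrics(recordings: Dict[RecordingKey, AveragedResponse],
                  cohort: Cohort, f0: float = 100.0) -> pd.DataFrame:
    """Tidy metrics table: one row per subject x gaze x channel.

    PAM peak-to-peak and latency come from the channel-subtracted click
    recordings (and are therefore identical for both channel rows); FFR
    rms, onset latency and F0-bin amplitude are per channel.
    """
    stim_name = f"ffr{int(f0)}"
    rows = []
    for prof in cohort.subjects:
        sid = prof.subject_id
        for pos in sorted(GAZE_ANGLES):
            pam_p2p = pam_lat = None
            km = (sid, "click", pos, "mastoid")
            kc = (sid, "click", pos, "c7")
            if km in recordings and kc in recordings:
                diff = isolate_pam(recordings[km], recordings[kc])
                pam_p2p = peak_to_peak(diff, PAM_WINDOW)
                pam_lat = onset_latency(diff, PAM_WINDOW)
            for chan in ("mastoid", "c7"):
                key = (sid, stim_name, pos, chan)
                if key not in recordings:
                    continue
                w = recordings[key].waveform
                rows.append({
                    "subject_id": sid,
                    "position": pos,
                    "angle": GAZE_ANGLES[pos],
                    "channel": chan,
                    "f0": f0,
                    "music_years": prof.music_years,
                    "pam_p2p": pam_p2p,
                    "pam_latency": pam_lat,
                    "ffr_rms": rms_amplitude(w, FFR_RMS_WINDOW),
                    "ffr_onset_latency": onset_latency(w, FFR_ONSET_WINDOW),
                    "f0_amp": spectrum_amplitude(w, f0, FFR_RMS_WINDOW),
                })
    return pd.DataFrame(rows)


def mastoid_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Subject x gaze observation rows used for the inferential battery."""
    return table[table["channel"] == "mastoid"].reset_index(drop=True)


def aggregated_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Observation rows for the correlation/regression/mediation battery.

    Mastoid FFR amplitude varies across the five gaze rows of each
    subject, while the PAM size measure is the subject-level one: the
    isolated-PAM peak-to-peak from the click run at maximal ipsilateral
    gaze (the condition the artifact is defined and measured in).
    """
    rows = mastoid_rows(table)
    ref = rows[rows["position"] == 5].set_index("subject_id")["pam_p2p"]
    rows = rows.copy()
    rows["pam_p2p"] = rows["subject_id"].map(ref)
    return rows


def analyze_cohort(seed: int, structure: EffectStructure = DEFAULT_EFFECTS,
                   n_subjects: int = 20, n_sweeps: int = 2000,
                   n_boot: int = 1000, f0: float = 100.0,
                   run_mediation: bool = True) -> dict:
    """Full pipeline on one seeded cohort; returns a summary dictionary.

    Keys of the returned dict (cohort-level scalars unless noted):

    - ``mean_pam_p2p_g5``: mean isolated-PAM peak-to-peak at maximal gaze (μV)
    - ``r_pam_ffr_g5``: Pearson r, PAM p2p vs mastoid FFR rms at gaze 5
    - ``model_mean_r`` / ``model_sd_r`` / ``model_mean_r2``: convolution-model
      cross-correlation summary at gaze 5
    - ``ratio_mastoid`` / ``ratio_c7``: mean FFR rms at ±70° over midline
    - ``r_music_ffr``, ``partial_pam_ffr``, ``partial_music_ffr``: simple and
      partial correlations on the aggregated subject x gaze rows
    - ``sobel_z``, ``sobel_p``, ``boot_ci``, ``mediation_label``
    - ``max_vif``, ``quad_t_mastoid``, ``quad_p_mastoid``, ``quad_p_c7``
    - ``metrics`` (DataFrame), ``model_fits`` (DataFrame)
    """
    cohort = sample_cohort(n_subjects, structure, seed)
    recordings = cohort_recordings(cohort, n_sweeps=n_sweeps, stimuli=("click", f0))
    table = build_metrics(recordings, cohort, f0=f0)
    rows = aggregated_rows(table)
    g5 = mastoid_rows(table).query("position == 5")

    stim_name = f"ffr{int(f0)}"
    abr_src = {s.subject_id: recordings[(s.subject_id, "click", 5, "mastoid")]
               for s in cohort.subjects}
    ffr_meas = {s.subject_id: recordings[(s.subject_id, stim_name, 5, "mastoid")]
                for s in cohort.subjects}
    fits = cohort_model_fit(abr_src, ffr_meas, StimSpec(f0=f0))

    def _gaze_ratio(channel: str) -> float:
        ch = table[table["channel"] == channel]
        extreme = ch[ch["position"].isin([1, 5])]["ffr_rms"].mean()
        mid = ch[ch["position"] == 3]["ffr_rms"].mean()
        return float(extreme / mid)

    r_g5, _ = pstats.correlate(g5, "pam_p2p", "ffr_rms")
    r_music, p_music = pstats.correlate(rows, "music_years", "ffr_rms")
    pr_pam, p_pr_pam = pstats.partial_correlation(rows, "pam_p2p", "ffr_rms", "music_years")
    pr_music, p_pr_music = pstats.partial_correlation(rows, "music_years", "ffr_rms", "pam_p2p")
    reg = pstats.fit_regression(rows)
    lin_m, quad_m = pstats.gaze_contrasts(table, "mastoid")
    lin_c, quad_c = pstats.gaze_contrasts(table, "c7")

    out = {
        "seed": seed,
        "n_subjects": n_subjects,
        "mean_pam_p2p_g5": float(g5["pam_p2p"].mean()),
        "pam_latency_g5": float(g5["pam_latency"].mean()),
        "r_pam_ffr_g5": r_g5,
        "model_mean_r": float(fits["r"].mean()),
        "model_sd_r": float(fits["r"].std()),
        "model_mean_r2": float(fits["r_squared"].mean()),
        "ratio_mastoid": _gaze_ratio("mastoid"),
        "ratio_c7": _gaze_ratio("c7"),
        "r_music_ffr": r_music,
        "p_music_ffr": p_music,
        "partial_pam_ffr": pr_pam,
        "partial_music_ffr": pr_music,
        "max_vif": float(max(reg.vif.values())),
        "f_interaction": reg.f_interaction,
        "quad_t_mastoid": quad_m.t_statistic,
        "quad_p_mastoid": quad_m.p_value,
        "lin_p_mastoid": lin_m.p_value,
        "quad_p_c7": quad_c.p_value,
        "lin_p_c7": lin_c.p_value,
        "metrics": table,
        "model_fits": fits,
    }
    if run_mediation:
        med = pstats.mediate(rows, "music_years", "pam_p2p", "ffr_rms",
                             n_boot=n_boot, seed=seed)
        out.update({
            "sobel_z": med.sobel_z,
            "sobel_p": med.sobel_p,
            "boot_ci": med.ci,
            "mediation_label": med.label,
            "mediation": med,
        })
    return out
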