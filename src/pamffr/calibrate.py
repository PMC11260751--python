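"""Calibration of the shipped generator defaults.

The study's observed cohort statistics (PAM amplitude mean, PAM–FFR
coupling, gaze amplification, convolution-model fit, mediation paths) are
*outputs* of the recording-and-analysis chain, not generative parameters.
The generator therefore exposes an :class:`~pamffr.cohort.EffectStructure`
whose numeric defaults were fixed once by the seeded search implemented
here: candidate structures are pushed through the *full* pipeline on a
handful of seeds and scored against the target statistics; the structure
is refined by coordinate steps until every target is inside its band.
The winning values are frozen as the dataclass defaults and are not
re-tuned afterwards.

Run via ``pamffr calibrate`` (slow; development tool).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np

from .cohort import DEFAULT_EFFECTS, EffectStructure
from .pipeline import analyze_cohort

__all__ = ["TARGETS", "evaluate_structure", "coordinate_search"]

#: Cohort statistics the defaults must reproduce: name -> (target, tolerance).
#: ``ratio_mastoid`` is a lower bound (3–4x amplification at extreme gaze).
TARGETS: Dict[str, Tuple[float, float]] = {
    "mean_pam_p2p_g5": (2.38, 0.15),
    "r_pam_ffr_g5": (0.72, 0.05),
    "model_mean_r": (0.71, 0.05),
    "model_mean_r2": (0.504, 0.05),
    "ratio_mastoid": (3.5, 0.5),
    "partial_pam_ffr": (0.49, 0.05),
    "partial_music_ffr": (0.21, 0.05),
    "r_music_ffr": (0.34, 0.05),
    "sobel_z": (2.72, 0.5),
}

_STAT_KEYS = tuple(TARGETS) + ("ratio_c7", "max_vif", "model_sd_r")


def evaluate_structure(structure: EffectStructure,
                       seeds: Sequence[int] = (1, 2, 3),
                       n_subjects: int = 20) -> Dict[str, float]:
    """Seed-averaged pipeline statistics for one candidate structure."""
    acc: Dict[str, list] = {k: [] for k in _STAT_KEYS}
    for seed in seeds:
        res = analyze_cohort(seed, structure, n_subjects=n_subjects, n_boot=200)
        for k in _STAT_KEYS:
            acc[k].append(res[k])
    return {k: float(np.mean(v)) for k, v in acc.items()}


def _loss(stats: Dict[str, float]) -> float:
    total = 0.0
    for k, (target, tol) in TARGETS.items():
        err = stats[k] - target
        if k == "ratio_mastoid" and err > 0:
            err = 0.0  # amplification is a lower bound
        total += (err / tol) ** 2
    return total


def coordinate_search(start: EffectStructure = DEFAULT_EFFECTS,
                      seeds: Sequence[int] = (1, 2, 3),
                      n_rounds: int = 2,
                      verbose: bool = True) -> Tuple[EffectStructure, Dict[str, float]]:
    """Greedy coordinate descent over the calibratable fields.

    Each round perturbs one field at a time by a multiplicative step and
    keeps the best candidate under the squared-relative-error loss against
    :data:`TARGETS`.  Deliberately simple: the search space is smooth and
    the defaults only need to land inside the target bands.
    """
    fields = ("log_pam_mu", "pam_state_sd", "noise_sd", "snr_neural_pam",
              "gaze_floor", "a_music_pam", "b_music_neural", "neural_gain_sigma")
    best = start
    best_stats = evaluate_structure(best, seeds)
    best_loss = _loss(best_stats)
    if verbose:
        print(f"start loss={best_loss:.2f} {best_stats}")
    for rnd in range(n_rounds):
        for f in fields:
            cur = getattr(best, f)
            for mult in (0.85, 1.18):
                cand_val = cur * mult
                if f in ("a_music_pam", "b_music_neural") and abs(cand_val) >= 1:
                    continue
                cand = replace(best, **{f: cand_val})
                stats = evaluate_structure(cand, seeds)
                loss = _loss(stats)
                if verbose:
                    print(f"  {f}={cand_val:.3f} loss={loss:.2f}")
                if loss < best_loss:
                    best, best_stats, best_loss = cand, stats, loss
        if verbose:
            print(f"round {rnd + 1}: loss={best_loss:.2f} {best}")
    return best, best_stats
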