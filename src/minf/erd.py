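"""Event-related desynchronization (ERD) quantification.

ERD% is the classical power-ratio measure: samples are squared, averaged
across trials (power averaging FIRST, then the relative change — the order
matters on heteroscedastic data), optionally smoothed with a short moving
average, and expressed as relative change against the mean power R of a
pre-MI reference interval:

    ERD(t) = (A(t) - R) / R * 100,   R = mean of A over the reference.

Negative values indicate desynchronization. Block summaries average the
timecourse over the MI interval; the NF summary pools NF1 and NF2 trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from minf.preprocessing import EpochSet, concat_epochs

REFERENCE_INTERVAL = (-6.0, -4.0)
MI_SUMMARY_WINDOW = (0.5, 4.5)
SMOOTH_S = 0.25


@dataclass
class ERDTimecourse:
    times: np.ndarray              # s relative to MI onset
    values: np.ndarray             # relative power change, %
    laterality: str                # 'contra' | 'ipsi'
    hand_pooled: bool
    run: str
    block: int
    n_trials: int
    fs: float

    def mean_over(self, window: tuple[float, float]) -> float:
        m = (self.times >= window[0]) & (self.times < window[1])
        return float(self.values[m].mean())


@dataclass
class ERDBlockSummary:
    participant: str
    group: str
    block: int
    T_MI_ERD: float                # mean % over MI interval, training run
    NF_MI_ERD: float               # mean % over MI interval, NF1+NF2 pooled
    baseline_power: float          # mean reference-interval power (NF runs)


def compute_erd(ep: EpochSet, reference: tuple[float, float] = REFERENCE_INTERVAL,
                smooth: float = SMOOTH_S, laterality: str = "contra",
                run: str = "", block: int = 0,
                hand_pooled: bool = False) -> ERDTimecourse:
    """Relative power timecourse of a (CSP-projected) epoch set.

    Rejected trials never enter the average. ``smooth`` is the moving-average
    width in seconds (0 disables smoothing).
    """
    kept = ep.select(ep.kept)
    if kept.n_trials == 0:
        raise ValueError("no usable trials")
    power = (kept.data**2).mean(axis=0)       # channels x samples
    a = power.mean(axis=0) if power.ndim == 2 else power
    if smooth > 0:
        w = max(int(round(smooth * ep.fs)), 1)
        a = uniform_filter1d(a, size=w, mode="nearest")
    sl = ep.sample_slice(reference)
    r = a[sl].mean()
    if r <= 0:
        raise ValueError("reference power is zero; ERD undefined")
    return ERDTimecourse(
        times=ep.times.copy(),
        values=(a - r) / r * 100.0,
        laterality=laterality,
        hand_pooled=hand_pooled,
        run=run,
        block=block,
        n_trials=int(kept.n_trials),
        fs=ep.fs,
    )


def average_contralateral(left_tc: ERDTimecourse,
                          right_tc: ERDTimecourse) -> ERDTimecourse:
    """Pointwise unweighted mean of the two hands' contralateral ERD."""
    if not np.allclose(left_tc.times, right_tc.times):
        raise ValueError("time axes differ")
    if left_tc.laterality != right_tc.laterality:
        raise ValueError("lateralities differ")
    return ERDTimecourse(
        times=left_tc.times.copy(),
        values=(left_tc.values + right_tc.values) / 2.0,
        laterality=left_tc.laterality,
        hand_pooled=True,
        run=left_tc.run,
        block=left_tc.block,
        n_trials=left_tc.n_trials + right_tc.n_trials,
        fs=left_tc.fs,
    )


def summarize_block(tcs: dict, participant: str = "", group: str = "",
                    block: int = 0,
                    mi_window: tuple[float, float] = MI_SUMMARY_WINDOW,
                    baseline_power_value: float = np.nan) -> ERDBlockSummary:
    """Scalar T- and NF-MI-ERD for one block.

    ``tcs`` maps run name to ERDTimecourse and must contain 'T' and either a
    pooled 'NF' timecourse or both 'NF1' and 'NF2' (then combined as the
    trial-count-weighted mean, i.e. NF trials pooled before averaging).
    """
    missing = [r for r in ("T",) if r not in tcs]
    if "NF" not in tcs:
        missing += [r for r in ("NF1", "NF2") if r not in tcs]
    if missing:
        raise ValueError(f"missing run(s) for block summary: {missing}")
    t_val = tcs["T"].mean_over(mi_window)
    if "NF" in tcs:
        nf_val = tcs["NF"].mean_over(mi_window)
    else:
        n1, n2 = tcs["NF1"].n_trials, tcs["NF2"].n_trials
        nf_val = (n1 * tcs["NF1"].mean_over(mi_window)
                  + n2 * tcs["NF2"].mean_over(mi_window)) / (n1 + n2)
    return ERDBlockSummary(
        participant=participant,
        group=group,
        block=block,
        T_MI_ERD=t_val,
        NF_MI_ERD=nf_val,
        baseline_power=float(baseline_power_value),
    )


def baseline_power(ep: EpochSet,
                   interval: tuple[float, float] = REFERENCE_INTERVAL) -> float:
    """Mean squared amplitude over the reference interval, trials pooled.

    Pass the concatenated NF1+NF2 epochs to obtain the single per-block
    baseline measure.
    """
    kept = ep.select(ep.kept)
    if kept.n_trials == 0:
        raise ValueError("no usable trials")
    sl = ep.sample_slice(interval)
    return float((kept.data[:, :, sl] ** 2).mean())


def summaries_to_frame(summaries: list[ERDBlockSummary]) -> pd.DataFrame:
    """Long-format table: one row per participant x block."""
    return pd.DataFrame(
        [dict(participant=s.participant, group=s.group, block=s.block,
              T_MI_ERD=s.T_MI_ERD, NF_MI_ERD=s.NF_MI_ERD,
              baseline_power=s.baseline_power)
         for s in summaries]
    ).sort_values(["participant", "block"], ignore_index=True)


def pooled_nf_epochs(nf1: EpochSet, nf2: EpochSet) -> EpochSet:
    """NF1+NF2 trials as one epoch set (for pooled ERD and baseline power)."""
    return concat_epochs([nf1, nf2])
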