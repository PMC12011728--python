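"""Synthetic sensorimotor EEG with a controllable, lateralized ERD.

Emulates a motor-imagery neurofeedback acquisition: 64 channels at 500 Hz,
trials of 5-s baseline, 3-s cue and 5-s motor-imagery (MI) interval separated
by a 0-4 s uniform inter-trial interval, three runs (T, NF1, NF2) per block.
During each MI interval the contralateral sensorimotor source's mu (8-12 Hz)
and beta (13-30 Hz) amplitudes are scaled by sqrt(1 - depth) so that band
POWER drops by exactly ``depth``; the ipsilateral source is scaled by
``ipsi_ratio * depth``. The background is spatially mixed 1/f noise.

The generator is deterministic end-to-end under a fixed seed; schedule,
recording and artifact randomness draw from independent child streams of the
config seed so that adding artifacts never perturbs the underlying EEG.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

RUN_NAMES = ("T", "NF1", "NF2")

#: linear amplitude ramp at MI start/end (s); avoids spectral edge artifacts
ERD_RAMP_S = 0.25

#: quiet padding before the first trial and after the last MI interval (s),
#: large enough for the widest epoch window used downstream (-7 to 9 s)
LEAD_PAD_S = 10.0
TAIL_PAD_S = 10.0
INTER_RUN_GAP_S = 20.0

#: background channel standard deviation (uV); realistic scalp-EEG scale
NOISE_SD_UV = 10.0

MU_BAND = (8.0, 12.0)
BETA_BAND = (13.0, 30.0)

SOURCE_SIGMA = 0.25          # spatial spread of sensorimotor sources
LEFT_SOURCE_POS = (-0.40, 0.05)   # left-hemisphere hand-knob area
RIGHT_SOURCE_POS = (0.40, 0.05)
BLINK_SOURCE_POS = (0.0, 0.95)    # frontal


class InvalidConfigError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated MI-NF session.

    Defaults mirror the study conditions of the emulated acquisition
    (64 channels, 500 Hz, 3 blocks x 3 runs x 40 trials, 5/3/5-s trial
    phases, uniform 0-4 s ITI). ERD depths, SNR and the noise exponent are
    free parameters of the generator.
    """

    n_channels: int = 64
    fs: float = 500.0
    n_runs_per_block: int = 3
    n_blocks: int = 3
    n_trials_per_run: int = 40
    baseline_dur: float = 5.0
    cue_dur: float = 3.0
    mi_dur: float = 5.0
    iti_range: tuple[float, float] = (0.0, 4.0)
    erd_depth_mu: float = 0.4
    erd_depth_beta: float = 0.25
    ipsi_ratio: float = 0.5
    noise_exponent: float = 1.0
    snr: float = 1.0
    artifact_rates: dict = field(
        default_factory=lambda: {"blinks_per_min": 2.0, "emg_bursts_per_min": 1.0}
    )
    seed: int = 0
    max_same_hand_repeats: int = 3

    def validate(self) -> None:
        if self.n_trials_per_run % 2 != 0:
            raise InvalidConfigError("n_trials_per_run must be even (balanced hands)")
        for name in ("baseline_dur", "cue_dur", "mi_dur", "fs"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        for name in ("erd_depth_mu", "erd_depth_beta", "ipsi_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_channels < 4:
            raise InvalidConfigError("need at least 4 channels")
        lo, hi = self.iti_range
        if lo < 0 or hi < lo:
            raise InvalidConfigError("iti_range must satisfy 0 <= lo <= hi")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible child stream of the config seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,))
        )

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class ContinuousRecording:
    """Multichannel time series in uV with an event table."""

    data: np.ndarray                # channels x samples
    fs: float
    channel_labels: list[str]
    channel_positions: np.ndarray   # channels x 2, flattened 2-D cap layout
    events: pd.DataFrame            # onset_sample, hand, run, block, trial_index

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels not unique")
        ons = self.events["onset_sample"].to_numpy()
        if len(ons) and (np.diff(ons) <= 0).any():
            raise ValueError("event onsets not strictly increasing")
        if len(ons) and (ons.max() >= self.n_samples or ons.min() < 0):
            raise ValueError("event onset outside recording")

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            channel_positions=self.channel_positions.copy(),
            events=self.events.copy(),
        )


def equidistant_layout(n_channels: int = 64) -> tuple[list[str], np.ndarray]:
    """Generic equidistant 2-D cap layout: concentric rings on the unit disk.

    Only relative topography matters for CSP, so a generic layout with
    labelled left/right sensorimotor neighbourhoods stands in for the
    custom cap. Rings start at the vertex (top), making the layout exactly
    mirror-symmetric about the midline (x -> -x maps channels onto
    channels), so hand-label swaps correspond to a relabelling of sensors.
    Returns (labels, positions[n, 2]); deterministic.
    """
    n_rings = max(1, int(round(np.sqrt(n_channels / 3.0))))
    radii = (np.arange(n_rings) + 0.5) / n_rings
    quota = radii / radii.sum() * n_channels
    counts = np.floor(quota).astype(int)
    remainder = np.argsort(quota - counts)[::-1]
    for i in range(n_channels - counts.sum()):
        counts[remainder[i % n_rings]] += 1
    pts = []
    for r, m in zip(radii, counts):
        theta = np.pi / 2 + 2 * np.pi * np.arange(m) / m
        pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    pos = np.vstack(pts)[:n_channels]
    pos[np.abs(pos) < 1e-12] = 0.0
    labels = [f"E{i + 1:02d}" for i in range(n_channels)]
    return labels, pos


def central_channel_subset(positions: np.ndarray, n_central: int = 49) -> np.ndarray:
    """Indices of the ``n_central`` innermost channels (sorted by radius)."""
    n_central = min(n_central, positions.shape[0])
    radius = np.linalg.norm(positions, axis=1)
    return np.sort(np.argsort(radius, kind="stable")[:n_central])


def sensorimotor_clusters(positions: np.ndarray, radius: float = 0.3):
    """(left_idx, right_idx) channel clusters around the two hand areas."""
    left = np.where(np.linalg.norm(positions - LEFT_SOURCE_POS, axis=1) < radius)[0]
    right = np.where(np.linalg.norm(positions - RIGHT_SOURCE_POS, axis=1) < radius)[0]
    return left, right


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def _balanced_hand_sequence(n_trials: int, rng: np.random.Generator,
                            max_repeats: int) -> np.ndarray:
    """Balanced left/right sequence with at most ``max_repeats`` in a row."""
    for _ in range(1_000):
        remaining = {"left": n_trials // 2, "right": n_trials // 2}
        seq: list[str] = []
        streak, last = 0, None
        ok = True
        for _ in range(n_trials):
            allowed = [h for h in ("left", "right") if remaining[h] > 0
                       and not (h == last and streak >= max_repeats)]
            if not allowed:
                ok = False
                break
            weights = np.array([remaining[h] for h in allowed], dtype=float)
            h = allowed[rng.choice(len(allowed), p=weights / weights.sum())]
            seq.append(h)
            streak = streak + 1 if h == last else 1
            last = h
            remaining[h] -= 1
        if ok:
            return np.array(seq, dtype=object)
    raise RuntimeError("could not satisfy pseudorandomization constraint")


def generate_schedule(config: SimulationConfig) -> pd.DataFrame:
    """Event table for a full session: one row per trial, onsets in samples.

    ``onset_sample`` marks MI onset (time 0 of every epoch downstream).
    Consecutive MI onsets within a run are separated by
    baseline + cue + MI + ITI with ITI ~ Uniform(iti_range); runs are laid
    out back to back on one continuous timeline with a quiet gap between.
    Hand order is pseudorandomized: balanced per run, no more than
    ``max_same_hand_repeats`` consecutive same-hand trials.
    """
    config.validate()
    rng = config.rng(0)
    fs = config.fs
    rows = []
    cursor = LEAD_PAD_S
    trial_span = config.baseline_dur + config.cue_dur + config.mi_dur
    trial_counter = 0
    for block in range(1, config.n_blocks + 1):
        for run in RUN_NAMES[: config.n_runs_per_block]:
            if config.n_trials_per_run > 0:
                hands = _balanced_hand_sequence(
                    config.n_trials_per_run, rng, config.max_same_hand_repeats
                )
                itis = rng.uniform(*config.iti_range, size=config.n_trials_per_run)
                for hand, iti in zip(hands, itis):
                    mi_onset = cursor + config.baseline_dur + config.cue_dur
                    rows.append(
                        dict(
                            onset_sample=int(round(mi_onset * fs)),
                            hand=hand,
                            run=run,
                            block=block,
                            trial_index=trial_counter,
                        )
                    )
                    cursor += trial_span + iti
                    trial_counter += 1
            cursor += INTER_RUN_GAP_S
    table = pd.DataFrame(
        rows, columns=["onset_sample", "hand", "run", "block", "trial_index"]
    )
    return table


# ---------------------------------------------------------------------------
# recording
# ---------------------------------------------------------------------------

def _band_noise(n_samples: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-SD band-limited Gaussian noise (stochastic narrowband rhythm)."""
    white = rng.standard_normal(n_samples)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _one_over_f_noise(shape: tuple[int, int], exponent: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Rows of 1/f^exponent noise, each scaled to unit SD."""
    n_src, n_samples = shape
    spec = rng.standard_normal((n_src, n_samples // 2 + 1)) + 1j * rng.standard_normal(
        (n_src, n_samples // 2 + 1)
    )
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _gaussian_topography(positions: np.ndarray, center, sigma: float) -> np.ndarray:
    d2 = ((positions - np.asarray(center)) ** 2).sum(axis=1)
    topo = np.exp(-d2 / (2.0 * sigma**2))
    return topo


def _erd_gain(n_samples: int, fs: float, events: pd.DataFrame, mi_dur: float,
              depth: float, source_side: str, ipsi_ratio: float) -> np.ndarray:
    """Amplitude gain time course for one hemisphere's rhythm source.

    Contralateral to the imagined hand the gain drops to sqrt(1 - depth)
    during MI (power drop = depth); ipsilateral to sqrt(1 - ipsi_ratio*depth).
    Transitions ramp linearly over ERD_RAMP_S.
    """
    gain = np.ones(n_samples)
    ramp_n = max(int(round(ERD_RAMP_S * fs)), 1)
    mi_n = int(round(mi_dur * fs))
    for _, ev in events.iterrows():
        contra = (ev["hand"] == "right") == (source_side == "left")
        d = depth if contra else ipsi_ratio * depth
        g = np.sqrt(1.0 - d)
        on = int(ev["onset_sample"])
        off = min(on + mi_n, n_samples)
        if on >= n_samples:
            continue
        gain[on:off] = g
        ramp = np.linspace(1.0, g, ramp_n, endpoint=False)
        lo = max(on - ramp_n, 0)
        gain[lo:on] = ramp[ramp_n - (on - lo):]
        hi = min(off + ramp_n, n_samples)
        gain[off:hi] = np.linspace(g, 1.0, ramp_n, endpoint=False)[: hi - off]
    return gain


def simulate_recording(config: SimulationConfig,
                       schedule: pd.DataFrame | None = None) -> ContinuousRecording:
    """Continuous multichannel EEG realizing the schedule's ERD structure.

    Two mirror-symmetric sensorimotor sources (left/right hemisphere), each
    carrying a mu and a beta rhythm, are projected through Gaussian spatial
    topographies onto the cap; the background is spatially mixed 1/f noise
    scaled so that each channel's SD is about 10 uV. Source amplitude at the
    topography peak equals ``snr`` times the background SD per rhythm.
    """
    config.validate()
    if schedule is None:
        schedule = generate_schedule(config)
    rng = config.rng(1)
    fs = config.fs
    if len(schedule):
        last = schedule["onset_sample"].max() / fs
    else:
        last = 0.0
    n_samples = int(round((last + config.mi_dur + TAIL_PAD_S) * fs))
    labels, positions = equidistant_layout(config.n_channels)

    # background: spatially mixed 1/f noise, per-channel SD == NOISE_SD_UV
    n_bg = min(config.n_channels, 32)
    bg_src = _one_over_f_noise((n_bg, n_samples), config.noise_exponent, rng)
    mix = rng.standard_normal((config.n_channels, n_bg)) / np.sqrt(n_bg)
    data = mix @ bg_src
    data *= NOISE_SD_UV / data.std(axis=1, keepdims=True)

    # lateralized rhythm sources
    amp = config.snr * NOISE_SD_UV
    for side, center in (("left", LEFT_SOURCE_POS), ("right", RIGHT_SOURCE_POS)):
        topo = _gaussian_topography(positions, center, SOURCE_SIGMA)
        for band, depth in ((MU_BAND, config.erd_depth_mu),
                            (BETA_BAND, config.erd_depth_beta)):
            src = _band_noise(n_samples, fs, band, rng)
            gain = _erd_gain(n_samples, fs, schedule, config.mi_dur,
                             depth, side, config.ipsi_ratio)
            data += np.outer(topo, amp * src * gain)

    rec = ContinuousRecording(
        data=data,
        fs=fs,
        channel_labels=labels,
        channel_positions=positions,
        events=schedule.reset_index(drop=True),
    )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def inject_artifacts(rec: ContinuousRecording, config: SimulationConfig
                     ) -> tuple[ContinuousRecording, pd.DataFrame]:
    """Add blink transients and EMG-like bursts; returns ground truth.

    Blinks: 0.3-s smooth frontal-topography transients (~120 uV at peak).
    EMG bursts: 1-2 s of high-frequency (>60 Hz), high-variance noise on the
    outermost (most peripheral) channels, which stand in for muscle-adjacent
    sensors. Rates of 0 leave the recording untouched. Ground-truth intervals
    are returned as a table (onset_sample, duration_samples, kind).
    """
    out = rec.copy()
    rng = config.rng(2)
    fs = rec.fs
    dur_min = rec.n_samples / fs / 60.0
    truth = []

    n_blinks = int(round(config.artifact_rates.get("blinks_per_min", 0.0) * dur_min))
    if n_blinks > 0:
        topo = _gaussian_topography(rec.channel_positions, BLINK_SOURCE_POS, 0.3)
        blink_n = int(round(0.3 * fs))
        wave = 120.0 * np.hanning(blink_n)
        for onset in np.sort(rng.integers(0, rec.n_samples - blink_n, n_blinks)):
            out.data[:, onset:onset + blink_n] += np.outer(topo, wave)
            truth.append(dict(onset_sample=int(onset),
                              duration_samples=blink_n, kind="blink"))

    n_emg = int(round(config.artifact_rates.get("emg_bursts_per_min", 0.0) * dur_min))
    if n_emg > 0:
        radius = np.linalg.norm(rec.channel_positions, axis=1)
        emg_channels = np.argsort(radius)[-4:]
        hi = min(240.0, fs / 2 * 0.96)
        sos = signal.butter(4, [60.0, hi], btype="bandpass", fs=fs, output="sos")
        for _ in range(n_emg):
            dur = int(round(rng.uniform(1.0, 2.0) * fs))
            onset = int(rng.integers(0, rec.n_samples - dur))
            burst = signal.sosfilt(sos, rng.standard_normal(dur))
            burst *= 50.0 / burst.std()
            window = np.hanning(dur)
            for ch in emg_channels:
                out.data[ch, onset:onset + dur] += burst * window
            truth.append(dict(onset_sample=onset, duration_samples=dur, kind="emg"))

    truth_df = pd.DataFrame(
        truth, columns=["onset_sample", "duration_samples", "kind"]
    ).sort_values("onset_sample", ignore_index=True)
    return out, truth_df
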