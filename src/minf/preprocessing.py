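"""Filtering, epoching, baseline handling, channel QC and artifact rejection.

The offline path uses zero-phase FIR filtering (forward-backward with edge
padding); the online neurofeedback path uses causal filters with a documented
group delay of order/2 samples. Epoch windows are expressed in seconds
relative to MI onset and are closed-open [start, end).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

from minf.simulate import ContinuousRecording


class QCError(RuntimeError):
    """Raised when quality control makes further processing unsound."""


@dataclass
class FilterSpec:
    """One linear filter of the processing chain.

    ``passband_ripple_db`` is carried for provenance with the Butterworth
    band-pass (the original acquisition software exposes such a parameter)
    but a Butterworth design is maximally flat and does not use it.
    """

    kind: str                      # fir-highpass | fir-lowpass | butter-bandpass
    cutoff_hz: float | tuple[float, float]
    order: int
    window: str = "hamming"
    passband_ripple_db: float | None = None
    mode: str = "zero-phase"       # zero-phase | causal

    def validate(self, fs: float) -> None:
        if self.order <= 0:
            raise ValueError("filter order must be > 0")
        cutoffs = np.atleast_1d(self.cutoff_hz)
        if np.any(cutoffs <= 0) or np.any(cutoffs >= fs / 2):
            raise ValueError(f"cutoff {self.cutoff_hz} outside (0, {fs / 2}) Hz")
        if self.kind not in ("fir-highpass", "fir-lowpass", "butter-bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.mode not in ("zero-phase", "causal"):
            raise ValueError(f"unknown filter mode {self.mode!r}")

    @property
    def group_delay_samples(self) -> float:
        """Group delay in causal mode (linear-phase FIR: order/2 samples)."""
        return self.order / 2.0


# named presets of the emulated processing chain
ONLINE_HIGHPASS = FilterSpec("fir-highpass", 8.0, 826, mode="causal")
ONLINE_LOWPASS = FilterSpec("fir-lowpass", 30.0, 220, mode="causal")
OFFLINE_HIGHPASS = FilterSpec("fir-highpass", 8.0, 826, mode="zero-phase")
OFFLINE_LOWPASS = FilterSpec("fir-lowpass", 30.0, 220, mode="zero-phase")
NF_BANDPASS = FilterSpec("butter-bandpass", (8.0, 30.0), 4,
                         passband_ripple_db=0.5, mode="causal")
EMG_HIGHPASS = FilterSpec("fir-highpass", 25.0, 264, mode="zero-phase")


@dataclass
class ChannelQCConfig:
    """Channel- and epoch-level rejection thresholds.

    ``msd_window``/``msd_factor`` encode the moving-standard-deviation rule
    (trial flagged when a 250-sample centered moving SD exceeds 2.5x the
    trial-channel SD); ``amp_threshold`` is the post-band-pass absolute
    amplitude criterion; ``sd_bound`` bounds channel SDs at
    mean +- sd_bound * SD across channels.
    """

    sd_bound: float = 2.0
    msd_window: int = 250
    msd_factor: float = 2.5
    amp_threshold: float = 100.0

    def validate(self) -> None:
        if min(self.sd_bound, self.msd_window, self.msd_factor,
               self.amp_threshold) <= 0:
            raise ValueError("all QC thresholds must be positive")


@dataclass
class EpochSet:
    """Trials x channels x samples with labels and a rejection mask."""

    data: np.ndarray
    times: np.ndarray              # s relative to MI onset, uniform at 1/fs
    labels: np.ndarray             # hand per trial
    runs: np.ndarray
    blocks: np.ndarray
    trial_index: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_positions: np.ndarray
    rejected: np.ndarray = field(default=None)
    reject_reason: np.ndarray = field(default=None)
    n_dropped: int = 0

    def __post_init__(self):
        n = self.data.shape[0]
        if self.rejected is None:
            self.rejected = np.zeros(n, dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = np.array([""] * n, dtype=object)
        if len(self.labels) != n:
            raise ValueError("labels length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def kept(self) -> np.ndarray:
        return ~self.rejected

    def copy(self) -> "EpochSet":
        return dataclasses.replace(
            self,
            data=self.data.copy(),
            rejected=self.rejected.copy(),
            reject_reason=self.reject_reason.copy(),
        )

    def sample_slice(self, interval: tuple[float, float]) -> slice:
        """Sample slice for a closed-open [start, end) interval in s."""
        start, end = interval
        if start < self.times[0] - 1e-9 or end > self.times[-1] + 1.0 / self.fs + 1e-9:
            raise ValueError(f"interval {interval} outside epoch window "
                             f"[{self.times[0]}, {self.times[-1] + 1 / self.fs})")
        i0 = int(round((start - self.times[0]) * self.fs))
        i1 = int(round((end - self.times[0]) * self.fs))
        return slice(i0, i1)

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset of trials (boolean or index mask)."""
        return dataclasses.replace(
            self,
            data=self.data[mask],
            labels=self.labels[mask],
            runs=self.runs[mask],
            blocks=self.blocks[mask],
            trial_index=self.trial_index[mask],
            rejected=self.rejected[mask],
            reject_reason=self.reject_reason[mask],
        )


def concat_epochs(parts: list[EpochSet]) -> EpochSet:
    """Concatenate epoch sets sharing channel set and time axis."""
    first = parts[0]
    for p in parts[1:]:
        if not np.allclose(p.times, first.times):
            raise ValueError("epoch time axes differ")
        if p.channel_labels != first.channel_labels:
            raise ValueError("channel sets differ")
    return dataclasses.replace(
        first,
        data=np.concatenate([p.data for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        runs=np.concatenate([p.runs for p in parts]),
        blocks=np.concatenate([p.blocks for p in parts]),
        trial_index=np.concatenate([p.trial_index for p in parts]),
        rejected=np.concatenate([p.rejected for p in parts]),
        reject_reason=np.concatenate([p.reject_reason for p in parts]),
        n_dropped=sum(p.n_dropped for p in parts),
    )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _design(spec: FilterSpec, fs: float):
    if spec.kind == "fir-highpass":
        taps = signal.firwin(spec.order + 1, spec.cutoff_hz, window=spec.window,
                             pass_zero=False, fs=fs)
        return ("fir", taps)
    if spec.kind == "fir-lowpass":
        taps = signal.firwin(spec.order + 1, spec.cutoff_hz, window=spec.window,
                             pass_zero=True, fs=fs)
        return ("fir", taps)
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="bandpass",
                        fs=fs, output="sos")
    return ("sos", sos)


def _fir_zero_phase(taps: np.ndarray, data: np.ndarray, padlen: int) -> np.ndarray:
    """Forward-backward FIR filtering via FFT convolution.

    Equivalent to filtfilt (odd-reflection edge padding) but runs the
    combined forward+backward pass as one convolution with the filter's
    autocorrelation, which is much faster for long FIR kernels.
    """
    if padlen > 0:
        left = 2 * data[..., :1] - data[..., padlen:0:-1]
        right = 2 * data[..., -1:] - data[..., -2:-padlen - 2:-1]
        ext = np.concatenate([left, data, right], axis=-1)
    else:
        ext = data
    kernel = np.convolve(taps, taps[::-1])  # zero-phase combined response
    shape = [1] * ext.ndim
    shape[-1] = kernel.size
    out = signal.fftconvolve(ext, kernel.reshape(shape), mode="same", axes=-1)
    return out[..., padlen:ext.shape[-1] - padlen]


def filter_array(data: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Filter along the last axis; zero-phase or causal per spec.mode."""
    spec.validate(fs)
    kind, coef = _design(spec, fs)
    n = data.shape[-1]
    if kind == "fir":
        if spec.mode == "zero-phase":
            padlen = min(3 * spec.order, n - 1)
            return _fir_zero_phase(coef, data, padlen)
        return signal.lfilter(coef, [1.0], data, axis=-1)
    if spec.mode == "zero-phase":
        return signal.sosfiltfilt(coef, data, axis=-1)
    return signal.sosfilt(coef, data, axis=-1)


def fir_filter(rec: ContinuousRecording, spec: FilterSpec) -> ContinuousRecording:
    """Per-channel linear filtering of a continuous recording."""
    out = rec.copy()
    out.data = filter_array(rec.data, spec, rec.fs)
    return out


def filter_chain(rec: ContinuousRecording,
                 specs: list[FilterSpec]) -> ContinuousRecording:
    for spec in specs:
        rec = fir_filter(rec, spec)
    return rec


def frequency_response(spec: FilterSpec, fs: float, freqs: np.ndarray) -> np.ndarray:
    """|H(f)| of the designed filter (doubled in dB for zero-phase use)."""
    spec.validate(fs)
    kind, coef = _design(spec, fs)
    if kind == "fir":
        _, h = signal.freqz(coef, [1.0], worN=freqs, fs=fs)
    else:
        _, h = signal.sosfreqz(coef, worN=freqs, fs=fs)
    mag = np.abs(h)
    return mag**2 if spec.mode == "zero-phase" else mag


# ---------------------------------------------------------------------------
# epoching / baseline
# ---------------------------------------------------------------------------

def epoch_data(rec: ContinuousRecording, events: pd.DataFrame,
               window: tuple[float, float] = (-7.0, 9.0)) -> EpochSet:
    """Segment one epoch per event over [start, end) s around MI onset.

    Events whose window would exceed the recording bounds are dropped and
    counted in ``n_dropped``. An empty event table yields a zero-trial set.
    """
    fs = rec.fs
    start, end = window
    for w in window:
        if abs(w * fs - round(w * fs)) > 1e-6:
            raise ValueError("window endpoints must be multiples of 1/fs")
    off0 = int(round(start * fs))
    n_samp = int(round((end - start) * fs))
    chunks, keep_rows = [], []
    dropped = 0
    for _, ev in events.iterrows():
        i0 = int(ev["onset_sample"]) + off0
        i1 = i0 + n_samp
        if i0 < 0 or i1 > rec.n_samples:
            dropped += 1
            continue
        chunks.append(rec.data[:, i0:i1])
        keep_rows.append(ev)
    if chunks:
        data = np.stack(chunks)
        kept = pd.DataFrame(keep_rows)
    else:
        data = np.empty((0, rec.data.shape[0], n_samp))
        kept = pd.DataFrame(columns=["hand", "run", "block", "trial_index"])
    times = start + np.arange(n_samp) / fs
    return EpochSet(
        data=data,
        times=times,
        labels=kept["hand"].to_numpy(dtype=object),
        runs=kept["run"].to_numpy(dtype=object),
        blocks=kept["block"].to_numpy(),
        trial_index=kept["trial_index"].to_numpy(),
        fs=fs,
        channel_labels=list(rec.channel_labels),
        channel_positions=rec.channel_positions.copy(),
        n_dropped=dropped,
    )


def baseline_correct(ep: EpochSet, interval: tuple[float, float] = (-6.0, -4.0)
                     ) -> EpochSet:
    """Subtract each trial/channel's mean over the baseline interval."""
    sl = ep.sample_slice(interval)
    out = ep.copy()
    out.data = ep.data - ep.data[:, :, sl].mean(axis=2, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# channel QC / referencing
# ---------------------------------------------------------------------------

def detect_bad_channels(rec: ContinuousRecording,
                        qc: ChannelQCConfig | None = None) -> list[str]:
    """Channels whose SD falls outside mean_SD +- sd_bound * SD of SDs."""
    qc = qc or ChannelQCConfig()
    qc.validate()
    if rec.data.shape[0] < 3:
        raise ValueError("need at least 3 channels for SD-based QC")
    sds = rec.data.std(axis=1)
    center, spread = sds.mean(), sds.std()
    bad = (sds > center + qc.sd_bound * spread) | (sds < center - qc.sd_bound * spread)
    return [rec.channel_labels[i] for i in np.where(bad)[0]]


def prepare_reference(ep: EpochSet, bad_channels: list[str],
                      max_neighbors: int = 6) -> EpochSet:
    """Interpolate bad channels then apply a common-average reference.

    Bad channels are replaced by the inverse-distance-weighted mean of up to
    ``max_neighbors`` nearest good channels, after which every sample's
    channel mean is zero. Aborts if more than 25% of channels are bad.
    """
    labels = ep.channel_labels
    unknown = set(bad_channels) - set(labels)
    if unknown:
        raise ValueError(f"bad channels not in channel set: {sorted(unknown)}")
    bad_idx = [labels.index(c) for c in bad_channels]
    if len(bad_idx) > 0.25 * len(labels):
        raise QCError(
            f"{len(bad_idx)}/{len(labels)} channels bad exceeds the 25% QC limit"
        )
    out = ep.copy()
    good_idx = np.setdiff1d(np.arange(len(labels)), bad_idx)
    for bi in bad_idx:
        d = np.linalg.norm(ep.channel_positions[good_idx]
                           - ep.channel_positions[bi], axis=1)
        order = np.argsort(d)[:max_neighbors]
        w = 1.0 / np.maximum(d[order], 1e-12)
        w /= w.sum()
        out.data[:, bi, :] = np.einsum(
            "k,tks->ts", w, out.data[:, good_idx[order], :]
        )
    out.data -= out.data.mean(axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# artifact rejection
# ---------------------------------------------------------------------------

def moving_std(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving SD along the last axis (edges replicate)."""
    m = uniform_filter1d(x, size=window, axis=-1, mode="nearest")
    m2 = uniform_filter1d(x * x, size=window, axis=-1, mode="nearest")
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def artifact_mask(ep: EpochSet, qc: ChannelQCConfig | None = None,
                  method: str = "msd") -> np.ndarray:
    """Flag trials by the MSD rule or an absolute amplitude criterion.

    msd: trial flagged when any channel's centered ``msd_window``-sample
    moving SD exceeds ``msd_factor`` times that trial-channel's overall SD.
    amplitude: trial flagged when |value| > amp_threshold anywhere. Flags are
    OR-ed into ``ep.rejected`` with a reason code; the mask is returned.
    """
    qc = qc or ChannelQCConfig()
    qc.validate()
    if method == "msd":
        if qc.msd_window >= ep.data.shape[-1]:
            raise ValueError("msd window must be shorter than the epoch")
        msd = moving_std(ep.data, qc.msd_window)
        sd = ep.data.std(axis=-1, keepdims=True)
        flagged = (msd > qc.msd_factor * sd).any(axis=(1, 2))
        reason = "msd"
    elif method == "amplitude":
        flagged = (np.abs(ep.data) > qc.amp_threshold).any(axis=(1, 2))
        reason = "amplitude"
    else:
        raise ValueError(f"unknown artifact method {method!r}")
    newly = flagged & ~ep.rejected
    ep.rejected |= flagged
    for i in np.where(newly)[0]:
        ep.reject_reason[i] = (ep.reject_reason[i] + "+" + reason).lstrip("+")
    return flagged
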