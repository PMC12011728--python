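"""BrainVision triplet (.vhdr/.vmrk/.eeg) writer and reader.

The writer emits the standard Core Data Format 1.0: an INI-style header, a
marker file with one ``Stimulus`` marker per trial (S  1 = left hand,
S  2 = right hand), and multiplexed binary data in either IEEE float32 or
16-bit signed integer dialect. The reader goes through MNE and restores the
event table from the sidecar CSV written next to the triplet.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from minf.simulate import ContinuousRecording, equidistant_layout

_HAND_TO_MARKER = {"left": 1, "right": 2}
_MARKER_TO_HAND = {v: k for k, v in _HAND_TO_MARKER.items()}

INT16_RESOLUTION_UV = 0.1   # amplitude resolution of the int16 dialect


def write_brainvision(rec: ContinuousRecording, basename: str,
                      fmt: str = "float32") -> str:
    """Write ``basename``.vhdr/.vmrk/.eeg plus ``basename``_events.csv.

    ``fmt`` selects the binary dialect: 'float32' (IEEE) or 'int16'
    (0.1 uV resolution). Returns the .vhdr path.
    """
    if fmt not in ("float32", "int16"):
        raise ValueError(f"unsupported BrainVision dialect: {fmt}")
    base_dir = os.path.dirname(os.path.abspath(basename))
    os.makedirs(base_dir, exist_ok=True)
    stem = os.path.basename(basename)
    vhdr, vmrk, eeg = (basename + ext for ext in (".vhdr", ".vmrk", ".eeg"))

    n_ch, _ = rec.data.shape
    if fmt == "float32":
        binfmt, res = "IEEE_FLOAT_32", 1.0
        raw = (rec.data / res).astype("<f4")
    else:
        binfmt, res = "INT_16", INT16_RESOLUTION_UV
        raw = np.clip(np.round(rec.data / res), -32768, 32767).astype("<i2")
    raw.T.reshape(-1).tofile(eeg)  # multiplexed: sample-major

    interval_us = 1e6 / rec.fs
    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={interval_us:.6f}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binfmt}",
        "",
        "[Channel Infos]",
    ]
    for i, label in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={label},,{res:g},µV")
    with open(vhdr, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")

    mlines = [
        "BrainVision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    for j, (_, ev) in enumerate(rec.events.iterrows(), start=2):
        code = _HAND_TO_MARKER[ev["hand"]]
        # BrainVision marker positions are 1-based
        mlines.append(
            f"Mk{j}=Stimulus,S{code:>3d},{int(ev['onset_sample']) + 1},1,0"
        )
    with open(vmrk, "w", encoding="utf-8") as fh:
        fh.write("\n".join(mlines) + "\n")

    rec.events.to_csv(basename + "_events.csv", index=False)
    return vhdr


def read_brainvision(vhdr_path: str) -> ContinuousRecording:
    """Read a BrainVision triplet via MNE into a ContinuousRecording (uV)."""
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    labels = list(raw.ch_names)

    events_csv = vhdr_path[: -len(".vhdr")] + "_events.csv"
    if os.path.exists(events_csv):
        events = pd.read_csv(events_csv)
    else:
        rows = []
        for ann in raw.annotations:
            desc = ann["description"]
            if desc.startswith("Stimulus/S"):
                code = int(desc.split("S")[-1])
                rows.append(dict(
                    onset_sample=int(round(ann["onset"] * raw.info["sfreq"])),
                    hand=_MARKER_TO_HAND.get(code, "left"),
                    run="T", block=1, trial_index=len(rows),
                ))
        events = pd.DataFrame(
            rows, columns=["onset_sample", "hand", "run", "block", "trial_index"]
        )
    _, positions = equidistant_layout(len(labels))
    return ContinuousRecording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        channel_positions=positions,
        events=events,
    )
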