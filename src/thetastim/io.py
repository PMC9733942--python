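"""Readers and writers: NPZ raw-session layout, HDF5 trial stores, TSV
reports, and (optionally, via mne) EDF continuous recordings."""

from __future__ import annotations

import json
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .types import ChannelInfo, PruneReport, RawRecording, TrialSet


def save_raw_npz(rec: RawRecording, path) -> None:
    """Plain NPZ layout: samples, fs, events, rest_segments, channel table."""
    channels = json.dumps([vars(ch) for ch in rec.channels])
    np.savez_compressed(
        path,
        samples=rec.samples,
        fs=np.asarray(rec.fs),
        events=rec.events,
        rest_segments=np.asarray(rec.rest_segments, dtype=float).reshape(-1, 2),
        channels=np.asarray(channels),
    )


def load_raw_npz(path) -> RawRecording:
    with np.load(path, allow_pickle=False) as f:
        channels = [ChannelInfo(**d) for d in json.loads(str(f["channels"]))]
        return RawRecording(
            samples=f["samples"],
            fs=float(f["fs"]),
            channels=channels,
            events=f["events"],
            rest_segments=[tuple(row) for row in f["rest_segments"]],
        )


def load_raw_edf(path, subject: str = "s0", region: str = "other") -> RawRecording:
    """Read an EDF continuous recording (requires the optional mne extra).

    EDF carries no stimulation events or rest segments; attach those on the
    returned object.  Voltages are converted to uV.
    """
    import mne  # optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    channels = [
        ChannelInfo(label=name, subject=subject, region=region) for name in raw.ch_names
    ]
    return RawRecording(
        samples=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]), channels=channels
    )


def save_trialsets_h5(path, trialsets: Iterable[TrialSet]) -> None:
    """One HDF5 group per channel: trials, time_ms, kept, optional phases."""
    with h5py.File(path, "w") as f:
        for i, ts in enumerate(trialsets):
            name = ts.channel.label if ts.channel is not None else f"channel{i}"
            g = f.create_group(name)
            g.create_dataset("trials", data=ts.trials)
            g.create_dataset("time_ms", data=ts.time_ms)
            g.create_dataset("kept", data=ts.kept)
            if ts.onset_phase_deg is not None:
                g.create_dataset("onset_phase_deg", data=ts.onset_phase_deg)
            if ts.onset_samples is not None:
                g.create_dataset("onset_samples", data=ts.onset_samples)
            if ts.channel is not None:
                for k, v in vars(ts.channel).items():
                    g.attrs[k] = v


def load_trialsets_h5(path) -> list[TrialSet]:
    out = []
    with h5py.File(path, "r") as f:
        for name in f:
            g = f[name]
            channel = (
                ChannelInfo(**{k: str(v) for k, v in g.attrs.items()})
                if "label" in g.attrs
                else None
            )
            out.append(
                TrialSet(
                    trials=g["trials"][()],
                    time_ms=g["time_ms"][()],
                    channel=channel,
                    kept=g["kept"][()],
                    onset_phase_deg=g["onset_phase_deg"][()] if "onset_phase_deg" in g else None,
                    onset_samples=g["onset_samples"][()] if "onset_samples" in g else None,
                )
            )
    return out


def prune_reports_to_tsv(reports: Iterable[PruneReport], path) -> pd.DataFrame:
    df = pd.DataFrame([r.to_row() for r in reports])
    df.to_csv(path, sep="\t", index=False)
    return df
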