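"""HDF5 / JSON / EDF input-output for recordings, annotations and features.

Native layout: one HDF5 file with ``/signal`` (channels x samples) and a
JSON metadata attribute block (sampling rate, channel grid, acquisition-file
boundaries). Seizure annotations travel separately as JSON
(``{"onsets_s": [...]}``).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .models import ImportanceReport, LstmParams
from .preprocess import BroadbandRecording, DerivedStreams

__all__ = [
    "save_recording",
    "load_recording",
    "save_annotations",
    "load_annotations",
    "save_derived",
    "save_feature_frames",
    "save_lstm_params",
    "load_lstm_params",
    "save_importance",
    "read_edf",
]


def save_recording(path, rec: BroadbandRecording) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("signal", data=rec.signal, compression="gzip", compression_opts=1)
        meta = {
            "fs": rec.fs,
            "t0": rec.t0,
            "file_bounds": [int(b) for b in rec.file_bounds],
            "channel_grid": np.asarray(rec.channel_grid).tolist(),
        }
        d.attrs["meta"] = json.dumps(meta)


def load_recording(path) -> BroadbandRecording:
    with h5py.File(path, "r") as f:
        d = f["signal"]
        meta = json.loads(d.attrs["meta"])
        return BroadbandRecording(
            d[...],
            float(meta["fs"]),
            np.asarray(meta["channel_grid"]),
            list(meta["file_bounds"]),
            float(meta.get("t0", 0.0)),
        )


def save_annotations(path, onsets_s) -> None:
    Path(path).write_text(json.dumps({"onsets_s": [float(o) for o in onsets_s]}))


def load_annotations(path) -> list[float]:
    return [float(o) for o in json.loads(Path(path).read_text())["onsets_s"]]


def save_derived(path, streams: DerivedStreams) -> None:
    """Write /lfp, /mua_counts, /mua_env groups with fs attributes."""
    with h5py.File(path, "w") as f:
        g = f.create_dataset("lfp", data=streams.lfp.signal, compression="gzip", compression_opts=1)
        g.attrs["fs"] = streams.lfp.fs
        g = f.create_dataset("mua_counts", data=streams.counts.counts, compression="gzip", compression_opts=1)
        g.attrs["fs"] = streams.counts.fs
        g = f.create_dataset("mua_env", data=streams.envelope.envelope, compression="gzip", compression_opts=1)
        g.attrs["fs"] = streams.envelope.fs
        f.attrs["artifact_intervals"] = json.dumps(streams.artifact_intervals)


def save_feature_frames(directory, frames: dict[str, pd.DataFrame], csv: bool = False) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with h5py.File(directory / "features.h5", "w") as f:
        for g, df in frames.items():
            grp = f.create_group(g)
            grp.create_dataset("t", data=df.index.to_numpy(dtype=float))
            grp.create_dataset("values", data=df.to_numpy())
            grp.attrs["columns"] = json.dumps(list(df.columns))
    if csv:
        for g, df in frames.items():
            df.to_csv(directory / f"{g}.csv")


def save_lstm_params(path, params: LstmParams) -> None:
    """Serialize fitted LSTM parameters (gate weights and dense readout)."""
    with h5py.File(path, "w") as f:
        for name, arr in params.arrays().items():
            f.create_dataset(name, data=arr)


def load_lstm_params(path) -> LstmParams:
    with h5py.File(path, "r") as f:
        return LstmParams(**{k: f[k][...] for k in ("Wx", "Wh", "b", "D", "d")})


def save_importance(path, report: ImportanceReport) -> None:
    """Importance table as CSV with (feature, base_feature, importance) columns."""
    report.table.to_csv(path, index=False)


def read_edf(path, channels=None) -> BroadbandRecording:
    """Optional EDF/EDF+ reader for real recordings (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF files requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels is not None:
        raw = raw.pick(channels)
    return BroadbandRecording(raw.get_data(), float(raw.info["sfreq"]))
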