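"""On-disk formats: raw float32 EEG + JSON sidecar, CSV tables, montage.

EEG is stored as channel-major raw float32 binary (microvolts) next to a
JSON sidecar documenting channel order, unit, sampling rate and sample
count.  Events and probe ratings are CSV with 0-based ``onset_sample``
columns; the montage is ASCII ``label x y z`` in meters.  Epoch sets and
ICA decompositions round-trip through .npy containers with JSON/CSV
sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix, ICADecomposition
from .preproc import ContinuousRecording, EpochSet
from .synth.experiment import ParticipantData
from .synth.montage import read_montage, write_montage  # noqa: F401  (re-export)

__all__ = [
    "write_recording",
    "read_recording",
    "write_participant",
    "read_participant",
    "write_epochs",
    "read_epochs",
    "write_decomposition",
    "read_decomposition",
    "write_features",
    "read_features",
]


def write_recording(rec: ContinuousRecording, prefix: Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(rec.data, dtype=np.float32)
    data.tofile(prefix.with_suffix(".bin"))
    sidecar = {
        "format": "raw-float32-channel-major",
        "unit": "uV",
        "rate_hz": rec.rate,
        "n_channels": len(rec.labels),
        "n_samples": rec.n_samples,
        "labels": list(rec.labels),
        "participant": rec.participant,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(prefix: Path,
                   events: pd.DataFrame | None = None) -> ContinuousRecording:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.fromfile(prefix.with_suffix(".bin"), dtype=np.float32)
    data = data.reshape(meta["n_channels"], meta["n_samples"])
    return ContinuousRecording(
        rate=meta["rate_hz"], data=data, labels=tuple(meta["labels"]),
        events=events if events is not None else pd.DataFrame(),
        participant=meta.get("participant", ""),
    )


def write_participant(pdata: ParticipantData, outdir: Path) -> None:
    """One participant: EEG, events.csv, ratings.csv, truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_recording(pdata.recording, outdir / f"{pdata.participant}_eeg")
    pdata.events.to_csv(outdir / f"{pdata.participant}_events.csv", index=False)
    pdata.probes.to_csv(outdir / f"{pdata.participant}_ratings.csv",
                        index=False)
    pdata.truth.to_csv(outdir / f"{pdata.participant}_truth.csv", index=False)


def read_participant(outdir: Path, participant: str) -> ParticipantData:
    outdir = Path(outdir)
    events = pd.read_csv(outdir / f"{participant}_events.csv")
    rec = read_recording(outdir / f"{participant}_eeg", events=events)
    probes = pd.read_csv(outdir / f"{participant}_ratings.csv")
    truth = pd.read_csv(outdir / f"{participant}_truth.csv")
    return ParticipantData(participant=participant, recording=rec,
                           events=events, probes=probes, truth=truth)


def write_epochs(epochs: EpochSet, prefix: Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.save(prefix.with_suffix(".npy"), epochs.data)
    epochs.metadata.to_csv(prefix.with_suffix(".trials.csv"), index=False)
    meta = {
        "rate_hz": epochs.rate,
        "labels": list(epochs.labels),
        "t_start": float(epochs.times[0]),
        "n_times": int(epochs.times.size),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_epochs(prefix: Path) -> EpochSet:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.load(prefix.with_suffix(".npy"))
    times = meta["t_start"] + np.arange(meta["n_times"]) / meta["rate_hz"]
    trials = pd.read_csv(prefix.with_suffix(".trials.csv"))
    return EpochSet(data=data, times=times, labels=tuple(meta["labels"]),
                    metadata=trials, rate=meta["rate_hz"])


def write_decomposition(dec: ICADecomposition, prefix: Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.save(prefix.with_suffix(".unmixing.npy"), dec.unmixing)
    np.save(prefix.with_suffix(".mixing.npy"), dec.mixing)
    meta = {
        "labels": list(dec.labels),
        "algorithm": dec.algorithm,
        "seed": dec.seed,
        "n_iter": dec.n_iter,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_decomposition(prefix: Path) -> ICADecomposition:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return ICADecomposition(
        unmixing=np.load(prefix.with_suffix(".unmixing.npy")),
        mixing=np.load(prefix.with_suffix(".mixing.npy")),
        labels=tuple(meta["labels"]),
        algorithm=meta["algorithm"],
        seed=meta["seed"],
        n_iter=meta["n_iter"],
    )


def write_features(fm: FeatureMatrix, prefix: Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        fm.values,
        columns=[f"IC{c}_bin{b}" for c, b in fm.columns],
    )
    df.to_csv(prefix.with_suffix(".csv"), index=False)
    fm.trials.to_csv(prefix.with_suffix(".trials.csv"), index=False)
    meta = {"bin_edges_s": fm.bin_edges.tolist()}
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_features(prefix: Path) -> FeatureMatrix:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"))
    pairs = [c.replace("IC", "").split("_bin") for c in df.columns]
    columns = pd.MultiIndex.from_tuples(
        [(int(a), int(b)) for a, b in pairs], names=["component", "bin"]
    )
    meta = json.loads(prefix.with_suffix(".json").read_text())
    trials = pd.read_csv(prefix.with_suffix(".trials.csv"))
    return FeatureMatrix(values=df.to_numpy(), columns=columns,
                         bin_edges=np.asarray(meta["bin_edges_s"]),
                         trials=trials)
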