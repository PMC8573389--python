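"""File formats for datasets and results.

Recordings are HDF5 (one ``data`` dataset, channels x samples, with ``fs`` and
``channel_labels`` attributes) with a plain-CSV fallback (one column per
channel, header row = labels).  Events, the channel-region map, clinical data
and all result tables are TSV; FC matrices and thresholded networks are TSV
matrices with a JSON sidecar carrying K, band, period, alpha and r_threshold.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import FCMatrix, ThresholdedNetwork
from .preprocess import Recording, SeizureEvent
from .synth import StudyDataset

EVENT_COLUMNS = ["recording_id", "onset_s", "offset_s"]


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------


def write_recording_h5(recording: Recording, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=recording.data)
        d.attrs["fs"] = recording.fs
        d.attrs["channel_labels"] = [c.encode() for c in recording.channel_labels]


def write_recording_csv(recording: Recording, path) -> None:
    path = Path(path)
    df = pd.DataFrame(recording.data.T, columns=recording.channel_labels)
    df.to_csv(path, index=False)


def read_recording(path, region_of: dict[str, str]) -> Recording:
    """Read a recording from HDF5 or CSV; ``region_of`` supplies the channel
    map (stored separately in ``regions.tsv``). CSV carries no sampling rate,
    so it must be attached afterwards by the caller — prefer HDF5."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            d = f["data"]
            labels = [
                c.decode() if isinstance(c, bytes) else str(c)
                for c in d.attrs["channel_labels"]
            ]
            return Recording(d[...], float(d.attrs["fs"]), labels, region_of)
    raise ValueError(f"unsupported recording format: {path.suffix}")


def read_recording_csv(path, fs: float, region_of: dict[str, str]) -> Recording:
    df = pd.read_csv(path)
    return Recording(df.to_numpy().T, fs, list(df.columns), region_of)


# ---------------------------------------------------------------------------
# Dataset tables
# ---------------------------------------------------------------------------


def write_events(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_regions(region_of: dict[str, str], path) -> None:
    pd.DataFrame(
        {"channel": list(region_of), "region": list(region_of.values())}
    ).to_csv(path, sep="\t", index=False)


def read_regions(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["channel"], df["region"]))


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Whole studies
# ---------------------------------------------------------------------------


def write_study(dataset: StudyDataset, out_dir) -> None:
    """Write a full synthetic study: recordings/, events.tsv, regions.tsv,
    clinical.tsv and a recordings.tsv index (recording_id -> patient)."""
    out = Path(out_dir)
    (out / "recordings").mkdir(parents=True, exist_ok=True)
    rows, index = [], []
    region_of: dict[str, str] = {}
    for rec_id, patient, rec, event in dataset.records:
        write_recording_h5(rec, out / "recordings" / f"{rec_id}.h5")
        region_of.update(rec.region_of)
        index.append({"recording_id": rec_id, "patient": patient})
        if event is not None:
            rows.append(
                {"recording_id": rec_id, "onset_s": event.onset_s, "offset_s": event.offset_s}
            )
    write_events(pd.DataFrame(rows, columns=EVENT_COLUMNS), out / "events.tsv")
    write_regions(region_of, out / "regions.tsv")
    write_clinical(dataset.clinical, out / "clinical.tsv")
    pd.DataFrame(index, columns=["recording_id", "patient"]).to_csv(
        out / "recordings.tsv", sep="\t", index=False
    )


def read_study(data_dir) -> StudyDataset:
    data = Path(data_dir)
    region_of = read_regions(data / "regions.tsv")
    events = read_events(data / "events.tsv").set_index("recording_id")
    index = pd.read_csv(data / "recordings.tsv", sep="\t").set_index("recording_id")
    clinical = read_clinical(data / "clinical.tsv")
    records = []
    for path in sorted((data / "recordings").glob("*.h5")):
        rec_id = path.stem
        rec = read_recording(path, region_of)
        event = None
        if rec_id in events.index:
            row = events.loc[rec_id]
            event = SeizureEvent(float(row["onset_s"]), float(row["offset_s"]))
        patient = int(index.loc[rec_id, "patient"]) if rec_id in index.index else -1
        records.append((rec_id, patient, rec, event))
    return StudyDataset(records=records, clinical=clinical)


# ---------------------------------------------------------------------------
# Matrices and networks
# ---------------------------------------------------------------------------


def _write_matrix_tsv(m: np.ndarray, labels: list[str], path) -> None:
    pd.DataFrame(m, index=labels, columns=labels).to_csv(path, sep="\t")


def write_fc_matrix(fc: FCMatrix, path_tsv) -> None:
    path_tsv = Path(path_tsv)
    _write_matrix_tsv(fc.R, fc.channel_labels, path_tsv)
    sidecar = {
        "K": int(fc.K),
        "band": fc.band.name if fc.band else None,
        "period": fc.period,
        "fs": fc.fs,
    }
    path_tsv.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def write_network(net: ThresholdedNetwork, path_tsv) -> None:
    path_tsv = Path(path_tsv)
    signed = net.adjacency.astype(int) * np.where(net.excitatory, 1, -1)
    _write_matrix_tsv(signed, net.channel_labels, path_tsv)
    sidecar = {
        "K": int(net.K),
        "k_used": int(net.k_used),
        "band": net.band.name if net.band else None,
        "period": net.period,
        "alpha": net.alpha,
        "r_threshold": net.r_threshold,
    }
    path_tsv.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
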