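"""Serialization: recordings to HDF5 + JSON sidecar, tables to TSV."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .megsim import Recording, SensorArray

__all__ = ["save_recording", "load_recording", "save_cohort_manifest"]


def save_recording(rec: Recording, path: str | Path,
                   sensors: SensorArray | None = None) -> None:
    """Write a continuous recording as HDF5 (data, events, sensor table) with
    a JSON sidecar holding the scalar metadata."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip", compression_opts=4)
        ev = f.create_group("events")
        ev.create_dataset("sample", data=rec.event_samples)
        ev.create_dataset("condition", data=np.array(rec.event_conditions, dtype="S"))
        ev.create_dataset("correct", data=rec.event_correct.astype(np.uint8))
        if sensors is not None:
            g = f.create_group("sensors")
            g.create_dataset("positions", data=sensors.positions)
            g.create_dataset("layout", data=sensors.layout)
    sidecar = {"sfreq": rec.sfreq, "subject_id": rec.subject_id, "seed": rec.seed,
               "n_channels": rec.n_channels, "n_samples": rec.n_samples}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        samples = f["events/sample"][()]
        conds = f["events/condition"][()].astype(str)
        correct = f["events/correct"][()].astype(bool)
    return Recording(data, meta["sfreq"], samples, conds, correct,
                     meta["subject_id"], meta["seed"])


def save_cohort_manifest(behavior: pd.DataFrame, familiarity: pd.Series,
                         path: str | Path) -> None:
    """Cohort-level manifest: per subject x condition behavioral rows joined
    with the familiarity rating, as TSV."""
    fam = familiarity.rename("familiarity").rename_axis("subject").reset_index()
    df = behavior.merge(fam, on="subject", how="left")
    df.to_csv(path, sep="\t", index=False)
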