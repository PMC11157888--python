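"""CSV readers and writers for epoch data, window annotations and summaries.

Formats (UTF-8, header required):

* epochs.csv — one row per epoch: ``subject_id,epoch_index,value_mg``
  with an optional ``state`` column (0 = rest, 1 = active). ``epoch_index``
  is 0-based and must be consecutive per subject; a ``timestamp`` column
  may stand in for ``epoch_index`` provided rows are in temporal order.
* windows.csv — ``subject_id,start_epoch,end_epoch,label`` with half-open,
  0-based intervals and ``label`` in {wake, sleep}.
* summary.csv — one row per subject with the fragmentation metric panel;
  floats are written with 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .series import WindowAnnotation

__all__ = ["read_epochs_csv", "read_windows_csv", "write_summary_csv",
           "write_epochs_csv", "write_windows_csv"]

FLOAT_FORMAT = "%.12g"


def read_epochs_csv(path) -> dict[str, pd.DataFrame]:
    """Read an epoch CSV into one ordered DataFrame per subject."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "value_mg" not in df.columns:
        raise ValueError("epoch CSV needs 'subject_id' and 'value_mg' columns")
    if "epoch_index" in df.columns:
        df = df.sort_values(["subject_id", "epoch_index"], kind="stable")
        for sid, grp in df.groupby("subject_id", sort=False):
            idx = grp["epoch_index"].to_numpy()
            if not np.array_equal(idx, np.arange(idx.size)):
                raise ValueError(
                    f"subject {sid!r}: epoch_index must be consecutive from 0"
                )
    elif "timestamp" not in df.columns:
        raise ValueError("epoch CSV needs an 'epoch_index' or 'timestamp' column")
    return {
        str(sid): grp.reset_index(drop=True)
        for sid, grp in df.groupby("subject_id", sort=False)
    }


def read_windows_csv(path) -> dict[str, WindowAnnotation]:
    """Read a window CSV into one WindowAnnotation per subject."""
    df = pd.read_csv(path)
    required = {"subject_id", "start_epoch", "end_epoch", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"window CSV missing columns: {sorted(missing)}")
    out = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("start_epoch", kind="stable")
        out[str(sid)] = WindowAnnotation(
            list(zip(grp["start_epoch"], grp["end_epoch"], grp["label"]))
        )
    return out


def write_summary_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_epochs_csv(path, subject_id: str, values, states=None) -> None:
    values = np.asarray(values, dtype=float)
    data = {
        "subject_id": subject_id,
        "epoch_index": np.arange(values.size),
        "value_mg": values,
    }
    if states is not None:
        data["state"] = np.asarray(states, dtype=int)
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_windows_csv(path, subject_id: str, annotation: WindowAnnotation) -> None:
    rows = [
        {"subject_id": subject_id, "start_epoch": s, "end_epoch": e, "label": lab}
        for s, e, lab in annotation.intervals
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_metadata_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
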