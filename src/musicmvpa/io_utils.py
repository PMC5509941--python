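"""File-format glue: NIfTI volumes, BIDS-style event tables, confusion CSVs."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "write_volume",
    "read_volume",
    "write_events",
    "read_events",
    "write_confusions",
    "read_confusions",
]

EVENT_COLUMNS = ("onset", "duration", "stimulus_id", "genre")


def write_volume(path, data: np.ndarray, affine: np.ndarray) -> None:
    """Write a 3-D or 4-D array as NIfTI-1, preserving dtype."""
    data = np.asarray(data)
    img = nib.Nifti1Image(data, np.asarray(affine, dtype=float))
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


def read_volume(path) -> tuple:
    """Read a NIfTI volume; returns (data, affine) with on-disk dtype."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=img.header.get_data_dtype())
    return data, img.affine


def write_events(path, events: pd.DataFrame) -> None:
    events[list(EVENT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    """Read a BIDS-style events.tsv; onsets are seconds from run start."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    for col in ("onset", "duration"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index.tolist()
            raise ValueError(f"non-numeric {col} in rows {bad}") from exc
    if (df["onset"] < 0).any():
        bad = df.index[df["onset"] < 0].tolist()
        raise ValueError(f"negative onset in rows {bad}")
    df["stimulus_id"] = df["stimulus_id"].astype(str)
    df["genre"] = df["genre"].astype(str)
    return df


def write_confusions(path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path)


def read_confusions(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
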