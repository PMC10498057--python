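"""Reading and writing recordings, behavior tables and connectome matrices.

The on-disk recording container is a tab-separated matrix, samples in rows
and channels in columns, with a header row of channel labels and a leading
comment line carrying the sampling rate (``# subject=<id> rate_hz=<rate>``).
EDF files are read through :mod:`mne` when a ``.edf`` path is given.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Recording

BEHAVIOR_COLUMNS = ["subject_id", "sex", "age", "rating"]


def write_recording(rec: Recording, path: str | os.PathLike) -> Path:
    """Write a recording as a delimited samples-by-channels matrix."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# subject={rec.subject_id} rate_hz={rec.rate:g}\n")
        fh.write("\t".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.samples.T, fmt="%.6g", delimiter="\t")
    return path


def read_recording(path: str | os.PathLike, subject_id: str | None = None) -> Recording:
    """Read a recording from a TSV matrix or an EDF file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, subject_id)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# subject=... rate_hz=...' header line")
        meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
        labels = fh.readline().strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return Recording(
        subject_id=subject_id or meta.get("subject", path.stem),
        channel_labels=labels,
        rate=float(meta["rate_hz"]),
        samples=data.T,
    )


def _read_edf(path: Path, subject_id: str | None) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        subject_id=subject_id or path.stem,
        channel_labels=list(raw.ch_names),
        rate=float(raw.info["sfreq"]),
        samples=raw.get_data() * 1e6,  # mne holds volts; we hold microvolts
    )


def write_behavior_table(table: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"behavior table missing columns {missing}")
    table[BEHAVIOR_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_behavior_table(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"behavior table {path} missing columns {missing}")
    return table


def write_matrix(matrix: np.ndarray, labels: list[str], path: str | os.PathLike) -> Path:
    """Write a square labelled matrix (e.g. one connectome) as TSV."""
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t", float_format="%.6g")
    return Path(path)


def read_matrix(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.to_numpy(dtype=float), [str(c) for c in frame.columns]
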