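"""File interchange: localization/track CSV, 6-column BED, TIFF stacks, and
ground-truth JSON sidecars.

Column names carry their units (``x_nm``, ``residence_s``, ``D_um2_s``);
BED files are 0-based half-open with strand in column 6.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_points_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_points_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tracks_csv(trackset, path) -> None:
    """Track CSV with the frame interval recorded in a leading comment."""
    with open(path, "w") as fh:
        fh.write(f"# dt_s={trackset.dt_s}\n")
        trackset.data.to_csv(fh, index=False)


def read_tracks_csv(path):
    from .synth import TrackSet

    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# dt_s="):
            raise ValueError("track CSV missing the dt_s header comment")
        dt_s = float(header.split("=", 1)[1])
        df = pd.read_csv(fh)
    return TrackSet(df, dt_s)


def write_bed(df: pd.DataFrame, path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :6]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_truth_json(truth: dict, path) -> None:
    """Ground-truth sidecar; numpy arrays are serialised as lists."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(truth, default=default, indent=1))


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())
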