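"""Plain-text I/O for traces, localization tables, and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_trace(path, times, intensities) -> None:
    """Two-column delimited text: time_s, intensity."""
    df = pd.DataFrame({"time_s": np.asarray(times),
                       "intensity": np.asarray(intensities)})
    df.to_csv(path, index=False)


def read_trace(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    cols = list(df.columns)
    return df[cols[0]].to_numpy(float), df[cols[1]].to_numpy(float)


def write_localizations(path, locs: pd.DataFrame, params: dict | None = None) -> None:
    """Localization table as delimited text with a run-parameters provenance
    block in '#'-prefixed header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        if params:
            fh.write("# run-parameters: " + json.dumps(params, default=str) + "\n")
        locs.to_csv(fh, index=False)


def read_localizations(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    params: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if "run-parameters:" in line:
                params = json.loads(line.split("run-parameters:", 1)[1])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, params


def write_report(path, data: dict) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=float))
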