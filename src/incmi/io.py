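"""Delimited-text input/output.

Formats
-------
spike times
    Two columns (neuron id, time in seconds), whitespace- or
    comma-delimited, optional header line.
binned trains
    A matrix of 0/1 integers, one row per neuron (or per trial).
delay profiles
    Tab-separated columns ``delta, value[, ci_low, ci_high,
    sig_threshold]`` with a header line.
metadata sidecars
    YAML mappings recording the parameters a run needs to be
    regenerated (seed, omega, delta grid, bias flag, ...).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BinnedTrain, DelayProfile, TrialSet

__all__ = [
    "read_spike_times",
    "read_binned_matrix",
    "write_binned_matrix",
    "read_trains",
    "read_trial_set",
    "write_profile",
    "read_profile",
    "write_metadata",
    "read_metadata",
]


def read_spike_times(path) -> dict[str, np.ndarray]:
    """Read a two-column (neuron id, time in seconds) text file.

    Returns a mapping from neuron id (as a string) to a sorted array of
    spike times.  A single header line is tolerated.
    """
    text = Path(path).read_text()
    rows: list[tuple[str, float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected two columns (neuron id, time), "
                f"got {len(parts)}"
            )
        try:
            t = float(parts[1])
        except ValueError:
            if lineno == 1:  # header line
                continue
            raise ValueError(
                f"{path}:{lineno}: could not parse time {parts[1]!r}"
            ) from None
        rows.append((parts[0], t))
    out: dict[str, list[float]] = {}
    for nid, t in rows:
        out.setdefault(nid, []).append(t)
    return {nid: np.sort(np.asarray(ts)) for nid, ts in out.items()}


def read_binned_matrix(path) -> np.ndarray:
    """Read a 0/1 matrix, one row per neuron or trial."""
    arr = np.atleast_2d(np.loadtxt(path, dtype=np.int64))
    if not np.isin(arr, (0, 1)).all():
        bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
        raise ValueError(
            f"{path}: value at row {bad[0] + 1}, column {bad[1] + 1} is not 0/1"
        )
    return arr


def write_binned_matrix(path, rows) -> None:
    arr = np.atleast_2d(np.asarray(rows, dtype=np.int64))
    np.savetxt(path, arr, fmt="%d")


def read_trains(path, bin_width: float | None = None) -> list[BinnedTrain]:
    """Read each row of a binned matrix as one train."""
    return [BinnedTrain(row, bin_width=bin_width) for row in read_binned_matrix(path)]


def read_trial_set(x_path, y_path, bin_width: float | None = None) -> TrialSet:
    """Build a trial set from two matrices with one row per trial."""
    xs = read_trains(x_path, bin_width)
    ys = read_trains(y_path, bin_width)
    if len(xs) != len(ys):
        raise ValueError(
            f"trial count mismatch: {x_path} has {len(xs)} rows, "
            f"{y_path} has {len(ys)}"
        )
    return TrialSet(tuple(zip(xs, ys)))


def write_profile(path, profile: DelayProfile) -> None:
    df = profile.to_frame()
    with open(path, "w") as fh:
        if profile.measure_name:
            fh.write(f"# measure: {profile.measure_name}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_profile(path) -> DelayProfile:
    text = Path(path).read_text()
    name = ""
    body = []
    for line in text.splitlines():
        if line.startswith("# measure:"):
            name = line.split(":", 1)[1].strip()
        elif line and not line.startswith("#"):
            body.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t")
    return DelayProfile(
        deltas=df["delta"].to_numpy(),
        values=df["value"].to_numpy(),
        measure_name=name,
        ci_low=df["ci_low"].to_numpy() if "ci_low" in df else None,
        ci_high=df["ci_high"].to_numpy() if "ci_high" in df else None,
        sig_threshold=df["sig_threshold"].to_numpy() if "sig_threshold" in df else None,
    )


def write_metadata(path, metadata: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=True)


def read_metadata(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
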