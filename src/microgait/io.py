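"""Echo containers, configuration files and CSV exports.

Echo formats:
  * CSV with columns (t, re, im); sample interval recovered from the stamps.
  * A simple binary container: 16-byte little-endian header (uint64 N,
    float64 sample interval) followed by N complex64 pairs; the carrier
    frequency travels alongside in the caller's config.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .boulic import Echo, SegmentTrajectory, WalkParams

__all__ = [
    "write_echo_csv",
    "read_echo_csv",
    "write_echo_bin",
    "read_echo_bin",
    "export_ground_truth",
    "load_walk_config",
]

_MAGIC = b"<Q d"  # struct layout of the header, also a sanity tag


def write_echo_csv(echo: Echo, path) -> None:
    df = pd.DataFrame(
        {"t": echo.times, "re": echo.samples.real, "im": echo.samples.imag}
    )
    df.to_csv(path, index=False)


def read_echo_csv(path, carrier_freq: float) -> Echo:
    df = pd.read_csv(path)
    dt = float(df["t"].iloc[1] - df["t"].iloc[0])
    return Echo(df["re"].to_numpy() + 1j * df["im"].to_numpy(), dt, carrier_freq)


def write_echo_bin(echo: Echo, path) -> None:
    with open(path, "wb") as fh:
        fh.write(struct.pack("<Qd", echo.n_samples, echo.sample_interval))
        echo.samples.astype(np.complex64).tofile(fh)


def read_echo_bin(path, carrier_freq: float) -> Echo:
    with open(path, "rb") as fh:
        n, dt = struct.unpack("<Qd", fh.read(16))
        samples = np.fromfile(fh, dtype=np.complex64, count=n)
    if samples.size != n:
        raise ValueError("truncated echo container")
    return Echo(samples.astype(np.complex128), dt, carrier_freq)


def export_ground_truth(trajs: dict[str, SegmentTrajectory], directory) -> list[Path]:
    """One CSV per segment: (t, range, velocity)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, tr in trajs.items():
        p = directory / f"{name.lower().replace(' ', '_')}.csv"
        pd.DataFrame(
            {"t": tr.times, "range": tr.ranges, "velocity": tr.velocities}
        ).to_csv(p, index=False)
        paths.append(p)
    return paths


def load_walk_config(path) -> WalkParams:
    """WalkParams from a YAML mapping (unknown keys rejected)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    allowed = set(WalkParams.__dataclass_fields__)
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return WalkParams(**cfg)
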