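"""File formats: packed binary streams, g2 curve tables, flat config files.

Packed stream (little-endian throughout)::

    magic   4 bytes  b"CDCS"
    version uint16   1
    n_channels        uint8
    bits_per_channel  uint8
    sampling_frequency_hz uint32
    n_words uint64
    payload n_words x uint32

Curve tables are plain CSV with columns ``tau_seconds, g2[, sigma],
n_frames``.  Config files are flat ``key = value`` text with ``#`` comments.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import AcquisitionSpec
from .bcd import PackedWordStream
from .correlator import G2Curve
from .exceptions import FormatError
from .flow import OpticalProperties

MAGIC = b"CDCS"
VERSION = 1
_HEADER = struct.Struct("<4sHBBIQ")


def write_packed_file(stream: PackedWordStream, path) -> None:
    spec = stream.spec
    fs = round(spec.sampling_frequency_hz)
    header = _HEADER.pack(
        MAGIC, VERSION, spec.n_channels, spec.bits_per_channel, fs, len(stream)
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(stream.words.astype("<u4").tobytes())


def read_packed_file(path, integration_time_s: float | None = None) -> PackedWordStream:
    """Read a packed stream; header fields rebuild the acquisition spec.

    The header does not store the integration time; by default the whole
    record is treated as one frame (t_int = n_words/f_s).  Pass
    ``integration_time_s`` to impose the frame structure used downstream.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER.size:
        raise FormatError(f"file shorter than the {_HEADER.size}-byte header")
    magic, version, n_ch, bits, fs, n_words = _HEADER.unpack_from(raw)
    if magic != MAGIC:
        raise FormatError(f"bad magic {magic!r} at offset 0 (expected {MAGIC!r})")
    if version != VERSION:
        raise FormatError(f"unsupported format version {version}")
    payload = raw[_HEADER.size :]
    if len(payload) != 4 * n_words:
        raise FormatError(
            f"header declares {n_words} words but payload holds "
            f"{len(payload) // 4} (truncated at byte offset {len(raw)})"
        )
    t_int = integration_time_s if integration_time_s is not None else n_words / fs
    spec = AcquisitionSpec(float(fs), t_int, n_ch, bits)
    words = np.frombuffer(payload, dtype="<u4")
    return PackedWordStream(words.copy(), spec)


def write_g2_csv(curve: G2Curve, path) -> None:
    cols = {"tau_seconds": curve.delays_s, "g2": curve.g2}
    if curve.sigma is not None:
        cols["sigma"] = curve.sigma
    cols["n_frames"] = curve.n_frames_averaged
    pd.DataFrame(cols).to_csv(path, index=False)


def read_g2_csv(path, sampling_frequency_hz: float, integration_time_s: float) -> G2Curve:
    df = pd.read_csv(path)
    tau = df["tau_seconds"].to_numpy()
    lags = np.round(tau * sampling_frequency_hz).astype(np.int64)
    return G2Curve(
        lags=lags,
        delays_s=lags / sampling_frequency_hz,
        g2=df["g2"].to_numpy(),
        mean_count_rate_hz=float("nan"),
        integration_time_s=integration_time_s,
        n_frames_averaged=int(df["n_frames"].iloc[0]) if "n_frames" in df else 1,
        sigma=df["sigma"].to_numpy() if "sigma" in df else None,
    )


def write_key_value(mapping: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in mapping.items():
            fh.write(f"{k} = {v}\n")


def read_key_value(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"malformed config line: {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


@dataclass
class RunConfig:
    """Everything the batch pipeline needs for one run.

    ``rho_groups`` maps a source-detector separation (cm) to the channel
    indices detecting at that separation; every channel belongs to exactly
    one group.
    """

    acquisition: AcquisitionSpec
    optics: OpticalProperties
    rho_groups: dict[float, list[int]]
    max_lag: int = 250
    tau_min_s: float | None = None
    tau_max_s: float | None = None
    weighted: bool = False
    average_frames: int = 1
    strict: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        assigned = sorted(ch for chans in self.rho_groups.values() for ch in chans)
        if len(assigned) != len(set(assigned)):
            raise ValueError("a channel is assigned to more than one rho group")
        bad = [c for c in assigned if not 0 <= c < self.acquisition.n_channels]
        if bad:
            raise ValueError(f"channel index {bad[0]} outside 0..n_channels-1")


def _parse_rho_groups(text: str) -> dict[float, list[int]]:
    # e.g. "1.0:0,1,2;2.5:3,4,5,6,7"
    groups: dict[float, list[int]] = {}
    for part in text.split(";"):
        rho, chans = part.split(":")
        groups[float(rho)] = [int(c) for c in chans.split(",")]
    return groups


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a flat key-value file."""
    kv = read_key_value(path)
    acq = AcquisitionSpec(
        sampling_frequency_hz=float(kv.get("sampling_frequency_hz", 1e6)),
        integration_time_s=float(kv.get("integration_time_s", 0.1)),
        n_channels=int(kv.get("n_channels", 8)),
        bits_per_channel=int(kv.get("bits_per_channel", 4)),
    )
    optics = OpticalProperties.from_nm(
        mu_a=float(kv.get("mu_a", 0.1)),
        mu_s_prime=float(kv.get("mu_sp", 10.0)),
        wavelength_nm=float(kv.get("wavelength_nm", 785.0)),
        n_rel=float(kv.get("n_rel", 1.4)),
    )
    tau_min = float(kv["tau_min_us"]) * 1e-6 if "tau_min_us" in kv else None
    tau_max = float(kv["tau_max_us"]) * 1e-6 if "tau_max_us" in kv else None
    return RunConfig(
        acquisition=acq,
        optics=optics,
        rho_groups=_parse_rho_groups(kv.get("rho_groups", "1.0:0,1,2;2.5:3,4,5,6,7")),
        max_lag=int(kv.get("max_lag", 250)),
        tau_min_s=tau_min,
        tau_max_s=tau_max,
        weighted=kv.get("weighted", "false").lower() in ("1", "true", "yes"),
        average_frames=int(kv.get("average_frames", 1)),
        strict=kv.get("strict", "false").lower() in ("1", "true", "yes"),
        out_dir=kv.get("out_dir"),
    )
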