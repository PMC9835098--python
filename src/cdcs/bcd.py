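"""Lossless packing of multi-channel photon counts into BCD-nibble words.

Eight 4-bit binary-coded-decimal counters sample eight detector channels in
parallel; their outputs concatenate into a single 32-bit word per sample bin.
Channel 0 occupies the least-significant nibble.  Because DCS count rates are
low (typically 0-2 photons per microsecond bin), 4 bits per channel are
sufficient and the scheme is lossless while using 1/8 of the bandwidth of
conventional 32-bit-per-channel counting.

The codec never wraps counts: values that do not fit the nibble raise.
Mod-10 counter rollover is a *hardware* loss mechanism and is emulated in
:mod:`cdcs.simulate`, not here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionSpec
from .exceptions import BcdValidityError, CountRangeError

BCD_MAX = 9  # largest value a decimal counter holds before wrapping


@dataclass
class ChannelCountMatrix:
    """Per-channel photon counts, shape ``(n_channels, n_samples)``."""

    counts: np.ndarray
    spec: AcquisitionSpec

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (n_channels, n_samples) array")
        if self.counts.shape[0] != self.spec.n_channels:
            raise ValueError(
                f"counts has {self.counts.shape[0]} rows, spec declares "
                f"{self.spec.n_channels} channels"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.counts < 0).any():
            raise ValueError("photon counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def mean_rate_hz(self) -> np.ndarray:
        """Realized count rate per channel (Hz)."""
        return self.counts.mean(axis=1) * self.spec.sampling_frequency_hz


@dataclass
class PackedWordStream:
    """Sequence of packed words, one per sample bin."""

    words: np.ndarray
    spec: AcquisitionSpec
    bcd_violations: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.words = np.asarray(self.words, dtype=np.uint32)

    def __len__(self) -> int:
        return self.words.size


def _check_frame(counts: np.ndarray, spec: AcquisitionSpec, strict: bool) -> None:
    if counts.shape != (spec.n_channels,):
        raise ValueError(f"expected {spec.n_channels} channel counts, got {counts.shape}")
    bad = np.flatnonzero((counts < 0) | (counts > spec.max_count_per_bin))
    if bad.size:
        raise CountRangeError(
            f"count {counts[bad[0]]} on channel {bad[0]} exceeds "
            f"{spec.bits_per_channel}-bit range 0-{spec.max_count_per_bin}"
        )
    if strict and spec.bits_per_channel == 4:
        bad = np.flatnonzero(counts > BCD_MAX)
        if bad.size:
            raise BcdValidityError(
                f"count {counts[bad[0]]} on channel {bad[0]} is not a valid "
                f"BCD digit (0-9)"
            )


def pack_frame(counts_one_bin, spec: AcquisitionSpec, strict: bool = True) -> int:
    """Pack one sample bin's per-channel counts into a single word.

    Channel ``c`` occupies bits ``[c*b, (c+1)*b)`` of the word, i.e. channel 0
    is the least-significant field.
    """
    counts = np.asarray(counts_one_bin, dtype=np.int64)
    _check_frame(counts, spec, strict)
    shifts = spec.bits_per_channel * np.arange(spec.n_channels, dtype=np.int64)
    return int((counts << shifts).sum())


def unpack_frame(word: int, spec: AcquisitionSpec, strict: bool = True) -> np.ndarray:
    """Invert :func:`pack_frame`: split one word into per-channel counts."""
    if not 0 <= word < (1 << spec.word_bits):
        raise ValueError(f"word {word:#x} outside {spec.word_bits}-bit range")
    shifts = spec.bits_per_channel * np.arange(spec.n_channels, dtype=np.int64)
    counts = (np.int64(word) >> shifts) & spec.max_count_per_bin
    if strict and spec.bits_per_channel == 4:
        bad = np.flatnonzero(counts > BCD_MAX)
        if bad.size:
            raise BcdValidityError(
                f"word {word:#010x}: nibble {bad[0]} holds {counts[bad[0]]} > 9"
            )
    return counts


def pack_stream(matrix: ChannelCountMatrix, strict: bool = True) -> PackedWordStream:
    """Pack a whole count matrix, one word per sample bin (vectorized)."""
    spec = matrix.spec
    counts = matrix.counts.astype(np.int64)
    limit = BCD_MAX if (strict and spec.bits_per_channel == 4) else spec.max_count_per_bin
    over = np.argwhere(counts > limit)
    if over.size:
        ch, samp = over[0]
        exc = BcdValidityError if limit == BCD_MAX else CountRangeError
        raise exc(
            f"count {counts[ch, samp]} on channel {ch} at sample {samp} "
            f"exceeds limit {limit}"
        )
    shifts = spec.bits_per_channel * np.arange(spec.n_channels, dtype=np.uint64)
    words = (counts.astype(np.uint64) << shifts[:, None]).sum(axis=0)
    return PackedWordStream(words.astype(np.uint32), spec)


def find_bcd_violations(words: np.ndarray, spec: AcquisitionSpec) -> np.ndarray:
    """Indices of words containing at least one nibble in 10-15."""
    words = np.asarray(words, dtype=np.uint64)
    shifts = spec.bits_per_channel * np.arange(spec.n_channels, dtype=np.uint64)
    nibbles = (words[None, :] >> shifts[:, None]) & np.uint64(spec.max_count_per_bin)
    return np.flatnonzero((nibbles > BCD_MAX).any(axis=0))


def unpack_stream(stream: PackedWordStream, strict: bool = True) -> ChannelCountMatrix:
    """Invert :func:`pack_stream`.

    In strict mode a word with a non-decimal nibble raises, identifying the
    offending sample.  In permissive mode the raw nibble values pass through
    and the violating sample indices are recorded on the stream's
    ``bcd_violations`` and flagged with a warning — useful when auditing
    recorded hardware streams.
    """
    spec = stream.spec
    if spec.bits_per_channel == 4:
        bad = find_bcd_violations(stream.words, spec)
        if bad.size:
            if strict:
                raise BcdValidityError(
                    f"word at sample {bad[0]} ({int(stream.words[bad[0]]):#010x}) "
                    f"contains a nibble > 9"
                )
            stream.bcd_violations = bad
            warnings.warn(
                f"{bad.size} words contain non-BCD nibbles; passed through",
                stacklevel=2,
            )
    shifts = spec.bits_per_channel * np.arange(spec.n_channels, dtype=np.uint64)
    counts = (stream.words.astype(np.uint64)[None, :] >> shifts[:, None]) & np.uint64(
        spec.max_count_per_bin
    )
    return ChannelCountMatrix(counts.astype(np.int64), spec)


def compression_efficiency(spec_or_bits, reference_bits_per_channel: int = 32) -> float:
    """Fraction of per-channel bandwidth saved versus conventional counting.

    ``1 - bits_per_channel / reference_bits_per_channel``: 4-bit BCD fields in
    place of 32-bit counters give 0.875 (87.5%).
    """
    bits = (
        spec_or_bits.bits_per_channel
        if isinstance(spec_or_bits, AcquisitionSpec)
        else int(spec_or_bits)
    )
    if bits <= 0 or reference_bits_per_channel <= 0:
        raise ValueError("bit widths must be positive")
    if reference_bits_per_channel < bits:
        raise ValueError("reference width must be at least the channel width")
    return 1.0 - bits / reference_bits_per_channel


def bandwidth_required(spec: AcquisitionSpec) -> tuple[float, float]:
    """Data rate of the packed stream.

    Returns ``(bytes_per_second, binary_megabytes_per_second)`` where the
    second value divides by 2^20 (so a 32-bit word at 1 MHz is 4e6 B/s =
    3.81 MB/s).
    """
    bps = (spec.word_bits / 8.0) * spec.sampling_frequency_hz
    return bps, bps / 2**20
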