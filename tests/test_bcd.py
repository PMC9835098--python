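"""Bit-exactness of the BCD nibble codec and its compression accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdcs import (
    AcquisitionSpec,
    ChannelCountMatrix,
    bandwidth_required,
    compression_efficiency,
    pack_frame,
    pack_stream,
    unpack_frame,
    unpack_stream,
)
from cdcs.bcd import find_bcd_violations, PackedWordStream
from cdcs.exceptions import BcdValidityError, CountRangeError


@pytest.mark.parametrize(
    "counts,word",
    [
        ([0] * 8, 0x00000000),
        ([2, 0, 0, 0, 0, 0, 0, 0], 0x00000002),
        ([9] * 8, 0x99999999),
        ([2, 1, 0, 0, 0, 0, 0, 0], 0x00000012),
        ([0, 0, 0, 0, 0, 0, 0, 5], 0x50000000),
    ],
)
def test_pack_frame_nibble_layout(acq8, counts, word):
    assert pack_frame(counts, acq8) == word
    np.testing.assert_array_equal(unpack_frame(word, acq8), counts)


def test_pack_frame_errors(acq8):
    with pytest.raises(CountRangeError, match="channel 3"):
        pack_frame([0, 0, 0, 16, 0, 0, 0, 0], acq8)
    with pytest.raises(BcdValidityError, match="channel 1"):
        pack_frame([0, 10, 0, 0, 0, 0, 0, 0], acq8)
    # 10-15 fit the nibble, so they pack fine in permissive mode
    assert pack_frame([10, 0, 0, 0, 0, 0, 0, 0], acq8, strict=False) == 0x0000000A


def test_unpack_frame_strict_rejects_non_decimal_nibble(acq8):
    with pytest.raises(BcdValidityError, match="nibble 0"):
        unpack_frame(0x0000000A, acq8)
    np.testing.assert_array_equal(
        unpack_frame(0x0000000A, acq8, strict=False), [10, 0, 0, 0, 0, 0, 0, 0]
    )


def test_exhaustive_single_channel_sweep(acq8):
    """Every decimal value in every channel position round-trips exactly."""
    for ch in range(8):
        for v in range(10):
            frame = np.zeros(8, dtype=np.int64)
            frame[ch] = v
            word = pack_frame(frame, acq8)
            assert word == v << (4 * ch)
            np.testing.assert_array_equal(unpack_frame(word, acq8), frame)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.lists(st.integers(0, 9), min_size=8, max_size=8))
def test_roundtrip_property(frame):
    acq = AcquisitionSpec(1e6, 0.05)
    np.testing.assert_array_equal(unpack_frame(pack_frame(frame, acq), acq), frame)


def test_channel_permutation_permutes_nibbles(acq8):
    rng = np.random.default_rng(0)
    frame = rng.integers(0, 10, 8)
    perm = rng.permutation(8)
    direct = unpack_frame(pack_frame(frame[perm], acq8), acq8)
    np.testing.assert_array_equal(direct, frame[perm])


def test_stream_roundtrip_random(acq8):
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 10, size=(8, 1000))
    matrix = ChannelCountMatrix(counts, acq8)
    stream = pack_stream(matrix)
    assert len(stream) == 1000
    np.testing.assert_array_equal(unpack_stream(stream).counts, counts)


def test_stream_length_matches_integration_window():
    """50 ms at 1 MHz clocks out a 50,000-word record."""
    acq = AcquisitionSpec(1e6, 0.05)
    assert acq.samples_per_frame == 50_000
    matrix = ChannelCountMatrix(np.zeros((8, acq.samples_per_frame), dtype=int), acq)
    assert len(pack_stream(matrix)) == 50_000


def test_strict_unpack_rejects_exactly_nonbcd_words(acq8):
    words = np.array([0x00000009, 0x0000000A, 0x99999999, 0xF0000000], dtype=np.uint32)
    bad = find_bcd_violations(words, acq8)
    np.testing.assert_array_equal(bad, [1, 3])
    with pytest.raises(BcdValidityError):
        unpack_stream(PackedWordStream(words, acq8), strict=True)
    with pytest.warns(UserWarning, match="non-BCD"):
        m = unpack_stream(PackedWordStream(words.copy(), acq8), strict=False)
    assert m.counts[0, 1] == 10  # raw nibble passes through


@pytest.mark.parametrize(
    "bits,ref,expected",
    [(4, 32, 0.875), (32, 32, 0.0), (2, 32, 0.9375)],
)
def test_compression_efficiency(bits, ref, expected):
    assert compression_efficiency(bits, ref) == expected


def test_compression_efficiency_validation(acq8):
    assert compression_efficiency(acq8) == 7 / 8
    with pytest.raises(ValueError):
        compression_efficiency(0)
    with pytest.raises(ValueError):
        compression_efficiency(8, 4)


def test_bandwidth_required():
    acq = AcquisitionSpec(1e6, 0.05)
    bps, mb = bandwidth_required(acq)
    assert bps == 4_000_000
    assert mb == pytest.approx(3.8147, abs=1e-4)
    half = AcquisitionSpec(1e6, 0.05, n_channels=4, word_bits=16)
    assert bandwidth_required(half)[0] == bps / 2
    with pytest.raises(ValueError):
        AcquisitionSpec(0.0, 0.05)


def test_spec_invariants():
    with pytest.raises(ValueError):
        AcquisitionSpec(1e6, 0.05, n_channels=9)  # 36 bits > 32
    with pytest.raises(ValueError):
        AcquisitionSpec(1e6, 1e-7)  # window shorter than one bin
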