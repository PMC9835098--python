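"""Pack an 8-channel photon-count stream into BCD-nibble words.

Builds a short synthetic count matrix, packs it losslessly into 32-bit
words (4 bits per channel, channel 0 in the least-significant nibble),
unpacks it back, and prints the compression accounting.
"""

import numpy as np

from cdcs import (
    AcquisitionSpec,
    ChannelCountMatrix,
    bandwidth_required,
    compression_efficiency,
    pack_stream,
    unpack_stream,
)

acq = AcquisitionSpec(sampling_frequency_hz=1e6, integration_time_s=0.05)
rng = np.random.default_rng(0)
counts = rng.poisson(0.5, size=(8, acq.samples_per_frame))  # ~500 kHz/channel

matrix = ChannelCountMatrix(counts, acq)
stream = pack_stream(matrix)
back = unpack_stream(stream)

bps, mb = bandwidth_required(acq)
print(f"packed {matrix.n_samples} sample bins x 8 channels into {len(stream)} words")
print(f"first word: {int(stream.words[0]):#010x}  (nibbles = counts of channels 7..0)")
print(f"lossless roundtrip: {bool((back.counts == counts).all())}")
print(f"compression efficiency vs 32-bit counters: {compression_efficiency(acq):.1%}")
print(f"stream bandwidth at 1 MHz: {bps:.0f} B/s = {mb:.2f} MB/s (binary MB)")
# A 50 ms integration window at a 1 MHz clock is exactly 50,000 words; the
# 87.5% figure is the 4-vs-32 bits-per-channel saving.
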