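"""Acquisition geometry: sampling clock, integration window, channel layout.

A measurement is organised in *frames*: photon counts are binned at the
sampling frequency ``f_s`` (one bin per reset of the hardware counters) and
accumulated for one integration time ``t_int`` before an autocorrelation
estimate is produced.  A 10 ms integration time therefore yields a 100 Hz
acquisition rate, and at ``f_s`` = 1 MHz each frame is a 10,000-point count
vector.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AcquisitionSpec:
    """Sampling parameters shared by the counters, codec and correlator.

    Parameters
    ----------
    sampling_frequency_hz:
        Rate at which the photon counters are read and reset (Hz).
    integration_time_s:
        Duration over which one autocorrelation frame is accumulated (s).
    n_channels:
        Number of simultaneously sampled detector channels.
    bits_per_channel:
        Counter width per channel; 4 for a binary-coded-decimal counter.
    word_bits:
        Width of the packed word holding all channels; default 32.
    """

    sampling_frequency_hz: float
    integration_time_s: float
    n_channels: int = 8
    bits_per_channel: int = 4
    word_bits: int = 32

    def __post_init__(self) -> None:
        if self.sampling_frequency_hz <= 0:
            raise ValueError("sampling_frequency_hz must be positive")
        if self.integration_time_s <= 0:
            raise ValueError("integration_time_s must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be a positive integer")
        if self.bits_per_channel < 1 or self.word_bits < 1:
            raise ValueError("bit widths must be positive")
        if self.n_channels * self.bits_per_channel > self.word_bits:
            raise ValueError(
                f"{self.n_channels} channels x {self.bits_per_channel} bits "
                f"do not fit in a {self.word_bits}-bit word"
            )
        if self.samples_per_frame < 1:
            raise ValueError("integration window shorter than one sample bin")

    @property
    def sample_time_s(self) -> float:
        """Duration of one count bin, 1/f_s (s)."""
        return 1.0 / self.sampling_frequency_hz

    @property
    def samples_per_frame(self) -> int:
        """Number of count bins accumulated per integration window."""
        return round(self.sampling_frequency_hz * self.integration_time_s)

    @property
    def frame_rate_hz(self) -> float:
        """Acquisition rate: autocorrelation frames per second."""
        return 1.0 / self.integration_time_s

    @property
    def max_count_per_bin(self) -> int:
        """Largest count representable in one channel field (2^bits - 1)."""
        return (1 << self.bits_per_channel) - 1
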