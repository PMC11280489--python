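"""WAV input/output, amplitude conventions and time alignment of paired recordings.

Every stage of the equalization pipeline consumes and produces
:class:`AudioSegment` objects: mono waveforms in full-scale float units
(range [-1, +1], where 1.0 is digital full scale) together with their
sample rate.  Field recorders used in passive acoustic monitoring write
uncompressed 16-bit PCM WAV, so 16-bit PCM is the tested interchange
format; integer codes are mapped to full scale by dividing by 2**15.

dBFS is defined throughout as ``20*log10(RMS)`` with full scale = 1.0, so
a −18.74 dBFS white-noise stimulus has RMS ≈ 0.1156.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.io import wavfile
from scipy.signal import correlate, correlation_lags

__all__ = [
    "AudioSegment",
    "AlignedPair",
    "WavFormatError",
    "EmptyAudioError",
    "AlignmentError",
    "SampleRateMismatchError",
    "read_wav",
    "write_wav",
    "align_pair",
    "apply_gain_db",
]

log = logging.getLogger(__name__)

#: 16-bit PCM full scale: integer code / 2**15 -> amplitude in [-1, 1).
PCM16_FULL_SCALE = 32768


class WavFormatError(ValueError):
    """The file is not a WAV encoding this pipeline accepts (PCM)."""


class EmptyAudioError(ValueError):
    """A recording contained zero samples."""


class AlignmentError(ValueError):
    """Two recordings cannot be aligned (no usable overlap)."""


class SampleRateMismatchError(ValueError):
    """An operation on paired recordings received differing sample rates."""


@dataclass(frozen=True)
class AudioSegment:
    """A mono waveform in full-scale units with its sample rate.

    Parameters
    ----------
    samples
        1-D float array of amplitudes; full scale is 1.0.
    sample_rate
        Sampling frequency in Hz (positive integer).
    source_label
        Free-text provenance (device id such as ``"831"`` or ``"SMM1393"``).
    """

    samples: np.ndarray
    sample_rate: int
    source_label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_seconds(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples)))) if len(self) else 0.0

    @property
    def rms_dbfs(self) -> float:
        rms = self.rms
        return 20.0 * np.log10(rms) if rms > 0 else -np.inf

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "AudioSegment":
        return replace(
            self,
            samples=samples,
            source_label=self.source_label if label is None else label,
        )


class AlignedPair(NamedTuple):
    """Result of :func:`align_pair`: both segments trimmed to the overlap.

    ``lag_samples`` is the delay of ``other`` relative to ``ref`` (positive
    means ``other`` starts later).
    """

    ref: AudioSegment
    other: AudioSegment
    lag_samples: int

    @property
    def lag_seconds(self) -> float:
        return self.lag_samples / self.ref.sample_rate


def read_wav(path: str | Path) -> AudioSegment:
    """Read a PCM WAV file into full-scale float units.

    Integer codes are divided by ``2**(bits-1)``; a multichannel file is
    reduced to channel 0 with a warning (the recorders targeted here are
    mono).

    Raises
    ------
    FileNotFoundError
        Missing file.
    WavFormatError
        Not a WAV, or a non-PCM (e.g. IEEE float) encoding.
    EmptyAudioError
        Zero-length audio stream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such WAV file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise WavFormatError(f"{path}: unreadable WAV ({exc})") from exc
    if data.dtype.kind == "f":
        raise WavFormatError(f"{path}: IEEE-float WAV is not PCM; 16-bit PCM expected")
    if data.size == 0:
        raise EmptyAudioError(f"{path}: zero-length audio stream")
    if data.ndim == 2:
        log.warning("%s: %d channels, keeping channel 0", path, data.shape[1])
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / PCM16_FULL_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2**31
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        raise WavFormatError(f"{path}: unsupported PCM sample width {data.dtype}")
    return AudioSegment(samples, int(rate), source_label=path.stem)


def write_wav(segment: AudioSegment, path: str | Path, bits: int = 16) -> Path:
    """Write a segment as 16-bit PCM WAV.

    Samples outside [-1, +1] are clamped (never wrapped — wrapping corrupts
    spectra) and the clip count is logged.  Round-trip error through
    :func:`read_wav` is at most 1 LSB = 2**-15 per sample.
    """
    if bits != 16:
        raise ValueError(f"only 16-bit PCM output is supported, got {bits}")
    if not np.all(np.isfinite(segment.samples)):
        raise ValueError("samples must be finite to be written")
    path = Path(path)
    n_clipped = int(np.count_nonzero(np.abs(segment.samples) > 1.0))
    if n_clipped:
        log.warning("%s: clipping %d samples outside [-1, 1]", path, n_clipped)
    codes = np.clip(
        np.round(segment.samples * PCM16_FULL_SCALE), -32768, 32767
    ).astype(np.int16)
    try:
        wavfile.write(str(path), segment.sample_rate, codes)
    except OSError as exc:
        raise OSError(f"cannot write WAV to {path}: {exc}") from exc
    return path


def align_pair(
    a: AudioSegment, b: AudioSegment, max_lag_s: float = 1.0
) -> AlignedPair:
    """Align two simultaneous recordings by normalized cross-correlation.

    Finds the integer-sample lag of ``b`` relative to ``a`` maximizing the
    cross-correlation of the mean-removed waveforms within ``±max_lag_s``,
    then trims both to the common overlapping window.  Field deployments
    traditionally cut simultaneous recordings by hand at millisecond
    accuracy; the integer-sample grid here is ~0.02 ms at 48 kHz.

    Raises
    ------
    SampleRateMismatchError
        Differing sample rates.
    AlignmentError
        Less than one second of overlap after shifting.
    """
    if a.sample_rate != b.sample_rate:
        raise SampleRateMismatchError(
            f"sample rates differ: {a.sample_rate} vs {b.sample_rate}"
        )
    fs = a.sample_rate
    max_lag = int(round(max_lag_s * fs))
    xa = a.samples - a.samples.mean()
    xb = b.samples - b.samples.mean()
    # correlate(xb, xa) peaks at lag d when b is a delayed (by d) copy of a
    corr = correlate(xb, xa, mode="full", method="fft")
    lags = correlation_lags(xb.size, xa.size, mode="full")
    window = np.abs(lags) <= max_lag
    if not window.any():
        raise AlignmentError("max_lag_s excludes every admissible lag")
    lag = int(lags[window][np.argmax(corr[window])])

    start_a, start_b = (0, lag) if lag >= 0 else (-lag, 0)
    n = min(len(a) - start_a, len(b) - start_b)
    if n < fs:
        raise AlignmentError(
            f"overlap after shifting is {n / fs:.3f} s; at least 1 s required"
        )
    return AlignedPair(
        a.with_samples(a.samples[start_a : start_a + n]),
        b.with_samples(b.samples[start_b : start_b + n]),
        lag,
    )


def apply_gain_db(segment: AudioSegment, gain_db: float) -> AudioSegment:
    """Scale a waveform by ``10**(gain_db / 20)``.

    No clipping is applied here (clipping is a write-time concern); a
    warning is logged if any sample exceeds full scale afterwards.  Used to
    amplify the reference meter's white noise (nominally +18 dB) before the
    curve computation, mirroring the gain set on the soundscape recorders.
    """
    if not np.isfinite(gain_db):
        raise ValueError(f"gain_db must be finite, got {gain_db}")
    out = segment.samples * 10.0 ** (gain_db / 20.0)
    if np.any(np.abs(out) > 1.0):
        log.warning(
            "gain %+.2f dB pushed %d samples beyond full scale",
            gain_db,
            int(np.count_nonzero(np.abs(out) > 1.0)),
        )
    return segment.with_samples(out)
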