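"""Equalization-curve computation and application.

The protocol has two separable stages, mirrored by two CLI steps:

1. *Curve computation* — record the same white-noise stimulus with the
   reference sound-level meter and with the soundscape device, amplify the
   reference to the device's amplifier gain (+18 dB nominally), estimate
   both Welch PSDs with nfft equal to the filter order, take
   ``sqrt(PSD_ref / PSD_dev)`` as the target magnitude grid, and design a
   linear-phase FIR by frequency sampling (interpolation onto a dense
   grid, inverse FFT, Hamming window).

2. *Application to field recordings* — remove the DC offset (its mean),
   convolve with the FIR taps, and cut the first ``order/2`` samples that
   the filter's constant group delay inserted as silence at the start.
   The recording shortens by ``order/2`` samples: 0.0053 s at order 512 up
   to 0.17 s at order 16,384 for 48 kHz audio.

Orders 512, 1024 and 16,384 are the validated defaults; the nfft of the
curve's PSDs is tied to the order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve, firwin2

from .audio_io import AudioSegment, SampleRateMismatchError, apply_gain_db
from .spectral import SegmentTooShortError, estimate_psd

__all__ = [
    "EqualizationCurve",
    "DEFAULT_ORDERS",
    "DEFAULT_REF_GAIN_DB",
    "GAIN_CAP_DB",
    "RATIO_FLOOR",
    "design_fir_frequency_sampling",
    "compute_curve",
    "remove_dc_offset",
    "group_delay_seconds",
    "equalize",
]

log = logging.getLogger(__name__)

#: Filter orders validated by the protocol (good accuracy, moderate phase cost).
DEFAULT_ORDERS = (512, 1024, 16384)

#: Reference-meter gain applied before the PSD ratio, matching the +18 dB
#: amplifier gain soundscape recorders are typically deployed with.
DEFAULT_REF_GAIN_DB = 18.0

#: Cap on the designed magnitude: a white-noise stimulus should never
#: legitimately demand more than +40 dB of correction at any bin.
GAIN_CAP_DB = 40.0

#: Floor on the device PSD in the ratio, preventing division blow-ups at
#: dead bins of degenerate synthetic inputs.
RATIO_FLOOR = 1e-20


class NonLinearPhaseError(ValueError):
    """Taps are not symmetric, so the constant-group-delay trim is invalid."""


@dataclass(frozen=True)
class EqualizationCurve:
    """A linear-phase FIR equalizer with its design grid and provenance.

    ``taps`` has length ``order + 1`` and is symmetric about its midpoint
    (Type-I linear phase), so the filter delays every frequency by exactly
    ``order/2`` samples.  ``design_freqs`` is the normalized grid in
    [0, 1] (1 = Nyquist) and ``design_mags`` the target linear-amplitude
    magnitudes at those points.
    """

    taps: np.ndarray
    order: int
    design_freqs: np.ndarray
    design_mags: np.ndarray
    sample_rate: int
    ref_label: str = ""
    dev_label: str = ""

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=np.float64)
        freqs = np.asarray(self.design_freqs, dtype=np.float64)
        mags = np.asarray(self.design_mags, dtype=np.float64)
        if self.order < 0 or self.order % 2:
            raise ValueError(f"order must be a non-negative even integer, got {self.order}")
        if taps.size != self.order + 1:
            raise ValueError(f"expected {self.order + 1} taps, got {taps.size}")
        scale = float(np.max(np.abs(taps))) or 1.0
        if np.max(np.abs(taps - taps[::-1])) > 1e-9 * scale:
            raise NonLinearPhaseError("taps are not symmetric (non-linear phase)")
        if freqs.size:
            if freqs[0] != 0.0 or freqs[-1] != 1.0 or np.any(np.diff(freqs) <= 0):
                raise ValueError("design_freqs must rise strictly from 0.0 to 1.0")
            if np.any(mags < 0):
                raise ValueError("design_mags must be non-negative")
        object.__setattr__(self, "taps", taps)
        object.__setattr__(self, "design_freqs", freqs)
        object.__setattr__(self, "design_mags", mags)

    def magnitude_response(self, n_points: int = 4096) -> tuple[np.ndarray, np.ndarray]:
        """(freqs in Hz, |H|) of the designed filter on a dense grid."""
        h = np.fft.rfft(self.taps, n=2 * n_points)
        f = np.fft.rfftfreq(2 * n_points, d=1.0 / self.sample_rate)
        return f, np.abs(h)

    def to_json(self, path: str | Path) -> Path:
        """Serialize to a sidecar JSON file (bit-exact round trip)."""
        path = Path(path)
        payload = {
            "format": "ecoeq-curve-v1",
            "sample_rate": self.sample_rate,
            "order": self.order,
            "ref_label": self.ref_label,
            "dev_label": self.dev_label,
            "taps": self.taps.tolist(),
            "design_freqs": self.design_freqs.tolist(),
            "design_mags": self.design_mags.tolist(),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "EqualizationCurve":
        payload = json.loads(Path(path).read_text())
        return cls(
            taps=np.asarray(payload["taps"], dtype=np.float64),
            order=int(payload["order"]),
            design_freqs=np.asarray(payload["design_freqs"], dtype=np.float64),
            design_mags=np.asarray(payload["design_mags"], dtype=np.float64),
            sample_rate=int(payload["sample_rate"]),
            ref_label=payload.get("ref_label", ""),
            dev_label=payload.get("dev_label", ""),
        )


def design_fir_frequency_sampling(
    freqs: np.ndarray, mags: np.ndarray, order: int
) -> np.ndarray:
    """Design Type-I linear-phase FIR taps from a magnitude grid.

    Frequency-sampling method: the (freqs, mags) pairs — normalized
    frequencies in [0, 1] with 1 = Nyquist — are interpolated onto a dense
    grid, inverse-Fourier transformed with a linear-phase term, and
    tapered with a Hamming window.  Returns ``order + 1`` real symmetric
    taps whose magnitude response tracks ``mags`` within ~0.5 dB for
    smooth grids at order >= 512.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    mags = np.asarray(mags, dtype=np.float64)
    if order <= 0 or order % 2:
        raise ValueError(f"order must be a positive even integer, got {order}")
    if freqs.ndim != 1 or freqs.shape != mags.shape:
        raise ValueError("freqs and mags must be 1-D arrays of equal length")
    if freqs[0] != 0.0 or freqs[-1] != 1.0 or np.any(np.diff(freqs) < 0):
        raise ValueError("freqs must rise from 0.0 to 1.0")
    if np.any(mags < 0) or not np.all(np.isfinite(mags)):
        raise ValueError("mags must be finite and non-negative")
    numtaps = order + 1
    nfreqs = 1 + 2 ** int(np.ceil(np.log2(numtaps + 1)))
    return firwin2(numtaps, freqs, mags, nfreqs=nfreqs, window="hamming")


def compute_curve(
    ref_noise: AudioSegment,
    dev_noise: AudioSegment,
    order: int,
    ref_gain_db: float = DEFAULT_REF_GAIN_DB,
) -> EqualizationCurve:
    """Derive a device's equalization curve from paired white-noise takes.

    ``ref_noise`` is the reference meter's recording of the stimulus and
    ``dev_noise`` the soundscape device's recording of the same stimulus.
    The reference is amplified by ``ref_gain_db`` first (the meter records
    at 0 dB gain while deployed recorders use ~+18 dB; amplifying the
    reference avoids altering the device gains optimized for distant
    events).  Both PSDs use nfft equal to the filter order.  The target
    magnitude is ``sqrt(PSD_ref / PSD_dev)`` — the square root converts
    the power ratio to an amplitude response — floored at
    :data:`RATIO_FLOOR` in the denominator and capped at
    :data:`GAIN_CAP_DB`.  Grid endpoints (DC and Nyquist, where one-sided
    PSD estimates are least reliable) are copied from their interior
    neighbors.
    """
    if ref_noise.sample_rate != dev_noise.sample_rate:
        raise SampleRateMismatchError(
            f"sample rates differ: {ref_noise.sample_rate} vs {dev_noise.sample_rate}"
        )
    if order <= 0 or order % 2:
        raise ValueError(f"order must be a positive even integer, got {order}")
    if len(ref_noise) < order or len(dev_noise) < order:
        raise SegmentTooShortError(
            f"both recordings need at least order={order} samples"
        )
    ref = apply_gain_db(ref_noise, ref_gain_db)
    spec_ref = estimate_psd(ref, nfft=order)
    spec_dev = estimate_psd(dev_noise, nfft=order)

    ratio = spec_ref.psd / np.maximum(spec_dev.psd, RATIO_FLOOR)
    mags = np.sqrt(ratio)
    mags = np.minimum(mags, 10.0 ** (GAIN_CAP_DB / 20.0))
    mags[0] = mags[1]
    mags[-1] = mags[-2]

    nyquist = ref_noise.sample_rate / 2.0
    design_freqs = spec_ref.freqs / nyquist
    design_freqs[0] = 0.0
    design_freqs[-1] = 1.0
    taps = design_fir_frequency_sampling(design_freqs, mags, order)
    return EqualizationCurve(
        taps=taps,
        order=order,
        design_freqs=design_freqs,
        design_mags=mags,
        sample_rate=ref_noise.sample_rate,
        ref_label=ref_noise.source_label,
        dev_label=dev_noise.source_label,
    )


def remove_dc_offset(segment: AudioSegment) -> AudioSegment:
    """Subtract the mean of the waveform (mean-estimation DC removal).

    Recorder electronics can bias the waveform away from zero; the bias
    shows up as spurious power in the first frequency bin and corrupts
    indices with no low-frequency limit.  Output mean is zero to rounding.
    """
    if len(segment) == 0:
        raise ValueError("cannot remove DC offset of an empty segment")
    return segment.with_samples(segment.samples - segment.samples.mean())


def group_delay_seconds(curve: EqualizationCurve) -> float:
    """Constant group delay of a linear-phase curve: ``(order/2) / fs``.

    For symmetric taps the group delay and phase delay are identical and
    frequency-independent, so the delay can be corrected by trimming a
    fixed number of samples (symmetry is enforced by the curve invariant).
    """
    return (curve.order / 2.0) / curve.sample_rate


def equalize(segment: AudioSegment, curve: EqualizationCurve) -> AudioSegment:
    """Apply an equalization curve to a recording.

    Pipeline: DC-offset removal → direct-form FIR convolution with the
    taps → trim of the first ``order/2`` output samples (the constant
    group delay, inserted as leading silence).  No trailing padding is
    appended, so the output is ``order/2`` samples shorter than the input
    — the final milliseconds of the take are lost, e.g. a 60 s recording
    keeps 59.83 s at order 16,384.
    """
    if segment.sample_rate != curve.sample_rate:
        raise SampleRateMismatchError(
            f"segment at {segment.sample_rate} Hz vs curve at {curve.sample_rate} Hz"
        )
    half = curve.order // 2
    if len(segment) <= half:
        raise SegmentTooShortError(
            f"segment of {len(segment)} samples too short for order {curve.order}"
        )
    x = remove_dc_offset(segment).samples
    y = fftconvolve(x, curve.taps, mode="full")[half : x.size]
    label = f"{segment.source_label}|eq{curve.order}" if segment.source_label else f"eq{curve.order}"
    return segment.with_samples(y, label=label)
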