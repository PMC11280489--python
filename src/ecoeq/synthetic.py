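"""Synthetic stimuli, device colorations and soundscape scenes.

The equalization protocol is exercised end-to-end on generated audio:

* a Gaussian white-noise stimulus at a stated dBFS RMS (the reference
  sound-level meter's take is the stimulus itself, since a class-1 meter
  is flat by definition);
* device-colored copies of any signal, produced by filtering through a
  parametric sensitivity curve (:class:`DeviceProfile`) built from
  Gaussian resonance peaks, sinusoidal ripple, first-order band-edge
  rolloffs, an overall gain and an electronic DC offset;
* soundscape-like scenes mixing low-frequency noise (anthropophony
  proxy, below ~1.7 kHz), randomly placed mid/high-frequency chirps and
  tones (biophony proxy, 2–10 kHz) and a faint broadband floor.

Three canonical profiles emulate recorder families seen in the field: a
peaked response with a mid-high resonance and poor low-frequency
sensitivity ("SMM-like"), a nearly flat response rolling off above 6 kHz
("SET-like"), and a strongly oscillating response as produced by a
waterproof case ("AM-cased-like").  Profile shapes are parametric, not
digitized device data.

All randomness flows through explicit integer seeds; generation is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, fftconvolve, sosfilt

from .audio_io import AudioSegment
from .equalizer import design_fir_frequency_sampling

__all__ = [
    "DeviceProfile",
    "generate_white_noise",
    "profile_magnitude",
    "simulate_device",
    "generate_scene",
    "smm_like_profile",
    "set_like_profile",
    "am_cased_like_profile",
    "canonical_profiles",
    "STIMULUS_RMS_DBFS",
    "STIMULUS_DURATION_S",
    "DEFAULT_SAMPLE_RATE",
]

#: White-noise stimulus convention: 48 kHz, RMS −18.74 dBFS, 20 s.
DEFAULT_SAMPLE_RATE = 48000
STIMULUS_RMS_DBFS = -18.74
STIMULUS_DURATION_S = 20.0


@dataclass(frozen=True)
class DeviceProfile:
    """Parametric sensitivity curve of a simulated recorder.

    The magnitude in dB at frequency f is the sum of ``gain_db``,
    Gaussian bumps ``height*exp(-0.5*((f-center)/width)**2)`` for each
    entry of ``peaks``, a sinusoidal ripple ``amp*sin(2*pi*f/period)``,
    and first-order low/high rolloffs of −3 dB at the stated corners.
    ``dc_offset`` (full-scale units) is added after filtering, emulating
    recorder electronics bias.
    """

    name: str
    gain_db: float = 0.0
    peaks: tuple[tuple[float, float, float], ...] = ()
    ripple: tuple[float, float] | None = None  # (period Hz, amplitude dB)
    lf_rolloff_hz: float | None = None
    hf_rolloff_hz: float | None = None
    dc_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for center, width, height in self.peaks:
            if width <= 0 or not np.isfinite(height):
                raise ValueError(f"bad peak ({center}, {width}, {height})")
        if self.ripple is not None and (self.ripple[0] <= 0):
            raise ValueError(f"ripple period must be positive, got {self.ripple}")
        for corner in (self.lf_rolloff_hz, self.hf_rolloff_hz):
            if corner is not None and corner <= 0:
                raise ValueError(f"rolloff corner must be positive, got {corner}")


def generate_white_noise(
    duration: float = STIMULUS_DURATION_S,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    rms_dbfs: float = STIMULUS_RMS_DBFS,
    seed: int = 0,
) -> AudioSegment:
    """Gaussian white noise scaled exactly to the requested RMS in dBFS."""
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    x = rng.standard_normal(n)
    x *= 10.0 ** (rms_dbfs / 20.0) / np.sqrt(np.mean(np.square(x)))
    return AudioSegment(x, sample_rate, source_label=f"white-noise-seed{seed}")


def profile_magnitude(profile: DeviceProfile, freqs: np.ndarray) -> np.ndarray:
    """Evaluate a profile's linear magnitude on a frequency grid (Hz)."""
    f = np.asarray(freqs, dtype=np.float64)
    db = np.full(f.shape, profile.gain_db)
    for center, width, height in profile.peaks:
        db += height * np.exp(-0.5 * np.square((f - center) / width))
    if profile.ripple is not None:
        period, amp = profile.ripple
        db += amp * np.sin(2.0 * np.pi * f / period)
    f_safe = np.maximum(f, 1.0)  # keep the curve finite (and positive) at DC
    if profile.lf_rolloff_hz is not None:
        db -= 10.0 * np.log10(1.0 + np.square(profile.lf_rolloff_hz / f_safe))
    if profile.hf_rolloff_hz is not None:
        db -= 10.0 * np.log10(1.0 + np.square(f / profile.hf_rolloff_hz))
    return 10.0 ** (db / 20.0)


def simulate_device(
    segment: AudioSegment, profile: DeviceProfile, order: int = 1024
) -> AudioSegment:
    """Color a recording through a device profile.

    The profile magnitude is sampled on a uniform grid, turned into a
    linear-phase FIR (same frequency-sampling designer the equalizer
    uses), convolved with the input, and the filter's own constant delay
    trimmed so the output stays time-aligned with (and as long as) the
    input.  The profile's DC offset is added afterwards.
    """
    fs = segment.sample_rate
    freqs = np.linspace(0.0, fs / 2.0, order // 2 + 1)
    mags = profile_magnitude(profile, freqs)
    taps = design_fir_frequency_sampling(freqs / (fs / 2.0), mags, order)
    half = order // 2
    y = fftconvolve(segment.samples, taps, mode="full")[half : half + len(segment)]
    y = y + profile.dc_offset
    return AudioSegment(y, fs, source_label=profile.name)


def generate_scene(
    duration: float = 60.0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    anthro_level_db: float = -30.0,
    bio_events: int = 12,
    seed: int = 0,
) -> AudioSegment:
    """A soundscape-like scene: low-frequency noise plus chirps and tones.

    The anthropophony proxy is white noise low-passed at 1.5 kHz and
    scaled to ``anthro_level_db`` RMS (dBFS); the biophony proxy is
    ``bio_events`` randomly placed 2–10 kHz chirps/tones of 0.1–0.5 s
    with Hann envelopes and peaks around −28 dBFS; a −80 dBFS broadband
    floor keeps every band minimally excited.  Deterministic per seed.
    """
    if duration < 1.0:
        raise ValueError(f"duration must be at least 1 s, got {duration}")
    rng = np.random.default_rng(seed)
    fs = sample_rate
    n = int(round(duration * fs))

    anthro = rng.standard_normal(n)
    sos = butter(4, 1500.0, btype="low", fs=fs, output="sos")
    anthro = sosfilt(sos, anthro)
    anthro *= 10.0 ** (anthro_level_db / 20.0) / np.sqrt(np.mean(np.square(anthro)))

    floor = rng.standard_normal(n)
    floor *= 10.0 ** (-80.0 / 20.0) / np.sqrt(np.mean(np.square(floor)))

    scene = anthro + floor
    for _ in range(bio_events):
        dur = rng.uniform(0.1, 0.5)
        m = int(dur * fs)
        start = rng.integers(0, max(n - m, 1))
        f0 = rng.uniform(2000.0, 9000.0)
        f1 = float(np.clip(f0 + rng.uniform(-1500.0, 1500.0), 2000.0, 10000.0))
        t = np.arange(m) / fs
        phase = 2.0 * np.pi * (f0 * t + 0.5 * (f1 - f0) / dur * t**2)
        amp = 10.0 ** (rng.uniform(-33.0, -23.0) / 20.0)
        event = amp * np.sin(phase) * np.hanning(m)
        scene[start : start + m] += event

    return AudioSegment(scene, fs, source_label=f"scene-seed{seed}")


def smm_like_profile(dc_offset: float = 0.02) -> DeviceProfile:
    """Peaked response: mid-high resonance, high-frequency dip, weak LF."""
    return DeviceProfile(
        name="SMM-like",
        peaks=((6500.0, 1500.0, 12.0), (12000.0, 2500.0, -9.0)),
        lf_rolloff_hz=120.0,
        dc_offset=dc_offset,
    )


def set_like_profile() -> DeviceProfile:
    """Nearly flat response up to ~6 kHz, gentle rolloff above."""
    return DeviceProfile(
        name="SET-like",
        hf_rolloff_hz=6000.0,
        lf_rolloff_hz=60.0,
    )


def am_cased_like_profile(dc_offset: float = 0.015) -> DeviceProfile:
    """Strongly oscillating response, as produced by a waterproof case."""
    return DeviceProfile(
        name="AM-cased-like",
        ripple=(900.0, 5.0),
        lf_rolloff_hz=150.0,
        dc_offset=dc_offset,
    )


def canonical_profiles() -> dict[str, DeviceProfile]:
    """The three canonical test profiles keyed by name."""
    profiles = (smm_like_profile(), set_like_profile(), am_cased_like_profile())
    return {p.name: p for p in profiles}
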