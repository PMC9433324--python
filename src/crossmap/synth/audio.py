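"""Render click trains into synthetic wideband audio for detector round-trips."""

from __future__ import annotations

import numpy as np

from ..utils import as_rng

AUDIO_RATE = 100_000.0  # Hz

# mean absolute deviation of a standard normal
_NORMAL_MAD = np.sqrt(2.0 / np.pi)


def click_template(sr: float = AUDIO_RATE, f0: float = 30_000.0,
                   sigma_us: float = 40.0) -> np.ndarray:
    """Gaussian-windowed cosine transient (~240 us support, energy 18-40 kHz)."""
    sigma = sigma_us * 1e-6
    half = 3.0 * sigma
    t = np.arange(-half, half, 1.0 / sr)
    return np.cos(2.0 * np.pi * f0 * t) * np.exp(-0.5 * (t / sigma) ** 2)


def save_wav(path: str, audio: np.ndarray, sr: float = AUDIO_RATE) -> None:
    """Write mono float audio as 16-bit WAV (scaled to 90% full range)."""
    from scipy.io import wavfile

    peak = np.max(np.abs(audio)) or 1.0
    data = (audio / peak * 0.9 * np.iinfo(np.int16).max).astype(np.int16)
    wavfile.write(path, int(sr), data)


def load_wav(path: str) -> tuple[np.ndarray, float]:
    from scipy.io import wavfile

    sr, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data.astype(float) / np.iinfo(np.int16).max
    return np.asarray(data, dtype=float), float(sr)


def render_click_audio(times: np.ndarray, duration: float, rng,
                       snr: float | np.ndarray = 300.0,
                       sr: float = AUDIO_RATE) -> np.ndarray:
    """Unit-variance Gaussian noise plus click transients of given SNR.

    SNR is defined against the session MAD of the background, matching the
    detector's normalisation; ``snr`` may be scalar or per-click.
    """
    rng = as_rng(rng)
    n = int(round(duration * sr))
    audio = rng.standard_normal(n)
    tmpl = click_template(sr)
    half = tmpl.size // 2
    snr = np.broadcast_to(np.asarray(snr, dtype=float), np.shape(times))
    for t0, s in zip(np.asarray(times, dtype=float), snr):
        i = int(round(t0 * sr)) - half
        lo, hi = max(0, i), min(n, i + tmpl.size)
        if hi <= lo:
            continue
        audio[lo:hi] += s * _NORMAL_MAD * tmpl[lo - i:hi - i]
    return audio
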