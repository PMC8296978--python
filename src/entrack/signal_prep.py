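"""Filtering, resampling, and envelope preprocessing for stimuli and EEG.

The envelope chain is: magnitude of the analytic signal, 25 Hz
least-squares-FIR low-pass, downsampling to the analysis rate, first
difference, half-wave rectification, and unit-area normalization. All
filters are applied with zero phase (symmetric FIR kernels convolved
with ``mode='same'``) so that no latency is introduced anywhere in the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .errors import (AlignmentError, DegenerateEnvelopeError, ParameterError,
                     SchemaError)

__all__ = [
    "Waveform",
    "ModulationEnvelope",
    "EEGEpoch",
    "hilbert_envelope",
    "preprocess_envelope",
    "fir_bandpass",
    "resample",
    "average_epochs",
    "read_wav",
    "write_wav",
    "read_eeg_container",
    "write_eeg_container",
    "logmel_features",
]

# Least-squares FIR orders scale as 4 * rate / transition_width; at audio
# rates that would be tens of thousands of taps, so the design is capped.
# At 16 kHz the cap widens the 25 Hz low-pass transition to ~31 Hz, which
# is irrelevant for a sub-10 Hz modulation envelope.
_MAX_FIR_ORDER = 2048


@dataclass
class Waveform:
    """A single-channel signal with a sampling rate and onset marker.

    Parameters
    ----------
    samples : ndarray
        Signal samples, arbitrary units.
    rate_hz : float
        Sampling rate in Hz, > 0.
    onset_index : int
        Sample index of stimulus onset (0 when the signal starts at onset).
    """

    samples: np.ndarray
    rate_hz: float
    onset_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise ParameterError("rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz


@dataclass
class ModulationEnvelope:
    """Preprocessed stimulus drive: nonnegative, unit area.

    ``samples`` is the half-wave-rectified first derivative of the
    low-passed amplitude envelope, normalized so that it sums to 1.
    """

    samples: np.ndarray
    rate_hz: float
    source_stimulus_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise ParameterError("rate_hz must be positive")
        if np.any(self.samples < 0):
            raise ParameterError("envelope samples must be nonnegative")
        if abs(self.samples.sum() - 1.0) > 1e-9:
            raise ParameterError("envelope samples must sum to 1")


@dataclass
class EEGEpoch:
    """Channel x time EEG matrix for one participant/stimulus/repetition."""

    data: np.ndarray  # (n_channels, n_times), microvolts
    rate_hz: float
    window_ms: tuple[float, float]  # (start, end) relative to onset
    participant_id: str = ""
    stimulus_id: str = ""
    repetition_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        start, end = self.window_ms
        if not (start < 0 < end):
            raise ParameterError("epoch window must straddle onset")
        if self.rate_hz <= 0:
            raise ParameterError("rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def onset_index(self) -> int:
        """Sample index corresponding to stimulus onset (t = 0)."""
        return int(round(-self.window_ms[0] / 1000.0 * self.rate_hz))


# ---------------------------------------------------------------------------
# FIR design and zero-phase application
# ---------------------------------------------------------------------------

_kernel_cache: dict[tuple, np.ndarray] = {}


def _ls_fir_order(rate_hz: float, transition_hz: float) -> int:
    order = int(round(4.0 * rate_hz / transition_hz / 2.0) * 2)
    return max(8, min(order, _MAX_FIR_ORDER))


def _ls_lowpass_kernel(rate_hz: float, cutoff_hz: float,
                       transition_hz: float = 5.0) -> np.ndarray:
    key = ("lslp", rate_hz, cutoff_hz, transition_hz)
    if key not in _kernel_cache:
        nyq = rate_hz / 2.0
        order = _ls_fir_order(rate_hz, transition_hz)
        eff_transition = max(transition_hz, 4.0 * rate_hz / order)
        stop = min(cutoff_hz + eff_transition, nyq * 0.999)
        # a linear ramp across the transition keeps the LSQ design from
        # blowing up in an unconstrained gap
        taps = sps.firls(order + 1,
                         [0, cutoff_hz, cutoff_hz, stop, stop, nyq],
                         [1, 1, 1, 0, 0, 0], fs=rate_hz)
        _kernel_cache[key] = taps
    return _kernel_cache[key]


def _ls_bandpass_kernel(rate_hz: float, lo_hz: float, hi_hz: float) -> np.ndarray:
    key = ("lsbp", rate_hz, lo_hz, hi_hz)
    if key not in _kernel_cache:
        nyq = rate_hz / 2.0
        if lo_hz == 0:
            return _ls_lowpass_kernel(rate_hz, hi_hz,
                                      transition_hz=min(5.0, (nyq - hi_hz) / 2))
        tw_lo = max(lo_hz / 2.0, 1.0)
        tw_hi = min(5.0, (nyq - hi_hz) / 2.0)
        order = _ls_fir_order(rate_hz, min(tw_lo, tw_hi))
        lo_stop = max(lo_hz - tw_lo, lo_hz / 2.0)
        hi_stop = hi_hz + tw_hi
        bands = [0, lo_stop, lo_stop, lo_hz, lo_hz, hi_hz,
                 hi_hz, hi_stop, hi_stop, nyq]
        desired = [0, 0, 0, 1, 1, 1, 1, 0, 0, 0]
        taps = sps.firls(order + 1, bands, desired, fs=rate_hz)
        _kernel_cache[key] = taps
    return _kernel_cache[key]


def _gaussian_kernel(rate_hz: float, lo_hz: float, hi_hz: float) -> np.ndarray:
    """FIR kernel with a Gaussian magnitude response centered on the band.

    sigma is half the band width; the time-domain kernel is truncated at
    four sigma of the corresponding Gaussian time constant.
    """
    key = ("gauss", rate_hz, lo_hz, hi_hz)
    if key not in _kernel_cache:
        center = (lo_hz + hi_hz) / 2.0
        sigma_f = (hi_hz - lo_hz) / 2.0
        sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
        numtaps = int(8.0 * sigma_t * rate_hz) | 1
        numtaps = max(numtaps, 9)
        nyq = rate_hz / 2.0
        freqs = np.linspace(0.0, nyq, 1025)
        gain = (np.exp(-0.5 * ((freqs - center) / sigma_f) ** 2)
                + np.exp(-0.5 * ((freqs + center) / sigma_f) ** 2))
        nfreqs = max(2 ** int(np.ceil(np.log2(numtaps))) * 2 + 1, 2049)
        taps = sps.firwin2(numtaps, freqs, gain, fs=rate_hz, nfreqs=nfreqs)
        _kernel_cache[key] = taps
    return _kernel_cache[key]


def _zero_phase(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve with a symmetric (linear-phase) kernel, compensating the
    group delay, so the output is zero-phase and the same length as x."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return sps.fftconvolve(x, kernel, mode="same")
    return sps.fftconvolve(x, kernel[np.newaxis, :], mode="same", axes=-1)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def hilbert_envelope(w: Waveform, cutoff_hz: float = 25.0,
                     transition_hz: float = 5.0) -> Waveform:
    """Amplitude envelope: |analytic signal| low-passed with a
    least-squares FIR filter.

    Parameters
    ----------
    w : Waveform
        Input signal; must have at least 2 samples and a sampling rate
        above twice the low-pass cutoff.
    cutoff_hz : float
        Low-pass cutoff applied to the rectified magnitude.

    Returns
    -------
    Waveform
        Nonnegative envelope at the input rate.
    """
    x = w.samples
    if len(x) < 2:
        raise ParameterError("input too short for envelope extraction")
    if w.rate_hz <= 2.0 * cutoff_hz:
        raise ParameterError(
            f"rate {w.rate_hz} Hz too low for a {cutoff_hz} Hz low-pass")
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(max(n, 2))))
    analytic = sps.hilbert(x, N=nfft)[:n]
    env = np.abs(analytic)
    kernel = _ls_lowpass_kernel(w.rate_hz, cutoff_hz, transition_hz)
    out = _zero_phase(env, kernel)
    np.clip(out, 0.0, None, out=out)
    return Waveform(out, w.rate_hz, w.onset_index)


def preprocess_envelope(env: Waveform, target_rate_hz: float,
                        stimulus_id: str = "") -> ModulationEnvelope:
    """Downsample, differentiate, half-wave rectify, unit-area normalize.

    The first derivative is the first difference scaled by the target
    rate (units 1/s); negative values are set to zero and the result is
    divided by its sum so the samples sum to exactly 1.

    Raises
    ------
    DegenerateEnvelopeError
        If the rectified derivative sums to zero (e.g. a constant or
        monotonically decreasing envelope).
    """
    if target_rate_hz <= 0:
        raise ParameterError("target_rate_hz must be positive")
    if target_rate_hz > env.rate_hz:
        raise ParameterError("target rate must not exceed the envelope rate")
    x = resample(env.samples, env.rate_hz, target_rate_hz)
    d = np.diff(x) * target_rate_hz
    np.clip(d, 0.0, None, out=d)
    total = d.sum()
    if total <= 0:
        raise DegenerateEnvelopeError(
            "rectified envelope derivative sums to zero; cannot normalize")
    d /= total
    # guard against accumulated floating error in the unit-area invariant
    d /= d.sum()
    return ModulationEnvelope(d, target_rate_hz, stimulus_id)


def fir_bandpass(x: Sequence[float], rate_hz: float, lo_hz: float,
                 hi_hz: float, kind: str = "least_squares") -> np.ndarray:
    """Zero-phase FIR band-pass (or low-pass when ``lo_hz`` is 0).

    ``kind='least_squares'`` uses a least-squares design with flat pass
    band; ``kind='gaussian'`` uses a kernel whose magnitude response is a
    Gaussian centered on the band (sigma = half band width), which suits
    narrow 2 Hz analysis bands.
    """
    if not (0 <= lo_hz < hi_hz < rate_hz / 2.0):
        raise ParameterError(
            f"band edges ({lo_hz}, {hi_hz}) invalid for rate {rate_hz}")
    if kind == "least_squares":
        kernel = (_ls_lowpass_kernel(rate_hz, hi_hz,
                                     min(5.0, (rate_hz / 2 - hi_hz) / 2))
                  if lo_hz == 0 else _ls_bandpass_kernel(rate_hz, lo_hz, hi_hz))
    elif kind == "gaussian":
        kernel = _gaussian_kernel(rate_hz, lo_hz, hi_hz)
    else:
        raise ParameterError(f"unknown filter kind {kind!r}")
    return _zero_phase(np.asarray(x, dtype=float), kernel)


def resample(x: Sequence[float], rate_from: float, rate_to: float) -> np.ndarray:
    """Anti-aliased rational-ratio resampling (polyphase).

    Output length is ``ceil(len(x) * rate_to / rate_from)``. The two
    rates must be rationally related within 1e-9 (denominator <= 10000).
    """
    if rate_from <= 0 or rate_to <= 0:
        raise ParameterError("rates must be positive")
    x = np.asarray(x, dtype=float)
    if rate_from == rate_to:
        return x.copy()
    frac = Fraction(rate_to / rate_from).limit_denominator(10000)
    if abs(float(frac) - rate_to / rate_from) > 1e-9:
        raise ParameterError("rates must be rationally related")
    return sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def average_epochs(epochs: Sequence[EEGEpoch],
                   channel_subset: Sequence[int]) -> np.ndarray:
    """Mean over repetitions, then mean over the channel subset.

    All epochs must share the sampling rate, window, and channel count.
    """
    if len(epochs) == 0:
        raise ParameterError("need at least one epoch")
    subset = np.asarray(channel_subset, dtype=int)
    if subset.size == 0:
        raise ParameterError("channel subset must be nonempty")
    ref = epochs[0]
    for ep in epochs[1:]:
        if (ep.rate_hz != ref.rate_hz or ep.window_ms != ref.window_ms
                or ep.data.shape != ref.data.shape):
            raise AlignmentError("epochs differ in rate, window, or shape")
    stacked = np.stack([ep.data for ep in epochs])
    return stacked.mean(axis=0)[subset].mean(axis=0)


# ---------------------------------------------------------------------------
# WAV I/O (16 kHz PCM mono stimuli)
# ---------------------------------------------------------------------------

def read_wav(path) -> Waveform:
    """Read a mono PCM WAV file into a float Waveform scaled to [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        raise ParameterError("expected a mono WAV file")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return Waveform(data.astype(float), float(rate))


def write_wav(path, w: Waveform) -> None:
    """Write a Waveform as 16-bit PCM, peak-normalized when needed."""
    x = w.samples
    peak = np.max(np.abs(x)) if len(x) else 0.0
    if peak > 1.0:
        x = x / peak
    wavfile.write(path, int(round(w.rate_hz)), (x * 32767.0).astype(np.int16))


# ---------------------------------------------------------------------------
# Hierarchical EEG epoch container (HDF5)
# ---------------------------------------------------------------------------
# Layout: /<participant_id>/<stimulus_id>/r<repetition> holds the
# channel x time matrix with attributes rate_hz and window_ms.

def write_eeg_container(path, epochs: Iterable[EEGEpoch]) -> None:
    """Write epochs to an HDF5 container, one dataset per repetition."""
    import h5py

    with h5py.File(path, "w") as f:
        for ep in epochs:
            name = (f"{ep.participant_id}/{ep.stimulus_id}"
                    f"/r{ep.repetition_index}")
            ds = f.create_dataset(name, data=ep.data)
            ds.attrs["rate_hz"] = ep.rate_hz
            ds.attrs["window_ms"] = list(ep.window_ms)


def read_eeg_container(path) -> list[EEGEpoch]:
    """Read every epoch from an HDF5 container.

    Raises
    ------
    SchemaError
        If a dataset lacks the rate_hz or window_ms attribute.
    """
    import h5py

    out: list[EEGEpoch] = []
    with h5py.File(path, "r") as f:
        for p_name, p_grp in sorted(f.items()):
            for s_name, s_grp in sorted(p_grp.items()):
                for r_name, ds in sorted(s_grp.items()):
                    for attr in ("rate_hz", "window_ms"):
                        if attr not in ds.attrs:
                            raise SchemaError(
                                f"{p_name}/{s_name}/{r_name} missing "
                                f"attribute {attr!r}")
                    out.append(EEGEpoch(
                        ds[()], float(ds.attrs["rate_hz"]),
                        tuple(ds.attrs["window_ms"]),
                        participant_id=p_name,
                        stimulus_id=s_name,
                        repetition_index=int(r_name.removeprefix("r"))))
    return out


# ---------------------------------------------------------------------------
# Log-mel features for the surrogate networks
# ---------------------------------------------------------------------------

def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_mels: int, n_fft: int, rate_hz: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_fft, 1.0 / rate_hz)
    edges = _mel_inv(np.linspace(_mel(0.0), _mel(rate_hz / 2.0), n_mels + 2))
    fb = np.zeros((n_mels, len(freqs)))
    for i in range(n_mels):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - freqs) / max(hi - mid, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def logmel_features(w: Waveform, frame_rate_hz: float = 50.0,
                    n_mels: int = 26, win_s: float = 0.032) -> np.ndarray:
    """Log-mel spectrogram frames (n_mels x n_frames) at a fixed stride.

    The hop is ``rate / frame_rate`` samples so the frame rate matches the
    network analysis rate.
    """
    hop = int(round(w.rate_hz / frame_rate_hz))
    if hop < 1:
        raise ParameterError("frame rate exceeds the audio rate")
    nper = max(int(round(win_s * w.rate_hz)), hop)
    n_fft = int(2 ** np.ceil(np.log2(nper)))
    # pad so the frame count covers the whole duration (>= n/hop frames)
    x = np.concatenate([w.samples, np.zeros(nper)])
    _, _, z = sps.stft(x, fs=w.rate_hz, nperseg=nper,
                       noverlap=nper - hop, nfft=n_fft, boundary=None,
                       padded=False)
    power = np.abs(z) ** 2
    fb = _mel_filterbank(n_mels, n_fft, w.rate_hz)
    return np.log(fb @ power + 1e-10)
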