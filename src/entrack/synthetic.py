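"""Synthetic stimuli, EEG, and network activations.

Every generator is a pure function of (config, master seed, indices), so
any subset of the data can be regenerated independently: EEG epochs are
streamed one participant/stimulus at a time rather than materialized.

The EEG model: the preprocessed stimulus drive convolved with a biphasic
kernel (negative lobe near 140 ms, positive near 220 ms, a difference of
two Gaussians — an N1-P2-like shape) appears, scaled per channel,
on top of 1/f ("pink") noise. Frontocentral channels carry the response
at full gain; the rest at a reduced gain.

The "trained" network model: each layer carries the (negated) stimulus
drive, delayed by a configurable lag, with a per-layer gain peaking at
the recurrent layer, plus unit white noise. Untrained networks are
random-weight surrogates run on log-mel features of the stimulus.

Both the EEG and the trained activations additionally carry a shared
per-stimulus *latent* time series that is not derivable from the
envelope. This emulates learned stimulus features: untrained networks
can only pass the envelope through, so representational similarity
between EEG and the trained network exceeds the untrained baseline, with
a margin that scales with the per-layer gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import signal_prep
from .activations import (LayerActivationSet, SurrogateNetworkSpec,
                          make_untrained_ensemble, surrogate_forward)
from .errors import ParameterError
from .signal_prep import EEGEpoch, ModulationEnvelope, Waveform

__all__ = [
    "SyntheticConfig",
    "gen_stimulus",
    "stimulus_envelope",
    "gen_eeg_epoch",
    "gen_eeg",
    "gen_network_responses",
    "untrained_specs",
    "pink_noise",
]

# Seed-stream identifiers: every RNG is seeded from
# SeedSequence((master_seed, STREAM, *indices)).
_STREAM_STIM = 1
_STREAM_EEG = 2
_STREAM_NET = 3
_STREAM_ENSEMBLE = 4
_STREAM_LATENT = 5

# Zero-based indices of the 12 frontocentral sensors of a 128-channel
# EGI net (sensors 4, 5, 6, 11, 12, 13, 20, 21, 25, 113, 119, 124).
DEFAULT_FRONTOCENTRAL = (3, 4, 5, 10, 11, 12, 19, 20, 24, 112, 118, 123)


@dataclass(frozen=True)
class SyntheticConfig:
    """Defaults mirror the study design: 25 stimuli of 5.5-6.5 s heard
    four times by 15 participants wearing a 128-channel net."""

    n_stimuli: int = 25
    n_participants: int = 15
    n_repetitions: int = 4
    n_channels: int = 128
    frontocentral_subset: tuple[int, ...] = DEFAULT_FRONTOCENTRAL
    stim_duration_s: tuple[float, float] = (5.5, 6.5)
    syllable_rate_hz: float = 5.0
    audio_rate_hz: float = 16000.0
    eeg_rate_hz: float = 250.0
    net_frame_rate_hz: float = 50.0
    epoch_window_ms: tuple[float, float] = (-700.0, 7800.0)
    # biphasic response kernel
    kernel_neg_latency_ms: float = 140.0
    kernel_pos_latency_ms: float = 220.0
    kernel_neg_amp: float = 1.0
    kernel_pos_amp: float = 0.8
    kernel_sigma_ms: float = 15.0
    snr_db: float = 0.0
    nonfocal_gain: float = 0.3
    # shared "learned feature" latent (EEG + trained network only)
    latent_gain_eeg: float = 2.0
    latent_mix: float = 2.0
    # trained-network emulation
    layer_gains: tuple[float, ...] = (0.1, 0.2, 0.3, 0.8, 0.5)
    layer_lag_ms: float = 140.0
    layer_sizes: tuple[int, ...] = (64, 64, 64, 64, 64)
    net_noise_sd: float = 1.0
    relu_clip: float = 20.0
    init_scale: float = 0.1
    n_untrained: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_stimuli, self.n_participants, self.n_repetitions,
               self.n_channels) < 1:
            raise ParameterError("all design counts must be >= 1")
        if max(self.frontocentral_subset, default=0) >= self.n_channels:
            raise ParameterError("frontocentral subset outside channel range")
        if not (self.epoch_window_ms[0] < 0 < self.epoch_window_ms[1]):
            raise ParameterError("epoch window must straddle onset")
        for lat in (self.kernel_neg_latency_ms, self.kernel_pos_latency_ms):
            if not 0 < lat < self.epoch_window_ms[1]:
                raise ParameterError("kernel latencies must be within epoch")


def _rng(cfg: SyntheticConfig, stream: int, *indices: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((cfg.master_seed, stream) + indices))


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """1/f-amplitude noise along the last axis, unit variance."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC drift
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

def gen_stimulus(cfg: SyntheticConfig, index: int) -> Waveform:
    """Noise carrier amplitude-modulated at a jittered syllable rate.

    Syllable "pulses" are Hann windows placed at quasi-periodic onsets
    (15% interval jitter), so the modulation spectrum peaks near
    ``syllable_rate_hz``.
    """
    if not 0 <= index < cfg.n_stimuli:
        raise ParameterError("stimulus index out of range")
    rng = _rng(cfg, _STREAM_STIM, index)
    lo, hi = cfg.stim_duration_s
    duration = lo + (hi - lo) * rng.uniform()
    rate = cfg.audio_rate_hz
    n = int(round(duration * rate))

    period = 1.0 / cfg.syllable_rate_hz
    width = int(round(0.7 * period * rate))
    pulse = np.hanning(width)
    env = np.zeros(n)
    t = 0.25 * period * rng.uniform()
    while t < duration:
        i0 = int(round(t * rate))
        i1 = min(i0 + width, n)
        env[i0:i1] += pulse[: i1 - i0] * (0.6 + 0.8 * rng.uniform())
        t += period * (1.0 + 0.15 * rng.standard_normal())
    env += 0.05  # low-level floor so the carrier never fully gates off

    carrier = rng.standard_normal(n)
    x = carrier * env
    x *= 0.1 / np.sqrt(np.mean(x ** 2))  # RMS normalize
    return Waveform(x, rate, onset_index=0)


def stimulus_envelope(cfg: SyntheticConfig, index: int,
                      target_rate_hz: float) -> ModulationEnvelope:
    """Preprocessed modulation envelope of stimulus ``index``."""
    return _cached_envelope(cfg, index, float(target_rate_hz))


@lru_cache(maxsize=512)
def _cached_envelope(cfg: SyntheticConfig, index: int,
                     target_rate_hz: float) -> ModulationEnvelope:
    w = gen_stimulus(cfg, index)
    env = signal_prep.hilbert_envelope(w)
    return signal_prep.preprocess_envelope(env, target_rate_hz,
                                           stimulus_id=f"s{index:03d}")


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _response_kernel(cfg: SyntheticConfig, rate_hz: float) -> np.ndarray:
    """Biphasic kernel: negative Gaussian lobe at the early latency,
    positive lobe at the late latency."""
    sigma = cfg.kernel_sigma_ms / 1000.0
    t_max = cfg.kernel_pos_latency_ms / 1000.0 + 5.0 * sigma
    t = np.arange(0.0, t_max, 1.0 / rate_hz)
    neg = np.exp(-0.5 * ((t - cfg.kernel_neg_latency_ms / 1000.0) / sigma) ** 2)
    pos = np.exp(-0.5 * ((t - cfg.kernel_pos_latency_ms / 1000.0) / sigma) ** 2)
    return -cfg.kernel_neg_amp * neg + cfg.kernel_pos_amp * pos


def stimulus_latent(cfg: SyntheticConfig, stimulus_index: int) -> np.ndarray:
    """Per-stimulus latent feature series at the network frame rate.

    Unit-RMS 1/f noise, a pure function of (config seed, stimulus); the
    same series drives both the synthetic EEG and the trained-network
    activations, emulating learned features the envelope does not carry.
    """
    rng = _rng(cfg, _STREAM_LATENT, stimulus_index)
    w = gen_stimulus(cfg, stimulus_index)
    n = int(np.ceil(w.duration_s * cfg.net_frame_rate_hz))
    lat = pink_noise(rng, (n,))
    return lat / np.sqrt(np.mean(lat ** 2))


def _clean_response(cfg: SyntheticConfig, stimulus_index: int) -> np.ndarray:
    """Noise-free single-channel response over the full epoch window.

    Normalized to unit RMS over its support so that the epoch noise
    level can be stimulus-independent (background EEG noise must not
    encode stimulus identity).
    """
    rate = cfg.eeg_rate_hz
    drive = stimulus_envelope(cfg, stimulus_index, rate).samples
    kernel = _response_kernel(cfg, rate)
    resp = np.convolve(drive, kernel)
    if cfg.latent_gain_eeg != 0:
        lat = signal_prep.resample(stimulus_latent(cfg, stimulus_index),
                                   cfg.net_frame_rate_hz, rate)
        n = min(len(lat), len(resp))
        rms = np.sqrt(np.mean(resp[:n] ** 2))
        resp[:n] = resp[:n] + cfg.latent_gain_eeg * rms * lat[:n]
    rms = np.sqrt(np.mean(resp ** 2))
    if rms > 0:
        resp = resp / rms
    n_epoch = _epoch_samples(cfg)
    onset = _onset_index(cfg)
    out = np.zeros(n_epoch)
    n_fit = min(len(resp), n_epoch - onset)
    out[onset:onset + n_fit] = resp[:n_fit]
    return out


def _epoch_samples(cfg: SyntheticConfig) -> int:
    start, end = cfg.epoch_window_ms
    return int(round((end - start) / 1000.0 * cfg.eeg_rate_hz))


def _onset_index(cfg: SyntheticConfig) -> int:
    return int(round(-cfg.epoch_window_ms[0] / 1000.0 * cfg.eeg_rate_hz))


def gen_eeg_epoch(cfg: SyntheticConfig, stimulus_index: int,
                  participant: int, repetition: int,
                  channels: np.ndarray | None = None) -> EEGEpoch:
    """One channel x time epoch with the planted envelope response.

    ``channels`` restricts generation to a channel subset (same values
    as the corresponding rows of the full epoch, since each channel has
    its own noise stream position in a channel-major block).
    """
    rng = _rng(cfg, _STREAM_EEG, stimulus_index, participant, repetition)
    n_epoch = _epoch_samples(cfg)
    clean = _clean_response(cfg, stimulus_index)

    gains = np.full(cfg.n_channels, cfg.nonfocal_gain)
    gains[list(cfg.frontocentral_subset)] = 1.0
    # small per-participant amplitude idiosyncrasy (seeded by participant)
    prng = _rng(cfg, _STREAM_EEG, participant)
    gains = gains * (1.0 + 0.1 * prng.standard_normal(cfg.n_channels))

    noise = pink_noise(rng, (cfg.n_channels, n_epoch))
    if cfg.kernel_neg_amp == 0 and cfg.kernel_pos_amp == 0:
        signal = np.zeros((cfg.n_channels, n_epoch))
    else:
        # clean response has unit RMS over its support, so the noise
        # level depends only on the configured snr, never on the stimulus
        noise_scale = 10.0 ** (-cfg.snr_db / 20.0)
        signal = gains[:, None] * clean[None, :]
        noise = noise * noise_scale
    data = signal + noise
    if channels is not None:
        data = data[np.asarray(channels, dtype=int)]
    return EEGEpoch(data, cfg.eeg_rate_hz, cfg.epoch_window_ms,
                    participant_id=f"p{participant:02d}",
                    stimulus_id=f"s{stimulus_index:03d}",
                    repetition_index=repetition)


def gen_eeg(cfg: SyntheticConfig, stimulus_index: int,
            channels: np.ndarray | None = None,
            ) -> dict[int, list[EEGEpoch]]:
    """All epochs for one stimulus: participant -> list of repetitions."""
    return {p: [gen_eeg_epoch(cfg, stimulus_index, p, r, channels=channels)
                for r in range(cfg.n_repetitions)]
            for p in range(cfg.n_participants)}


# ---------------------------------------------------------------------------
# Network activations
# ---------------------------------------------------------------------------

def untrained_specs(cfg: SyntheticConfig,
                    n: int | None = None) -> list[SurrogateNetworkSpec]:
    """The untrained-ensemble surrogate specs for this configuration."""
    template = SurrogateNetworkSpec(
        layer_sizes=tuple(cfg.layer_sizes),
        input_feature_count=26,
        frame_rate_hz=cfg.net_frame_rate_hz,
        relu_clip=cfg.relu_clip,
        init_scale=cfg.init_scale)
    ensemble_seed = int(_rng(cfg, _STREAM_ENSEMBLE).integers(2 ** 31))
    return make_untrained_ensemble(template,
                                   cfg.n_untrained if n is None else n,
                                   ensemble_seed)


def gen_network_responses(cfg: SyntheticConfig, stimulus_index: int,
                          mode: str = "trained",
                          spec: SurrogateNetworkSpec | None = None,
                          ) -> list[LayerActivationSet]:
    """Five layers of activations for one stimulus.

    ``trained``: unit activations follow the negated, delayed stimulus
    drive with per-layer gain (peaking at the recurrent layer 4) plus
    white unit noise, so matched correlograms show a trough at
    ``layer_lag_ms``. ``untrained``: a random-weight surrogate network
    is run on log-mel features of the stimulus (pass ``spec`` to select
    the ensemble member).
    """
    sid = f"s{stimulus_index:03d}"
    if mode == "untrained":
        if spec is None:
            spec = untrained_specs(cfg, n=1)[0]
        feats = signal_prep.logmel_features(
            gen_stimulus(cfg, stimulus_index),
            frame_rate_hz=cfg.net_frame_rate_hz)
        return surrogate_forward(spec, feats,
                                 network_id=f"untrained-{spec.seed}",
                                 stimulus_id=sid)
    if mode != "trained":
        raise ParameterError("mode must be 'trained' or 'untrained'")

    rate = cfg.net_frame_rate_hz
    drive = stimulus_envelope(cfg, stimulus_index, rate).samples
    lag = int(round(cfg.layer_lag_ms / 1000.0 * rate))
    delayed = np.concatenate([np.zeros(lag), drive])
    drive_rms = float(np.sqrt(np.mean(delayed ** 2)))
    latent = stimulus_latent(cfg, stimulus_index) * drive_rms
    n = len(delayed)
    lat = np.zeros(n)
    m = min(len(latent), n - lag)
    lat[lag:lag + m] = latent[:m]
    max_gain = max(cfg.layer_gains)
    out = []
    for li, (gain, size) in enumerate(zip(cfg.layer_gains, cfg.layer_sizes),
                                      start=1):
        # unit gains/mixes are properties of the network, fixed across
        # stimuli; the distractor and noise are per (stimulus, layer)
        wrng = _rng(cfg, _STREAM_NET, li)
        unit_gain = wrng.uniform(0.5, 1.5, size=size)
        mix = cfg.latent_mix * wrng.standard_normal(size)
        rng = _rng(cfg, _STREAM_NET, stimulus_index, li)
        # low-gain layers replace the missing stimulus structure with a
        # layer-specific distractor of matched power, so total activation
        # power is layer-independent while the informative fraction (and
        # hence RDM similarity and envelope tracking) follows the gain
        fake_drive = pink_noise(rng, (n,))
        fake_drive *= drive_rms / np.sqrt(np.mean(fake_drive ** 2))
        fake_lat = pink_noise(rng, (n,)) * drive_rms
        beta = float(np.sqrt(max(max_gain ** 2 - gain ** 2, 0.0)))
        base = (gain * (-unit_gain[:, None] * delayed[None, :]
                        + mix[:, None] * lat[None, :])
                + beta * (-unit_gain[:, None] * fake_drive[None, :]
                          + mix[:, None] * fake_lat[None, :]))
        noise = cfg.net_noise_sd * drive_rms * rng.standard_normal(base.shape)
        out.append(LayerActivationSet(
            base + noise, layer_index=li, frame_rate_hz=rate,
            network_id="trained", trained=True, stimulus_id=sid))
    return out
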