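"""Per-layer network activations and untrained surrogate networks.

The analysis treats a trained speech-recognition network as a data
source: its activations arrive in a hierarchical container. What this
module builds itself is the architecture-matched *untrained* surrogate:
three clipped-ReLU layers, a unidirectional LSTM layer, and a final
clipped-ReLU layer, with weights drawn once from a seed. The softmax
output layer is excluded from all analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import h5py
import numpy as np

from .errors import ParameterError, SchemaError

__all__ = [
    "LayerActivationSet",
    "SurrogateNetworkSpec",
    "surrogate_forward",
    "make_untrained_ensemble",
    "write_activation_container",
    "read_activation_container",
]

N_ANALYSIS_LAYERS = 5
RECURRENT_LAYER_INDEX = 4


@dataclass
class LayerActivationSet:
    """Unit x frame activations for one network instance, layer, stimulus."""

    data: np.ndarray  # (n_units, n_frames)
    layer_index: int  # 1..5
    frame_rate_hz: float
    network_id: str
    trained: bool
    stimulus_id: str = ""
    shuffle_seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not 1 <= self.layer_index <= N_ANALYSIS_LAYERS:
            raise ParameterError("layer_index must be in 1..5")
        if self.frame_rate_hz <= 0:
            raise ParameterError("frame_rate_hz must be positive")

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SurrogateNetworkSpec:
    """Recipe for one random-weight surrogate network."""

    layer_sizes: tuple[int, int, int, int, int] = (64, 64, 64, 64, 64)
    input_feature_count: int = 26
    frame_rate_hz: float = 50.0
    relu_clip: float = 20.0
    init_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) != N_ANALYSIS_LAYERS:
            raise ParameterError("exactly five layer sizes required")
        if any(s < 1 for s in self.layer_sizes):
            raise ParameterError("layer sizes must be >= 1")
        if self.relu_clip <= 0 or self.init_scale <= 0:
            raise ParameterError("relu_clip and init_scale must be positive")


def _clipped_relu(x: np.ndarray, clip: float) -> np.ndarray:
    return np.clip(x, 0.0, clip)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def surrogate_forward(spec: SurrogateNetworkSpec, features: np.ndarray,
                      network_id: str = "", stimulus_id: str = "",
                      ) -> list[LayerActivationSet]:
    """Run features through a random-weight surrogate network.

    Layers 1-3 and 5 are affine maps followed by a clipped ReLU
    (``min(max(x, 0), relu_clip)``); layer 4 is a standard unidirectional
    LSTM over frames. Weights are uniform in [-init_scale, +init_scale],
    biases zero, all drawn once from ``spec.seed`` in a fixed order, so
    equal specs and features give bit-identical activations.

    Parameters
    ----------
    features : ndarray
        feature x frame matrix aligned to stimulus onset.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ParameterError("features must be a 2-D feature x frame matrix")
    if not np.all(np.isfinite(x)):
        raise ParameterError("features must be finite")
    if x.shape[0] != spec.input_feature_count:
        raise ParameterError(
            f"expected {spec.input_feature_count} features, got {x.shape[0]}")
    rng = np.random.default_rng(spec.seed)
    s = spec.init_scale
    h1, h2, h3, h4, h5 = spec.layer_sizes

    def draw(rows: int, cols: int) -> np.ndarray:
        return rng.uniform(-s, s, size=(rows, cols))

    w1, w2, w3 = draw(h1, x.shape[0]), draw(h2, h1), draw(h3, h2)
    wx, wh = draw(4 * h4, h3), draw(4 * h4, h4)
    w5 = draw(h5, h4)

    a1 = _clipped_relu(w1 @ x, spec.relu_clip)
    a2 = _clipped_relu(w2 @ a1, spec.relu_clip)
    a3 = _clipped_relu(w3 @ a2, spec.relu_clip)

    n_frames = x.shape[1]
    zx = wx @ a3  # input contribution precomputed for all frames
    h = np.zeros(h4)
    c = np.zeros(h4)
    a4 = np.empty((h4, n_frames))
    for t in range(n_frames):
        z = zx[:, t] + wh @ h
        i = _sigmoid(z[:h4])
        f = _sigmoid(z[h4:2 * h4])
        g = np.tanh(z[2 * h4:3 * h4])
        o = _sigmoid(z[3 * h4:])
        c = f * c + i * g
        h = o * np.tanh(c)
        a4[:, t] = h

    a5 = _clipped_relu(w5 @ a4, spec.relu_clip)

    return [
        LayerActivationSet(a, layer_index=k + 1,
                           frame_rate_hz=spec.frame_rate_hz,
                           network_id=network_id, trained=False,
                           stimulus_id=stimulus_id, shuffle_seed=spec.seed)
        for k, a in enumerate((a1, a2, a3, a4, a5))
    ]


def make_untrained_ensemble(spec_template: SurrogateNetworkSpec, n: int,
                            master_seed: int) -> list[SurrogateNetworkSpec]:
    """n surrogate specs with distinct seeds derived from master_seed."""
    if n < 1:
        raise ParameterError("ensemble size must be >= 1")
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [replace(spec_template, seed=int(c.generate_state(1)[0]))
            for c in children]


# ---------------------------------------------------------------------------
# Hierarchical activation container (HDF5)
# ---------------------------------------------------------------------------
# Layout: /net-<network_id>/stim-<stimulus_id>/layer-<k>
# with attributes layer_index, frame_rate_hz, trained, and optionally
# shuffle_seed on each dataset.

_REQUIRED_ATTRS = ("layer_index", "frame_rate_hz", "trained")


def write_activation_container(path, sets: Sequence[LayerActivationSet]) -> None:
    """Write activation sets to an HDF5 container (lossless round trip)."""
    with h5py.File(path, "w") as f:
        for s in sets:
            grp = f.require_group(f"net-{s.network_id}/stim-{s.stimulus_id}")
            ds = grp.create_dataset(f"layer-{s.layer_index}", data=s.data)
            ds.attrs["layer_index"] = s.layer_index
            ds.attrs["frame_rate_hz"] = s.frame_rate_hz
            ds.attrs["trained"] = s.trained
            if s.shuffle_seed is not None:
                ds.attrs["shuffle_seed"] = s.shuffle_seed


def read_activation_container(path) -> list[LayerActivationSet]:
    """Read every activation set from an HDF5 container.

    Raises
    ------
    SchemaError
        If any dataset lacks a required attribute.
    """
    out: list[LayerActivationSet] = []
    with h5py.File(path, "r") as f:
        for net_name, net_grp in sorted(f.items()):
            network_id = net_name.removeprefix("net-")
            for stim_name, stim_grp in sorted(net_grp.items()):
                stimulus_id = stim_name.removeprefix("stim-")
                for ds_name, ds in sorted(stim_grp.items()):
                    for attr in _REQUIRED_ATTRS:
                        if attr not in ds.attrs:
                            raise SchemaError(
                                f"{net_name}/{stim_name}/{ds_name} missing "
                                f"attribute {attr!r}")
                    seed = ds.attrs.get("shuffle_seed")
                    out.append(LayerActivationSet(
                        data=ds[()],
                        layer_index=int(ds.attrs["layer_index"]),
                        frame_rate_hz=float(ds.attrs["frame_rate_hz"]),
                        network_id=network_id,
                        trained=bool(ds.attrs["trained"]),
                        stimulus_id=stimulus_id,
                        shuffle_seed=None if seed is None else int(seed)))
    return out
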