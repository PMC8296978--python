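"""Representational similarity analysis.

Representational dissimilarity matrices (RDMs) are Euclidean-distance
matrices over per-stimulus response vectors. RDM comparisons use the
Spearman rank correlation over the strictly-lower triangle with
average-tie ranks; this makes comparisons invariant to any strictly
increasing transform of either matrix's distances.

EEG RDM pipeline order: response vectors per repetition -> RDM per
repetition -> mean over repetitions -> per-participant RDM. Group
analyses either correlate per-participant RDMs (one rho per participant)
or the across-participant mean RDM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from . import signal_prep
from .activations import LayerActivationSet
from .errors import AlignmentError, ParameterError, UndefinedCorrelationError
from .signal_prep import EEGEpoch
from .tracking import PairedTestResult

__all__ = [
    "RDM",
    "RSAComparison",
    "NoiseCeiling",
    "ElectrodeMap",
    "LayerProfile",
    "response_vector",
    "activation_vector",
    "compute_rdm",
    "average_rdms",
    "compare_rdms",
    "layer_profile",
    "band_rsa",
    "electrode_rsa",
    "noise_ceiling",
    "rank_transform",
]


@dataclass
class RDM:
    """Symmetric stimulus x stimulus dissimilarity matrix."""

    matrix: np.ndarray
    stimulus_order: tuple
    metric: str = "euclidean"
    source: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.stimulus_order = tuple(self.stimulus_order)
        n = len(self.stimulus_order)
        if self.matrix.shape != (n, n):
            raise AlignmentError("matrix shape must match stimulus order")
        if not np.all(np.isfinite(self.matrix)):
            raise ParameterError("RDM entries must be finite")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ParameterError("RDM must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-10):
            raise ParameterError("RDM diagonal must be zero")

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_order)

    def lower_triangle(self) -> np.ndarray:
        """Strictly-lower-triangle entries, n(n-1)/2 values."""
        i, j = np.tril_indices(self.n_stimuli, k=-1)
        return self.matrix[i, j]


@dataclass
class RSAComparison:
    rho: float
    layer_index: int
    subject_or_instance: str = ""
    group: str = "trained"  # or "untrained"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ParameterError("rho must lie in [-1, 1]")


@dataclass
class NoiseCeiling:
    lower: float
    upper: float


@dataclass
class LayerProfile:
    """Per-layer trained-vs-untrained group comparison."""

    mean_rho_trained: np.ndarray  # (n_layers,)
    mean_rho_untrained: np.ndarray
    rho_trained: np.ndarray  # (n_participants, n_layers)
    rho_untrained: np.ndarray  # ensemble-averaged, same shape
    tests: list[PairedTestResult]  # one per layer


@dataclass
class ElectrodeMap:
    """Per-electrode, per-layer RSA with a significance mask."""

    rho: np.ndarray  # (n_electrodes, n_layers) mean trained rho
    rho_untrained: np.ndarray
    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray  # boolean, p < alpha
    masked_rho: np.ndarray  # rho where mask, exactly 0 elsewhere
    alpha: float


# ---------------------------------------------------------------------------
# Vector construction
# ---------------------------------------------------------------------------

def response_vector(epoch: EEGEpoch, channel_subset: Sequence[int],
                    window_s: tuple[float, float]) -> np.ndarray:
    """Pool channel time series into one vector (channel-major order).

    ``window_s`` is (start, end) in seconds relative to stimulus onset;
    all stimuli are truncated to this common window so vectors are
    comparable in length.
    """
    subset = np.asarray(channel_subset, dtype=int)
    if subset.size == 0:
        raise ParameterError("channel subset must be nonempty")
    i0 = epoch.onset_index + int(round(window_s[0] * epoch.rate_hz))
    i1 = epoch.onset_index + int(round(window_s[1] * epoch.rate_hz))
    if i0 < 0 or i1 > epoch.data.shape[1] or i0 >= i1:
        raise AlignmentError("window outside epoch extent")
    return epoch.data[subset, i0:i1].ravel()


def activation_vector(act: LayerActivationSet, n_frames: int) -> np.ndarray:
    """Flatten a unit x frame activation matrix truncated to n_frames."""
    if act.n_frames < n_frames:
        raise AlignmentError(
            f"activation has {act.n_frames} frames, need {n_frames}")
    return act.data[:, :n_frames].ravel()


# ---------------------------------------------------------------------------
# RDM construction and comparison
# ---------------------------------------------------------------------------

def compute_rdm(vectors: Mapping, metric: str = "euclidean",
                source: str = "") -> RDM:
    """Pairwise Euclidean distances between per-stimulus vectors.

    ``vectors`` maps stimulus id -> equal-length 1-D vector; the RDM row
    order follows the mapping's iteration order.
    """
    ids = tuple(vectors.keys())
    if len(ids) < 2:
        raise ParameterError("need at least two stimuli")
    arrs = [np.asarray(vectors[i], dtype=float).ravel() for i in ids]
    lengths = {len(a) for a in arrs}
    if len(lengths) != 1:
        raise AlignmentError(f"vectors have unequal lengths: {sorted(lengths)}")
    mat = squareform(pdist(np.stack(arrs), metric=metric))
    return RDM(mat, ids, metric=metric, source=source)


def average_rdms(rdms: Sequence[RDM]) -> RDM:
    """Elementwise mean of RDMs sharing a stimulus order."""
    if len(rdms) == 0:
        raise ParameterError("need at least one RDM")
    ref = rdms[0]
    for r in rdms[1:]:
        if r.stimulus_order != ref.stimulus_order:
            raise AlignmentError("RDMs differ in stimulus order")
    mean = np.mean([r.matrix for r in rdms], axis=0)
    return RDM(mean, ref.stimulus_order, metric=ref.metric,
               source=f"mean({len(rdms)})")


def compare_rdms(a: RDM, b: RDM) -> float:
    """Spearman rank correlation over the strictly-lower triangles."""
    if a.stimulus_order != b.stimulus_order:
        raise AlignmentError("RDMs differ in stimulus order")
    x, y = a.lower_triangle(), b.lower_triangle()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "RDM lower triangle is constant; Spearman rho undefined")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def rank_transform(rdm: RDM) -> RDM:
    """Rank-transform distances and scale them into [0, 1].

    Lower-triangle values are replaced by their average-tie ranks mapped
    linearly onto [0, 1] (all 0.5 when every distance ties), mirrored to
    the upper triangle; the diagonal stays 0. The output is a strictly
    monotone function of the input, so Spearman comparisons are
    unchanged.
    """
    vals = rdm.lower_triangle()
    m = len(vals)
    ranks = stats.rankdata(vals, method="average")
    scaled = (ranks - 1.0) / (m - 1.0) if m > 1 else np.full(m, 0.5)
    if m > 1 and np.ptp(vals) == 0:
        scaled = np.full(m, 0.5)
    out = np.zeros_like(rdm.matrix)
    i, j = np.tril_indices(rdm.n_stimuli, k=-1)
    out[i, j] = scaled
    out[j, i] = scaled
    return RDM(out, rdm.stimulus_order, metric=rdm.metric,
               source=f"rank({rdm.source})")


# ---------------------------------------------------------------------------
# Group analyses
# ---------------------------------------------------------------------------

def _untrained_mean_rho(participant_rdm: RDM,
                        ensemble_layer_rdms: Sequence[Mapping[int, RDM]],
                        layer: int) -> float:
    return float(np.mean([compare_rdms(participant_rdm, inst[layer])
                          for inst in ensemble_layer_rdms]))


def layer_profile(eeg_rdms: Sequence[RDM],
                  trained_layer_rdms: Mapping[int, RDM],
                  untrained_layer_rdms: Sequence[Mapping[int, RDM]],
                  mode: str = "two_sample") -> LayerProfile:
    """Trained vs untrained RDM similarity per layer.

    For each participant and layer, compute rho against the trained
    network RDM and the mean rho over the untrained ensemble; per layer,
    compare the two sets of participant coefficients with a two-tailed
    t-test (``two_sample``: df = 2 n - 2, as reported for group
    comparisons; ``paired`` also available). Positive t means the
    trained network is the more brain-like.
    """
    from .tracking import paired_peak_test  # local import avoids cycle noise

    if len(eeg_rdms) < 2:
        raise ParameterError("need at least two participants")
    if len(untrained_layer_rdms) < 1:
        raise ParameterError("need at least one untrained instance")
    layers = sorted(trained_layer_rdms.keys())
    n_p = len(eeg_rdms)
    rho_t = np.empty((n_p, len(layers)))
    rho_u = np.empty((n_p, len(layers)))
    for pi, prdm in enumerate(eeg_rdms):
        for li, layer in enumerate(layers):
            rho_t[pi, li] = compare_rdms(prdm, trained_layer_rdms[layer])
            rho_u[pi, li] = _untrained_mean_rho(prdm, untrained_layer_rdms,
                                                layer)
    tests = [paired_peak_test(rho_t[:, li], rho_u[:, li], mode=mode)
             for li in range(len(layers))]
    return LayerProfile(rho_t.mean(axis=0), rho_u.mean(axis=0),
                        rho_t, rho_u, tests)


def _participant_rdm(epochs: Mapping, channel_subset, window_s,
                     source: str) -> RDM:
    """Per-repetition RDMs averaged into one participant RDM.

    ``epochs`` maps stimulus id -> list of EEGEpoch (repetitions).
    """
    ids = list(epochs.keys())
    n_reps = min(len(v) for v in epochs.values())
    per_rep = []
    for rep in range(n_reps):
        vectors = {sid: response_vector(epochs[sid][rep], channel_subset,
                                        window_s) for sid in ids}
        per_rep.append(compute_rdm(vectors, source=source))
    return average_rdms(per_rep)


def band_rsa(epochs_by_participant: Mapping,
             channel_subset: Sequence[int],
             window_s: tuple[float, float],
             bands: Sequence[tuple[float, float]],
             layer_rdms: Mapping[int, RDM],
             filter_kind: str = "gaussian") -> np.ndarray:
    """rho per (band, layer) between band-filtered EEG and layer RDMs.

    EEG epochs are filtered per band (Gaussian FIR by default), RDMs
    rebuilt per repetition, averaged over repetitions and participants,
    and the across-participant mean RDM is compared with each layer RDM.

    Returns an array of shape (n_bands, n_layers) in ascending layer
    order.
    """
    layers = sorted(layer_rdms.keys())
    per_band: list[list[RDM]] = [[] for _ in bands]
    # participants outer so epochs_by_participant may be a lazy mapping
    for pid, by_stim in epochs_by_participant.items():
        by_stim = dict(by_stim)
        for bi, (lo, hi) in enumerate(bands):
            filtered = {}
            for sid, reps in by_stim.items():
                filtered[sid] = [
                    EEGEpoch(signal_prep.fir_bandpass(ep.data, ep.rate_hz,
                                                      lo, hi, filter_kind),
                             ep.rate_hz, ep.window_ms, ep.participant_id,
                             ep.stimulus_id, ep.repetition_index)
                    for ep in reps]
            per_band[bi].append(_participant_rdm(
                filtered, channel_subset, window_s,
                source=f"eeg_band({lo},{hi})"))
    out = np.empty((len(bands), len(layers)))
    for bi in range(len(bands)):
        mean_rdm = average_rdms(per_band[bi])
        for li, layer in enumerate(layers):
            out[bi, li] = compare_rdms(mean_rdm, layer_rdms[layer])
    return out


def electrode_rsa(epochs_by_participant: Mapping,
                  n_electrodes: int,
                  window_s: tuple[float, float],
                  trained_layer_rdms: Mapping[int, RDM],
                  untrained_layer_rdms: Sequence[Mapping[int, RDM]],
                  alpha: float = 0.05,
                  bh_correct: bool = False) -> ElectrodeMap:
    """Per-electrode RSA with trained-vs-untrained significance masking.

    For each electrode and layer: per-participant rho against the
    trained RDM and the ensemble-averaged untrained rho; a two-sample
    two-tailed t-test across participants; electrodes with p < alpha
    form the mask, and the masked mean trained rho is exactly 0
    elsewhere. Benjamini-Hochberg correction across electrodes is
    available per layer (off by default).
    """
    layers = sorted(trained_layer_rdms.keys())
    pids = list(epochs_by_participant.keys())
    n_p = len(pids)
    if n_p < 2:
        raise ParameterError("need at least two participants")
    rho_t = np.empty((n_electrodes, len(layers), n_p))
    rho_u = np.empty((n_electrodes, len(layers), n_p))
    for pi, pid in enumerate(pids):
        by_stim = epochs_by_participant[pid]
        for e in range(n_electrodes):
            prdm = _participant_rdm(by_stim, [e], window_s,
                                    source=f"eeg_electrode {e}")
            for li, layer in enumerate(layers):
                rho_t[e, li, pi] = compare_rdms(prdm,
                                                trained_layer_rdms[layer])
                rho_u[e, li, pi] = _untrained_mean_rho(
                    prdm, untrained_layer_rdms, layer)
    t = np.empty((n_electrodes, len(layers)))
    p = np.empty((n_electrodes, len(layers)))
    for e in range(n_electrodes):
        for li in range(len(layers)):
            res = stats.ttest_ind(rho_t[e, li], rho_u[e, li])
            t[e, li], p[e, li] = res.statistic, res.pvalue
    if bh_correct:
        mask = np.zeros_like(p, dtype=bool)
        for li in range(len(layers)):
            mask[:, li] = _benjamini_hochberg(p[:, li], alpha)
    else:
        mask = p < alpha
    mean_rho = rho_t.mean(axis=2)
    masked = np.where(mask, mean_rho, 0.0)
    return ElectrodeMap(mean_rho, rho_u.mean(axis=2), t, p, mask, masked,
                        alpha)


def _benjamini_hochberg(p: np.ndarray, alpha: float) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if np.any(passed):
        mask[order[: np.max(np.flatnonzero(passed)) + 1]] = True
    return mask


def noise_ceiling(participant_rdms: Sequence[RDM]) -> NoiseCeiling:
    """Upper/lower bounds on attainable RDM correlation.

    Upper bound: mean over participants of rho(participant RDM, mean RDM
    of all participants). Lower bound: the same with the leave-one-out
    mean. Spearman throughout.
    """
    if len(participant_rdms) < 2:
        raise ParameterError("need at least two participants")
    n = len(participant_rdms)
    grand = average_rdms(participant_rdms)
    upper = np.mean([compare_rdms(r, grand) for r in participant_rdms])
    lowers = []
    for i in range(n):
        rest = [r for j, r in enumerate(participant_rdms) if j != i]
        lowers.append(compare_rdms(participant_rdms[i], average_rdms(rest)))
    return NoiseCeiling(lower=float(np.mean(lowers)), upper=float(upper))
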