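"""Envelope-response cross-correlation analysis.

Correlograms here are *raw* lagged inner products, not correlation
coefficients: with a unit-area envelope the magnitudes stay comparable
across stimuli of slightly different lengths. Positive lags mean the
response follows the stimulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

from .errors import AlignmentError, PairingError, ParameterError
from .signal_prep import ModulationEnvelope

__all__ = [
    "CrossCorrelogram",
    "PeakResult",
    "PairedTestResult",
    "cross_correlate",
    "make_null_pairing",
    "select_top_nodes",
    "extract_peak",
    "paired_peak_test",
]


@dataclass
class CrossCorrelogram:
    """Raw stimulus-response cross-correlation over signed lags (ms)."""

    lags_ms: np.ndarray
    values: np.ndarray
    rate_hz: float
    pairing: str = "matched"  # or "null"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags_ms.shape != self.values.shape:
            raise AlignmentError("lag axis and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("correlogram values must be finite")
        if self.pairing not in ("matched", "null"):
            raise ParameterError("pairing must be 'matched' or 'null'")


@dataclass
class PeakResult:
    """Extremum of a correlogram within a lag search window."""

    latency_ms: float
    value: float
    search_window_ms: tuple[float, float]
    polarity: str  # "min" or "max"
    at_edge: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.search_window_ms
        if not lo <= self.latency_ms <= hi:
            raise ParameterError("peak latency outside search window")


@dataclass
class PairedTestResult:
    t_statistic: float
    p_value: float
    df: int
    n_pairs: int
    mode: str = "paired"


def cross_correlate(env: ModulationEnvelope, response: Sequence[float],
                    rate_hz: float, max_lag_ms: float = 1000.0,
                    response_onset: int = 0, pairing: str = "matched",
                    ) -> CrossCorrelogram:
    """Raw lagged inner product c(tau) = sum_t env(t) * response(t + tau).

    The response may be longer than the envelope (e.g. an epoch spanning
    pre- and post-stimulus time); samples outside the overlap contribute
    zero. ``response_onset`` is the response sample index corresponding
    to stimulus onset, so lags are reported relative to onset.

    Parameters
    ----------
    env : ModulationEnvelope
        Unit-area stimulus drive; its rate must equal ``rate_hz``.
    response : sequence
        Response samples at ``rate_hz``.
    max_lag_ms : float
        Lags with \\|tau\\| <= max_lag_ms are returned.
    """
    if abs(env.rate_hz - rate_hz) > 1e-9:
        raise AlignmentError(
            f"envelope rate {env.rate_hz} != response rate {rate_hz}")
    r = np.asarray(response, dtype=float)
    if r.ndim != 1:
        raise ParameterError("response must be one-dimensional")
    e = env.samples
    full = sps.correlate(r, e, mode="full", method="auto")
    lags = sps.correlation_lags(len(r), len(e), mode="full") - response_onset
    max_lag = int(np.floor(max_lag_ms / 1000.0 * rate_hz))
    keep = np.abs(lags) <= max_lag
    lags_ms = lags[keep] * 1000.0 / rate_hz
    values = full[keep]
    # pad so the lag axis is always symmetric about zero
    want = np.arange(-max_lag, max_lag + 1) * 1000.0 / rate_hz
    if len(lags_ms) < len(want):
        padded = np.zeros(len(want))
        idx = np.searchsorted(want, lags_ms)
        padded[idx] = values
        lags_ms, values = want, padded
    return CrossCorrelogram(lags_ms, values, rate_hz, pairing=pairing)


def make_null_pairing(stimulus_ids: Sequence, seed: int) -> dict:
    """Map each stimulus to a uniformly chosen *different* stimulus.

    Reproducible from ``seed``; self-pairs are excluded but a full
    derangement is not enforced.
    """
    ids = list(stimulus_ids)
    if len(ids) < 2:
        raise PairingError("need at least two stimuli for a null pairing")
    rng = np.random.default_rng(seed)
    mapping = {}
    for sid in ids:
        others = [o for o in ids if o != sid]
        mapping[sid] = others[rng.integers(len(others))]
    return mapping


def _selection_stat(c: CrossCorrelogram, signed: bool) -> float:
    return float(np.max(c.values)) if signed else float(np.max(np.abs(c.values)))


def select_top_nodes(per_node: Sequence[CrossCorrelogram],
                     percentile: float = 20.0,
                     signed: bool = False) -> CrossCorrelogram:
    """Average the correlograms of nodes above the given percentile.

    Each node's selection statistic is its maximum absolute correlogram
    value (maximum signed value when ``signed``). Nodes strictly above
    the percentile of these statistics are kept and averaged pointwise;
    if ties leave the selection empty, all nodes are used and a warning
    is emitted.
    """
    if len(per_node) == 0:
        raise ParameterError("need at least one node")
    ref = per_node[0]
    for c in per_node[1:]:
        if not np.array_equal(c.lags_ms, ref.lags_ms):
            raise AlignmentError("nodes must share a common lag axis")
    stats_ = np.array([_selection_stat(c, signed) for c in per_node])
    threshold = np.percentile(stats_, percentile)
    keep = stats_ > threshold
    if not np.any(keep):
        warnings.warn("node selection empty after percentile threshold; "
                      "falling back to all nodes", stacklevel=2)
        keep = np.ones(len(per_node), dtype=bool)
    mean = np.mean([c.values for c, k in zip(per_node, keep) if k], axis=0)
    return CrossCorrelogram(
        ref.lags_ms.copy(), mean, ref.rate_hz, pairing=ref.pairing,
        provenance={"n_nodes": len(per_node), "n_kept": int(keep.sum()),
                    "percentile": percentile})


def extract_peak(c: CrossCorrelogram, center_ms: float, half_width_ms: float,
                 polarity: str) -> PeakResult:
    """Extremum value and latency within [center - hw, center + hw]."""
    if polarity not in ("min", "max"):
        raise ParameterError("polarity must be 'min' or 'max'")
    lo, hi = center_ms - half_width_ms, center_ms + half_width_ms
    if lo < c.lags_ms[0] or hi > c.lags_ms[-1]:
        raise ParameterError("search window outside correlogram lag axis")
    mask = (c.lags_ms >= lo) & (c.lags_ms <= hi)
    idx = np.flatnonzero(mask)
    vals = c.values[idx]
    k = idx[np.argmin(vals) if polarity == "min" else np.argmax(vals)]
    return PeakResult(
        latency_ms=float(c.lags_ms[k]), value=float(c.values[k]),
        search_window_ms=(lo, hi), polarity=polarity,
        at_edge=bool(k == idx[0] or k == idx[-1]))


def paired_peak_test(matched_values: Sequence[float],
                     null_values: Sequence[float],
                     mode: str = "paired") -> PairedTestResult:
    """Two-tailed t-test comparing matched vs null peak values.

    ``mode='paired'`` tests the per-stimulus differences (df = n - 1);
    ``mode='two_sample'`` is the independent-samples variant
    (df = 2n - 2). When the differences have zero variance the test is
    degenerate: t is reported as +/-inf (0 when the mean is also zero)
    and p as 0 (or 1).
    """
    m = np.asarray(matched_values, dtype=float)
    u = np.asarray(null_values, dtype=float)
    if m.shape != u.shape or m.ndim != 1:
        raise ParameterError("matched and null values must be equal-length 1-D")
    n = len(m)
    if n < 3:
        raise ParameterError("need at least three pairs")
    if mode == "paired":
        d = m - u
        sd = d.std(ddof=1)
        if sd == 0:
            mean = d.mean()
            if mean == 0:
                return PairedTestResult(0.0, 1.0, n - 1, n, mode)
            return PairedTestResult(float(np.sign(mean)) * np.inf, 0.0,
                                    n - 1, n, mode)
        t, p = stats.ttest_rel(m, u)
        return PairedTestResult(float(t), float(p), n - 1, n, mode)
    if mode == "two_sample":
        if m.std(ddof=1) == 0 and u.std(ddof=1) == 0:
            diff = m.mean() - u.mean()
            if diff == 0:
                return PairedTestResult(0.0, 1.0, 2 * n - 2, n, mode)
            return PairedTestResult(float(np.sign(diff)) * np.inf, 0.0,
                                    2 * n - 2, n, mode)
        t, p = stats.ttest_ind(m, u)
        return PairedTestResult(float(t), float(p), 2 * n - 2, n, mode)
    raise ParameterError("mode must be 'paired' or 'two_sample'")
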