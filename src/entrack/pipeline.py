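"""Orchestration: configuration, synthetic-data generation, and the
tracking / RSA analysis stages with CSV/JSON outputs.

Because every synthetic generator is a pure function of the
configuration and seed manifest, the analysis stages regenerate their
inputs deterministically from the manifest written by the ``synth``
stage; the optional data containers written alongside are the
interchange surface for external (real) data. Identical config + seed
therefore yields byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from collections.abc import Mapping
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import rsa as rsa_mod
from . import signal_prep, synthetic
from .activations import write_activation_container
from .errors import ParameterError
from .synthetic import SyntheticConfig
from .tracking import (cross_correlate, extract_peak, make_null_pairing,
                       paired_peak_test, select_top_nodes)

__all__ = ["RunConfig", "load_config", "cmd_synth", "cmd_tracking",
           "cmd_rsa", "cmd_all"]

log = logging.getLogger("entrack")

_STREAM_NULL = 17  # seed stream for the null stimulus pairing

TEST_PROFILE_OVERRIDES = dict(
    n_stimuli=6, n_participants=4, n_repetitions=2, n_channels=16,
    frontocentral_subset=(0, 1, 2, 3), layer_sizes=(16,) * 5,
    n_untrained=3, stim_duration_s=(5.5, 6.0))


@dataclass(frozen=True)
class RunConfig:
    """Analysis parameters plus the synthetic-data configuration."""

    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    out_dir: str = "entrack_out"
    profile: str = "full"  # or "test"
    max_lag_ms: float = 1000.0
    node_percentile: float = 20.0
    peak_windows: tuple = ((140.0, 40.0, "min"), (220.0, 40.0, "max"))
    band_edges_hz: tuple = tuple((float(lo), float(lo + 2)) for lo in
                                 range(0, 20, 2))
    alpha: float = 0.05
    rsa_window_s: tuple[float, float] = (0.0, 5.5)
    write_eeg_container: bool = False

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (out_dir excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path=None, profile: str | None = None,
                seed: int | None = None, out_dir: str | None = None,
                ) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides.

    The YAML file may contain any RunConfig field at top level and
    SyntheticConfig fields under a ``synth`` key.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
    synth_raw = raw.pop("synth", {})
    cfg = RunConfig(**{k: tuple(v) if isinstance(v, list) else v
                       for k, v in raw.items()})
    if profile is not None:
        cfg = replace(cfg, profile=profile)
    if cfg.profile == "test":
        merged = dict(TEST_PROFILE_OVERRIDES)
        merged.update(synth_raw)
        synth_raw = merged
        if "write_eeg_container" not in raw:
            cfg = replace(cfg, write_eeg_container=True)
    elif cfg.profile != "full":
        raise ParameterError(f"unknown profile {cfg.profile!r}")
    synth_raw = {k: tuple(v) if isinstance(v, list) else v
                 for k, v in synth_raw.items()}
    if seed is not None:
        synth_raw["master_seed"] = seed
    cfg = replace(cfg, synth=SyntheticConfig(**synth_raw))
    if out_dir is not None:
        cfg = replace(cfg, out_dir=out_dir)
    return cfg


# ---------------------------------------------------------------------------
# Shared synthetic-data access
# ---------------------------------------------------------------------------

class LazySyntheticEEG(Mapping):
    """participant -> {stimulus_id: [epochs]} mapping, generated on access.

    Keeps only one participant's epochs alive at a time, which matters
    at the full 128-channel study scale.
    """

    def __init__(self, cfg: SyntheticConfig,
                 channels: np.ndarray | None = None):
        self._cfg = cfg
        self._channels = channels

    def __len__(self) -> int:
        return self._cfg.n_participants

    def __iter__(self):
        return iter(range(self._cfg.n_participants))

    def __getitem__(self, participant: int):
        cfg = self._cfg
        if not 0 <= participant < cfg.n_participants:
            raise KeyError(participant)
        return {f"s{s:03d}": [synthetic.gen_eeg_epoch(cfg, s, participant, r,
                                                      channels=self._channels)
                              for r in range(cfg.n_repetitions)]
                for s in range(cfg.n_stimuli)}


def _stimulus_ids(cfg: SyntheticConfig) -> list[str]:
    return [f"s{i:03d}" for i in range(cfg.n_stimuli)]


def _null_map(cfg: SyntheticConfig) -> dict[str, str]:
    seed = int(np.random.default_rng(
        np.random.SeedSequence((cfg.master_seed, _STREAM_NULL))
    ).integers(2 ** 31))
    return make_null_pairing(_stimulus_ids(cfg), seed)


def _manifest(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d.pop("out_dir")  # not analysis-relevant; keeps runs comparable
    return {"config": d, "config_hash": cfg.config_hash(),
            "master_seed": cfg.synth.master_seed}


def _write_manifest(cfg: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as f:
        json.dump(_manifest(cfg), f, indent=2, sort_keys=True, default=str)


def _require_manifest(cfg: RunConfig, out: Path) -> None:
    path = out / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(
            f"no manifest at {path}; run the 'synth' stage first")
    with open(path) as f:
        manifest = json.load(f)
    if manifest.get("config_hash") != cfg.config_hash():
        raise ParameterError(
            "manifest config hash does not match the current configuration")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def cmd_synth(cfg: RunConfig) -> Path:
    """Generate stimuli, activations, and (optionally) EEG containers.

    Always writes the seed manifest; the analysis stages regenerate the
    synthetic data deterministically from it.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    scfg = cfg.synth
    _write_manifest(cfg, out)

    stim_dir = out / "stimuli"
    stim_dir.mkdir(exist_ok=True)
    for i in range(scfg.n_stimuli):
        signal_prep.write_wav(stim_dir / f"s{i:03d}.wav",
                              synthetic.gen_stimulus(scfg, i))

    sets = []
    for i in range(scfg.n_stimuli):
        sets.extend(synthetic.gen_network_responses(scfg, i, "trained"))
    for spec in synthetic.untrained_specs(scfg):
        for i in range(scfg.n_stimuli):
            sets.extend(synthetic.gen_network_responses(
                scfg, i, "untrained", spec=spec))
    write_activation_container(out / "activations.h5", sets)

    if cfg.write_eeg_container:
        epochs = (synthetic.gen_eeg_epoch(scfg, s, p, r)
                  for p in range(scfg.n_participants)
                  for s in range(scfg.n_stimuli)
                  for r in range(scfg.n_repetitions))
        signal_prep.write_eeg_container(out / "eeg.h5", epochs)
    log.info("synth stage done in %.1f s -> %s", time.time() - t0, out)
    return out


def _eeg_response(cfg: RunConfig, stimulus_index: int,
                  participant: int) -> tuple[np.ndarray, int]:
    """Repetition- and channel-averaged EEG at the envelope rate."""
    scfg = cfg.synth
    epochs = [synthetic.gen_eeg_epoch(scfg, stimulus_index, participant, r)
              for r in range(scfg.n_repetitions)]
    avg = signal_prep.average_epochs(epochs,
                                     list(scfg.frontocentral_subset))
    resampled = signal_prep.resample(avg, scfg.eeg_rate_hz,
                                     scfg.net_frame_rate_hz)
    onset = int(round(-scfg.epoch_window_ms[0] / 1000.0
                      * scfg.net_frame_rate_hz))
    return resampled, onset


def _grand(correlograms):
    from .tracking import CrossCorrelogram
    ref = correlograms[0]
    return CrossCorrelogram(ref.lags_ms.copy(),
                            np.mean([c.values for c in correlograms], axis=0),
                            ref.rate_hz, pairing=ref.pairing)


def cmd_tracking(cfg: RunConfig) -> dict:
    """Cross-correlation stage: EEG and network correlograms + peak tests."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    _require_manifest(cfg, out)
    scfg = cfg.synth
    rate = scfg.net_frame_rate_hz
    ids = _stimulus_ids(scfg)
    null_map = _null_map(scfg)
    idx_of = {sid: i for i, sid in enumerate(ids)}

    envelopes = {sid: synthetic.stimulus_envelope(scfg, i, rate)
                 for i, sid in enumerate(ids)}

    rows = []
    peak_rows = []
    tests: dict = {}

    def analyze_source(source: str, matched: dict, null: dict) -> None:
        """matched/null: stimulus_id -> participant-averaged correlogram."""
        for pairing, table in (("matched", matched), ("null", null)):
            for sid, c in table.items():
                for lag, val in zip(c.lags_ms, c.values):
                    rows.append((source, sid, pairing, lag, val))
            g = _grand(list(table.values()))
            for lag, val in zip(g.lags_ms, g.values):
                rows.append((source, "grand", pairing, lag, val))
        tests[source] = {}
        for center, hw, pol in cfg.peak_windows:
            m_vals, n_vals = [], []
            for sid in ids:
                pm = extract_peak(matched[sid], center, hw, pol)
                pn = extract_peak(null[sid], center, hw, pol)
                m_vals.append(pm.value)
                n_vals.append(pn.value)
                peak_rows.append((source, sid, "matched", pol, center,
                                  pm.latency_ms, pm.value, pm.at_edge))
                peak_rows.append((source, sid, "null", pol, center,
                                  pn.latency_ms, pn.value, pn.at_edge))
            tests[source][f"{pol}@{center:g}ms"] = {
                mode: vars(paired_peak_test(m_vals, n_vals, mode=mode))
                for mode in ("paired", "two_sample")}

    # --- EEG ---
    matched, null = {}, {}
    for sid in ids:
        per_p_m, per_p_n = [], []
        for p in range(scfg.n_participants):
            resp, onset = _eeg_response(cfg, idx_of[sid], p)
            per_p_m.append(cross_correlate(envelopes[sid], resp, rate,
                                           cfg.max_lag_ms, onset, "matched"))
            resp_null, onset_null = _eeg_response(cfg, idx_of[null_map[sid]],
                                                  p)
            per_p_n.append(cross_correlate(envelopes[sid], resp_null, rate,
                                           cfg.max_lag_ms, onset_null,
                                           "null"))
        matched[sid] = _grand(per_p_m)
        null[sid] = _grand(per_p_n)
    analyze_source("eeg", matched, null)

    # --- trained network, per layer ---
    def layer_correlograms(acts_by_stim: dict) -> None:
        """acts_by_stim: sid -> list of 5 LayerActivationSet."""
        for layer in range(1, 6):
            m, n = {}, {}
            for sid in ids:
                env = envelopes[sid]
                acts = acts_by_stim[sid][layer - 1]
                per_node = [cross_correlate(env, acts.data[u], rate,
                                            cfg.max_lag_ms, 0, "matched")
                            for u in range(acts.n_units)]
                m[sid] = select_top_nodes(per_node, cfg.node_percentile)
                acts_null = acts_by_stim[null_map[sid]][layer - 1]
                per_node_n = [cross_correlate(env, acts_null.data[u], rate,
                                              cfg.max_lag_ms, 0, "null")
                              for u in range(acts_null.n_units)]
                n[sid] = select_top_nodes(per_node_n, cfg.node_percentile)
            yield layer, m, n

    trained = {sid: synthetic.gen_network_responses(scfg, idx_of[sid],
                                                    "trained")
               for sid in ids}
    for layer, m, n in layer_correlograms(trained):
        analyze_source(f"trained_layer_{layer}", m, n)

    # --- untrained ensemble, per layer, averaged across instances ---
    specs = synthetic.untrained_specs(scfg)
    acc_m: dict = {}
    acc_n: dict = {}
    for spec in specs:
        acts = {sid: synthetic.gen_network_responses(scfg, idx_of[sid],
                                                     "untrained", spec=spec)
                for sid in ids}
        for layer, m, n in layer_correlograms(acts):
            for sid in ids:
                acc_m.setdefault((layer, sid), []).append(m[sid])
                acc_n.setdefault((layer, sid), []).append(n[sid])
    for layer in range(1, 6):
        m = {sid: _grand(acc_m[(layer, sid)]) for sid in ids}
        n = {sid: _grand(acc_n[(layer, sid)]) for sid in ids}
        analyze_source(f"untrained_layer_{layer}", m, n)

    meta = {"config_hash": cfg.config_hash(),
            "master_seed": scfg.master_seed,
            "null_pairing": null_map}
    pd.DataFrame(rows, columns=["source", "stimulus_id", "pairing",
                                "lag_ms", "value"]
                 ).to_csv(out / "correlograms.csv", index=False)
    pd.DataFrame(peak_rows, columns=["source", "stimulus_id", "pairing",
                                     "polarity", "center_ms", "latency_ms",
                                     "value", "at_edge"]
                 ).to_csv(out / "peaks.csv", index=False)
    with open(out / "peak_tests.json", "w") as f:
        json.dump({"meta": meta, "tests": tests}, f, indent=2, sort_keys=True)
    log.info("tracking stage done in %.1f s", time.time() - t0)
    return tests


def _network_layer_rdms(cfg: RunConfig, mode: str, spec=None) -> dict:
    scfg = cfg.synth
    n_frames = int(np.floor((cfg.rsa_window_s[1] - cfg.rsa_window_s[0])
                            * scfg.net_frame_rate_hz))
    ids = _stimulus_ids(scfg)
    per_layer: dict[int, dict] = {layer: {} for layer in range(1, 6)}
    for i, sid in enumerate(ids):
        acts = synthetic.gen_network_responses(scfg, i, mode, spec=spec)
        for layer in range(1, 6):
            per_layer[layer][sid] = rsa_mod.activation_vector(
                acts[layer - 1], n_frames)
    return {layer: rsa_mod.compute_rdm(vecs, source=f"{mode}_layer_{layer}")
            for layer, vecs in per_layer.items()}


def cmd_rsa(cfg: RunConfig) -> dict:
    """RSA stage: layer profile, noise ceiling, band and electrode maps."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    _require_manifest(cfg, out)
    scfg = cfg.synth
    subset = list(scfg.frontocentral_subset)

    trained_rdms = _network_layer_rdms(cfg, "trained")
    untrained_rdms = [_network_layer_rdms(cfg, "untrained", spec=spec)
                      for spec in synthetic.untrained_specs(scfg)]

    eeg = LazySyntheticEEG(scfg)
    participant_rdms = []
    for p in eeg:
        participant_rdms.append(rsa_mod._participant_rdm(
            eeg[p], subset, cfg.rsa_window_s, source=f"eeg_pooled p{p:02d}"))

    profile = rsa_mod.layer_profile(participant_rdms, trained_rdms,
                                    untrained_rdms)
    ceiling = rsa_mod.noise_ceiling(participant_rdms)
    band_table = rsa_mod.band_rsa(eeg, subset, cfg.rsa_window_s,
                                  cfg.band_edges_hz, trained_rdms)
    band_untrained = rsa_mod.band_rsa(eeg, subset, cfg.rsa_window_s,
                                      cfg.band_edges_hz, untrained_rdms[0])
    emap = rsa_mod.electrode_rsa(eeg, scfg.n_channels, cfg.rsa_window_s,
                                 trained_rdms, untrained_rdms,
                                 alpha=cfg.alpha)

    layers = sorted(trained_rdms.keys())
    rows = []
    for li, layer in enumerate(layers):
        for pi in range(len(participant_rdms)):
            rows.append((f"p{pi:02d}", layer, "trained",
                         profile.rho_trained[pi, li]))
            rows.append((f"p{pi:02d}", layer, "untrained",
                         profile.rho_untrained[pi, li]))
    pd.DataFrame(rows, columns=["participant", "layer", "group", "rho"]
                 ).to_csv(out / "layer_profile.csv", index=False)

    band_rows = []
    for bi, (lo, hi) in enumerate(cfg.band_edges_hz):
        for li, layer in enumerate(layers):
            band_rows.append((lo, hi, layer, band_table[bi, li],
                              band_untrained[bi, li]))
    pd.DataFrame(band_rows, columns=["band_lo_hz", "band_hi_hz", "layer",
                                     "rho_trained", "rho_untrained"]
                 ).to_csv(out / "band_rsa.csv", index=False)

    el_rows = []
    for e in range(scfg.n_channels):
        for li, layer in enumerate(layers):
            el_rows.append((e, layer, emap.rho[e, li],
                            emap.rho_untrained[e, li], emap.t[e, li],
                            emap.p[e, li], bool(emap.mask[e, li]),
                            emap.masked_rho[e, li]))
    pd.DataFrame(el_rows, columns=["electrode", "layer", "rho_trained",
                                   "rho_untrained", "t", "p", "significant",
                                   "masked_rho"]
                 ).to_csv(out / "electrode_map.csv", index=False)

    mean_eeg_rdm = rsa_mod.average_rdms(participant_rdms)
    _write_rdm_csv(out / "rdm_eeg_mean.csv", mean_eeg_rdm)
    _write_rdm_csv(out / "rdm_eeg_mean_ranked.csv",
                   rsa_mod.rank_transform(mean_eeg_rdm))
    for layer in layers:
        _write_rdm_csv(out / f"rdm_trained_layer_{layer}.csv",
                       trained_rdms[layer])

    summary = {
        "config_hash": cfg.config_hash(),
        "master_seed": scfg.master_seed,
        "noise_ceiling": {"lower": ceiling.lower, "upper": ceiling.upper},
        "layer_tests": {
            str(layer): {"t": profile.tests[li].t_statistic,
                         "p": profile.tests[li].p_value,
                         "df": profile.tests[li].df,
                         "mean_rho_trained": profile.mean_rho_trained[li],
                         "mean_rho_untrained": profile.mean_rho_untrained[li]}
            for li, layer in enumerate(layers)},
    }
    with open(out / "rsa_summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
    log.info("rsa stage done in %.1f s", time.time() - t0)
    return summary


def _write_rdm_csv(path, rdm) -> None:
    pd.DataFrame(rdm.matrix, index=list(rdm.stimulus_order),
                 columns=list(rdm.stimulus_order)).to_csv(path)


def cmd_all(cfg: RunConfig) -> None:
    cmd_synth(cfg)
    cmd_tracking(cfg)
    cmd_rsa(cfg)
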