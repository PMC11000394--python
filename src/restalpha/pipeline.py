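"""End-to-end glue: configuration, per-subject processing, cohort analysis."""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .edfio import Recording
from .montage import ROI_ELECTRODES, Montage, standard_montage
from .preprocess import (EpochSet, bandpass_filter, remove_artifact_components,
                         rereference, screen_epochs)
from .spectral import AlphaMetrics, compute_psd, subject_alpha_metrics
from .stats import GroupComparison, compare_groups, iaf_comparison

log = logging.getLogger("restalpha")

DEFAULT_CONFIG: dict = {
    "filter": {"low_hz": 1.0, "high_hz": 45.0, "hp_order": 2, "lp_order": 6},
    "reference": {"scheme": "T9T10"},
    "epochs": {"length_s": 20.0, "n_select": 8, "hard_threshold_uv": 400.0},
    "ica": {"enabled": False, "corr_threshold": 0.8},
    "spectrum": {"segment_len_s": 4.0, "overlap": 0.5},
    "iaf": {"mode": "per_electrode", "band": [8.0, 13.0]},
    "stats": {"roi": list(ROI_ELECTRODES), "alpha_level": 0.05},
}


def merged_config(overrides: Optional[dict] = None) -> dict:
    """Deep-merge user overrides into the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if overrides:
        merge(cfg, overrides)
    return cfg


def load_config(path) -> dict:
    import yaml
    with open(path) as fh:
        return merged_config(yaml.safe_load(fh) or {})


def preprocess_recording(recording: Recording,
                         config: Optional[dict] = None) -> EpochSet:
    """Filter -> re-reference -> epoch screen (-> optional ICA)."""
    cfg = config if config is not None else merged_config()
    rec = bandpass_filter(recording, low=cfg["filter"]["low_hz"],
                          high=cfg["filter"]["high_hz"],
                          hp_order=cfg["filter"]["hp_order"],
                          lp_order=cfg["filter"]["lp_order"])
    rec = rereference(rec, scheme=cfg["reference"]["scheme"])
    epochs = screen_epochs(rec, epoch_len=cfg["epochs"]["length_s"],
                           n_select=cfg["epochs"]["n_select"],
                           hard_threshold=cfg["epochs"]["hard_threshold_uv"])
    if cfg["ica"]["enabled"]:
        epochs = remove_artifact_components(
            epochs, corr_threshold=cfg["ica"]["corr_threshold"])
    return epochs


def subject_metrics(recording: Recording,
                    config: Optional[dict] = None) -> AlphaMetrics:
    cfg = config if config is not None else merged_config()
    epochs = preprocess_recording(recording, cfg)
    spec = compute_psd(epochs, segment_len=cfg["spectrum"]["segment_len_s"],
                       overlap=cfg["spectrum"]["overlap"])
    return subject_alpha_metrics(epochs, mode=cfg["iaf"]["mode"],
                                 band=tuple(cfg["iaf"]["band"]),
                                 spectrum=spec)


def build_metric_table(metrics: Sequence[AlphaMetrics],
                       manifest: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: demographics + per-electrode alpha_psd and iaf."""
    meta = manifest.set_index("subject_id")
    rows = []
    for m in metrics:
        if m.subject_id not in meta.index:
            log.warning("subject %s missing from manifest; excluded",
                        m.subject_id)
            continue
        info = meta.loc[m.subject_id]
        row = {"subject_id": m.subject_id, "group": info["group"],
               "age": info.get("age", np.nan), "sex": info.get("sex", ""),
               "migraine": bool(info.get("migraine", False))}
        for ch in m.channels:
            row[f"alpha_psd_{ch}"] = m.alpha_psd[ch]
            row[f"iaf_{ch}"] = m.iaf[ch]
            row[f"peak_quality_{ch}"] = m.peak_quality[ch]
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_cohort(recordings: Sequence[Recording], manifest: pd.DataFrame,
                   config: Optional[dict] = None,
                   montage: Optional[Montage] = None
                   ) -> tuple[pd.DataFrame, GroupComparison, pd.DataFrame]:
    """Full pipeline: recordings -> metric table, group stats, IAF table."""
    cfg = config if config is not None else merged_config()
    montage = montage if montage is not None else standard_montage()
    metrics = [subject_metrics(rec, cfg) for rec in recordings]
    table = build_metric_table(metrics, manifest)
    comparison = compare_groups(table, roi=cfg["stats"]["roi"],
                                alpha_level=cfg["stats"]["alpha_level"])
    iaf_table = iaf_comparison(table, electrodes=("O1", "O2"),
                               stratify_by_migraine=True,
                               alpha_level=cfg["stats"]["alpha_level"])
    return table, comparison, iaf_table


def write_parameter_log(cfg: dict, path) -> None:
    """Record every parameter actually used, as JSON."""
    Path(path).write_text(json.dumps(cfg, indent=2, sort_keys=True))
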