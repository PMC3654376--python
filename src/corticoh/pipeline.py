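"""End-to-end spike-coherence workflow.

segment spikes -> carve pre/spike/post intervals -> inverse source
estimation per epoch -> parcel averaging -> coherence per interval ->
band summaries -> top-K coherence edges. The same linear inverse
operator is applied to every epoch of a recording, so the solve is done
once on the concatenated epochs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .events import INTERVALS, SensorRecording, epochs_from_recording
from .geometry import LaplacianOperator
from .inverse import (LeadField, average_reference, choose_alpha,
                      solve_inverse)
from .spectral import (CoherenceResult, ParcelMap, average_by_parcel,
                       coherence_matrix, top_k_edges)

logger = logging.getLogger("corticoh.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "ConfigError", "analyze",
           "run_pipeline"]

METHODS = ("minimum_norm", "csl")


class ConfigError(ValueError):
    """Invalid pipeline configuration; message names the offending field."""


@dataclass
class PipelineConfig:
    """File-level configuration of a full pipeline run."""

    eeg: str
    events: str
    leadfield: str
    parcels: str
    laplacian: str | None = None
    method: str = "csl"
    alpha: float | str = "gcv"
    pre_s: float = 1.5
    post_s: float = 1.5
    top_k: int = 100
    pooled: bool = False
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(
                f"method: unknown inverse method {self.method!r}; "
                f"expected one of {METHODS}")
        if self.method == "csl" and self.laplacian is None:
            raise ConfigError("laplacian: required when method is 'csl'")
        if not (self.alpha == "gcv" or
                (isinstance(self.alpha, (int, float)) and self.alpha >= 0)):
            raise ConfigError("alpha: must be 'gcv' or a number >= 0")
        if self.top_k < 1:
            raise ConfigError("top_k: must be >= 1")
        for fld in ("eeg", "events", "leadfield", "parcels", "laplacian"):
            p = getattr(self, fld)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{fld}: file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as f:
            raw = yaml.safe_load(f)
        if not isinstance(raw, dict):
            raise ConfigError("config: YAML root must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"config: unknown fields {sorted(unknown)}")
        missing = {"eeg", "events", "leadfield", "parcels"} - set(raw)
        if missing:
            raise ConfigError(f"config: missing required fields "
                              f"{sorted(missing)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    """Coherence matrices and top-K edges for the three intervals."""

    coherence: dict[str, CoherenceResult]
    edges: dict[str, list[tuple]]
    alpha: float
    method: str
    n_epochs: int
    parcels: list[str] = field(default_factory=list)


def analyze(rec: SensorRecording, leadfield: LeadField,
            parcel_map: ParcelMap, W: LaplacianOperator | None = None,
            method: str = "csl", alpha: float | str = "gcv",
            pre_s: float = 1.5, post_s: float = 1.5, top_k: int = 100,
            pooled: bool = False) -> PipelineResult:
    """Run the full analysis on in-memory inputs.

    Scalp data and lead-field columns are average-referenced before
    solving. With ``alpha="gcv"`` the regularization weight is selected
    by generalized cross-validation on the spike-interval epochs.
    """
    if method not in METHODS:
        raise ConfigError(f"method: unknown inverse method {method!r}")
    Wop = None if method == "minimum_norm" else W
    if method == "csl" and Wop is None:
        raise ConfigError("laplacian: required when method is 'csl'")
    K = average_reference(leadfield.K)
    rec = SensorRecording(data=average_reference(rec.data), fs=rec.fs,
                          spike_times=rec.spike_times,
                          channel_names=rec.channel_names)
    epochs = epochs_from_recording(rec, pre_s, post_s)
    n_ep, n_ch, n_samp = epochs.epochs["spike"].shape

    if alpha == "gcv":
        spike_flat = np.moveaxis(epochs.epochs["spike"], 0, 1
                                 ).reshape(n_ch, -1)
        alpha = choose_alpha(K, spike_flat, Wop)
        logger.info("GCV selected alpha = %.4g", alpha)
    alpha = float(alpha)

    coherences: dict[str, CoherenceResult] = {}
    edges: dict[str, list[tuple]] = {}
    labels = None
    for interval in INTERVALS:
        flat = np.moveaxis(epochs.epochs[interval], 0, 1).reshape(n_ch, -1)
        est = solve_inverse(K, flat, Wop, alpha)
        J = est.J_hat.reshape(-1, n_ep, n_samp).transpose(1, 0, 2)
        parcel_epochs, labels = average_by_parcel(J, parcel_map)
        result = coherence_matrix(parcel_epochs, labels, rec.fs)
        coherences[interval] = result
        edges[interval] = top_k_edges(result, k=top_k, pooled=pooled)
        logger.info("interval %-5s: %d epochs, %d parcels", interval, n_ep,
                    len(labels))
    return PipelineResult(coherence=coherences, edges=edges, alpha=alpha,
                          method=method, n_epochs=n_ep, parcels=labels)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps({k: getattr(config, k)
                       for k in config.__dataclass_fields__},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-level pipeline: read inputs, analyze, write all outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        spike_times = cio.read_events(config.events)
        rec = cio.read_edf(config.eeg, spike_times=spike_times)
        lf = cio.read_leadfield(config.leadfield)
        parcel_map = cio.read_parcels(config.parcels)
        W = cio.read_laplacian(config.laplacian) if config.laplacian else None
    except Exception as exc:
        raise RuntimeError(f"input stage failed: {exc}") from exc
    if lf.n_sensors != rec.n_channels:
        raise ConfigError(
            f"leadfield: {lf.n_sensors} sensors but EEG has "
            f"{rec.n_channels} channels")
    result = analyze(rec, lf, parcel_map, W, method=config.method,
                     alpha=config.alpha, pre_s=config.pre_s,
                     post_s=config.post_s, top_k=config.top_k,
                     pooled=config.pooled)
    for interval, coh in result.coherence.items():
        cio.write_coherence(out, interval, coh)
    cio.write_edges(out / "edges.tsv", result.edges)
    import corticoh
    cio.write_json(out / "provenance.json", {
        "config": {k: getattr(config, k) for k in
                   config.__dataclass_fields__},
        "config_hash": _config_hash(config),
        "alpha": result.alpha,
        "method": result.method,
        "n_epochs": result.n_epochs,
        "versions": {"corticoh": corticoh.__version__,
                     "numpy": np.__version__},
    })
    logger.info("pipeline complete: %d epochs, alpha=%.4g, outputs in %s",
                result.n_epochs, result.alpha, out)
    return result
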