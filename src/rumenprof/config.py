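"""Pipeline configuration: column maps, size window, detection and binning knobs.

A single plain-text YAML file (flat ``key: value`` mapping) controls the
whole pipeline; every key has a default so an empty or absent file is a
valid configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # delimited-text dialect; None = auto-detect among tab/comma
    delimiter: str | None = None
    # column maps for instrument exports, which vary by software
    peak_sample_col: str = "sample_id"
    peak_size_col: str = "size_bp"
    peak_height_col: str = "height_rfu"
    ct_sample_col: str = "sample_id"
    ct_taxon_col: str = "taxon"
    ct_value_col: str = "ct"
    # T-RF processing
    min_bp: float = 27.0
    max_bp: float = 520.0
    k_sd: float = 3.0
    binning_tolerance: float = 0.5
    # qPCR QC
    ct_sd_threshold: float = 0.5
    # simulation
    sim_n_taxa: int = 10
    sim_n_background: int = 150
    sim_background_scale: float = 50.0
    sim_signal_scale: float = 20000.0
    sim_ct_total: float = 20.0
    sim_ct_noise_sd: float = 0.2
    sim_n_replicates: int = 3
    sim_n_animals: int = 4
    sim_sigma_animal: float = 0.3
    sim_sigma_e: float = 0.1
    seed: int | None = None

    extras: dict = field(default_factory=dict, repr=False)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a flat YAML config, falling back to defaults for absent keys.

    Unknown keys are kept in ``extras`` rather than rejected, so configs
    may carry user annotations.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must be a key: value mapping")
        data.update(loaded)
    data.update(overrides)

    known = {f.name for f in fields(PipelineConfig) if f.name != "extras"}
    kwargs = {k: v for k, v in data.items() if k in known}
    extras = {k: v for k, v in data.items() if k not in known}
    return PipelineConfig(**kwargs, extras=extras)
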