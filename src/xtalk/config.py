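"""Pipeline configuration.

All analysis thresholds live here (never hard-coded in stages), with the
study's published defaults: per-timepoint DEG gate p < 0.01, enrichment gate
p < 0.01, top-pathway cutoff -log10(p) > 5, VIM edge selection above the 99th
percentile, and a +/-0.4 log2FC call cutoff for cross-study validation. One
seed drives every stochastic stage through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError

_SIM_KEYS = {
    "n_source",
    "n_target",
    "n_background",
    "edges_per_target",
    "timepoints",
    "n_chow",
    "n_hfd",
    "dispersion",
    "shared_animal_sd",
    "saturating",
}

# substream labels -> spawn keys for seed fan-out
_STAGE_KEYS = {"simulate": 0, "simulate_study2": 1, "grn_lipid_fibrosis": 2, "grn_inflammation": 3}


@dataclass
class PipelineConfig:
    outdir: str = "results"
    seed: int = 0
    # inputs (paths; filled automatically by the simulate stage if `simulate`)
    liver_counts: str | None = None
    aorta_counts: str | None = None
    sample_sheet: str | None = None
    gene_sets: str | None = None
    phenotype: str | None = None
    study2_deg: str | None = None
    # thresholds (study defaults)
    deg_p: float = 0.01
    enrich_p: float = 0.01
    top_cutoff: float = 5.0
    vim_percentile: float = 99.0
    fc_cutoff: float = 0.4
    # GRN settings
    n_trees: int = 1000
    alpha_mode: str | float = "from_data"
    ensemble: str = "extra_trees"
    # synthetic-study parameters (None: run on provided input files)
    simulate: dict | None = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise ConfigError("seed must be an integer")
        for name in ("deg_p", "enrich_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if not (0.0 <= self.vim_percentile < 100.0):
            raise ConfigError(
                f"vim_percentile must lie in [0, 100), got {self.vim_percentile}"
            )
        if self.fc_cutoff < 0:
            raise ConfigError("fc_cutoff must be >= 0")
        if self.top_cutoff < 0:
            raise ConfigError("top_cutoff must be >= 0")
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if self.simulate is not None:
            unknown = set(self.simulate) - _SIM_KEYS
            if unknown:
                raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream of the config seed."""
        key = _STAGE_KEYS[stage]
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def describe(self) -> list[str]:
        """Threshold/seed lines for the run log."""
        return [
            f"seed\t{self.seed}",
            f"deg_p\t{self.deg_p}",
            f"enrich_p\t{self.enrich_p}",
            f"top_cutoff\t{self.top_cutoff}",
            f"vim_percentile\t{self.vim_percentile}",
            f"fc_cutoff\t{self.fc_cutoff}",
            f"n_trees\t{self.n_trees}",
            f"alpha_mode\t{self.alpha_mode}",
            f"ensemble\t{self.ensemble}",
        ]
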