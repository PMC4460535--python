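"""Pipeline configuration: a validated, YAML-loadable parameter bundle.

One root seed fans out into named substreams (schedule, noise, folds,
net-init, permutation, bootstrap) so every stage is reproducible from
(config, seed) alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig", "substream"]

SUBSTREAMS = ("schedule", "noise", "folds", "net_init", "permutation",
              "bootstrap", "sensitivity")


def substream(seed: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from the root seed."""
    if name not in SUBSTREAMS:
        raise ValueError(f"unknown substream: {name!r}")
    idx = SUBSTREAMS.index(name)
    return int(np.random.SeedSequence(seed).generate_state(len(SUBSTREAMS))[idx]
               % (2 ** 31))


@dataclass
class PipelineConfig:
    # schedule / simulation
    seed: int = 0
    n_runs: int = 4
    tr: float = 2.5
    block_s: float = 15.0
    n_voxels: int = 200
    n_informative: int = 20
    effect_scale: float = 1.0
    white_sd: float = 1.0
    ar1_coeff: float = 0.4
    ordinal_similarity: bool = False
    shuffle_labels: bool = False
    # preprocessing
    discard_s: float = 15.0
    nsr: float = 0.02
    hrf_duration: float = 32.0
    # feature selection
    selection_mode: str = "classification_target"
    selection_k: int | None = 50
    # classifier / CV
    classifier: dict = field(default_factory=lambda: {
        "name": "nn", "hidden_grid": [4, 8, 16], "n_restarts": 3,
        "max_epochs": 200})
    split_unit: str = "block"
    folds: int | None = None
    aggregate: str | None = "output_average"
    # inference
    n_perm: int = 0
    n_boot: int = 2000
    # sensitivity mapping
    run_sensitivity: bool = False
    n_nets: int = 20
    # output
    out_dir: str = "blockdecode_out"

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.tr <= 0 or self.block_s <= 0:
            raise ValueError("invalid schedule parameters")
        if not (0 <= self.ar1_coeff < 1) or self.white_sd < 0:
            raise ValueError("invalid noise parameters")
        if self.nsr < 0 or self.discard_s < 0:
            raise ValueError("invalid preprocessing parameters")
        if self.split_unit not in ("frame", "block", "half_run", "run"):
            raise ValueError("invalid split_unit")
        if self.aggregate not in (None, "frame", "input_average", "block_vote",
                                  "confidence_vote", "output_average"):
            raise ValueError("invalid aggregation method")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
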