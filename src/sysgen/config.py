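"""Pipeline configuration: one strict YAML schema, one root seed.

Defaults are the study-protocol values used throughout the pipeline
(1-cM walk, 10-cM CIM window and merge radius, 3000 permutations at
alpha 0.05, soft powers 1-20, minimum module size 30, eigengene merge at
0.75, hard edge cut |r| 0.75, 4-Mb cis window, intensity floor 20 at 30%
frequency, fold-change 2 at FDR 0.05). Unknown keys are rejected; every
stage derives its RNG stream from the root seed and its own name so
stages can rerun independently yet deterministically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig", "load_config", "stage_seed"]


@dataclass
class PipelineConfig:
    # file paths (all optional: stages validate what they need)
    map_file: str | None = None
    genotype_file: str | None = None
    expression_file: str | None = None
    positions_file: str | None = None
    trait_file: str | None = None
    out_dir: str = "results"

    # scan engine
    walk_cM: float = 1.0
    cim_window_cM: float = 10.0
    max_cofactors: int = 5
    n_permutations: int = 3000
    alpha: float = 0.05
    merge_radius_cM: float = 10.0
    map_function: str = "haldane"

    # expression preprocessing
    intensity_floor: float = 20.0
    min_frequency: float = 0.30
    fold_change: float = 2.0
    fdr: float = 0.05
    lowess_span: float = 0.3

    # network
    soft_powers: tuple = tuple(range(1, 21))
    scale_free_cut: float = 0.8
    min_module_size: int = 30
    me_merge_similarity: float = 0.75
    hard_edge_cut: float = 0.75
    tree_cut_height: float = 0.99

    # eQTL
    cis_window_bp: int = 4_000_000
    gpt_transcripts: int = 100
    gpt_perms_each: int = 10
    eqtl_engine: str = "IM"

    # integration
    coloc_radius_cM: float = 10.0
    module_trait_alpha: float = 0.05

    seed: int = 0
    simulate: dict = field(default_factory=dict)   # passed to SimConfig


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "soft_powers" in raw:
        raw["soft_powers"] = tuple(raw["soft_powers"])
    return PipelineConfig(**raw)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2^31."""
    ss = np.random.SeedSequence([int(root_seed) % (2 ** 31),
                                 int.from_bytes(stage.encode(), "little") % (2 ** 31)])
    return int(ss.generate_state(1)[0] % (2 ** 31))
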