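"""Pipeline configuration: defaults mirror the method's published thresholds
(500-UMI / 1%-mito filters, k=50 SNN, size ratio 20, sqrt(N) discard, 3
markers at 10%/20%, ridge 0.01/0.001, top-10 pairing, likelihood window 30,
confidence 0.3 of max 0.5, 150/20 bead UMIs, 50/100 reference cells, 5,000
tailored genes, nz 0.35, NP thresholds, pseudocell size rule, ARG
0.3/99.5%/0.05, prune 1.3, degree 18, 7 clusters, 95% coverage, 100-type
cap, 60% rule). Unknown keys are rejected; every run writes a resolved
snapshot next to its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .clustering import ClusteringConfig
from .mapping import MappingConfig
from .synthetic import GeneratorConfig

__all__ = ["PipelineConfig", "load_config"]

STAGES = ["simulate", "qc", "cluster", "map", "markers", "diversity",
          "pseudocell", "arg", "saturation"]


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: tuple = tuple(STAGES)
    # synthetic inputs
    generator: GeneratorConfig = field(default_factory=lambda: GeneratorConfig(
        n_types=8, n_genes=300, n_regions=2,
        activity_targets=(("Junb", 0.7), ("Egr1", 0.6), ("Arc", 0.6),
                          ("Fosb", 0.5), ("Npas4", 0.5)),
    ))
    n_cells: int = 5000
    cell_depth_median: float = 5000.0
    n_beads: int = 2000
    bead_depth_median: float = 1000.0
    bead_doublet_fraction: float = 0.2
    # module configs
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    # qc
    min_umis: int = 500
    max_mito: float = 0.01
    run_quality_network: bool = True
    # set cover
    tau_on: float = 0.5
    tau_off: float = 0.1
    max_cover_size: int = 8
    # diversity
    coverage_q: float = 0.95
    neighbourhood_cap: int = 100
    neighbourhood_non_neuronal: float = 0.6
    # ARG
    arg_r_min: float = 0.3
    arg_quantile: float = 0.995
    arg_alpha: float = 0.05
    arg_prune: float = 1.3
    arg_core_degree: int = 18
    arg_k_clusters: int = 7
    # saturation (defaults are the published study's parameters)
    sat_k: int = 19
    sat_n_rarest: int = 101
    sat_total: int = 4_210_212
    sat_c_fraction: float = 0.8
    sat_at: int = 4_388_420

    def resolved(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: enc(getattr(obj, f.name)) for f in fields(obj)}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (int, float, str, bool)) or obj is None:
                return obj
            return str(obj)
        return enc(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()).hexdigest()[:12]


def _build(dc_type, data: dict, where: str):
    allowed = {f.name for f in fields(dc_type)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    coerced = {}
    for f in fields(dc_type):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(tuple(x) if isinstance(x, list) else x
                                    for x in v) if isinstance(v, list) else v
    return dc_type(**coerced)


def load_config(path_or_dict) -> PipelineConfig:
    """Build a PipelineConfig from YAML (or a dict), rejecting unknown keys."""
    if isinstance(path_or_dict, (str, Path)):
        data = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        data = dict(path_or_dict)
    nested = {"generator": GeneratorConfig, "clustering": ClusteringConfig,
              "mapping": MappingConfig}
    kwargs = {}
    for key, sub in list(data.items()):
        if key in nested:
            kwargs[key] = _build(nested[key], sub or {}, key)
            del data[key]
    top = _build(PipelineConfig, {k: v for k, v in data.items()}, "pipeline")
    for k, v in kwargs.items():
        setattr(top, k, v)
    return top
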