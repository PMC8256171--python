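"""Run configuration: a validated YAML file driving the full pipeline.

Every section maps onto one stage's parameter dataclass; unknown keys are
rejected at load so typos fail fast rather than silently using defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bsa import ScanParams
from .haplotypes import HardFilterParams, WindowParams
from .synthetic import IbdSegment, IbdSpec, PoolSeqParams, QtlLocus, QtlSpec


@dataclass(frozen=True)
class GenomeConfig:
    n_chromosomes: int = 10


@dataclass(frozen=True)
class SimulateConfig:
    n_sites_per_chrom: int = 3000
    divergence: float = 0.5
    resistant_lines: tuple[str, ...] = ("B49", "B75", "B96")
    susceptible: str = "B73"
    ibd_segments: tuple[dict, ...] = ()
    leak_rate: float = 0.0
    qtl: tuple[dict, ...] = ()
    crosses: tuple[str, ...] = ("B49",)
    n_f2: int = 200
    n_replicates: int = 2
    bulk_size: int = 50
    mean_pool_depth: float = 4.0
    read_error: float = 0.001
    exclusion_prob: float = 0.0


@dataclass(frozen=True)
class MetaConfig:
    window_bp: int = 5_000_000
    offset_bp: int = 1_000_000
    fraction_of_max: float = 0.9


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "mitemap_run"
    log_level: str = "INFO"
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    scan: ScanParams = field(default_factory=ScanParams)
    hard_filter: HardFilterParams = field(default_factory=HardFilterParams)
    windows: WindowParams = field(default_factory=WindowParams)
    meta: MetaConfig = field(default_factory=MetaConfig)

    def ibd_spec(self) -> IbdSpec:
        segments = tuple(
            IbdSegment(
                chrom=d["chrom"], start=int(d["start"]), end=int(d["end"]),
                members=frozenset(d["members"]),
            )
            for d in self.simulate.ibd_segments
        )
        return IbdSpec(segments=segments, mutation_leak_rate=self.simulate.leak_rate)

    def qtl_spec(self, source_line: str) -> QtlSpec:
        loci = tuple(
            QtlLocus(
                chrom=d["chrom"], pos=int(d["pos"]),
                source_line=d.get("source_line", source_line),
                mode=d.get("mode", "recessive"),
                variance_explained=float(d.get("variance_explained", 0.70)),
            )
            for d in self.simulate.qtl
            if d.get("source_line", source_line) == source_line
        )
        return QtlSpec(loci=loci, exclusion_prob=self.simulate.exclusion_prob)

    def pool_params(self, seed: int) -> PoolSeqParams:
        return PoolSeqParams(
            pool_size=self.simulate.bulk_size,
            mean_depth=self.simulate.mean_pool_depth,
            read_error=self.simulate.read_error,
            seed=seed,
        )


def _build(cls, data: dict):
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {cls.__name__}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


_SECTIONS = {
    "genome": GenomeConfig,
    "simulate": SimulateConfig,
    "scan": ScanParams,
    "hard_filter": HardFilterParams,
    "windows": WindowParams,
    "meta": MetaConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    scalars = {"seed", "out_dir", "log_level"}
    unknown = set(raw) - scalars - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown configuration section(s): {sorted(unknown)}")
    kwargs: dict = {k: raw[k] for k in scalars if k in raw}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name])
    config = RunConfig(**kwargs)
    config.ibd_spec()  # validate segments eagerly
    return config
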