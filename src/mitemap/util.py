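"""Small shared helpers: coverage arithmetic, seeding, parameter hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass

import numpy as np

MAIZE_GENOME_BP = 2.4e9


def fold_coverage(read_pairs: float, read_length: int = 125,
                  genome_bp: float = MAIZE_GENOME_BP) -> float:
    """Sequencing fold coverage from paired-end read-pair counts.

    Each pair contributes two reads of ``read_length`` bases; e.g.
    26.8 million 125-bp pairs over a 2.4 Gb genome is ~2.8-fold.
    """
    if read_pairs < 0 or read_length <= 0 or genome_bp <= 0:
        raise ValueError("invalid coverage arithmetic inputs")
    return 2.0 * read_pairs * read_length / genome_bp


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31) derived from the
    single global seed and a stage name; no stage reads OS entropy."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, stage))


def params_hash(obj) -> str:
    """Short stable hash of a parameter object (dataclass or mapping)."""
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)

    def default(o):
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, (set, frozenset, tuple)):
            return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
        return str(o)

    payload = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
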