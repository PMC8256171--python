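import numpy as np
import pandas as pd
import pytest

from mitemap.genome import GenomeModel
from mitemap.synthetic import ParentPanel


@pytest.fixture
def small_genome() -> GenomeModel:
    """Two short chromosomes with distinct map lengths."""
    return GenomeModel(
        chromosomes=(("chr1", 50_000_000), ("chr2", 30_000_000)),
        centromeres={"chr1": 20_000_000, "chr2": 12_000_000},
        genetic_map={"chr1": 0.8, "chr2": 0.5},
    )


@pytest.fixture
def one_chrom_genome() -> GenomeModel:
    return GenomeModel(
        chromosomes=(("chr1", 100_000_000),),
        centromeres={"chr1": 40_000_000},
        genetic_map={"chr1": 1.0},
    )


def build_panel(
    model: GenomeModel,
    positions: dict[str, np.ndarray],
    genotypes: dict[str, dict[str, np.ndarray]],
    annotations: dict[str, pd.DataFrame] | None = None,
    depth: float = 30.0,
    susceptible: str = "B73",
) -> ParentPanel:
    """Hand-constructed panel with controllable annotations for filter tests."""
    line_ids = list(genotypes)
    ann = annotations or {}
    site_ann = {}
    depths = {l: {} for l in line_ids}
    ref, alt = {}, {}
    for chrom in model.names:
        n = len(positions[chrom])
        if chrom in ann:
            site_ann[chrom] = ann[chrom]
        else:
            site_ann[chrom] = pd.DataFrame({
                "QD": np.full(n, 10.0), "SOR": np.full(n, 1.0), "MQ": np.full(n, 60.0),
                "MQRankSum": np.zeros(n), "ReadPosRankSum": np.zeros(n),
            })
        for line in line_ids:
            depths[line][chrom] = np.full(n, depth)
        ref[chrom] = np.full(n, "A")
        alt[chrom] = np.full(n, "T")
    return ParentPanel(
        line_ids=line_ids, susceptible=susceptible, model=model,
        positions={c: np.asarray(p, dtype=np.int64) for c, p in positions.items()},
        ref_allele=ref, alt_allele=alt,
        genotypes={l: {c: np.asarray(g, dtype=np.int8) for c, g in per.items()}
                   for l, per in genotypes.items()},
        site_annotations=site_ann, depth=depths,
    )
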