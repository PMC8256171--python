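"""Genome coordinate frame for the simulated maize-like genome.

Physical coordinates are 1-based base pairs throughout; genetic map lengths
are in Morgans and drive the expected crossover count per meiosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome sizes, centromere positions, and genetic map lengths.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    centromeres
        Chromosome name -> centromere position (bp). Used only as an
        annotation on meta-analysis output.
    genetic_map
        Chromosome name -> total genetic length in Morgans. A length of 0
        means no recombination on that chromosome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: dict[str, int] = field(default_factory=dict)
    genetic_map: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            if name in seen:
                raise ValueError(f"duplicate chromosome name {name!r}")
            seen.add(name)
        for name, pos in self.centromeres.items():
            if name not in seen:
                raise ValueError(f"centromere for unknown chromosome {name!r}")
            if not 1 <= pos <= self.length_of(name):
                raise ValueError(f"centromere position {pos} outside chromosome {name!r}")
        for name, morgans in self.genetic_map.items():
            if name not in seen:
                raise ValueError(f"genetic map for unknown chromosome {name!r}")
            if morgans < 0:
                raise ValueError(f"negative map length for chromosome {name!r}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def length_of(self, name: str) -> int:
        for chrom, length in self.chromosomes:
            if chrom == name:
                return length
        raise KeyError(name)

    def map_length(self, name: str) -> float:
        return self.genetic_map.get(name, 0.0)


def default_genome(n_chromosomes: int = 10) -> GenomeModel:
    """Desk-scale analog of the maize genome.

    Ten chromosomes spanning 300 Mb down to 150 Mb of coordinate space so
    that Mb-based sliding windows are exercised at realistic physical
    scales.  Genetic lengths are proportional to physical length (about
    2.0 M for the largest chromosome, in line with maize linkage maps),
    and the chromosome-6 analog carries its centromere at ~50 Mb.
    """
    lengths = [300_000_000 - i * 150_000_000 // max(n_chromosomes - 1, 1)
               for i in range(n_chromosomes)]
    chroms = tuple((f"chr{i + 1}", length) for i, length in enumerate(lengths))
    centromeres = {}
    genetic_map = {}
    for name, length in chroms:
        centromeres[name] = 50_000_000 if name == "chr6" else int(0.4 * length)
        genetic_map[name] = round(length / 1.5e8, 3)
    return GenomeModel(chromosomes=chroms, centromeres=centromeres, genetic_map=genetic_map)
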