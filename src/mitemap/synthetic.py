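"""Synthetic parental genomes, F2 populations, phenotypes, and pooled
allele-depth tables.

The generator emulates the structure of a maize bulked-segregant resistance
mapping experiment: inbred (homozygous) parental lines carrying SNPs against
a reference-like susceptible line, identical-by-descent segments shared among
related resistant lines, F2 populations produced by selfing the F1 with a
no-interference (Haldane) recombination model, a 1-to-7 visual damage score
controlled by one or more large-effect loci, and pooled sequencing of
phenotypic-extreme bulks as Poisson read depths with binomial allele
sampling.

All randomness flows from explicit integer seeds; regenerating with the same
seed is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome import GenomeModel
from .io import SNP_COLUMNS

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: INFO-style site annotations shared across lines (as in a joint-called VCF).
SITE_ANNOTATIONS = ("QD", "SOR", "MQ", "MQRankSum", "ReadPosRankSum")


@dataclass(frozen=True)
class IbdSegment:
    chrom: str
    start: int
    end: int
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"IBD segment start {self.start} >= end {self.end}")


@dataclass(frozen=True)
class IbdSpec:
    """Identical-by-descent segments to implant among parental lines."""

    segments: tuple[IbdSegment, ...] = ()
    mutation_leak_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_leak_rate <= 0.01:
            raise ValueError("mutation_leak_rate must be in [0, 0.01]")
        # Overlapping segments are only consistent if their member sets agree.
        by_chrom: dict[str, list[IbdSegment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for segs in by_chrom.values():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end and a.members != b.members:
                    raise ValueError(
                        f"overlapping IBD segments on {a.chrom} "
                        f"({a.start}-{a.end} vs {b.start}-{b.end}) have "
                        f"inconsistent member sets {set(a.members)} vs {set(b.members)}"
                    )


@dataclass(frozen=True)
class QtlLocus:
    chrom: str
    pos: int
    source_line: str
    mode: str = "recessive"  # recessive | additive | dominant
    variance_explained: float = 0.70

    def __post_init__(self) -> None:
        if self.mode not in ("recessive", "additive", "dominant"):
            raise ValueError(f"unknown QTL mode {self.mode!r}")
        if not 0.0 <= self.variance_explained < 1.0:
            raise ValueError("variance_explained must be in [0, 1)")


@dataclass(frozen=True)
class QtlSpec:
    """Genetic architecture and phenotype model for an F2 population.

    ``variance_explained`` is the target coefficient of determination of the
    marker genotype among the two homozygous classes, matching how the
    single-locus variance-explained analysis is computed downstream.  The
    damage score lives on the 1-7 visual scale (1 = least damage = most
    resistant); progeny counts follow a negative binomial whose mean
    increases linearly with the damage score, with the slope calibrated so
    the damage-vs-progeny regression attains ``progeny_r2``.
    """

    loci: tuple[QtlLocus, ...]
    scale: tuple[float, float] = (1.0, 7.0)
    noise_sd: float = 0.5
    susceptible_mean: float = 5.2
    progeny_intercept: float = 2.0
    progeny_slope: float | None = None  # None -> calibrated to progeny_r2
    progeny_dispersion: float = 5.0
    progeny_r2: float = 0.83
    exclusion_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.progeny_r2 < 1.0:
            raise ValueError("progeny_r2 must be in [0, 1)")
        if not 0.0 <= self.exclusion_prob < 1.0:
            raise ValueError("exclusion_prob must be in [0, 1)")


@dataclass(frozen=True)
class PoolSeqParams:
    """Pooled-sequencing model: Poisson depth, binomial allele sampling."""

    pool_size: int = 50
    mean_depth: float = 4.0
    read_error: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.read_error <= 0.05:
            raise ValueError("read_error must be in [0, 0.05]")


@dataclass
class ParentPanel:
    """Homozygous parental SNP matrix with joint-call style annotations.

    ``genotypes`` codes each site per line as 0 (reference allele),
    1 (alternate allele), or -1 (missing).  The susceptible line is
    reference-like (all 0).  QD/SOR/MQ/rank-sum annotations are per site
    (shared across lines, as INFO fields of a joint-called VCF); read depth
    is per line per site.
    """

    line_ids: list[str]
    susceptible: str
    model: GenomeModel
    positions: dict[str, np.ndarray]
    ref_allele: dict[str, np.ndarray]
    alt_allele: dict[str, np.ndarray]
    genotypes: dict[str, dict[str, np.ndarray]]
    site_annotations: dict[str, pd.DataFrame]
    depth: dict[str, dict[str, np.ndarray]]

    @property
    def resistant_lines(self) -> list[str]:
        return [l for l in self.line_ids if l != self.susceptible]

    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())


@dataclass
class F2Population:
    """F2 individuals as parental-origin mosaics plus derived genotypes.

    ``genotypes[chrom]`` is an (n_individuals, n_sites) int8 array counting
    resistant-parent chromosomes (0 = SS, 1 = RS, 2 = RR).  ``gametes``
    retains the crossover mosaics so genotypes can be derived at arbitrary
    positions (e.g. PCR marker loci).
    """

    cross: tuple[str, str]  # (resistant line, susceptible line)
    model: GenomeModel
    positions: dict[str, np.ndarray]
    ref_allele: dict[str, np.ndarray]
    alt_allele: dict[str, np.ndarray]
    informative: dict[str, np.ndarray]  # bool: resistant parent differs from susceptible
    genotypes: dict[str, np.ndarray]
    gametes: list[dict[str, tuple[np.ndarray, int, np.ndarray, int]]]
    damage: np.ndarray | None = None
    progeny: np.ndarray | None = None
    excluded: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.gametes)

    def genotype_at(self, chrom: str, pos: int | float) -> np.ndarray:
        """Diploid resistant-allele count (0/1/2) for every individual at ``pos``."""
        out = np.empty(self.n, dtype=np.int8)
        for i, ind in enumerate(self.gametes):
            b1, s1, b2, s2 = ind[chrom]
            o1 = (s1 + np.searchsorted(b1, pos)) % 2
            o2 = (s2 + np.searchsorted(b2, pos)) % 2
            out[i] = o1 + o2
        return out

    def marker_genotypes(self, chrom: str, pos: int) -> np.ndarray:
        """Genotype class labels (``SS``/``Het``/``RR``) at a marker position."""
        g = self.genotype_at(chrom, pos)
        return np.array(["SS", "Het", "RR"])[g]


def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """Sorted unique 1-based positions, uniform over the chromosome."""
    pool = np.unique(rng.integers(1, length + 1, size=int(n * 1.1) + 16))
    while len(pool) < n:  # pragma: no cover - vanishing collision probability
        pool = np.unique(np.concatenate([pool, rng.integers(1, length + 1, size=n)]))
    keep = np.sort(rng.choice(len(pool), size=n, replace=False))
    return pool[keep].astype(np.int64)


def _draw_annotations(
    rng: np.random.Generator, n: int, fail_rate: float
) -> pd.DataFrame:
    """Per-site hard-filter annotations; a ``fail_rate`` fraction fails each
    criterion independently.  Rank sums are missing (NaN) at a fixed fraction
    of sites, mimicking sites with no heterozygous carrier in the caller."""

    def mix(pass_draw, fail_draw):
        vals = pass_draw()
        fails = rng.random(n) < fail_rate
        vals[fails] = fail_draw(int(fails.sum()))
        return vals

    qd = mix(lambda: rng.uniform(5.0, 30.0, n), lambda m: rng.uniform(0.0, 1.99, m))
    sor = mix(lambda: rng.uniform(0.3, 2.5, n), lambda m: rng.uniform(3.01, 9.0, m))
    mq = mix(lambda: rng.uniform(55.0, 60.0, n), lambda m: rng.uniform(20.0, 49.9, m))
    mqrs = mix(lambda: rng.uniform(-7.5, 7.5, n), lambda m: rng.uniform(-20.0, -8.01, m))
    rprs = mix(lambda: rng.uniform(-7.5, 7.5, n), lambda m: rng.uniform(-20.0, -8.01, m))
    missing = rng.random(n) < 0.15
    mqrs[missing] = np.nan
    rprs[missing] = np.nan
    return pd.DataFrame(
        {"QD": qd, "SOR": sor, "MQ": mq, "MQRankSum": mqrs, "ReadPosRankSum": rprs}
    )


def simulate_parents(
    model: GenomeModel,
    n_sites_per_chrom: int,
    ibd: IbdSpec | None = None,
    divergence: float = 0.5,
    seed: int = 0,
    resistant_lines: tuple[str, ...] = ("B49", "B75", "B96"),
    susceptible: str = "B73",
    mean_depth: float = 30.0,
    annotation_fail_rate: float = 0.02,
) -> ParentPanel:
    """Simulate a panel of inbred parental lines.

    Each resistant line carries the alternate allele at an independent
    ``divergence`` fraction of sites; inside an IBD segment all member lines
    copy a single donor haplotype, mismatching only at leaked sites.
    """
    if n_sites_per_chrom < 50:
        raise ValueError("n_sites_per_chrom must be >= 50")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    ibd = ibd or IbdSpec()
    line_ids = [susceptible, *resistant_lines]
    for seg in ibd.segments:
        if not set(seg.members) <= set(line_ids):
            raise ValueError(f"IBD members {set(seg.members)} not all in panel {line_ids}")
        model.length_of(seg.chrom)  # raises KeyError for unknown chromosome

    rng = np.random.default_rng(seed)
    positions: dict[str, np.ndarray] = {}
    ref_allele: dict[str, np.ndarray] = {}
    alt_allele: dict[str, np.ndarray] = {}
    genotypes: dict[str, dict[str, np.ndarray]] = {l: {} for l in line_ids}
    annotations: dict[str, pd.DataFrame] = {}
    depth: dict[str, dict[str, np.ndarray]] = {l: {} for l in line_ids}

    for chrom, length in model.chromosomes:
        pos = _draw_positions(rng, length, n_sites_per_chrom)
        positions[chrom] = pos
        ref_idx = rng.integers(0, 4, n_sites_per_chrom)
        alt_idx = (ref_idx + rng.integers(1, 4, n_sites_per_chrom)) % 4
        ref_allele[chrom] = _BASES[ref_idx]
        alt_allele[chrom] = _BASES[alt_idx]
        genotypes[susceptible][chrom] = np.zeros(n_sites_per_chrom, dtype=np.int8)
        for line in resistant_lines:
            g = (rng.random(n_sites_per_chrom) < divergence).astype(np.int8)
            genotypes[line][chrom] = g
        annotations[chrom] = _draw_annotations(rng, n_sites_per_chrom, annotation_fail_rate)
        for line in line_ids:
            fold = rng.uniform(0.5, 1.4, n_sites_per_chrom)
            fails = rng.random(n_sites_per_chrom) < annotation_fail_rate
            n_fail = int(fails.sum())
            low = rng.random(n_fail) < 0.5
            bad = np.where(low, rng.uniform(0.01, 0.24, n_fail), rng.uniform(1.6, 3.0, n_fail))
            fold[fails] = bad
            depth[line][chrom] = fold * mean_depth

    # Implant IBD segments: members copy one donor haplotype.
    for seg in ibd.segments:
        pos = positions[seg.chrom]
        sel = (pos >= seg.start) & (pos <= seg.end)
        m = int(sel.sum())
        if m == 0:
            continue
        if susceptible in seg.members:
            donor = np.zeros(m, dtype=np.int8)
        else:
            donor = (rng.random(m) < divergence).astype(np.int8)
        for line in sorted(seg.members):
            if line == susceptible:
                continue
            hap = donor.copy()
            if ibd.mutation_leak_rate > 0:
                leak = rng.random(m) < ibd.mutation_leak_rate
                hap[leak] ^= 1
            genotypes[line][seg.chrom][sel] = hap

    return ParentPanel(
        line_ids=line_ids,
        susceptible=susceptible,
        model=model,
        positions=positions,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        genotypes=genotypes,
        site_annotations=annotations,
        depth=depth,
    )


def _meiosis(
    rng: np.random.Generator, length: int, morgans: float
) -> tuple[np.ndarray, int]:
    """One F1 gamete: Poisson crossover count, breakpoints uniform in bp."""
    n_xo = rng.poisson(morgans)
    breaks = np.sort(rng.uniform(1.0, float(length), size=n_xo))
    start = int(rng.integers(0, 2))
    return breaks, start


def _origins(breaks: np.ndarray, start: int, pos: np.ndarray) -> np.ndarray:
    return (start + np.searchsorted(breaks, pos)) % 2


def simulate_f2(
    parents: ParentPanel,
    cross: tuple[str, str],
    n: int,
    model: GenomeModel | None = None,
    seed: int = 0,
) -> F2Population:
    """Simulate ``n`` F2 individuals from selfing the F1 of ``cross``.

    Recombination follows a no-interference model: crossover count per
    chromosome is Poisson with mean equal to the genetic map length in
    Morgans, breakpoint positions uniform in bp.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    resistant, susceptible = cross
    for line in cross:
        if line not in parents.line_ids:
            raise ValueError(f"cross parent {line!r} not in panel {parents.line_ids}")
    model = model or parents.model
    rng = np.random.default_rng(seed)

    genotypes: dict[str, np.ndarray] = {}
    informative: dict[str, np.ndarray] = {}
    for chrom in model.names:
        m = len(parents.positions[chrom])
        genotypes[chrom] = np.empty((n, m), dtype=np.int8)
        g_res = parents.genotypes[resistant][chrom]
        g_sus = parents.genotypes[susceptible][chrom]
        informative[chrom] = (g_res != g_sus) & (g_res >= 0) & (g_sus >= 0)

    gametes: list[dict[str, tuple[np.ndarray, int, np.ndarray, int]]] = []
    for i in range(n):
        ind: dict[str, tuple[np.ndarray, int, np.ndarray, int]] = {}
        for chrom, length in model.chromosomes:
            morgans = model.map_length(chrom)
            b1, s1 = _meiosis(rng, length, morgans)
            b2, s2 = _meiosis(rng, length, morgans)
            ind[chrom] = (b1, s1, b2, s2)
            pos = parents.positions[chrom]
            genotypes[chrom][i] = _origins(b1, s1, pos) + _origins(b2, s2, pos)
        gametes.append(ind)

    return F2Population(
        cross=(resistant, susceptible),
        model=model,
        positions={c: parents.positions[c] for c in model.names},
        ref_allele={c: parents.ref_allele[c] for c in model.names},
        alt_allele={c: parents.alt_allele[c] for c in model.names},
        informative=informative,
        genotypes=genotypes,
        gametes=gametes,
    )


def _effect_fraction(g: np.ndarray, mode: str) -> np.ndarray:
    if mode == "recessive":
        return (g == 2).astype(float)
    if mode == "dominant":
        return (g >= 1).astype(float)
    return g / 2.0  # additive


def _solve_progeny_link(
    scores: np.ndarray, target_r2: float, intercept: float, dispersion: float
) -> tuple[float, float]:
    """Slope (and possibly raised dispersion) so the expected OLS R-squared
    of progeny on damage equals ``target_r2``.

    Under a linear mean link mu = c0 + b*s and negative binomial noise with
    size k, the expected R-squared is b^2 V / (b^2 V + mean(mu + mu^2/k));
    its supremum over b is 1 / (1 + mean(s^2)/(V k)).  When the requested
    target exceeds that supremum for the given dispersion, the dispersion is
    raised to twice the minimal feasible size before solving for the slope.
    """
    v = float(np.var(scores))
    if v == 0:
        raise ValueError("damage scores have zero variance; cannot calibrate progeny link")
    ms2 = float(np.mean(scores**2))

    def expected_r2(b: float, k: float) -> float:
        mu = intercept + b * scores
        noise = float(np.mean(mu + mu**2 / k))
        return b * b * v / (b * b * v + noise)

    k = dispersion
    sup = 1.0 / (1.0 + ms2 / (v * k))
    if sup <= target_r2 + 0.02:
        k_min = ms2 * target_r2 / (v * (1.0 - target_r2))
        k = 2.0 * k_min
    hi = 1.0
    while expected_r2(hi, k) < target_r2:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover
            raise RuntimeError("progeny link calibration failed to bracket")
    b = brentq(lambda x: expected_r2(x, k) - target_r2, 1e-12, hi)
    return float(b), float(k)


def simulate_phenotypes(pop: F2Population, qtl: QtlSpec, seed: int = 0) -> F2Population:
    """Fill damage scores and progeny counts in place (and return ``pop``).

    The latent damage score is the susceptible-class mean minus additive
    locus effects plus Gaussian noise, clamped to the visual scale.  Each
    locus effect size is set so the variance explained among the two
    homozygous classes at that locus equals its target:
    ``delta = 2 * sd * sqrt(h / (1 - h))`` (homozygous classes are
    equifrequent in an F2, so the between-class variance is delta^2/4).
    """
    rng = np.random.default_rng(seed)
    lo, hi = qtl.scale
    sd = qtl.noise_sd
    latent = np.full(pop.n, qtl.susceptible_mean)
    effects = []
    for locus in qtl.loci:
        pos_arr = pop.positions[locus.chrom]
        idx = int(np.searchsorted(pos_arr, locus.pos))
        if idx >= len(pos_arr) or pos_arr[idx] != locus.pos:
            raise ValueError(
                f"QTL position {locus.chrom}:{locus.pos} is not a simulated site"
            )
        h = locus.variance_explained
        ref_sd = sd if sd > 0 else 1.0
        delta = 2.0 * ref_sd * np.sqrt(h / (1.0 - h)) if h > 0 else 0.0
        if sd == 0 and h > 0:
            delta = 2.0  # noise-free: any non-zero separation is deterministic
        g = pop.genotypes[locus.chrom][:, idx]
        latent = latent - delta * _effect_fraction(g, locus.mode)
        effects.append(delta)
    damage = latent + (rng.normal(0.0, sd, pop.n) if sd > 0 else 0.0)
    damage = np.clip(damage, lo, hi)

    slope, dispersion = (
        (qtl.progeny_slope, qtl.progeny_dispersion)
        if qtl.progeny_slope is not None
        else _solve_progeny_link(damage, qtl.progeny_r2, qtl.progeny_intercept, qtl.progeny_dispersion)
    )
    mu = np.maximum(qtl.progeny_intercept + slope * damage, 1e-9)
    p = dispersion / (dispersion + mu)
    progeny = rng.negative_binomial(dispersion, p)

    excluded = (
        rng.random(pop.n) < qtl.exclusion_prob
        if qtl.exclusion_prob > 0
        else np.zeros(pop.n, dtype=bool)
    )

    pop.damage = damage
    pop.progeny = progeny.astype(np.int64)
    pop.excluded = excluded
    pop.meta.update(
        {"qtl_effects": effects, "progeny_slope": slope, "progeny_dispersion": dispersion}
    )
    return pop


def round_damage_for_display(damage: np.ndarray) -> np.ndarray:
    """Round the continuous averaged damage score to 0.5 steps for display."""
    return np.round(np.asarray(damage) * 2.0) / 2.0


def make_bulks(pop: F2Population, k: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Phenotypic-extreme bulks: ``k`` most resistant (lowest damage) and
    ``k`` most sensitive (highest damage) non-excluded individuals.

    Ties are broken by a seeded uniform draw.
    """
    if pop.damage is None:
        raise ValueError("population has no phenotypes; run simulate_phenotypes first")
    excluded = pop.excluded if pop.excluded is not None else np.zeros(pop.n, dtype=bool)
    avail = np.flatnonzero(~excluded)
    if 2 * k > len(avail):
        raise ValueError(f"cannot draw two bulks of {k} from {len(avail)} available plants")
    rng = np.random.default_rng(seed)
    jitter = rng.random(len(avail))
    order = avail[np.lexsort((jitter, pop.damage[avail]))]
    resistant = np.sort(order[:k])
    sensitive = np.sort(order[-k:])
    return resistant, sensitive


def simulate_pool_seq(
    pop: F2Population,
    bulks: tuple[np.ndarray, np.ndarray],
    params: PoolSeqParams,
) -> pd.DataFrame:
    """Pooled allele-depth table for the two bulks at informative sites.

    At each site the true pool alternate-allele frequency is the resistant
    allele count over the 2 * pool_size sampled chromosomes; observed depth
    is Poisson(mean_depth) per pool and alternate read counts are binomial
    with a symmetric per-base miscall probability.  GQ uses a coarse
    depth-based rule (min(99, 10 * DP)); only its interaction with the
    GQ >= 20 filter matters downstream.
    """
    resistant_ids, sensitive_ids = bulks
    if len(resistant_ids) == 0 or len(sensitive_ids) == 0:
        raise ValueError("bulks must be non-empty")
    rng = np.random.default_rng(params.seed)
    err = params.read_error
    frames = []
    for chrom in pop.model.names:
        keep = pop.informative[chrom]
        if not keep.any():
            continue
        pos = pop.positions[chrom][keep]
        ref = pop.ref_allele[chrom][keep]
        alt = pop.alt_allele[chrom][keep]
        row = {"CHROM": np.repeat(chrom, len(pos)), "POS": pos, "REF": ref, "ALT": alt}
        for label, ids in (("RES", resistant_ids), ("SENS", sensitive_ids)):
            counts = pop.genotypes[chrom][ids][:, keep].sum(axis=0)
            freq = counts / (2.0 * len(ids))
            dp = rng.poisson(params.mean_depth, len(pos))
            f_obs = freq * (1.0 - err) + (1.0 - freq) * err
            ad_alt = rng.binomial(dp, f_obs)
            row[f"AD_REF_{label}"] = dp - ad_alt
            row[f"AD_ALT_{label}"] = ad_alt
            row[f"DP_{label}"] = dp
            row[f"GQ_{label}"] = np.minimum(99, 10 * dp)
        frames.append(pd.DataFrame(row))
    if not frames:
        return pd.DataFrame(columns=SNP_COLUMNS)
    return pd.concat(frames, ignore_index=True)[SNP_COLUMNS]
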