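"""Parameter-recovery replication studies.

Each function re-creates one of the study designs end to end from the
synthetic generator — F2 cross, phenotyping, extreme bulks, pooled
sequencing, scan or marker analysis — and measures how reliably the
analysis recovers what was simulated.  These are the workhorses behind
the acceptance checks and are also useful for power exploration.

Design constants follow the mapping experiment: two replicates of 200 F2
plants per cross, 50-plant extreme bulks, ~4-fold pool coverage, a
recessive chromosome-6 locus at 60 Mb explaining 0.70 of the variance
among homozygous marker classes, and 1,000 SNP sites per chromosome
(10,000 genome-wide).  Replicates are combined for scanning with depth
thresholds doubled, as in the published analysis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from . import bsa, haplotypes, meta, phenotypes, synthetic
from .genome import GenomeModel, default_genome
from .pipeline import nearest_site
from .util import stage_seed

logger = logging.getLogger(__name__)

N_F2 = 200
BULK_SIZE = 50
POOL_DEPTH = 4.0
N_SITES_PER_CHROM = 1_000
N_REPLICATES = 2


@dataclass
class ScanRun:
    intervals: object
    qtl_positions: dict[str, int]


def _simulate_cross_scan(
    model: GenomeModel,
    loci: list[tuple[str, int, float]],
    seed: int,
    n_replicates: int = N_REPLICATES,
    n_sites_per_chrom: int = N_SITES_PER_CHROM,
) -> ScanRun:
    """One full mapping run: parents, replicates, bulks, pools, merged scan."""
    panel = synthetic.simulate_parents(
        model, n_sites_per_chrom, divergence=1.0,
        seed=stage_seed(seed, "parents"), resistant_lines=("R",),
    )
    qtl = tuple(
        synthetic.QtlLocus(chrom, nearest_site(panel, chrom, pos), "R", "recessive", h)
        for chrom, pos, h in loci
    )
    spec = synthetic.QtlSpec(loci=qtl)
    tables = []
    for rep in range(n_replicates):
        pop = synthetic.simulate_f2(
            panel, ("R", "B73"), N_F2, model, seed=stage_seed(seed, f"f2:{rep}")
        )
        synthetic.simulate_phenotypes(pop, spec, seed=stage_seed(seed, f"pheno:{rep}"))
        bulks = synthetic.make_bulks(pop, BULK_SIZE, seed=stage_seed(seed, f"bulks:{rep}"))
        tables.append(
            synthetic.simulate_pool_seq(
                pop, bulks,
                synthetic.PoolSeqParams(
                    pool_size=BULK_SIZE, mean_depth=POOL_DEPTH,
                    seed=stage_seed(seed, f"pools:{rep}"),
                ),
            )
        )
    params = bsa.ScanParams()
    if n_replicates > 1:
        table = bsa.merge_replicates(tables)
        params = params.doubled()
    else:
        table = tables[0]
    track = bsa.scan(table, params)
    intervals = bsa.call_qtl(track, params.fdr, params.window_bp)
    return ScanRun(intervals, {l.chrom: l.pos for l in qtl})


def single_qtl_recovery(n_runs: int = 50, seed: int = 0,
                        tolerance_bp: int = 10_000_000) -> dict:
    """Recessive chr6 QTL: fraction of runs reporting exactly one interval on
    the correct chromosome with the peak within ``tolerance_bp`` of the locus.

    Also reports the fraction where the strongest interval localizes the
    locus regardless of additional interval calls (detection vs bookkeeping).
    """
    model = default_genome()
    strict = localized = 0
    for run in range(n_runs):
        res = _simulate_cross_scan(model, [("chr6", 60_000_000, 0.70)],
                                   stage_seed(seed, f"single:{run}"))
        iv = res.intervals
        qpos = res.qtl_positions["chr6"]
        on_target = iv[(iv["chrom"] == "chr6")
                       & ((iv["peak_pos"] - qpos).abs() <= tolerance_bp)]
        if len(iv) == 1 and len(on_target) == 1:
            strict += 1
        if len(iv) and iv.iloc[int(iv["peak_gprime"].idxmax())]["chrom"] == "chr6" \
                and abs(iv.iloc[int(iv["peak_gprime"].idxmax())]["peak_pos"] - qpos) <= tolerance_bp:
            localized += 1
    return {"strict_rate": strict / n_runs, "localized_rate": localized / n_runs,
            "n_runs": n_runs}


def null_scan_fraction(n_runs: int = 5, seed: int = 0) -> dict:
    """No-QTL null: mean per-run fraction of sites with q below the FDR."""
    model = default_genome()
    fractions = []
    for run in range(n_runs):
        panel = synthetic.simulate_parents(
            model, N_SITES_PER_CHROM, divergence=1.0,
            seed=stage_seed(seed, f"nullp:{run}"), resistant_lines=("R",),
        )
        tables = []
        for rep in range(N_REPLICATES):
            pop = synthetic.simulate_f2(
                panel, ("R", "B73"), N_F2, model,
                seed=stage_seed(seed, f"nullf2:{run}:{rep}"),
            )
            synthetic.simulate_phenotypes(
                pop, synthetic.QtlSpec(loci=()),
                seed=stage_seed(seed, f"nullph:{run}:{rep}"),
            )
            bulks = synthetic.make_bulks(pop, BULK_SIZE,
                                         seed=stage_seed(seed, f"nullb:{run}:{rep}"))
            tables.append(synthetic.simulate_pool_seq(
                pop, bulks,
                synthetic.PoolSeqParams(pool_size=BULK_SIZE, mean_depth=POOL_DEPTH,
                                        seed=stage_seed(seed, f"nullpool:{run}:{rep}")),
            ))
        params = bsa.ScanParams().doubled()
        track = bsa.scan(bsa.merge_replicates(tables), params)
        fractions.append(float((track["q"] < params.fdr).mean()) if len(track) else 0.0)
    arr = np.asarray(fractions)
    return {"mean_fraction": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "n_runs": n_runs}


def two_qtl_recovery(n_runs: int = 50, seed: int = 0,
                     tolerance_bp: int = 10_000_000) -> dict:
    """Two-locus architecture (chr1 + chr6, equal large effects): fraction of
    runs recovering both intervals and no others."""
    model = default_genome()
    loci = [("chr1", 67_000_000, 0.70), ("chr6", 60_000_000, 0.70)]
    strict = both_found = 0
    for run in range(n_runs):
        res = _simulate_cross_scan(model, loci, stage_seed(seed, f"two:{run}"))
        iv = res.intervals
        hits = {}
        for chrom, qpos in res.qtl_positions.items():
            sub = iv[(iv["chrom"] == chrom)
                     & ((iv["peak_pos"] - qpos).abs() <= tolerance_bp)]
            hits[chrom] = len(sub)
        if all(v >= 1 for v in hits.values()):
            both_found += 1
            if len(iv) == 2:
                strict += 1
    return {"strict_rate": strict / n_runs, "both_found_rate": both_found / n_runs,
            "n_runs": n_runs}


def marker_r2_recovery(n_reps: int = 500, seed: int = 0, n_genotyped: int = 180,
                       target: float = 0.70) -> dict:
    """Single-marker variance-explained recovery on a one-chromosome design.

    Each replicate simulates 200 F2 plants, genotypes 180 of them at the QTL
    marker (emulating occasional PCR failures), and runs the genotype-class
    analysis; reports the mean homozygous-class R-squared and the fraction of
    replicates classified recessive.
    """
    model = GenomeModel(chromosomes=(("chr6", 216_000_000),),
                        genetic_map={"chr6": 1.44}, centromeres={"chr6": 50_000_000})
    panel = synthetic.simulate_parents(model, 200, divergence=1.0,
                                       seed=stage_seed(seed, "mparents"),
                                       resistant_lines=("R",))
    qpos = nearest_site(panel, "chr6", 73_400_000)
    spec = synthetic.QtlSpec(
        loci=(synthetic.QtlLocus("chr6", qpos, "R", "recessive", target),)
    )
    r2 = []
    recessive = 0
    for rep in range(n_reps):
        pop = synthetic.simulate_f2(panel, ("R", "B73"), N_F2, model,
                                    seed=stage_seed(seed, f"mf2:{rep}"))
        synthetic.simulate_phenotypes(pop, spec, seed=stage_seed(seed, f"mph:{rep}"))
        rng = np.random.default_rng(stage_seed(seed, f"mgt:{rep}"))
        idx = rng.choice(N_F2, n_genotyped, replace=False)
        res = phenotypes.marker_effect_analysis(
            pop.marker_genotypes("chr6", qpos)[idx], pop.damage[idx]
        )
        r2.append(res.r2_homozygous)
        recessive += res.mode == "recessive"
    return {"mean_r2": float(np.mean(r2)), "sd_r2": float(np.std(r2)),
            "recessive_rate": recessive / n_reps, "n_reps": n_reps}


def progeny_r2_recovery(n_reps: int = 200, seed: int = 0, n_plants: int = 100) -> dict:
    """Damage-vs-progeny regression: mean realized R-squared against the
    generator's 0.83 target."""
    model = GenomeModel(chromosomes=(("chr6", 216_000_000),),
                        genetic_map={"chr6": 1.44})
    panel = synthetic.simulate_parents(model, 200, divergence=1.0,
                                       seed=stage_seed(seed, "pparents"),
                                       resistant_lines=("R",))
    qpos = nearest_site(panel, "chr6", 60_000_000)
    spec = synthetic.QtlSpec(
        loci=(synthetic.QtlLocus("chr6", qpos, "R", "recessive", 0.70),)
    )
    r2 = []
    for rep in range(n_reps):
        pop = synthetic.simulate_f2(panel, ("R", "B73"), n_plants, model,
                                    seed=stage_seed(seed, f"pf2:{rep}"))
        synthetic.simulate_phenotypes(pop, spec, seed=stage_seed(seed, f"pph:{rep}"))
        r2.append(phenotypes.damage_productivity_fit(pop.damage, pop.progeny)[0])
    return {"mean_r2": float(np.mean(r2)), "n_reps": n_reps}


def haplotype_recovery(seed: int = 0, n_sites_per_chrom: int = 4_000) -> dict:
    """Zero-leak IBD recovery: implanted multi-line segments are recovered as
    >99%-similarity shared blocks; reports the worst boundary error in
    windows.  The chr6 segment mirrors the shared-haplotype span; a chr1
    segment shared by only two lines must not appear in the three-line
    blocks."""
    model = default_genome()
    trio = frozenset({"B49", "B75", "B96"})
    segments = (
        synthetic.IbdSegment("chr6", 7_895_601, 109_684_471, trio),
        synthetic.IbdSegment("chr3", 100_000_001, 118_000_000, trio),
        synthetic.IbdSegment("chr1", 30_000_001, 60_000_000, frozenset({"B49", "B96"})),
    )
    panel = synthetic.simulate_parents(
        model, n_sites_per_chrom, ibd=synthetic.IbdSpec(segments, 0.0),
        divergence=0.5, seed=stage_seed(seed, "hparents"),
    )
    masks = haplotypes.hard_filter(panel)
    wp = haplotypes.WindowParams()
    pairs = list(itertools.combinations(["B49", "B75", "B96"], 2))
    tracks = {p: haplotypes.window_similarity(panel, *p, masks, wp) for p in pairs}
    blocks, per_pair = haplotypes.shared_blocks(tracks, wp)

    errors = []
    for seg in segments[:2]:
        sub = blocks[blocks["chrom"] == seg.chrom]
        if not len(sub):
            errors.append(np.inf)
            continue
        widths = (sub["end"] - sub["start"]).to_numpy()
        row = sub.iloc[int(np.argmax(widths))]
        errors.append(max(abs(row["start"] - seg.start), abs(row["end"] - seg.end))
                      / wp.window_bp)
    chr1_trio = blocks[blocks["chrom"] == "chr1"]
    self_track = haplotypes.window_similarity(panel, "B49", "B49", masks, wp)
    valid = self_track[self_track["valid"]]
    return {
        "max_boundary_error_windows": float(max(errors)),
        "n_trio_blocks_chr1": int(len(chr1_trio)),
        "self_similarity_min": float(valid["similarity"].min()),
        "n_blocks": int(len(blocks)),
    }


def meta_plateau_recovery(seed: int = 0) -> dict:
    """Constructed plateau of known extent: the peak interval must recover
    the plateau boundaries within one 1-Mb window offset."""
    import pandas as pd

    rng = np.random.default_rng(stage_seed(seed, "plateau"))
    n = 400
    pos = np.sort(rng.choice(60_000_000, n, replace=False)) + 7_895_601
    counts = pd.DataFrame({
        "CHROM": "chr6", "POS": pos, "RES_ALLELE": "T", "SENS_ALLELE": "A",
    })
    lo, hi = 7_895_601 + 20_000_000, 7_895_601 + 40_000_000
    inside = (pos >= lo) & (pos <= hi)
    depth = 40
    counts["RES_POOL_RES"] = np.where(inside, int(0.95 * depth), int(0.55 * depth))
    counts["RES_POOL_SENS"] = depth - counts["RES_POOL_RES"]
    counts["SENS_POOL_RES"] = int(0.35 * depth)
    counts["SENS_POOL_SENS"] = depth - counts["SENS_POOL_RES"]
    track = meta.window_freq_difference(counts)
    peak = meta.peak_interval(track, 0.9)
    err_bp = max(abs(peak["start"] - lo), abs(peak["end"] - hi))
    return {"boundary_error_bp": float(err_bp), "peak_delta": peak["peak_delta"]}
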