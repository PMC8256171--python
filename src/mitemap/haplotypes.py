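"""Sliding-window haplotype identity among inbred lines.

Six GATK-style hard filters select high-confidence SNPs per line; pairwise
similarity is then computed in 5 Mb windows advanced by 500 kb.  A window is
only scored when at least 20% of its SNP sites pass QC in both lines and
more than 20 variable sites remain; similarity is the fraction of variable
passing sites at which the two lines carry the same allele.  Windows that
are near-identical (>99%) across every pair of a line set merge into shared
haplotype blocks, the signature of identity by descent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ParentPanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HardFilterParams:
    """The six hard-filter criteria for high-confidence SNPs."""

    depth_fold_min: float = 0.25
    depth_fold_max: float = 1.5
    min_qd: float = 2.0
    max_sor: float = 3.0
    min_mq: float = 50.0
    min_mq_rank_sum: float = -8.0
    min_read_pos_rank_sum: float = -8.0

    def __post_init__(self) -> None:
        if self.depth_fold_min >= self.depth_fold_max:
            raise ValueError("depth_fold_min must be < depth_fold_max")


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window geometry and validity rules."""

    window_bp: int = 5_000_000
    offset_bp: int = 500_000
    min_pass_fraction: float = 0.20
    min_variable_sites: int = 21  # "greater than 20 variable sites"
    identity_threshold: float = 0.99

    def __post_init__(self) -> None:
        if self.offset_bp > self.window_bp:
            raise ValueError("offset_bp must be <= window_bp")
        if not 0.0 < self.min_pass_fraction <= 1.0:
            raise ValueError("min_pass_fraction must be in (0, 1]")


def hard_filter(panel: ParentPanel, p: HardFilterParams | None = None) -> dict[str, dict[str, np.ndarray]]:
    """Per-line, per-chromosome boolean pass masks.

    A site passes for a line iff its depth is within the fold bounds of that
    line's genome-wide average depth and the five site annotations meet
    their thresholds.  Missing rank-sum annotations (sites with no
    heterozygous carrier in the caller) pass those criteria; a missing
    QD/SOR/MQ fails.  Sites without a homozygous call for the line
    (heterozygous or missing) also fail, since inbred lines are compared as
    haploids.
    """
    p = p or HardFilterParams()
    masks: dict[str, dict[str, np.ndarray]] = {}
    for line in panel.line_ids:
        all_depth = np.concatenate([panel.depth[line][c] for c in panel.model.names])
        mean_depth = float(all_depth.mean()) if len(all_depth) else 0.0
        if mean_depth <= 0:
            raise ValueError(f"line {line!r} has zero genome-wide average depth")
        masks[line] = {}
        for chrom in panel.model.names:
            ann = panel.site_annotations[chrom]
            fold = panel.depth[line][chrom] / mean_depth
            qd = ann["QD"].to_numpy()
            sor = ann["SOR"].to_numpy()
            mq = ann["MQ"].to_numpy()
            mqrs = ann["MQRankSum"].to_numpy()
            rprs = ann["ReadPosRankSum"].to_numpy()
            ok = (
                (fold >= p.depth_fold_min)
                & (fold <= p.depth_fold_max)
                & (qd >= p.min_qd)
                & (sor <= p.max_sor)
                & (mq >= p.min_mq)
                & (np.isnan(mqrs) | (mqrs >= p.min_mq_rank_sum))
                & (np.isnan(rprs) | (rprs >= p.min_read_pos_rank_sum))
                & (panel.genotypes[line][chrom] >= 0)
            )
            masks[line][chrom] = ok
    return masks


def window_grid(length: int, wp: WindowParams) -> list[tuple[int, int]]:
    """Window (start, end) pairs tiling [1, length] at offset steps.

    Windows are truncated at the chromosome end; a final partial window is
    kept only if it covers at least half the window length.
    """
    grid = []
    start = 1
    while start <= length:
        end = min(start + wp.window_bp - 1, length)
        if end - start + 1 >= wp.window_bp / 2:
            grid.append((start, end))
        start += wp.offset_bp
    return grid


def window_similarity(
    panel: ParentPanel,
    line_a: str,
    line_b: str,
    masks: dict[str, dict[str, np.ndarray]],
    wp: WindowParams | None = None,
) -> pd.DataFrame:
    """Windowed similarity track for one pair of lines.

    A site contributes only if it passes QC in both lines; it is variable if
    at least one of the two lines carries the non-reference allele.
    Similarity is matches / variable passing sites, reported together with
    the raw counts so the alternative denominator (all passing sites) can be
    recomputed.  Invalid windows carry NaN similarity.
    """
    if line_a == line_b:
        logger.info("self-comparison %s vs %s", line_a, line_b)
    wp = wp or WindowParams()
    rows = []
    for chrom, length in panel.model.chromosomes:
        pos = panel.positions[chrom]
        ga = panel.genotypes[line_a][chrom]
        gb = panel.genotypes[line_b][chrom]
        pair_pass = masks[line_a][chrom] & masks[line_b][chrom]
        variable = pair_pass & ((ga == 1) | (gb == 1))
        match = variable & (ga == gb)
        for start, end in window_grid(length, wp):
            i0, i1 = np.searchsorted(pos, [start, end + 1])
            n_sites = i1 - i0
            n_pass = int(pair_pass[i0:i1].sum())
            n_var = int(variable[i0:i1].sum())
            n_match = int(match[i0:i1].sum())
            valid = (
                n_sites > 0
                and n_pass / n_sites >= wp.min_pass_fraction
                and n_var >= wp.min_variable_sites
            )
            rows.append({
                "line_a": line_a, "line_b": line_b, "chrom": chrom,
                "start": start, "end": end,
                "n_sites": n_sites, "n_pass": n_pass,
                "n_variable": n_var, "n_match": n_match,
                "similarity": n_match / n_var if valid else np.nan,
                "valid": valid,
            })
    return pd.DataFrame(rows)


def shared_blocks(
    tracks: dict[tuple[str, str], pd.DataFrame],
    wp: WindowParams | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], pd.DataFrame]]:
    """Merge runs of near-identical windows into shared haplotype blocks.

    A window is shared by all lines iff every pairwise track is valid there
    with similarity >= the identity threshold; maximal runs of consecutive
    shared windows merge into blocks spanning the union of window spans.
    Returns the all-lines blocks and per-pair blocks.  All tracks must use
    the same window grid.
    """
    wp = wp or WindowParams()
    if not tracks:
        raise ValueError("no similarity tracks given")
    pair_keys = list(tracks)
    grids = [tuple(map(tuple, t[["chrom", "start", "end"]].itertuples(index=False, name=None)))
             for t in tracks.values()]
    if len(set(grids)) > 1:
        raise ValueError("similarity tracks use inconsistent window grids")

    def runs_to_blocks(shared: np.ndarray, grid: pd.DataFrame, sims: np.ndarray,
                       members: tuple[str, ...]) -> pd.DataFrame:
        blocks = []
        idx = np.flatnonzero(shared)
        if len(idx):
            chroms = grid["chrom"].to_numpy()
            splits = np.flatnonzero((np.diff(idx) > 1) | (chroms[idx][1:] != chroms[idx][:-1]))
            for run in np.split(idx, splits + 1):
                blocks.append({
                    "chrom": chroms[run[0]],
                    "start": int(grid["start"].iloc[run[0]]),
                    "end": int(grid["end"].iloc[run[-1]]),
                    "members": ",".join(members),
                    "min_similarity": float(np.nanmin(sims[run])),
                    "n_windows": len(run),
                })
        return pd.DataFrame(blocks, columns=["chrom", "start", "end", "members",
                                             "min_similarity", "n_windows"])

    grid = next(iter(tracks.values()))[["chrom", "start", "end"]].reset_index(drop=True)
    all_ok = np.ones(len(grid), dtype=bool)
    min_sim = np.full(len(grid), np.inf)
    per_pair: dict[tuple[str, str], pd.DataFrame] = {}
    for key in pair_keys:
        t = tracks[key].reset_index(drop=True)
        ok = t["valid"].to_numpy() & (t["similarity"].to_numpy() >= wp.identity_threshold)
        all_ok &= ok
        min_sim = np.minimum(min_sim, t["similarity"].to_numpy())
        per_pair[key] = runs_to_blocks(ok, grid, t["similarity"].to_numpy(), key)
    members = tuple(sorted({l for key in pair_keys for l in key}))
    trio = runs_to_blocks(all_ok, grid, np.where(np.isfinite(min_sim), min_sim, np.nan), members)
    return trio, per_pair
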