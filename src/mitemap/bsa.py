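"""Bulked-segregant G' QTL scan.

At each biallelic SNP the two bulks form a 2x2 allele-count table; the
likelihood-ratio statistic

    G = 2 * sum_i n_i * ln(n_i / nhat_i)

(with expectations nhat from the row x column marginals, zero cells
contributing zero) measures the allele-frequency differentiation between the
pools.  G is tricube-smoothed over a physical window (G'), a log-normal null
is fitted to Hampel-filtered G' values, and contiguous runs of sites below a
Benjamini-Hochberg FDR threshold are called as QTL intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanParams:
    """SNP filters and scan settings for one replicate.

    Depth thresholds are per-run values (the defaults are the low end of the
    per-sample ranges used with pool coverages of a few fold); when
    replicates are merged the four depth thresholds should be doubled
    (see :meth:`doubled`).
    """

    min_total_depth: int = 6
    max_total_depth: int = 36
    max_depth_difference: int = 8
    min_sample_depth: int = 3
    ref_freq_cutoff: float = 0.2
    min_gq: int = 20
    window_bp: int = 10_000_000
    fdr: float = 0.01
    hampel_g: float = 5.2

    def __post_init__(self) -> None:
        if self.min_total_depth > self.max_total_depth:
            raise ValueError("min_total_depth > max_total_depth")
        if not 0.0 < self.ref_freq_cutoff <= 0.5:
            raise ValueError("ref_freq_cutoff must be in (0, 0.5]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must be in (0, 1)")

    def doubled(self) -> "ScanParams":
        """Depth thresholds doubled, for a table merged from two replicates."""
        return replace(
            self,
            min_total_depth=2 * self.min_total_depth,
            max_total_depth=2 * self.max_total_depth,
            max_depth_difference=2 * self.max_depth_difference,
            min_sample_depth=2 * self.min_sample_depth,
        )


def merge_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum per-pool AD and DP across replicate tables, site by site.

    Sites absent from a replicate contribute zeros; sites with conflicting
    REF/ALT across replicates are dropped (count logged and recorded in
    ``attrs['n_conflicts']``).  GQ of a merged site is the minimum across
    the replicates that cover it.  Callers scanning a merged table should
    double the depth thresholds (:meth:`ScanParams.doubled`).
    """
    if not tables:
        raise ValueError("no tables to merge")
    tables = [t for t in tables if len(t)] or [tables[0]]
    chrom_order = list(dict.fromkeys(c for t in tables for c in t["CHROM"]))
    df = pd.concat(tables, ignore_index=True)
    key = ["CHROM", "POS"]
    nuniq = df.groupby(key)[["REF", "ALT"]].nunique()
    bad = nuniq[(nuniq["REF"] > 1) | (nuniq["ALT"] > 1)].index
    n_conflicts = len(bad)
    if n_conflicts:
        logger.warning("dropping %d sites with conflicting REF/ALT", n_conflicts)
        df = df[~pd.MultiIndex.from_frame(df[key]).isin(bad)]
    agg = {
        "REF": "first", "ALT": "first",
        "AD_REF_RES": "sum", "AD_ALT_RES": "sum", "DP_RES": "sum", "GQ_RES": "min",
        "AD_REF_SENS": "sum", "AD_ALT_SENS": "sum", "DP_SENS": "sum", "GQ_SENS": "min",
    }
    merged = df.groupby(key, as_index=False).agg(agg)
    merged["CHROM"] = pd.Categorical(merged["CHROM"], categories=chrom_order, ordered=True)
    merged = merged.sort_values(key, ignore_index=True)
    merged["CHROM"] = merged["CHROM"].astype(str)
    merged.attrs["n_conflicts"] = n_conflicts
    return merged


def filter_snps(table: pd.DataFrame, p: ScanParams) -> pd.DataFrame:
    """Apply the depth / depth-difference / GQ / reference-allele-frequency
    filters; returns the retained (possibly empty) table."""
    dp_r = table["DP_RES"].to_numpy()
    dp_s = table["DP_SENS"].to_numpy()
    total = dp_r + dp_s
    ad_ref = table["AD_REF_RES"].to_numpy() + table["AD_REF_SENS"].to_numpy()
    ad_tot = ad_ref + table["AD_ALT_RES"].to_numpy() + table["AD_ALT_SENS"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ref_freq = np.where(ad_tot > 0, ad_ref / np.maximum(ad_tot, 1), np.nan)
    keep = (
        (total >= p.min_total_depth)
        & (total <= p.max_total_depth)
        & (np.abs(dp_r - dp_s) <= p.max_depth_difference)
        & (dp_r >= p.min_sample_depth)
        & (dp_s >= p.min_sample_depth)
        & (table["GQ_RES"].to_numpy() >= p.min_gq)
        & (table["GQ_SENS"].to_numpy() >= p.min_gq)
        & (ref_freq >= p.ref_freq_cutoff)
        & (ref_freq <= 1.0 - p.ref_freq_cutoff)
    )
    out = table[keep].reset_index(drop=True)
    logger.info("filter_snps: retained %d of %d sites", len(out), len(table))
    return out


def g_statistic(counts: np.ndarray) -> np.ndarray:
    """Likelihood-ratio G for 2x2 allele-count tables (pool x allele).

    ``counts`` has shape (..., 2, 2).  Cells with n=0 contribute zero; a
    table with any zero marginal is degenerate and yields NaN (the site is
    skipped by the scan).
    """
    n = np.asarray(counts, dtype=float)
    rows = n.sum(axis=-1, keepdims=True)
    cols = n.sum(axis=-2, keepdims=True)
    tot = n.sum(axis=(-1, -2), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expect = rows * cols / tot
        terms = np.where(n > 0, n * np.log(n / expect), 0.0)
    g = 2.0 * terms.sum(axis=(-1, -2))
    degenerate = (rows == 0).any(axis=(-1, -2)) | (cols == 0).any(axis=(-1, -2))
    return np.where(degenerate, np.nan, np.maximum(g, 0.0))


def smooth_gprime(positions: np.ndarray, g: np.ndarray, window_bp: int) -> np.ndarray:
    """Tricube-kernel smoothing of G over a centered physical window.

    For site i, G'_i is the weighted mean of G over sites within
    window_bp/2, with tricube weights (1 - (d/D)^3)^3 normalized to sum to
    one.  Windows are truncated (not reflected) at chromosome ends.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    pos = np.asarray(positions, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(pos) == 0:
        return np.empty(0)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    half = window_bp / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    out = np.empty_like(g)
    for i in range(len(pos)):
        d = np.abs(pos[lo[i]:hi[i]] - pos[i]) / half
        w = (1.0 - d**3) ** 3
        out[i] = np.dot(w, g[lo[i]:hi[i]]) / w.sum()
    return out


def null_fit_pvalues(gprime: np.ndarray, hampel_g: float = 5.2) -> tuple[np.ndarray, np.ndarray]:
    """Upper-tail p-values under a log-normal null fitted to Hampel-filtered
    G', and Benjamini-Hochberg q-values over all scanned sites.

    The Hampel filter removes sites with |G' - median| > hampel_g * MAD.
    The null location is ln(median) of the retained set; the scale is the
    (normal-consistent) MAD of ln G' of the retained set.
    """
    x = np.asarray(gprime, dtype=float)
    if len(x) < 100:
        logger.warning("null fit on only %d sites; p-values will be unstable", len(x))
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    retained = x[np.abs(x - med) <= hampel_g * mad] if mad > 0 else x
    retained = retained[retained > 0]
    if len(retained) == 0 or np.all(retained == retained[0]):
        logger.warning("degenerate G' null (all retained values identical)")
        p = np.full_like(x, 0.5)
        return p, multipletests(p, method="fdr_bh")[1]
    logx = np.log(retained)
    loc = np.log(np.median(retained))
    scale = 1.4826 * np.median(np.abs(logx - np.median(logx)))
    if scale == 0:
        logger.warning("degenerate G' null (zero log-scale)")
        p = np.where(x > np.exp(loc), 0.0, np.where(x < np.exp(loc), 1.0, 0.5))
    else:
        p = stats.lognorm.sf(x, s=scale, scale=np.exp(loc))
    q = multipletests(p, method="fdr_bh")[1]
    return p, q


def scan(table: pd.DataFrame, params: ScanParams) -> pd.DataFrame:
    """Full per-replicate scan: filter -> G -> G' -> lognormal p -> BH q.

    Returns a per-site track with columns CHROM, POS, G, Gprime, p, q.
    Sites with a zero allele-count marginal (G undefined) are skipped.
    """
    kept = filter_snps(table, params)
    if len(kept) == 0:
        return pd.DataFrame(columns=["CHROM", "POS", "G", "Gprime", "p", "q"])
    counts = np.stack(
        [
            np.stack([kept["AD_REF_RES"], kept["AD_ALT_RES"]], axis=-1),
            np.stack([kept["AD_REF_SENS"], kept["AD_ALT_SENS"]], axis=-1),
        ],
        axis=-2,
    )
    g = g_statistic(counts)
    ok = ~np.isnan(g)
    kept = kept[ok].reset_index(drop=True)
    g = g[ok]
    gprime = np.empty_like(g)
    chrom_order = list(dict.fromkeys(kept["CHROM"]))
    for chrom in chrom_order:
        sel = (kept["CHROM"] == chrom).to_numpy()
        gprime[sel] = smooth_gprime(kept["POS"].to_numpy()[sel], g[sel], params.window_bp)
    p, q = null_fit_pvalues(gprime, params.hampel_g)
    return pd.DataFrame(
        {"CHROM": kept["CHROM"], "POS": kept["POS"], "G": g, "Gprime": gprime, "p": p, "q": q}
    )


def call_qtl(track: pd.DataFrame, fdr: float = 0.01, window_bp: int = 10_000_000) -> pd.DataFrame:
    """QTL intervals: maximal runs of contiguous sites with q < fdr.

    Runs on the same chromosome separated by less than one window width are
    joined.  The peak is the leftmost argmax of G' within the interval.
    Returns columns chrom, start, end, peak_pos, peak_gprime, min_q.
    """
    intervals = []
    for chrom in dict.fromkeys(track["CHROM"]):
        sub = track[track["CHROM"] == chrom].reset_index(drop=True)
        sig = (sub["q"] < fdr).to_numpy()
        if not sig.any():
            continue
        idx = np.flatnonzero(sig)
        # split into contiguous index runs
        splits = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, splits + 1)
        # join runs separated by < window_bp
        pos = sub["POS"].to_numpy()
        joined: list[np.ndarray] = [runs[0]]
        for run in runs[1:]:
            if pos[run[0]] - pos[joined[-1][-1]] < window_bp:
                joined[-1] = np.concatenate([joined[-1], run])
            else:
                joined.append(run)
        for run in joined:
            seg = sub.iloc[run[0]: run[-1] + 1]
            gp = seg["Gprime"].to_numpy()
            peak = int(np.argmax(gp))  # leftmost argmax
            intervals.append({
                "chrom": chrom,
                "start": int(seg["POS"].iloc[0]),
                "end": int(seg["POS"].iloc[-1]),
                "peak_pos": int(seg["POS"].iloc[peak]),
                "peak_gprime": float(gp[peak]),
                "min_q": float(seg["q"].min()),
            })
    return pd.DataFrame(intervals, columns=["chrom", "start", "end", "peak_pos", "peak_gprime", "min_q"])
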