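"""Cross-pooled allele-frequency meta-analysis over a shared haplotype.

Reads from all resistant pools (across crosses and replicates) are combined,
and likewise all sensitive pools.  At each haplotype-defining SNP, read
counts supporting the resistant-parent allele and the susceptible-parent
allele are tallied per merged pool; the per-window difference in
resistant-allele frequency between the pools peaks at the causal locus, and
forms a plateau where recombination is suppressed (e.g. near a centromere).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["CHROM", "POS", "RES_ALLELE", "SENS_ALLELE"]


def haplotype_sites(panel, block: dict | pd.Series, members: list[str] | None = None) -> pd.DataFrame:
    """Haplotype-defining SNPs within a shared block.

    Sites where every resistant member line carries the alternate allele and
    the susceptible line the reference allele; the resistant allele is then
    the ALT base and the sensitive allele the REF base.
    """
    chrom = block["chrom"]
    members = members or [m for m in str(block["members"]).split(",") if m != panel.susceptible]
    pos = panel.positions[chrom]
    sel = (pos >= int(block["start"])) & (pos <= int(block["end"]))
    for line in members:
        sel &= panel.genotypes[line][chrom] == 1
    return pd.DataFrame({
        "CHROM": chrom,
        "POS": pos[sel],
        "RES_ALLELE": panel.alt_allele[chrom][sel],
        "SENS_ALLELE": panel.ref_allele[chrom][sel],
    })


def pool_counts_at_sites(tables: list[pd.DataFrame], sites: pd.DataFrame) -> pd.DataFrame:
    """Sum resistant/sensitive-allele read counts over all tables, per pool.

    Each table contributes its resistant-pool and sensitive-pool AD counts,
    with REF/ALT mapped onto the site's sensitive/resistant alleles; tables
    whose alleles match neither orientation at a site are ignored there
    (multi-allelic disagreement is discarded, not error-corrected).  Sites
    absent from all tables are retained with zero counts.
    """
    for col in SITE_COLUMNS:
        if col not in sites.columns:
            raise ValueError(f"sites table lacks column {col!r}")
    out = sites[SITE_COLUMNS].reset_index(drop=True).copy()
    acc = np.zeros((len(out), 4), dtype=np.int64)  # rp_res rp_sens sp_res sp_sens
    key = pd.MultiIndex.from_frame(out[["CHROM", "POS"]])
    lookup = pd.Series(np.arange(len(out)), index=key)
    for table in tables:
        hit = pd.MultiIndex.from_frame(table[["CHROM", "POS"]]).isin(key)
        sub = table[hit]
        if not len(sub):
            continue
        rows = lookup.loc[pd.MultiIndex.from_frame(sub[["CHROM", "POS"]])].to_numpy()
        res_al = out["RES_ALLELE"].to_numpy()[rows]
        sens_al = out["SENS_ALLELE"].to_numpy()[rows]
        ref = sub["REF"].to_numpy()
        alt = sub["ALT"].to_numpy()
        fwd = (ref == sens_al) & (alt == res_al)   # ALT is the resistant allele
        rev = (ref == res_al) & (alt == sens_al)   # REF is the resistant allele
        ar_r = sub["AD_REF_RES"].to_numpy()
        aa_r = sub["AD_ALT_RES"].to_numpy()
        ar_s = sub["AD_REF_SENS"].to_numpy()
        aa_s = sub["AD_ALT_SENS"].to_numpy()
        np.add.at(acc[:, 0], rows[fwd], aa_r[fwd])
        np.add.at(acc[:, 1], rows[fwd], ar_r[fwd])
        np.add.at(acc[:, 2], rows[fwd], aa_s[fwd])
        np.add.at(acc[:, 3], rows[fwd], ar_s[fwd])
        np.add.at(acc[:, 0], rows[rev], ar_r[rev])
        np.add.at(acc[:, 1], rows[rev], aa_r[rev])
        np.add.at(acc[:, 2], rows[rev], ar_s[rev])
        np.add.at(acc[:, 3], rows[rev], aa_s[rev])
    out["RES_POOL_RES"] = acc[:, 0]
    out["RES_POOL_SENS"] = acc[:, 1]
    out["SENS_POOL_RES"] = acc[:, 2]
    out["SENS_POOL_SENS"] = acc[:, 3]
    return out


def window_freq_difference(
    counts: pd.DataFrame,
    window_bp: int = 5_000_000,
    offset_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Sliding-window resistant-allele frequencies and their difference.

    Windows are anchored at the first haplotype site of each chromosome
    (the analysis is restricted to the shared-haplotype span).  Windows
    with zero informative reads in either pool are flagged undefined
    (NaN delta).
    """
    rows = []
    for chrom in dict.fromkeys(counts["CHROM"]):
        sub = counts[counts["CHROM"] == chrom].sort_values("POS")
        pos = sub["POS"].to_numpy()
        anchor, last = int(pos[0]), int(pos[-1])
        start = anchor
        while start <= last:
            end = start + window_bp - 1
            i0, i1 = np.searchsorted(pos, [start, end + 1])
            rp_res = int(sub["RES_POOL_RES"].iloc[i0:i1].sum())
            rp_sens = int(sub["RES_POOL_SENS"].iloc[i0:i1].sum())
            sp_res = int(sub["SENS_POOL_RES"].iloc[i0:i1].sum())
            sp_sens = int(sub["SENS_POOL_SENS"].iloc[i0:i1].sum())
            rp_tot, sp_tot = rp_res + rp_sens, sp_res + sp_sens
            if rp_tot > 0 and sp_tot > 0:
                f_r, f_s = rp_res / rp_tot, sp_res / sp_tot
                delta = f_r - f_s
            else:
                f_r = f_s = delta = np.nan
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "freq_res_pool": f_r, "freq_sens_pool": f_s, "delta": delta,
                "n_res_reads": rp_tot, "n_sens_reads": sp_tot,
                "n_sites": int(i1 - i0),
            })
            start += offset_bp
    return pd.DataFrame(rows)


def peak_interval(
    track: pd.DataFrame,
    fraction_of_max: float = 0.9,
    centromere: int | None = None,
) -> dict:
    """Peak plateau: the maximal run of windows with delta >= fraction_of_max
    times the maximum delta that contains the argmax window."""
    delta = track["delta"].to_numpy(dtype=float)
    defined = np.isfinite(delta)
    if not defined.any():
        raise ValueError("all windows undefined; no informative reads")
    imax = int(np.nanargmax(delta))
    thresh = fraction_of_max * delta[imax]
    high = defined & (delta >= thresh)
    lo = imax
    while lo > 0 and high[lo - 1]:
        lo -= 1
    hi = imax
    while hi < len(delta) - 1 and high[hi + 1]:
        hi += 1
    return {
        "chrom": track["chrom"].iloc[imax],
        "start": int(track["start"].iloc[lo]),
        "end": int(track["end"].iloc[hi]),
        "peak_start": int(track["start"].iloc[imax]),
        "peak_end": int(track["end"].iloc[imax]),
        "peak_delta": float(delta[imax]),
        "centromere": centromere,
    }
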