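"""Readers and writers for the interchange formats.

The canonical interchange format is the tab-delimited SNP table derived
from a two-sample variant-call table (fields CHROM, POS, REF, ALT and
per-pool AD, DP, GQ, PL).  On disk the per-pool fields carry a pool suffix
(``AD.RES``/``AD.SENS`` etc.) and AD is a ``ref,alt`` comma pair; PL is
accepted on input but ignored.  Coordinates are 1-based inclusive in all
internal tables; exported BED is 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical in-memory SNP-table columns (RES = resistant bulk, SENS = sensitive)
SNP_COLUMNS = [
    "CHROM", "POS", "REF", "ALT",
    "AD_REF_RES", "AD_ALT_RES", "DP_RES", "GQ_RES",
    "AD_REF_SENS", "AD_ALT_SENS", "DP_SENS", "GQ_SENS",
]

_FILE_FIELDS = ["CHROM", "POS", "REF", "ALT",
                "AD.RES", "DP.RES", "GQ.RES", "PL.RES",
                "AD.SENS", "DP.SENS", "GQ.SENS", "PL.SENS"]


def _version_header(params_hash: str | None = None) -> str:
    from . import __version__

    tail = f" params={params_hash}" if params_hash else ""
    return f"# mitemap {__version__}{tail}"


def write_snp_table(table: pd.DataFrame, path: str | Path,
                    params_hash: str | None = None) -> None:
    """Write the two-pool tab table with AD as ``ref,alt`` pairs per pool."""
    path = Path(path)
    out = pd.DataFrame({
        "CHROM": table["CHROM"],
        "POS": table["POS"],
        "REF": table["REF"],
        "ALT": table["ALT"],
        "AD.RES": table["AD_REF_RES"].astype(str) + "," + table["AD_ALT_RES"].astype(str),
        "DP.RES": table["DP_RES"],
        "GQ.RES": table["GQ_RES"],
        "PL.RES": 0,
        "AD.SENS": table["AD_REF_SENS"].astype(str) + "," + table["AD_ALT_SENS"].astype(str),
        "DP.SENS": table["DP_SENS"],
        "GQ.SENS": table["GQ_SENS"],
        "PL.SENS": 0,
    })
    with path.open("w") as fh:
        fh.write(_version_header(params_hash) + "\n")
        out.to_csv(fh, sep="\t", index=False)


def read_snp_table(path: str | Path, dialect: str = "table8") -> pd.DataFrame:
    """Read a SNP table (``table8`` tab dialect or a two-sample ``vcf``).

    Malformed rows (unparseable fields, multiallelic ALT) are skipped and
    counted; one percent or more malformed rows is a hard error.
    """
    if dialect == "vcf":
        return _read_snp_vcf(path)
    if dialect != "table8":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows: list[tuple] = []
    n_bad = 0
    header: list[str] | None = None
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                for col in ("CHROM", "POS", "REF", "ALT", "AD.RES", "AD.SENS"):
                    if col not in header:
                        raise ValueError(f"missing mandatory column {col!r} in {path}")
                idx = {c: header.index(c) for c in header}
                continue
            parts = line.split("\t")
            try:
                alt = parts[idx["ALT"]]
                if "," in alt:  # biallelic contract
                    raise ValueError("multiallelic")
                ad_r = parts[idx["AD.RES"]].split(",")
                ad_s = parts[idx["AD.SENS"]].split(",")
                if len(ad_r) != 2 or len(ad_s) != 2:
                    raise ValueError("AD not a ref,alt pair")
                rows.append((
                    parts[idx["CHROM"]], int(parts[idx["POS"]]),
                    parts[idx["REF"]], alt,
                    int(ad_r[0]), int(ad_r[1]),
                    int(parts[idx["DP.RES"]]), int(parts[idx["GQ.RES"]]),
                    int(ad_s[0]), int(ad_s[1]),
                    int(parts[idx["DP.SENS"]]), int(parts[idx["GQ.SENS"]]),
                ))
            except (ValueError, IndexError):
                n_bad += 1
    if header is None:
        raise ValueError(f"{path} has no header line")
    total = len(rows) + n_bad
    if total and n_bad / total >= 0.01:
        raise ValueError(f"{n_bad}/{total} malformed rows in {path} (>= 1%)")
    if n_bad:
        logger.warning("skipped %d malformed rows in %s", n_bad, path)
    table = pd.DataFrame(rows, columns=SNP_COLUMNS)
    table.attrs["n_malformed"] = n_bad
    return table


def _read_snp_vcf(path: str | Path) -> pd.DataFrame:
    """Two-sample VCF ingestion (sample order: resistant pool, sensitive pool)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 2:
        raise ValueError(f"expected two sample columns, found {len(vcf.samples)}")
    rows = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        ad = v.format("AD")
        dp = v.format("DP").reshape(-1)
        gq = v.format("GQ").reshape(-1)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0],
                     int(ad[0][0]), int(ad[0][1]), int(dp[0]), int(gq[0]),
                     int(ad[1][0]), int(ad[1][1]), int(dp[1]), int(gq[1])))
    table = pd.DataFrame(rows, columns=SNP_COLUMNS)
    table.attrs["n_malformed"] = n_skipped
    return table


def write_bed(intervals: pd.DataFrame, path: str | Path,
              params_hash: str | None = None) -> None:
    """Write intervals as BED (internal 1-based inclusive -> 0-based half-open).

    ``intervals`` needs columns ``chrom``, ``start``, ``end``; any extra
    columns are appended as BED name fields.  Adjacent intervals are written
    as-is, never merged.
    """
    path = Path(path)
    extra = [c for c in intervals.columns if c not in ("chrom", "start", "end")]
    with path.open("w") as fh:
        fh.write(_version_header(params_hash) + "\n")
        for _, row in intervals.iterrows():
            fields = [str(row["chrom"]), str(int(row["start"]) - 1), str(int(row["end"]))]
            fields += [str(row[c]) for c in extra]
            fh.write("\t".join(fields) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path,
              params_hash: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_version_header(params_hash) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_panel_vcf(panel, path: str | Path) -> None:
    """Minimal VCF v4.2 for a parental panel: GT:DP per line, hard-filter
    annotations as INFO keys."""
    path = Path(path)
    lines = panel.line_ids
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=mitemap\n")
        for chrom, length in panel.model.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for key in ("QD", "SOR", "MQ", "MQRankSum", "ReadPosRankSum"):
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(lines) + "\n")
        for chrom in panel.model.names:
            pos = panel.positions[chrom]
            ref = panel.ref_allele[chrom]
            alt = panel.alt_allele[chrom]
            ann = panel.site_annotations[chrom]
            for i in range(len(pos)):
                info = []
                for key in ("QD", "SOR", "MQ", "MQRankSum", "ReadPosRankSum"):
                    val = ann[key].iloc[i]
                    if not np.isnan(val):
                        info.append(f"{key}={val:.4g}")
                samples = []
                for line in lines:
                    g = panel.genotypes[line][chrom][i]
                    gt = {0: "0/0", 1: "1/1"}.get(int(g), "./.")
                    dp = int(round(panel.depth[line][chrom][i]))
                    samples.append(f"{gt}:{dp}")
                fh.write(f"{chrom}\t{pos[i]}\t.\t{ref[i]}\t{alt[i]}\t.\t.\t"
                         f"{';'.join(info) or '.'}\tGT:DP\t" + "\t".join(samples) + "\n")


def read_panel_vcf(path: str | Path, susceptible: str | None = None):
    """Load a parental panel from a multi-sample VCF (GT:DP + INFO keys).

    Heterozygous or missing calls become missing (-1): inbred lines are
    treated as haploid for the haplotype comparison.
    """
    from cyvcf2 import VCF

    from .genome import GenomeModel
    from .synthetic import ParentPanel

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    susceptible = susceptible or lines[0]
    contigs = [(c, vcf.seqlens[i]) for i, c in enumerate(vcf.seqnames)]
    model = GenomeModel(chromosomes=tuple(contigs))
    data: dict[str, dict[str, list]] = {c: {"pos": [], "ref": [], "alt": [], "ann": [], "gt": [], "dp": []}
                                        for c, _ in contigs}
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        d = data[v.CHROM]
        d["pos"].append(v.POS)
        d["ref"].append(v.REF)
        d["alt"].append(v.ALT[0])
        d["ann"].append(tuple(v.INFO.get(k) if v.INFO.get(k) is not None else np.nan
                              for k in ("QD", "SOR", "MQ", "MQRankSum", "ReadPosRankSum")))
        codes = []
        for gt in v.genotypes:
            alleles = gt[:-1]
            if any(a < 0 for a in alleles) or len(set(alleles)) > 1:
                codes.append(-1)
            else:
                codes.append(alleles[0])
        d["gt"].append(codes)
        dp = v.format("DP")
        d["dp"].append(dp.reshape(-1) if dp is not None else np.zeros(len(lines)))

    positions, ref_allele, alt_allele = {}, {}, {}
    annotations = {}
    genotypes = {l: {} for l in lines}
    depth = {l: {} for l in lines}
    for chrom, _ in contigs:
        d = data[chrom]
        positions[chrom] = np.asarray(d["pos"], dtype=np.int64)
        ref_allele[chrom] = np.asarray(d["ref"])
        alt_allele[chrom] = np.asarray(d["alt"])
        annotations[chrom] = pd.DataFrame(
            d["ann"], columns=["QD", "SOR", "MQ", "MQRankSum", "ReadPosRankSum"]
        )
        gt = np.asarray(d["gt"], dtype=np.int8) if d["gt"] else np.empty((0, len(lines)), np.int8)
        dp = np.asarray(d["dp"], dtype=float) if d["dp"] else np.empty((0, len(lines)))
        for j, line in enumerate(lines):
            genotypes[line][chrom] = gt[:, j]
            depth[line][chrom] = dp[:, j]
    return ParentPanel(
        line_ids=lines, susceptible=susceptible, model=model,
        positions=positions, ref_allele=ref_allele, alt_allele=alt_allele,
        genotypes=genotypes, site_annotations=annotations, depth=depth,
    )
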