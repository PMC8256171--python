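"""End-to-end workflow: simulate -> per-replicate and merged G' scans ->
haplotype identity -> cross-pooled meta-analysis.

Every stage draws its randomness from a named substream of the single
global seed, and a manifest records parameter hashes and output checksums,
so re-running an identical configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bsa, haplotypes, io, meta, synthetic
from .config import RunConfig
from .genome import default_genome
from .util import params_hash, stage_seed

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def nearest_site(panel: synthetic.ParentPanel, chrom: str, pos: int) -> int:
    """Panel site position nearest to ``pos`` on ``chrom``."""
    sites = panel.positions[chrom]
    idx = int(np.clip(np.searchsorted(sites, pos), 1, len(sites) - 1))
    lo, hi = sites[idx - 1], sites[idx]
    return int(lo if abs(int(lo) - pos) <= abs(int(hi) - pos) else hi)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the full workflow; returns the artifact directory."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    phash = params_hash(dataclasses.asdict(config))
    manifest: dict = {"seed": config.seed, "params_hash": phash, "stages": {}}
    outputs: list[Path] = []

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].setdefault(stage, []).extend(str(p.name) for p in paths)
        outputs.extend(paths)

    try:
        # --- stage: simulate parents -----------------------------------
        model = default_genome(config.genome.n_chromosomes)
        panel = synthetic.simulate_parents(
            model,
            config.simulate.n_sites_per_chrom,
            ibd=config.ibd_spec(),
            divergence=config.simulate.divergence,
            seed=stage_seed(config.seed, "parents"),
            resistant_lines=tuple(config.simulate.resistant_lines),
            susceptible=config.simulate.susceptible,
        )
        panel_vcf = out / "parents.vcf"
        io.write_panel_vcf(panel, panel_vcf)
        record("simulate_parents", panel_vcf)
        logger.info("simulated %d parental sites across %d chromosomes",
                    panel.n_sites(), len(model.names))

        # --- stage: per-cross F2, phenotypes, pools, scans --------------
        scan_tables: dict[str, list] = {}
        for cross_line in config.simulate.crosses:
            qtl_spec = config.qtl_spec(cross_line)
            loci = tuple(
                dataclasses.replace(l, pos=nearest_site(panel, l.chrom, l.pos))
                for l in qtl_spec.loci
            )
            qtl_spec = dataclasses.replace(qtl_spec, loci=loci)
            tables = []
            for rep in range(1, config.simulate.n_replicates + 1):
                tag = f"{cross_line}x{config.simulate.susceptible}_rep{rep}"
                pop = synthetic.simulate_f2(
                    panel, (cross_line, config.simulate.susceptible),
                    config.simulate.n_f2, model,
                    seed=stage_seed(config.seed, f"f2:{tag}"),
                )
                synthetic.simulate_phenotypes(
                    pop, qtl_spec, seed=stage_seed(config.seed, f"pheno:{tag}")
                )
                bulks = synthetic.make_bulks(
                    pop, config.simulate.bulk_size,
                    seed=stage_seed(config.seed, f"bulks:{tag}"),
                )
                table = synthetic.simulate_pool_seq(
                    pop, bulks, config.pool_params(stage_seed(config.seed, f"pools:{tag}"))
                )
                tpath = out / f"snps_{tag}.tsv"
                io.write_snp_table(table, tpath, params_hash=phash)
                pheno = out / f"phenotypes_{tag}.tsv"
                io.write_tsv(
                    pd.DataFrame({
                        "plant": np.arange(pop.n),
                        "damage_score": synthetic.round_damage_for_display(pop.damage),
                        "progeny_count": pop.progeny,
                        "excluded": pop.excluded.astype(int),
                    }),
                    pheno, params_hash=phash,
                )
                record("simulate_f2", tpath, pheno)
                tables.append(table)

                track = bsa.scan(table, config.scan)
                spath = out / f"scan_{tag}.tsv"
                io.write_tsv(track, spath, params_hash=phash)
                record("scan_replicates", spath)
            scan_tables[cross_line] = tables

            merged = bsa.merge_replicates(tables)
            track = bsa.scan(merged, config.scan.doubled())
            intervals = bsa.call_qtl(track, config.scan.fdr, config.scan.window_bp)
            mpath = out / f"scan_{cross_line}_merged.tsv"
            ipath = out / f"qtl_{cross_line}.tsv"
            bpath = out / f"qtl_{cross_line}.bed"
            io.write_tsv(track, mpath, params_hash=phash)
            io.write_tsv(intervals, ipath, params_hash=phash)
            io.write_bed(intervals, bpath, params_hash=phash)
            record("scan_merged", mpath, ipath, bpath)
            logger.info("cross %s: %d QTL interval(s)", cross_line, len(intervals))

        # --- stage: haplotype similarity --------------------------------
        pairs = list(itertools.combinations(panel.resistant_lines, 2))
        if not pairs:
            logger.info("fewer than two resistant lines; haplotype and meta stages skipped")
            manifest["checksums"] = {p.name: _sha256(p) for p in outputs}
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True) + "\n")
            return out
        masks = haplotypes.hard_filter(panel, config.hard_filter)
        tracks = {
            pair: haplotypes.window_similarity(panel, *pair, masks, config.windows)
            for pair in pairs
        }
        blocks, _ = haplotypes.shared_blocks(tracks, config.windows)
        for pair, track in tracks.items():
            path = out / f"similarity_{pair[0]}_{pair[1]}.tsv"
            io.write_tsv(track, path, params_hash=phash)
            record("haplotype", path)
        blk_tsv = out / "shared_blocks.tsv"
        blk_bed = out / "shared_blocks.bed"
        io.write_tsv(blocks, blk_tsv, params_hash=phash)
        io.write_bed(blocks, blk_bed, params_hash=phash)
        record("haplotype", blk_tsv, blk_bed)

        # --- stage: meta-analysis ---------------------------------------
        if len(blocks):
            widths = blocks["end"] - blocks["start"]
            block = blocks.iloc[int(widths.idxmax())]
            sites = meta.haplotype_sites(panel, block)
            all_tables = [t for tables in scan_tables.values() for t in tables]
            counts = meta.pool_counts_at_sites(all_tables, sites)
            mtrack = meta.window_freq_difference(
                counts, config.meta.window_bp, config.meta.offset_bp
            )
            peak = meta.peak_interval(
                mtrack, config.meta.fraction_of_max,
                centromere=model.centromeres.get(str(block["chrom"])),
            )
            sites_path = out / "haplotype_sites.tsv"
            track_path = out / "meta_track.tsv"
            peak_path = out / "meta_peak.json"
            io.write_tsv(sites, sites_path, params_hash=phash)
            io.write_tsv(mtrack, track_path, params_hash=phash)
            peak_path.write_text(json.dumps(peak, indent=2, default=str) + "\n")
            record("meta", sites_path, track_path, peak_path)
        else:
            logger.info("no shared haplotype block; meta-analysis skipped")
    except Exception as exc:  # abort with stage context
        done = list(manifest["stages"])
        stage = done[-1] if done else "startup"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    manifest["checksums"] = {p.name: _sha256(p) for p in outputs}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
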