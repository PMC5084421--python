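"""Empirical-outlier candidate regions and gene overlap.

The genome-wide empirical distribution of each axis score serves as its
own null: the strict rule calls fixed 1-Mb bins holding at least
``min_snps`` SNPs above the top-0.1% quantile (adjacent called bins
merged); the relaxed rule merges top-5% SNPs within a 1-Mb gap into
regions for downstream enrichment.  Thresholds are computed per population
and axis over that population's genome-wide scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GeneAnnotation, ScoreTrack

log = logging.getLogger(__name__)


@dataclass
class RegionCall:
    chrom: str
    start_bp: int   # 1-based inclusive
    end_bp: int
    axis: int
    population: str
    n_top_snps: int
    peak_snp: str
    rule: str


def empirical_threshold(scores: ScoreTrack, q: float) -> float:
    """(1 - q) linear-interpolation quantile of the non-missing scores."""
    vals = scores.values[scores.mask]
    if vals.size < 1.0 / q:
        raise ValueError(
            f"only {vals.size} values; need at least {int(np.ceil(1 / q))} "
            f"for q={q}")
    return float(np.quantile(vals, 1.0 - q))


def _outlier_snps(scores: ScoreTrack, q: float) -> np.ndarray:
    thr = empirical_threshold(scores, q)
    return np.flatnonzero(scores.mask & (scores.values > thr))


def call_strict_regions(scores: ScoreTrack, axis: int = 0, population=None,
                        q: float = 0.001, min_snps: int = 25,
                        bin_bp: int = 1_000_000) -> list:
    """Fixed 1-Mb tiling from position 1; bins holding >= ``min_snps``
    top-q SNPs are called and adjacent called bins merged."""
    population = population if population is not None else scores.population
    snp_map = scores.snp_map
    top = _outlier_snps(scores, q)
    out = []
    for chrom, (lo, hi) in snp_map.chrom_blocks().items():
        sel = top[(top >= lo) & (top < hi)]
        if sel.size == 0:
            continue
        bins = (snp_map.pos_bp[sel] - 1) // bin_bp
        uniq, counts = np.unique(bins, return_counts=True)
        called = uniq[counts >= min_snps]
        if called.size == 0:
            continue
        # merge runs of adjacent called bins
        breaks = np.flatnonzero(np.diff(called) > 1)
        runs = np.split(called, breaks + 1)
        for run in runs:
            b0, b1 = int(run[0]), int(run[-1])
            start, end = b0 * bin_bp + 1, (b1 + 1) * bin_bp
            inside = sel[(bins >= b0) & (bins <= b1)]
            peak = inside[np.argmax(scores.values[inside])]
            out.append(RegionCall(chrom, start, end, axis, population,
                                  int(inside.size), str(snp_map.snp_id[peak]),
                                  "strict_0.1pct"))
    return out


def call_relaxed_regions(scores: ScoreTrack, axis: int = 0, population=None,
                         q: float = 0.05, merge_gap_bp: int = 1_000_000) -> list:
    """Merge top-q SNPs within ``merge_gap_bp`` of each other into regions;
    single-SNP regions allowed."""
    population = population if population is not None else scores.population
    snp_map = scores.snp_map
    top = _outlier_snps(scores, q)
    out = []
    for chrom, (lo, hi) in snp_map.chrom_blocks().items():
        sel = top[(top >= lo) & (top < hi)]
        if sel.size == 0:
            continue
        pos = snp_map.pos_bp[sel]
        breaks = np.flatnonzero(np.diff(pos) > merge_gap_bp)
        for grp in np.split(np.arange(sel.size), breaks + 1):
            inside = sel[grp]
            peak = inside[np.argmax(scores.values[inside])]
            out.append(RegionCall(chrom, int(pos[grp[0]]), int(pos[grp[-1]]),
                                  axis, population, int(inside.size),
                                  str(snp_map.snp_id[peak]), "relaxed_5pct"))
    return out


def overlap_genes(regions, ann: GeneAnnotation):
    """Genes intersecting each region by >= 1 bp.

    Returns ``(per_region, universe)``: a list of gene-name lists parallel
    to ``regions`` and the deduplicated union (the enrichment-tool input).
    Raises on chromosome names absent from the annotation."""
    ann_chroms = set(ann.chrom.tolist())
    missing = sorted({r.chrom for r in regions} - ann_chroms)
    if missing:
        raise ValueError(f"chromosomes absent from annotation: {missing}")
    per_region = []
    universe = []
    seen = set()
    for r in regions:
        hits = []
        for g in range(len(ann)):
            if (ann.chrom[g] == r.chrom and ann.start_bp[g] <= r.end_bp
                    and ann.end_bp[g] >= r.start_bp):
                hits.append(str(ann.gene_name[g]))
                if ann.gene_id[g] not in seen:
                    seen.add(ann.gene_id[g])
                    universe.append(str(ann.gene_name[g]))
        per_region.append(hits)
    return per_region, universe


def write_regions_bed(path, regions) -> None:
    """BED output (0-based half-open at the boundary); byte-deterministic."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t"
                     f"axis{r.axis}_{r.population}_{r.rule}\t{r.n_top_snps}\n")


def write_regions_tsv(path, regions) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart_bp\tend_bp\taxis\tpopulation\tn_top_snps\t"
                 "peak_snp\trule\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\t{r.axis}\t"
                     f"{r.population}\t{r.n_top_snps}\t{r.peak_snp}\t{r.rule}\n")
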