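"""Haplotype-length selection scans: EHH/iHH, iHS, nSL, H12 and XP-EHH.

These tests exploit the hitchhiking footprint directly: a recently swept
allele sits on an unusually long stretch of haplotype identity.  iHS and
nSL contrast the ancestral- and derived-allele haplotype classes within a
population; XP-EHH contrasts whole populations; H12 measures pooled
haplotype homozygosity in windows and picks up both hard and soft sweeps.

Scan parameters default to the selscan-documented conventions: EHH
truncation 0.05, maximum inter-SNP gap 200 kb, derived-frequency bounds
0.05/0.95 and 50 frequency bins for the iHS/nSL standardization.  When the
SNP map carries no genetic distances, a constant 1 cM/Mb is assumed with a
logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .io import ABS_IS_EVIDENCE, HIGH_IS_EVIDENCE, HaplotypeSet, ScoreTrack

log = logging.getLogger(__name__)

DEFAULT_TRUNCATION = 0.05
DEFAULT_MAX_GAP_BP = 200_000
DEFAULT_MAF = 0.05
DEFAULT_FREQ_BINS = 50
DEFAULT_MIN_BIN_CORES = 20
DEFAULT_NSL_EXTENSION = 200
DEFAULT_MAX_EXTENSION_SNPS = 2000


@dataclass
class EhhCurve:
    """EHH decay outward from a core SNP for one allele class."""

    core_snp: int
    allele_class: str
    offsets: np.ndarray        # SNP indices, core excluded, outward order
    ehh_values: np.ndarray     # pair homozygosity at each offset
    distances_cm: np.ndarray   # |cM - cM(core)| at each offset
    truncated_by_edge: bool


def _chrom_bounds_of(snp_map, core):
    for lo, hi in snp_map.chrom_blocks().values():
        if lo <= core < hi:
            return lo, hi
    raise IndexError(f"core SNP {core} out of range")


def _cm_or_default(snp_map):
    cm = snp_map.pos_cm
    if np.allclose(cm, 0.0):
        log.warning("SNP map has no genetic distances; assuming 1 cM/Mb")
        return snp_map.pos_bp.astype(np.float64) * 1e-6
    return cm


def _buffers(n, cap):
    return (np.empty(cap + 1, np.int64), np.empty(cap + 1, np.float64),
            np.empty(n, np.int64), np.empty(2 * n + 2, np.int64),
            np.empty(n, np.int64))


def ehh(haps: HaplotypeSet, core_snp: int, allele_class,
        truncation: float = DEFAULT_TRUNCATION,
        max_gap_bp: int = DEFAULT_MAX_GAP_BP, direction: int = +1,
        population=None, cap: int = DEFAULT_MAX_EXTENSION_SNPS):
    """EHH decay curve from ``core_snp`` in one direction.

    ``allele_class`` is ``"ancestral"``/``"derived"`` (or 0/1).  Returns
    ``None`` when fewer than two haplotypes carry the class allele.
    """
    A = haps.alleles if population is None else haps.pop_alleles(population)
    want = 1 if allele_class in ("derived", 1) else 0
    rows = np.flatnonzero(A[:, core_snp] == want).astype(np.int64)
    if rows.size < 2:
        return None
    lo, hi = _chrom_bounds_of(haps.snp_map, core_snp)
    cm = _cm_or_default(haps.snp_map)
    idx_buf, hom_buf, labels, tmp, cnt = _buffers(A.shape[0], cap)
    n, reason = K._ehh_fill(np.ascontiguousarray(A), rows, core_snp, direction,
                            lo, hi, truncation, haps.snp_map.pos_bp,
                            max_gap_bp, cap, idx_buf, hom_buf, labels, tmp, cnt)
    offs = idx_buf[:n].copy()
    return EhhCurve(core_snp, "derived" if want else "ancestral", offs,
                    hom_buf[:n].copy(), np.abs(cm[offs] - cm[core_snp]),
                    truncated_by_edge=(reason == K.STOP_EDGE))


def ihh(curve: EhhCurve, truncation: float = DEFAULT_TRUNCATION) -> float:
    """Trapezoidal integral of one EHH curve over genetic distance, down to
    the truncation value (the core contributes EHH = 1 at distance 0)."""
    if curve is None:
        return np.nan
    area = 0.0
    prev_d, prev_h = 0.0, 1.0
    for d, h in zip(curve.distances_cm, curve.ehh_values):
        if h < truncation:
            if prev_h > truncation and prev_h > h:
                frac = (prev_h - truncation) / (prev_h - h)
                area += 0.5 * (prev_h + truncation) * (d - prev_d) * frac
            return area
        area += 0.5 * (prev_h + h) * (d - prev_d)
        prev_d, prev_h = d, h
    return area


def standardize_in_bins(values: np.ndarray, freqs: np.ndarray,
                        n_bins: int = DEFAULT_FREQ_BINS,
                        min_count: int = DEFAULT_MIN_BIN_CORES) -> np.ndarray:
    """Z-score ``values`` within equal-width frequency bins.

    Bins with fewer than ``min_count`` cores are merged with their left
    neighbour (the first bin merges right), logged.  NaN values pass
    through."""
    out = np.full_like(values, np.nan, dtype=np.float64)
    ok = ~np.isnan(values)
    if not np.any(ok):
        return out
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_of = np.clip(np.digitize(freqs[ok], edges) - 1, 0, n_bins - 1)
    # merge sparse bins left-to-right
    remap = np.arange(n_bins)
    counts = np.bincount(bin_of, minlength=n_bins)
    merged = 0
    cur = 0
    groups = []
    acc = 0
    start = 0
    for b in range(n_bins):
        acc += counts[b]
        if acc >= min_count:
            groups.append((start, b))
            start = b + 1
            acc = 0
    if start < n_bins or acc > 0:
        if groups:
            s, _ = groups.pop()
            groups.append((s, n_bins - 1))
        else:
            groups.append((0, n_bins - 1))
    for g, (s, e) in enumerate(groups):
        remap[s:e + 1] = g
        if e > s:
            merged += e - s
    if merged:
        log.info("merged %d sparse frequency bins", merged)
    grp = remap[bin_of]
    v = values[ok]
    z = np.empty_like(v)
    for g in np.unique(grp):
        sel = grp == g
        mu = v[sel].mean()
        sd = v[sel].std()
        z[sel] = 0.0 if sd == 0 else (v[sel] - mu) / sd
    out[ok] = z
    return out


def _blocks_arrays(snp_map):
    blocks = list(snp_map.chrom_blocks().values())
    return (np.asarray([b[0] for b in blocks], dtype=np.int64),
            np.asarray([b[1] for b in blocks], dtype=np.int64))


def ihs_track(haps: HaplotypeSet, population, freq_bins: int = DEFAULT_FREQ_BINS,
              truncation: float = DEFAULT_TRUNCATION,
              max_gap_bp: int = DEFAULT_MAX_GAP_BP, maf: float = DEFAULT_MAF,
              cap: int = DEFAULT_MAX_EXTENSION_SNPS,
              min_bin_cores: int = DEFAULT_MIN_BIN_CORES,
              absolute: bool = True) -> ScoreTrack:
    """|iHS| per SNP: ln(iHH_anc/iHH_der), z-scored within derived-frequency
    bins genome-wide, absolute-valued (``absolute=False`` keeps the sign)."""
    A = np.ascontiguousarray(haps.pop_alleles(population))
    starts, stops = _blocks_arrays(haps.snp_map)
    cm = _cm_or_default(haps.snp_map)
    raw, freq = K.ihs_unstandardized(
        A, haps.snp_map.pos_bp, cm, haps.snp_map.ancestral_known,
        starts, stops, maf, truncation, max_gap_bp, cap)
    z = standardize_in_bins(raw, freq, freq_bins, min_bin_cores)
    vals = np.abs(z) if absolute else z
    return ScoreTrack("IHS", population, vals,
                      HIGH_IS_EVIDENCE if absolute else ABS_IS_EVIDENCE,
                      haps.snp_map)


def nsl_track(haps: HaplotypeSet, population,
              max_extension: int = DEFAULT_NSL_EXTENSION,
              freq_bins: int = DEFAULT_FREQ_BINS, maf: float = DEFAULT_MAF,
              min_bin_cores: int = DEFAULT_MIN_BIN_CORES,
              absolute: bool = True) -> ScoreTrack:
    """|nSL| per SNP: like iHS but with identity run lengths counted in
    segregating sites (no genetic map needed), capped at ``max_extension``
    sites per direction."""
    A = np.ascontiguousarray(haps.pop_alleles(population))
    n = A.shape[0]
    c = A.sum(axis=0)
    segidx = np.flatnonzero((c > 0) & (c < n))
    out = np.full(haps.n_snp, np.nan)
    if segidx.size:
        Aseg = np.ascontiguousarray(A[:, segidx])
        # chromosome blocks in segregating-site coordinates
        starts, stops = _blocks_arrays(haps.snp_map)
        s2 = np.searchsorted(segidx, starts)
        e2 = np.searchsorted(segidx, stops)
        known = haps.snp_map.ancestral_known[segidx]
        raw, freq = K.nsl_unstandardized(Aseg, known, s2.astype(np.int64),
                                         e2.astype(np.int64), maf, max_extension)
        z = standardize_in_bins(raw, freq, freq_bins, min_bin_cores)
        out[segidx] = np.abs(z) if absolute else z
    return ScoreTrack("NSL", population, out,
                      HIGH_IS_EVIDENCE if absolute else ABS_IS_EVIDENCE,
                      haps.snp_map)


def h12_track(haps: HaplotypeSet, population, window: int = 100,
              step: int = 1) -> ScoreTrack:
    """Windowed H12 assigned to each window's central SNP."""
    if step != 1:
        raise NotImplementedError("per-SNP tracks require step=1")
    A = np.ascontiguousarray(haps.pop_alleles(population))
    out = np.full(haps.n_snp, np.nan)
    half = window // 2
    for chrom, (lo, hi) in haps.snp_map.chrom_blocks().items():
        L = hi - lo
        if L < window:
            log.warning("chromosome %s shorter than window; left missing", chrom)
            continue
        vals = K.h12_windows(A[:, lo:hi], window)
        centers = np.arange(half, L - half)
        out[lo + centers] = vals[centers - half]
    return ScoreTrack("H12", population, out, HIGH_IS_EVIDENCE, haps.snp_map)


def xpehh_pair(haps: HaplotypeSet, pop_a, pop_b,
               truncation: float = DEFAULT_TRUNCATION,
               max_gap_bp: int = DEFAULT_MAX_GAP_BP,
               cap: int = DEFAULT_MAX_EXTENSION_SNPS,
               standardize: bool = True) -> np.ndarray:
    """XP-EHH values for the ordered pair (A, B): ln(IHH_A / IHH_B) per SNP,
    optionally z-scored genome-wide.  Positive = longer haplotypes in A."""
    rows_a = haps.pop_rows(pop_a).astype(np.int64)
    rows_b = haps.pop_rows(pop_b).astype(np.int64)
    starts, stops = _blocks_arrays(haps.snp_map)
    cm = _cm_or_default(haps.snp_map)
    raw = K.xpehh_unstandardized(np.ascontiguousarray(haps.alleles),
                                 rows_a, rows_b, haps.snp_map.pos_bp, cm,
                                 starts, stops, truncation, max_gap_bp, cap)
    if not standardize:
        return raw
    ok = ~np.isnan(raw)
    if ok.sum() > 1 and raw[ok].std() > 0:
        raw[ok] = (raw[ok] - raw[ok].mean()) / raw[ok].std()
    return raw


def xpehh_tracks(haps: HaplotypeSet, populations=None,
                 truncation: float = DEFAULT_TRUNCATION,
                 max_gap_bp: int = DEFAULT_MAX_GAP_BP,
                 cap: int = DEFAULT_MAX_EXTENSION_SNPS) -> dict:
    """One averaged XP-EHH track per population.

    Every unordered pair is scanned once; each population's track is the
    mean of its genome-wide-standardized pairwise tracks with the focal
    population in the numerator.  Populations with < 4 haplotypes are
    excluded (logged).  Orientation is ``abs_is_evidence``: extreme values
    of either sign flag a sweep on one side of the comparison.
    """
    pops = list(populations) if populations is not None else haps.populations
    kept = []
    for p in pops:
        if haps.pop_rows(p).size >= 4:
            kept.append(p)
        else:
            log.warning("population %s excluded from XP-EHH (<4 haplotypes)", p)
    pops = kept
    if len(pops) < 2:
        raise ValueError("XP-EHH needs at least two populations")
    acc = {p: [] for p in pops}
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            z = xpehh_pair(haps, pops[i], pops[j], truncation, max_gap_bp, cap)
            acc[pops[i]].append(z)
            acc[pops[j]].append(-z)
    out = {}
    for p in pops:
        stack = np.vstack(acc[p])
        ok = ~np.isnan(stack)
        s = np.where(ok, stack, 0.0).sum(axis=0)
        cnt = ok.sum(axis=0)
        mean = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
        out[p] = ScoreTrack("XPEHH", p, mean, ABS_IS_EVIDENCE, haps.snp_map)
    return out
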