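"""Population-differentiation scans: windowed pairwise FST and VarLD.

FST follows Wright's variance decomposition on haplotype frequencies,
(H_T - H_S)/H_T with H = 2p(1-p): H_S is the unweighted mean within-pair
expected heterozygosity and H_T uses the count-pooled frequency.  Per-SNP
pair values are averaged over sliding 100-SNP windows, assigned to the
central SNP, and each population's track is the mean over its pairs.

VarLD compares local linkage-disequilibrium structure between two
populations: per window, the signed Pearson correlation matrices of the
SNP columns are eigendecomposed and the raw score is the L1 distance
between the rank-matched descending eigenvalue spectra.  Raw scores are
z-scored genome-wide per pair (the VarLD program's documented practice)
and averaged per population like FST.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import HIGH_IS_EVIDENCE, HaplotypeSet, ScoreTrack
from .sfs import window_centers

log = logging.getLogger(__name__)


def fst_snp(count_a, n_a, count_b, n_b, convention: str = "wright"):
    """FST between two populations at one SNP (or arrays of SNPs) from
    derived-allele counts and haplotype totals.

    ``convention="wright"`` gives (H_T - H_S)/H_T; ``"printed"`` gives the
    inverted orientation (H_S - H_T)/H_T for exactness experiments.
    Monomorphic pooled SNPs yield NaN.  Small negative values are possible.
    """
    count_a = np.asarray(count_a, dtype=np.float64)
    count_b = np.asarray(count_b, dtype=np.float64)
    if n_a <= 0 or n_b <= 0:
        raise ValueError("zero haplotypes in a population")
    pa = count_a / n_a
    pb = count_b / n_b
    pbar = (count_a + count_b) / (n_a + n_b)
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = (2.0 * pa * (1.0 - pa) + 2.0 * pb * (1.0 - pb)) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / ht, np.nan)
    if convention == "printed":
        fst = -fst
    elif convention != "wright":
        raise ValueError(f"unknown FST convention {convention!r}")
    return fst if fst.ndim else float(fst)


def _window_mean(values: np.ndarray, window: int, lo: int, hi: int,
                 out: np.ndarray) -> None:
    """Sliding-window mean (NaN skipped) assigned to central SNPs, within
    one chromosome block [lo, hi)."""
    L = hi - lo
    if L < window:
        return
    x = values[lo:hi]
    ok = ~np.isnan(x)
    xf = np.where(ok, x, 0.0)
    cs = np.concatenate(([0.0], np.cumsum(xf)))
    cn = np.concatenate(([0.0], np.cumsum(ok.astype(np.float64))))
    sums = cs[window:] - cs[:-window]
    cnts = cn[window:] - cn[:-window]
    centers = np.asarray(window_centers(L, window))
    starts = centers - window // 2
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(cnts[starts] > 0, sums[starts] / cnts[starts], np.nan)
    out[lo + centers] = means


def fst_pair_values(haps: HaplotypeSet, pop_a, pop_b,
                    convention: str = "wright") -> np.ndarray:
    """Per-SNP FST for one unordered population pair."""
    A = haps.pop_alleles(pop_a)
    B = haps.pop_alleles(pop_b)
    return fst_snp(A.sum(axis=0), A.shape[0], B.sum(axis=0), B.shape[0],
                   convention)


def fst_tracks(haps: HaplotypeSet, populations=None, window: int = 100,
               step: int = 1, convention: str = "wright") -> dict:
    """Window-averaged FST, one track per population (mean over its pairs)."""
    if step != 1:
        raise NotImplementedError("per-SNP tracks require step=1")
    pops = list(populations) if populations is not None else haps.populations
    if len(pops) < 2:
        raise ValueError("FST needs at least two populations")
    blocks = haps.snp_map.chrom_blocks()
    per_pop = {p: [] for p in pops}
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            vals = fst_pair_values(haps, pops[i], pops[j], convention)
            win = np.full(haps.n_snp, np.nan)
            for lo, hi in blocks.values():
                _window_mean(vals, window, lo, hi, win)
            per_pop[pops[i]].append(win)
            per_pop[pops[j]].append(win)
    out = {}
    for p in pops:
        mean = _nanmean_stack(per_pop[p])
        out[p] = ScoreTrack("FST", p, mean, HIGH_IS_EVIDENCE, haps.snp_map)
    return out


def _window_corr(X: np.ndarray) -> np.ndarray:
    """Signed Pearson correlation matrix of SNP columns over haplotypes.

    Zero-variance SNPs get correlation 0 to all partners and 1 on the
    diagonal, preserving the trace."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, Xc / sd, 0.0)
    C = Z.T @ Z / n
    np.fill_diagonal(C, 1.0)
    return C


def varld_window_raw(Xa: np.ndarray, Xb: np.ndarray) -> float:
    """Raw VarLD score of one window: L1 distance between the descending
    eigenvalue spectra of the two within-window SNP-correlation matrices."""
    la = np.linalg.eigvalsh(_window_corr(Xa))[::-1]
    lb = np.linalg.eigvalsh(_window_corr(Xb))[::-1]
    return float(np.abs(la - lb).sum())


def varld_pair_raw(haps: HaplotypeSet, pop_a, pop_b, window: int = 100,
                   chunk: int = 256) -> np.ndarray:
    """Raw (unstandardized) VarLD scores per central SNP for one pair."""
    if window < 2:
        raise ValueError("VarLD window must span at least 2 SNPs")
    A = np.asarray(haps.pop_alleles(pop_a), dtype=np.float64)
    B = np.asarray(haps.pop_alleles(pop_b), dtype=np.float64)
    out = np.full(haps.n_snp, np.nan)
    half = window // 2
    for chrom, (lo, hi) in haps.snp_map.chrom_blocks().items():
        L = hi - lo
        if L < window:
            log.warning("chromosome %s shorter than VarLD window; left missing",
                        chrom)
            continue
        centers = np.asarray(window_centers(L, window))
        starts = centers - half
        for c0 in range(0, len(starts), chunk):
            sel = starts[c0:c0 + chunk]
            stack_a = np.empty((len(sel), window, window))
            stack_b = np.empty((len(sel), window, window))
            for k, s in enumerate(sel):
                stack_a[k] = _window_corr(A[:, lo + s:lo + s + window])
                stack_b[k] = _window_corr(B[:, lo + s:lo + s + window])
            la = np.sort(np.linalg.eigvalsh(stack_a), axis=1)[:, ::-1]
            lb = np.sort(np.linalg.eigvalsh(stack_b), axis=1)[:, ::-1]
            out[lo + centers[c0:c0 + chunk]] = np.abs(la - lb).sum(axis=1)
    return out


def varld_tracks(haps: HaplotypeSet, populations=None, window: int = 100,
                 step: int = 1) -> dict:
    """Genome-standardized VarLD, one track per population (mean over pairs)."""
    if step != 1:
        raise NotImplementedError("per-SNP tracks require step=1")
    pops = list(populations) if populations is not None else haps.populations
    if len(pops) < 2:
        raise ValueError("VarLD needs at least two populations")
    per_pop = {p: [] for p in pops}
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            raw = varld_pair_raw(haps, pops[i], pops[j], window)
            ok = ~np.isnan(raw)
            z = np.full_like(raw, np.nan)
            if ok.sum() > 1 and raw[ok].std() > 0:
                z[ok] = (raw[ok] - raw[ok].mean()) / raw[ok].std()
            elif ok.any():
                z[ok] = 0.0
            per_pop[pops[i]].append(z)
            per_pop[pops[j]].append(z)
    out = {}
    for p in pops:
        mean = _nanmean_stack(per_pop[p])
        out[p] = ScoreTrack("VarLD", p, mean, HIGH_IS_EVIDENCE, haps.snp_map)
    return out


def _nanmean_stack(rows) -> np.ndarray:
    """Column-wise mean ignoring NaN, without the all-NaN warning."""
    stack = np.vstack(rows)
    ok = ~np.isnan(stack)
    cnt = ok.sum(axis=0)
    s = np.where(ok, stack, 0.0).sum(axis=0)
    return np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
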