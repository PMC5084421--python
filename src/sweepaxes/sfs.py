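"""Site-frequency-spectrum scan statistics over sliding SNP windows.

Three classic neutrality tests are computed per population from the window
SFS: Tajima's D (pairwise diversity vs. Watterson's estimator, with the
full 1989 standardization), Fay & Wu's H (pairwise diversity vs. the
homozygosity-weighted estimator that up-weights high-frequency derived
alleles; reported unstandardized), and Fu & Li's D* (segregating sites vs.
singletons, within-sample variant with the published 1993 normalizing
constants).  Low values of all three are the sweep-like tail, so the
emitted tracks are oriented ``low_is_evidence``.

Window θ estimators are per-window (not per-site); only genome-wide ranks
are consumed downstream, so the scale is immaterial as long as window size
is fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io import LOW_IS_EVIDENCE, HaplotypeSet, ScoreTrack

log = logging.getLogger(__name__)


@dataclass
class SfsWindowStats:
    """Window summaries feeding the three SFS tests.

    ``derived_counts`` holds per-site derived counts (1..n-1) at sites with a
    known ancestral state only; ``eta_s`` counts any-allele singletons (an
    allele carried by exactly one haplotype), as Fu & Li's D* requires.
    """

    n_hap: int
    S: int
    theta_pi: float
    theta_w: float
    theta_h: float
    eta_s: int
    derived_counts: np.ndarray


def window_thetas(window: np.ndarray, ancestral_known=None) -> SfsWindowStats:
    """Compute the window SFS summaries for one population's haplotypes.

    ``window`` is an (n_hap, n_snp) 0/1 matrix; ``ancestral_known`` marks
    columns whose 0/1 coding is ancestral/derived (default: all).
    θπ, S and the singleton count are polarity-free; θH and the derived
    counts use polarized columns only.
    """
    window = np.asarray(window)
    n, m = window.shape
    if n < 2:
        raise ValueError("at least 2 haplotypes required")
    if ancestral_known is None:
        ancestral_known = np.ones(m, dtype=bool)
    c = window.sum(axis=0).astype(np.int64)
    seg = (c > 0) & (c < n)
    S = int(seg.sum())
    denom = n * (n - 1)
    theta_pi = float(np.sum(2.0 * c[seg] * (n - c[seg])) / denom)
    a1 = _a1(n)
    theta_w = S / a1
    pol = seg & np.asarray(ancestral_known, dtype=bool)
    theta_h = float(np.sum(2.0 * c[pol] ** 2) / denom)
    eta_s = int(np.sum((c == 1) | (c == n - 1)))
    return SfsWindowStats(n, S, theta_pi, theta_w, theta_h, eta_s,
                          derived_counts=c[pol].copy())


@lru_cache(maxsize=None)
def _a1(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


@lru_cache(maxsize=None)
def _a2(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n) ** 2))


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> tuple:
    """The 1989 constants (a1, a2, b1, b2, c1, c2, e1, e2) for sample size n."""
    a1, a2 = _a1(n), _a2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def tajima_d(stats: SfsWindowStats) -> float:
    """Standardized θπ − θW; NaN when the window has no segregating sites."""
    if stats.S == 0:
        return np.nan
    *_, e1, e2 = tajima_constants(stats.n_hap)
    var = e1 * stats.S + e2 * stats.S * (stats.S - 1)
    num = stats.theta_pi - stats.theta_w
    if var <= 0:
        # n = 2 and n = 3 degenerate: the numerator is identically 0 there
        return 0.0 if abs(num) < 1e-9 else np.nan
    return num / np.sqrt(var)


def fay_wu_h(stats: SfsWindowStats) -> float:
    """Unstandardized H = θπ − θH over polarizable sites.

    Both terms are restricted to sites with a known ancestral state so the
    difference is not biased by unpolarizable columns; NaN when no
    polarizable segregating site is present.
    """
    if stats.derived_counts.size == 0:
        return np.nan
    n = stats.n_hap
    c = stats.derived_counts
    return float(np.sum(2.0 * c * (n - 2.0 * c)) / (n * (n - 1)))


@lru_cache(maxsize=None)
def fu_li_dstar_constants(n: int) -> tuple:
    """(u_D*, v_D*) normalizing constants of Fu & Li's within-sample D*."""
    a = _a1(n)
    b = _a2(n)
    if n == 2:
        cn = 1.0
    else:
        cn = 2.0 * (n * a - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    an1 = a + 1.0 / n  # a_{n+1}
    dn = cn + (n - 2.0) / (n - 1) ** 2 + 2.0 / (n - 1) * (
        1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n) if n > 2 else cn
    vd = ((n / (n - 1.0)) ** 2 * b + a ** 2 * dn
          - 2.0 * n * a * (a + 1) / (n - 1.0) ** 2) / (a ** 2 + b)
    ud = (n / (n - 1.0)) * (a - n / (n - 1.0)) - vd
    return ud, vd


def fu_li(stats: SfsWindowStats) -> float:
    """Fu & Li's D*: excess of any-allele singletons relative to S."""
    if stats.S == 0:
        return np.nan
    n = stats.n_hap
    ud, vd = fu_li_dstar_constants(n)
    var = ud * stats.S + vd * stats.S ** 2
    num = n / (n - 1.0) * stats.S - _a1(n) * stats.eta_s
    if var <= 0:
        # the published constants vanish for n < 4
        return 0.0 if abs(num) < 1e-9 else np.nan
    return num / np.sqrt(var)


def window_centers(length: int, window: int):
    """Central-SNP indices of the sliding windows on a chromosome of
    ``length`` SNPs: the first and last ``window//2`` SNPs get no value;
    center ``c`` summarizes SNPs ``[c - window//2, c - window//2 + window)``."""
    half = window // 2
    return range(half, length - half)


def sliding_sfs_tracks(haps: HaplotypeSet, population, window: int = 100,
                       step: int = 1) -> dict:
    """Per-SNP tracks of Tajima's D, Fay & Wu's H and Fu & Li's D* for one
    population, each window's value assigned to its central SNP.

    Returns ``{"TajimaD": ScoreTrack, "FayWuH": ..., "FuLiD": ...}``; all
    three oriented ``low_is_evidence``.  Chromosomes shorter than the window
    stay missing (warning logged).
    """
    if step != 1:
        raise NotImplementedError("per-SNP tracks require step=1")
    A = haps.pop_alleles(population)
    n = A.shape[0]
    known = haps.snp_map.ancestral_known
    out = {k: np.full(haps.n_snp, np.nan) for k in ("TajimaD", "FayWuH", "FuLiD")}
    a1 = _a1(n)
    *_, e1, e2 = tajima_constants(n)
    ud, vd = fu_li_dstar_constants(n)
    denom = n * (n - 1)
    for chrom, (lo, hi) in haps.snp_map.chrom_blocks().items():
        L = hi - lo
        if L < window:
            log.warning("chromosome %s has %d SNPs (< window %d); left missing",
                        chrom, L, window)
            continue
        c = A[:, lo:hi].sum(axis=0).astype(np.float64)
        seg = ((c > 0) & (c < n)).astype(np.float64)
        pi_site = 2.0 * c * (n - c) / denom * seg
        kchr = known[lo:hi]
        h_site = 2.0 * c * (n - 2.0 * c) / denom * seg * kchr  # πsite − Hsite
        single = ((c == 1) | (c == n - 1)).astype(np.float64)
        polseg = seg * kchr

        S = _winsum(seg, window)
        pi = _winsum(pi_site, window)
        fw = _winsum(h_site, window)
        eta = _winsum(single, window)
        npol = _winsum(polseg, window)

        with np.errstate(invalid="ignore", divide="ignore"):
            var_t = e1 * S + e2 * S * (S - 1)
            num_t = pi - S / a1
            d_taj = np.where(var_t > 0, num_t / np.sqrt(var_t),
                             np.where((S > 0) & (np.abs(num_t) < 1e-9),
                                      0.0, np.nan))
            var_f = ud * S + vd * S ** 2
            num_f = n / (n - 1.0) * S - a1 * eta
            d_fl = np.where(var_f > 0, num_f / np.sqrt(var_f),
                            np.where((S > 0) & (np.abs(num_f) < 1e-9),
                                     0.0, np.nan))
            h_fw = np.where(npol > 0, fw, np.nan)
        centers = np.asarray(window_centers(L, window))
        starts = centers - window // 2
        out["TajimaD"][lo + centers] = d_taj[starts]
        out["FayWuH"][lo + centers] = h_fw[starts]
        out["FuLiD"][lo + centers] = d_fl[starts]
    return {name: ScoreTrack(name, population, vals, LOW_IS_EVIDENCE, haps.snp_map)
            for name, vals in out.items()}


def _winsum(x: np.ndarray, w: int) -> np.ndarray:
    """Sliding-window sums of length w (result has len(x) - w + 1 entries)."""
    cs = np.concatenate(([0.0], np.cumsum(x)))
    return cs[w:] - cs[:-w]
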