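"""Summarizing many selection scans into three canonical axes.

Genome scans disagree: SFS, haplotype-length and differentiation tests see
sweeps of different ages.  This module condenses the per-SNP evidence of
all tests into a small number of interpretable axes: each track is mapped
onto a common "evidence" scale by a signed log transform, the per-SNP
score matrix (rows = SNP x population, columns = tests) is z-scored and
correlated, and a principal-axis factor analysis with varimax rotation
yields per-SNP axis scores whose loadings typically separate the three
test families.

The transform is ``sign(v) * ln(1 + |v|)`` of the evidence value ``v``
(the raw score, its negative, or its absolute value depending on the
track's declared orientation).  It is strictly increasing in evidence and
defined for the negative values SFS tests produce; a plain ``ln`` is
available for strictly positive tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .io import (ABS_IS_EVIDENCE, HIGH_IS_EVIDENCE, LOW_IS_EVIDENCE,
                 ScoreTrack)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# transform and score matrix

def evidence_values(track: ScoreTrack) -> np.ndarray:
    """Map raw scores onto the common 'more = more evidence' direction."""
    if track.orientation == HIGH_IS_EVIDENCE:
        return track.values.copy()
    if track.orientation == LOW_IS_EVIDENCE:
        return -track.values
    if track.orientation == ABS_IS_EVIDENCE:
        return np.abs(track.values)
    raise ValueError(f"undeclared orientation {track.orientation!r}")


def transform_track(track: ScoreTrack, method: str = "log1p") -> np.ndarray:
    """Signed log transform of a track's evidence values.

    ``method="log1p"`` (default) is sign(v)*ln(1+|v|); ``method="log"``
    is plain ln and requires a strictly positive track.
    """
    v = evidence_values(track)
    if method == "log1p":
        return np.sign(v) * np.log1p(np.abs(v))
    if method == "log":
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.log(v)
        if np.any(v[~np.isnan(v)] <= 0):
            raise ValueError("plain-ln transform needs strictly positive values")
        return out
    raise ValueError(f"unknown transform {method!r}")


@dataclass
class ScoreMatrix:
    """Transformed, column-standardized scores: rows are (population, SNP)
    pairs stacked population-major; columns are tests."""

    data: np.ndarray            # rows x tests, NaN = missing
    test_names: list
    row_population: np.ndarray  # population label per row
    row_snp: np.ndarray         # SNP index per row
    col_mean: np.ndarray        # transform-scale means used for z-scoring
    col_sd: np.ndarray

    @property
    def complete(self) -> np.ndarray:
        return ~np.isnan(self.data).any(axis=1)


def build_score_matrix(tracks, transform: str = "log1p") -> ScoreMatrix:
    """Stack tracks into a (population x SNP) by test matrix.

    ``tracks`` is an iterable of ScoreTrack covering every (test,
    population) combination on one shared SnpMap; a missing combination is
    an error.  Columns are z-scored (complete rows only) after the log
    transform."""
    by_key = {}
    tests, pops = [], []
    snp_map = None
    for t in tracks:
        if snp_map is None:
            snp_map = t.snp_map
        elif len(t.snp_map) != len(snp_map):
            raise ValueError("tracks aligned to different SNP maps")
        by_key[(t.test_name, t.population)] = t
        if t.test_name not in tests:
            tests.append(t.test_name)
        if t.population not in pops:
            pops.append(t.population)
    gaps = [(te, po) for te in tests for po in pops if (te, po) not in by_key]
    if gaps:
        raise ValueError(f"missing (test, population) combinations: {gaps}")
    m = len(snp_map)
    data = np.empty((len(pops) * m, len(tests)))
    row_pop = np.empty(len(pops) * m, dtype=object)
    row_snp = np.tile(np.arange(m), len(pops))
    for pi, po in enumerate(pops):
        row_pop[pi * m:(pi + 1) * m] = po
        for ti, te in enumerate(tests):
            data[pi * m:(pi + 1) * m, ti] = transform_track(by_key[(te, po)],
                                                            transform)
    complete = ~np.isnan(data).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("%d of %d rows incomplete; excluded from correlation/FA",
                 n_dropped, data.shape[0])
    sub = data[complete]
    if sub.shape[0] < 3:
        raise ValueError("fewer than 3 complete rows")
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0)
    if np.any(sd == 0):
        bad = [tests[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant column(s): {bad}")
    data = (data - mean) / sd
    return ScoreMatrix(data, tests, row_pop, row_snp, mean, sd)


def correlation_matrix(m: ScoreMatrix):
    """Pearson correlations between tests over complete rows, plus the
    average-linkage leaf order on distance 1 - r (the heatmap ordering)."""
    sub = m.data[m.complete]
    if sub.shape[0] < 3:
        raise ValueError("fewer than 3 complete rows")
    sd = sub.std(axis=0)
    if np.any(sd == 0):
        bad = [m.test_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant column(s): {bad}")
    corr = np.corrcoef(sub, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    order = leaves_list(average(squareform(dist, checks=False)))
    return corr, order


# ---------------------------------------------------------------------------
# factor analysis

@dataclass
class FactorModel:
    """Three-axis varimax factor model of the test battery.

    ``loadings`` are the correlations between tests and rotated axes;
    ``weights`` the regression score coefficients; ``communalities`` the
    per-test variance captured by the retained axes."""

    test_names: list
    loadings: np.ndarray      # tests x k
    weights: np.ndarray       # tests x k
    rotation: np.ndarray      # k x k orthogonal
    explained: np.ndarray     # per-axis share of total variance
    communalities: np.ndarray


def communalities(loadings: np.ndarray) -> np.ndarray:
    """Per-variable sum of squared loadings across the retained axes."""
    return np.sum(np.asarray(loadings, dtype=np.float64) ** 2, axis=1)


def varimax_rotation(loadings: np.ndarray, kaiser: bool = True,
                     tol: float = 1e-10, max_sweeps: int = 1000):
    """Classical pairwise varimax: planar rotations of axis pairs that
    maximize the variance of squared loadings, with Kaiser row
    normalization, swept to convergence of the criterion.

    Returns (rotated loadings, k x k rotation matrix)."""
    L = np.asarray(loadings, dtype=np.float64).copy()
    p, k = L.shape
    h = np.sqrt(np.sum(L ** 2, axis=1))
    if kaiser:
        h_safe = np.where(h > 0, h, 1.0)
        L = L / h_safe[:, None]
    R = np.eye(k)

    def criterion(M):
        sq = M ** 2
        return float(np.sum(sq ** 2) - np.sum(sq.sum(axis=0) ** 2) / p)

    last = criterion(L)
    for _ in range(max_sweeps):
        max_phi = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = L[:, i], L[:, j]
                u = x ** 2 - y ** 2
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                C = np.sum(u ** 2 - v ** 2)
                D = np.sum(2.0 * u * v)
                num = D - 2.0 * A * B / p
                den = C - (A ** 2 - B ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                max_phi = max(max_phi, abs(phi))
                if abs(phi) < 1e-15:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                L[:, [i, j]] = L[:, [i, j]] @ rot
                R[:, [i, j]] = R[:, [i, j]] @ rot
        cur = criterion(L)
        # both the criterion and the remaining rotation angles must be tiny
        if cur - last < tol * max(1.0, abs(last)) and max_phi < 1e-9:
            break
        last = cur
    if kaiser:
        L = L * np.where(h > 0, h, 1.0)[:, None]
    return L, R


def factor_analysis(corr: np.ndarray, n_factors: int = 3,
                    test_names=None, kaiser: bool = True,
                    tol: float = 1e-10, max_sweeps: int = 1000) -> FactorModel:
    """Principal-axis extraction of the top ``n_factors`` eigenpairs of the
    correlation matrix, varimax-rotated.

    Unrotated loading column j is eigvec_j * sqrt(eigval_j).  Axes are
    ordered by explained variance and sign-fixed so each axis's largest
    |loading| is positive.  Score weights are corr^-1 @ loadings (the
    regression method)."""
    corr = np.asarray(corr, dtype=np.float64)
    p = corr.shape[0]
    if n_factors >= p:
        raise ValueError("n_factors must be smaller than the number of tests")
    vals, vecs = np.linalg.eigh((corr + corr.T) / 2)
    if vals[0] < -1e-8:
        raise ValueError(f"correlation matrix not PSD (min eigenvalue {vals[0]:.3g})")
    vals = np.clip(vals, 0.0, None)
    top = np.argsort(vals)[::-1][:n_factors]
    L0 = vecs[:, top] * np.sqrt(vals[top])
    L, R = varimax_rotation(L0, kaiser=kaiser, tol=tol, max_sweeps=max_sweeps)
    explained = np.sum(L ** 2, axis=0) / p
    order = np.argsort(explained)[::-1]
    L = L[:, order]
    R = R[:, order]
    explained = explained[order]
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(n_factors)])
    signs[signs == 0] = 1.0
    L = L * signs
    R = R * signs
    weights = np.linalg.solve(corr, L)
    names = list(test_names) if test_names is not None else \
        [f"test{i}" for i in range(p)]
    return FactorModel(names, L, weights, R, explained, communalities(L))


def factor_scores(m: ScoreMatrix, model: FactorModel) -> np.ndarray:
    """Per-row axis scores (rows x k), rescaled to unit variance over
    complete rows; incomplete rows yield NaN."""
    if list(m.test_names) != list(model.test_names):
        raise ValueError("score matrix and factor model cover different tests")
    raw = m.data @ model.weights
    complete = m.complete
    raw[~complete] = np.nan
    sd = raw[complete].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    mu = raw[complete].mean(axis=0)
    return (raw - mu) / sd


def axis_score_tracks(m: ScoreMatrix, model: FactorModel, snp_map) -> dict:
    """Axis scores reshaped into ScoreTracks: {(axis_index, population):
    ScoreTrack} with axis_index 1-based."""
    scores = factor_scores(m, model)
    out = {}
    for po in _unique_keep_order(m.row_population):
        rows = m.row_population == po
        snps = m.row_snp[rows]
        for a in range(scores.shape[1]):
            vals = np.full(len(snp_map), np.nan)
            vals[snps] = scores[rows, a]
            out[(a + 1, po)] = ScoreTrack(f"axis{a + 1}", po, vals,
                                          ABS_IS_EVIDENCE, snp_map)
    return out


def axis_population_correlations(axis_tracks: dict):
    """Per-axis Pearson correlation of SNP scores between population pairs.

    Returns ``(corrs, averages)`` where ``corrs[axis]`` is a (pops, pops)
    matrix (shared non-missing SNPs per pair) and ``averages[axis]`` the
    mean over distinct pairs."""
    axes = sorted({a for a, _ in axis_tracks})
    pops = _unique_keep_order([p for _, p in axis_tracks])
    corrs, averages = {}, {}
    for a in axes:
        mat = np.eye(len(pops))
        vals = []
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                ta = axis_tracks[(a, pops[i])].values
                tb = axis_tracks[(a, pops[j])].values
                ok = ~np.isnan(ta) & ~np.isnan(tb)
                if ok.sum() < 100:
                    log.warning("axis %d: only %d shared SNPs between %s and %s",
                                a, int(ok.sum()), pops[i], pops[j])
                r = np.corrcoef(ta[ok], tb[ok])[0, 1] if ok.sum() > 1 else np.nan
                mat[i, j] = mat[j, i] = r
                vals.append(r)
        corrs[a] = mat
        averages[a] = float(np.nanmean(vals)) if vals else np.nan
    return corrs, averages


def label_axes(model: FactorModel, families: dict) -> dict:
    """Post-hoc axis labels: each axis gets the family whose tests load
    highest on it (mean |loading|).  ``families`` maps family name to a
    list of test names.  A report annotation, not an algorithmic step."""
    out = {}
    for a in range(model.loadings.shape[1]):
        best, best_val = None, -np.inf
        for fam, tests in families.items():
            idx = [model.test_names.index(t) for t in tests
                   if t in model.test_names]
            if not idx:
                continue
            v = float(np.mean(np.abs(model.loadings[idx, a])))
            if v > best_val:
                best, best_val = fam, v
        out[a + 1] = best
    return out


def _unique_keep_order(seq):
    seen, out = set(), []
    for x in seq:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


# ---------------------------------------------------------------------------
# sklearn-style front end

class FactorSummarizer:
    """Sklearn-compatible transformer wrapping the factor summarization.

    ``fit`` takes the transformed score matrix (rows x tests, NaN allowed;
    complete rows used), ``transform`` returns the per-row axis scores.
    Fitted attributes: ``correlation_``, ``loadings_``, ``weights_``,
    ``rotation_``, ``explained_variance_ratio_``, ``communalities_``,
    ``means_``, ``scales_``.
    """

    def __init__(self, n_factors: int = 3, kaiser: bool = True,
                 tol: float = 1e-10, max_sweeps: int = 1000):
        self.n_factors = n_factors
        self.kaiser = kaiser
        self.tol = tol
        self.max_sweeps = max_sweeps

    def get_params(self, deep: bool = True) -> dict:
        return {"n_factors": self.n_factors, "kaiser": self.kaiser,
                "tol": self.tol, "max_sweeps": self.max_sweeps}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        complete = ~np.isnan(X).any(axis=1)
        sub = X[complete]
        if sub.shape[0] < 3:
            raise ValueError("fewer than 3 complete rows")
        self.means_ = sub.mean(axis=0)
        self.scales_ = sub.std(axis=0)
        if np.any(self.scales_ == 0):
            raise ValueError("constant column in score matrix")
        Z = (sub - self.means_) / self.scales_
        self.correlation_ = np.corrcoef(Z, rowvar=False)
        model = factor_analysis(self.correlation_, self.n_factors,
                                kaiser=self.kaiser, tol=self.tol,
                                max_sweeps=self.max_sweeps)
        self.loadings_ = model.loadings
        self.weights_ = model.weights
        self.rotation_ = model.rotation
        self.explained_variance_ratio_ = model.explained
        self.communalities_ = model.communalities
        raw = Z @ self.weights_
        self.score_means_ = raw.mean(axis=0)
        self.score_scales_ = np.where(raw.std(axis=0) > 0, raw.std(axis=0), 1.0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        Z = (X - self.means_) / self.scales_
        raw = Z @ self.weights_
        return (raw - self.score_means_) / self.score_scales_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
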