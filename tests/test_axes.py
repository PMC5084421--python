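"""Transform, correlation and varimax factor machinery.

The rotation is checked against R's base ``stats::varimax`` (an
independent, established implementation available via Rscript)."""

import shutil
import subprocess

import numpy as np
import pytest

from sweepaxes.axes import (FactorSummarizer, axis_population_correlations,
                            axis_score_tracks, build_score_matrix,
                            communalities, correlation_matrix,
                            factor_analysis, factor_scores, transform_track,
                            varimax_rotation)
from sweepaxes.io import ScoreTrack

from conftest import make_map


def track(values, name="t", pop="p", orientation="high_is_evidence",
          snp_map=None):
    values = np.asarray(values, dtype=float)
    snp_map = snp_map or make_map(len(values))
    return ScoreTrack(name, pop, values, orientation, snp_map)


def block_corr(p_per_block=3, blocks=3, r=0.8):
    p = p_per_block * blocks
    corr = np.eye(p)
    for b in range(blocks):
        s = slice(b * p_per_block, (b + 1) * p_per_block)
        corr[s, s] = r
    np.fill_diagonal(corr, 1.0)
    return corr


class TestTransform:
    def test_low_is_evidence_flips_then_logs(self):
        t = track([-2.0], orientation="low_is_evidence")
        assert transform_track(t)[0] == pytest.approx(np.log(3))

    def test_high_is_evidence_log1p(self):
        t = track([1.0])
        assert transform_track(t)[0] == pytest.approx(np.log(2))

    def test_abs_is_evidence(self):
        t = track([-3.0, 3.0], orientation="abs_is_evidence")
        out = transform_track(t)
        assert out[0] == out[1] == pytest.approx(np.log(4))

    def test_monotone_in_evidence(self, rng):
        v = np.sort(rng.normal(size=200))
        out = transform_track(track(v))
        assert np.all(np.diff(out) > 0)

    def test_plain_ln_requires_positive(self):
        with pytest.raises(ValueError):
            transform_track(track([1.0, -0.5]), method="log")

    def test_plain_ln_scale_invariant_after_zscore(self, rng):
        """ln transform: a positive rescale shifts the column by a constant,
        which z-scoring removes exactly."""
        v = rng.uniform(0.5, 5.0, 100)
        a = transform_track(track(v), "log")
        b = transform_track(track(v * 7.3), "log")
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        np.testing.assert_allclose(za, zb, atol=1e-12)


class TestScoreMatrix:
    def _tracks(self, rng, pops=("a", "b"), tests=("T1", "T2", "T3"), m=10,
                missing=None):
        snp_map = make_map(m)
        out = []
        for p in pops:
            for t in tests:
                vals = rng.normal(size=m)
                if missing and (t, p) in missing:
                    vals[missing[(t, p)]] = np.nan
                out.append(ScoreTrack(t, p, vals, "high_is_evidence", snp_map))
        return out

    def test_shape_two_pops_three_tests(self, rng):
        m = build_score_matrix(self._tracks(rng))
        assert m.data.shape == (20, 3)

    def test_complete_case_per_population(self, rng):
        tracks = self._tracks(rng, missing={("T2", "a"): [3]})
        m = build_score_matrix(tracks)
        rows_a = np.flatnonzero((m.row_population == "a") & (m.row_snp == 3))
        rows_b = np.flatnonzero((m.row_population == "b") & (m.row_snp == 3))
        assert not m.complete[rows_a].any()
        assert m.complete[rows_b].all()

    def test_columns_standardized(self, rng):
        m = build_score_matrix(self._tracks(rng, m=50))
        sub = m.data[m.complete]
        np.testing.assert_allclose(sub.mean(0), 0.0, atol=1e-12)
        np.testing.assert_allclose(sub.std(0), 1.0, atol=1e-12)

    def test_missing_combination_errors(self, rng):
        tracks = self._tracks(rng)[:-1]
        with pytest.raises(ValueError, match="missing"):
            build_score_matrix(tracks)


class TestCorrelation:
    def test_duplicated_column_correlates_one(self, rng):
        snp_map = make_map(30)
        v = rng.normal(size=30)
        tracks = [ScoreTrack("A", "p", v, "high_is_evidence", snp_map),
                  ScoreTrack("B", "p", v.copy(), "high_is_evidence", snp_map),
                  ScoreTrack("C", "p", rng.normal(size=30),
                             "high_is_evidence", snp_map)]
        corr, _ = correlation_matrix(build_score_matrix(tracks))
        assert corr[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        snp_map = make_map(100_000)
        tracks = [ScoreTrack(f"T{i}", "p", rng.normal(size=100_000),
                             "high_is_evidence", snp_map) for i in range(4)]
        corr, _ = correlation_matrix(build_score_matrix(tracks))
        off = corr[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.02

    def test_constant_column_named(self, rng):
        snp_map = make_map(20)
        tracks = [ScoreTrack("flat", "p", np.ones(20), "high_is_evidence",
                             snp_map),
                  ScoreTrack("ok", "p", rng.normal(size=20),
                             "high_is_evidence", snp_map),
                  ScoreTrack("ok2", "p", rng.normal(size=20),
                             "high_is_evidence", snp_map)]
        with pytest.raises(ValueError, match="flat"):
            build_score_matrix(tracks)

    def test_block_structure_orders_blocks_together(self, rng):
        corr, order = _block_tracks_corr(rng)
        # within-block correlations exceed between-block
        for b in range(3):
            s = slice(3 * b, 3 * b + 3)
            within = corr[s, s][~np.eye(3, dtype=bool)]
            outside = np.delete(corr[s, :], np.arange(3 * b, 3 * b + 3),
                                axis=1)
            assert within.min() > np.abs(outside).max()


def _block_tracks_corr(rng, m=20_000):
    snp_map = make_map(m)
    latent = rng.normal(size=(m, 3))
    tracks = []
    for i in range(9):
        v = 0.8 * latent[:, i // 3] + 0.6 * rng.normal(size=m)
        tracks.append(ScoreTrack(f"T{i}", "p", v, "high_is_evidence", snp_map))
    mat = build_score_matrix(tracks)
    corr, order = correlation_matrix(mat)
    return corr, order


def r_varimax(loadings, kaiser=True):
    """Oracle: R's stats::varimax via Rscript."""
    p, k = loadings.shape
    inp = "\n".join(",".join(f"{v:.17g}" for v in row) for row in loadings)
    script = (
        f'x <- matrix(scan("stdin", sep=","), ncol={k}, byrow=TRUE);'
        f'r <- varimax(x, normalize={"TRUE" if kaiser else "FALSE"}, eps=1e-12);'
        f'cat(sprintf("%.17g", as.vector(r$loadings)), sep="\\n")')
    out = subprocess.run(["Rscript", "-e", script], input=inp, text=True,
                         capture_output=True, check=True)
    vals = np.array([float(s) for s in out.stdout.split()])
    return vals.reshape((p, k), order="F")  # R vectorizes column-major


def align_columns(A, B):
    """Permute/sign-flip B's columns to best match A."""
    k = A.shape[1]
    out = np.empty_like(B)
    used = set()
    for j in range(k):
        scores = [abs(A[:, j] @ B[:, l]) if l not in used else -1
                  for l in range(k)]
        l = int(np.argmax(scores))
        used.add(l)
        sign = np.sign(A[:, j] @ B[:, l]) or 1.0
        out[:, j] = sign * B[:, l]
    return out


needs_r = pytest.mark.skipif(shutil.which("Rscript") is None,
                             reason="Rscript not available")


class TestVarimax:
    def test_rotation_orthogonal_and_communality_preserving(self, rng):
        for _ in range(20):
            L0 = rng.normal(size=(8, 3))
            L, R = varimax_rotation(L0)
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-9)
            np.testing.assert_allclose((L ** 2).sum(1), (L0 ** 2).sum(1),
                                       atol=1e-9)
            np.testing.assert_allclose(L, L0 @ R, atol=1e-9)

    def test_fixed_point_on_already_optimal_loadings(self):
        L0 = np.zeros((9, 3))
        for b in range(3):
            L0[3 * b:3 * b + 3, b] = 0.9
        L, R = varimax_rotation(L0)
        np.testing.assert_allclose(np.abs(R), np.eye(3), atol=1e-9)

    @needs_r
    def test_matches_r_reference_implementation(self, rng):
        """Loadings agree with stats::varimax up to column order/sign.

        The criterion is locally quadratic, so R's eps=1e-12 stopping rule
        leaves angle errors up to ~1e-5; the rigorous check is that our
        solution's varimax criterion is >= R's, with a loose element-wise
        agreement on top."""
        for trial in range(10):
            p, k = int(rng.integers(5, 12)), int(rng.integers(2, 4))
            L0 = rng.normal(size=(p, k))
            mine, _ = varimax_rotation(L0, kaiser=True)
            ref = r_varimax(L0, kaiser=True)
            h = np.sqrt((L0 ** 2).sum(1))

            def crit(M):
                sq = (M / h[:, None]) ** 2
                return np.sum(sq ** 2) - np.sum(sq.sum(0) ** 2) / p

            assert crit(mine) >= crit(ref) - 1e-10
            aligned = align_columns(mine, ref)
            np.testing.assert_allclose(mine, aligned, atol=1e-4)


class TestFactorAnalysis:
    def test_block_matrix_recovers_blocks(self):
        corr = block_corr(r=0.8)
        model = factor_analysis(corr, 3)
        for i in range(9):
            own = i // 3
            load = np.abs(model.loadings[i])
            # own-block axis may be any column; find it
            assert load.max() > 0.85
            others = np.delete(load, np.argmax(load))
            assert np.all(others < 0.15)

    def test_communalities_preserved_by_rotation(self):
        corr = block_corr(r=0.6)
        vals, vecs = np.linalg.eigh(corr)
        top = np.argsort(vals)[::-1][:3]
        L0 = vecs[:, top] * np.sqrt(vals[top])
        model = factor_analysis(corr, 3)
        np.testing.assert_allclose(model.communalities, (L0 ** 2).sum(1),
                                   atol=1e-9)

    def test_explained_ordered_and_bounded(self):
        model = factor_analysis(block_corr(r=0.7), 3)
        assert np.all(np.diff(model.explained) <= 1e-12)
        assert model.explained.sum() <= 1.0 + 1e-12
        assert np.all((model.communalities >= 0)
                      & (model.communalities <= 1 + 1e-9))

    def test_non_psd_rejected(self):
        corr = np.array([[1.0, 0.99, -0.99],
                         [0.99, 1.0, 0.99],
                         [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            factor_analysis(corr, 2)

    @needs_r
    def test_loadings_match_r_on_random_psd(self, rng):
        for _ in range(5):
            X = rng.normal(size=(60, 7))
            corr = np.corrcoef(X, rowvar=False)
            model = factor_analysis(corr, 3)
            vals, vecs = np.linalg.eigh(corr)
            top = np.argsort(vals)[::-1][:3]
            L0 = vecs[:, top] * np.sqrt(vals[top])
            ref = r_varimax(L0)
            aligned = align_columns(model.loadings, ref)
            np.testing.assert_allclose(model.loadings, aligned, atol=1e-5)


class TestScores:
    def test_unit_variance_and_mean_row_zero(self, rng):
        snp_map = make_map(500)
        tracks = [ScoreTrack(f"T{i}", "p", rng.normal(size=500),
                             "high_is_evidence", snp_map) for i in range(6)]
        m = build_score_matrix(tracks)
        corr, _ = correlation_matrix(m)
        model = factor_analysis(corr, 3, m.test_names)
        s = factor_scores(m, model)
        ok = ~np.isnan(s).any(axis=1)
        np.testing.assert_allclose(s[ok].std(axis=0), 1.0, atol=1e-6)
        np.testing.assert_allclose(s[ok].mean(axis=0), 0.0, atol=1e-6)

    def test_block_extreme_snps_score_on_own_axis(self, rng):
        m_snps = 5000
        snp_map = make_map(m_snps)
        latent = rng.normal(size=(m_snps, 3))
        spikes = {0: slice(0, 50), 1: slice(100, 150), 2: slice(200, 250)}
        for b, s in spikes.items():
            latent[s, b] += 6.0
        tracks = []
        for i in range(9):
            v = 0.8 * latent[:, i // 3] + 0.6 * rng.normal(size=m_snps)
            tracks.append(ScoreTrack(f"T{i}", "p", v, "high_is_evidence",
                                     snp_map))
        mat = build_score_matrix(tracks)
        corr, _ = correlation_matrix(mat)
        model = factor_analysis(corr, 3, mat.test_names)
        scores = factor_scores(mat, model)
        # map each true block to its axis via loadings
        for b, s in spikes.items():
            axis = int(np.argmax(np.abs(model.loadings[3 * b])))
            mean_scores = scores[s].mean(axis=0)
            assert np.argmax(mean_scores) == axis

    def test_test_set_mismatch_errors(self, rng):
        snp_map = make_map(50)
        tracks = [ScoreTrack(f"T{i}", "p", rng.normal(size=50),
                             "high_is_evidence", snp_map) for i in range(4)]
        m = build_score_matrix(tracks)
        corr, _ = correlation_matrix(m)
        model = factor_analysis(corr, 3, ["X1", "X2", "X3", "X4"])
        with pytest.raises(ValueError, match="different tests"):
            factor_scores(m, model)


class TestAxisPopulationCorrelations:
    def test_identical_tracks_correlate_one(self, rng):
        snp_map = make_map(200)
        v = rng.normal(size=200)
        at = {(1, "a"): ScoreTrack("axis1", "a", v, "abs_is_evidence", snp_map),
              (1, "b"): ScoreTrack("axis1", "b", v.copy(), "abs_is_evidence",
                                   snp_map)}
        corrs, avgs = axis_population_correlations(at)
        assert corrs[1][0, 1] == pytest.approx(1.0)
        assert avgs[1] == pytest.approx(1.0)

    def test_independent_tracks_near_zero(self, rng):
        snp_map = make_map(100_000)
        at = {(1, p): ScoreTrack("axis1", p, rng.normal(size=100_000),
                                 "abs_is_evidence", snp_map)
              for p in ("a", "b")}
        _, avgs = axis_population_correlations(at)
        assert abs(avgs[1]) < 0.05


class TestFactorSummarizer:
    def test_sklearn_contract(self, rng):
        est = FactorSummarizer(n_factors=2)
        assert est.get_params()["n_factors"] == 2
        est.set_params(n_factors=3)
        X = rng.normal(size=(400, 6))
        X[:, 3] += X[:, 0]
        s = est.fit_transform(X)
        assert s.shape == (400, 3)
        np.testing.assert_allclose(s.std(axis=0), 1.0, atol=1e-6)
        np.testing.assert_allclose(est.rotation_.T @ est.rotation_,
                                   np.eye(3), atol=1e-9)

    def test_nan_rows_propagate(self, rng):
        X = rng.normal(size=(100, 4))
        X[7, 2] = np.nan
        s = FactorSummarizer(n_factors=2).fit(X).transform(X)
        assert np.isnan(s[7]).all()
        assert np.isfinite(np.delete(s, 7, axis=0)).all()


class TestCommunalities:
    def test_sum_of_squared_loadings(self):
        L = np.array([[0.6, 0.8], [1.0, 0.0]])
        np.testing.assert_allclose(communalities(L), [1.0, 1.0])
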