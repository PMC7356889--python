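import itertools

import numpy as np
import pytest
from scipy import stats

from fffmon.robpca import (
    ROBPCA,
    ClassicalPCADiagnostics,
    classify,
    cutoffs,
    fit_cpca_diagnostics,
    fit_robpca,
)


def subspace_gaussian(rng, n=100, p=6, k=2, noise=0.0, scales=(4.0, 2.0)):
    B = np.linalg.qr(rng.standard_normal((p, k)))[0]
    T = rng.standard_normal((n, k)) * np.asarray(scales)
    X = T @ B.T
    if noise:
        X = X + noise * rng.standard_normal((n, p))
    return X, B


def principal_angle_deg(A, B):
    """Largest principal angle between the column spaces of A and B."""
    qa, qb = np.linalg.qr(A)[0], np.linalg.qr(B)[0]
    s = np.clip(np.linalg.svd(qa.T @ qb, compute_uv=False), 0, 1)
    return float(np.degrees(np.arccos(s.min())))


class TestFit:
    def test_exact_subspace_full_recovery(self):
        rng = np.random.default_rng(0)
        X, _ = subspace_gaussian(rng, n=50, p=6, k=2)
        m = ROBPCA(n_components=2, random_state=0).fit(X)
        assert m.explained_variance_fraction_ == pytest.approx(1.0)
        _, od = m.distances(X)
        np.testing.assert_allclose(od, 0.0, atol=1e-8)

    def test_loadings_orthonormal_eigenvalues_descending(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((80, 7)) * np.linspace(3, 1, 7)
        m = ROBPCA(n_components=4, random_state=1).fit(X)
        np.testing.assert_allclose(m.components_ @ m.components_.T, np.eye(4), atol=1e-8)
        assert np.all(np.diff(m.eigenvalues_) <= 1e-12)

    def test_matches_classical_pca_on_clean_data(self):
        rng = np.random.default_rng(2)
        X, B = subspace_gaussian(rng, n=200, p=10, k=3, noise=0.2, scales=(6.0, 4.0, 2.5))
        m = ROBPCA(n_components=3, random_state=2).fit(X)
        _, _, Vt = np.linalg.svd(X - X.mean(0), full_matrices=False)
        assert principal_angle_deg(m.components_.T, Vt[:3].T) < 5.0

    def test_k_exceeding_rank_rejected(self):
        rng = np.random.default_rng(3)
        X, _ = subspace_gaussian(rng, n=30, p=6, k=2)
        with pytest.raises(ValueError, match="rank"):
            ROBPCA(n_components=5, random_state=0).fit(X)

    def test_small_alpha_with_large_k_rejected(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((12, 10))
        with pytest.raises(ValueError, match="alpha"):
            ROBPCA(n_components=9, alpha=0.6, random_state=0).fit(X)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 8))
        a = ROBPCA(n_components=3, random_state=9).fit(X)
        b = ROBPCA(n_components=3, random_state=9).fit(X)
        np.testing.assert_array_equal(a.sd_, b.sd_)
        np.testing.assert_array_equal(a.support_, b.support_)


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((100, 5)) * np.array([3.0, 2.0, 1.0, 0.3, 0.2])
    return ROBPCA(n_components=2, random_state=6).fit(X)


class TestDistances:

    def test_center_has_zero_distances(self, model):
        sd, od = model.distances(model.center_[None, :])
        assert sd[0] == pytest.approx(0.0, abs=1e-10)
        assert od[0] == pytest.approx(0.0, abs=1e-10)

    def test_in_plane_shift_closed_form(self, model):
        c = 5.0
        x = model.center_ + c * np.sqrt(model.eigenvalues_[0]) * model.components_[0]
        sd, od = model.distances(x[None, :])
        assert sd[0] == pytest.approx(c, rel=1e-10)
        assert od[0] == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_shift_closed_form(self, model):
        # build v orthogonal to the loading plane
        P = model.components_
        v = np.ones(5)
        v -= P.T @ (P @ v)
        v /= np.linalg.norm(v)
        x = model.center_ + 3.0 * v
        sd, od = model.distances(x[None, :])
        assert sd[0] == pytest.approx(0.0, abs=1e-8)
        assert od[0] == pytest.approx(3.0, rel=1e-8)

    def test_rotation_equivariance(self, model):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((50, 5)) * np.array([3.0, 2.0, 1.0, 0.3, 0.2])
        R = np.linalg.qr(rng.standard_normal((5, 5)))[0]
        m1 = ROBPCA(n_components=2, random_state=3).fit(X)
        m2 = ROBPCA(n_components=2, random_state=3).fit(X @ R)
        sd1, od1 = m1.distances(X)
        sd2, od2 = m2.distances(X @ R)
        np.testing.assert_allclose(sd1, sd2, rtol=1e-6)
        np.testing.assert_allclose(od1, od2, rtol=1e-6, atol=1e-8)


class TestCutoffsAndClassification:
    def test_sd_cutoff_is_chi2_quantile(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100, 6))
        m = ROBPCA(n_components=2, random_state=8).fit(X)
        assert m.sd_cutoff_ == pytest.approx(np.sqrt(7.3778), abs=1e-3)
        assert m.sd_cutoff_ == pytest.approx(2.7162, abs=1e-3)

    def test_quantile_near_one_flags_nothing(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((100, 6))
        m = ROBPCA(n_components=2, random_state=9).fit(X)
        sd_hi, od_hi = cutoffs(m, quantile=1 - 1e-12)
        assert sd_hi > m.sd_.max() and od_hi > m.od_.max()
        assert (classify(m.sd_, m.od_, sd_hi, od_hi) == "regular").all()

    def test_full_rank_model_suppresses_od_classification(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((40, 3))
        m = ROBPCA(n_components=3, random_state=10).fit(X)
        assert m.od_cutoff_ is None
        assert set(m.quadrants_) <= {"regular", "score_outlier"}

    def test_quadrant_labels(self):
        sd = np.array([0.0, 5.0, 0.5, 5.0])
        od = np.array([0.0, 0.1, 7.0, 7.0])
        labels = classify(sd, od, sd_cut=2.0, od_cut=3.0)
        assert labels.tolist() == ["regular", "score_outlier", "orthogonal_outlier", "both"]

    def test_boundary_equality_is_regular(self):
        labels = classify(np.array([2.0]), np.array([3.0]), 2.0, 3.0)
        assert labels[0] == "regular"

    def test_nominal_sd_flag_rate_on_clean_gaussian(self):
        flags, total = 0, 0
        for seed in range(3):
            rng = np.random.default_rng(40 + seed)
            X = rng.standard_normal((500, 10)) * np.linspace(3, 1, 10)
            m = ROBPCA(variance_target=0.80, random_state=seed).fit(X)
            flags += int((m.sd_ > m.sd_cutoff_).sum())
            total += 500
        assert 0.005 <= flags / total <= 0.075


class TestContributions:
    def test_zero_at_center(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((60, 5))
        m = ROBPCA(n_components=2, random_state=11).fit(X)
        c = m.score_contributions(m.center_[None, :])
        np.testing.assert_allclose(c, 0.0, atol=1e-10)

    def test_sums_to_squared_score_distance(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((80, 6)) * np.linspace(2, 1, 6)
        m = ROBPCA(n_components=3, random_state=12).fit(X)
        c = m.score_contributions(X)
        sd, _ = m.distances(X)
        np.testing.assert_allclose(c.sum(axis=1), sd**2, rtol=1e-6)

    def test_single_variable_perturbation_dominates(self):
        # variables independent: a shift in one coordinate aligned with a
        # loading should be attributed almost entirely to that variable
        rng = np.random.default_rng(13)
        X = rng.standard_normal((100, 5)) * np.array([3.0, 1.0, 1.0, 1.0, 1.0])
        m = ROBPCA(n_components=2, random_state=13).fit(X)
        x = m.center_.copy()
        x[0] += 10.0
        c = np.abs(m.score_contributions(x[None, :])[0])
        assert c[0] / c.sum() >= 0.99


def mcd_instance(rng):
    """6-point hexagonal clean cluster plus two gross outliers in opposite
    corners: the exhaustive-MCD optimum is the clean subset by construction
    (no near-collinear 6-subset can beat it)."""
    ang = np.arange(6) * np.pi / 3
    hexagon = 2.0 * np.c_[np.cos(ang), np.sin(ang)]
    return np.vstack([
        hexagon + rng.normal(0, 0.3, (6, 2)),
        rng.normal(0, 0.5, (1, 2)) + [12.0, 12.0],
        rng.normal(0, 0.5, (1, 2)) + [-12.0, 12.0],
    ])


class TestMcdOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_h_subset_matches_exhaustive_mcd(self, seed):
        X = mcd_instance(np.random.default_rng(300 + seed))
        m = ROBPCA(n_components=1, random_state=seed).fit(X)
        best, best_det = None, np.inf
        for subset in itertools.combinations(range(8), m.h_):
            det = float(np.linalg.det(np.cov(X[list(subset)], rowvar=False)))
            if det < best_det:
                best_det, best = det, subset
        assert set(np.flatnonzero(m.support_)) == set(best)


class TestRobustness:
    def test_contamination_barely_moves_robust_subspace(self):
        hits_rob, hits_cls = [], []
        for seed in range(5):
            rng = np.random.default_rng(500 + seed)
            X, B = subspace_gaussian(rng, n=100, p=8, k=3, noise=0.2, scales=(5.0, 3.0, 2.0))
            v = np.linalg.qr(np.hstack([B, rng.standard_normal((8, 1))]))[0][:, 3]
            out = rng.choice(100, 20, replace=False)  # 20% gross off-plane outliers
            Xc = X.copy()
            Xc[out] += 50.0 * v
            m = ROBPCA(n_components=3, random_state=seed).fit(Xc)
            hits_rob.append(principal_angle_deg(m.components_.T, B))
            _, _, Vt = np.linalg.svd(Xc - Xc.mean(0), full_matrices=False)
            hits_cls.append(principal_angle_deg(Vt[:3].T, B))
        assert max(hits_rob) < 10.0
        assert min(hits_cls) > 30.0

    def test_planted_noise_lot_flagged_in_campaigns(self):
        # the abnormal-lot motif: one lot with 1.3x sensor noise on one LP
        # signal, at the 58-lot campaign shape.  Whether the excess noise
        # surfaces in the score or the orthogonal distance depends on whether
        # the affected spread features span the model plane; flagged is
        # flagged either way.
        from fffmon.features import build_feature_matrix, drop_zero_variance, impute_missing, scale_features
        from fffmon.phase_rules import apply_ruleset, default_lp_ruleset
        from fffmon.phase_step import detect_step_phases
        from fffmon.synthetic import (
            CampaignSpec, Contamination, default_feature_specs, default_step_config,
            generate_campaign,
        )

        flagged = 0
        n_campaigns = 10
        for seed in range(n_campaigns):
            spec = CampaignSpec(
                n_lots=58,
                contaminations=[Contamination(lot_index=21, mechanism="noise_inflation",
                                              signal="LP2", factor=1.3)],
                master_seed=900 + seed,
            )
            batches, _, _ = generate_campaign(spec)
            cfg = default_step_config()
            segs = {
                b.lot_id: {
                    s: detect_step_phases(b.series[s], cfg)
                    for s in ("LP1", "LP2", "LP3", "LP5", "LP6", "LP7")
                }
                for b in batches
            }
            rules = {b.lot_id: apply_ruleset(default_lp_ruleset(), b).phases for b in batches}
            specs = [s for s in default_feature_specs() if not s.signal_name.startswith("SF")]
            fm = build_feature_matrix(batches, segs, rules, specs)
            fm, _ = drop_zero_variance(fm)
            fm, _ = impute_missing(fm)
            fm, _ = scale_features(fm)
            m = ROBPCA(variance_target=0.80, random_state=seed).fit(fm.to_numpy())
            idx = fm.lot_ids.index("L022")
            flagged += int(m.quadrants_[idx] != "regular")
        assert flagged >= 0.8 * n_campaigns


class TestClassicalDiagnostics:
    def test_subspace_data_zero_dmodx(self):
        rng = np.random.default_rng(20)
        X, _ = subspace_gaussian(rng, n=60, p=6, k=2)
        d = fit_cpca_diagnostics(X, k=2)
        np.testing.assert_allclose(d.dmodx_, 0.0, atol=1e-6)

    def test_t2_limit_formula(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((50, 8))
        d = fit_cpca_diagnostics(X, k=3)
        n, k = 50, 3
        expected = k * (n - 1) * (n + 1) / (n * (n - k)) * stats.f.ppf(0.95, k, n - k)
        assert d.t2_limit_ == pytest.approx(expected)

    def test_nominal_t2_exceedance_on_clean_gaussian(self):
        flags, total = 0, 0
        for seed in range(4):
            rng = np.random.default_rng(30 + seed)
            X = rng.standard_normal((200, 10)) * np.linspace(3, 1, 10)
            d = fit_cpca_diagnostics(X, k=3)
            flags += int((d.t2_ > d.t2_limit_).sum())
            total += 200
        assert 0.01 <= flags / total <= 0.10

    def test_excessive_k_rejected(self):
        rng = np.random.default_rng(22)
        with pytest.raises(ValueError):
            fit_cpca_diagnostics(rng.standard_normal((10, 4)), k=4)

    def test_masking_direction_cpca_flags_fewer_planted(self):
        rob_hits = cls_hits = 0
        for seed in range(10):
            rng = np.random.default_rng(600 + seed)
            n, p, k = 60, 20, 3
            B = np.linalg.qr(rng.standard_normal((p, k)))[0]
            X = rng.standard_normal((n, k)) * np.array([4.0, 3.0, 2.0]) @ B.T
            X += 0.3 * rng.standard_normal((n, p))
            planted = rng.choice(n, 6, replace=False)
            X[planted] += 8.0 * 4.0 * B[:, 0]
            m = fit_robpca(X, k=3, seed=seed)
            rob_hits += int((m.sd_[planted] > m.sd_cutoff_).sum())
            d = fit_cpca_diagnostics(X, k=3)
            cls_hits += int((d.t2_[planted] > d.t2_limit_).sum())
        assert cls_hits < rob_hits
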