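"""Robust PCA outlier diagnostics for the lot x feature matrix.

:class:`ROBPCA` implements the three-stage projection-pursuit / MCD hybrid:

1. the data are reduced to the affine subspace they actually span (SVD);
2. Stahel-Donoho outlyingness is computed over a deterministic-plus-seeded
   set of projection directions through pairs of observations, and the
   ``h`` least outlying points are kept,
   ``h = max(floor(alpha*N), floor((N + k + 1)/2))``;
3. the eigenvectors of the kept points' covariance define a k-dimensional
   score space, inside which a reweighted minimum-covariance-determinant
   (MCD) estimate refines center and scatter.

Every observation then gets a *score distance* ``SD_i`` (robust Mahalanobis
distance of its scores) and an *orthogonal distance* ``OD_i`` (Euclidean
distance to the model plane).  Cutoffs at a chi-squared quantile (default
97.5%) split the SD/OD plane into four quadrants: regular lots, score
outliers, orthogonal outliers, and lots outlying in both senses.  A
per-variable decomposition of ``SD_i^2`` (the contribution plot) points at
the features responsible for an outlying score.

:class:`ClassicalPCADiagnostics` provides the non-robust benchmark: ordinary
PCA with Hotelling T² (F-distribution 95% limit) and normalized DModX.
Classical eigenvalues are inflated by the very outliers one is hunting,
which masks them; comparing both models on the same matrix demonstrates the
effect.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.covariance import MinCovDet
from sklearn.utils.validation import check_array, check_is_fitted

from .cleaning import MAD_SCALE

__all__ = [
    "ROBPCA",
    "ClassicalPCADiagnostics",
    "QUADRANTS",
    "fit_robpca",
    "distances",
    "cutoffs",
    "classify",
    "score_contributions",
    "fit_cpca_diagnostics",
]

QUADRANTS = ("regular", "score_outlier", "orthogonal_outlier", "both")

#: combinatorial budget below which the MCD subset search is exhaustive
_EXHAUSTIVE_MCD_LIMIT = 20_000


def _consistency_factor(beta: float, k: int) -> float:
    """Asymptotic factor making a central-subset covariance Gaussian-consistent."""
    q = stats.chi2.ppf(beta, k)
    return beta / stats.chi2.cdf(q, k + 2)


def _mcd(T: np.ndarray, h: int, random_state: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw MCD in low dimension: (subset mask, location, consistent scatter).

    Exhaustive over all h-subsets when the combinatorics allow (ties broken
    towards the lexicographically first subset, so the result is
    deterministic); FAST-MCD otherwise.
    """
    n, k = T.shape
    if h >= n:
        mask = np.ones(n, dtype=bool)
    elif math.comb(n, h) <= _EXHAUSTIVE_MCD_LIMIT:
        best_det, best_subset = np.inf, None
        for subset in itertools.combinations(range(n), h):
            S = np.cov(T[list(subset)], rowvar=False).reshape(k, k)
            det = float(np.linalg.det(S))
            # strict < plus lexicographic enumeration: first minimum wins, ties deterministic
            if best_subset is None or det < best_det:
                best_det, best_subset = det, subset
        mask = np.zeros(n, dtype=bool)
        mask[list(best_subset)] = True
    else:
        mcd = MinCovDet(support_fraction=h / n, random_state=random_state).fit(T)
        mask = mcd.raw_support_.astype(bool)
    loc = T[mask].mean(axis=0)
    scatter = np.cov(T[mask], rowvar=False).reshape(k, k)
    scatter = scatter * _consistency_factor(mask.sum() / n, k)
    return mask, loc, scatter


def _reweight(
    T: np.ndarray, loc: np.ndarray, scatter: np.ndarray, quantile: float = 0.975
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One reweighting step: keep points within the chi-squared quantile."""
    k = T.shape[1]
    d2 = _mahalanobis_sq(T, loc, scatter)
    w = d2 <= stats.chi2.ppf(quantile, k)
    if w.sum() < k + 1:  # degenerate: keep the raw estimate
        return np.ones(T.shape[0], dtype=bool), loc, scatter
    loc_w = T[w].mean(axis=0)
    scatter_w = np.cov(T[w], rowvar=False).reshape(k, k)
    scatter_w = scatter_w * (
        stats.chi2.cdf(stats.chi2.ppf(quantile, k), k)
        / stats.chi2.cdf(stats.chi2.ppf(quantile, k), k + 2)
    )
    return w, loc_w, scatter_w


def _mahalanobis_sq(T: np.ndarray, loc: np.ndarray, scatter: np.ndarray) -> np.ndarray:
    diff = T - loc
    return np.einsum("ij,ij->i", diff @ np.linalg.pinv(scatter), diff)


class ROBPCA(BaseEstimator):
    """Robust principal component analysis with SD/OD outlier diagnostics.

    Parameters
    ----------
    n_components : int, optional
        Number of retained components ``k``; when ``None`` the smallest
        ``k`` whose cumulative explained variance reaches
        ``variance_target`` is used.
    variance_target : float
        Cumulative explained-variance goal for automatic ``k`` (default 0.80).
    alpha : float
        Coverage fraction in (0.5, 1]; ``h ~ alpha * N`` observations are
        assumed uncontaminated (default 0.75).
    n_random_directions : int
        Seeded random projection directions added to the deterministic
        all-pairs set (which is only enumerated when ``N <= 25``).
    quantile : float
        Chi-squared quantile for the SD and OD cutoff lines (default 0.975).
    random_state : int
        Seed for direction sampling and the FAST-MCD fallback.

    Attributes (after ``fit``)
    --------------------------
    center_ : (p,) robust center.
    components_ : (k, p) orthonormal loadings, rows ordered by eigenvalue.
    eigenvalues_ : (k,) robust eigenvalues, descending.
    n_components_, h_, support_, explained_variance_fraction_
    sd_, od_ : training score / orthogonal distances.
    sd_cutoff_, od_cutoff_ : quadrant boundaries (``od_cutoff_`` is ``None``
        when the model spans the full data space and OD is identically 0).
    quadrants_ : training quadrant labels.
    """

    def __init__(
        self,
        n_components: int | None = None,
        variance_target: float = 0.80,
        alpha: float = 0.75,
        n_random_directions: int = 250,
        quantile: float = 0.975,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.variance_target = variance_target
        self.alpha = alpha
        self.n_random_directions = n_random_directions
        self.quantile = quantile
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def _directions(self, Z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        # directions through pairs of observations: deterministic all-pairs for
        # small campaigns, a seeded sample of pairs otherwise.  Data-driven
        # directions keep the outlyingness exactly rotation-equivariant.
        n, r = Z.shape
        dirs = []
        if n <= 25:
            for i, j in itertools.combinations(range(n), 2):
                dirs.append(Z[i] - Z[j])
        else:
            ii = rng.integers(0, n, size=2 * self.n_random_directions)
            jj = rng.integers(0, n, size=2 * self.n_random_directions)
            keep = ii != jj
            dirs.extend(Z[ii[keep]][: self.n_random_directions] - Z[jj[keep]][: self.n_random_directions])
        D = np.asarray(dirs, dtype=float)
        norms = np.linalg.norm(D, axis=1)
        D = D[norms > 1e-12] / norms[norms > 1e-12, None]
        return D

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=4)
        n, p = X.shape
        if not (0.5 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0.5, 1]")
        rng = np.random.default_rng(self.random_state)

        # stage 1: restrict to the affine subspace actually spanned
        mean0 = X.mean(axis=0)
        Xc = X - mean0
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        tol = S.max() * max(n, p) * np.finfo(float).eps if S.size else 0.0
        r = int((S > tol).sum())
        if r == 0:
            raise ValueError("data matrix has rank 0")
        B1 = Vt[:r].T  # p x r
        Z = Xc @ B1  # n x r

        k_for_h = self.n_components if self.n_components is not None else 1
        h = max(int(np.floor(self.alpha * n)), int(np.floor((n + k_for_h + 1) / 2)))
        h = min(h, n)

        # stage 2: Stahel-Donoho outlyingness, keep the h least outlying
        D = self._directions(Z, rng)
        proj = Z @ D.T  # n x n_dirs
        med = np.median(proj, axis=0)
        mad = MAD_SCALE * np.median(np.abs(proj - med), axis=0)
        ok = mad > 1e-12
        if not ok.any():
            outl = np.zeros(n)
        else:
            outl = np.max(np.abs(proj[:, ok] - med[ok]) / mad[ok], axis=1)
        order = np.argsort(outl, kind="stable")
        H0 = np.sort(order[:h])

        # covariance of the kept points fixes the candidate subspace
        muH = Z[H0].mean(axis=0)
        SH = np.cov(Z[H0], rowvar=False).reshape(r, r)
        evals, evecs = np.linalg.eigh(SH)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        evals = np.clip(evals, 0.0, None)
        total = evals.sum()
        cum = np.cumsum(evals) / total if total > 0 else np.ones_like(evals)

        if self.n_components is not None:
            k = int(self.n_components)
            if k > r:
                raise ValueError(f"n_components={k} exceeds data rank {r}")
        else:
            k = int(np.searchsorted(cum, self.variance_target - 1e-12) + 1)
            k = min(k, r)
        if np.floor(self.alpha * n) < k + 1:
            raise ValueError(f"alpha*N = {self.alpha * n:.1f} too small for k={k} components")

        E = evecs[:, :k]  # r x k
        T = (Z - muH) @ E  # n x k scores in the candidate frame

        # stage 3: reweighted MCD refinement in score space.  Gross off-plane
        # points (huge preliminary orthogonal distance) are screened out
        # first: they project harmlessly into the score space and would
        # otherwise be invisible to the MCD.  The screen is deliberately
        # loose (99.9%) — mild orthogonal outliers must not displace clean
        # points from the subset budget.
        h = max(h, int(np.floor((n + k + 1) / 2)))  # MCD solvability for the chosen k
        keep = np.ones(n, dtype=bool)
        if k < r:
            od_pre = np.linalg.norm(Z - muH - T @ E.T, axis=1)
            if not np.allclose(od_pre, 0.0, atol=1e-10):
                od23 = od_pre ** (2.0 / 3.0)
                c0 = np.median(od23)
                s0 = MAD_SCALE * np.median(np.abs(od23 - c0))
                if s0 > 0:
                    keep = od_pre <= (c0 + s0 * stats.norm.ppf(0.999)) ** 1.5
        if keep.sum() < max(k + 1, 4):
            keep = np.ones(n, dtype=bool)
        kept_idx = np.flatnonzero(keep)
        h_score = min(h, kept_idx.size)
        sub_mask, loc_raw, scat_raw = _mcd(
            T[kept_idx], h_score, random_state=int(rng.integers(0, 2**31 - 1))
        )
        mask = np.zeros(n, dtype=bool)
        mask[kept_idx[sub_mask]] = True
        _, loc_w, scat_w = _reweight(T, loc_raw, scat_raw, quantile=0.975)
        lam, G = np.linalg.eigh(scat_w)
        lam, G = lam[::-1], G[:, ::-1]
        lam = np.clip(lam, np.finfo(float).tiny, None)

        self.n_features_in_ = p
        self.n_components_ = k
        self.rank_ = r
        self.h_ = int(h)
        self.support_ = mask
        self.center_ = mean0 + B1 @ (muH + E @ loc_w)
        self.components_ = (B1 @ E @ G).T  # k x p, orthonormal rows
        self.eigenvalues_ = lam
        self.explained_variance_fraction_ = float(cum[k - 1])
        self.stage2_subset_ = H0

        self.sd_, self.od_ = self.distances(X)
        self.sd_cutoff_, self.od_cutoff_ = self._cutoffs(self.od_)
        self.quadrants_ = classify(self.sd_, self.od_, self.sd_cutoff_, self.od_cutoff_)
        return self

    # ----------------------------------------------------------- diagnostics

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        return (X - self.center_) @ self.components_.T

    def distances(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Score distances and orthogonal distances of the rows of X."""
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        T = (X - self.center_) @ self.components_.T
        sd = np.sqrt(np.sum(T**2 / self.eigenvalues_, axis=1))
        resid = X - self.center_ - T @ self.components_
        od = np.linalg.norm(resid, axis=1)
        return sd, od

    def _cutoffs(self, od_train: np.ndarray) -> tuple[float, float | None]:
        sd_cut = float(np.sqrt(stats.chi2.ppf(self.quantile, self.n_components_)))
        if self.n_components_ >= self.rank_ or np.allclose(od_train, 0.0, atol=1e-10):
            # model spans the data space: OD is identically zero, no OD line
            return sd_cut, None
        od23 = od_train ** (2.0 / 3.0)
        center = float(np.median(od23))
        scale = MAD_SCALE * float(np.median(np.abs(od23 - center)))
        z = stats.norm.ppf(self.quantile)
        od_cut = float((center + scale * z) ** 1.5)
        return sd_cut, od_cut

    def predict(self, X) -> np.ndarray:
        """Quadrant label per row of X (``regular`` / ``score_outlier`` / ...)."""
        sd, od = self.distances(X)
        return classify(sd, od, self.sd_cutoff_, self.od_cutoff_)

    def score_contributions(self, X) -> np.ndarray:
        """Per-variable additive decomposition of ``SD_i^2``.

        ``c_ij = (x_ij - mu_j) * sum_k P_kj t_ik / lambda_k``; rows sum to
        the squared score distance exactly.
        """
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        T = (X - self.center_) @ self.components_.T
        return (X - self.center_) * ((T / self.eigenvalues_) @ self.components_)


class ClassicalPCADiagnostics(BaseEstimator):
    """Ordinary PCA with Hotelling T² and normalized DModX control limits.

    ``t2_limit_`` is the 95% F-distribution limit
    ``k (N-1)(N+1) / (N (N-k)) * F_{0.95; k, N-k}``; ``t2_median_`` is the
    empirical median of the fitted T² values.  ``dmodx_`` is each lot's
    residual standard deviation divided by the pooled one, with the 95%
    limit ``sqrt(F_{0.95; p-k, (N-k-1)(p-k)})``.
    """

    def __init__(self, n_components: int = 2, level: float = 0.95):
        self.n_components = n_components
        self.level = level

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=4)
        n, p = X.shape
        k = int(self.n_components)
        if k >= min(n - 1, p):
            raise ValueError(f"n_components={k} must be < min(N-1, p) = {min(n - 1, p)}")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        self.components_ = Vt[:k]
        self.eigenvalues_ = (S[:k] ** 2) / (n - 1)
        T = Xc @ self.components_.T
        self.t2_ = np.sum(T**2 / self.eigenvalues_, axis=1)
        f_crit = stats.f.ppf(self.level, k, n - k)
        self.t2_limit_ = float(k * (n - 1) * (n + 1) / (n * (n - k)) * f_crit)
        self.t2_median_ = float(np.median(self.t2_))

        resid = Xc - T @ self.components_
        sse = np.sum(resid**2, axis=1)
        dof_i = p - k
        dof_pool = (n - k - 1) * (p - k)
        s_i = np.sqrt(sse / dof_i)
        s0 = np.sqrt(sse.sum() / dof_pool)
        # data numerically inside the model plane: no residual spread to
        # normalize by, every observation is at distance zero
        data_scale = np.sqrt(np.mean(Xc**2)) or 1.0
        self.dmodx_ = s_i / s0 if s0 > 1e-10 * data_scale else np.zeros(n)
        self.dmodx_limit_ = float(np.sqrt(stats.f.ppf(self.level, dof_i, dof_pool)))
        self.n_features_in_ = p
        return self


# ----------------------------------------------------------------- wrappers


def fit_robpca(
    X,
    k: int | None = None,
    variance_target: float = 0.80,
    alpha: float = 0.75,
    seed: int = 0,
    quantile: float = 0.975,
) -> ROBPCA:
    """Functional wrapper over :class:`ROBPCA`."""
    return ROBPCA(
        n_components=k,
        variance_target=variance_target,
        alpha=alpha,
        quantile=quantile,
        random_state=seed,
    ).fit(X)


def distances(model: ROBPCA, X) -> tuple[np.ndarray, np.ndarray]:
    return model.distances(X)


def cutoffs(model: ROBPCA, quantile: float = 0.975) -> tuple[float, float | None]:
    """Recompute cutoffs at another quantile from the fitted training OD."""
    saved = model.quantile
    try:
        model.quantile = quantile
        return model._cutoffs(model.od_)
    finally:
        model.quantile = saved


def classify(
    sd: np.ndarray, od: np.ndarray, sd_cut: float, od_cut: float | None
) -> np.ndarray:
    """Quadrant labels; strict inequality flags, boundary equality is regular."""
    sd = np.asarray(sd, dtype=float)
    od = np.asarray(od, dtype=float)
    sd_out = sd > sd_cut
    od_out = np.zeros_like(sd_out) if od_cut is None else od > od_cut
    labels = np.where(
        sd_out & od_out, "both",
        np.where(sd_out, "score_outlier", np.where(od_out, "orthogonal_outlier", "regular")),
    )
    return labels.astype(object)


def score_contributions(model: ROBPCA, x) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return model.score_contributions(x)[0] if x.shape[0] == 1 else model.score_contributions(x)


def fit_cpca_diagnostics(X, k: int, level: float = 0.95) -> ClassicalPCADiagnostics:
    return ClassicalPCADiagnostics(n_components=k, level=level).fit(X)
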