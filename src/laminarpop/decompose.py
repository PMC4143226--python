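"""PCA truncation and spatial / temporal / spatiotemporal ICA of CSD maps.

The space x time CSD matrix ``X`` (n_grid x n_times) is first reduced by
truncated SVD, ``X_K = U_K Gamma_K V_K``, keeping the K largest singular
values (columns of ``U_K`` are eigenimages, rows of ``V_K``
eigensequences).  ICA then searches for an invertible K x K recombination
``W`` of the retained subspace:

* spatial profiles   ``S = W U_K^T``          (rows = candidate images),
* time courses       ``T = W^-T Gamma_K V_K`` (the duals),

so that ``S^T T = X_K`` exactly for every invertible ``W``.  ``W`` is chosen
to maximize an infomax (maximum-likelihood) objective

    f(W) = alpha * [ E log p_s(S) + log|det W| ]
         + (1 - alpha) * [ E log p_t(T) - log|det W| ]

with a heavy-tailed (logistic / tanh-score) source model for the spatial
side and a sub-Gaussian (quartic log-density, cubic score) model for the
temporal side.  ``alpha = 1`` is pure spatial ICA, ``alpha = 0`` pure
temporal ICA, intermediate values spatiotemporal ICA with the diagonal
scaling freedom between the two sides acting as the usual stICA ``Lambda``.
The objective is maximized by L-BFGS with an analytic gradient and
multi-restart over random orthogonal initializations.

Components are ordered by the variance of their rank-1 map and
sign-normalized so each spatial profile's largest-magnitude entry is
positive.  All results are deterministic given (input, K, alpha, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .kcsd import CSDEstimate

__all__ = [
    "PCAResult",
    "ICAResult",
    "ConvergenceError",
    "pca_truncate",
    "spatial_ica",
    "temporal_ica",
    "spatiotemporal_ica",
    "components_to_maps",
    "SpatialICA",
    "TemporalICA",
    "SpatiotemporalICA",
]


class ConvergenceError(RuntimeError):
    """Raised when no ICA restart reaches the convergence criterion."""


@dataclass
class PCAResult:
    """Truncated SVD of a space x time matrix.

    ``eigenimages`` (n_grid x K) has orthonormal columns, ``singular_values``
    are non-increasing and ``eigensequences`` (K x n_times) has orthonormal
    rows.  Signs are fixed so each eigenimage's largest-magnitude entry is
    positive.
    """

    eigenimages: np.ndarray
    singular_values: np.ndarray
    eigensequences: np.ndarray

    @property
    def k(self) -> int:
        return self.singular_values.size

    def reconstruction(self) -> np.ndarray:
        """The best rank-K approximation ``U_K Gamma_K V_K``."""
        return (self.eigenimages * self.singular_values) @ self.eigensequences


@dataclass
class ICAResult:
    """Independent components of a PCA-truncated CSD matrix.

    ``spatial`` (K x n_grid) and ``temporal`` (K x n_times) have unit-norm
    rows; ``scales`` are the non-negative component amplitudes, ordered
    non-increasing, so that ``sum_k scales[k] * outer(spatial[k],
    temporal[k])`` equals the PCA-truncated input.  ``unmixing`` is the
    K x K matrix W applied to the eigenimages.
    """

    spatial: np.ndarray
    temporal: np.ndarray
    scales: np.ndarray
    unmixing: np.ndarray
    mode: str
    alpha: float
    objective: float
    n_iter: int
    converged: bool

    @property
    def k(self) -> int:
        return self.scales.size

    def reconstruction(self) -> np.ndarray:
        return (self.spatial.T * self.scales) @ self.temporal


def _as_matrix(csd) -> np.ndarray:
    if isinstance(csd, CSDEstimate):
        return csd.values
    return np.asarray(csd, dtype=float)


def pca_truncate(csd, k: int) -> PCAResult:
    """Best rank-``k`` approximation of a CSD matrix (truncated SVD)."""
    X = _as_matrix(csd)
    if not 1 <= k <= min(X.shape):
        raise ValueError(f"k must be in [1, {min(X.shape)}], got {k}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: largest-|.| entry of each eigenimage positive
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    return PCAResult(eigenimages=U * flip, singular_values=s, eigensequences=Vt * flip[:, None])


# ---------------------------------------------------------------------------
# infomax core


def _log_cosh(x: np.ndarray) -> np.ndarray:
    # overflow-safe log cosh
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)


def _objective_and_grad(w: np.ndarray, A, B, alpha: float, k: int):
    """Negative infomax objective and gradient over the unmixing matrix.

    ``A`` (K x n_s) are the scaled eigenimage rows, ``B`` (K x n_t) the
    scaled eigensequence rows carrying the singular-value structure.
    """
    W = w.reshape(k, k)
    sign, logdet = np.linalg.slogdet(W)
    if sign <= 0 or not np.isfinite(logdet):
        return np.inf, np.zeros(k * k)
    f = (2.0 * alpha - 1.0) * logdet
    grad = (2.0 * alpha - 1.0) * np.linalg.inv(W).T
    if alpha > 0.0:
        S = W @ A
        n_s = A.shape[1]
        f += alpha * np.sum(-_log_cosh(S)) / n_s
        grad += alpha * ((-np.tanh(S)) @ A.T) / n_s
    if alpha < 1.0:
        Winv_T = np.linalg.inv(W).T
        T = Winv_T @ B
        n_t = B.shape[1]
        f += (1.0 - alpha) * np.sum(-0.25 * T**4) / n_t
        G_t = -(T**3)
        grad += -(1.0 - alpha) / n_t * (T @ G_t.T) @ Winv_T
    return -f, -grad.ravel()


def _random_orthogonal(k: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(k, k)))
    return q * np.sign(np.diag(r))


def _fit_infomax(
    pca: PCAResult,
    alpha: float,
    seed: int,
    n_restarts: int = 5,
    max_iter: int = 10000,
    tol: float = 1e-9,
    rank_tol: float = 1e-8,
):
    """Maximize the alpha-weighted infomax objective; best of n restarts."""
    k = pca.k
    n_s = pca.eigenimages.shape[0]
    n_t = pca.eigensequences.shape[1]
    s = pca.singular_values
    if s[0] <= 0:
        raise ValueError("input matrix is identically zero")
    # restrict the unmixing search to directions carrying signal: PCA
    # directions with numerically negligible singular values are whitened
    # noise and would otherwise be rotated into the real components
    r = int(np.sum(s >= rank_tol * s[0]))
    if r < k:
        warnings.warn(
            f"input has numerical rank {r} < K={k}; the trailing "
            f"{k - r} component(s) are passed through un-rotated and are "
            "not meaningful"
        )
    r = max(r, 1)
    # scaled coordinates: unit-variance rows on both sides (a fixed,
    # invertible rescaling; the entropy trade-off convention of the package)
    A = np.sqrt(n_s) * pca.eigenimages.T[:r]
    B0 = (s[:r] / s[0])[:, None] * pca.eigensequences[:r]
    B = np.sqrt(n_t) * B0 / np.sqrt(np.mean(B0**2) * r) if alpha < 1.0 else B0

    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(c) for c in ss.spawn(max(n_restarts, 1))]
    best = None
    total_iter = 0
    any_converged = False
    for i, rng in enumerate(rngs):
        W0 = np.eye(r) if i == 0 else _random_orthogonal(r, rng)
        res = minimize(
            _objective_and_grad,
            W0.ravel(),
            args=(A, B, alpha, r),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
        )
        total_iter += res.nit
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        raise ConvergenceError(
            f"no ICA restart converged within {max_iter} iterations "
            f"(best objective {-best.fun:.6g}, grad norm "
            f"{np.linalg.norm(best.jac):.3g}); increase max_iter or restarts"
        )
    W = np.eye(k)
    W[:r, :r] = best.x.reshape(r, r)
    return W, -best.fun, total_iter, any_converged


def _package_result(
    pca: PCAResult, W: np.ndarray, mode: str, alpha: float,
    objective: float, n_iter: int, converged: bool,
) -> ICAResult:
    """Convert an unmixing matrix into ordered, sign-fixed components."""
    S = W @ pca.eigenimages.T  # (K, n_grid)
    T = np.linalg.inv(W).T @ (pca.singular_values[:, None] * pca.eigensequences)
    s_norm = np.linalg.norm(S, axis=1)
    t_norm = np.linalg.norm(T, axis=1)
    s_norm[s_norm == 0] = 1.0
    t_norm[t_norm == 0] = 1.0
    scales = s_norm * t_norm
    S = S / s_norm[:, None]
    T = T / t_norm[:, None]
    order = np.argsort(-scales, kind="stable")
    S, T, scales, W = S[order], T[order], scales[order], W[order]
    flip = np.sign(S[np.arange(S.shape[0]), np.abs(S).argmax(axis=1)])
    flip[flip == 0] = 1.0
    S *= flip[:, None]
    T *= flip[:, None]
    W = W * flip[:, None]
    return ICAResult(
        spatial=S, temporal=T, scales=scales, unmixing=W,
        mode=mode, alpha=alpha, objective=objective,
        n_iter=n_iter, converged=converged,
    )


def _fastica_unmixing(pca: PCAResult, mode: str, seed: int, max_iter: int) -> np.ndarray:
    """Independent cross-check backend (fixed-point ICA)."""
    from sklearn.decomposition import FastICA

    fun = "logcosh" if mode == "spatial" else "cube"
    data = pca.eigenimages if mode == "spatial" else pca.eigensequences.T
    ica = FastICA(
        n_components=pca.k, fun=fun, whiten="unit-variance",
        random_state=np.random.default_rng(seed).integers(0, 2**31),
        max_iter=max_iter if max_iter < 10000 else 1000, tol=1e-6,
    )
    ica.fit(data)
    # sources = data @ components_.T ; express as W acting on eigenimages
    Wh = ica.components_  # (K, K) acting on the data columns
    if mode == "spatial":
        return Wh
    # temporal: sources are rows of Wh V ; the dual W on eigenimages is
    # defined by T = W^-T Gamma V  =>  W = Gamma (Wh)^-1 ... transposed
    return np.linalg.inv(Wh @ np.diag(1.0 / pca.singular_values)).T


def spatial_ica(
    pca: PCAResult,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 10000,
    solver: str = "infomax",
) -> ICAResult:
    """Unmix the eigenimages into spatially independent profiles.

    Uses a heavy-tailed (high-kurtosis) source model, appropriate for
    spatially localized CSD profiles; the time courses are the duals that
    keep the rank-K reconstruction exact.
    """
    if solver == "fastica":
        W = _fastica_unmixing(pca, "spatial", seed, max_iter)
        return _package_result(pca, W, "spatial", 1.0, np.nan, 0, True)
    W, obj, nit, conv = _fit_infomax(pca, 1.0, seed, n_restarts, max_iter)
    return _package_result(pca, W, "spatial", 1.0, obj, nit, conv)


def temporal_ica(
    pca: PCAResult,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 10000,
    solver: str = "infomax",
) -> ICAResult:
    """Unmix the eigensequences into independent time courses.

    Uses a sub-Gaussian (low-kurtosis) source model; spatial profiles are
    the duals.
    """
    if solver == "fastica":
        W = _fastica_unmixing(pca, "temporal", seed, max_iter)
        return _package_result(pca, W, "temporal", 0.0, np.nan, 0, True)
    W, obj, nit, conv = _fit_infomax(pca, 0.0, seed, n_restarts, max_iter)
    return _package_result(pca, W, "temporal", 0.0, obj, nit, conv)


def spatiotemporal_ica(
    pca: PCAResult,
    alpha: float = 0.5,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 10000,
) -> ICAResult:
    """Joint spatial/temporal ICA weighting the two entropies by ``alpha``.

    ``alpha = 1`` reproduces :func:`spatial_ica` exactly, ``alpha = 0``
    :func:`temporal_ica`; the diagonal scaling between the two sides is
    absorbed into the unconstrained unmixing matrix.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    W, obj, nit, conv = _fit_infomax(pca, alpha, seed, n_restarts, max_iter)
    return _package_result(pca, W, "spatiotemporal", alpha, obj, nit, conv)


def components_to_maps(ica: ICAResult) -> np.ndarray:
    """Rank-1 spatiotemporal map of each component: (K, n_grid, n_times).

    The maps sum to the ICA reconstruction (= the PCA-truncated input) and
    are invariant under joint sign flips of a profile and its course.
    """
    return ica.scales[:, None, None] * (
        ica.spatial[:, :, None] * ica.temporal[:, None, :]
    )


# ---------------------------------------------------------------------------
# estimator front-ends


class _BaseICAEstimator(BaseEstimator):
    _mode: str = ""

    def __init__(
        self,
        n_components: int = 5,
        random_state: int = 0,
        n_restarts: int = 5,
        max_iter: int = 10000,
        solver: str = "infomax",
    ):
        self.n_components = n_components
        self.random_state = random_state
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.solver = solver

    def _decompose(self, pca: PCAResult) -> ICAResult:
        raise NotImplementedError

    def fit(self, X, y=None):
        """Fit on a CSDEstimate or a (n_grid, n_times) matrix."""
        pca = pca_truncate(X, self.n_components)
        result = self._decompose(pca)
        self.pca_ = pca
        self.result_ = result
        self.spatial_profiles_ = result.spatial
        self.time_courses_ = result.temporal
        self.scales_ = result.scales
        self.unmixing_ = result.unmixing
        self.objective_ = result.objective
        return self

    def component_maps(self) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        return components_to_maps(self.result_)


class SpatialICA(_BaseICAEstimator):
    """Spatial ICA of a CSD matrix (PCA truncation + infomax unmixing)."""

    _mode = "spatial"

    def _decompose(self, pca: PCAResult) -> ICAResult:
        return spatial_ica(
            pca, seed=self.random_state, n_restarts=self.n_restarts,
            max_iter=self.max_iter, solver=self.solver,
        )


class TemporalICA(_BaseICAEstimator):
    """Temporal ICA of a CSD matrix (sub-Gaussian source model)."""

    _mode = "temporal"

    def _decompose(self, pca: PCAResult) -> ICAResult:
        return temporal_ica(
            pca, seed=self.random_state, n_restarts=self.n_restarts,
            max_iter=self.max_iter, solver=self.solver,
        )


class SpatiotemporalICA(_BaseICAEstimator):
    """Spatiotemporal ICA weighting spatial vs temporal entropy by alpha."""

    _mode = "spatiotemporal"

    def __init__(
        self,
        n_components: int = 5,
        alpha: float = 0.5,
        random_state: int = 0,
        n_restarts: int = 5,
        max_iter: int = 10000,
        solver: str = "infomax",
    ):
        super().__init__(
            n_components=n_components, random_state=random_state,
            n_restarts=n_restarts, max_iter=max_iter, solver=solver,
        )
        self.alpha = alpha

    def _decompose(self, pca: PCAResult) -> ICAResult:
        return spatiotemporal_ica(
            pca, alpha=self.alpha, seed=self.random_state,
            n_restarts=self.n_restarts, max_iter=self.max_iter,
        )
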