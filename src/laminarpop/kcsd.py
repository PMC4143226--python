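"""1D kernel current source density (kCSD) estimation with ridge regression.

The estimator assumes sources are constant on discs of radius ``R``
orthogonal to the measurement line and models the 1D depth profile ``C(z)``
as a combination of ``M`` basis profiles (Gaussian or step) densely covering
the estimation span.  Each basis profile ``b~_i`` maps forward to a
potential profile

    b_i(x) = integral  b~_i(z) * A(x - z) dz,
    A(d)   = (sqrt(d^2 + R^2) - |d|) / (2 sigma),

the closed-form potential of a uniform disc source.  With the kernel
``K(x, x') = sum_i b_i(x) b_i(x')`` evaluated at contact pairs and the
cross-kernel ``K~(z, x) = sum_i b~_i(z) b_i(x)``, the ridge estimate of the
CSD at the grid points is

    C* = K~ . (K + lambda I)^(-1) . V,

applied columnwise over time.  Sign convention: positive CSD = current
source, negative = sink.

``lambda`` is dimensionless in this implementation: the solve uses
``K + lambda * mean(diag K) * I``, so the same numerical value means the
same relative amount of regularization regardless of geometry or units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from sklearn.base import BaseEstimator

from .forward import ElectrodeArray, PotentialRecording

__all__ = [
    "BasisConfig",
    "Basis1D",
    "CSDEstimate",
    "build_basis",
    "basis_potentials",
    "KernelCSD",
    "reconstruct",
    "choose_lambda",
    "traditional_csd",
]


@dataclass
class CSDEstimate:
    """CSD values on an estimation grid: (n_grid, n_times), nA/um^3."""

    grid: np.ndarray
    values: np.ndarray
    lam: float | None = None
    dt: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid depths must be strictly increasing")
        if self.values.shape[0] != self.grid.size:
            raise ValueError("values rows must match grid size")

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


@dataclass
class BasisConfig:
    """Configuration of the kCSD source basis.

    ``n_bases`` (M) must be at least the number of contacts; ``width`` is
    the Gaussian standard deviation (or the step half-support scale) in um;
    ``disc_radius`` (R) the lateral extent of the disc sources; ``span`` the
    depth interval covered by basis centers and the estimation grid.
    """

    n_bases: int
    basis: str = "gaussian"
    width: float = 50.0
    disc_radius: float = 150.0
    span: tuple[float, float] = (0.0, 2700.0)
    n_grid: int = 100

    def __post_init__(self) -> None:
        if self.basis not in ("gaussian", "step"):
            raise ValueError("basis must be 'gaussian' or 'step'")
        if not self.width > 0 or not self.disc_radius > 0:
            raise ValueError("width and disc_radius must be positive")
        lo, hi = self.span
        if not lo < hi:
            raise ValueError("span must be increasing")
        if self.n_bases < 2:
            raise ValueError("need at least 2 basis elements")

    @property
    def tile_halfwidth(self) -> float:
        lo, hi = self.span
        return 0.5 * (hi - lo) / self.n_bases

    def validate_for(self, array: ElectrodeArray) -> None:
        if self.n_bases < array.n_contacts:
            raise ValueError(
                f"n_bases ({self.n_bases}) must be >= number of contacts "
                f"({array.n_contacts})"
            )
        lo, hi = self.span
        if array.depths.min() < lo or array.depths.max() > hi:
            raise ValueError("span must cover the electrode span")


@dataclass
class Basis1D:
    """A concrete basis: centers plus profile evaluation and supports."""

    config: BasisConfig
    centers: np.ndarray

    def profiles(self, z: np.ndarray) -> np.ndarray:
        """Evaluate all basis profiles at depths ``z``: (len(z), M)."""
        z = np.asarray(z, dtype=float)
        d = z[:, None] - self.centers[None, :]
        if self.config.basis == "gaussian":
            return np.exp(-0.5 * (d / self.config.width) ** 2)
        half = self.config.tile_halfwidth
        return ((d >= -half) & (d < half)).astype(float)

    def support(self, i: int) -> tuple[float, float]:
        """Integration support of basis element ``i``."""
        c = self.centers[i]
        if self.config.basis == "gaussian":
            w = 10.0 * self.config.width
        else:
            w = self.config.tile_halfwidth
        return (c - w, c + w)


def build_basis(config: BasisConfig, array: ElectrodeArray | None = None) -> Basis1D:
    """Place ``M`` equally spaced basis elements over the span.

    Gaussian centers run from ``lo`` to ``hi`` inclusive; step elements tile
    the span with disjoint supports.
    """
    if array is not None:
        config.validate_for(array)
    lo, hi = config.span
    if config.basis == "gaussian":
        centers = np.linspace(lo, hi, config.n_bases)
    else:
        h = (hi - lo) / config.n_bases
        centers = lo + h * (np.arange(config.n_bases) + 0.5)
    return Basis1D(config=config, centers=centers)


def _disc_weight(d: np.ndarray, R: float, sigma: float) -> np.ndarray:
    """Axial potential factor of a unit-density disc source (mV per nA/um^3)."""
    return (np.sqrt(d**2 + R**2) - np.abs(d)) / (2.0 * sigma)


def basis_potentials(
    basis: Basis1D,
    points: np.ndarray,
    sigma: float,
    quad_tol: float = 1e-8,
) -> np.ndarray:
    """Forward-map every basis element to potentials at ``points``.

    Adaptive quadrature of ``integral b~_i(z) A(x - z) dz`` per (element,
    point) pair, with the integration interval split at the evaluation
    point (kink of ``|x - z|``).  Returns (len(points), M).
    """
    points = np.asarray(points, dtype=float)
    cfg = basis.config
    M = cfg.n_bases
    out = np.empty((points.size, M))
    # absolute tolerance anchored to the peak of a basis potential
    peak = _disc_weight(np.array(0.0), cfg.disc_radius, sigma) * cfg.width
    for i in range(M):
        lo, hi = basis.support(i)
        for j, x in enumerate(points):
            pts = [x] if lo < x < hi else None
            val, err = integrate.quad(
                lambda z: basis.profiles(np.atleast_1d(z))[0, i]
                * _disc_weight(x - z, cfg.disc_radius, sigma),
                lo,
                hi,
                points=pts,
                epsabs=quad_tol * float(peak),
                epsrel=quad_tol,
                limit=200,
            )
            if not np.isfinite(val) or err > 1e-3 * max(abs(val), float(peak)):
                raise RuntimeError(
                    f"quadrature failed for basis {i} at x={x}: "
                    f"value={val}, error estimate={err}"
                )
            out[j, i] = val
    return out


class KernelCSD(BaseEstimator):
    """Kernel CSD estimator for laminar recordings (sklearn-style).

    Parameters
    ----------
    n_bases : int or None
        Number of basis elements M; default 3x the number of contacts.
    basis : {"gaussian", "step"}
    width : float or None
        Basis width in um; default = inter-contact spacing.
    disc_radius : float
        Disc radius R in um (default 150).
    span : (float, float)
        Depth interval for basis centers and the estimation grid
        (default 0-2700 um).
    n_grid : int
        Number of estimation grid points (default 100).
    lam : float or "cv"
        Dimensionless ridge parameter; "cv" selects it by leave-one-contact-
        out cross-validation over ``lambdas`` at transform time.
    lambdas : sequence of float or None
        CV candidates; default ``logspace(-12, 0, 13)``.

    Attributes (after ``fit``)
    --------------------------
    basis_ : Basis1D
    grid_ : (n_grid,) estimation depths
    K_ : (N_e, N_e) kernel at contact pairs (symmetric PSD)
    Kcross_ : (n_grid, N_e) cross-kernel
    kappa_ : float, mean of diag(K_); the ridge unit
    lambda_ : float, ridge value actually used (set by transform when "cv")
    """

    def __init__(
        self,
        n_bases: int | None = None,
        basis: str = "gaussian",
        width: float | None = None,
        disc_radius: float = 150.0,
        span: tuple[float, float] = (0.0, 2700.0),
        n_grid: int = 100,
        lam: float | str = 1e-8,
        lambdas: np.ndarray | None = None,
        quad_tol: float = 1e-8,
    ):
        self.n_bases = n_bases
        self.basis = basis
        self.width = width
        self.disc_radius = disc_radius
        self.span = span
        self.n_grid = n_grid
        self.lam = lam
        self.lambdas = lambdas
        self.quad_tol = quad_tol

    # -- fitting -----------------------------------------------------------

    def fit(self, recording: PotentialRecording, y=None) -> "KernelCSD":
        """Precompute basis potentials and kernels for this geometry."""
        array = recording.array
        n_bases = self.n_bases if self.n_bases is not None else 3 * array.n_contacts
        width = self.width if self.width is not None else array.pitch
        config = BasisConfig(
            n_bases=n_bases,
            basis=self.basis,
            width=width,
            disc_radius=self.disc_radius,
            span=self.span,
            n_grid=self.n_grid,
        )
        config.validate_for(array)
        self.config_ = config
        self.sigma_ = recording.sigma
        self.depths_ = array.depths.copy()
        self.basis_ = build_basis(config, array)
        self.grid_ = np.linspace(config.span[0], config.span[1], config.n_grid)
        self.phi_contacts_ = basis_potentials(
            self.basis_, array.depths, recording.sigma, self.quad_tol
        )
        self.btilde_grid_ = self.basis_.profiles(self.grid_)
        self.K_ = self.phi_contacts_ @ self.phi_contacts_.T
        self.Kcross_ = self.btilde_grid_ @ self.phi_contacts_.T
        self.kappa_ = float(np.trace(self.K_)) / self.K_.shape[0]
        if isinstance(self.lam, str):
            if self.lam != "cv":
                raise ValueError("lam must be a float or 'cv'")
            self.lambda_ = None
        else:
            self.lambda_ = float(self.lam)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "K_"):
            raise RuntimeError("KernelCSD must be fitted before use")

    def _check_compatible(self, recording: PotentialRecording) -> None:
        self._check_fitted()
        if not np.allclose(recording.array.depths, self.depths_):
            raise ValueError("recording geometry differs from the fitted geometry")
        if not np.isclose(recording.sigma, self.sigma_):
            raise ValueError("recording conductivity differs from the fitted one")

    def _solve(self, V: np.ndarray, lam: float) -> np.ndarray:
        K = self.K_ + lam * self.kappa_ * np.eye(self.K_.shape[0])
        try:
            return np.linalg.solve(K, V)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"kernel system singular at lambda={lam}; use lambda > 0"
            ) from exc

    # -- estimation --------------------------------------------------------

    def transform(self, recording: PotentialRecording) -> CSDEstimate:
        """Reconstruct the CSD of a recording on the estimation grid."""
        self._check_compatible(recording)
        lam = self.lambda_
        if lam is None:
            lam = choose_lambda(recording, estimator=self, lambdas=self.lambdas)
            self.lambda_ = lam
        alpha = self._solve(recording.values, lam)
        values = self.Kcross_ @ alpha
        return CSDEstimate(grid=self.grid_, values=values, lam=lam, dt=recording.dt)

    def fit_transform(self, recording: PotentialRecording, y=None) -> CSDEstimate:
        return self.fit(recording).transform(recording)

    def fitted_potentials(self, recording: PotentialRecording, lam: float | None = None):
        """Potentials implied by the estimate: ``K (K + lam I)^-1 V``."""
        self._check_compatible(recording)
        if lam is None:
            lam = self.lambda_
            if lam is None:
                raise ValueError("no lambda set; pass lam explicitly")
        return self.K_ @ self._solve(recording.values, lam)

    def loo_errors(
        self, recording: PotentialRecording, lambdas: np.ndarray
    ) -> np.ndarray:
        """Leave-one-contact-out squared prediction error per candidate."""
        self._check_compatible(recording)
        V = recording.values
        n_e = V.shape[0]
        if n_e < 3:
            raise ValueError("cross-validation needs at least 3 contacts")
        errs = np.empty(len(lambdas))
        for li, lam in enumerate(lambdas):
            total = 0.0
            for j in range(n_e):
                keep = np.arange(n_e) != j
                Koo = self.K_[np.ix_(keep, keep)] + lam * self.kappa_ * np.eye(n_e - 1)
                pred = self.K_[j, keep] @ np.linalg.solve(Koo, V[keep])
                total += float(np.sum((V[j] - pred) ** 2))
            errs[li] = total
        return errs


def choose_lambda(
    recording: PotentialRecording,
    estimator: KernelCSD | None = None,
    lambdas: np.ndarray | None = None,
    **kcsd_kwargs,
) -> float:
    """Pick the ridge parameter by leave-one-contact-out cross-validation.

    Deterministic; ties are broken toward the smaller candidate.  A single
    candidate is returned as-is.
    """
    if lambdas is None:
        lambdas = np.logspace(-12, 0, 13)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))
    if lambdas.size == 1:
        return float(lambdas[0])
    if estimator is None:
        estimator = KernelCSD(**kcsd_kwargs).fit(recording)
    errs = estimator.loo_errors(recording, lambdas)
    return float(lambdas[int(np.argmin(errs))])  # argmin takes first == smallest


def reconstruct(
    recording: PotentialRecording, lam: float | str = 1e-8, **kcsd_kwargs
) -> CSDEstimate:
    """One-shot kCSD reconstruction (thin wrapper over :class:`KernelCSD`)."""
    return KernelCSD(lam=lam, **kcsd_kwargs).fit(recording).transform(recording)


def traditional_csd(recording: PotentialRecording) -> CSDEstimate:
    """Second-central-difference CSD at interior contacts.

    ``C(z) = -sigma (V(z - h) - 2 V(z) + V(z + h)) / h^2`` for uniformly
    spaced contacts; boundary contacts are excluded.
    """
    depths = recording.array.depths
    if depths.size < 3:
        raise ValueError("traditional CSD needs at least 3 contacts")
    h = recording.array.pitch  # raises on unequal spacing
    V = recording.values
    values = -recording.sigma * (V[:-2] - 2.0 * V[1:-1] + V[2:]) / h**2
    return CSDEstimate(grid=depths[1:-1], values=values, lam=None, dt=recording.dt)
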