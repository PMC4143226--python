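"""Forward modeling of extracellular potentials from current sources.

A point transmembrane current :math:`I_j` at position :math:`x_j` in a
uniform, homogeneous, purely resistive medium of conductivity ``sigma``
contributes

.. math:: V(r) = \\frac{1}{4 \\pi \\sigma} \\frac{I_j}{|r - x_j|}

to the extracellular potential, and contributions from many sources add
linearly.  Equivalently, potential and the volume density of current sources
(CSD) :math:`C` are related by the Poisson equation
:math:`\\sigma \\nabla^2 V = -C`.

Unit system used throughout the package: distances in um, currents in nA,
conductivity in S/m, time in ms.  With these, ``I / (4 pi sigma r)`` comes
out directly in mV, so no conversion constants appear anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy.spatial.distance import cdist

__all__ = [
    "PointSourceSet",
    "LineSourceSet",
    "ElectrodeArray",
    "PotentialRecording",
    "potential_from_points",
    "potential_from_lines",
    "lowpass_lfp",
    "coarse_grain_csd",
]

#: minimal admissible source-contact distance (um); below this the point
#: approximation is meaningless and the potential diverges.
_MIN_DISTANCE = 1e-9


@dataclass
class PointSourceSet:
    """A set of point current sources with time-varying currents.

    Parameters
    ----------
    positions : (n_sources, 3) array
        Source coordinates in um; the third column is depth below the
        cortical surface (positive downward).
    currents : (n_sources, n_times) array
        Transmembrane current of each source in nA.
    dt : float
        Sampling interval in ms.
    labels : (n_sources,) array of str, optional
        Population label per source.  When ``conserve_current`` is set, the
        currents of each labelled group must sum to zero at every time
        sample (no net monopole per population).
    conserve_current : bool
        If True, validate per-group current conservation on construction.
    """

    positions: np.ndarray
    currents: np.ndarray
    dt: float
    labels: np.ndarray | None = None
    conserve_current: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_sources, 3)")
        if self.currents.ndim != 2:
            raise ValueError("currents must have shape (n_sources, n_times)")
        if self.positions.shape[0] != self.currents.shape[0]:
            raise ValueError(
                "positions and currents disagree on source count: "
                f"{self.positions.shape[0]} vs {self.currents.shape[0]}"
            )
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.positions.shape[0]:
                raise ValueError("labels length must match source count")
        if self.conserve_current:
            self._check_conservation()

    def _check_conservation(self, atol_scale: float = 1e-9) -> None:
        groups = (
            [None]
            if self.labels is None
            else list(np.unique(self.labels))
        )
        scale = max(np.abs(self.currents).max(), 1.0)
        for g in groups:
            mask = slice(None) if g is None else self.labels == g
            net = self.currents[mask].sum(axis=0)
            if np.abs(net).max() > atol_scale * scale * self.currents.shape[0]:
                raise ValueError(
                    f"current not conserved for group {g!r}: "
                    f"max |net current| = {np.abs(net).max():.3g} nA"
                )

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    @property
    def n_times(self) -> int:
        return self.currents.shape[1]


@dataclass
class LineSourceSet:
    """Line segments carrying uniformly distributed currents.

    ``starts``/``ends`` are (n_segments, 3) arrays of endpoints in um and
    ``currents`` is (n_segments, n_times) in nA.  Every segment must have
    positive length.
    """

    starts: np.ndarray
    ends: np.ndarray
    currents: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.starts.shape != self.ends.shape or self.starts.shape[1] != 3:
            raise ValueError("starts/ends must both have shape (n_segments, 3)")
        if self.starts.shape[0] != self.currents.shape[0]:
            raise ValueError("endpoints and currents disagree on segment count")
        lengths = np.linalg.norm(self.ends - self.starts, axis=1)
        if np.any(lengths <= 0):
            raise ValueError("every segment must have positive length")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.ends - self.starts, axis=1)


@dataclass
class ElectrodeArray:
    """A laminar probe: contacts along a vertical line.

    ``depths`` are strictly increasing contact depths in um below the
    cortical surface; ``lateral`` is the (x, y) position of the vertical
    line in um.
    """

    depths: np.ndarray
    lateral: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.ndim != 1 or self.depths.size < 1:
            raise ValueError("depths must be a non-empty 1D array")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")

    @property
    def n_contacts(self) -> int:
        return self.depths.size

    @property
    def positions(self) -> np.ndarray:
        """(n_contacts, 3) contact coordinates in um."""
        x, y = self.lateral
        out = np.empty((self.n_contacts, 3))
        out[:, 0] = x
        out[:, 1] = y
        out[:, 2] = self.depths
        return out

    @property
    def pitch(self) -> float:
        """Inter-contact spacing (um); raises if contacts are not uniform."""
        d = np.diff(self.depths)
        if d.size == 0:
            raise ValueError("pitch undefined for a single contact")
        if not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError("contacts are not uniformly spaced")
        return float(d[0])


def uniform_array(
    n_contacts: int = 26,
    pitch: float = 50.0,
    top: float = 150.0,
    lateral: tuple[float, float] = (0.0, 0.0),
) -> ElectrodeArray:
    """Default laminar probe: 26 contacts every 50 um starting at 150 um."""
    depths = top + pitch * np.arange(n_contacts)
    return ElectrodeArray(depths=depths, lateral=lateral)


@dataclass
class PotentialRecording:
    """Potentials on a laminar array: (n_contacts, n_times) matrix in mV."""

    array: ElectrodeArray
    values: np.ndarray
    sigma: float
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D (contacts x time) matrix")
        if self.values.shape[0] != self.array.n_contacts:
            raise ValueError(
                f"values has {self.values.shape[0]} rows but the array has "
                f"{self.array.n_contacts} contacts"
            )
        if not self.sigma > 0:
            raise ValueError("conductivity sigma must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "PotentialRecording":
        return PotentialRecording(
            array=self.array, values=values, sigma=self.sigma, dt=self.dt
        )


def potential_from_points(
    sources: PointSourceSet, array: ElectrodeArray, sigma: float
) -> PotentialRecording:
    """Extracellular potential of point sources on a laminar array.

    ``V_i(t) = (1 / 4 pi sigma) sum_j I_j(t) / |r_i - x_j|``.

    Raises
    ------
    ValueError
        If a source (nearly) coincides with a contact.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    dist = cdist(array.positions, sources.positions)
    if dist.min(initial=np.inf) < _MIN_DISTANCE:
        raise ValueError(
            "degenerate geometry: a source coincides with a contact "
            f"(min distance {dist.min():.3g} um)"
        )
    values = (dist**-1 @ sources.currents) / (4.0 * np.pi * sigma)
    return PotentialRecording(array=array, values=values, sigma=sigma, dt=sources.dt)


def potential_from_lines(
    sources: LineSourceSet, array: ElectrodeArray, sigma: float
) -> PotentialRecording:
    """Extracellular potential of uniform line sources (closed form).

    For a segment of length ``L`` carrying total current ``I`` spread
    uniformly along it, the potential at radial distance ``r`` and
    longitudinal projection coordinate ``xi`` (measured from the segment
    start along its direction) is

    ``V = I / (4 pi sigma L) * [asinh((L - xi)/r) + asinh(xi/r)]``,

    the standard closed form of the line-source integral.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    pos = array.positions  # (n_e, 3)
    a = sources.starts
    b = sources.ends
    L = sources.lengths  # (n_seg,)
    u = (b - a) / L[:, None]
    # xi: longitudinal coordinate of each contact's projection, per segment
    diff = pos[:, None, :] - a[None, :, :]  # (n_e, n_seg, 3)
    xi = np.einsum("esk,sk->es", diff, u)
    r2 = np.einsum("esk,esk->es", diff, diff) - xi**2
    r = np.sqrt(np.maximum(r2, 0.0))
    on_line = r < _MIN_DISTANCE
    inside = on_line & (xi > -_MIN_DISTANCE) & (xi < L[None, :] + _MIN_DISTANCE)
    if np.any(inside):
        raise ValueError(
            "degenerate geometry: a contact lies on a segment within its extent"
        )
    safe_r = np.where(on_line, 1.0, r)
    with np.errstate(divide="ignore", invalid="ignore"):
        # collinear-but-outside contacts use the r -> 0 limit of the integral
        factor = np.where(
            on_line,
            np.abs(np.log(np.abs(xi) / np.abs(xi - L[None, :]))),
            np.arcsinh((L[None, :] - xi) / safe_r) + np.arcsinh(xi / safe_r),
        )
    weights = factor / (4.0 * np.pi * sigma * L[None, :])  # (n_e, n_seg)
    values = weights @ sources.currents
    return PotentialRecording(array=array, values=values, sigma=sigma, dt=sources.dt)


def lowpass_lfp(recording: PotentialRecording, cutoff_hz: float = 500.0) -> PotentialRecording:
    """Zero-phase second-order Butterworth low-pass along time.

    Applied forward-backward (``filtfilt``), so the effective amplitude
    response is the squared single-pass response (gain 0.5 at the cutoff)
    and the phase is exactly zero.  DC gain is 1.
    """
    fs = 1000.0 / recording.dt  # Hz
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={fs / 2} Hz)"
        )
    sos = _signal.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    values = _signal.sosfiltfilt(sos, recording.values, axis=1)
    return recording.copy_with(values)


def coarse_grain_csd(
    sources: PointSourceSet,
    grid: np.ndarray,
    sigma_kernel: float = 80.0,
) -> np.ndarray:
    """Coarse-grained 1D CSD: Gaussian running average of point currents.

    ``C(z, t) = sum_j I_j(t) g(z - z_j)`` with the normalized kernel
    ``g(d) = exp(-d^2 / 2 s^2) / (s sqrt(2 pi))``, ``s = sigma_kernel`` (um,
    default 80).  The kernel is normalized so the depth integral of the map
    equals the total current; units are nA/um.

    Parameters
    ----------
    grid : (n_grid,) array
        Depths (um) at which to evaluate the smoothed density.

    Returns
    -------
    (n_grid, n_times) array
    """
    if not sigma_kernel > 0:
        raise ValueError("sigma_kernel must be positive")
    grid = np.asarray(grid, dtype=float)
    if sources.n_sources == 0:
        warnings.warn("empty source set: coarse-grained CSD is identically zero")
        return np.zeros((grid.size, sources.n_times))
    d = grid[:, None] - sources.positions[None, :, 2]
    g = np.exp(-0.5 * (d / sigma_kernel) ** 2) / (sigma_kernel * np.sqrt(2 * np.pi))
    return g @ sources.currents
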