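"""Synthetic ground-truth generator for multi-population laminar datasets.

Real cortical LFP is generated by a handful of spatially organized cell
populations whose transmembrane currents are, to a good approximation, of
low spatiotemporal rank: the activity of a population is close to a sum of
one or two products (spatial profile) x (time course).  This module builds
such ground truth directly: each population is a cloud of point sources in a
layered cylindrical column whose currents are an exact rank-1 or rank-2
sum of dipolar spatial weight vectors times temporal activation courses,
with per-population current conservation enforced to machine precision.

This parametric generator deliberately spans exactly the structure that the
downstream analysis (kCSD -> PCA -> ICA -> grouping) can in principle
recover; what it does *not* emulate (spiking, synaptic dynamics, morphology,
cross-frequency structure of a real network) is documented in the methods
note.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from .forward import (
    ElectrodeArray,
    PointSourceSet,
    PotentialRecording,
    lowpass_lfp,
    potential_from_points,
    uniform_array,
)

__all__ = [
    "ColumnGeometry",
    "PopulationSpec",
    "Population",
    "GroundTruthDataset",
    "Scenario",
    "default_scenario",
    "build_population",
    "synthesize_dataset",
    "add_noise",
    "shift_population",
    "subsample_electrodes",
]

#: sources are kept at least this radial distance (um) from the probe axis;
#: the probe shank displaces tissue, and a point source micrometers from a
#: contact would dominate the whole recording.
PROBE_EXCLUSION_RADIUS = 30.0


@dataclass
class ColumnGeometry:
    """Layered cylindrical cortical column.

    Default layer depth intervals (um below the surface): layer 2/3 =
    450-850, layer 4 = 850-1150, layer 5 = 1150-1650, layer 6 = 1650-2150;
    column radius 200 um.
    """

    layers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "L2/3": (450.0, 850.0),
            "L4": (850.0, 1150.0),
            "L5": (1150.0, 1650.0),
            "L6": (1650.0, 2150.0),
        }
    )
    radius: float = 200.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        prev_hi = -np.inf
        for name, (lo, hi) in self.layers.items():
            if not lo < hi:
                raise ValueError(f"layer {name!r} interval must be increasing")
            if lo < prev_hi:
                raise ValueError("layer intervals must be non-overlapping and ordered")
            prev_hi = hi

    @property
    def depth_span(self) -> tuple[float, float]:
        his = [hi for _, hi in self.layers.values()]
        return (0.0, max(his))


@dataclass
class PopulationSpec:
    """Parameters of one synthetic population.

    ``rank`` is the number of (spatial profile) x (time course) product
    terms in the population's current pattern; ``amplitude`` its relative
    current strength; ``dipole_extent`` the vertical sink-source separation
    in um.  ``temporal_class`` is one of ``pulse`` (damped burst evoked by a
    brief stimulus), ``oscillatory`` (sustained sinusoid at ``frequency``
    Hz) or ``damped_burst`` (alias of ``pulse``).
    """

    name: str
    depth_range: tuple[float, float]
    n_sources: int = 120
    rank: int = 1
    amplitude: float = 1.0
    temporal_class: str = "pulse"
    frequency: float = 60.0
    dipole_extent: float = 400.0
    lag_ms: float = 0.0
    rank2_amplitude: float = 0.7

    def __post_init__(self) -> None:
        if self.rank not in (1, 2):
            raise ValueError("rank must be 1 or 2")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.n_sources < 2:
            raise ValueError("current conservation needs at least 2 sources")
        if self.temporal_class not in ("pulse", "oscillatory", "damped_burst"):
            raise ValueError(f"unknown temporal class {self.temporal_class!r}")
        lo, hi = self.depth_range
        if not lo < hi:
            raise ValueError("depth_range must be increasing")


@dataclass
class Population:
    """Ground truth for one population: its sources and its own LFP."""

    spec: PopulationSpec
    sources: PointSourceSet
    lfp: PotentialRecording


@dataclass
class GroundTruthDataset:
    """Per-population sources and LFPs plus the total (and noisy) LFP.

    Invariants: ``total.values`` equals the elementwise sum of the
    per-population LFPs exactly, and each population's net current is zero
    at every time sample.
    """

    populations: dict[str, Population]
    total: PotentialRecording
    total_noisy: PotentialRecording
    geometry: ColumnGeometry
    seed: int
    noise_percent: float = 0.0
    noise_seed: int | None = None
    cutoff_hz: float = 500.0

    @property
    def array(self) -> ElectrodeArray:
        return self.total.array

    @property
    def sigma(self) -> float:
        return self.total.sigma

    @property
    def dt(self) -> float:
        return self.total.dt

    def population_names(self) -> list[str]:
        return list(self.populations)


# ---------------------------------------------------------------------------
# temporal courses


def _time_axis(duration: float, dt: float) -> np.ndarray:
    n = int(round(duration / dt))
    return dt * np.arange(n)


def _damped_burst(t: np.ndarray, onset: float, tau: float, freq: float) -> np.ndarray:
    rel = t - onset
    out = np.where(
        rel >= 0, np.exp(-np.maximum(rel, 0.0) / tau) * np.sin(2e-3 * np.pi * freq * rel), 0.0
    )
    return out


def _unit_rms(x: np.ndarray) -> np.ndarray:
    r = np.sqrt(np.mean(x**2))
    if r == 0:
        raise ValueError("degenerate temporal course (identically zero)")
    return x / r


def _temporal_courses(
    spec: PopulationSpec, t: np.ndarray, coupling: float, stimulus_onset: float
) -> np.ndarray:
    """(rank, n_times) unit-RMS rows; exactly orthogonal when rank = 2.

    All populations share a common drive waveform mixed in with weight
    ``coupling`` (at the population's own lag), emulating that real
    populations are strongly coupled rather than independent.
    """
    onset = stimulus_onset + spec.lag_ms
    if spec.temporal_class in ("pulse", "damped_burst"):
        own = _damped_burst(t, onset, tau=10.0, freq=spec.frequency)
        shared = _damped_burst(t, onset, tau=20.0, freq=35.0)
        b1 = (1.0 - coupling) * _unit_rms(own) + coupling * _unit_rms(shared)
        raw2 = _damped_burst(t, onset + 3.0, tau=7.0, freq=1.9 * spec.frequency)
    else:  # oscillatory
        ramp = np.clip((t - stimulus_onset) / 20.0, 0.0, 1.0)
        own = ramp * np.sin(2e-3 * np.pi * spec.frequency * (t - onset))
        shared = ramp * np.sin(2e-3 * np.pi * spec.frequency * (t - stimulus_onset))
        b1 = (1.0 - coupling) * _unit_rms(own) + coupling * _unit_rms(shared)
        raw2 = ramp * np.sin(2e-3 * np.pi * 2.0 * spec.frequency * (t - onset))
    b1 = _unit_rms(b1)
    if spec.rank == 1:
        return b1[None, :]
    b2 = raw2 - (raw2 @ b1) / (b1 @ b1) * b1  # exact orthogonality
    b2 = _unit_rms(b2)
    return np.vstack([b1, b2])


# ---------------------------------------------------------------------------
# spatial profiles


def _dipolar_weights(depths: np.ndarray, spec: PopulationSpec) -> np.ndarray:
    """(rank, n_sources) unit-norm, exactly zero-sum spatial weight vectors.

    The first vector is a two-lobe (sink/source) dipole with vertical lobe
    separation ``dipole_extent``; the rank-2 vector is a three-lobe pattern
    orthogonalized against the first.
    """
    lo, hi = spec.depth_range
    span = hi - lo

    def lobe(center: float, s: float) -> np.ndarray:
        return np.exp(-0.5 * ((depths - center) / s) ** 2)

    if spec.rank == 1:
        center = 0.5 * (lo + hi)
        half = 0.5 * spec.dipole_extent
        # narrow lobes: laminar sinks/sources are thin sheets relative to
        # their separation, and spatial ICA relies on that sparseness
        s = spec.dipole_extent / 10.0
        w1 = lobe(center - half, s) - lobe(center + half, s)
        w1 = w1 - w1.mean()  # exact current conservation
        n1 = np.linalg.norm(w1)
        if n1 == 0:
            raise ValueError("degenerate spatial profile; widen depth range or sources")
        return (w1 / n1)[None, :]

    # rank 2: two interleaved dipoles occupying alternating depth slots
    # (two synaptic pathways targeting staggered dendritic subdomains);
    # interleaving keeps the patterns spatially disjoint, which is what
    # makes them separable as independent spatial components downstream
    s = 0.06 * span
    z = [lo + f * span for f in (0.05, 0.35, 0.65, 0.95)]
    w1 = lobe(z[0], s) - lobe(z[2], s)
    w1 = w1 - w1.mean()
    n1 = np.linalg.norm(w1)
    if n1 == 0:
        raise ValueError("degenerate spatial profile; widen depth range or sources")
    w1 /= n1
    w2 = lobe(z[1], s) - lobe(z[3], s)
    w2 = w2 - w2.mean()
    w2 = w2 - (w2 @ w1) * w1  # w1 is unit norm and zero-sum
    n2 = np.linalg.norm(w2)
    if n2 == 0:
        raise ValueError("degenerate rank-2 spatial profile")
    w2 /= n2
    return np.vstack([w1, w2])


def build_population(
    spec: PopulationSpec,
    geometry: ColumnGeometry,
    dt: float = 0.1,
    duration: float = 90.0,
    seed: int | np.random.SeedSequence = 0,
    coupling: float = 0.3,
    stimulus_onset: float = 20.0,
) -> PointSourceSet:
    """Place a population's sources and build its rank-limited currents.

    Sources are uniform in the spec's depth range within the column radius
    (outside the probe-exclusion cylinder); currents are
    ``amplitude * sum_k lambda_k w_k (x) b_k(t)`` with unit-norm zero-sum
    spatial weights and unit-RMS time courses.  Deterministic given seed.
    """
    lo, hi = spec.depth_range
    g_lo, g_hi = geometry.depth_span
    if lo < g_lo or hi > g_hi:
        raise ValueError(
            f"population {spec.name!r} depth range {spec.depth_range} lies "
            f"outside the modeled column span {geometry.depth_span}"
        )
    rng = np.random.default_rng(seed)
    n = spec.n_sources
    depths = rng.uniform(lo, hi, size=n)
    r_min2 = PROBE_EXCLUSION_RADIUS**2
    r = np.sqrt(rng.uniform(r_min2, geometry.radius**2, size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    positions = np.column_stack([r * np.cos(theta), r * np.sin(theta), depths])

    t = _time_axis(duration, dt)
    b = _temporal_courses(spec, t, coupling, stimulus_onset)
    w = _dipolar_weights(depths, spec)
    lam = np.array([1.0, spec.rank2_amplitude])[: spec.rank]
    currents = spec.amplitude * (w.T * lam) @ b
    labels = np.full(n, spec.name)
    return PointSourceSet(
        positions=positions, currents=currents, dt=dt, labels=labels, conserve_current=True
    )


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class Scenario:
    """A reproducible description of a synthetic study condition."""

    specs: list[PopulationSpec]
    geometry: ColumnGeometry = field(default_factory=ColumnGeometry)
    n_contacts: int = 26
    pitch: float = 50.0
    top_contact: float = 450.0
    sigma: float = 0.3
    dt: float = 0.1
    duration: float = 90.0
    coupling: float = 0.3
    cutoff_hz: float = 500.0
    stimulus_onset: float = 20.0
    noise_percent: float = 0.0

    def make_array(self) -> ElectrodeArray:
        return uniform_array(self.n_contacts, self.pitch, self.top_contact)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"]["layers"] = {k: list(v) for k, v in self.geometry.layers.items()}
        for s in d["specs"]:
            s["depth_range"] = list(s["depth_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = copy.deepcopy(d)
        geo = d.pop("geometry")
        geometry = ColumnGeometry(
            layers={k: tuple(v) for k, v in geo["layers"].items()}, radius=geo["radius"]
        )
        specs = [
            PopulationSpec(**{**s, "depth_range": tuple(s["depth_range"])})
            for s in d.pop("specs")
        ]
        return cls(specs=specs, geometry=geometry, **d)


def default_scenario(temporal_class: str = "pulse", frequency: float = 50.0) -> Scenario:
    """The default three-population study condition.

    Two strong rank-limited pyramidal-like populations (layer 2/3, rank 2;
    layer 5, rank 1) and one weak layer-6 population at relative amplitude
    0.3, on a 26-contact 50-um laminar probe.  Pulse scenarios run 90 ms at
    dt = 0.1 ms (900 samples); oscillatory ones 500 ms (5000 samples).
    """
    geometry = ColumnGeometry()
    osc = temporal_class == "oscillatory"
    specs = [
        # supragranular pyramids: somata in L2/3 but transmembrane
        # currents along the whole dendritic tree, which for deep L3 cells
        # reaches into upper L4 -- hence the source range 450-950 um
        PopulationSpec(
            name="pyr23",
            depth_range=(450.0, 950.0),
            n_sources=400,
            rank=2,
            amplitude=1.0,
            temporal_class=temporal_class,
            frequency=frequency if osc else 75.0,
            dipole_extent=300.0,
            lag_ms=4.0,
            rank2_amplitude=0.7,
        ),
        PopulationSpec(
            name="pyr5",
            depth_range=geometry.layers["L5"],
            n_sources=400,
            rank=1,
            amplitude=1.0,
            temporal_class=temporal_class,
            frequency=frequency if osc else 55.0,
            dipole_extent=300.0,
            lag_ms=7.0,
        ),
        # deep pyramidal population: somata in layer 6 but transmembrane
        # currents concentrated along the proximal apical dendrites, so the
        # source cloud sits in the upper part of L6 / bottom of L5
        PopulationSpec(
            name="pyr6",
            depth_range=(1550.0, 1950.0),
            n_sources=400,
            rank=1,
            amplitude=0.3,
            temporal_class=temporal_class,
            frequency=frequency if osc else 90.0,
            dipole_extent=200.0,
            lag_ms=10.0,
        ),
    ]
    return Scenario(
        specs=specs,
        geometry=geometry,
        duration=500.0 if osc else 90.0,
    )


def synthesize_dataset(scenario: Scenario, seed: int = 0) -> GroundTruthDataset:
    """Build a ground-truth dataset: per-population LFPs and their sum.

    Each population's sources go through the point-source forward model and
    the Butterworth LFP filter; the total LFP is the exact elementwise sum
    of the per-population LFPs.  Noise (``scenario.noise_percent``) is added
    to the total only; ground truth stays clean.
    """
    if not scenario.specs:
        raise ValueError("scenario must contain at least one population")
    array = scenario.make_array()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(scenario.specs) + 1)
    populations: dict[str, Population] = {}
    total = None
    for spec, child in zip(scenario.specs, children[:-1]):
        sources = build_population(
            spec,
            scenario.geometry,
            dt=scenario.dt,
            duration=scenario.duration,
            seed=child,
            coupling=scenario.coupling,
            stimulus_onset=scenario.stimulus_onset,
        )
        raw = potential_from_points(sources, array, scenario.sigma)
        lfp = lowpass_lfp(raw, scenario.cutoff_hz)
        populations[spec.name] = Population(spec=spec, sources=sources, lfp=lfp)
        total = lfp.values if total is None else total + lfp.values
    total_rec = PotentialRecording(
        array=array, values=total, sigma=scenario.sigma, dt=scenario.dt
    )
    dataset = GroundTruthDataset(
        populations=populations,
        total=total_rec,
        total_noisy=total_rec,
        geometry=scenario.geometry,
        seed=seed,
        noise_percent=0.0,
        cutoff_hz=scenario.cutoff_hz,
    )
    if scenario.noise_percent > 0:
        noise_seed = int(np.random.default_rng(children[-1]).integers(0, 2**31))
        dataset = add_noise(dataset, scenario.noise_percent, noise_seed)
    return dataset


def add_noise(
    dataset: GroundTruthDataset, level_percent: float, seed: int = 0
) -> GroundTruthDataset:
    """Add white measurement noise to the total LFP.

    The noise standard deviation is ``level_percent / 100`` times the pooled
    standard deviation of all clean total-LFP values (all contacts, all
    times pooled), drawn i.i.d. and added independently on every electrode.
    Per-population ground truth stays noise-free.
    """
    if level_percent < 0:
        raise ValueError("noise level must be non-negative")
    if level_percent == 0:
        return dataset
    pooled_std = dataset.total.values.std()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, (level_percent / 100.0) * pooled_std, dataset.total.values.shape)
    noisy = dataset.total.copy_with(dataset.total.values + noise)
    return GroundTruthDataset(
        populations=dataset.populations,
        total=dataset.total,
        total_noisy=noisy,
        geometry=dataset.geometry,
        seed=dataset.seed,
        noise_percent=level_percent,
        noise_seed=seed,
        cutoff_hz=dataset.cutoff_hz,
    )


def shift_population(
    dataset: GroundTruthDataset, name: str, shift: float
) -> GroundTruthDataset:
    """Translate one population's sources vertically by ``shift`` um.

    Currents are unchanged (the population's dynamics does not move with
    it); the population's LFP and the total are recomputed.  Noise, if the
    dataset had any, is re-applied at the same level with the stored seed.
    """
    if name not in dataset.populations:
        raise KeyError(f"no population named {name!r}")
    pop = dataset.populations[name]
    new_positions = pop.sources.positions.copy()
    new_positions[:, 2] += shift
    lo, hi = dataset.geometry.depth_span
    if new_positions[:, 2].min() < lo or new_positions[:, 2].max() > hi:
        raise ValueError(
            f"shift {shift} um pushes population {name!r} outside the "
            f"modeled depth span {dataset.geometry.depth_span}"
        )
    new_sources = PointSourceSet(
        positions=new_positions,
        currents=pop.sources.currents,
        dt=pop.sources.dt,
        labels=pop.sources.labels,
        conserve_current=True,
    )
    raw = potential_from_points(new_sources, dataset.array, dataset.sigma)
    new_lfp = lowpass_lfp(raw, dataset.cutoff_hz)
    populations = dict(dataset.populations)
    populations[name] = Population(spec=pop.spec, sources=new_sources, lfp=new_lfp)
    total = sum(p.lfp.values for p in populations.values())
    total_rec = dataset.total.copy_with(np.asarray(total))
    out = GroundTruthDataset(
        populations=populations,
        total=total_rec,
        total_noisy=total_rec,
        geometry=dataset.geometry,
        seed=dataset.seed,
        noise_percent=0.0,
        cutoff_hz=dataset.cutoff_hz,
    )
    if dataset.noise_percent > 0:
        out = add_noise(out, dataset.noise_percent, dataset.noise_seed or 0)
    return out


def subsample_electrodes(recording: PotentialRecording, n: int) -> PotentialRecording:
    """Keep ``n`` regularly spaced contacts spanning the largest extent.

    Uses the arithmetic stride ``s = (N - 1) // (n - 1)`` starting from the
    first contact, the nearest feasible regular subsampling that always
    includes the first contact and reaches as deep as an equal-stride
    selection can (for ``n = 2`` this is exactly the two extreme contacts;
    for 13 of 26 it is every second contact).
    """
    n_e = recording.array.n_contacts
    if not 2 <= n <= n_e:
        raise ValueError(f"n must be in [2, {n_e}], got {n}")
    if n == n_e:
        return recording
    stride = (n_e - 1) // (n - 1)
    idx = stride * np.arange(n)
    array = ElectrodeArray(
        depths=recording.array.depths[idx], lateral=recording.array.lateral
    )
    return PotentialRecording(
        array=array, values=recording.values[idx], sigma=recording.sigma, dt=recording.dt
    )
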