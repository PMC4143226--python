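"""Forward model: point/line source potentials, LFP filter, coarse CSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laminarpop.forward import (
    ElectrodeArray,
    LineSourceSet,
    PointSourceSet,
    PotentialRecording,
    coarse_grain_csd,
    lowpass_lfp,
    potential_from_lines,
    potential_from_points,
    uniform_array,
)

SIGMA = 0.3


def _sources(positions, currents, dt=0.1):
    return PointSourceSet(
        positions=np.asarray(positions, float),
        currents=np.asarray(currents, float),
        dt=dt,
    )


class TestPointSources:
    def test_unit_identity(self):
        # a current of 4*pi*sigma nA at 1 um distance gives exactly 1 mV
        array = ElectrodeArray(depths=np.array([0.0]))
        src = _sources([[1.0, 0.0, 0.0]], [[4 * np.pi * SIGMA]])
        rec = potential_from_points(src, array, SIGMA)
        assert rec.values[0, 0] == pytest.approx(1.0, rel=1e-12)

    def test_zero_currents_zero_potentials(self):
        array = uniform_array(5)
        src = _sources(np.random.default_rng(0).uniform(10, 100, (7, 3)), np.zeros((7, 4)))
        rec = potential_from_points(src, array, SIGMA)
        assert np.all(rec.values == 0)

    def test_superposition_against_scalar_oracle(self, rng):
        """Vectorized potentials equal a per-source scalar-loop evaluation."""
        array = uniform_array(8)
        pos = rng.uniform(50, 800, (5, 3))
        cur = rng.normal(size=(5, 3))
        rec = potential_from_points(_sources(pos, cur), array, SIGMA)
        expected = np.zeros_like(rec.values)
        for j in range(5):  # independent scalar oracle
            for i, p in enumerate(array.positions):
                d = np.sqrt(((p - pos[j]) ** 2).sum())
                expected[i] += cur[j] / (4 * np.pi * SIGMA * d)
        np.testing.assert_allclose(rec.values, expected, rtol=1e-13)

    def test_one_over_r_law(self):
        array1 = ElectrodeArray(depths=np.array([100.0]))
        array2 = ElectrodeArray(depths=np.array([200.0]))
        src = _sources([[0.0, 0.0, 0.0]], [[1.0]])
        v1 = potential_from_points(src, array1, SIGMA).values[0, 0]
        v2 = potential_from_points(src, array2, SIGMA).values[0, 0]
        assert v1 == pytest.approx(2 * v2, rel=1e-14)

    def test_dipole_decays_faster_than_monopole(self):
        # current-conserving pair: far-field potential falls faster than 1/r
        src = _sources([[0, 0, -10.0], [0, 0, 10.0]], [[1.0], [-1.0]])
        far = ElectrodeArray(depths=np.array([1000.0, 2000.0]))
        v = potential_from_points(src, far, SIGMA).values[:, 0]
        assert abs(v[1] / v[0]) < 0.5

    def test_coincident_source_raises(self):
        array = ElectrodeArray(depths=np.array([100.0]))
        src = _sources([[0.0, 0.0, 100.0]], [[1.0]])
        with pytest.raises(ValueError, match="degenerate"):
            potential_from_points(src, array, SIGMA)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_superposition_over_partitions(self, seed):
        """Splitting the source set in two and summing changes nothing."""
        r = np.random.default_rng(seed)
        array = uniform_array(4)
        pos = r.uniform(30, 500, (6, 3))
        cur = r.normal(size=(6, 2))
        full = potential_from_points(_sources(pos, cur), array, SIGMA).values
        a = potential_from_points(_sources(pos[:3], cur[:3]), array, SIGMA).values
        b = potential_from_points(_sources(pos[3:], cur[3:]), array, SIGMA).values
        np.testing.assert_allclose(full, a + b, rtol=1e-12, atol=1e-15)


class TestLineSources:
    def test_zero_currents(self):
        array = uniform_array(4)
        lines = LineSourceSet(
            starts=[[0, 0, 0]], ends=[[0, 0, 50.0]], currents=np.zeros((1, 3)), dt=0.1
        )
        assert np.all(potential_from_lines(lines, array, SIGMA).values == 0)

    def test_matches_dense_point_quadrature(self):
        """A segment agrees with 1000 point sources along it to < 0.5%."""
        seg = LineSourceSet(
            starts=[[50.0, 0, 200.0]], ends=[[50.0, 0, 300.0]],
            currents=[[2.0]], dt=0.1,
        )
        array = uniform_array(10, pitch=100.0, top=0.0)
        v_line = potential_from_lines(seg, array, SIGMA).values[:, 0]
        n = 1000
        frac = (np.arange(n) + 0.5) / n
        pts = seg.starts[0] + frac[:, None] * (seg.ends[0] - seg.starts[0])
        v_pts = potential_from_points(
            _sources(pts, np.full((n, 1), 2.0 / n)), array, SIGMA
        ).values[:, 0]
        np.testing.assert_allclose(v_line, v_pts, rtol=5e-3)

    def test_far_field_equals_point_source(self):
        seg = LineSourceSet(
            starts=[[0, 0, 0]], ends=[[0, 0, 20.0]], currents=[[1.0]], dt=0.1
        )
        array = ElectrodeArray(depths=np.array([5000.0]))
        v_line = potential_from_lines(seg, array, SIGMA).values[0, 0]
        v_point = potential_from_points(
            _sources([[0, 0, 10.0]], [[1.0]]), array, SIGMA
        ).values[0, 0]
        assert v_line == pytest.approx(v_point, rel=1e-2)

    def test_contact_on_segment_raises(self):
        seg = LineSourceSet(
            starts=[[0, 0, 0]], ends=[[0, 0, 200.0]], currents=[[1.0]], dt=0.1
        )
        array = ElectrodeArray(depths=np.array([100.0]))
        with pytest.raises(ValueError, match="degenerate"):
            potential_from_lines(seg, array, SIGMA)


class TestLowpass:
    def _rec(self, values, dt=0.1):
        array = uniform_array(values.shape[0])
        return PotentialRecording(array=array, values=values, sigma=SIGMA, dt=dt)

    def test_dc_passes_unchanged(self):
        rec = self._rec(np.full((3, 400), 2.5))
        out = lowpass_lfp(rec, 500.0)
        np.testing.assert_allclose(out.values, rec.values, atol=1e-10)

    def test_cutoff_gain_is_half(self):
        # zero-phase application squares the half-power single-pass gain
        dt = 0.1
        t = dt * np.arange(40000)
        f = 500.0
        x = np.sin(2e-3 * np.pi * f * t)[None, :]
        out = lowpass_lfp(self._rec(x, dt), f)
        mid = slice(10000, 30000)  # avoid edges
        gain = out.values[0, mid].std() / x[0, mid].std()
        assert gain == pytest.approx(0.5, abs=0.01)

    def test_linearity(self, rng):
        x = rng.normal(size=(2, 300))
        y = rng.normal(size=(2, 300))
        fx = lowpass_lfp(self._rec(x)).values
        fy = lowpass_lfp(self._rec(y)).values
        fxy = lowpass_lfp(self._rec(3.0 * x - 0.5 * y)).values
        np.testing.assert_allclose(fxy, 3.0 * fx - 0.5 * fy, rtol=1e-10, atol=1e-12)

    def test_idempotent_on_band_limited(self):
        # content far below the cutoff is untouched by a second pass
        dt = 0.1
        t = dt * np.arange(4000)
        x = (np.sin(2e-3 * np.pi * 5.0 * t) + 0.5 * np.sin(2e-3 * np.pi * 10.0 * t))[None, :]
        once = lowpass_lfp(self._rec(x, dt), 500.0)
        twice = lowpass_lfp(once, 500.0)
        mid = slice(400, 3600)
        err = np.abs(twice.values[:, mid] - once.values[:, mid]).max()
        assert err < 1e-6 * np.abs(once.values).max()

    def test_cutoff_above_nyquist_rejected(self):
        rec = self._rec(np.zeros((2, 100)))
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_lfp(rec, 6000.0)


class TestCoarseGrain:
    def test_single_source_gaussian_bump(self):
        src = _sources([[0, 0, 500.0]], [[1.0]])
        grid = np.linspace(0, 1000, 101)
        m = coarse_grain_csd(src, grid, sigma_kernel=80.0)
        assert grid[np.argmax(m[:, 0])] == pytest.approx(500.0, abs=10.0)

    def test_mass_conservation(self, rng):
        pos = np.column_stack([np.zeros((20, 2)), rng.uniform(400, 600, 20)])
        cur = rng.normal(size=(20, 1))
        grid = np.linspace(0, 1000, 2001)
        m = coarse_grain_csd(_sources(pos, cur), grid, sigma_kernel=50.0)
        total = np.trapezoid(m[:, 0], grid)
        assert total == pytest.approx(cur.sum(), rel=1e-6)

    def test_delta_limit_matches_histogram(self, rng):
        # sources placed away from bin edges so kernel mass stays in-bin
        depths = 50.0 * rng.integers(2, 18, 50) + rng.uniform(10, 40, 50)
        pos = np.column_stack([np.zeros((50, 2)), depths])
        cur = rng.normal(size=(50, 1))
        edges = np.linspace(0, 1000, 21)
        grid = np.linspace(0, 1000, 5001)
        m = coarse_grain_csd(_sources(pos, cur), grid, sigma_kernel=1.0)[:, 0]
        hist, _ = np.histogram(depths, bins=edges, weights=cur[:, 0])
        binned = np.array(
            [np.trapezoid(m[(grid >= a) & (grid <= b)], grid[(grid >= a) & (grid <= b)])
             for a, b in zip(edges[:-1], edges[1:])]
        )
        np.testing.assert_allclose(binned, hist, atol=1e-3 * np.abs(hist).max())

    def test_empty_sources_warns(self):
        src = _sources(np.empty((0, 3)), np.empty((0, 4)))
        with pytest.warns(UserWarning, match="empty"):
            m = coarse_grain_csd(src, np.linspace(0, 100, 5))
        assert m.shape == (5, 4) and np.all(m == 0)
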