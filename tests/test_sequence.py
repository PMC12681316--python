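"""Steady-state signal equations, normalization and the slice dictionary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfcurrent import (
    PulseSpec,
    SequenceParams,
    SliceProfileDictionary,
    afi_signals,
    build_slice_dictionary,
    lookup_signals,
    normalize_voxel,
)
from rfcurrent.sequence import slice_profile


class TestAfiSignals:
    def test_zero_lambda_gives_zero(self, seq):
        for which in "ab":
            s1, s2 = afi_signals(0.0, 1000.0, seq, which)
            assert s1 == 0.0 and s2 == 0.0

    def test_symmetric_exchange(self):
        # identical flip angles and TRs make the two interleaves equal
        seq = SequenceParams(
            alpha_a1=40.0, alpha_a2=40.0, tr_a1=30.0, tr_a2=30.0
        )
        s1, s2 = afi_signals(0.8, 900.0, seq, "a")
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_fully_relaxed_limit(self, seq):
        # TR >> T1: spoiled GRE signals reduce to sin of the actual flip
        lam = 0.7
        s1, s2 = afi_signals(lam, 1e-6, seq, "a")
        assert s1 == pytest.approx(np.sin(np.deg2rad(seq.alpha_a1) * lam), rel=1e-6)
        assert s2 == pytest.approx(np.sin(np.deg2rad(seq.alpha_a2) * lam), rel=1e-6)

    def test_classic_afi_flip_estimator(self):
        """With equal flip angles and short TRs the signal ratio obeys the
        classic AFI estimator cos(λα) ≈ (r·n − 1)/(n − r) to within 1%."""
        t1 = 1000.0
        tr1, tr2 = 10.0, 50.0  # TR1/T1 = 0.01
        alpha = 60.0
        seq = SequenceParams(
            alpha_a1=alpha, alpha_a2=alpha, tr_a1=tr1, tr_a2=tr2
        )
        n = tr2 / tr1
        for lam_alpha_deg in np.linspace(5.0, 85.0, 17):
            lam = lam_alpha_deg / alpha
            s1, s2 = afi_signals(lam, t1, seq, "a")
            r = s2 / s1
            est = (r * n - 1.0) / (n - r)
            assert abs(est - np.cos(np.deg2rad(lam_alpha_deg))) < 0.01

    def test_invalid_inputs(self, seq):
        with pytest.raises(ValueError):
            afi_signals(1.0, -5.0, seq, "a")
        with pytest.raises(ValueError):
            afi_signals(1.0, 1000.0, seq, "c")
        with pytest.raises(ValueError):
            SequenceParams(tr_a1=0.0)
        with pytest.raises(ValueError):
            SequenceParams(alpha_b2=190.0)


class TestNormalize:
    @pytest.mark.parametrize(
        "signals, expected",
        [
            ((1.0, 1.0, 1.0, 1.0), (0.5, 0.5, 0.5, 0.5)),
            ((3.0, 4.0, 0.0, 0.0), (0.6, 0.8, 0.0, 0.0)),
        ],
    )
    def test_examples(self, signals, expected):
        assert normalize_voxel(signals) == pytest.approx(expected)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            normalize_voxel((0.0, 0.0, 0.0, 0.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        s=st.lists(
            st.floats(min_value=0.0, max_value=1e3), min_size=4, max_size=4
        ).filter(lambda v: sum(v) > 1e-6),
        k=st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_unit_norm_and_scale_invariance(self, s, k):
        """The normalized 4-vector has unit norm and is invariant under
        any positive per-voxel scale — the property that removes B1−,
        proton density and T2* weighting."""
        out = normalize_voxel(s)
        assert np.linalg.norm(out) == pytest.approx(1.0, rel=1e-9)
        np.testing.assert_allclose(out, normalize_voxel(np.array(s) * k),
                                   rtol=1e-9, atol=1e-12)


class TestSliceProfile:
    def test_bloch_profile_shape(self):
        z, p = slice_profile(PulseSpec())
        assert p[len(p) // 2] == pytest.approx(1.0)
        # passband near 1 inside the slice, decayed outside
        inside = np.abs(z) < 0.3
        outside = np.abs(z) > 1.5
        assert p[inside].min() > 0.8
        assert p[outside].max() < 0.15

    def test_boxcar_profile(self):
        z, p = slice_profile(PulseSpec(shape="boxcar"))
        assert set(np.unique(p)) <= {0.0, 1.0}
        assert p[np.abs(z) <= 0.5].min() == 1.0


class TestDictionary:
    def test_zero_row(self, dictionary):
        assert np.allclose(dictionary.lookup(0.0), 0.0)

    def test_exact_at_grid_nodes(self, dictionary):
        k = 137
        lam = dictionary.lambda_grid[k]
        np.testing.assert_allclose(dictionary.lookup(lam), dictionary.signals[k])

    def test_midpoint_is_mean_of_neighbors(self, dictionary):
        k = 512
        lam = 0.5 * (dictionary.lambda_grid[k] + dictionary.lambda_grid[k + 1])
        expected = 0.5 * (dictionary.signals[k] + dictionary.signals[k + 1])
        np.testing.assert_allclose(dictionary.lookup(lam), expected, rtol=1e-12)

    def test_out_of_range_raises(self, dictionary):
        with pytest.raises(ValueError):
            dictionary.lookup(dictionary.lambda_max + 1.0)
        with pytest.raises(ValueError):
            dictionary.lookup(-0.1)

    def test_monotone_near_zero(self, dictionary):
        sel = dictionary.lambda_grid < 0.2
        assert np.all(np.diff(dictionary.signals[sel], axis=0) > 0)

    def test_boxcar_matches_in_slice_closed_form(self, seq):
        """With an ideal rectangular profile the dictionary equals the
        closed-form signals scaled by the in-slice fraction of the
        averaging window."""
        pulse = PulseSpec(shape="boxcar", n_positions=201, extent_factor=2.0)
        grid = np.linspace(0.0, 3.0, 31)
        d = build_slice_dictionary(seq, pulse=pulse, t1=800.0, grid=grid)
        z, p = slice_profile(pulse)
        frac = p.mean()  # fraction of through-plane positions inside the slice
        for j, (which, idx) in enumerate([("a", 0), ("a", 1), ("b", 0), ("b", 1)]):
            s = afi_signals(grid, 800.0, seq, which)[idx]
            np.testing.assert_allclose(d.signals[:, j], s * frac, rtol=1e-10)

    def test_lookup_matches_direct_computation(self, seq, dictionary):
        """Interpolated lookup reproduces direct through-plane averaging at
        arbitrary λ to well below the grid-resolution tolerance."""
        z, p = slice_profile(PulseSpec())
        rng = np.random.default_rng(3)
        lam = rng.uniform(0.05, 25.0, 40)
        direct = np.empty((lam.size, 4))
        for j, (which, idx) in enumerate([("a", 0), ("a", 1), ("b", 0), ("b", 1)]):
            s = afi_signals(lam[:, None] * p[None, :], 1000.0, seq, which)[idx]
            direct[:, j] = s.mean(axis=1)
        looked = dictionary.lookup(lam)
        assert np.max(np.abs(looked - direct)) < 2e-5

    def test_t1_robustness_of_normalized_vectors(self, seq):
        """Normalized signal vectors move only modestly under a 30% T1
        mismatch across the working λ range."""
        d1 = build_slice_dictionary(seq, t1=1000.0)
        d2 = build_slice_dictionary(seq, t1=1300.0)
        lam = np.linspace(0.2, 3.0, 30)
        s1 = np.abs(d1.lookup(lam))
        s2 = np.abs(d2.lookup(lam))
        n1 = s1 / np.linalg.norm(s1, axis=-1, keepdims=True)
        n2 = s2 / np.linalg.norm(s2, axis=-1, keepdims=True)
        assert np.max(np.abs(n1 - n2)) < 0.08

    def test_csv_round_trip(self, dictionary, tmp_path):
        path = tmp_path / "dict.csv"
        dictionary.to_csv(path)
        loaded = SliceProfileDictionary.from_csv(path)
        np.testing.assert_allclose(loaded.lambda_grid, dictionary.lambda_grid)
        np.testing.assert_allclose(loaded.signals, dictionary.signals, atol=1e-9)
        assert loaded.profile_meta == dictionary.profile_meta

    def test_invalid_grid_rejected(self, seq):
        with pytest.raises(ValueError):
            build_slice_dictionary(seq, grid=np.array([0.0, 0.0, 1.0]))

    def test_lookup_signals_wrapper(self, dictionary):
        np.testing.assert_allclose(
            lookup_signals(dictionary, 1.0), dictionary.lookup(1.0)
        )
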