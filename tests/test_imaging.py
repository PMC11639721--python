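"""Image-encoding correctness against brute-force oracles and hand values."""

import numpy as np
import pytest

from ecgfusion.imaging import (
    ImagingConfig,
    encode_beat,
    fuse,
    gadf,
    gasf,
    mtf,
    normalize,
    recurrence,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles (explicit loops, no vectorised shortcuts)
# ---------------------------------------------------------------------------

def _oracle_gasf(x):
    n = len(x)
    lo, hi = min(x), max(x)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            xi = ((x[i] - hi) + (x[i] - lo)) / (hi - lo)
            xj = ((x[j] - hi) + (x[j] - lo)) / (hi - lo)
            out[i, j] = np.cos(np.arccos(xi) + np.arccos(xj))
    return out


def _oracle_gadf(x, variant):
    n = len(x)
    lo, hi = min(x), max(x)
    fn = np.cos if variant == "paper" else np.sin
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            xi = ((x[i] - hi) + (x[i] - lo)) / (hi - lo)
            xj = ((x[j] - hi) + (x[j] - lo)) / (hi - lo)
            out[i, j] = fn(np.arccos(xi) - np.arccos(xj))
    return out


def _oracle_rp(x, eps):
    n = len(x)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = 1.0 if abs(x[i] - x[j]) <= eps else 0.0
    return out


def _oracle_mtf(x, q):
    n = len(x)
    edges = np.quantile(x, np.linspace(0, 1, q + 1))
    edges = np.unique(edges)
    interior = edges[1:-1]

    def bin_of(v):
        b = 0
        for e in interior:
            if v >= e:
                b += 1
        return b

    nbins = max(bin_of(max(x)) + 1, 1)
    counts = np.zeros((nbins, nbins))
    for k in range(n - 1):
        counts[bin_of(x[k]), bin_of(x[k + 1])] += 1
    W = np.empty_like(counts)
    for i in range(nbins):
        s = counts[i].sum()
        W[i] = counts[i] / s if s > 0 else 1.0 / nbins
    out = np.empty((n, n))
    for k in range(n):
        for l in range(n):
            out[k, l] = W[bin_of(x[k]), bin_of(x[l])]
    return out


# ---------------------------------------------------------------------------
# hand-derived examples
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_endpoints_forced(self):
        np.testing.assert_allclose(
            normalize([0, 10], "[-1,1]").values, [-1, 1], atol=1e-12
        )

    def test_midpoint(self):
        np.testing.assert_allclose(
            normalize([0, 5, 10], "[-1,1]").values, [-1, 0, 1], atol=1e-12
        )

    def test_unit_range_mode(self):
        np.testing.assert_allclose(
            normalize([0, 5, 10], "[0,1]").values, [0, 0.5, 1], atol=1e-12
        )

    def test_constant_degenerates_to_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize([3.0, 3.0, 3.0])
        np.testing.assert_array_equal(out.values, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize([])


class TestGramianFields:
    def test_gasf_hand_example(self):
        # x~ = [-1, 0, 1] -> phi = (pi, pi/2, 0)
        expected = [[1, 0, -1], [0, -1, 0], [-1, 0, 1]]
        np.testing.assert_allclose(
            gasf(np.array([-1.0, 0.0, 1.0])), expected, atol=1e-12
        )

    def test_gasf_all_zero_series(self):
        np.testing.assert_allclose(gasf(np.zeros(5)), -1.0, atol=1e-12)

    def test_gadf_paper_hand_example(self):
        expected = [[1, 0, -1], [0, 1, 0], [-1, 0, 1]]
        np.testing.assert_allclose(
            gadf(np.array([-1.0, 0.0, 1.0]), "paper"), expected, atol=1e-12
        )

    def test_gadf_paper_unit_diagonal(self):
        x = np.random.default_rng(0).uniform(-1, 1, 20)
        np.testing.assert_allclose(np.diag(gadf(x, "paper")), 1.0, atol=1e-12)

    def test_gadf_standard_antisymmetric_zero_diagonal(self):
        x = np.random.default_rng(1).uniform(-1, 1, 20)
        m = gadf(x, "standard")
        np.testing.assert_allclose(np.diag(m), 0.0, atol=1e-12)
        np.testing.assert_allclose(m, -m.T, atol=1e-12)

    def test_gasf_diagonal_identity(self):
        """diag(GASF) = 2 x~^2 - 1 for 100 random series."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.uniform(-1, 1, rng.integers(4, 32))
            np.testing.assert_allclose(
                np.diag(gasf(x)), 2 * x**2 - 1, atol=1e-9
            )

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            gasf(np.array([0.0, 1.5]))


class TestRecurrence:
    def test_hand_example(self):
        expected = [[1, 1, 0], [1, 1, 1], [0, 1, 1]]
        np.testing.assert_array_equal(
            recurrence(np.array([0.0, 1.0, 2.0]), 1.5, "binary"), expected
        )

    def test_epsilon_above_range_gives_all_ones(self):
        x = np.random.default_rng(0).normal(size=12)
        np.testing.assert_array_equal(
            recurrence(x, x.max() - x.min(), "binary"), 1.0
        )

    def test_distance_mode_zero_diagonal(self):
        x = np.random.default_rng(1).normal(size=12)
        m = recurrence(x, mode="distance")
        np.testing.assert_array_equal(np.diag(m), 0.0)
        np.testing.assert_allclose(m, m.T)

    def test_monotone_in_epsilon(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=16)
        prev = recurrence(x, 0.0, "binary")
        for eps in np.linspace(0.05, 3.0, 20):
            cur = recurrence(x, eps, "binary")
            assert np.all(cur >= prev)  # a 1 never becomes a 0
            prev = cur

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            recurrence(np.zeros(4), -0.1, "binary")


class TestMtf:
    def test_hand_enumerated_example(self):
        m, tm = mtf(np.array([1.0, 2.0, 3.0, 4.0]), 2)
        np.testing.assert_allclose(tm.W, [[0.5, 0.5], [0.0, 1.0]])
        expected = [
            [0.5, 0.5, 0.5, 0.5],
            [0.5, 0.5, 0.5, 0.5],
            [0.0, 0.0, 1.0, 1.0],
            [0.0, 0.0, 1.0, 1.0],
        ]
        np.testing.assert_allclose(m, expected)

    def test_constant_series_is_all_ones(self):
        with pytest.warns(UserWarning):
            m, _ = mtf(np.full(6, 2.0), 4)
        np.testing.assert_array_equal(m, 1.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            _, tm = mtf(rng.normal(size=rng.integers(8, 40)), 8)
            np.testing.assert_allclose(tm.W.sum(axis=1), 1.0, atol=1e-9)
            assert (tm.W >= 0).all()

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            mtf(np.arange(5.0), 1)


class TestOracleEquivalence:
    """Each encoder matches an explicit double/triple-loop implementation."""

    def test_all_encoders_match_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 33))
            x = rng.normal(size=n)
            xn = normalize(x, "[-1,1]").values
            np.testing.assert_allclose(gasf(xn), _oracle_gasf(x), atol=1e-9)
            np.testing.assert_allclose(
                gadf(xn, "paper"), _oracle_gadf(x, "paper"), atol=1e-9
            )
            np.testing.assert_allclose(
                gadf(xn, "standard"), _oracle_gadf(x, "standard"), atol=1e-9
            )
            eps = float(rng.uniform(0.1, 2.0))
            np.testing.assert_allclose(
                recurrence(x, eps, "binary"), _oracle_rp(x, eps), atol=1e-9
            )
            q = int(rng.integers(2, 6))
            np.testing.assert_allclose(mtf(x, q)[0], _oracle_mtf(x, q), atol=1e-9)


class TestFuse:
    def test_channel_axis_order_and_shape(self):
        a, b, c = (np.full((4, 4), v) for v in (1.0, 2.0, 3.0))
        stack = fuse(a, b, c, "channel")
        assert stack.channels.shape == (3, 4, 4)
        np.testing.assert_array_equal(stack.channels[0], a)
        assert stack.channel_names == ["RP", "GAF", "MTF"]

    def test_height_axis_shape(self):
        a = np.zeros((4, 4))
        assert fuse(a, a, a, "height").channels.shape == (1, 12, 4)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.zeros((4, 4)), np.zeros((5, 5)), np.zeros((4, 4)))


class TestEncodeBeat:
    def test_ranges_and_symmetry_of_fused_stack(self):
        """GAF in [-1,1], MTF in [0,1], binary RP in {0,1}; RP/GASF symmetric."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            beat = rng.normal(size=32)
            rp, gaf_img, mtf_img = encode_beat(beat).channels
            assert set(np.unique(rp)) <= {0.0, 1.0}
            assert gaf_img.min() >= -1 - 1e-12 and gaf_img.max() <= 1 + 1e-12
            assert mtf_img.min() >= -1e-12 and mtf_img.max() <= 1 + 1e-12
            np.testing.assert_allclose(rp, rp.T)
            np.testing.assert_allclose(gaf_img, gaf_img.T, atol=1e-12)

    def test_gadf_variant_selectable(self):
        beat = np.random.default_rng(0).normal(size=16)
        cfg = ImagingConfig(gaf_kind="gadf", gadf_variant="standard")
        gaf_img = encode_beat(beat, cfg).channels[1]
        np.testing.assert_allclose(np.diag(gaf_img), 0.0, atol=1e-12)
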