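"""GR-KAN layer: safe Padé evaluation, grouped forward pass, variance-
preserving initialization and parameter accounting, each checked against
independent scalar oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mctgnet import (
    RationalFunctionParams,
    RationalGroupLayer,
    count_learnables,
    eval_rational,
    grkan_forward,
    init_variance_preserving,
)


def horner_rational(num, den, scale, x):
    """Scalar digit-by-digit Horner oracle for the safe Padé unit."""
    p = 0.0
    for a in reversed(num):
        p = p * x + a
    q = 0.0
    for b in reversed(den):
        q = q * x + b
    q *= x  # denominator polynomial has no constant term
    return scale * p / (1.0 + abs(q))


def random_params(rng, m=5, n=4):
    return RationalFunctionParams(
        rng.standard_normal(m + 1), rng.standard_normal(n), float(rng.standard_normal())
    )


class TestEvalRational:
    def test_linear_numerator_zero_denominator(self):
        p = RationalFunctionParams([0.0, 1.0], np.zeros(4), scale=2.0)
        assert eval_rational(p, 3.0) == pytest.approx(6.0)

    def test_origin_returns_scaled_constant(self, rng):
        p = random_params(rng)
        assert eval_rational(p, 0.0) == pytest.approx(p.scale * p.numerator_coeffs[0])

    def test_matches_horner_oracle_on_grid(self, rng):
        xs = np.linspace(-10, 10, 101)
        for _ in range(50):
            p = random_params(rng)
            expected = np.array(
                [
                    horner_rational(p.numerator_coeffs, p.denominator_coeffs, p.scale, x)
                    for x in xs
                ]
            )
            assert np.allclose(eval_rational(p, xs), expected, atol=1e-10)

    def test_rejects_non_finite_input(self):
        p = RationalFunctionParams.silu_like()
        with pytest.raises(ValueError):
            eval_rational(p, np.array([1.0, np.inf]))

    def test_rejects_non_finite_coefficients(self):
        with pytest.raises(ValueError):
            RationalFunctionParams([0.0, np.nan], np.zeros(4))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        x=st.floats(-1e6, 1e6, allow_nan=False),
    )
    def test_safe_pade_is_always_finite(self, seed, x):
        """The 1 + |Q| denominator has no poles anywhere on the real line."""
        p = random_params(np.random.default_rng(seed))
        val = eval_rational(p, x)
        assert np.isfinite(val)

    def test_silu_fit_tracks_silu_on_fit_interval(self):
        x = np.linspace(-3, 3, 301)
        silu = x / (1 + np.exp(-x))
        fit = eval_rational(RationalFunctionParams.silu_like(), x)
        assert np.max(np.abs(fit - silu)) < 1e-5


def grkan_oracle(layer, batch):
    """Triple-loop scalar reference for the grouped forward pass."""
    B = batch.shape[0]
    out = np.zeros((B, layer.dout))
    fns = layer.group_functions
    for b in range(B):
        for i in range(layer.dout):
            acc = 0.0 if layer.bias is None else layer.bias.data[i]
            for j in range(layer.din):
                f = fns[j // layer.group_width]
                acc += layer.weight.data[j, i] * horner_rational(
                    f.numerator_coeffs, f.denominator_coeffs, f.scale, batch[b, j]
                )
            out[b, i] = acc
    return out


class TestGroupLayer:
    def test_identity_composition(self):
        layer = RationalGroupLayer(4, 4, groups=1, seed=0,
                                   init_functions=[RationalFunctionParams.identity()])
        layer.weight.data = np.eye(4)
        layer.bias.data = np.zeros(4)
        x = np.random.default_rng(1).standard_normal((3, 4))
        assert np.allclose(grkan_forward(layer, x), x, atol=1e-12)

    def test_matches_scalar_oracle_one_group_per_dim(self, rng):
        layer = RationalGroupLayer(8, 3, groups=8, seed=11)
        layer.numerator.data = rng.standard_normal((8, 6))
        layer.denominator.data = rng.standard_normal((8, 4))
        x = rng.standard_normal((4, 8))
        assert np.allclose(grkan_forward(layer, x), grkan_oracle(layer, x), atol=1e-5)

    @pytest.mark.parametrize("groups", [1, 2, 4, 8])
    def test_matches_scalar_oracle_random_layers(self, groups, rng):
        for _ in range(5):
            din = groups * int(rng.integers(1, 5))
            dout = int(rng.integers(1, 9))
            layer = RationalGroupLayer(din, dout, groups=groups, seed=int(rng.integers(2**31)))
            layer.numerator.data = rng.standard_normal((groups, 6))
            layer.denominator.data = rng.standard_normal((groups, 4))
            x = rng.standard_normal((3, din))
            assert np.allclose(grkan_forward(layer, x), grkan_oracle(layer, x), atol=1e-5)

    def test_duplicated_sample_gives_duplicated_row(self, rng):
        layer = RationalGroupLayer(8, 5, groups=4, seed=2)
        x = rng.standard_normal((3, 8))
        batch = np.vstack([x, x[1:2]])
        out = grkan_forward(layer, batch)
        assert np.array_equal(out[1], out[3])

    def test_within_group_permutation_invariance(self, rng):
        """Swapping two inputs of one group together with the matching
        weight columns leaves the output unchanged (shared activation)."""
        layer = RationalGroupLayer(8, 3, groups=2, seed=3)
        x = rng.standard_normal((5, 8))
        base = grkan_forward(layer, x)
        # dims 1 and 2 belong to group 0 (width 4)
        perm = np.arange(8)
        perm[[1, 2]] = perm[[2, 1]]
        layer.weight.data = layer.weight.data[perm]
        assert np.allclose(grkan_forward(layer, x[:, perm]), base, atol=1e-12)

    def test_rejects_indivisible_group_count(self):
        with pytest.raises(ValueError):
            RationalGroupLayer(10, 4, groups=4, seed=0)

    def test_rejects_width_mismatch(self):
        layer = RationalGroupLayer(8, 2, groups=2, seed=0)
        with pytest.raises(ValueError):
            grkan_forward(layer, np.zeros((2, 7)))


class TestInitialization:
    def test_identity_closed_form_weight_std(self):
        layer = RationalGroupLayer(
            100, 10, groups=1, seed=5,
            init_functions=[RationalFunctionParams.identity()],
        )
        gain = init_variance_preserving(layer, seed=5, sample_count=200_000)
        # E[x^2] = 1 under N(0,1), so weight_std -> 1/sqrt(100) = 0.1
        assert gain.weight_std == pytest.approx(0.1, rel=0.01)

    def test_variance_ratio_near_unity(self):
        layer = RationalGroupLayer(64, 64, groups=8, seed=6)
        rng = np.random.default_rng(123)
        x = rng.standard_normal((100_000, 64))
        out = grkan_forward(layer, x)
        ratio = out.var() / x.var()
        assert 0.8 <= ratio <= 1.2

    def test_same_seed_bit_identical_weights(self):
        a = RationalGroupLayer(16, 8, groups=4, seed=42)
        b = RationalGroupLayer(16, 8, groups=4, seed=42)
        assert np.array_equal(a.weight.data, b.weight.data)
        assert np.array_equal(a.numerator.data, b.numerator.data)

    def test_degenerate_rational_raises_naming_group(self):
        zero = RationalFunctionParams(np.zeros(6), np.zeros(4))
        with pytest.raises(ValueError, match="group 1"):
            RationalGroupLayer(
                4, 2, groups=2, seed=0,
                init_functions=[RationalFunctionParams.silu_like(), zero],
            )


class TestParameterAccounting:
    def test_hand_counted_example(self):
        layer = RationalGroupLayer(16, 4, groups=8, bias=False, seed=0)
        assert count_learnables(layer) == 144  # 64 weights + 8 groups * 10 coeffs

    def test_count_matches_actual_learnables(self):
        for din, dout, g, bias in [(16, 4, 8, False), (32, 16, 4, True), (8, 8, 1, True)]:
            layer = RationalGroupLayer(din, dout, groups=g, bias=bias, seed=1)
            assert count_learnables(layer) == layer.n_parameters()
            assert count_learnables(layer) == dout * din + (dout if bias else 0) + g * 10

    def test_monotone_in_group_count(self):
        lo = RationalGroupLayer(16, 4, groups=1, seed=0)
        hi = RationalGroupLayer(16, 4, groups=16, seed=0)
        assert count_learnables(lo) < count_learnables(hi)

    def test_ten_activation_coefficients_per_group(self):
        layer = RationalGroupLayer(16, 4, groups=8, seed=0)
        per_group = layer.numerator.data.shape[1] + layer.denominator.data.shape[1]
        assert per_group == 10  # m+1 + n with the default degrees 5 and 4
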