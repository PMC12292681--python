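"""Group-rational Kolmogorov–Arnold (GR-KAN) layers.

A GR-KAN layer applies a learnable *safe Padé* rational activation

    phi(x) = w * P(x) / (1 + |Q(x)|),
    P(x) = a_0 + a_1 x + ... + a_m x^m,   Q(x) = b_1 x + ... + b_n x^n,

elementwise to its input, sharing one rational function among each of
``g`` contiguous input groups, and then mixes the activated vector with a
dense linear map.  The ``1 + |Q|`` denominator is bounded below by 1, so
the activation has no poles anywhere on the real line.  Degrees default
to m=5, n=4.

Initialization is variance preserving: the second moment E[F(x)^2] of
each group's rational function is estimated by Monte Carlo under
x ~ N(0, 1), and the mixing weights are drawn i.i.d. from
N(0, 1/(din * E[F(x)^2])), which makes Var[output] ≈ Var[input] for
standard-normal inputs.  The rational coefficients themselves start from
a precomputed least-squares fit of the safe Padé form to the SiLU
activation on [-3, 3] (constants below), so training begins from a
known-good activation shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly

from . import nn
from .autodiff import Tensor, as_tensor, no_grad

__all__ = [
    "RationalFunctionParams",
    "RationalGroupLayer",
    "InitGain",
    "eval_rational",
    "grkan_forward",
    "init_variance_preserving",
    "count_learnables",
    "SILU_FIT_NUMERATOR",
    "SILU_FIT_DENOMINATOR",
]

# Least-squares fit of P(x)/(1+|Q(x)|) (m=5, n=4) to SiLU(x)=x/(1+e^-x)
# on [-3, 3]; max abs fit error ~1.1e-6.  Precomputed once and frozen.
SILU_FIT_NUMERATOR = np.array(
    [
        3.2944731062709069e-07,
        4.9999999999300776e-01,
        2.4999732185921580e-01,
        5.3264402485399480e-02,
        5.8022034123882561e-03,
        2.7508747152299071e-04,
    ]
)
SILU_FIT_DENOMINATOR = np.array(
    [
        -3.5713261988433918e-08,
        1.0652882279732961e-01,
        -3.4635257861718081e-09,
        5.5017520449977592e-04,
    ]
)


@dataclass
class RationalFunctionParams:
    """Coefficients of one safe Padé unit.

    ``numerator_coeffs`` holds a_0..a_m (ascending), ``denominator_coeffs``
    holds b_1..b_n (no constant term — the constant 1 is structural), and
    ``scale`` is the multiplicative coefficient w.
    """

    numerator_coeffs: np.ndarray
    denominator_coeffs: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        self.numerator_coeffs = np.asarray(self.numerator_coeffs, dtype=np.float64)
        self.denominator_coeffs = np.asarray(self.denominator_coeffs, dtype=np.float64)
        if self.numerator_coeffs.ndim != 1 or self.numerator_coeffs.size < 2:
            raise ValueError("numerator needs at least degree m >= 1 (two coefficients)")
        if self.denominator_coeffs.ndim != 1:
            raise ValueError("denominator coefficients must be one-dimensional")
        if not (
            np.all(np.isfinite(self.numerator_coeffs))
            and np.all(np.isfinite(self.denominator_coeffs))
            and np.isfinite(self.scale)
        ):
            raise ValueError("rational coefficients must be finite")

    @property
    def m(self) -> int:
        return self.numerator_coeffs.size - 1

    @property
    def n(self) -> int:
        return self.denominator_coeffs.size

    @classmethod
    def silu_like(cls) -> "RationalFunctionParams":
        return cls(SILU_FIT_NUMERATOR.copy(), SILU_FIT_DENOMINATOR.copy(), 1.0)

    @classmethod
    def identity(cls, m: int = 5, n: int = 4) -> "RationalFunctionParams":
        num = np.zeros(m + 1)
        num[1] = 1.0
        return cls(num, np.zeros(n), 1.0)


def eval_rational(params: RationalFunctionParams, x):
    """Evaluate the safe Padé unit elementwise: scale * P(x) / (1 + |Q(x)|)."""
    arr = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("eval_rational requires finite input")
    p = npoly.polyval(arr, params.numerator_coeffs)
    q = npoly.polyval(arr, np.concatenate([[0.0], params.denominator_coeffs]))
    out = params.scale * p / (1.0 + np.abs(q))
    return out if arr.shape else float(out)


@dataclass
class InitGain:
    """Record of a variance-preserving initialization."""

    expected_square: float
    weight_std: float
    sample_count: int
    seed: int


class RationalGroupLayer(nn.Module):
    """GR-KAN layer: grouped rational activation followed by linear mixing.

    Input width ``din`` must be divisible by the group count ``g``; group
    k (0-based) owns input dimensions [k*dg, (k+1)*dg) with dg = din/g and
    all dimensions of a group share one rational function.  The mixing
    weight is stored as a (din, dout) matrix applied on the right
    (``y = F(x) @ weight + bias``).
    """

    def __init__(
        self,
        din: int,
        dout: int,
        groups: int = 8,
        m: int = 5,
        n: int = 4,
        bias: bool = True,
        seed: Optional[int] = None,
        init_functions: Optional[Sequence[RationalFunctionParams]] = None,
        gain_samples: int = 100_000,
    ):
        super().__init__()
        if din <= 0 or dout <= 0 or groups <= 0:
            raise ValueError("din, dout and groups must be positive")
        if din % groups != 0:
            raise ValueError(f"din={din} is not divisible by groups={groups}")
        if m < 1 or n < 0:
            raise ValueError(f"need m >= 1 and n >= 0, got m={m}, n={n}")
        self.din, self.dout, self.groups, self.m, self.n = din, dout, groups, m, n
        self.group_width = din // groups

        if init_functions is None:
            init_functions = [RationalFunctionParams.silu_like() for _ in range(groups)]
        if len(init_functions) != groups:
            raise ValueError(f"expected {groups} rational functions, got {len(init_functions)}")
        num = np.zeros((groups, m + 1))
        den = np.zeros((groups, n))
        scale = np.zeros(groups)
        for k, f in enumerate(init_functions):
            if f.m != m or f.n != n:
                raise ValueError(f"group {k}: degrees ({f.m},{f.n}) do not match layer ({m},{n})")
            num[k] = f.numerator_coeffs
            den[k] = f.denominator_coeffs
            scale[k] = f.scale
        self.numerator = nn.Parameter(num)
        self.denominator = nn.Parameter(den)
        # the per-group scale w multiplies P(x) and is therefore redundant
        # with the numerator coefficients; it is kept as a fixed buffer so
        # the learnable count stays dout*din + dout + g*(m+1+n)
        self.scale = np.asarray(scale, dtype=np.float64)
        self.weight = nn.Parameter(np.zeros((din, dout)))
        self.bias = nn.Parameter(np.zeros(dout)) if bias else None

        seed = int(np.random.default_rng().integers(2**31)) if seed is None else int(seed)
        self.init_gain = init_variance_preserving(self, seed=seed, sample_count=gain_samples)

    # ------------------------------------------------------------------
    def group_function(self, k: int) -> RationalFunctionParams:
        """A snapshot of group ``k``'s rational function."""
        return RationalFunctionParams(
            self.numerator.data[k].copy(),
            self.denominator.data[k].copy(),
            float(self.scale[k]),
        )

    @property
    def group_functions(self):
        return [self.group_function(k) for k in range(self.groups)]

    def activate(self, x):
        """Apply the grouped rational activation (no mixing), shape-preserving."""
        x = as_tensor(x)
        lead = x.shape[:-1]
        xg = x.reshape(lead + (self.groups, self.group_width))
        # Horner evaluation with per-group coefficient columns
        p = self.numerator[:, self.m].reshape(self.groups, 1)
        for i in range(self.m - 1, -1, -1):
            p = p * xg + self.numerator[:, i].reshape(self.groups, 1)
        if self.n > 0:
            q = self.denominator[:, self.n - 1].reshape(self.groups, 1)
            for i in range(self.n - 2, -1, -1):
                q = q * xg + self.denominator[:, i].reshape(self.groups, 1)
            q = q * xg
            denom = q.abs() + 1.0
        else:
            denom = 1.0
        phi = p / denom * self.scale[:, None]
        return phi.reshape(lead + (self.din,))

    def forward(self, x):
        x = as_tensor(x)
        if x.shape[-1] != self.din:
            raise ValueError(f"input width {x.shape[-1]} != layer din {self.din}")
        out = self.activate(x) @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


def grkan_forward(layer: RationalGroupLayer, batch: np.ndarray) -> np.ndarray:
    """Run a GR-KAN layer on a (B, din) array without recording gradients."""
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim != 2 or batch.shape[1] != layer.din:
        raise ValueError(f"expected batch of shape (B, {layer.din}), got {batch.shape}")
    with no_grad():
        return layer(Tensor(batch)).data


def init_variance_preserving(
    layer: RationalGroupLayer, seed: int, sample_count: int = 100_000
) -> InitGain:
    """Variance-preserving re-initialization of the mixing weights.

    Estimates E[F_k(x)^2] for each group under x ~ N(0, 1) by Monte Carlo
    and draws the columns of group k from N(0, 1/(din * E[F_k(x)^2])).
    The bias (if present) is set to zero.  Deterministic given ``seed``.
    """
    if sample_count < 2:
        raise ValueError("sample_count must be at least 2")
    rng = np.random.default_rng(seed)
    per_group = np.empty(layer.groups)
    for k in range(layer.groups):
        z = rng.standard_normal(sample_count)
        per_group[k] = float(np.mean(eval_rational(layer.group_function(k), z) ** 2))
        if per_group[k] <= 1e-12:
            raise ValueError(
                f"group {k}: rational function is degenerate (E[F(x)^2] ~ 0); "
                "cannot derive a variance-preserving weight scale"
            )
    col_std = np.repeat(1.0 / np.sqrt(layer.din * per_group), layer.group_width)
    layer.weight.data = rng.standard_normal((layer.din, layer.dout)) * col_std[:, None]
    if layer.bias is not None:
        layer.bias.data = np.zeros(layer.dout)
    expected_square = float(per_group.mean())
    gain = InitGain(
        expected_square=expected_square,
        weight_std=float(1.0 / np.sqrt(layer.din * expected_square)),
        sample_count=sample_count,
        seed=int(seed),
    )
    layer.init_gain = gain
    return gain


def count_learnables(layer: RationalGroupLayer) -> int:
    """Exact learnable-parameter count: dout*din + dout*[bias] + g*(m+1+n)."""
    bias = layer.dout if layer.bias is not None else 0
    return layer.dout * layer.din + bias + layer.groups * (layer.m + 1 + layer.n)
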