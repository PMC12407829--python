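"""Sinh-arcsinh (SHASH) response warp.

The warp ``W(y) = sinh(b * arcsinh(y) - a)`` maps a skewed/kurtotic
response onto a Gaussian latent scale: ``a`` controls skew (a > 0 pulls
the right tail in), ``b > 0`` controls tail weight.  ``(a, b) = (0, 1)``
is the identity.  ``W`` is strictly increasing for every valid ``(a, b)``,
so the inverse is global and the Jacobian ``W'`` is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WarpParams", "shash_warp", "shash_inverse", "shash_derivative"]


def _check_b(b) -> None:
    if not np.all(np.asarray(b) > 0):
        raise ValueError(f"SHASH shape parameter b must be > 0, got {b!r}")


@dataclass(frozen=True)
class WarpParams:
    """Skew (``a``) and tail-weight (``b``) parameters of the SHASH warp."""

    a: float = 0.0
    b: float = 1.0

    def __post_init__(self) -> None:
        _check_b(self.b)

    @property
    def is_identity(self) -> bool:
        return self.a == 0.0 and self.b == 1.0

    def forward(self, y):
        return shash_warp(y, self.a, self.b)

    def inverse(self, z):
        return shash_inverse(z, self.a, self.b)

    def derivative(self, y):
        return shash_derivative(y, self.a, self.b)


def shash_warp(y, a: float, b: float):
    """W(y) = sinh(b * arcsinh(y) - a)."""
    _check_b(b)
    return np.sinh(b * np.arcsinh(y) - a)


def shash_inverse(z, a: float, b: float):
    """W^-1(z) = sinh((arcsinh(z) + a) / b)."""
    _check_b(b)
    return np.sinh((np.arcsinh(z) + a) / b)


def shash_derivative(y, a: float, b: float):
    """W'(y) = b * cosh(b * arcsinh(y) - a) / sqrt(1 + y^2)."""
    _check_b(b)
    y = np.asarray(y, dtype=float)
    return b * np.cosh(b * np.arcsinh(y) - a) / np.sqrt(1.0 + y * y)
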