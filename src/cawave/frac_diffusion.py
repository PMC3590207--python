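"""Discrete space-fractional diffusion operators (order 2 <= beta < 3).

The one-sided Riemann-Liouville derivatives are discretized with the
right-shifted Gruenwald-Letnikov formula; the symmetric (Riesz-type)
spatial operator used by the wave model combines the left- and right-sided
operators with the normalization -1/(2 cos(pi beta / 2)), the unique
direction-unbiased choice that reduces exactly to the classical Laplacian
at beta = 2.

Reflecting (zero-flux) walls sit half a grid cell outside the first and
last node; the nonlocal stencil is evaluated on the even extension of the
field across each wall, truncated after one domain width.  Each row is
then corrected on the diagonal so that constant fields are annihilated
exactly (a flat concentration has zero diffusion rate), which the
truncated extension alone would only satisfy in the limit of an infinite
sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


def gl_weights(beta: float, K: int) -> np.ndarray:
    """Gruenwald-Letnikov weights g_k = (-1)^k C(beta, k), k = 0..K.

    Computed with the stable recurrence g_0 = 1, g_k = g_{k-1} (k-1-beta)/k,
    which avoids the overflowing gamma-function quotients of the closed form.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if beta <= 0:
        raise ValueError("beta must be positive")
    g = np.empty(K + 1)
    g[0] = 1.0
    for k in range(1, K + 1):
        g[k] = g[k - 1] * (k - 1.0 - beta) / k
    return g


def _reflect(j: int, n: int) -> int | None:
    """Map an extended index onto the grid by one even reflection per wall.

    Walls lie at j = -1/2 and j = n - 1/2, so the mirror of -1 is 0 and the
    mirror of n is n-1.  Indices beyond a single reflection (more than one
    domain width away) return None and are truncated.
    """
    if 0 <= j < n:
        return j
    if -n <= j < 0:
        return -1 - j
    if n <= j < 2 * n:
        return 2 * n - 1 - j
    return None


def directional_matrix(beta: float, n: int, h: float, side: str = "left") -> np.ndarray:
    """Dense matrix of the one-sided shifted-GL fractional derivative.

    Left side: (d^beta/dx^beta) C |_i ~ h^-beta sum_k g_k C_{i-k+1};
    right side is the mirror image.  Reflecting walls via even extension
    (one reflection), rows corrected to zero sum.
    """
    if n < 4:
        raise ValueError("n must be at least 4")
    if h <= 0:
        raise ValueError("h must be positive")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    g = gl_weights(beta, 2 * n + 1)
    A = np.zeros((n, n))
    for i in range(n):
        for k in range(len(g)):
            j = i - k + 1 if side == "left" else i + k - 1
            jj = _reflect(j, n)
            if jj is not None:
                A[i, jj] += g[k]
    A /= h**beta
    # zero-row-sum correction: exact annihilation of constant profiles
    A[np.arange(n), np.arange(n)] -= A.sum(axis=1)
    return A


def riesz_matrix(beta: float, n: int, h: float, D: float = 1.0) -> np.ndarray:
    """Symmetric fractional-diffusion matrix D * c_beta * (left + right).

    c_beta = -1 / (2 cos(pi beta / 2)); at beta = 2 this is +1/2 and the
    operator equals D times the standard three-point Laplacian with
    zero-flux walls.
    """
    if not 2.0 <= beta < 3.0:
        raise ValueError("beta must satisfy 2 <= beta < 3")
    c = math.cos(math.pi * beta / 2.0)
    if abs(c) < 1e-12:
        raise ValueError("beta too close to 3: Riesz normalization is singular")
    coef = -D / (2.0 * c)
    return coef * (directional_matrix(beta, n, h, "left")
                   + directional_matrix(beta, n, h, "right"))


@dataclass
class FractionalOperator:
    """Precomputed directional fractional-diffusion operator.

    ``matrix`` maps a 1-D concentration profile (uM) along one grid
    direction to its diffusion rate (uM/ms).  Precomputed once per
    (beta, n, h, D) and reused across all time steps.
    """

    beta: float
    n: int
    h: float
    D: float
    matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = riesz_matrix(self.beta, self.n, self.h, self.D)

    def apply(self, profile: np.ndarray) -> np.ndarray:
        """Diffusion rate of a profile (first axis = this direction)."""
        return self.matrix @ profile
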