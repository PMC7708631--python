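"""Baseline scan-path dynamics: map evolution and target-selection map.

The model maintains two activation streams on the grid.  The attention
stream ``A`` relaxes toward the Gaussian-windowed local saliency around the
current fixation; the inhibition stream ``F`` relaxes toward a Gaussian blob
at the fixation, tagging visited locations.  Both follow

    dM/dt = omega * (target - M),

whose closed-form solution over a phase of length ``dt`` with a constant
target is used exclusively (no numerical ODE stepping in production code).
The two streams combine subtractively into a priority map, which after
rectification and admixture of uniform noise ``zeta`` becomes the
probability map ``pi`` over saccade targets.
"""

from __future__ import annotations

import numpy as np

from .core import Grid, normalize_map

__all__ = [
    "attention_input",
    "evolve_map",
    "combine_priority",
    "rectify",
    "selection_probability",
    "shape_map",
]


def attention_input(S: np.ndarray, G_A: np.ndarray) -> np.ndarray:
    """Sum-normalized Gaussian-weighted local saliency ``S*G_A / sum``.

    This is the fixed point the attention stream relaxes toward during a
    fixation.  Raises if the saliency is degenerate under the aperture
    (zero overlap), which would leave the stream without input.
    """
    if (S < 0).any():
        raise ValueError("saliency map must be nonnegative")
    prod = S * G_A
    s = float(prod.sum())
    if not (s > 0):
        raise ValueError("degenerate saliency: zero overlap with attention window")
    return prod / s


def evolve_map(M0: np.ndarray, target: np.ndarray, omega: float, dt: float) -> np.ndarray:
    """Closed-form relaxation ``target + exp(-omega dt) (M0 - target)``.

    Exact solution of ``dM/dt = omega (target - M)`` with constant target;
    serves both the attention stream (target = normalized local saliency)
    and the inhibition stream (target = normalized fixation Gaussian).
    """
    if dt < 0:
        raise ValueError(f"dt must be nonnegative, got {dt}")
    if not (omega > 0):
        raise ValueError(f"omega must be positive, got {omega}")
    decay = np.exp(-omega * dt)
    return target + decay * (M0 - target)


def shape_map(M: np.ndarray, gamma: float) -> np.ndarray:
    """Sum-normalized ``M**gamma``; clips tiny negative round-off at 0."""
    M = np.maximum(M, 0.0)
    shaped = M if gamma == 1.0 else np.power(M, gamma)
    s = float(shaped.sum())
    if not (s > 0):
        raise ValueError("cannot shape an all-zero map")
    return shaped / s


def combine_priority(A: np.ndarray, F: np.ndarray, gamma: float, C_F: float) -> np.ndarray:
    """Signed priority map ``A^g/sum - C_F * F^g/sum``.

    With ``gamma = 1`` and ``C_F = 0`` this reduces to Luce's choice rule
    over the attention map.
    """
    return shape_map(A, gamma) - C_F * shape_map(F, gamma)


def rectify(u: np.ndarray) -> np.ndarray:
    """Positive part of the signed priority map: ``max(u, 0)`` elementwise."""
    return np.maximum(u, 0.0)


def selection_probability(u_star: np.ndarray, zeta: float) -> np.ndarray:
    """Target-selection probability map ``pi``.

    pi = (1 - zeta) * u_star / sum(u_star) + zeta / n_cells

    ``zeta`` in (0, 1] mixes in a uniform floor so every cell keeps
    positive probability; with ``zeta = 0`` an all-zero rectified map is an
    error because no target could be chosen.
    """
    if not (0 <= zeta <= 1):
        raise ValueError(f"zeta must lie in [0, 1], got {zeta}")
    n_cells = u_star.size
    s = float(u_star.sum())
    if s > 0 and zeta < 1:
        pi = (1.0 - zeta) * (u_star / s) + zeta / n_cells
    elif zeta > 0:
        pi = np.full_like(u_star, 1.0 / n_cells, dtype=float)
    else:
        raise ValueError("all-zero priority map with zeta = 0: no selectable target")
    return pi
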