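"""Exact per-fixation likelihood of observed scan paths.

The likelihood of a scan path factorizes over fixations,

    L(theta | f_1..f_n) = P(f_1) * prod_{i=2}^{n} P(f_i | f_1..f_{i-1}, theta),

where each conditional probability is read off the model's selection map
at the instant ``t_fix - tau_pre`` of the preceding fixation, with the
observed fixations driving the map evolution (teacher forcing — the
model's own samples are never substituted).  Per-fixation probabilities
are reported as log2 so model performance carries the unit *bit*: a
uniform selection map on a 128 x 128 grid scores log2(1/128^2) = -14 bits
per fixation; a perfect predictor would score 0.

Model comparison uses the mean log2-likelihood per fixation; parameter
estimation uses the non-normalized sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Grid, ModelParams, Scanpath, deg_to_cell, gaussian_map
from .dynamics import rectify, selection_probability
from .engine import SceneWalkEngine

__all__ = [
    "LikelihoodResult",
    "scanpath_loglik",
    "dataset_mean_bits",
    "dataset_sum_log2",
    "density_sampling_log2",
    "local_saliency_loglik",
    "train_test_split_images",
]

LOG2 = float(np.log(2.0))


@dataclass(frozen=True)
class LikelihoodResult:
    """Per-fixation log2 probabilities of one scan path."""

    per_fixation_log2: tuple[float, ...]
    subject: str = "subject"
    image: str = "image"

    @property
    def sum_log2(self) -> float:
        return float(np.sum(self.per_fixation_log2))

    @property
    def sum_nats(self) -> float:
        return self.sum_log2 * LOG2

    @property
    def mean_log2(self) -> float:
        return self.sum_log2 / len(self.per_fixation_log2)

    @property
    def n_fixations(self) -> int:
        return len(self.per_fixation_log2)

    @property
    def has_zero_probability(self) -> bool:
        """True when an observed fixation had zero model probability."""
        return any(np.isneginf(v) for v in self.per_fixation_log2)


def _log2_at(pi: np.ndarray, pos: Sequence[float], grid: Grid) -> float:
    i, j = deg_to_cell(pos, grid)
    p = float(pi[i, j])
    return float(np.log2(p)) if p > 0 else float("-inf")


def scanpath_loglik(
    path: Scanpath,
    S: np.ndarray,
    params: ModelParams,
    grid: Grid | None = None,
    fast: bool = True,
) -> LikelihoodResult:
    """Replay one observed scan path and score every fixation.

    ``P(f_1)`` comes from the initial map (center-bias Gaussian for the
    extended variant, uniform otherwise); each later fixation is scored on
    the selection map frozen at ``t_fix - tau_pre`` of its predecessor.
    A zero-probability fixation (possible only with ``zeta = 0``) yields
    an explicit ``-inf`` entry rather than being dropped.

    ``fast=True`` uses the compiled replay kernel; ``fast=False`` runs the
    reference engine (identical results up to floating-point tolerance).
    """
    grid = grid or Grid()
    if fast:
        logs = _fast_log2(path, S, params, grid)
        return LikelihoodResult(tuple(logs), subject=path.subject,
                                image=path.image)
    eng = SceneWalkEngine(S, params, grid)
    logs = [_log2_at(eng.initial_selection_map(), path.fixations[0].pos, grid)]
    eng.begin(path.fixations[0].pos)
    for cur, nxt in zip(path.fixations, path.fixations[1:]):
        pi, _ = eng.step(cur.duration, next_pos=nxt.pos)
        logs.append(_log2_at(pi, nxt.pos, grid))
    return LikelihoodResult(tuple(logs), subject=path.subject, image=path.image)


def _fast_log2(path: Scanpath, S: np.ndarray, params: ModelParams,
               grid: Grid) -> np.ndarray:
    from ._fastreplay import replay_log2

    S = np.asarray(S, dtype=float)
    if S.shape != grid.shape:
        raise ValueError(f"saliency shape {S.shape} != grid shape {grid.shape}")
    if (S < 0).any() or not (S.sum() > 0):
        raise ValueError("saliency map must be nonnegative and not all zero")
    pos = path.positions()
    cells = np.array([deg_to_cell(p, grid) for p in pos], dtype=np.int64)
    p = params
    extended = p.variant == "extended"
    return replay_log2(
        S, grid.x, grid.y,
        np.ascontiguousarray(pos[:, 0]), np.ascontiguousarray(pos[:, 1]),
        path.durations(), cells[:, 0], cells[:, 1],
        p.omega_A, p.omega_F, p.sigma_A, p.sigma_F, p.gamma, p.C_F, p.zeta,
        p.tau_pre, p.tau_post, p.eta if extended else 0.0,
        p.sigma_post_eff, p.nu, p.omega_FoR,
        p.chi, p.psi if extended else 0.0, p.omp_sign == "subtract",
        bool(p.facilitation), bool(p.center_bias),
        p.omega_CB, p.sigma_CB_x, p.sigma_CB_y,
    )


def _resolve_saliency(path: Scanpath, S) -> np.ndarray:
    if isinstance(S, dict):
        return S[path.image]
    return S


def dataset_mean_bits(
    paths: Sequence[Scanpath],
    S,
    params: ModelParams,
    grid: Grid | None = None,
) -> float:
    """Mean log2-likelihood per fixation pooled over all scan paths.

    ``S`` is either one saliency map or a dict keyed by image id.
    """
    if len(paths) == 0:
        raise ValueError("empty dataset")
    total, n = 0.0, 0
    for p in paths:
        r = scanpath_loglik(p, _resolve_saliency(p, S), params, grid)
        total += r.sum_log2
        n += r.n_fixations
    return total / n


def dataset_sum_log2(
    paths: Sequence[Scanpath],
    S,
    params: ModelParams,
    grid: Grid | None = None,
) -> float:
    """Non-normalized sum log2-likelihood (the estimation objective)."""
    if len(paths) == 0:
        raise ValueError("empty dataset")
    return float(sum(
        scanpath_loglik(p, _resolve_saliency(p, S), params, grid).sum_log2
        for p in paths
    ))


# -- reference comparators (no dynamics) -------------------------------------

def density_sampling_log2(
    paths: Sequence[Scanpath],
    reference_paths: Sequence[Scanpath],
    grid: Grid | None = None,
    floor: float = 1e-3,
) -> float:
    """Mean bits of a static comparator: the long-run 2-D fixation density.

    Every fixation is scored on one fixed map — the normalized histogram of
    ``reference_paths`` fixations over the grid, mixed with a small uniform
    floor so unseen cells keep positive probability.
    """
    grid = grid or Grid()
    counts = np.zeros(grid.shape)
    for p in reference_paths:
        for f in p.fixations:
            i, j = deg_to_cell(f.pos, grid)
            counts[i, j] += 1
    if not (counts.sum() > 0):
        raise ValueError("no reference fixations")
    pi = (1 - floor) * counts / counts.sum() + floor / grid.n_cells
    total, n = 0.0, 0
    for p in paths:
        for f in p.fixations:
            total += _log2_at(pi, f.pos, grid)
            n += 1
    return total / n


def local_saliency_loglik(
    path: Scanpath,
    S: np.ndarray,
    params: ModelParams,
    grid: Grid | None = None,
) -> LikelihoodResult:
    """Comparator without map dynamics: saliency through the attention window.

    Each next fixation is scored on the Gaussian-windowed saliency around
    the current fixation (with selection noise ``zeta``); the first on the
    uniform map.
    """
    grid = grid or Grid()
    logs = [float(np.log2(1.0 / grid.n_cells))]
    for cur, nxt in zip(path.fixations, path.fixations[1:]):
        g = gaussian_map(cur.pos, params.sigma_A, grid)
        pi = selection_probability(rectify(S * g), params.zeta)
        logs.append(_log2_at(pi, nxt.pos, grid))
    return LikelihoodResult(tuple(logs), subject=path.subject, image=path.image)


def train_test_split_images(
    images: Sequence[str], rng: np.random.Generator, test_fraction: float = 1 / 3
) -> tuple[list[str], list[str]]:
    """Random image split (default 2/3 train, 1/3 test)."""
    images = list(images)
    n_test = int(round(test_fraction * len(images)))
    perm = rng.permutation(len(images))
    test = sorted(images[i] for i in perm[:n_test])
    train = sorted(images[i] for i in perm[n_test:])
    return train, test
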