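"""Scan-path generation from either model variant.

Fixation durations are drawn from a gamma distribution (default shape 9,
scale 0.0305 s: mean about 275 ms with coefficient of variation about 1/3,
typical of free scene viewing).  The first fixation starts at the image
center for the baseline variant and is sampled from the center-bias map
for the extended variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core import Fixation, Grid, ModelParams, Scanpath, cell_to_deg
from .engine import SceneWalkEngine

__all__ = ["SimConfig", "sample_duration", "sample_target", "simulate_scanpath",
           "simulate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings for one scan path."""

    n_fixations: int = 30
    duration_shape: float = 9.0
    duration_scale: float = 0.0305
    seed: int | None = None
    first_fix: Literal["auto", "center", "sample"] = "auto"
    first_fix_duration: float | None = None  # None: gamma-sampled

    def __post_init__(self) -> None:
        if self.n_fixations < 1:
            raise ValueError("n_fixations must be >= 1")
        if not (self.duration_shape > 0 and self.duration_scale > 0):
            raise ValueError("gamma duration parameters must be positive")


def sample_duration(shape: float, scale: float, rng: np.random.Generator) -> float:
    """One gamma-distributed fixation duration in seconds."""
    if not (shape > 0 and scale > 0):
        raise ValueError("gamma parameters must be positive")
    return float(rng.gamma(shape, scale))


def sample_target(pi: np.ndarray, rng: np.random.Generator) -> tuple[int, int]:
    """Multinomial draw of a grid cell from the selection map ``pi``."""
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 2 or (pi < 0).any() or abs(float(pi.sum()) - 1.0) > 1e-8:
        raise ValueError("pi must be a 2-D probability map summing to 1")
    flat = rng.choice(pi.size, p=pi.ravel() / pi.sum())
    return tuple(int(v) for v in divmod(int(flat), pi.shape[1]))  # type: ignore[return-value]


def simulate_scanpath(
    S: np.ndarray,
    params: ModelParams,
    cfg: SimConfig,
    grid: Grid | None = None,
    rng: np.random.Generator | None = None,
    image: str = "image",
    subject: str = "subject",
) -> Scanpath:
    """Generate one scan path on saliency map ``S``.

    With a fixed seed (or an externally supplied generator) the output is
    bit-reproducible.
    """
    grid = grid or Grid()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    eng = SceneWalkEngine(S, params, grid)

    rule = cfg.first_fix
    if rule == "auto":
        rule = "sample" if params.center_bias else "center"
    if rule == "center":
        first = grid.center
    else:
        pi0 = eng.initial_selection_map()
        first = cell_to_deg(sample_target(pi0, rng), grid)

    if cfg.first_fix_duration is not None:
        d0 = cfg.first_fix_duration
    elif params.variant == "baseline" and rule == "center":
        d0 = 0.275
    else:
        d0 = sample_duration(cfg.duration_shape, cfg.duration_scale, rng)

    eng.begin(first)
    fixes = [Fixation(first[0], first[1], d0)]
    for _ in range(cfg.n_fixations - 1):
        _, nxt = eng.step(fixes[-1].duration, rng=rng)
        dur = sample_duration(cfg.duration_shape, cfg.duration_scale, rng)
        fixes.append(Fixation(nxt[0], nxt[1], dur))
    return Scanpath(tuple(fixes), image=image, subject=subject)


def simulate_dataset(
    S_by_image: dict[str, np.ndarray],
    params_by_subject: dict[str, ModelParams],
    cfg: SimConfig,
    grid: Grid | None = None,
    seed: int | None = None,
) -> list[Scanpath]:
    """Simulate every subject on every image; one path per pair."""
    grid = grid or Grid()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out = []
    for subject, params in params_by_subject.items():
        for image, S in S_by_image.items():
            out.append(
                simulate_scanpath(S, params, cfg, grid, rng=rng,
                                  image=image, subject=subject)
            )
    return out
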