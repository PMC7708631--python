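"""Synthetic fixtures: saliency maps, benchmark scan paths, gaze traces.

Everything here is a pure function of (spec, seed), so tests and the
acceptance analyses are reproducible without any downloaded corpus.  The
module also carries the velocity-based saccade detector applied to raw
gaze traces: saccades exceed the trial's median-based velocity SD by a
factor lambda (default 6) for at least ``min_samples`` consecutive samples
(6 samples = 12 ms at 500 Hz) and have a minimum amplitude of 0.5 deg;
the epochs between saccades are the fixations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import Fixation, Grid, ModelParams, Scanpath, gaussian_map, normalize_map
from .io import save_saliency, write_fixations
from .simulate import SimConfig, simulate_scanpath

__all__ = [
    "SyntheticSaliencySpec",
    "RawGazeTrace",
    "make_saliency",
    "make_benchmark_dataset",
    "synthesize_trace",
    "detect_saccades",
]


@dataclass(frozen=True)
class SyntheticSaliencySpec:
    """Mixture-of-Gaussian-blobs saliency with a uniform floor."""

    n_blobs: int = 5
    sigma_range: tuple[float, float] = (1.0, 4.0)
    weight_range: tuple[float, float] = (0.5, 1.0)
    background: float = 0.1  # uniform floor as a fraction of total mass
    margin: float = 2.0  # keep blob centers this far from the border (deg)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be nonnegative")
        if not (0 <= self.background <= 1):
            raise ValueError("background must lie in [0, 1]")
        if self.n_blobs == 0 and self.background == 0:
            raise ValueError("degenerate spec: no blobs and no background")
        if not (0 < self.sigma_range[0] <= self.sigma_range[1]):
            raise ValueError("invalid sigma_range")


def make_saliency(spec: SyntheticSaliencySpec, grid: Grid | None = None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Sum-normalized synthetic saliency map; reproducible under the seed."""
    grid = grid or Grid()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    blobs = np.zeros(grid.shape)
    for _ in range(spec.n_blobs):
        cx = rng.uniform(spec.margin, grid.extent_x - spec.margin)
        cy = rng.uniform(spec.margin, grid.extent_y - spec.margin)
        sigma = rng.uniform(*spec.sigma_range)
        w = rng.uniform(*spec.weight_range)
        blobs += w * gaussian_map((cx, cy), sigma, grid)
    uniform = np.full(grid.shape, 1.0 / grid.n_cells)
    if spec.n_blobs == 0:
        return uniform
    return (1 - spec.background) * normalize_map(blobs) + spec.background * uniform


def _jitter_params(params: ModelParams, rng: np.random.Generator,
                   rel_sd: float) -> ModelParams:
    """Per-subject multiplicative jitter of the estimated parameters."""
    if rel_sd == 0:
        return params
    updates = {
        name: getattr(params, name) * float(np.exp(rng.normal(0.0, rel_sd)))
        for name in ("omega_A", "sigma_A", "sigma_F", "gamma")
    }
    updates["log_zeta"] = min(0.0, params.log_zeta + float(rng.normal(0.0, rel_sd)))
    return params.with_updates(**updates)


def make_benchmark_dataset(
    params: ModelParams,
    n_subjects: int = 5,
    n_images: int = 3,
    n_fix: int = 30,
    seed: int | None = 0,
    grid: Grid | None = None,
    subject_jitter: float = 0.15,
    saliency_spec: SyntheticSaliencySpec | None = None,
    sim: SimConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[Scanpath], dict[str, np.ndarray], dict[str, ModelParams]]:
    """Ground-truth benchmark: jittered subjects viewing synthetic images.

    Returns ``(paths, saliency_by_image, true_params_by_subject)`` with one
    ``n_fix``-fixation path per (subject, image) pair.  When ``out_dir`` is
    given, writes ``fixations.csv``, one saliency matrix per image, and a
    ``truth.json`` record of each subject's true parameters.
    """
    grid = grid or Grid()
    rng = np.random.default_rng(seed)
    sim = sim or SimConfig(n_fixations=n_fix)
    spec = saliency_spec or SyntheticSaliencySpec()
    S_by_image = {f"img{k:03d}": make_saliency(spec, grid, rng)
                  for k in range(n_images)}
    truth = {f"subj{s:03d}": _jitter_params(params, rng, subject_jitter)
             for s in range(n_subjects)}
    paths = []
    for subject, p in truth.items():
        for image, S in S_by_image.items():
            paths.append(simulate_scanpath(S, p, sim, grid, rng=rng,
                                           image=image, subject=subject))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fixations(paths, out / "fixations.csv")
        for image, S in S_by_image.items():
            save_saliency(S, out / f"{image}.txt")
        record = {
            subj: {k: getattr(p, k) for k in
                   ("omega_A", "sigma_A", "sigma_F", "gamma", "log_zeta",
                    "chi", "eta", "log_psi", "variant")}
            for subj, p in truth.items()
        }
        (out / "truth.json").write_text(json.dumps(record, indent=2))
    return paths, S_by_image, truth


# -- raw gaze traces and saccade detection -----------------------------------

@dataclass(frozen=True)
class RawGazeTrace:
    """Uniformly sampled gaze positions in degrees."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate: float = 500.0

    def __post_init__(self) -> None:
        for arr in (self.t, self.x, self.y):
            if not np.all(np.isfinite(arr)):
                raise ValueError("trace contains non-finite samples")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")

    def __len__(self) -> int:
        return len(self.t)


def synthesize_trace(
    path: Scanpath,
    rate: float = 500.0,
    noise_sd: float = 0.05,
    saccade_duration: float = 0.04,
    rng: np.random.Generator | None = None,
) -> RawGazeTrace:
    """Raw gaze samples from a known scan path.

    Fixations hold their position with Gaussian jitter of ``noise_sd``
    degrees; saccades follow a raised-cosine position profile over
    ``saccade_duration`` seconds (a smooth ballistic velocity bump).
    """
    rng = rng or np.random.default_rng(0)
    dt = 1.0 / rate
    xs: list[float] = []
    ys: list[float] = []
    fx = path.fixations
    for k, f in enumerate(fx):
        n = max(1, int(round(f.duration * rate)))
        xs.extend(f.x + rng.normal(0, noise_sd, n))
        ys.extend(f.y + rng.normal(0, noise_sd, n))
        if k + 1 < len(fx):
            nxt = fx[k + 1]
            m = max(2, int(round(saccade_duration * rate)))
            s = (1 - np.cos(np.pi * np.arange(1, m + 1) / (m + 1))) / 2
            xs.extend(f.x + (nxt.x - f.x) * s)
            ys.extend(f.y + (nxt.y - f.y) * s)
    t = np.arange(len(xs)) * dt
    return RawGazeTrace(t=t, x=np.array(xs), y=np.array(ys), rate=rate)


def _velocity(pos: np.ndarray, rate: float) -> np.ndarray:
    """5-point smoothed differentiation (padded at the ends)."""
    n = len(pos)
    v = np.zeros(n)
    if n >= 5:
        v[2:-2] = (pos[4:] + pos[3:-1] - pos[1:-3] - pos[:-4]) * rate / 6.0
        v[:2] = v[2]
        v[-2:] = v[-3]
    elif n >= 2:
        v[1:] = np.diff(pos) * rate
        v[0] = v[1]
    return v


def _median_sd(v: np.ndarray) -> float:
    """Robust SD: 1.4826 x median absolute deviation."""
    return 1.4826 * float(np.median(np.abs(v - np.median(v))))


def detect_saccades(
    trace: RawGazeTrace,
    lam: float = 6.0,
    min_samples: int = 6,
    min_amplitude: float = 0.5,
) -> Scanpath:
    """Velocity-threshold saccade detection; returns the fixation sequence.

    A sample is saccadic when its velocity exceeds the trial's elliptic
    threshold ``(vx / (lam sx))^2 + (vy / (lam sy))^2 > 1`` built from the
    per-component median-based SDs; runs of at least ``min_samples`` such
    samples whose displacement reaches ``min_amplitude`` degrees count as
    saccades.  Inter-saccade epochs become fixations with the epoch-mean
    position and epoch duration.
    """
    n = len(trace)
    dt = 1.0 / trace.rate
    if n < max(2, min_samples):
        return Scanpath((Fixation(float(np.mean(trace.x)), float(np.mean(trace.y)),
                                  max(n, 1) * dt),))
    vx = _velocity(trace.x, trace.rate)
    vy = _velocity(trace.y, trace.rate)
    sx, sy = _median_sd(vx), _median_sd(vy)
    sx = sx if sx > 0 else 1e-12
    sy = sy if sy > 0 else 1e-12
    hot = (vx / (lam * sx)) ** 2 + (vy / (lam * sy)) ** 2 > 1.0

    # candidate runs of consecutive above-threshold samples
    saccade_spans: list[tuple[int, int]] = []
    start = None
    for k in range(n + 1):
        if k < n and hot[k]:
            if start is None:
                start = k
        elif start is not None:
            if k - start >= min_samples:
                amp = math.hypot(trace.x[k - 1] - trace.x[start],
                                 trace.y[k - 1] - trace.y[start])
                if amp >= min_amplitude:
                    saccade_spans.append((start, k))
            start = None

    # fixations = epochs between saccades
    fixes: list[Fixation] = []
    edges = [0] + [e for span in saccade_spans for e in span] + [n]
    for a, b in zip(edges[::2], edges[1::2]):
        if b > a:
            fixes.append(Fixation(float(trace.x[a:b].mean()),
                                  float(trace.y[a:b].mean()),
                                  (b - a) * dt))
    if not fixes:
        fixes = [Fixation(float(trace.x.mean()), float(trace.y.mean()), n * dt)]
    return Scanpath(tuple(fixes))
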