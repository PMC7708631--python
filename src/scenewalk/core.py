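"""Grid geometry, shared data types, and Gaussian map primitives.

Conventions
-----------
Coordinates are continuous positions in degrees of visual angle; activation
maps live on cell centers of a rectangular grid (default 128 x 128).  A map
is a 2-D :class:`numpy.ndarray` of shape ``(n_x, n_y)`` whose element
``[i, j]`` belongs to the cell centered at ``(x_i, y_j)``.  All map
normalizations are plain discrete sums over grid cells (no cell-area
factor): Gaussians near the image border are therefore implicitly truncated
and renormalized by downstream sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "Grid",
    "Fixation",
    "Scanpath",
    "ModelParams",
    "MapState",
    "deg_to_cell",
    "cell_to_deg",
    "gaussian_map",
    "normalize_map",
]

# ratio fixing the slow time scales: omega_F = omega_FoR = omega_A / 10
SLOW_STREAM_RATIO = 10.0


@dataclass(frozen=True)
class Grid:
    """Discretization of the image plane in degrees of visual angle.

    Cell ``(i, j)`` is centered at ``(x[i], y[j])`` with
    ``x[i] = (i + 1/2) * extent_x / n_x`` so the cells tile ``[0, extent_x]
    x [0, extent_y]`` exactly.
    """

    n_x: int = 128
    n_y: int = 128
    extent_x: float = 32.0
    extent_y: float = 24.0

    def __post_init__(self) -> None:
        if self.n_x < 2 or self.n_y < 2:
            raise ValueError("grid needs at least 2 cells per axis")
        if not (self.extent_x > 0 and self.extent_y > 0):
            raise ValueError("grid extent must be positive")

    @property
    def dx(self) -> float:
        return self.extent_x / self.n_x

    @property
    def dy(self) -> float:
        return self.extent_y / self.n_y

    @cached_property
    def x(self) -> np.ndarray:
        """Cell-center x coordinates, shape ``(n_x,)``."""
        return (np.arange(self.n_x) + 0.5) * self.dx

    @cached_property
    def y(self) -> np.ndarray:
        """Cell-center y coordinates, shape ``(n_y,)``."""
        return (np.arange(self.n_y) + 0.5) * self.dy

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    @property
    def center(self) -> tuple[float, float]:
        return (self.extent_x / 2.0, self.extent_y / 2.0)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_x, self.n_y)


def deg_to_cell(p: Sequence[float], grid: Grid) -> tuple[int, int]:
    """Index of the grid cell whose center is nearest ``p`` (degrees).

    Coordinates outside the image extent clamp to the border cell, which
    never moves a point by more than half the extent along each axis.
    """
    x, y = float(p[0]), float(p[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite coordinates: {p!r}")
    i = min(max(math.floor(x / grid.dx), 0), grid.n_x - 1)
    j = min(max(math.floor(y / grid.dy), 0), grid.n_y - 1)
    return int(i), int(j)


def cell_to_deg(idx: Sequence[int], grid: Grid) -> tuple[float, float]:
    """Degree coordinates of the center of cell ``idx = (i, j)``."""
    i, j = int(idx[0]), int(idx[1])
    if not (0 <= i < grid.n_x and 0 <= j < grid.n_y):
        raise ValueError(f"cell index {idx!r} outside grid {grid.shape}")
    return ((i + 0.5) * grid.dx, (j + 0.5) * grid.dy)


def gaussian_map(
    center: Sequence[float],
    sigma: float | Sequence[float],
    grid: Grid,
) -> np.ndarray:
    """Isotropic (or per-axis) 2-D Gaussian evaluated at all cell centers.

    G(x, y) = 1/(2 pi sx sy) exp(-(x-xc)^2/(2 sx^2) - (y-yc)^2/(2 sy^2))

    The map is strictly positive everywhere and peaks at the cell nearest
    ``center``; the center itself may lie outside the image extent, in
    which case the visible tail is what downstream sums renormalize.
    """
    if np.isscalar(sigma):
        sx = sy = float(sigma)  # type: ignore[arg-type]
    else:
        sx, sy = float(sigma[0]), float(sigma[1])  # type: ignore[index]
    if not (sx > 0 and sy > 0):
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    xc, yc = float(center[0]), float(center[1])
    if not (math.isfinite(xc) and math.isfinite(yc)):
        raise ValueError(f"non-finite Gaussian center: {center!r}")
    gx = np.exp(-((grid.x - xc) ** 2) / (2.0 * sx * sx))
    gy = np.exp(-((grid.y - yc) ** 2) / (2.0 * sy * sy))
    return np.outer(gx, gy) / (2.0 * math.pi * sx * sy)


def normalize_map(m: np.ndarray) -> np.ndarray:
    """Divide a nonnegative map by its discrete sum so it sums to 1."""
    s = float(m.sum())
    if not (s > 0):
        raise ValueError("cannot normalize a map with non-positive sum")
    return m / s


@dataclass(frozen=True)
class Fixation:
    """One fixation: position in degrees and duration in seconds."""

    x: float
    y: float
    duration: float

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValueError(f"fixation duration must be > 0, got {self.duration}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("fixation position must be finite")

    @property
    def pos(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class Scanpath:
    """Ordered fixation sequence of one subject on one image."""

    fixations: tuple[Fixation, ...]
    image: str = "image"
    subject: str = "subject"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixations", tuple(self.fixations))
        if len(self.fixations) < 1:
            raise ValueError("a scan path holds at least one fixation")

    def __len__(self) -> int:
        return len(self.fixations)

    def __iter__(self) -> Iterator[Fixation]:
        return iter(self.fixations)

    def positions(self) -> np.ndarray:
        """Fixation positions as an ``(n, 2)`` array in degrees."""
        return np.array([[f.x, f.y] for f in self.fixations], dtype=float)

    def durations(self) -> np.ndarray:
        return np.array([f.duration for f in self.fixations], dtype=float)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the scan-path model.

    Estimated parameters (both variants): ``omega_A`` (attention build-up /
    decay rate, 1/s), ``sigma_A`` / ``sigma_F`` (attention and inhibition
    Gaussian widths, deg), ``gamma`` (map-shaping exponent), ``log_zeta``
    (log of the uniform selection-noise weight).  The extended variant adds
    ``chi`` (steepness of the oculomotor potential), ``eta`` (post-saccadic
    remap distance, deg) and ``log_psi`` (log weight of the oculomotor
    potential).

    Fixed parameters and couplings: the inhibition stream and the
    facilitation-of-return window decay ten times slower than attention
    (``omega_F = omega_FoR = omega_A / 10``); inhibition weight
    ``C_F = 0.3``; center-bias widths ``sigma_CB_x = sigma_CB_y = 4.3`` deg
    with decay ``omega_CB = 1.5`` 1/s; facilitation window half-size
    ``nu = 2`` deg (about the fovea); phase durations ``tau_pre = 0.1`` s
    and ``tau_post = 0.05`` s.  ``sigma_post`` (width of the post-saccadic
    attention Gaussian) defaults to ``sigma_A``.
    """

    omega_A: float
    sigma_A: float
    sigma_F: float
    gamma: float
    log_zeta: float
    variant: Literal["baseline", "extended"] = "baseline"
    # extended-variant estimated parameters
    chi: float = 0.0
    eta: float = 0.0
    log_psi: float = float("-inf")
    # fixed parameters
    C_F: float = 0.3
    sigma_CB_x: float = 4.3
    sigma_CB_y: float = 4.3
    omega_CB: float = 1.5
    nu: float = 2.0
    tau_pre: float = 0.1
    tau_post: float = 0.05
    sigma_post: float | None = None
    center_bias: bool | None = None
    facilitation: bool | None = None
    # how the oculomotor potential enters the priority map; "subtract"
    # penalizes off-cardinal cells, "literal" adds |−OMP/Σ OMP| verbatim
    omp_sign: Literal["subtract", "literal"] = "subtract"
    slow_ratio: float = field(default=SLOW_STREAM_RATIO)

    def __post_init__(self) -> None:
        for name in ("omega_A", "sigma_A", "sigma_F", "gamma", "omega_CB",
                     "sigma_CB_x", "sigma_CB_y", "nu"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.variant not in ("baseline", "extended"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (0 < self.zeta <= 1):
            raise ValueError("zeta = exp(log_zeta) must lie in (0, 1]")
        if self.tau_pre < 0 or self.tau_post < 0:
            raise ValueError("phase durations must be nonnegative")
        if self.chi < 0:
            raise ValueError("chi must be nonnegative")
        if self.variant == "extended" and not (self.eta > 0):
            raise ValueError("extended variant requires eta > 0")
        if self.sigma_post is not None and not (self.sigma_post > 0):
            raise ValueError("sigma_post must be positive when given")
        if self.center_bias is None:
            object.__setattr__(self, "center_bias", self.variant == "extended")
        if self.facilitation is None:
            object.__setattr__(self, "facilitation", self.variant == "extended")
        if self.variant == "baseline":
            # the baseline model has no perisaccadic machinery
            object.__setattr__(self, "tau_pre", 0.0)
            object.__setattr__(self, "tau_post", 0.0)
            object.__setattr__(self, "center_bias", False)
            object.__setattr__(self, "facilitation", False)

    # -- derived quantities -------------------------------------------------
    @property
    def zeta(self) -> float:
        return math.exp(self.log_zeta)

    @property
    def psi(self) -> float:
        return math.exp(self.log_psi) if math.isfinite(self.log_psi) else 0.0

    @property
    def omega_F(self) -> float:
        """Inhibition decay rate, fixed at ``omega_A / 10``."""
        return self.omega_A / self.slow_ratio

    @property
    def omega_FoR(self) -> float:
        """Facilitation-of-return decay rate, fixed at ``omega_A / 10``."""
        return self.omega_A / self.slow_ratio

    @property
    def sigma_post_eff(self) -> float:
        return self.sigma_A if self.sigma_post is None else self.sigma_post

    def with_updates(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    # Table-style reference values (posterior means over subjects of the
    # original corpus fits) used as simulation defaults.
    @classmethod
    def baseline_defaults(cls) -> "ModelParams":
        return cls(omega_A=14.802, sigma_A=7.482, sigma_F=4.629,
                   gamma=0.935, log_zeta=-1.132, variant="baseline")

    @classmethod
    def extended_defaults(cls) -> "ModelParams":
        return cls(omega_A=9.996, sigma_A=7.320, sigma_F=6.834,
                   gamma=0.956, log_zeta=-1.727, variant="extended",
                   chi=0.059, eta=0.415, log_psi=-0.613)


@dataclass
class MapState:
    """Evolving model state: activation ``A``, inhibition ``F``, time ``t``."""

    A: np.ndarray
    F: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.A.shape != self.F.shape:
            raise ValueError("A and F must share one grid shape")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.F))):
            raise ValueError("maps must be finite")
        if (self.A < 0).any() or (self.F < 0).any():
            raise ValueError("maps must be nonnegative")

    def copy(self) -> "MapState":
        return MapState(self.A.copy(), self.F.copy(), self.t)
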