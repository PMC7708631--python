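"""Perisaccadic mechanisms of the extended model.

Within every fixation, attention passes through up to three phases with
discrete, constant-duration shifts of the attention Gaussian:

========================  ==========================  ====================
phase                     attention center            inhibition center
========================  ==========================  ====================
post-saccadic shift       remap point (previous        current fixation
(0 .. tau_post)           saccade vector extended
                          by eta beyond landing)
main                      current fixation             current fixation
(tau_post .. t-tau_pre)
pre-saccadic shift        next fixation target         current fixation
(t-tau_pre .. t)
========================  ==========================  ====================

The saccade target is selected from the priority map at ``t_fix - tau_pre``.
Additional mechanisms: facilitation of return (slower attention decay in a
square window at the previous fixation), a center-bias initialization of
the activation map, and a plus-shaped oculomotor potential favoring
cardinal-direction saccades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Grid, MapState, ModelParams, gaussian_map, normalize_map
from .dynamics import attention_input, evolve_map

__all__ = [
    "Phase",
    "PhaseSchedule",
    "ShiftTarget",
    "schedule_phases",
    "presaccadic_gaussian",
    "postsaccadic_gaussian",
    "remap_location",
    "evolve_attention_with_FoR",
    "for_window_mask",
    "initial_activation_center_bias",
    "initial_state_center_bias",
    "oculomotor_map",
    "apply_oculomotor",
]


@dataclass(frozen=True)
class Phase:
    name: str  # "post_shift" | "main" | "pre_shift"
    start: float
    end: float
    a_center: tuple[float, float] | None  # None: decided at selection time
    f_center: tuple[float, float]

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PhaseSchedule:
    """Contiguous phases spanning ``[0, t_fix]`` for one fixation."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        ps = self.phases
        if not ps or ps[0].start != 0.0:
            raise ValueError("phases must start at 0")
        for a, b in zip(ps, ps[1:]):
            if not math.isclose(a.end, b.start, abs_tol=1e-12):
                raise ValueError("phases must be contiguous")
        if any(p.duration < 0 for p in ps):
            raise ValueError("phase durations must be nonnegative")

    @property
    def t_fix(self) -> float:
        return self.phases[-1].end

    @property
    def selection_time(self) -> float:
        """Instant the saccade target is read off the priority map."""
        pre = [p for p in self.phases if p.name == "pre_shift"]
        return pre[0].start if pre else self.t_fix

    def __iter__(self):
        return iter(self.phases)


@dataclass(frozen=True)
class ShiftTarget:
    """Post-saccadic remap point and the saccade vector that produced it."""

    x: float
    y: float
    saccade_vec: tuple[float, float]

    @property
    def pos(self) -> tuple[float, float]:
        return (self.x, self.y)


def schedule_phases(
    t_fix: float,
    tau_pre: float,
    tau_post: float,
    has_prev_saccade: bool,
    fix_n: Sequence[float],
    fix_next: Sequence[float] | None = None,
    remap: Sequence[float] | None = None,
) -> PhaseSchedule:
    """Phase boundaries for one fixation of duration ``t_fix``.

    The first fixation of a trial has no incoming saccade, hence no
    post-saccadic phase.  For short fixations (``t_fix < tau_pre +
    tau_post``) the pre-saccadic phase keeps priority — target selection
    must occur — the post-saccadic phase is truncated to
    ``max(0, t_fix - tau_pre)`` and the main phase to the remainder.
    """
    if not (t_fix > 0):
        raise ValueError(f"t_fix must be positive, got {t_fix}")
    if tau_pre < 0 or tau_post < 0:
        raise ValueError("phase durations must be nonnegative")
    fix_n = (float(fix_n[0]), float(fix_n[1]))
    pre_dur = min(tau_pre, t_fix)
    post_dur = min(tau_post, t_fix - pre_dur) if has_prev_saccade else 0.0
    main_end = t_fix - pre_dur
    phases: list[Phase] = []
    if has_prev_saccade:
        r = None if remap is None else (float(remap[0]), float(remap[1]))
        phases.append(Phase("post_shift", 0.0, post_dur, r, fix_n))
    phases.append(Phase("main", post_dur, main_end, fix_n, fix_n))
    nxt = None if fix_next is None else (float(fix_next[0]), float(fix_next[1]))
    phases.append(Phase("pre_shift", main_end, t_fix, nxt, fix_n))
    return PhaseSchedule(tuple(phases))


def presaccadic_gaussian(next_fix: Sequence[float], sigma_A: float, grid: Grid) -> np.ndarray:
    """Attention Gaussian re-centered on the upcoming fixation target."""
    return gaussian_map(next_fix, sigma_A, grid)


def remap_location(
    fix_prev: Sequence[float], fix_curr: Sequence[float], eta: float
) -> ShiftTarget:
    """Extend the previous saccade vector by ``eta`` degrees beyond landing.

    The remap point lies on the ray from ``fix_prev`` through ``fix_curr``
    at distance ``eta`` past ``fix_curr``; it may fall outside the image
    (the Gaussian evaluated there is border-truncated, never clamped).
    """
    dx = float(fix_curr[0]) - float(fix_prev[0])
    dy = float(fix_curr[1]) - float(fix_prev[1])
    norm = math.hypot(dx, dy)
    if norm == 0.0:
        raise ValueError("zero-length saccade: remap direction undefined")
    return ShiftTarget(
        float(fix_curr[0]) + dx / norm * eta,
        float(fix_curr[1]) + dy / norm * eta,
        (dx, dy),
    )


def postsaccadic_gaussian(shift: ShiftTarget, sigma_post: float, grid: Grid) -> np.ndarray:
    """Attention Gaussian centered at the post-saccadic remap point."""
    return gaussian_map(shift.pos, sigma_post, grid)


def for_window_mask(prev_fix: Sequence[float], nu: float, grid: Grid) -> np.ndarray:
    """Boolean mask of the square facilitation window around ``prev_fix``.

    Cells with ``|x - x_prev| < nu`` and ``|y - y_prev| < nu`` (coordinate-
    wise, side ``2 nu``) decay with the slow rate ``omega_FoR``.
    """
    if not (nu > 0):
        raise ValueError("nu must be positive")
    mx = np.abs(grid.x - float(prev_fix[0])) < nu
    my = np.abs(grid.y - float(prev_fix[1])) < nu
    return np.outer(mx, my)


def evolve_attention_with_FoR(
    A0: np.ndarray,
    target: np.ndarray,
    omega_A: float,
    omega_FoR: float,
    prev_fix: Sequence[float] | None,
    nu: float,
    dt: float,
    grid: Grid,
) -> np.ndarray:
    """Attention relaxation with locally slowed decay at the last fixation.

    Outside the facilitation window the map follows the ordinary closed
    form at rate ``omega_A``; inside it decays at ``omega_FoR <= omega_A``,
    so residual activation at the previous fixation lingers — the substrate
    of return saccades.  The fixed point is unchanged.
    """
    if prev_fix is None or omega_FoR == omega_A:
        return evolve_map(A0, target, omega_A, dt)
    if omega_FoR > omega_A:
        raise ValueError("omega_FoR must not exceed omega_A")
    fast = evolve_map(A0, target, omega_A, dt)
    slow = evolve_map(A0, target, omega_FoR, dt)
    mask = for_window_mask(prev_fix, nu, grid)
    return np.where(mask, slow, fast)


def initial_activation_center_bias(params: ModelParams, grid: Grid) -> np.ndarray:
    """Sum-normalized central Gaussian used as the activation state at t=0."""
    return normalize_map(
        gaussian_map(grid.center, (params.sigma_CB_x, params.sigma_CB_y), grid)
    )


def initial_state_center_bias(
    S: np.ndarray,
    params: ModelParams,
    grid: Grid,
    first_fix: Sequence[float],
    t: float = 0.0,
) -> MapState:
    """Model state during the first fixation under center-bias initialization.

    The activation map starts as a central Gaussian of widths
    ``(sigma_CB_x, sigma_CB_y)`` and relaxes — at the slow center-bias rate
    ``omega_CB`` — toward the ordinary local-saliency input at the first
    fixation (attention Gaussian of width ``sigma_A``).  Inhibition starts
    at zero.
    """
    A0 = initial_activation_center_bias(params, grid)
    target = attention_input(S, gaussian_map(first_fix, params.sigma_A, grid))
    A = evolve_map(A0, target, params.omega_CB, t)
    F = np.zeros(grid.shape)
    return MapState(A=A, F=F, t=t)


def oculomotor_map(fix: Sequence[float], chi: float, grid: Grid) -> np.ndarray:
    """Plus-shaped oculomotor potential ``((x-xf)^2 (y-yf)^2)^chi``.

    Exactly zero on the cardinal cross through the fixation (cells sharing
    its row or column when it sits on a cell center); ``0^0`` at
    ``chi = 0`` is defined as 0 so the plus shape persists continuously.
    """
    if chi < 0:
        raise ValueError("chi must be nonnegative")
    dx2 = (grid.x - float(fix[0])) ** 2
    dy2 = (grid.y - float(fix[1])) ** 2
    base = np.outer(dx2, dy2)
    if chi == 0.0:
        return np.where(base > 0.0, 1.0, 0.0)
    return np.power(base, chi)


def apply_oculomotor(u: np.ndarray, omp: np.ndarray, psi: float,
                     sign: str = "subtract") -> np.ndarray:
    """Add the normalized oculomotor potential to the signed priority map.

    Default convention (``sign="subtract"``): ``u - psi * OMP / sum(OMP)``,
    which leaves the cardinal cross untouched and suppresses off-cardinal
    cells, producing the cardinal-direction peaks in the absolute-angle
    distribution.  ``sign="literal"`` applies ``u + psi * |−OMP/sum(OMP)|``
    instead (the additive form), kept behind a flag because it rewards
    off-cardinal cells.
    """
    if psi == 0.0:
        return u
    s = float(omp.sum())
    if not (s > 0):
        raise ValueError("oculomotor map sums to zero with psi != 0")
    if sign == "subtract":
        return u - psi * (omp / s)
    if sign == "literal":
        return u + psi * np.abs(-omp / s)
    raise ValueError(f"unknown oculomotor sign convention {sign!r}")
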