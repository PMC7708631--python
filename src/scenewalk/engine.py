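"""Phase-driven scan-path engine shared by simulation and likelihood.

One code path replays or generates a scan path: the same sequence of
post-saccadic / main / pre-saccadic phases, facilitation of return,
center-bias initialization and oculomotor potential runs whether the next
fixation is sampled from the selection map (simulation) or supplied from
data (teacher-forced likelihood evaluation).

Timing convention: the saccade target is selected from the priority map at
``t_fix - tau_pre``; the attention stream then relaxes toward the chosen
target during the pre-saccadic phase, while inhibition stays centered on
the current fixation for the entire fixation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import Grid, MapState, ModelParams, gaussian_map, normalize_map
from .dynamics import (
    attention_input,
    combine_priority,
    evolve_map,
    rectify,
    selection_probability,
    shape_map,
)
from .perisaccadic import (
    apply_oculomotor,
    for_window_mask,
    initial_activation_center_bias,
    oculomotor_map,
    remap_location,
    schedule_phases,
)

__all__ = ["SceneWalkEngine"]


class SceneWalkEngine:
    """Stateful evolution of the activation and inhibition maps on one image.

    Usage::

        eng = SceneWalkEngine(S, params, grid)
        pi0 = eng.initial_selection_map()      # predicts the first fixation
        eng.begin(first_fix)
        pi, nxt = eng.step(duration, next_pos=observed)   # replay, or
        pi, nxt = eng.step(duration, rng=rng)             # simulate

    Each ``step`` evolves the maps through the current fixation's
    post-saccadic and main phases, builds the selection map, fixes the next
    fixation position (observed or sampled), runs the pre-saccadic phase,
    and advances the current fixation to ``next_pos``.
    """

    def __init__(self, S: np.ndarray, params: ModelParams, grid: Grid):
        S = np.asarray(S, dtype=float)
        if S.shape != grid.shape:
            raise ValueError(f"saliency shape {S.shape} != grid shape {grid.shape}")
        if (S < 0).any():
            raise ValueError("saliency map must be nonnegative")
        if not (S.sum() > 0):
            raise ValueError("saliency map must not be identically zero")
        self.S = S
        self.params = params
        self.grid = grid
        self._uniform = np.full(grid.shape, 1.0 / grid.n_cells)
        self._facilitation = bool(params.facilitation)
        self.state: MapState | None = None
        self._fix: tuple[float, float] | None = None
        self._prev_fix: tuple[float, float] | None = None
        self._fix_index = 0
        # small memo caches: attention targets recur between the pre-shift
        # of one fixation and the main phase of the next
        self._target_cache: dict[tuple, np.ndarray] = {}
        self._mask_cache: dict[tuple, np.ndarray] = {}

    # -- initialization -----------------------------------------------------
    def initial_selection_map(self) -> np.ndarray:
        """Probability map for the first fixation of a trial.

        Under center-bias initialization this is the central Gaussian (plus
        selection noise); otherwise the initial activation is uniform and
        so is the map.
        """
        p = self.params
        if p.center_bias:
            A0 = initial_activation_center_bias(p, self.grid)
            return selection_probability(rectify(A0), p.zeta)
        return self._uniform.copy()

    def begin(self, first_fix: Sequence[float]) -> None:
        """Reset state for a new scan path starting at ``first_fix``."""
        p = self.params
        if p.center_bias:
            A0 = initial_activation_center_bias(p, self.grid)
            F0 = np.zeros(self.grid.shape)
        else:
            A0 = self._uniform.copy()
            F0 = self._uniform.copy()
        self.state = MapState(A=A0, F=F0, t=0.0)
        self._fix = (float(first_fix[0]), float(first_fix[1]))
        self._prev_fix = None
        self._fix_index = 0

    # -- internals ----------------------------------------------------------
    def _attention_target(self, center: Sequence[float], sigma: float) -> np.ndarray:
        key = (float(center[0]), float(center[1]), float(sigma))
        hit = self._target_cache.get(key)
        if hit is None:
            hit = attention_input(self.S, gaussian_map(center, sigma, self.grid))
            if len(self._target_cache) > 8:
                self._target_cache.clear()
            self._target_cache[key] = hit
        return hit

    def _for_mask(self) -> np.ndarray:
        key = self._prev_fix
        hit = self._mask_cache.get(key)
        if hit is None:
            hit = for_window_mask(self._prev_fix, self.params.nu, self.grid)
            if len(self._mask_cache) > 4:
                self._mask_cache.clear()
            self._mask_cache[key] = hit
        return hit

    def _evolve_A(self, A: np.ndarray, target: np.ndarray, omega: float,
                  dt: float) -> np.ndarray:
        if dt <= 0:
            return A
        if self._facilitation and self._prev_fix is not None:
            fast = evolve_map(A, target, omega, dt)
            slow = evolve_map(A, target, self.params.omega_FoR, dt)
            return np.where(self._for_mask(), slow, fast)
        return evolve_map(A, target, omega, dt)

    def _selection_map(self, A: np.ndarray, F: np.ndarray) -> np.ndarray:
        p = self.params
        if float(F.sum()) > 0:
            u = combine_priority(A, F, p.gamma, p.C_F)
        else:
            # inhibition not yet built up (center-bias start, very short
            # first fixation): pure attention read-out
            u = shape_map(A, p.gamma)
        if p.variant == "extended" and p.psi != 0.0:
            omp = oculomotor_map(self._fix, p.chi, self.grid)
            u = apply_oculomotor(u, omp, p.psi, sign=p.omp_sign)
        return selection_probability(rectify(u), p.zeta)

    # -- one fixation -------------------------------------------------------
    def step(
        self,
        duration: float,
        next_pos: Sequence[float] | None = None,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, tuple[float, float]]:
        """Process the current fixation and move to the next one.

        Exactly one of ``next_pos`` (teacher forcing) or ``rng`` (sampling
        from the selection map) must be given.  Returns ``(pi, next_pos)``
        where ``pi`` is the selection map the next fixation was (or would
        have been) drawn from.
        """
        if self.state is None or self._fix is None:
            raise RuntimeError("call begin() before step()")
        if (next_pos is None) == (rng is None):
            raise ValueError("give exactly one of next_pos or rng")
        p, grid = self.params, self.grid
        fix = self._fix
        first = self._fix_index == 0

        has_prev = self._prev_fix is not None and tuple(self._prev_fix) != fix
        remap = None
        if has_prev and p.variant == "extended" and p.tau_post > 0:
            remap = remap_location(self._prev_fix, fix, p.eta).pos
        sched = schedule_phases(
            duration, p.tau_pre, p.tau_post,
            has_prev_saccade=remap is not None, fix_n=fix, remap=remap)
        pre_dur = duration - sched.selection_time

        A, F = self.state.A, self.state.F
        gf = normalize_map(gaussian_map(fix, p.sigma_F, grid))
        main_rate = p.omega_CB if (first and p.center_bias) else p.omega_A

        for phase in sched:
            if phase.name == "pre_shift":
                break
            if phase.duration <= 0:
                continue
            if phase.name == "post_shift":
                target = self._attention_target(phase.a_center, p.sigma_post_eff)
                A = self._evolve_A(A, target, p.omega_A, phase.duration)
            else:  # main
                target = self._attention_target(fix, p.sigma_A)
                A = self._evolve_A(A, target, main_rate, phase.duration)
        F = evolve_map(F, gf, p.omega_F, sched.selection_time)

        pi = self._selection_map(A, F)
        if next_pos is None:
            flat = rng.choice(grid.n_cells, p=pi.ravel())
            i, j = divmod(int(flat), grid.n_y)
            nxt = ((i + 0.5) * grid.dx, (j + 0.5) * grid.dy)
        else:
            nxt = (float(next_pos[0]), float(next_pos[1]))

        if pre_dur > 0:
            target = self._attention_target(nxt, p.sigma_A)
            A = self._evolve_A(A, target, p.omega_A, pre_dur)
            F = evolve_map(F, gf, p.omega_F, pre_dur)

        self.state = MapState(A=A, F=F, t=self.state.t + duration)
        self._prev_fix = fix
        self._fix = nxt
        self._fix_index += 1
        return pi, nxt
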