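"""Bayesian parameter estimation via differential-evolution MCMC.

The posterior P(theta | data) is proportional to L(theta | data) P(theta),
with the likelihood the teacher-forced scan-path likelihood (sum over a
subject's training paths, in nats) and broad bounded-uniform priors.
Sampling uses a DREAM-class scheme: multiple chains propose jumps built
from differences of states in a growing past archive (DE-MC(Z), ter Braak
& Vrugt style), with occasional snooker updates for scale changes.  Fixed
parameter couplings (inhibition rate = attention rate / 10, inhibition
weight 0.3, center-bias constants, phase durations) live inside the
likelihood and are never sampled.

Point estimates follow the highest-posterior-density convention: the
shortest interval containing 50% of the draws, reported with its bounds;
the estimate is the interval midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import Grid, ModelParams, Scanpath
from .likelihood import LOG2, dataset_sum_log2

__all__ = [
    "PriorSpec",
    "PosteriorSample",
    "MCMCResult",
    "default_prior",
    "log_posterior",
    "make_log_posterior",
    "run_mcmc",
    "hpd_point_estimate",
    "gelman_rubin",
    "credible_interval",
    "fit_subject",
]

BASELINE_PARAMS = ("omega_A", "sigma_A", "sigma_F", "gamma", "log_zeta")
EXTENDED_PARAMS = BASELINE_PARAMS + ("chi", "eta", "log_psi")

# broad bounded-uniform supports per parameter (natural or log scale as the
# parameter is defined); chosen to bracket plausible subject-level estimates
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "omega_A": (0.1, 60.0),
    "sigma_A": (0.5, 15.0),
    "sigma_F": (0.5, 15.0),
    "gamma": (0.1, 3.0),
    "log_zeta": (-6.0, 0.0),
    "chi": (0.0, 0.5),
    "eta": (1e-3, 3.0),
    "log_psi": (-4.0, 1.0),
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent bounded-uniform priors over the estimated parameters."""

    names: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name in self.names:
            lo, hi = self.bounds[name]
            if not (hi > lo):
                raise ValueError(f"empty prior support for {name}")

    @property
    def dim(self) -> int:
        return len(self.names)

    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in self.names])

    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in self.names])

    def log_prior(self, theta: np.ndarray) -> float:
        lo, hi = self.lower(), self.upper()
        if np.any(theta <= lo) or np.any(theta >= hi):
            return float("-inf")
        return float(-np.sum(np.log(hi - lo)))

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        lo, hi = self.lower(), self.upper()
        return rng.uniform(lo, hi, size=(n, self.dim))


def default_prior(variant: str = "extended") -> PriorSpec:
    names = EXTENDED_PARAMS if variant == "extended" else BASELINE_PARAMS
    return PriorSpec(names=names, bounds=dict(DEFAULT_BOUNDS))


@dataclass(frozen=True)
class PosteriorSample:
    chain: int
    iteration: int
    theta: tuple[float, ...]
    log_posterior: float


@dataclass
class MCMCResult:
    """Chains, diagnostics and tidy access to posterior draws."""

    names: tuple[str, ...]
    chains: np.ndarray  # (n_chains, n_iter, dim)
    log_post: np.ndarray  # (n_chains, n_iter)
    acceptance_rate: np.ndarray  # per chain
    seed: int | None = None
    burn_fraction: float = 0.5

    def samples(self, burn: float | None = None) -> list[PosteriorSample]:
        burn = self.burn_fraction if burn is None else burn
        start = int(burn * self.chains.shape[1])
        return [
            PosteriorSample(c, i, tuple(self.chains[c, i]), float(self.log_post[c, i]))
            for c in range(self.chains.shape[0])
            for i in range(start, self.chains.shape[1])
        ]

    def draws(self, name: str, burn: float | None = None) -> np.ndarray:
        burn = self.burn_fraction if burn is None else burn
        start = int(burn * self.chains.shape[1])
        k = self.names.index(name)
        return self.chains[:, start:, k].ravel()

    def rhat(self, burn: float | None = None) -> dict[str, float]:
        burn = self.burn_fraction if burn is None else burn
        start = int(burn * self.chains.shape[1])
        return {
            n: gelman_rubin(self.chains[:, start:, k])
            for k, n in enumerate(self.names)
        }

    def to_frame(self, burn: float | None = None) -> pd.DataFrame:
        burn = self.burn_fraction if burn is None else burn
        start = int(burn * self.chains.shape[1])
        rows = []
        for c in range(self.chains.shape[0]):
            for i in range(start, self.chains.shape[1]):
                rows.append((c, i, *self.chains[c, i], float(self.log_post[c, i])))
        return pd.DataFrame(rows, columns=["chain", "iter", *self.names, "log_posterior"])


def log_posterior(
    theta: np.ndarray,
    paths: Sequence[Scanpath],
    S,
    prior: PriorSpec,
    template: ModelParams,
    grid: Grid | None = None,
) -> float:
    """log P(theta) + log L(theta | paths), in nats, up to the evidence.

    Out-of-support parameter vectors score ``-inf``; so does a non-finite
    likelihood.  The per-path likelihood terms enter through a plain sum,
    so the value is independent of evaluation order by construction.
    """
    lp = prior.log_prior(np.asarray(theta, dtype=float))
    if not math.isfinite(lp):
        return float("-inf")
    try:
        params = template.with_updates(**dict(zip(prior.names, map(float, theta))))
        ll = dataset_sum_log2(paths, S, params, grid) * LOG2
    except (ValueError, FloatingPointError):
        return float("-inf")
    if not math.isfinite(ll):
        return float("-inf")
    return lp + ll


def make_log_posterior(
    paths: Sequence[Scanpath],
    S,
    prior: PriorSpec,
    template: ModelParams,
    grid: Grid | None = None,
) -> Callable[[np.ndarray], float]:
    return lambda theta: log_posterior(theta, paths, S, prior, template, grid)


# -- DE-MC(Z) sampler --------------------------------------------------------

def run_mcmc(
    log_post: Callable[[np.ndarray], float],
    prior: PriorSpec,
    n_chains: int = 3,
    n_iter: int = 2000,
    seed: int | None = None,
    snooker_prob: float = 0.1,
    archive_thin: int = 10,
    jitter: float = 1e-6,
) -> MCMCResult:
    """Multi-chain differential-evolution MCMC with snooker updates.

    Each chain proposes ``x + gamma (z1 - z2) + e`` with ``z1, z2`` drawn
    from the archive of past states (``gamma = 2.38 / sqrt(2 d)``, set to 1
    every tenth iteration to allow mode jumps), or — with probability
    ``snooker_prob`` — a snooker move along the line through the chain and
    an archive point.  The archive grows by the current chain states every
    ``archive_thin`` iterations, which preserves ergodicity at few chains.
    """
    rng = np.random.default_rng(seed)
    d = prior.dim
    if n_chains < 3:
        raise ValueError("need at least 3 chains for difference proposals")

    # Initialization: score a pool of prior draws, start the chains at the
    # best ones (a standard overdispersed-but-informed start), and seed the
    # archive with the whole pool.
    n_pool = max(10 * d, 4 * n_chains)
    pool = prior.sample(rng, n_pool)
    pool_lp = np.array([log_post(x) for x in pool])
    if not np.isfinite(pool_lp).any():
        raise RuntimeError("could not find a finite-posterior start point")
    order = np.argsort(pool_lp)[::-1]
    X = pool[order[:n_chains]].copy()
    lp = pool_lp[order[:n_chains]].copy()
    Z = list(pool)

    chains = np.empty((n_chains, n_iter, d))
    lps = np.empty((n_chains, n_iter))
    accepts = np.zeros(n_chains)
    crossovers = (max(1, d // 3), max(1, (2 * d) // 3), d)

    for it in range(n_iter):
        for c in range(n_chains):
            x, lx = X[c], lp[c]
            if rng.random() < snooker_prob and len(Z) >= 3:
                # snooker: jump along the line x - z, using projections of
                # two further archive points onto that line
                idx = rng.choice(len(Z), size=3, replace=False)
                z, z1, z2 = (Z[i] for i in idx)
                dvec = x - z
                nrm2 = float(dvec @ dvec)
                if nrm2 == 0.0:
                    continue
                gs = rng.uniform(1.2, 2.2)
                proj = ((z1 - z2) @ dvec) / nrm2
                y = x + gs * proj * dvec
                ly = log_post(y)
                norm_ratio = float((y - z) @ (y - z)) / nrm2
                log_alpha = (ly - lx) + 0.5 * (d - 1) * math.log(norm_ratio) \
                    if norm_ratio > 0 else float("-inf")
            else:
                # parallel-direction move in a random coordinate subspace
                # (DREAM-style crossover improves acceptance at higher d)
                idx = rng.choice(len(Z), size=2, replace=False)
                diff = Z[idx[0]] - Z[idx[1]]
                k = crossovers[rng.integers(len(crossovers))]
                active = rng.choice(d, size=k, replace=False) if k < d \
                    else np.arange(d)
                gamma = 1.0 if (it % 10) == 9 else 2.38 / math.sqrt(2 * k)
                step = np.zeros(d)
                step[active] = (gamma * (1 + rng.uniform(-0.1, 0.1))
                                * diff[active]
                                + rng.normal(0.0, jitter, size=k))
                y = x + step
                ly = log_post(y)
                log_alpha = ly - lx
            if math.isfinite(ly) and math.log(rng.random()) < log_alpha:
                X[c], lp[c] = y, ly
                accepts[c] += 1
        chains[:, it] = X
        lps[:, it] = lp
        if (it + 1) % archive_thin == 0:
            Z.extend(X.copy())

    return MCMCResult(
        names=prior.names,
        chains=chains,
        log_post=lps,
        acceptance_rate=accepts / n_iter,
        seed=seed,
    )


def hpd_point_estimate(
    samples: Sequence[float], alpha: float = 0.5
) -> tuple[float, float, float]:
    """Midpoint and bounds of the shortest interval holding ``alpha`` mass.

    Assumes a unimodal marginal.  Returns ``(estimate, lower, upper)``.
    """
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n < 100:
        raise ValueError(f"need at least 100 draws for an HPD estimate, got {n}")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    k = max(2, int(math.ceil(alpha * n)))
    widths = s[k - 1:] - s[: n - k + 1]
    i = int(np.argmin(widths))
    lo, hi = float(s[i]), float(s[i + k - 1])
    return (lo + hi) / 2.0, lo, hi


def credible_interval(samples: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Central (equal-tailed) credible interval from posterior draws."""
    q = (1 - level) / 2
    lo, hi = np.quantile(np.asarray(samples, dtype=float), [q, 1 - q])
    return float(lo), float(hi)


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor R-hat for one parameter.

    ``chains`` has shape (n_chains, n_iter).  Values near 1 indicate the
    chains have mixed; > 1.1 is the conventional warning level.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2 or n < 2:
        return float("nan")
    means = chains.mean(axis=1)
    variances = chains.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * means.var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    if W == 0:
        return 1.0
    return float(math.sqrt(var_hat / W))


def fit_subject(
    paths: Sequence[Scanpath],
    S,
    template: ModelParams,
    prior: PriorSpec | None = None,
    grid: Grid | None = None,
    n_chains: int = 3,
    n_iter: int = 2000,
    seed: int | None = None,
) -> MCMCResult:
    """Independent fit of one subject's training scan paths.

    Convergence is surfaced, not hidden: inspect ``result.rhat()`` after
    the run (values above 1.1 mean the chains have not mixed).
    """
    prior = prior or default_prior(template.variant)
    lp = make_log_posterior(paths, S, prior, template, grid)
    return run_mcmc(lp, prior, n_chains=n_chains, n_iter=n_iter, seed=seed)
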