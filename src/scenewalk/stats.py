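"""Gaze statistics computed identically for empirical and simulated data.

All statistics operate on :class:`SaccadeRecord` rows derived from scan
paths, so the empirical and simulated pipelines share one code path.
Conventions: saccade amplitude is the Euclidean distance between the two
fixations (degrees); absolute direction is measured in 0..360 degrees with
0 = rightward; the turning angle is the signed divergence of a saccade
from its predecessor's direction, in (-180, 180], with 0 = forward
continuation and 180 = full reversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Scanpath

__all__ = [
    "SaccadeRecord",
    "saccades_from_path",
    "saccades_from_paths",
    "turning_angle",
    "normalized_joint_density",
    "binned_by_turning_angle",
    "distribution_summaries",
]


@dataclass(frozen=True)
class SaccadeRecord:
    """One saccade with the quantities the gaze analyses need."""

    subject: str
    image: str
    launch: tuple[float, float]
    landing: tuple[float, float]
    amplitude: float
    direction: float  # absolute, degrees in [0, 360)
    turning: float | None  # signed, (-180, 180]; None on a path's first saccade
    preceding_duration: float  # duration of the launch fixation (s)


def turning_angle(prev_vec: Sequence[float], next_vec: Sequence[float]) -> float:
    """Signed angle (degrees) between consecutive saccade vectors.

    0 means the second saccade continues the first's direction; 180 means
    it reverses it.  Result lies in (-180, 180].
    """
    px, py = float(prev_vec[0]), float(prev_vec[1])
    nx, ny = float(next_vec[0]), float(next_vec[1])
    if (px == 0 and py == 0) or (nx == 0 and ny == 0):
        raise ValueError("turning angle undefined for a zero-length saccade")
    ang = math.degrees(math.atan2(ny, nx) - math.atan2(py, px))
    ang = (ang + 180.0) % 360.0 - 180.0
    return 180.0 if ang == -180.0 else ang


def saccades_from_path(path: Scanpath) -> list[SaccadeRecord]:
    """n-1 saccade records from an n-fixation path (empty when n < 2)."""
    records: list[SaccadeRecord] = []
    fx = path.fixations
    for k in range(len(fx) - 1):
        a, b = fx[k], fx[k + 1]
        vec = (b.x - a.x, b.y - a.y)
        amp = math.hypot(*vec)
        direction = math.degrees(math.atan2(vec[1], vec[0])) % 360.0
        turning = None
        if k > 0:
            prev = (a.x - fx[k - 1].x, a.y - fx[k - 1].y)
            if (prev != (0.0, 0.0)) and amp > 0:
                turning = turning_angle(prev, vec)
        records.append(SaccadeRecord(
            subject=path.subject, image=path.image,
            launch=(a.x, a.y), landing=(b.x, b.y),
            amplitude=amp, direction=direction, turning=turning,
            preceding_duration=a.duration,
        ))
    return records


def saccades_from_paths(paths: Iterable[Scanpath]) -> list[SaccadeRecord]:
    return [r for p in paths for r in saccades_from_path(p)]


def normalized_joint_density(
    paths: Iterable[Scanpath],
    window: float = 2.0,
    bin_width: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Joint density of successive saccades in saccade-relative coordinates.

    Each next-saccade landing point is translated so the current fixation
    sits at the origin, rotated so the previous saccade points along +x,
    and scaled by the previous amplitude — i.e., the previous saccade moved
    from (-1, 0) to (0, 0).  A return saccade of equal amplitude lands at
    (-1, 0); a forward continuation at (1, 0).

    Returns ``(H, edges, n_skipped)``: the normalized 2-D histogram over
    ``[-window, window]^2`` (x indexed first), its shared bin edges, and
    the number of pairs skipped for a zero-amplitude previous saccade.
    """
    edges = np.arange(-window, window + bin_width / 2, bin_width)
    pts = []
    skipped = 0
    for path in paths:
        recs = saccades_from_path(path)
        for prev, nxt in zip(recs, recs[1:]):
            if prev.amplitude == 0:
                skipped += 1
                continue
            dx = nxt.landing[0] - nxt.launch[0]
            dy = nxt.landing[1] - nxt.launch[1]
            c = (prev.landing[0] - prev.launch[0]) / prev.amplitude
            s = (prev.landing[1] - prev.launch[1]) / prev.amplitude
            # rotate by -angle(prev) and scale by 1/|prev|
            pts.append(((c * dx + s * dy) / prev.amplitude,
                        (-s * dx + c * dy) / prev.amplitude))
    if not pts:
        raise ValueError("no saccade pairs available")
    arr = np.asarray(pts)
    H, _, _ = np.histogram2d(arr[:, 0], arr[:, 1], bins=[edges, edges])
    total = H.sum()
    if total > 0:
        H = H / total
    return H, edges, skipped


def binned_by_turning_angle(
    records: Sequence[SaccadeRecord],
    value: str = "preceding_duration",
    bin_width: float = 30.0,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Mean of a saccade property per folded turning-angle bin.

    Angles are folded to [0, 180] (forward vs. return is symmetric in
    sign), binned at ``bin_width`` degrees, and summarized per bin by the
    mean over saccades plus a percentile bootstrap 95% CI over subjects.
    Empty bins are reported as missing rows, never as zeros.
    """
    if value not in ("preceding_duration", "amplitude"):
        raise ValueError(f"unsupported value {value!r}")
    rows = [
        (r.subject, min(abs(r.turning), 180.0), getattr(r, value))
        for r in records if r.turning is not None
    ]
    if not rows:
        raise ValueError("no saccades with a defined turning angle")
    df = pd.DataFrame(rows, columns=["subject", "angle", "value"])
    edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
    df["bin"] = np.clip(np.digitize(df["angle"], edges) - 1, 0, len(edges) - 2)
    rng = np.random.default_rng(seed)
    subjects = df["subject"].unique()
    out = []
    for b in range(len(edges) - 1):
        sub = df[df["bin"] == b]
        if sub.empty:
            continue
        mean = float(sub["value"].mean())
        per_subj = sub.groupby("subject")["value"].mean()
        if len(subjects) > 1 and n_boot > 0:
            boots = [
                per_subj.reindex(rng.choice(per_subj.index, len(per_subj))).mean()
                for _ in range(n_boot)
            ]
            lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        else:
            lo = hi = float("nan")
        out.append((edges[b], edges[b + 1], (edges[b] + edges[b + 1]) / 2,
                    mean, float(lo), float(hi), len(sub)))
    return pd.DataFrame(
        out, columns=["bin_lo", "bin_hi", "bin_center", "mean", "ci_lo", "ci_hi", "n"])


def _per_subject_hist(values_by_subject: dict[str, np.ndarray],
                      edges: np.ndarray) -> pd.DataFrame:
    rows = {}
    for subject, vals in values_by_subject.items():
        h, _ = np.histogram(vals, bins=edges)
        total = h.sum()
        rows[subject] = h / total if total > 0 else h.astype(float)
    return pd.DataFrame(rows, index=0.5 * (edges[:-1] + edges[1:]))


def _band(df: pd.DataFrame, n_boot: int, rng: np.random.Generator) -> pd.DataFrame:
    out = pd.DataFrame({"center": df.index, "mean": df.mean(axis=1)})
    if df.shape[1] > 1 and n_boot > 0:
        boots = np.empty((n_boot, len(df)))
        cols = np.asarray(df.columns)
        for b in range(n_boot):
            pick = rng.choice(cols, size=len(cols))
            boots[b] = df[pick].mean(axis=1)
        out["lo"], out["hi"] = np.percentile(boots, [2.5, 97.5], axis=0)
    else:
        out["lo"] = out["hi"] = float("nan")
    return out.reset_index(drop=True)


def distribution_summaries(
    records: Sequence[SaccadeRecord],
    amplitude_bin: float = 1.0,
    angle_bin: float = 10.0,
    max_amplitude: float | None = None,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> dict[str, pd.DataFrame]:
    """Amplitude, absolute-angle and turning-angle histograms with bands.

    Histograms are normalized per subject, then summarized across subjects
    by the mean and a percentile-bootstrap 95% band (omitted for a single
    subject).  Returns a dict with keys ``amplitude``, ``absolute_angle``
    and ``turning_angle``, each a tidy frame with columns
    ``center, mean, lo, hi``.
    """
    if not records:
        raise ValueError("no saccade records")
    rng = np.random.default_rng(seed)
    subjects = sorted({r.subject for r in records})
    amp = {s: np.array([r.amplitude for r in records if r.subject == s])
           for s in subjects}
    ang = {s: np.array([r.direction for r in records if r.subject == s])
           for s in subjects}
    turn = {s: np.array([r.turning for r in records
                         if r.subject == s and r.turning is not None])
            for s in subjects}
    if max_amplitude is None:
        max_amplitude = max(float(v.max()) for v in amp.values() if v.size)
    amp_edges = np.arange(0.0, max_amplitude + amplitude_bin, amplitude_bin)
    ang_edges = np.arange(0.0, 360.0 + angle_bin / 2, angle_bin)
    turn_edges = np.arange(-180.0, 180.0 + angle_bin / 2, angle_bin)
    return {
        "amplitude": _band(_per_subject_hist(amp, amp_edges), n_boot, rng),
        "absolute_angle": _band(_per_subject_hist(ang, ang_edges), n_boot, rng),
        "turning_angle": _band(_per_subject_hist(turn, turn_edges), n_boot, rng),
    }
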