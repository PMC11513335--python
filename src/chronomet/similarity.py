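"""Trajectory-similarity search.

Candidate metabolites are ranked against a reference trajectory using a
time-windowed (banded) discrete Fréchet distance, plain Euclidean/Manhattan
distances, or Pearson correlation, either on per-subject curves (averaged
across subjects) or on the cross-subject mean trajectories.  All measures
assume z-scored data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientOverlapError, LookupFailure
from .study import DEFAULT_BLOCK_SPACER_MIN, ProfileDataset, StudyDesign

MEASURES = ("frechet", "euclidean", "manhattan", "pearson")
MODES = ("per_subject_mean", "mean_trajectory")

#: Minimum shared observed time points for a per-subject comparison.
MIN_SHARED_POINTS = 3


@dataclass(frozen=True)
class BandPolicy:
    """Coupling windows for the banded Fréchet distance.

    Two curve points may be matched only if their time stamps differ by at
    most the window: ±30 min by default, relaxed to ±120 min when either
    stamp lies inside the extended-fasting challenge span.
    """

    default_window_min: float = 30.0
    fasting_window_min: float = 120.0

    def __post_init__(self) -> None:
        if self.default_window_min < 0 or self.fasting_window_min < 0:
            raise DomainError("windows must be non-negative")

    def window(self, t1: float, t2: float, fasting_span: tuple[float, float] | None) -> float:
        if fasting_span is not None:
            lo, hi = fasting_span
            if lo <= t1 <= hi or lo <= t2 <= hi:
                return self.fasting_window_min
        return self.default_window_min


def banded_frechet(
    P: list[tuple[float, float]],
    Q: list[tuple[float, float]],
    band: BandPolicy | None = None,
    design: StudyDesign | None = None,
    spacer: float = DEFAULT_BLOCK_SPACER_MIN,
) -> float:
    """Discrete Fréchet distance with a time-stamp coupling band.

    The point cost is |v_i − v_j| when |t_i − t_j| is within the band's
    window and +inf otherwise; the recurrence is the standard discrete
    Fréchet dynamic programme.  Returns ``inf`` when no finite monotone
    coupling exists.
    """
    if not P or not Q:
        raise DomainError("banded_frechet requires non-empty curves")
    band = band or BandPolicy()
    span = design.fasting_axis_span(spacer) if design is not None else None

    tp = np.array([t for t, _ in P])
    vp = np.array([v for _, v in P])
    tq = np.array([t for t, _ in Q])
    vq = np.array([v for _, v in Q])
    n, m = len(P), len(Q)

    cost = np.abs(vp[:, None] - vq[None, :])
    dt = np.abs(tp[:, None] - tq[None, :])
    if span is not None:
        in_span = ((span[0] <= tp) & (tp <= span[1]))[:, None] | (
            (span[0] <= tq) & (tq <= span[1])
        )[None, :]
        win = np.where(in_span, band.fasting_window_min, band.default_window_min)
    else:
        win = np.full((n, m), band.default_window_min)
    cost = np.where(dt <= win, cost, np.inf)

    c = np.full((n, m), np.inf)
    c[0, 0] = cost[0, 0]
    for j in range(1, m):
        c[0, j] = max(c[0, j - 1], cost[0, j])
    for i in range(1, n):
        c[i, 0] = max(c[i - 1, 0], cost[i, 0])
        prev, cur = c[i - 1], c[i]
        for j in range(1, m):
            cur[j] = max(min(prev[j], cur[j - 1], prev[j - 1]), cost[i, j])
    return float(c[n - 1, m - 1])


def pointwise_distance(x, y, metric: str) -> float:
    """Euclidean / Manhattan distance or Pearson correlation of two aligned vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("x and y must have the same length")
    min_n = 3 if metric == "pearson" else 2
    if len(x) < min_n:
        raise DomainError(f"{metric} needs at least {min_n} points, got {len(x)}")
    if metric == "euclidean":
        return float(math.sqrt(np.sum((x - y) ** 2)))
    if metric == "manhattan":
        return float(np.sum(np.abs(x - y)))
    if metric == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    raise DomainError(f"unknown metric {metric!r}")


def _aligned_values(ds, ref, cand, subject, tp_range, spacer):
    """Shared observed (times, ref values, cand values) for one subject/mean."""
    a = dict(ds.trajectory(ref, subject, spacer, tp_range))
    b = dict(ds.trajectory(cand, subject, spacer, tp_range))
    times = sorted(set(a) & set(b))
    return times, [a[t] for t in times], [b[t] for t in times]


def trajectory_similarity(
    ds: ProfileDataset,
    ref: str,
    cand: str,
    measure: str = "frechet",
    mode: str = "mean_trajectory",
    subjects=None,
    tp_range: tuple[int, int] | None = None,
    band: BandPolicy | None = None,
    spacer: float = DEFAULT_BLOCK_SPACER_MIN,
) -> tuple[float, int]:
    """Similarity of a candidate to a reference metabolite.

    ``per_subject_mean`` computes the measure within each chosen subject on
    their shared observed time points (subjects with fewer than 3 shared
    points are skipped) and returns the unweighted mean over retained
    subjects; ``mean_trajectory`` applies the measure once to the two
    cross-subject mean trajectories.  Returns (score, subjects used).
    """
    if measure not in MEASURES:
        raise DomainError(f"unknown measure {measure!r}")
    if mode not in MODES:
        raise DomainError(f"unknown mode {mode!r}")
    subjects = list(subjects) if subjects is not None else list(ds.design.subjects)

    if mode == "mean_trajectory":
        sub = ds if set(subjects) == set(ds.design.subjects) else ds.subset(subjects=subjects)
        if measure == "frechet":
            P = sub.trajectory(ref, "mean", spacer, tp_range)
            Q = sub.trajectory(cand, "mean", spacer, tp_range)
            if not P or not Q:
                raise InsufficientOverlapError(f"empty mean trajectory for {ref!r} or {cand!r}")
            return banded_frechet(P, Q, band, ds.design, spacer), len(subjects)
        times, xv, yv = _aligned_values(sub, ref, cand, "mean", tp_range, spacer)
        if len(times) < (3 if measure == "pearson" else 2):
            raise InsufficientOverlapError(
                f"mean trajectories of {ref!r} and {cand!r} share too few points"
            )
        return pointwise_distance(xv, yv, measure), len(subjects)

    scores = []
    for subj in subjects:
        times, xv, yv = _aligned_values(ds, ref, cand, subj, tp_range, spacer)
        if len(times) < MIN_SHARED_POINTS:
            continue
        if measure == "frechet":
            scores.append(
                banded_frechet(
                    list(zip(times, xv)), list(zip(times, yv)), band, ds.design, spacer
                )
            )
        else:
            scores.append(pointwise_distance(xv, yv, measure))
    if not scores:
        raise InsufficientOverlapError(
            f"no subject shares >= {MIN_SHARED_POINTS} observed points for "
            f"{ref!r} vs {cand!r}"
        )
    return float(np.mean(scores)), len(scores)


@dataclass
class SimilarityResult:
    """Ranked similarity of candidates to a reference metabolite."""

    reference: str
    measure: str
    mode: str
    rows: list[tuple[str, float | None, int]]  # (uid, score, n_subjects_used)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "uid": uid,
                    "score": score,
                    "measure": self.measure,
                    "mode": self.mode,
                    "n_subjects_used": n,
                }
                for i, (uid, score, n) in enumerate(self.rows)
            ]
        )

    def rank_of(self, uid: str) -> int:
        for i, (u, _, _) in enumerate(self.rows):
            if u == uid:
                return i + 1
        raise LookupFailure(f"uid {uid!r} not in result")


def rank_similar(
    ds: ProfileDataset,
    ref: str,
    candidates=None,
    measure: str = "frechet",
    mode: str = "mean_trajectory",
    subjects=None,
    tp_range: tuple[int, int] | None = None,
    band: BandPolicy | None = None,
    spacer: float = DEFAULT_BLOCK_SPACER_MIN,
) -> SimilarityResult:
    """Rank candidate metabolites by similarity to the reference.

    Distances sort ascending, Pearson descending; ties break on uid;
    candidates whose overlap rules fail get a null score at the end.
    """
    if ref not in set(ds.uids):
        raise LookupFailure(f"unknown reference uid {ref!r}")
    candidates = list(candidates) if candidates is not None else list(ds.uids)
    scored, failed = [], []
    for cand in candidates:
        try:
            score, n_used = trajectory_similarity(
                ds, ref, cand, measure, mode, subjects, tp_range, band, spacer
            )
        except InsufficientOverlapError:
            failed.append((cand, None, 0))
            continue
        if math.isnan(score):
            failed.append((cand, None, n_used))
        else:
            scored.append((cand, score, n_used))
    reverse = measure == "pearson"
    scored.sort(key=lambda r: ((-r[1] if reverse else r[1]), r[0]))
    failed.sort(key=lambda r: r[0])
    return SimilarityResult(ref, measure, mode, scored + failed)
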