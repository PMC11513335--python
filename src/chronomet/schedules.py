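"""Built-in study designs.

``humet56`` approximates the two-block, four-day human challenge study that
this toolkit targets: 56 plasma time points (16 of them with urine), sampled
at variable intervals (15 min - 4 h), with extended fasting, three liquid-meal
drinks, an oral glucose and an oral lipid tolerance test, a 30-min exercise
bout and a cold-stress test.  The exact published sampling table is not
reproduced here; the layout below matches the published challenge periods
(fasting tested 12-36 h, OGTT 0-2 h, SLD2 0-3 h, PAT 0-30 min, OLTT 0-4 h,
stress 0-30 min) on an approximate clock grid and is intended as a realistic
default, not a replica.  All algorithms are schedule-agnostic: any
user-supplied design JSON is accepted.
"""

from __future__ import annotations

from .errors import LookupFailure
from .study import ChallengeWindow, StudyDesign, TimePoint

_HOUR = 60.0

# (index, block, day, clock_min) — block clocks restart at 0 (8 a.m. of the
# block's first sampling day); day-2/day-4 clocks continue past 1440.
_HUMET56_TPS = (
    # block 1, day 1: extended fasting, 2-h sampling 8 a.m. - 10 p.m.
    [(i + 1, 1, 1, 120.0 * i) for i in range(8)]
    # block 1, day 2: late fasting (4 a.m., 6 a.m., 8 a.m.), then SLDR
    # breakfast drink and SLD1 lunch drink with dense postprandial sampling
    + [
        (9, 1, 2, 1200.0),
        (10, 1, 2, 1320.0),
        (11, 1, 2, 1440.0),   # 36 h of fasting; SLDR ingested after this draw
        (12, 1, 2, 1455.0),
        (13, 1, 2, 1470.0),
        (14, 1, 2, 1485.0),
        (15, 1, 2, 1500.0),
        (16, 1, 2, 1530.0),
        (17, 1, 2, 1560.0),
        (18, 1, 2, 1620.0),
        (19, 1, 2, 1680.0),   # noon; SLD1 ingested after this draw
        (20, 1, 2, 1695.0),
        (21, 1, 2, 1710.0),
        (22, 1, 2, 1725.0),
        (23, 1, 2, 1740.0),
        (24, 1, 2, 1770.0),
        (25, 1, 2, 1800.0),
        (26, 1, 2, 1860.0),
        (27, 1, 2, 1920.0),
        (28, 1, 2, 2040.0),
    ]
    # block 2, day 3: OGTT at 8 a.m., SLD2 at noon, exercise at 4:30 p.m.
    + [
        (29, 2, 3, 0.0),      # OGTT baseline
        (30, 2, 3, 15.0),
        (31, 2, 3, 30.0),
        (32, 2, 3, 45.0),
        (33, 2, 3, 60.0),
        (34, 2, 3, 90.0),
        (35, 2, 3, 120.0),
        (36, 2, 3, 180.0),
        (37, 2, 3, 240.0),    # SLD2 baseline
        (38, 2, 3, 255.0),
        (39, 2, 3, 270.0),
        (40, 2, 3, 300.0),
        (41, 2, 3, 330.0),
        (42, 2, 3, 360.0),
        (43, 2, 3, 420.0),
        (44, 2, 3, 510.0),    # PAT baseline
        (45, 2, 3, 525.0),
        (46, 2, 3, 540.0),
    ]
    # block 2, day 4: OLTT at 8 a.m., cold stress at 2 p.m.
    + [
        (47, 2, 4, 1440.0),   # OLTT baseline
        (48, 2, 4, 1470.0),
        (49, 2, 4, 1500.0),
        (50, 2, 4, 1530.0),
        (51, 2, 4, 1560.0),
        (52, 2, 4, 1620.0),
        (53, 2, 4, 1680.0),
        (54, 2, 4, 1800.0),   # stress baseline
        (55, 2, 4, 1815.0),
        (56, 2, 4, 1830.0),
    ]
)

_HUMET56_URINE = {1, 5, 8, 9, 11, 15, 19, 26, 29, 33, 35, 37, 43, 47, 53, 54}

_HUMET56_CHALLENGES = [
    # fasting started at dinner the evening before sampling (13 h earlier);
    # the tested period covers fasting hours 12-36
    ChallengeWindow("FASTING", 1, tuple(range(2, 12)), -780.0, "12-36 h"),
    ChallengeWindow("SLDR", 11, tuple(range(12, 20)), 1440.0, "0-4 h"),
    ChallengeWindow("SLD1", 19, tuple(range(20, 27)), 1680.0, "0-3 h"),
    ChallengeWindow("OGTT", 29, tuple(range(30, 36)), 0.0, "0-2 h"),
    ChallengeWindow("SLD2", 37, tuple(range(38, 44)), 240.0, "0-3 h"),
    ChallengeWindow("PAT", 44, (45, 46), 510.0, "0-30 min"),
    ChallengeWindow("OLTT", 47, tuple(range(48, 54)), 1440.0, "0-4 h"),
    ChallengeWindow("STRESS", 54, (55, 56), 1800.0, "0-30 min"),
]


def _humet56(subjects: list[int]) -> StudyDesign:
    tps = [
        TimePoint(
            index=i,
            block=b,
            day=d,
            clock_min=c,
            fluids_sampled=frozenset({"P", "U"} if i in _HUMET56_URINE else {"P"}),
        )
        for i, b, d, c in _HUMET56_TPS
    ]
    return StudyDesign(tps, list(_HUMET56_CHALLENGES), subjects)


def _uniform(subjects: list[int], spacing: float, n: int, n_blocks: int) -> StudyDesign:
    per_block = n // n_blocks
    tps, challenges = [], []
    idx = 0
    for block in range(1, n_blocks + 1):
        count = per_block if block < n_blocks else n - per_block * (n_blocks - 1)
        first = idx + 1
        for k in range(count):
            idx += 1
            tps.append(
                TimePoint(
                    index=idx,
                    block=block,
                    day=block,
                    clock_min=spacing * k,
                    fluids_sampled=frozenset({"P"}),
                )
            )
        if count >= 2:
            name = "OGTT" if block == 1 else "OLTT"
            challenges.append(
                ChallengeWindow(
                    name, first, tuple(range(first + 1, idx + 1)), 0.0, "synthetic"
                )
            )
    return StudyDesign(tps, challenges, subjects)


def build_schedule(
    name: str,
    subjects: list[int] | None = None,
    spacing: float = 60.0,
    n: int = 16,
    n_blocks: int = 1,
) -> StudyDesign:
    """Return a built-in study design.

    ``humet56``: the approximate 56-time-point, two-block challenge design.
    ``uniform``: a regular grid (``spacing`` minutes, ``n`` points over
    ``n_blocks`` blocks) with one synthetic challenge per block, whose
    baseline is the block's first time point.
    """
    subjects = list(subjects) if subjects is not None else list(range(1, 16))
    if name == "humet56":
        return _humet56(subjects)
    if name == "uniform":
        return _uniform(subjects, spacing, n, n_blocks)
    raise LookupFailure(f"unknown schedule {name!r}")
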