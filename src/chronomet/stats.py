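"""Paired challenge-response testing, effect sizes and power.

Each scan compares metabolite levels at tested time points of one challenge
against the challenge baseline with two-sided paired t-tests on log2 values.
Multiple-testing control is reactive: the Bonferroni threshold is
0.05 / (metabolites x time points actually submitted), and the
Benjamini-Hochberg adjustment runs over the non-null p values of the same
scan.  The power module inverts the noncentral-t power function of the
paired design for the required sample size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .errors import ConfigError, DomainError, NumericError
from .study import ProfileDataset, StudyDesign

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChallengeTestResult:
    uid: str
    challenge: str
    tp: int
    n_pairs: int
    log2fc: float | None
    t_stat: float | None
    p: float | None
    p_bonf_threshold: float
    q_bh: float | None
    significant_bonf: bool
    significant_fdr: bool

    @property
    def is_null(self) -> bool:
        return self.p is None


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise DomainError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def paired_t_scan(
    ds: ProfileDataset,
    challenge: str,
    tps: str | int = "all",
    design: StudyDesign | None = None,
    alpha: float = 0.05,
) -> list[ChallengeTestResult]:
    """Paired t-tests of every metabolite at tested time points vs baseline.

    ``tps`` is ``"all"`` (every tested time point of the challenge window) or
    a single time point index.  Pairs with fewer than 3 subjects observed at
    both time points, or zero-variance differences, yield null statistics.
    """
    if ds.transform_tag not in ("log2",):
        raise DomainError("paired_t_scan expects log2-transformed data")
    design = design or ds.design
    ch = design.challenge(challenge)
    if ch.baseline_tp not in set(design.tp_indices):
        raise ConfigError(f"baseline tp {ch.baseline_tp} not in design")
    tested = list(ch.tested_tps) if tps == "all" else [int(tps)]
    unknown = [t for t in tested if t not in set(ch.tested_tps)]
    if unknown:
        raise ConfigError(f"tp(s) {unknown} are not in the {ch.name} tested window")

    n_tests = len(ds.uids) * len(tested)
    bonf = alpha / n_tests
    base = ds.values.xs(ch.baseline_tp, level="tp")

    raw: list[dict] = []
    for tp in tested:
        cur = ds.values.xs(tp, level="tp")
        for uid in ds.uids:
            d = (cur[uid] - base[uid]).dropna()
            row = {"uid": uid, "tp": tp, "n_pairs": int(d.size)}
            if d.size < 3 or float(d.std(ddof=1)) == 0.0:
                if d.size >= 3:
                    log.warning(
                        "paired_t_scan: zero-variance differences for %s at tp %d", uid, tp
                    )
                row.update(log2fc=None, t=None, p=None)
            else:
                t, p = sps.ttest_rel(cur[uid].loc[d.index], base[uid].loc[d.index])
                row.update(log2fc=float(d.mean()), t=float(t), p=float(p))
            raw.append(row)

    non_null = [r for r in raw if r["p"] is not None]
    q = adjust_bh([r["p"] for r in non_null])
    for r, qv in zip(non_null, q):
        r["q"] = float(qv)

    results = []
    for r in raw:
        null = r["p"] is None
        results.append(
            ChallengeTestResult(
                uid=r["uid"],
                challenge=ch.name,
                tp=r["tp"],
                n_pairs=r["n_pairs"],
                log2fc=r.get("log2fc"),
                t_stat=r.get("t"),
                p=r.get("p"),
                p_bonf_threshold=bonf,
                q_bh=r.get("q"),
                significant_bonf=(not null) and r["p"] < bonf,
                significant_fdr=(not null) and r["q"] < alpha,
            )
        )
    return results


def scan_to_frame(results: list[ChallengeTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "uid": r.uid,
                "challenge": r.challenge,
                "tp": r.tp,
                "n_pairs": r.n_pairs,
                "log2fc": r.log2fc,
                "t_stat": r.t_stat,
                "p": r.p,
                "q_bh": r.q_bh,
                "p_bonf_threshold": r.p_bonf_threshold,
                "significant_bonf": r.significant_bonf,
                "significant_fdr": r.significant_fdr,
            }
            for r in results
        ]
    )


def volcano_frame(results: list[ChallengeTestResult]) -> pd.DataFrame:
    """(log2fc, −log10 p) rows for the non-null scan results."""
    rows = [
        {
            "uid": r.uid,
            "challenge": r.challenge,
            "tp": r.tp,
            "log2fc": r.log2fc,
            "neg_log10_p": -math.log10(r.p) if r.p > 0 else math.inf,
            "significant_bonf": r.significant_bonf,
            "significant_fdr": r.significant_fdr,
        }
        for r in results
        if not r.is_null
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EffectSize:
    """Paired Cohen's d with the small-sample (Hedges) correction."""

    d: float
    d_corrected: float
    n_subjects: int


def hedges_d(diffs) -> EffectSize:
    """Paired Cohen's d = mean/SD of the differences; corrected by (n−2)/(n−1.25)."""
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 3:
        raise DomainError("hedges_d needs at least 3 paired differences")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DomainError("hedges_d undefined for zero-variance differences")
    cohen = float(d.mean()) / sd
    return EffectSize(d=cohen, d_corrected=cohen * (n - 2) / (n - 1.25), n_subjects=n)


def paired_t_power(n: float, d: float, alpha: float, two_sided: bool = True) -> float:
    """Power of the paired t-test at (fractional) sample size n.

    Under the noncentral t with df = n−1 and ncp = d·sqrt(n); both rejection
    tails are counted for the two-sided test.
    """
    df = n - 1.0
    ncp = d * math.sqrt(n)
    if two_sided:
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        upper = float(sps.nct.sf(tcrit, df, ncp))
        lower = float(sps.nct.cdf(-tcrit, df, ncp))
        if math.isnan(lower):  # numerically negligible opposite tail
            lower = 0.0
        if math.isnan(upper):
            raise NumericError("noncentral-t power evaluation failed")
        return upper + lower
    tcrit = sps.t.ppf(1.0 - alpha, df)
    return float(sps.nct.sf(tcrit, df, ncp))


def solve_n_for_power(
    d_corrected: float,
    alpha: float,
    power: float = 0.8,
    two_sided: bool = True,
) -> tuple[float, int]:
    """Smallest real n ≥ 2 achieving the requested power; returns (n, ceil(n))."""
    if d_corrected == 0.0:
        raise DomainError("effect size must be nonzero")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise DomainError("alpha and power must be in (0, 1)")
    d = abs(d_corrected)

    def gap(n: float) -> float:
        return paired_t_power(n, d, alpha, two_sided) - power

    lo = 2.0
    if gap(lo) >= 0.0:
        return lo, 2
    hi = 4.0
    while gap(hi) < 0.0:
        hi *= 2.0
        if hi > 1e7:
            raise NumericError("power target unreachable below n = 1e7")
    n = float(optimize.brentq(gap, lo, hi, xtol=1e-4 / 10.0))
    return n, int(math.ceil(n - 1e-9))
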