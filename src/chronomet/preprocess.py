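"""Curation, transformation, filtering and imputation.

Implements the pipeline's data-hygiene rules: log2 transformation, the
4-SD outlier screen with its challenge-onset exemption, the <30%-missingness
metabolite filter, z-score / fold-change transforms, and two imputation
schemes (within-block linear interpolation, correlation-preselected KNN).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .study import ProfileDataset, StudyDesign

log = logging.getLogger(__name__)

EXEMPTION_WINDOW_MIN = 30.0


def log2_values(ds: ProfileDataset) -> ProfileDataset:
    """log2-transform a raw dataset."""
    arr = ds.values.to_numpy()
    bad = np.argwhere(np.isfinite(arr) & (arr <= 0))
    if bad.size:
        s, t = ds.values.index[bad[0, 0]]
        raise DomainError(
            f"non-positive value at (subject {s}, tp {t}, uid {ds.values.columns[bad[0, 1]]!r})"
        )
    return ds.with_values(np.log2(ds.values), "log2")


@dataclass
class OutlierReport:
    """Result of the 4-SD screen.

    ``flagged`` rows are (subject, tp, uid, log2 value, tp mean, SD used);
    ``exempted`` lists deviant points skipped because their time point falls
    within 30 min after a challenge onset; ``skipped_groups`` counts
    (tp, uid) groups with fewer than 3 values or zero spread.
    """

    flagged: list[tuple[int, int, str, float, float, float]] = field(default_factory=list)
    exempted: list[tuple[int, int, str]] = field(default_factory=list)
    skipped_groups: int = 0

    def flagged_keys(self) -> set[tuple[int, int, str]]:
        return {(s, t, u) for s, t, u, *_ in self.flagged}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.flagged,
            columns=["subject", "tp", "uid", "log2_value", "tp_mean", "sd"],
        )


def flag_outliers(
    ds: ProfileDataset,
    design: StudyDesign | None = None,
    n_sd: float = 4.0,
    sd_scope: str = "metabolite",
) -> OutlierReport:
    """Flag points outside mean ± ``n_sd``·SD for their metabolite and time point.

    The mean is always the cross-subject mean at the point's own time point.
    ``sd_scope`` picks the spread estimate: ``"metabolite"`` (default) pools
    the within-time-point variance over all of the metabolite's time points,
    which keeps the screen calibrated at small subject counts;
    ``"timepoint"`` uses the single-time-point SD literally.  With 15
    subjects the literal per-time-point rule is vacuous: one contaminated
    point among n inflates its own SD so much that |x − mean|/SD is bounded
    by (n−1)/√n < 4, so nothing can ever be flagged (see docs).

    Points whose time point lies within [onset, onset + 30 min] after any
    challenge onset of the same block are exempted, never flagged.  Groups
    with fewer than 3 non-missing values or zero SD are skipped.
    """
    if sd_scope not in ("metabolite", "timepoint"):
        raise ConfigError(f"unknown sd_scope {sd_scope!r}")
    if ds.transform_tag != "log2":
        raise DomainError("flag_outliers expects a log2-transformed dataset")
    design = design or ds.design

    exempt_tp: set[int] = set()
    for tp in design.timepoints:
        for onset in design.challenge_onsets_in_block(tp.block):
            if onset <= tp.clock_min <= onset + EXEMPTION_WINDOW_MIN:
                exempt_tp.add(tp.index)
                break

    report = OutlierReport()
    grouped = ds.values.groupby(level="tp")
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    counts = grouped.count()
    # pooled per-metabolite spread: rms of the per-time-point SDs over
    # groups where an SD is defined
    with np.errstate(invalid="ignore"):
        pooled = np.sqrt((sds**2).mean(axis=0))

    for uid in ds.uids:
        for tp_index in ds.design.tp_indices:
            n = counts.at[tp_index, uid]
            sd_tp = sds.at[tp_index, uid]
            if n < 3 or not sd_tp > 0:
                if n >= 1:
                    report.skipped_groups += 1
                continue
            sd = pooled[uid] if sd_scope == "metabolite" else sd_tp
            mean = means.at[tp_index, uid]
            col = ds.values[uid].xs(tp_index, level="tp")
            for subj, v in col.items():
                if pd.isna(v) or abs(v - mean) <= n_sd * sd:
                    continue
                if tp_index in exempt_tp:
                    report.exempted.append((subj, tp_index, uid))
                else:
                    report.flagged.append(
                        (subj, tp_index, uid, float(v), float(mean), float(sd))
                    )
    return report


def drop_flagged(ds: ProfileDataset, report: OutlierReport) -> ProfileDataset:
    """Remove every flagged entry (turn it into a missing value)."""
    vals = ds.values.copy()
    for subj, tp, uid, *_ in report.flagged:
        vals.at[(subj, tp), uid] = np.nan
    return ds.with_values(vals)


def filter_missingness(ds: ProfileDataset, max_missing_frac: float = 0.30) -> ProfileDataset:
    """Drop metabolites with >= ``max_missing_frac`` missingness.

    The denominator is the number of scheduled (subject, time point) samples
    of the metabolite's own fluid; metabolites strictly below the threshold
    are retained.
    """
    keep = []
    n_subjects = len(ds.design.subjects)
    for m in ds.catalog:
        scheduled = len(ds.design.tps_for_fluid(m.fluid)) * n_subjects
        if scheduled == 0:
            continue
        n_obs = int(ds.values[m.uid].notna().sum())
        if (scheduled - n_obs) / scheduled < max_missing_frac:
            keep.append(m.uid)
    return ds.subset(uids=keep) if keep else ds.subset(uids=[])


def transform(ds: ProfileDataset, mode: str, design: StudyDesign | None = None) -> ProfileDataset:
    """z-score or fold-change transform of a log2 dataset.

    ``zscore``: per metabolite over all non-missing entries (zero-variance
    metabolites become all-missing, with a warning).  ``log2fc_block``: per
    (subject, metabolite, block) relative to the subject's value at the
    block's first time point.  ``log2fc_challenge``: per (subject,
    metabolite, challenge) relative to the challenge baseline; entries whose
    reference value is missing become missing, and time points not covered
    by any challenge window are dropped.
    """
    if ds.transform_tag != "log2":
        raise DomainError("transform expects a log2-transformed dataset")
    design = design or ds.design
    vals = ds.values

    if mode == "zscore":
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        degenerate = ~(sd > 0)
        if degenerate.any():
            log.warning(
                "zscore: %d zero-variance metabolite(s) emitted as all-missing",
                int(degenerate.sum()),
            )
        out = (vals - mu) / sd.where(~degenerate)
        return ds.with_values(out, "zscore")

    if mode == "log2fc_block":
        out = vals.copy()
        for block in (1, 2):
            tps = [tp.index for tp in design.timepoints if tp.block == block]
            if not tps:
                continue
            first = tps[0]
            block_rows = vals.index.get_level_values("tp").isin(tps)
            ref = vals.xs(first, level="tp")  # indexed by subject
            ref_aligned = ref.reindex(vals.index.get_level_values("subject")).to_numpy()
            out[block_rows] = (vals - ref_aligned)[block_rows]
        return ds.with_values(out, "log2fc_block")

    if mode == "log2fc_challenge":
        out = pd.DataFrame(np.nan, index=vals.index, columns=vals.columns)
        for ch in design.challenges:
            ref = vals.xs(ch.baseline_tp, level="tp")
            ref_aligned = ref.reindex(vals.index.get_level_values("subject")).to_numpy()
            rows = vals.index.get_level_values("tp").isin((ch.baseline_tp, *ch.tested_tps))
            fc = vals - ref_aligned
            out[rows] = fc[rows]
        return ds.with_values(out, "log2fc_challenge")

    raise ConfigError(f"unknown transform mode {mode!r}")


def impute_linear(ds: ProfileDataset, design: StudyDesign | None = None) -> ProfileDataset:
    """Within-block linear interpolation against clock time, per subject.

    Only gaps with an observed point on both sides within the same block are
    filled; leading/trailing missing entries stay missing.
    """
    design = design or ds.design
    vals = ds.values.copy()
    for block in (1, 2):
        tps = [tp.index for tp in design.timepoints if tp.block == block]
        if len(tps) < 2:
            continue
        clocks = np.array([design.tp(t).clock_min for t in tps])
        for subj in design.subjects:
            rows = [(subj, t) for t in tps]
            block_vals = vals.loc[rows]
            for uid in ds.uids:
                y = block_vals[uid].to_numpy(dtype=float)
                miss = np.isnan(y)
                if not miss.any() or miss.all():
                    continue
                obs = ~miss
                inner = miss & (np.cumsum(obs) > 0) & (np.cumsum(obs[::-1])[::-1] > 0)
                if not inner.any():
                    continue
                y[inner] = np.interp(clocks[inner], clocks[obs], y[obs])
                for t, filled, v in zip(tps, inner, y):
                    if filled:
                        vals.at[(subj, t), uid] = v
    return ds.with_values(vals)


def impute_knn(ds: ProfileDataset, k: int = 10, n_preselect: int = 20) -> ProfileDataset:
    """Correlation-preselected K-nearest-neighbour imputation.

    For each missing (sample, target) entry: rank the other metabolites of
    the same fluid+platform by absolute Pearson correlation with the target
    over complete pairs (at least 10 required), keep the top ``n_preselect``,
    and measure sample-to-sample Euclidean distance over the z-scored
    preselected metabolites restricted to coordinates observed in both
    samples, scaled by the square root of the shared-coordinate count so
    unequal overlaps stay comparable.  The imputed value is the unweighted
    mean of the target's values in the ``k`` nearest samples in which the
    target is observed (all of them if fewer than ``k``; the target's overall
    mean if none).
    """
    vals = ds.values
    zs = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
    out = vals.copy()
    by_group: dict[tuple[str, str], list[str]] = {}
    for m in ds.catalog:
        by_group.setdefault((m.fluid, m.platform), []).append(m.uid)

    for (_fluid, _platform), group_uids in by_group.items():
        sub = vals[group_uids]
        if sub.isna().to_numpy().sum() == 0:
            continue
        corr = sub.corr(min_periods=10)
        zsub = zs[group_uids]
        z_arr = zsub.to_numpy()
        obs_mask = ~np.isnan(z_arr)
        index = list(sub.index)
        col_pos = {u: i for i, u in enumerate(group_uids)}
        for uid in group_uids:
            target = sub[uid]
            missing_rows = np.where(target.isna().to_numpy())[0]
            if missing_rows.size == 0:
                continue
            observed_rows = np.where(target.notna().to_numpy())[0]
            target_vals = target.to_numpy()
            overall_mean = float(np.nanmean(target_vals)) if observed_rows.size else math.nan
            ranked = corr[uid].drop(index=uid).abs().dropna().sort_values(
                ascending=False, kind="stable"
            )
            pres = [col_pos[u] for u in ranked.index[:n_preselect]]
            for qi in missing_rows:
                if not pres or observed_rows.size == 0:
                    if math.isnan(overall_mean):
                        log.warning("impute_knn: no data at all for %s; left missing", uid)
                    else:
                        out.iloc[qi, out.columns.get_loc(uid)] = overall_mean
                    continue
                q = z_arr[qi, pres]
                cand = z_arr[observed_rows][:, pres]
                shared = ~np.isnan(q)[None, :] & ~np.isnan(cand)
                diff = np.where(shared, (cand - q[None, :]) ** 2, 0.0)
                n_shared = shared.sum(axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    dist = np.sqrt(diff.sum(axis=1)) / np.sqrt(n_shared)
                dist[n_shared == 0] = np.inf
                usable = np.isfinite(dist)
                if not usable.any():
                    out.iloc[qi, out.columns.get_loc(uid)] = overall_mean
                    continue
                order = np.argsort(dist[usable], kind="stable")
                chosen = observed_rows[usable][order[:k]]
                out.iloc[qi, out.columns.get_loc(uid)] = float(
                    np.mean(target_vals[chosen])
                )
    return ds.with_values(out)
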